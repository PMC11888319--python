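"""TaqI-3C quantification: formula oracles, invariances, round trips."""

import numpy as np
import pytest

from hsrpipe import synth, threec
from hsrpipe.threec import (
    DigestionAssay,
    InteractionResult,
    ThreeCAssay,
    ThreeCError,
    digestion_efficiency,
    fold_change_interaction,
    fold_over_reference,
    ligation_dependent_signal,
    normalized_interaction_frequency,
)


@pytest.mark.parametrize(
    "do_r, do_ars, und_r, und_ars, expected",
    [
        (28.0, 20.0, 25.0, 20.0, 0.875),        # 1 - 2**-3
        (25.0, 20.0, 25.0, 20.0, 0.0),          # no digestion
        (30.0, 20.0, 20.0, 20.0, 1.0 - 2.0 ** -10),
    ],
)
def test_digestion_efficiency_formula(do_r, do_ars, und_r, und_ars, expected):
    assay = DigestionAssay(ct_r_do=do_r, ct_ars_do=do_ars,
                           ct_r_und=und_r, ct_ars_und=und_ars)
    assert digestion_efficiency(assay) == pytest.approx(expected, abs=1e-12)


def test_digestion_efficiency_rejects_negative_ddct():
    # digested template looks a full cycle MORE abundant than undigested
    assay = DigestionAssay(ct_r_do=24.0, ct_ars_do=20.0,
                           ct_r_und=25.0, ct_ars_und=20.0)
    with pytest.raises(ThreeCError, match="more abundant"):
        digestion_efficiency(assay)


@pytest.mark.parametrize(
    "target, reference, expected",
    [(26.0, 24.0, 0.25), (24.0, 24.0, 1.0), (20.0, 26.0, 64.0)],
)
def test_fold_over_reference(target, reference, expected):
    assert fold_over_reference(target, reference, 40.0) == pytest.approx(expected)


def test_fold_over_reference_warns_below_detection():
    with pytest.warns(UserWarning, match="below detection"):
        fold_over_reference(41.0, 24.0, 40.0)


@pytest.mark.parametrize(
    "lig, do, expected",
    [(0.25, 0.015625, 16.0), (0.3, 0.3, 1.0), (0.1, 0.4, 0.25)],
)
def test_ligation_dependent_signal(lig, do, expected):
    assert ligation_dependent_signal(lig, do) == pytest.approx(expected)


def test_lds_zero_denominator():
    with pytest.raises(ThreeCError):
        ligation_dependent_signal(0.25, 0.0)


def _assay(ct_lig_3c=22.0, ct_do_3c=26.0, ct_lig_gdna=20.0 - np.log2(0.78125),
           ct_do_gdna=26.0, ars=20.0, ntc=40.0, e1=0.8, e2=0.8,
           e1g=1.0, e2g=1.0):
    return ThreeCAssay(
        ct_lig_3c=ct_lig_3c, ct_do_3c=ct_do_3c,
        ct_lig_gdna=ct_lig_gdna, ct_do_gdna=ct_do_gdna,
        ct_ars={"Lig3C": ars, "DO3C": ars, "LiggDNA": ars, "DOgDNA": ars},
        ct_ntc=ntc, eff_site1=e1, eff_site2=e2,
        eff_site1_gdna=e1g, eff_site2_gdna=e2g,
    )


def test_normalized_frequency_worked_example():
    # LDS_3C = 16 with efficiencies 0.8 * 0.8, LDS_gDNA = 50 uncorrected
    freq, flags = normalized_interaction_frequency(_assay())
    assert freq == pytest.approx(0.5, abs=1e-12)
    assert flags == []


def test_normalized_frequency_identity():
    # equal LDS on both branches and equal efficiencies cancel to 1
    assay = _assay(ct_lig_3c=22.0, ct_lig_gdna=22.0, e1g=0.8, e2g=0.8)
    freq, _ = normalized_interaction_frequency(assay)
    assert freq == pytest.approx(1.0, abs=1e-12)


def test_unreliable_digestion_raises():
    with pytest.raises(ThreeCError, match="reliability floor"):
        normalized_interaction_frequency(_assay(e1=0.05))
    with pytest.raises(ThreeCError, match="not positive"):
        normalized_interaction_frequency(_assay(e1=0.0))


def test_low_digestion_flagged_not_fatal():
    freq, flags = normalized_interaction_frequency(_assay(e1=0.3))
    assert any(f.startswith("low_digestion") for f in flags)
    assert freq > 0


def test_reference_shift_invariance(rng):
    """Adding a constant to every Ct of one template (junction, reference
    and NTC together) leaves the frequency unchanged."""
    base = _assay()
    freq0, _ = normalized_interaction_frequency(base)
    for shift in rng.normal(0.0, 3.0, 25):
        ars = dict(base.ct_ars)
        ars["Lig3C"] += shift
        shifted = ThreeCAssay(
            ct_lig_3c=base.ct_lig_3c + shift, ct_do_3c=base.ct_do_3c,
            ct_lig_gdna=base.ct_lig_gdna, ct_do_gdna=base.ct_do_gdna,
            ct_ars=ars, ct_ntc=base.ct_ntc + shift,
            eff_site1=base.eff_site1, eff_site2=base.eff_site2,
            eff_site1_gdna=base.eff_site1_gdna, eff_site2_gdna=base.eff_site2_gdna,
        )
        freq, _ = normalized_interaction_frequency(shifted)
        assert freq == pytest.approx(freq0, rel=1e-12)


def test_ntc_cancellation(rng):
    base = _assay()
    freq0, _ = normalized_interaction_frequency(base)
    for ntc in rng.uniform(35.0, 45.0, 10):
        freq, _ = normalized_interaction_frequency(_assay(ntc=float(ntc)))
        assert freq == pytest.approx(freq0, rel=1e-12)


def test_frequency_monotone_in_ligated_ct():
    freqs = [normalized_interaction_frequency(_assay(ct_lig_3c=ct))[0]
             for ct in (24.0, 23.0, 22.0, 21.0)]
    assert all(a < b for a, b in zip(freqs, freqs[1:]))


@pytest.mark.parametrize("hs, nhs, expected",
                         [(0.8, 0.2, 4.0), (0.3, 0.3, 1.0), (0.1, 0.4, 0.25)])
def test_fold_change_interaction(hs, nhs, expected):
    a = InteractionResult.from_replicates("p", [hs])
    b = InteractionResult.from_replicates("p", [nhs])
    assert fold_change_interaction(a, b) == pytest.approx(expected)


def test_fold_change_zero_reference_is_infinite():
    a = InteractionResult.from_replicates("p", [0.8])
    b = InteractionResult.from_replicates("p", [0.0])
    assert fold_change_interaction(a, b) == float("inf")


def test_fold_change_mismatched_pairs():
    a = InteractionResult.from_replicates("p", [0.8])
    b = InteractionResult.from_replicates("q", [0.2])
    with pytest.raises(ThreeCError):
        fold_change_interaction(a, b)


def test_roundtrip_noiseless_random_truths(rng):
    """Pipeline frequency equals generator truth to 1e-9 relative for
    random frequencies and digestion efficiencies."""
    for i in range(25):
        f = float(rng.uniform(0.01, 10.0))
        e1, e2 = (float(v) for v in rng.uniform(0.5, 1.0, 2))
        table = synth.gen_3c_ct_table(
            synth.QpcrTruth(noise_sd=0.0, seed=i),
            {"pairA": f}, {"site1": e1, "site2": e2})
        results, _ = threec.quantify_ct_table(table)
        assert results["mean"].iloc[0] == pytest.approx(f, rel=1e-9)
        assert results["sd"].iloc[0] == pytest.approx(0.0, abs=1e-9)


def test_roundtrip_full_digestion_exact():
    table = synth.gen_3c_ct_table(
        synth.QpcrTruth(noise_sd=0.0, seed=0),
        {"pairA": 1.0}, {"site1": 1.0, "site2": 1.0})
    results, _ = threec.quantify_ct_table(table)
    assert results["mean"].iloc[0] == pytest.approx(1.0, rel=1e-9)


def test_gdna_branch_efficiency_modes():
    """With distinct gDNA digestion efficiencies the 'measured' mode
    recovers truth; the 'chromatin' fallback is biased by exactly the
    efficiency mismatch."""
    f, e1, e2, eg1, eg2 = 0.5, 0.8, 0.9, 0.95, 0.85
    table = synth.gen_3c_ct_table(
        synth.QpcrTruth(noise_sd=0.0, seed=1),
        {"pairA": f}, {"site1": e1, "site2": e2},
        gdna_digestion_effs={"site1": eg1, "site2": eg2})
    measured, _ = threec.quantify_ct_table(table, gdna_efficiencies="measured")
    assert measured["mean"].iloc[0] == pytest.approx(f, rel=1e-9)
    chromatin, _ = threec.quantify_ct_table(table, gdna_efficiencies="chromatin")
    assert chromatin["mean"].iloc[0] == pytest.approx(
        f * (e1 * e2) / (eg1 * eg2), rel=1e-9)


def test_quantify_reports_measured_efficiencies():
    table = synth.gen_3c_ct_table(
        synth.QpcrTruth(noise_sd=0.0, seed=2),
        {"pairA": 2.0}, {"site1": 0.75, "site2": 0.6})
    _, qc = threec.quantify_ct_table(table)
    chromatin = {r["site"]: r["efficiency"]
                 for r in qc["digestion_efficiencies"]
                 if r["branch"] == "chromatin"}
    assert chromatin["site1"] == pytest.approx(0.75, rel=1e-9)
    assert chromatin["site2"] == pytest.approx(0.6, rel=1e-9)
    assert any("low_digestion" in w for w in qc["warnings"]) is False
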