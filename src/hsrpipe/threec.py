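"""TaqI-3C interaction-frequency quantification from qPCR cycle thresholds.

Quantitative chromosome conformation capture (TaqI-3C) reads out the abundance
of a proximity-ligation junction by qPCR.  Four templates are assayed with the
same junction-spanning primer pair:

* ``Lig3C``   -- crosslinked chromatin, TaqI digested and ligated
* ``DO3C``    -- crosslinked chromatin, digested only (no ligase)
* ``LiggDNA`` -- purified genomic DNA, digested and ligated (random-collision
  control with every junction at copy-number parity)
* ``DOgDNA``  -- purified genomic DNA, digested only

Every template also carries a reference amplicon at a TaqI-free locus
(ARS504), which absorbs differences in template recovery.  The normalized
frequency of interaction is

    F = [LDS_3C / (e1 * e2)] / [LDS_gDNA / (e1g * e2g)]

where LDS (ligation-dependent signal) is the ratio of reference-normalized
fold signals of the ligated and digested-only templates, and ``e1, e2`` are
the TaqI digestion efficiencies of the two restriction sites flanking the
junction, measured per branch (chromatin / gDNA) with a site-spanning
amplicon on digested-only versus undigested template.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DigestionAssay",
    "ThreeCAssay",
    "InteractionResult",
    "ThreeCError",
    "digestion_efficiency",
    "fold_over_reference",
    "ligation_dependent_signal",
    "normalized_interaction_frequency",
    "fold_change_interaction",
    "quantify_ct_table",
]

#: template classes carrying junction amplicons
JUNCTION_TEMPLATES = ("Lig3C", "DO3C", "LiggDNA", "DOgDNA")
#: template classes used for digestion-efficiency checks, keyed by branch
DIGESTION_TEMPLATES = {
    "chromatin": ("DO3C", "UND3C"),
    "gdna": ("DOgDNA", "UNDgDNA"),
}
REFERENCE_LOCUS = "ARS504"

# A digested-only template may not look *more* abundant than undigested by
# more than this many cycles before we call the assay broken.
DDCT_TOLERANCE = 0.5
EFFICIENCY_ERROR_FLOOR = 0.10
EFFICIENCY_WARN_FLOOR = 0.50


class ThreeCError(ValueError):
    """Raised for invalid or data-quality-failing 3C inputs."""


@dataclass(frozen=True)
class DigestionAssay:
    """Ct quartet for one TaqI site: site-spanning amplicon (R) and the
    ARS504 reference on digested-only (DO) and undigested (UND) template."""

    ct_r_do: float
    ct_ars_do: float
    ct_r_und: float
    ct_ars_und: float

    def __post_init__(self) -> None:
        for name in ("ct_r_do", "ct_ars_do", "ct_r_und", "ct_ars_und"):
            if not math.isfinite(getattr(self, name)):
                raise ThreeCError(f"{name} must be finite")


@dataclass(frozen=True)
class ThreeCAssay:
    """Per-junction Ct values (technical replicates already averaged) plus
    the digestion efficiencies of the two flanking TaqI sites."""

    ct_lig_3c: float
    ct_do_3c: float
    ct_lig_gdna: float
    ct_do_gdna: float
    ct_ars: dict  # template class -> reference Ct on that template
    ct_ntc: float
    eff_site1: float
    eff_site2: float
    eff_site1_gdna: float | None = None  # default: chromatin values
    eff_site2_gdna: float | None = None


@dataclass
class InteractionResult:
    """Normalized interaction frequency for one locus pair, summarized over
    biological replicates (mean +/- SD)."""

    locus_pair: str
    frequency: float
    per_bio_rep: list = field(default_factory=list)
    mean: float = float("nan")
    sd: float = float("nan")
    kind: str = "intergenic"
    flags: list = field(default_factory=list)

    @classmethod
    def from_replicates(cls, locus_pair, per_bio_rep, kind="intergenic", flags=()):
        reps = [float(v) for v in per_bio_rep]
        mean = float(np.mean(reps))
        sd = float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0
        return cls(locus_pair=locus_pair, frequency=mean, per_bio_rep=reps,
                   mean=mean, sd=sd, kind=kind, flags=list(flags))


def digestion_efficiency(assay: DigestionAssay) -> float:
    """Fraction of template cut at one TaqI site.

    efficiency = 1 - 2**-ddCt with
    ddCt = (CtR - CtARS504)_DO - (CtR - CtARS504)_UND.

    An uncut site amplifies equally well on both templates (ddCt = 0,
    efficiency 0); a fully cut site loses its DO amplicon (ddCt -> inf,
    efficiency -> 1).  100x the returned fraction is the percent digestion.
    """
    ddct = (assay.ct_r_do - assay.ct_ars_do) - (assay.ct_r_und - assay.ct_ars_und)
    if ddct < -DDCT_TOLERANCE:
        raise ThreeCError(
            f"digested-only template appears {-ddct:.2f} cycles more abundant "
            "than undigested; digestion assay unreliable"
        )
    return max(0.0, 1.0 - 2.0 ** (-ddct))


def fold_over_reference(ct_target: float, ct_reference: float, ct_ntc: float) -> float:
    """Fold signal of a target amplicon over the ARS504 reference.

    Computed as 2**-(ct_target - ct_ntc) / 2**-(ct_reference - ct_ntc); the
    no-template-control terms cancel algebraically (the value is
    2**(ct_reference - ct_target)) but the NTC is retained for a
    below-detection QC warning.
    """
    if ct_target >= ct_ntc:
        warnings.warn(
            f"target Ct {ct_target:.2f} at or beyond NTC Ct {ct_ntc:.2f}: "
            "signal below detection limit",
            stacklevel=2,
        )
    return 2.0 ** (ct_reference - ct_target)


def ligation_dependent_signal(fold_lig: float, fold_do: float) -> float:
    """Ratio of ligated to digested-only fold-over-reference signals (LDS)."""
    if fold_do == 0:
        raise ThreeCError("digested-only fold signal is zero; LDS undefined")
    if fold_lig < 0 or fold_do < 0:
        raise ThreeCError("fold signals must be positive")
    return fold_lig / fold_do


def _check_efficiency(eff: float, label: str, flags: list) -> None:
    if eff <= 0:
        raise ThreeCError(f"{label} digestion efficiency {eff} is not positive")
    if eff < EFFICIENCY_ERROR_FLOOR:
        raise ThreeCError(
            f"{label} digestion efficiency {eff:.3f} below reliability floor "
            f"{EFFICIENCY_ERROR_FLOOR}"
        )
    if eff < EFFICIENCY_WARN_FLOOR:
        flags.append(f"low_digestion:{label}:{eff:.3f}")


def normalized_interaction_frequency(assay: ThreeCAssay) -> tuple[float, list]:
    """Normalized frequency of interaction for one junction.

    Returns ``(frequency, flags)`` where flags collect data-quality warnings
    (below-detection Cts, low digestion efficiencies).
    """
    flags: list = []
    e1, e2 = assay.eff_site1, assay.eff_site2
    e1g = assay.eff_site1_gdna if assay.eff_site1_gdna is not None else e1
    e2g = assay.eff_site2_gdna if assay.eff_site2_gdna is not None else e2
    for eff, label in ((e1, "site1"), (e2, "site2"), (e1g, "site1_gdna"), (e2g, "site2_gdna")):
        _check_efficiency(eff, label, flags)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fold_lig_3c = fold_over_reference(assay.ct_lig_3c, assay.ct_ars["Lig3C"], assay.ct_ntc)
        fold_do_3c = fold_over_reference(assay.ct_do_3c, assay.ct_ars["DO3C"], assay.ct_ntc)
        fold_lig_g = fold_over_reference(assay.ct_lig_gdna, assay.ct_ars["LiggDNA"], assay.ct_ntc)
        fold_do_g = fold_over_reference(assay.ct_do_gdna, assay.ct_ars["DOgDNA"], assay.ct_ntc)
    flags.extend("below_detection" for _ in caught)

    lds_3c = ligation_dependent_signal(fold_lig_3c, fold_do_3c)
    lds_gdna = ligation_dependent_signal(fold_lig_g, fold_do_g)
    frequency = (lds_3c / (e1 * e2)) / (lds_gdna / (e1g * e2g))
    return frequency, flags


def fold_change_interaction(hs: InteractionResult, nhs: InteractionResult) -> float:
    """Heat-shock / non-heat-shock ratio of mean interaction frequencies."""
    if hs.locus_pair != nhs.locus_pair:
        raise ThreeCError(
            f"locus pairs differ: {hs.locus_pair!r} vs {nhs.locus_pair!r}"
        )
    if nhs.mean == 0:
        return float("inf")
    return hs.mean / nhs.mean


# ---------------------------------------------------------------------------
# table-level quantification
# ---------------------------------------------------------------------------

def _tech_mean(df: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates per (template, primer_pair, locus, bio_rep)."""
    keys = ["template_class", "primer_pair", "locus", "condition", "bio_rep"]
    return df.groupby(keys, as_index=False)["ct"].mean()


def measure_digestion_efficiencies(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Digestion efficiency per (branch, site, condition, bio_rep) from the
    DO/UND template rows of a Ct table."""
    sub = ct_table[ct_table["template_class"].isin(
        [t for pair in DIGESTION_TEMPLATES.values() for t in pair])]
    mean = _tech_mean(sub)
    rows = []
    for branch, (do_cls, und_cls) in DIGESTION_TEMPLATES.items():
        branch_df = mean[mean["template_class"].isin([do_cls, und_cls])]
        if branch_df.empty:
            continue
        sites = sorted(set(branch_df["locus"]) - {REFERENCE_LOCUS})
        for (condition, bio_rep), grp in branch_df.groupby(["condition", "bio_rep"]):
            idx = grp.set_index(["template_class", "locus"])["ct"]
            for site in sites:
                try:
                    assay = DigestionAssay(
                        ct_r_do=idx[(do_cls, site)],
                        ct_ars_do=idx[(do_cls, REFERENCE_LOCUS)],
                        ct_r_und=idx[(und_cls, site)],
                        ct_ars_und=idx[(und_cls, REFERENCE_LOCUS)],
                    )
                except KeyError:
                    continue
                rows.append({
                    "branch": branch, "site": site, "condition": condition,
                    "bio_rep": bio_rep,
                    "efficiency": digestion_efficiency(assay),
                })
    return pd.DataFrame(rows)


def quantify_ct_table(
    ct_table: pd.DataFrame,
    pair_sites: dict | None = None,
    pair_kinds: dict | None = None,
    gdna_efficiencies: str = "measured",
) -> tuple[pd.DataFrame, dict]:
    """Quantify every junction primer pair in a long-format Ct table.

    Parameters
    ----------
    ct_table
        Long-format table with columns sample_id, template_class,
        primer_pair, locus, condition, bio_rep, tech_rep, ct.
    pair_sites
        Mapping locus-pair id -> (site1, site2).  When omitted and exactly
        two digestion sites are present, every pair uses both.
    pair_kinds
        Optional mapping locus-pair id -> "intragenic" | "intergenic".
    gdna_efficiencies
        "measured": use gDNA-branch DO/UND rows for the gDNA correction;
        "chromatin": reuse the chromatin-branch efficiencies.

    Returns
    -------
    (results, qc) where results has one row per (locus pair, condition) with
    mean/SD over biological replicates, and qc lists digestion efficiencies
    and warning flags.
    """
    if gdna_efficiencies not in ("measured", "chromatin"):
        raise ThreeCError("gdna_efficiencies must be 'measured' or 'chromatin'")
    required = {"template_class", "primer_pair", "locus", "condition", "bio_rep", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ThreeCError(f"Ct table missing columns: {sorted(missing)}")

    effs = measure_digestion_efficiencies(ct_table)
    eff_lookup = {}
    if not effs.empty:
        eff_lookup = effs.set_index(
            ["branch", "site", "condition", "bio_rep"])["efficiency"].to_dict()

    junction = ct_table[ct_table["template_class"].isin(JUNCTION_TEMPLATES)]
    mean = _tech_mean(junction)
    ntc = ct_table[ct_table["template_class"] == "NTC"]
    ntc_lookup = (
        ntc.groupby(["primer_pair", "condition"])["ct"].mean().to_dict()
        if not ntc.empty else {}
    )

    # junction primer pairs are the ones with a ligated-chromatin amplicon;
    # digestion-site amplicons share the DO template classes but never Lig3C
    pairs = sorted(
        set(mean.loc[mean["template_class"] == "Lig3C", "primer_pair"])
        - {REFERENCE_LOCUS})
    all_sites = sorted(set(effs["site"])) if not effs.empty else []
    if pair_sites is None:
        if len(all_sites) == 2:
            pair_sites = {p: tuple(all_sites) for p in pairs}
        elif not all_sites:
            pair_sites = {}
        else:
            raise ThreeCError(
                "pair_sites mapping required when the table carries "
                f"{len(all_sites)} digestion sites"
            )

    results = []
    qc: dict = {
        "digestion_efficiencies": effs.to_dict(orient="records"),
        "warnings": [],
    }
    for pair in pairs:
        pair_df = mean[mean["primer_pair"] == pair]
        ars_df = mean[(mean["primer_pair"] == REFERENCE_LOCUS)]
        for condition, cond_df in pair_df.groupby("condition"):
            per_rep, flags = [], []
            for bio_rep, rep_df in cond_df.groupby("bio_rep"):
                ct_by_template = rep_df.set_index("template_class")["ct"]
                ars_rep = ars_df[(ars_df["condition"] == condition)
                                 & (ars_df["bio_rep"] == bio_rep)]
                ct_ars = ars_rep.set_index("template_class")["ct"].to_dict()
                site1, site2 = pair_sites.get(pair, (None, None))

                def _eff(branch, site, _c=condition, _b=bio_rep):
                    if site is None:
                        return 1.0
                    key = (branch, site, _c, _b)
                    if key in eff_lookup:
                        return eff_lookup[key]
                    if branch == "gdna":  # fall back to chromatin measurement
                        return eff_lookup.get(("chromatin", site, _c, _b), 1.0)
                    return 1.0

                gdna_branch = "measured" if gdna_efficiencies == "measured" else "chromatin"
                assay = ThreeCAssay(
                    ct_lig_3c=ct_by_template["Lig3C"],
                    ct_do_3c=ct_by_template["DO3C"],
                    ct_lig_gdna=ct_by_template["LiggDNA"],
                    ct_do_gdna=ct_by_template["DOgDNA"],
                    ct_ars=ct_ars,
                    ct_ntc=ntc_lookup.get((pair, condition), float("inf")),
                    eff_site1=_eff("chromatin", site1),
                    eff_site2=_eff("chromatin", site2),
                    eff_site1_gdna=_eff(
                        "gdna" if gdna_branch == "measured" else "chromatin", site1),
                    eff_site2_gdna=_eff(
                        "gdna" if gdna_branch == "measured" else "chromatin", site2),
                )
                freq, rep_flags = normalized_interaction_frequency(assay)
                per_rep.append(freq)
                flags.extend(f"{condition}/bio{bio_rep}:{f}" for f in rep_flags)
            kind = (pair_kinds or {}).get(pair, "intergenic")
            res = InteractionResult.from_replicates(
                pair, per_rep, kind=kind, flags=flags)
            results.append({
                "locus_pair": pair, "condition": condition, "kind": kind,
                "mean": res.mean, "sd": res.sd, "n_bio_reps": len(per_rep),
                **{f"bio_rep_{i + 1}": v for i, v in enumerate(per_rep)},
            })
            qc["warnings"].extend(flags)
    return pd.DataFrame(results), qc


def write_results(results: pd.DataFrame, qc: dict, out_tsv, qc_json=None) -> None:
    """Write the interaction table as TSV and the QC report as JSON."""
    results.to_csv(out_tsv, sep="\t", index=False)
    if qc_json is not None:
        with open(qc_json, "w") as fh:
            json.dump(qc, fh, indent=2, default=float)
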