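"""Synthetic-data generators with known ground truth.

Every input class the pipeline consumes can be generated here: qPCR Ct
tables for TaqI-3C and RT-qPCR built by inverting the quantification
formulas (so noiseless tables quantify back to truth exactly), expression
matrices with additive-in-log genotype effects plus an optional interaction
term, 3D fluorescence stacks with planted Gaussian foci, and logistic
growth curves.  All generators are deterministic under their seed.

The qPCR model is ideal doubling per cycle: a template present at relative
amount ``a`` crosses threshold at ``Ct = ct_ref - log2(a)``; Gaussian noise
(default SD 0.15 cycles, typical technical-replicate scatter) is added on
the Ct scale.  No-template controls sit at the instrument maximum
(default Ct 40).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.ndimage import gaussian_filter

from .threec import REFERENCE_LOCUS

__all__ = [
    "QpcrTruth",
    "GenotypeEffectSpec",
    "ImageTruth",
    "GrowthTruth",
    "gen_3c_ct_table",
    "gen_rtqpcr_ct_table",
    "gen_expression_matrix",
    "gen_image_stack",
    "gen_growth_curves",
    "sample_image_truth",
]

CT_COLUMNS = [
    "sample_id", "template_class", "primer_pair", "locus",
    "condition", "bio_rep", "tech_rep", "ct",
]


@dataclass(frozen=True)
class QpcrTruth:
    """qPCR instrument/noise model shared by the Ct-table generators.

    ct_ref is the cycle threshold of a template at relative amount 1.0;
    ntc_ct the no-template-control ceiling.  Replicate structure defaults to
    two biological and four technical replicates.
    """

    ct_ref: float = 20.0
    noise_sd: float = 0.15
    ntc_ct: float = 40.0
    n_tech_reps: int = 4
    n_bio_reps: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_tech_reps < 1 or self.n_bio_reps < 1:
            raise ValueError("replicate counts must be positive")
        if self.ntc_ct <= self.ct_ref:
            raise ValueError("ntc_ct must exceed ct_ref")


def _ct_from_amount(amount: float, truth: QpcrTruth) -> float:
    """Ideal-doubling Ct; amounts at/below detection floor clip to the NTC Ct."""
    floor = 2.0 ** (truth.ct_ref - truth.ntc_ct)
    if amount <= floor:
        return truth.ntc_ct
    return truth.ct_ref - math.log2(amount)


def _emit(rows, truth, rng, *, template_class, primer_pair, locus, condition,
          amount=None, ct=None):
    """Append one amplicon (all bio x tech replicates) to a Ct-table row list."""
    for bio in range(1, truth.n_bio_reps + 1):
        for tech in range(1, truth.n_tech_reps + 1):
            if ct is None:
                value = _ct_from_amount(amount, truth)
                if truth.noise_sd > 0:
                    value += rng.normal(0.0, truth.noise_sd)
            else:
                value = ct
            rows.append({
                "sample_id": f"{condition}_b{bio}",
                "template_class": template_class,
                "primer_pair": primer_pair,
                "locus": locus,
                "condition": condition,
                "bio_rep": bio,
                "tech_rep": tech,
                "ct": value,
            })


def gen_3c_ct_table(
    truth: QpcrTruth,
    interaction_freqs: dict,
    digestion_effs: dict,
    pair_sites: dict | None = None,
    gdna_digestion_effs: dict | None = None,
    condition: str = "HS",
    lds_gdna: float = 50.0,
    do_background: float = 0.01,
) -> pd.DataFrame:
    """Generate a TaqI-3C Ct table whose quantification recovers the given
    interaction frequencies.

    Relative template amounts are constructed by inverting the normalized
    frequency-of-interaction formula: per junction, the ligated-chromatin
    amount is set so that LDS_3C = F * (e1*e2) * LDS_gDNA / (e1g*e2g).
    Digestion-check amplicons (DO vs UND templates, both branches) are
    emitted so the quantifier can measure the efficiencies it corrects with.
    gDNA digestion efficiencies default to the chromatin values (the sites
    are the same sequence).

    Parameters mirror the quantification inputs; see
    :func:`hsrpipe.threec.quantify_ct_table`.
    """
    for pair, f in interaction_freqs.items():
        if f <= 0:
            raise ValueError(f"interaction frequency for {pair!r} must be positive")
    for site, e in digestion_effs.items():
        if not (0 < e <= 1):
            raise ValueError(f"digestion efficiency for {site!r} must be in (0, 1]")
    if gdna_digestion_effs is None:
        gdna_digestion_effs = dict(digestion_effs)
    for site, e in gdna_digestion_effs.items():
        if not (0 < e <= 1):
            raise ValueError(f"gDNA digestion efficiency for {site!r} must be in (0, 1]")
    sites = sorted(digestion_effs)
    if pair_sites is None:
        if len(sites) == 2:
            pair_sites = {p: tuple(sites) for p in interaction_freqs}
        elif len(sites) == 2 * len(interaction_freqs):
            raise ValueError("pair_sites mapping required for per-pair sites")
        else:
            raise ValueError(
                "pair_sites mapping required unless exactly two sites are given")

    rng = np.random.default_rng(truth.seed)
    rows: list = []

    # reference amplicon on every junction-bearing template
    for template in ("Lig3C", "DO3C", "LiggDNA", "DOgDNA"):
        _emit(rows, truth, rng, template_class=template,
              primer_pair=REFERENCE_LOCUS, locus=REFERENCE_LOCUS,
              condition=condition, amount=1.0)

    # junction amplicons
    for pair, freq in interaction_freqs.items():
        s1, s2 = pair_sites[pair]
        e3c = digestion_effs[s1] * digestion_effs[s2]
        eg = gdna_digestion_effs[s1] * gdna_digestion_effs[s2]
        lds_3c = freq * e3c * lds_gdna / eg
        amounts = {
            "Lig3C": lds_3c * do_background,
            "DO3C": do_background,
            "LiggDNA": lds_gdna * do_background,
            "DOgDNA": do_background,
        }
        for template, amount in amounts.items():
            _emit(rows, truth, rng, template_class=template, primer_pair=pair,
                  locus=pair, condition=condition, amount=amount)
        _emit(rows, truth, rng, template_class="NTC", primer_pair=pair,
              locus=pair, condition=condition, ct=truth.ntc_ct)

    # digestion-efficiency amplicons: DO amplifies the uncut fraction
    for branch, effs, (do_cls, und_cls) in (
        ("chromatin", digestion_effs, ("DO3C", "UND3C")),
        ("gdna", gdna_digestion_effs, ("DOgDNA", "UNDgDNA")),
    ):
        for site in sites:
            _emit(rows, truth, rng, template_class=do_cls, primer_pair=site,
                  locus=site, condition=condition, amount=1.0 - effs[site])
            _emit(rows, truth, rng, template_class=und_cls, primer_pair=site,
                  locus=site, condition=condition, amount=1.0)
        _emit(rows, truth, rng, template_class=und_cls,
              primer_pair=REFERENCE_LOCUS, locus=REFERENCE_LOCUS,
              condition=condition, amount=1.0)
    _emit(rows, truth, rng, template_class="NTC", primer_pair=REFERENCE_LOCUS,
          locus=REFERENCE_LOCUS, condition=condition, ct=truth.ntc_ct)

    return pd.DataFrame(rows, columns=CT_COLUMNS)


def gen_rtqpcr_ct_table(
    truth: QpcrTruth,
    rel_expression: dict,
    normalizer: str = "SCR1",
    conditions: tuple | None = None,
) -> pd.DataFrame:
    """Generate an RT-qPCR Ct table whose ddCt quantification recovers the
    given relative expression values.

    ``rel_expression`` maps gene -> {condition: relative amount}.  A
    normalizer amplicon (SCR1, a Pol III transcript whose level is
    condition-independent) is emitted for every condition.
    """
    if not rel_expression:
        raise ValueError("rel_expression must not be empty")
    if normalizer is None:
        raise ValueError("a normalizer transcript must be specified")
    gene_conditions = {c for per in rel_expression.values() for c in per}
    if conditions is None:
        conditions = tuple(sorted(gene_conditions))
    for gene, per in rel_expression.items():
        for cond, v in per.items():
            if v <= 0:
                raise ValueError(f"relative expression {gene}/{cond} must be positive")

    rng = np.random.default_rng(truth.seed)
    rows: list = []
    for cond in conditions:
        _emit(rows, truth, rng, template_class="cDNA", primer_pair=normalizer,
              locus=normalizer, condition=cond, amount=1.0)
        for gene, per in rel_expression.items():
            _emit(rows, truth, rng, template_class="cDNA", primer_pair=gene,
                  locus=gene, condition=cond, amount=per[cond])
    for gene in list(rel_expression) + [normalizer]:
        _emit(rows, truth, rng, template_class="NTC", primer_pair=gene,
              locus=gene, condition=conditions[0], ct=truth.ntc_ct)
    return pd.DataFrame(rows, columns=CT_COLUMNS)


# ---------------------------------------------------------------------------
# expression matrices for double-mutant cycles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeEffectSpec:
    """Ground truth for a WT / m1 / m2 / m1m2 expression matrix.

    Effects are additive in log2: the double mutant's true expression is
    baseline * 2**(lfc_m1 + lfc_m2 + interaction_gamma).  ``cv`` is the
    coefficient of variation of multiplicative lognormal replicate noise.
    """

    n_genes: int = 42
    baseline: np.ndarray | float = 100.0
    lfc_m1: np.ndarray | float = 0.0
    lfc_m2: np.ndarray | float = 0.0
    interaction_gamma: np.ndarray | float = 0.0
    cv: float = 0.1
    n_reps: int = 2
    seed: int = 0

    def _vec(self, value) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(value, dtype=float), (self.n_genes,))
        return np.array(arr)

    def true_expression(self) -> dict:
        base = self._vec(self.baseline)
        if np.any(base <= 0):
            raise ValueError("baseline expression must be positive")
        m1 = self._vec(self.lfc_m1)
        m2 = self._vec(self.lfc_m2)
        gamma = self._vec(self.interaction_gamma)
        return {
            "WT": base,
            "m1": base * 2.0 ** m1,
            "m2": base * 2.0 ** m2,
            "m1m2": base * 2.0 ** (m1 + m2 + gamma),
        }


def gen_expression_matrix(spec: GenotypeEffectSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Genes x samples expression matrix for a double-mutant cycle.

    Returns ``(matrix, metadata, truth)``: the matrix has genes as rows and
    ``{genotype}_r{rep}`` columns; metadata carries (sample, genotype,
    condition, replicate); truth is a sidecar with the noiseless values and
    the spec's effect vectors.
    """
    if spec.cv < 0:
        raise ValueError("cv must be nonnegative")
    rng = np.random.default_rng(spec.seed)
    true = spec.true_expression()
    genes = [f"gene{i + 1:03d}" for i in range(spec.n_genes)]
    # mean-preserving lognormal multiplicative noise
    sigma = math.sqrt(math.log1p(spec.cv ** 2))
    data, meta = {}, []
    for genotype, values in true.items():
        for rep in range(1, spec.n_reps + 1):
            col = f"{genotype}_r{rep}"
            if sigma > 0:
                noise = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma,
                                      size=spec.n_genes)
            else:
                noise = np.ones(spec.n_genes)
            data[col] = values * noise
            meta.append({"sample": col, "genotype": genotype,
                         "condition": "basal", "replicate": rep})
    matrix = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    truth = {
        "true_expression": {g: v.tolist() for g, v in true.items()},
        "lfc_m1": spec._vec(spec.lfc_m1).tolist(),
        "lfc_m2": spec._vec(spec.lfc_m2).tolist(),
        "interaction_gamma": spec._vec(spec.interaction_gamma).tolist(),
        "genes": genes,
    }
    return matrix, pd.DataFrame(meta), truth


# ---------------------------------------------------------------------------
# image stacks with planted foci
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageTruth:
    """Ground truth for one synthetic nuclear stack.

    ``foci`` is a list of (centroid_zyx, amplitude, sigma) with centroids in
    voxel units; all centroids must fall inside ``nucleus_mask``.  The
    rendered image emulates post-deconvolution confocal data: Gaussian foci
    on a flat nuclear background, with Poisson shot noise whose residual is
    smoothed (``smooth_sigma``) to stand in for the noise suppression of
    Richardson-Lucy deconvolution while the scene itself stays sharp.
    """

    shape_zyx: tuple = (8, 48, 48)
    nucleus_mask: np.ndarray | None = None
    foci: tuple = ()
    background_mean: float = 100.0
    poisson_noise: bool = True
    smooth_sigma: float = 1.3
    z_spacing_factor: float = 0.25 / 0.065  # 0.25 um z step over ~65 nm xy pixels
    seed: int = 0


def default_nucleus_mask(shape_zyx: tuple) -> np.ndarray:
    """Ellipsoidal nucleus mask spanning most of the stack."""
    nz, ny, nx = shape_zyx
    z, y, x = np.ogrid[:nz, :ny, :nx]
    cz, cy, cx = (nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2
    rz, ry, rx = nz / 2, ny * 0.35, nx * 0.35
    return ((z - cz) ** 2 / rz ** 2 + (y - cy) ** 2 / ry ** 2
            + (x - cx) ** 2 / rx ** 2) <= 1.0


def gen_image_stack(truth: ImageTruth) -> tuple[np.ndarray, dict]:
    """Render a 16-bit single-channel (z, y, x) stack plus truth sidecar."""
    mask = truth.nucleus_mask
    if mask is None:
        mask = default_nucleus_mask(truth.shape_zyx)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(truth.shape_zyx):
        raise ValueError("nucleus_mask shape must match shape_zyx")
    if truth.background_mean <= 0:
        raise ValueError("background_mean must be positive")

    scene = np.where(mask, float(truth.background_mean), 0.0)
    zz, yy, xx = np.indices(truth.shape_zyx, dtype=float)
    for centroid, amplitude, sigma in truth.foci:
        cz, cy, cx = centroid
        izyx = tuple(int(round(c)) for c in centroid)
        if not (0 <= izyx[0] < mask.shape[0] and 0 <= izyx[1] < mask.shape[1]
                and 0 <= izyx[2] < mask.shape[2]) or not mask[izyx]:
            raise ValueError(f"focus centroid {centroid} lies outside the nucleus mask")
        if amplitude <= 0 or sigma <= 0:
            raise ValueError("focus amplitude and sigma must be positive")
        d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
        scene += amplitude * np.exp(-d2 / (2.0 * sigma ** 2)) * mask

    rng = np.random.default_rng(truth.seed)
    if truth.poisson_noise:
        # Emulate deconvolved data: the sharp scene is recovered, while the
        # shot noise survives as a low-amplitude, spatially correlated
        # residual.  Smoothing only the residual avoids darkening the mask
        # edge, which would distort the in-ROI background statistics.
        residual = rng.poisson(scene).astype(float) - scene
        if truth.smooth_sigma > 0:
            residual = gaussian_filter(residual, truth.smooth_sigma)
        image = scene + residual
    else:
        image = scene
    image = np.clip(np.round(image), 0, 2 ** 16 - 1).astype(np.uint16)
    sidecar = {
        "foci": [{"centroid_zyx": list(map(float, c)), "amplitude": float(a),
                  "sigma": float(s)} for c, a, s in truth.foci],
        "background_mean": float(truth.background_mean),
        "poisson_noise": bool(truth.poisson_noise),
        "smooth_sigma": float(truth.smooth_sigma),
        "z_spacing_factor": float(truth.z_spacing_factor),
        "seed": int(truth.seed),
    }
    return image, sidecar


def sample_image_truth(
    rng: np.random.Generator,
    n_foci: int,
    shape_zyx: tuple = (8, 48, 48),
    background_mean: float = 100.0,
    sigma: float = 1.5,
    min_separation_sigmas: float = 4.0,
    amplitude_range_sd: tuple = (10.0, 16.0),
) -> ImageTruth:
    """Random stack truth with well-separated planted foci.

    Amplitudes are drawn in ``amplitude_range_sd`` multiples of the shot-noise
    SD (sqrt of the background mean); centroids keep a pairwise Euclidean
    separation of at least ``min_separation_sigmas * sigma`` voxels and stay
    clear of the mask boundary.
    """
    mask = default_nucleus_mask(shape_zyx)
    sd = math.sqrt(background_mean)
    min_sep = min_separation_sigmas * sigma
    # keep foci clear of the mask boundary so their measured regions are not
    # clipped (a clipped region biases the intensity-weighted centroid)
    margin = int(round(1.5 * sigma))
    ball = np.zeros((2 * margin + 1,) * 3, dtype=bool)
    bz, by, bx = np.ogrid[-margin:margin + 1, -margin:margin + 1,
                          -margin:margin + 1]
    ball[bz ** 2 + by ** 2 + bx ** 2 <= margin ** 2] = True
    interior = ndimage.binary_erosion(mask, structure=ball)
    allowed = np.argwhere(interior)
    if len(allowed) == 0:
        raise ValueError("nucleus mask too small for the requested focus size")
    centers: list = []
    attempts = 0
    while len(centers) < n_foci:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError("could not place foci with requested separation")
        voxel = allowed[rng.integers(len(allowed))]
        c = tuple(float(v) + rng.uniform(-0.5, 0.5) for v in voxel)
        if not interior[tuple(int(round(v)) for v in c)]:
            continue
        if all(math.dist(c, o) >= min_sep for o in centers):
            centers.append(c)
    foci = tuple(
        (c, rng.uniform(*amplitude_range_sd) * sd, sigma) for c in centers
    )
    return ImageTruth(shape_zyx=shape_zyx, nucleus_mask=mask, foci=foci,
                      background_mean=background_mean,
                      seed=int(rng.integers(2 ** 31)))


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthTruth:
    """Logistic growth-curve parameters for one genotype.

    OD(t) = K / (1 + (K/od0 - 1) * exp(-rate * (t - lag))) for t > lag,
    flat at od0 during the lag.
    """

    od0: float = 0.15
    carrying_capacity: float = 1.5
    rate: float = 0.35
    lag: float = 2.0
    t_grid: tuple = tuple(np.arange(0.0, 48.5, 0.5))
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.t_grid, dtype=float)
        if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("t_grid must be strictly increasing with >= 2 points")
        if self.od0 <= 0 or self.od0 > self.carrying_capacity:
            raise ValueError("need 0 < od0 <= carrying_capacity")
        if self.rate < 0 or self.lag < 0:
            raise ValueError("rate and lag must be nonnegative")

    def od(self) -> np.ndarray:
        t = np.asarray(self.t_grid, dtype=float)
        if self.rate == 0:
            return np.full_like(t, self.od0)
        shifted = np.clip(t - self.lag, 0.0, None)
        k, n0 = self.carrying_capacity, self.od0
        return k / (1.0 + (k / n0 - 1.0) * np.exp(-self.rate * shifted))


def gen_growth_curves(
    truths: dict, n_reps: int = 2, seed: int = 0
) -> pd.DataFrame:
    """Long-format growth-curve set: genotype, replicate, time_h, od600."""
    rng = np.random.default_rng(seed)
    frames = []
    for genotype, truth in truths.items():
        base = truth.od()
        t = np.asarray(truth.t_grid, dtype=float)
        for rep in range(1, n_reps + 1):
            od = base.copy()
            if truth.noise_sd > 0:
                od = od + rng.normal(0.0, truth.noise_sd, size=len(od))
            frames.append(pd.DataFrame({
                "genotype": genotype, "replicate": rep,
                "time_h": t, "od600": np.clip(od, 0.0, None),
            }))
    return pd.concat(frames, ignore_index=True)
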