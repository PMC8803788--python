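"""Quantitative evaluation: VOI statistics, lesion segmentation, and the
paired-comparison / observer-agreement statistics.

The quantification protocol works on fixed 7x7x7-voxel cubes: five VOIs in
the liver and five in the lungs per case for SUV_mean, noise (voxel SD
within a VOI) and background variability, plus one 7x7x7 bounding box per
lesion inside which the lesion is segmented by adaptive thresholding at
42% of the (max - min) SUV range.  Organ VOIs are defined once on the
reference series and copied verbatim to every other series of a case;
lesion segmentation is re-run per series because the threshold adapts to
the series' own intensity range.

Agreement statistics: signed/absolute percent differences against the
reference series, OLS scatter slope, Bland-Altman limits of agreement
(mean +/- 1.96 sample SD of the paired differences), the Wilcoxon
signed-rank test (exact by sign-pattern enumeration up to n = 12, normal
approximation with tie-corrected variance and continuity correction
beyond), quadratic weighted kappa for ordinal reader scores, and pooled
summaries of Likert score / preference-rank tables.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter
from scipy.stats import norm, rankdata

logger = logging.getLogger("petdle.evalsuite")

VOI_EXTENT = 7  # fixed cube edge, voxels
_HALF = VOI_EXTENT // 2

__all__ = [
    "VOI",
    "LesionROI",
    "QuantMetrics",
    "BlandAltmanResult",
    "KappaResult",
    "voi_stats",
    "find_organ_vois",
    "segment_lesion",
    "transfer_rois",
    "percent_difference",
    "scatter_slope",
    "bland_altman",
    "wilcoxon_signed_rank",
    "quadratic_weighted_kappa",
    "aggregate_reader_tables",
    "validate_rank_vector",
]


# ---------------------------------------------------------------------------
# VOI statistics

@dataclass(frozen=True)
class VOI:
    """A 7x7x7 cube of voxels identified by its center voxel."""

    center: tuple[int, int, int]
    organ: str  # "liver" | "lung"

    def slices(self):
        return tuple(slice(c - _HALF, c + _HALF + 1) for c in self.center)


@dataclass
class LesionROI:
    """Adaptive-threshold segmentation of one lesion inside its 7^3 box."""

    bbox_center: tuple[int, int, int]
    mask: np.ndarray  # boolean, shape (7, 7, 7)
    threshold: float
    suv_max: float
    suv_mean: float
    source_series: str = ""


@dataclass
class QuantMetrics:
    """Per-organ aggregates over the five VOIs of one series."""

    voi_means: np.ndarray
    voi_sds: np.ndarray
    organ_suv_mean: float
    liver_noise_sd: float  # mean of the per-VOI voxel SDs
    background_variability: float  # SD of VOI means / mean of VOI means


def _check_voi_inside(voi: VOI, shape) -> None:
    for c, n in zip(voi.center, shape):
        if c - _HALF < 0 or c + _HALF >= n:
            raise ValueError(f"VOI at {voi.center} extends outside the volume {shape}")


def voi_stats(values: np.ndarray, vois: list[VOI]) -> QuantMetrics:
    """Mean and voxel SD per VOI plus organ-level aggregates.

    The per-VOI SD is the population SD over the 343 voxels; the organ
    noise figure is the arithmetic mean of the per-VOI SDs; background
    variability is the coefficient of variation (sample SD / mean) of the
    five VOI means.
    """
    values = np.asarray(values)
    if not vois:
        raise ValueError("no VOIs given")
    means, sds = [], []
    for voi in vois:
        _check_voi_inside(voi, values.shape)
        cube = values[voi.slices()]
        means.append(float(cube.mean()))
        sds.append(float(cube.std()))  # population SD over the cube
    means = np.array(means)
    sds = np.array(sds)
    mean_of_means = float(means.mean())
    bv = 0.0
    if len(means) > 1 and mean_of_means != 0:
        bv = float(means.std(ddof=1) / mean_of_means)
    return QuantMetrics(
        voi_means=means,
        voi_sds=sds,
        organ_suv_mean=mean_of_means,
        liver_noise_sd=float(sds.mean()),
        background_variability=bv,
    )


def find_organ_vois(organ_mask: np.ndarray, organ: str, n: int = 5) -> list[VOI]:
    """Deterministically place ``n`` non-overlapping 7^3 VOIs inside a mask.

    Eligible centers are voxels whose whole cube lies in the mask (erosion
    by the cube); candidates are ranked by distance from the mask boundary
    (deepest first, lexicographic tie-break) and picked greedily, skipping
    any candidate whose cube would overlap an already chosen one.
    """
    mask = np.asarray(organ_mask, dtype=bool)
    eligible = minimum_filter(mask.astype(np.uint8), size=VOI_EXTENT,
                              mode="constant", cval=0).astype(bool)
    if not eligible.any():
        raise ValueError(f"mask cannot host a single {VOI_EXTENT}^3 VOI")
    # depth = how far a cube can be re-centred while staying eligible
    from scipy.ndimage import distance_transform_edt

    depth = distance_transform_edt(eligible)
    coords = np.argwhere(eligible)

    def greedy(order):
        chosen: list[np.ndarray] = []
        for idx in order:
            c = coords[idx]
            if any(np.max(np.abs(c - p)) < VOI_EXTENT for p in chosen):
                continue
            chosen.append(c)
            if len(chosen) == n:
                break
        return chosen

    best = greedy(np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0],
                              -depth[tuple(coords.T)])))
    # depth-first greedy can pack badly; retry with seeded shuffles
    attempt = 0
    while len(best) < n and attempt < 200:
        order = np.random.default_rng(attempt).permutation(len(coords))
        trial = greedy(order)
        if len(trial) > len(best):
            best = trial
        attempt += 1
    if len(best) < n:
        raise ValueError(
            f"could only place {len(best)} of {n} VOIs in the {organ} mask")
    return [VOI(center=tuple(int(v) for v in c), organ=organ) for c in best[:n]]


# ---------------------------------------------------------------------------
# lesion segmentation

def segment_lesion(values: np.ndarray, bbox_center, series: str = "") -> LesionROI:
    """Adaptive-threshold lesion segmentation in a 7x7x7 bounding box.

    Threshold T = min + 0.42 (max - min) over the box; the mask keeps
    voxels with value >= T (boundary values included), so the arg-max
    voxel is always in the mask and lesion SUV_max equals the box max.
    A constant box is degenerate: the whole box is returned with a
    warning.
    """
    values = np.asarray(values)
    voi = VOI(center=tuple(int(c) for c in bbox_center), organ="lesion")
    _check_voi_inside(voi, values.shape)
    box = values[voi.slices()]
    lo, hi = float(box.min()), float(box.max())
    threshold = lo + 0.42 * (hi - lo)
    mask = box >= threshold
    if lo == hi:
        logger.warning("segment_lesion: constant box at %s (degenerate lesion)",
                       voi.center)
    return LesionROI(
        bbox_center=voi.center,
        mask=mask,
        threshold=threshold,
        suv_max=hi,
        suv_mean=float(box[mask].mean()),
        source_series=series,
    )


def transfer_rois(reference_values: np.ndarray, series_values: np.ndarray,
                  vois: list[VOI], lesion_centers, series: str = ""):
    """Apply reference-defined ROIs to another series on the same grid.

    Organ VOIs are copied verbatim; lesion segmentation is re-run on the
    target series at the same bounding-box centers (the threshold is
    adaptive, so masks may differ between series).  Returns
    (liver QuantMetrics, lung QuantMetrics, list[LesionROI]).
    """
    if np.shape(reference_values) != np.shape(series_values):
        raise ValueError("series grids do not match")
    liver = [v for v in vois if v.organ == "liver"]
    lung = [v for v in vois if v.organ == "lung"]
    liver_m = voi_stats(series_values, liver) if liver else None
    lung_m = voi_stats(series_values, lung) if lung else None
    lesions = [segment_lesion(series_values, c, series) for c in lesion_centers]
    return liver_m, lung_m, lesions


# ---------------------------------------------------------------------------
# paired-comparison statistics

def percent_difference(series_value: float, reference_value: float) -> float:
    """Signed percent difference, 100 (series - reference) / reference."""
    if reference_value == 0:
        raise ZeroDivisionError("reference value is zero")
    return 100.0 * (series_value - reference_value) / reference_value


def scatter_slope(x, y, through_origin: bool = False):
    """OLS fit y = a + b x for lesion SUV_max concordance plots.

    Returns (gradient, intercept); ``through_origin`` forces a = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: zero variance")
    if through_origin:
        b = float(np.dot(x, y) / np.dot(x, x))
        return b, 0.0
    b, a = np.polyfit(x, y, 1)
    return float(b), float(a)


@dataclass
class BlandAltmanResult:
    mean_difference: float
    loa_low: float
    loa_high: float
    sd_difference: float
    n: int


def bland_altman(pairs) -> BlandAltmanResult:
    """Mean difference and 1.96-SD limits of agreement.

    ``pairs`` is a sequence of (reference, series) values; differences are
    series - reference and the SD is the sample SD (ddof = 1).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (reference, series) pairs")
    d = arr[:, 1] - arr[:, 0]
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(mean_difference=mean,
                             loa_low=mean - 1.96 * sd,
                             loa_high=mean + 1.96 * sd,
                             sd_difference=sd, n=len(d))


class AllDifferencesZero(ValueError):
    """Wilcoxon signed-rank is undefined when every paired difference is 0."""


def wilcoxon_signed_rank(x, y, exact_max_n: int = 12):
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are dropped; |d| are ranked with mid-ranks for ties.
    For effective n <= ``exact_max_n`` the p value is exact, from full
    enumeration of the 2^n sign assignments; otherwise a normal
    approximation with tie-corrected variance and a 0.5 continuity
    correction is used.  Returns (W_plus, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise AllDifferencesZero("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        # distribution of W+ under H0: each rank positive w.p. 1/2
        totals = np.zeros(2 ** n)
        for i, signs in enumerate(itertools.product((0.0, 1.0), repeat=n)):
            totals[i] = np.dot(signs, ranks)
        p_low = np.mean(totals <= w_plus + 1e-9)
        p_high = np.mean(totals >= w_plus - 1e-9)
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, counts = np.unique(ranks, return_counts=True)
        var -= np.sum(counts ** 3 - counts) / 48.0
        dev = w_plus - mean
        z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
        p = min(1.0, p)
    return w_plus, p


# ---------------------------------------------------------------------------
# reader-study statistics

@dataclass
class KappaResult:
    kappa: float
    weighting: str
    categories: int


class UndefinedKappa(ValueError):
    """Kappa is undefined when both raters use a single identical category."""


def quadratic_weighted_kappa(scores_a, scores_b, n_categories: int) -> KappaResult:
    """Chance-corrected ordinal agreement with quadratic weights.

    kappa = 1 - sum(w O) / sum(w E) with w_ij = (i-j)^2 / (k-1)^2, O the
    observed k x k table and E the outer product of the marginals scaled
    to n.  kappa = 1 iff the raters agree on every item.
    """
    a = np.asarray(scores_a, dtype=int)
    b = np.asarray(scores_b, dtype=int)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("score vectors must be equal-length and non-empty")
    k = int(n_categories)
    if ((a < 0) | (a >= k) | (b < 0) | (b >= k)).any():
        raise ValueError("scores outside the category range")
    obs = np.zeros((k, k))
    np.add.at(obs, (a, b), 1.0)
    n = a.size
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    w = (ii - jj) ** 2 / (k - 1) ** 2 if k > 1 else np.zeros((k, k))
    denom = float((w * expected).sum())
    if denom == 0:
        raise UndefinedKappa(
            "both raters used a single category; kappa undefined")
    kappa = 1.0 - float((w * obs).sum()) / denom
    return KappaResult(kappa=kappa, weighting="quadratic", categories=k)


def validate_rank_vector(ranks) -> None:
    """Check competition ("1224") ranking: tied series share a rank and the
    next rank number is skipped."""
    r = sorted(int(v) for v in ranks)
    for i, v in enumerate(r):
        expected_if_new = i + 1
        if i == 0:
            if v != 1:
                raise ValueError(f"rank vector must start at 1, got {r}")
        elif v not in (r[i - 1], expected_if_new):
            raise ValueError(
                f"invalid competition ranking {r}: position {i + 1} must be "
                f"{r[i - 1]} (tie) or {expected_if_new}")


def aggregate_reader_tables(table: pd.DataFrame) -> pd.DataFrame:
    """Pool Likert scores and preference ranks over readers and cases.

    ``table`` columns: case, series, metric, reader, score (0-5 integer),
    rank (competition ranking within each (case, metric, reader)).  The
    output has one row per (series, metric) with mean score, sample SD,
    mean rank, and the percentage of scores >= 3.
    """
    required = {"case", "series", "metric", "reader", "score", "rank"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"missing columns: {sorted(missing_cols)}")
    if not table["score"].isin(range(6)).all():
        bad = table.loc[~table["score"].isin(range(6)), "score"].unique()
        raise ValueError(f"scores outside 0..5: {bad}")
    # completeness: every (case, metric, reader) must rate every series
    series_list = list(dict.fromkeys(table["series"]))
    missing = []
    for (case, metric, reader), grp in table.groupby(["case", "metric", "reader"],
                                                     sort=False):
        absent = set(series_list) - set(grp["series"])
        if absent:
            missing.append((case, metric, reader, sorted(absent)))
        else:
            validate_rank_vector(grp["rank"])
    if missing:
        raise ValueError(f"missing cells: {missing}")
    out = (table.groupby(["series", "metric"], sort=False)
           .agg(mean_score=("score", "mean"),
                sd_score=("score", lambda s: s.std(ddof=1)),
                mean_rank=("rank", "mean"),
                pct_score_ge_3=("score", lambda s: 100.0 * (s >= 3).mean()))
           .reset_index())
    # keep the caller's series ordering
    out["series"] = pd.Categorical(out["series"], categories=series_list,
                                   ordered=True)
    return out.sort_values(["metric", "series"]).reset_index(drop=True)
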