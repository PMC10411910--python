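"""smFISH quantification: spot tables -> per-cell counts and noise statistics.

Input is tabular: one row per detected fluorescent spot (image, cell,
compartment, 3D position, PSF amplitude) and one row per segmented cell
(length, width, nucleus count, replicate).  Spot detection, PSF fitting and
segmentation happen upstream; this module covers everything downstream:

* per-image intensity normalization (divide by the median cytoplasmic
  amplitude, so a typical single-molecule spot has value 1);
* three counting methods -- ``spot`` (one molecule per spot), ``intensity``
  (sum of normalized intensities) and ``hybrid`` (spots below the 95th
  percentile of cytoplasmic intensities in the sample count as one molecule,
  brighter spots count as their normalized intensity);
* nascent / mature-nuclear / cytoplasmic classification from the bimodal
  distribution of spot-to-transcription-site distances;
* cell filters (length outliers, width/length bounds, TS-label QC);
* size-corrected and sliding-window Fano factors and the nuclear-cytoplasmic
  covariance, with bootstrap confidence intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FilterConfig",
    "NoiseSummary",
    "NascentClassification",
    "SizeCorrectedFano",
    "CovarianceResult",
    "normalize_intensities",
    "count_cells",
    "pivot_counts",
    "classify_nascent",
    "filter_cells",
    "cell_volume",
    "size_corrected_fano",
    "sliding_window_fano",
    "nuc_cyto_covariance",
    "noise_summary",
]

COMPARTMENTS = ("nuclear", "cytoplasmic")

#: sliding-window retention thresholds per nucleation stratum:
#: (min cells pooled, min cells single replicate, min consecutive windows)
WINDOW_THRESHOLDS = {"all": (50, 40, 20), "mono": (40, 30, 10), "bi": (30, 20, 6)}


# ---------------------------------------------------------------------------
# intensity normalization and counting
# ---------------------------------------------------------------------------

def normalize_intensities(spots: pd.DataFrame) -> pd.DataFrame:
    """Add ``normalized_intensity``: amplitude over the per-image cytoplasmic median.

    Images without any cytoplasmic spot cannot be normalized and are dropped
    with a warning.  After normalization the median normalized intensity of
    cytoplasmic spots in every retained image is exactly 1.
    """
    if (spots["intensity"] <= 0).any():
        raise ValueError("spot intensities must be positive")
    med = (
        spots.loc[spots["compartment"] == "cytoplasmic"]
        .groupby("image_id")["intensity"]
        .median()
    )
    missing = set(spots["image_id"].unique()) - set(med.index)
    if missing:
        warnings.warn(
            f"images without cytoplasmic spots excluded: {sorted(missing)}",
            UserWarning,
            stacklevel=2,
        )
        spots = spots[~spots["image_id"].isin(missing)]
    out = spots.copy()
    out["normalized_intensity"] = out["intensity"] / out["image_id"].map(med).to_numpy()
    return out


def count_cells(
    spots: pd.DataFrame,
    method: str = "hybrid",
    percentile_threshold: float = 95.0,
    cells: pd.DataFrame | None = None,
    sample_col: str | None = None,
) -> pd.DataFrame:
    """Per-cell, per-compartment mRNA counts from a (normalized) spot table.

    ``spot`` counts every spot as one molecule; ``intensity`` sums normalized
    intensities; ``hybrid`` counts spots as one molecule unless their
    normalized intensity exceeds the ``percentile_threshold`` of *cytoplasmic*
    spot intensities in the same sample, in which case the normalized
    intensity is used.  The threshold is computed per sample (``replicate_id``
    when present, else per image).

    Passing ``cells`` fills in zero counts for cells without any spot.
    """
    if method not in ("spot", "intensity", "hybrid"):
        raise ValueError(f"unknown counting method {method!r}")
    spots = spots.copy()
    if method in ("intensity", "hybrid") and "normalized_intensity" not in spots:
        raise ValueError("run normalize_intensities before intensity/hybrid counting")

    if method == "spot":
        spots["molecules"] = 1.0
    elif method == "intensity":
        spots["molecules"] = spots["normalized_intensity"]
    else:
        if sample_col is None:
            sample_col = "replicate_id" if "replicate_id" in spots else "image_id"
        thr = (
            spots.loc[spots["compartment"] == "cytoplasmic"]
            .groupby(sample_col)["normalized_intensity"]
            .quantile(percentile_threshold / 100.0)
        )
        t = spots[sample_col].map(thr).to_numpy()
        norm = spots["normalized_intensity"].to_numpy()
        spots["molecules"] = np.where(norm <= t, 1.0, norm)

    counts = (
        spots.groupby(["image_id", "cell_id", "compartment"], as_index=False)["molecules"]
        .sum()
        .rename(columns={"molecules": "count"})
    )
    if method == "spot":
        counts["count"] = counts["count"].astype(int)
    if cells is not None:
        full = cells[["image_id", "cell_id"]].merge(
            pd.DataFrame({"compartment": list(COMPARTMENTS)}), how="cross"
        )
        counts = full.merge(counts, on=["image_id", "cell_id", "compartment"], how="left")
        counts["count"] = counts["count"].fillna(0)
        if method == "spot":
            counts["count"] = counts["count"].astype(int)
    return counts


def pivot_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Long per-compartment counts -> one row per cell with nuclear/cytoplasmic columns."""
    wide = counts.pivot_table(
        index=["image_id", "cell_id"], columns="compartment", values="count", fill_value=0
    ).reset_index()
    wide.columns.name = None
    for comp in COMPARTMENTS:
        if comp not in wide:
            wide[comp] = 0
    return wide.rename(columns={"nuclear": "nuclear_count", "cytoplasmic": "cytoplasmic_count"})


# ---------------------------------------------------------------------------
# nascent classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NascentClassification:
    labels: pd.Series                 # {'nascent','mature_nuclear','cytoplasmic'}
    cutoffs: dict                     # image_id -> distance cutoff (um)
    excluded_cells: tuple = ()        # (image_id, cell_id) pairs, 'filter' mode only


def _otsu_threshold(values: np.ndarray) -> float:
    """1D two-class split minimizing within-class variance (threshold between classes)."""
    v = np.sort(values)
    best, best_t = -np.inf, v[0]
    total_mean = v.mean()
    n = v.size
    csum = np.cumsum(v)
    for i in range(1, n):
        w0 = i / n
        m0 = csum[i - 1] / i
        m1 = (csum[-1] - csum[i - 1]) / (n - i)
        between = w0 * (1 - w0) * (m0 - m1) ** 2
        if between > best:
            best = between
            best_t = 0.5 * (v[i - 1] + v[i])
    return best_t


def _kde_modes(logd: np.ndarray, n_grid: int = 256):
    kde = stats.gaussian_kde(logd)
    grid = np.linspace(logd.min() - 0.5, logd.max() + 0.5, n_grid)
    dens = kde(grid)
    peaks = [
        i for i in range(1, n_grid - 1)
        if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1] and dens[i] > 0.05 * dens.max()
    ]
    return grid, dens, peaks


def _kde_min_threshold(logd: np.ndarray) -> float | None:
    grid, dens, peaks = _kde_modes(logd)
    if len(peaks) < 2:
        return None
    top = sorted(sorted(peaks, key=lambda i: dens[i])[-2:])
    valley = top[0] + int(np.argmin(dens[top[0]: top[1] + 1]))
    return float(grid[valley])


def classify_nascent(
    spots: pd.DataFrame,
    ts_spots: pd.DataFrame | None = None,
    fallback_cutoff: float = 0.6,
    backend: str = "otsu",
    ts_outside_mode: str = "expand",
    min_spots: int = 10,
) -> NascentClassification:
    """Split spots into nascent, mature nuclear and cytoplasmic classes.

    The 3D distance of each FISH spot to its nearest labeled transcription
    site is bimodal: a tight mode at the TS (nascent transcripts) and a broad
    mode across the nucleoplasm.  The cutoff is found per image at the split
    between the two modes, either by a two-class variance split on log
    distances (``backend='otsu'``) or at the KDE minimum between the two modes
    (``backend='kde'``).  Images whose distance distribution is unimodal fall
    back to ``fallback_cutoff`` (um) with a warning.

    ``ts_outside_mode`` handles transcription sites just outside the nuclear
    mask: ``'expand'`` relabels cytoplasmic spots within the cutoff of a TS as
    nascent (isotropic nucleus expansion); ``'filter'`` leaves labels alone and
    reports the affected cells for exclusion.
    """
    if backend not in ("otsu", "kde"):
        raise ValueError("backend must be 'otsu' or 'kde'")
    if ts_outside_mode not in ("expand", "filter"):
        raise ValueError("ts_outside_mode must be 'expand' or 'filter'")
    spots = spots.copy()
    if "nearest_ts_distance" not in spots:
        if ts_spots is None:
            raise ValueError("need nearest_ts_distance column or a ts_spots table")
        spots["nearest_ts_distance"] = _nearest_ts_distances(spots, ts_spots)

    labels = spots["compartment"].astype(object).copy()
    cutoffs: dict = {}
    excluded: list[tuple] = []
    for image_id, sub in spots.groupby("image_id"):
        d = sub["nearest_ts_distance"].dropna()
        d = d[d > 0]
        cutoff = None
        if len(d) >= min_spots:
            logd = np.log(d.to_numpy())
            _, _, peaks = _kde_modes(logd)
            if len(peaks) >= 2:
                if backend == "otsu":
                    cutoff = float(np.exp(_otsu_threshold(logd)))
                else:
                    t = _kde_min_threshold(logd)
                    cutoff = float(np.exp(t)) if t is not None else None
        if cutoff is None:
            warnings.warn(
                f"image {image_id!r}: unimodal TS-distance distribution; "
                f"using fixed cutoff {fallback_cutoff} um",
                UserWarning,
                stacklevel=2,
            )
            cutoff = fallback_cutoff
        cutoffs[image_id] = cutoff

        idx = sub.index
        dist = sub["nearest_ts_distance"].to_numpy()
        near = dist < cutoff
        nuc = (sub["compartment"] == "nuclear").to_numpy()
        cyt = ~nuc
        labels.loc[idx[nuc & near]] = "nascent"
        labels.loc[idx[nuc & ~near]] = "mature_nuclear"
        outside = idx[cyt & near & np.isfinite(dist)]
        if len(outside):
            if ts_outside_mode == "expand":
                labels.loc[outside] = "nascent"
            else:
                excluded += list(
                    spots.loc[outside, ["image_id", "cell_id"]].itertuples(index=False)
                )
    labels.name = "spot_class"
    return NascentClassification(
        labels=labels, cutoffs=cutoffs, excluded_cells=tuple(set(excluded))
    )


def _nearest_ts_distances(spots: pd.DataFrame, ts_spots: pd.DataFrame) -> np.ndarray:
    """Distance from each spot to the nearest TS spot in the same cell (NaN if none)."""
    out = np.full(len(spots), np.nan)
    ts_by_cell = {
        key: sub[["x", "y", "z"]].to_numpy()
        for key, sub in ts_spots.groupby(["image_id", "cell_id"])
    }
    pos = spots[["x", "y", "z"]].to_numpy()
    for i, (img, cell) in enumerate(zip(spots["image_id"], spots["cell_id"])):
        ts = ts_by_cell.get((img, cell))
        if ts is not None and len(ts):
            out[i] = np.sqrt(((ts - pos[i]) ** 2).sum(axis=1)).min()
    return out


# ---------------------------------------------------------------------------
# cell filters and geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterConfig:
    """Which cell filters are active.

    ``length_sd``: remove cells with length more than this many SDs from the
    sample mean (applied once, per replicate when available).  ``width_range``
    and ``max_length`` are absolute bounds used when reanalyzing legacy data.
    ``require_ts_labels`` enforces TS-labeling QC: 1-2 GFP spots per nucleus
    and no cytoplasmic GFP spot.
    """

    length_sd: float | None = 4.0
    width_range: tuple[float, float] | None = None
    max_length: float | None = None
    require_ts_labels: bool = False


def filter_cells(
    cells: pd.DataFrame, rules: FilterConfig = FilterConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the active filters; return (retained cells, exclusion log).

    The exclusion log has one row per excluded cell with the rule that
    triggered it.  The length-SD rule uses the mean/SD of the input sample
    (not recomputed after exclusions).
    """
    drop = pd.Series(False, index=cells.index)
    reason = pd.Series("", index=cells.index, dtype=object)

    def mark(mask: pd.Series, rule: str) -> None:
        new = mask & ~drop
        drop[new] = True
        reason[new] = rule

    if rules.length_sd is not None:
        group = cells["replicate_id"] if "replicate_id" in cells else pd.Series(0, index=cells.index)
        mu = cells.groupby(group)["length"].transform("mean")
        sd = cells.groupby(group)["length"].transform("std").fillna(0.0)
        mark((cells["length"] - mu).abs() > rules.length_sd * sd,
             f"length >{rules.length_sd} SD from sample mean")
    if rules.width_range is not None:
        lo, hi = rules.width_range
        mark((cells["width"] < lo) | (cells["width"] > hi),
             f"width outside [{lo}, {hi}] um")
    if rules.max_length is not None:
        mark(cells["length"] > rules.max_length, f"length > {rules.max_length} um")
    if rules.require_ts_labels:
        if "n_gfp_spots" in cells:
            mark((cells["n_gfp_spots"] < 1) | (cells["n_gfp_spots"] > 2),
                 "GFP spots per nucleus outside 1-2")
        if "cytoplasmic_gfp" in cells:
            mark(cells["cytoplasmic_gfp"].astype(bool), "cytoplasmic GFP spot")

    log = cells.loc[drop, ["image_id", "cell_id"]].copy()
    log["rule"] = reason[drop].to_numpy()
    return cells.loc[~drop].copy(), log.reset_index(drop=True)


def cell_volume(length, width):
    """Cell volume (um^3), modeling the cell as a cylinder with hemispherical caps.

    ``V = pi (w/2)^2 (L - w) + (4/3) pi (w/2)^3``; at ``L == w`` this
    degenerates to a sphere.
    """
    length = np.asarray(length, dtype=float)
    width = np.asarray(width, dtype=float)
    if (width <= 0).any() or (length < width).any():
        raise ValueError("require length >= width > 0")
    r = width / 2.0
    vol = math.pi * r**2 * (length - width) + (4.0 / 3.0) * math.pi * r**3
    return vol if vol.ndim else float(vol)


# ---------------------------------------------------------------------------
# noise statistics
# ---------------------------------------------------------------------------

def _boot_indices(rng: np.random.Generator, n: int, n_boot: int, chunk: int = 2000):
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        yield rng.integers(0, n, size=(b, n))
        done += b


def _fano_corrected(counts: np.ndarray, sizes: np.ndarray) -> tuple[float, float]:
    """(size-corrected Fano, OLS slope of count on size)."""
    var_s = sizes.var(ddof=1)
    cov = np.cov(counts, sizes, ddof=1)[0, 1]
    slope = cov / var_s
    f = (counts.var(ddof=1) - slope**2 * var_s) / counts.mean()
    return float(f), float(slope)


@dataclass(frozen=True)
class SizeCorrectedFano:
    value: float
    ci: tuple[float, float]
    se: float
    raw_fano: float
    slope: float
    n: int


def size_corrected_fano(
    counts,
    sizes,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> SizeCorrectedFano:
    """Fano factor with the cell-size-explained variance removed.

    An ordinary least squares fit of count on size gives slope ``b``; the
    corrected Fano factor is ``(Var(count) - b^2 Var(size)) / mean(count)``,
    i.e. total variance minus the size-explained component, over the mean.
    The 95% CI is a nonparametric percentile bootstrap over cells; ``se`` is
    the bootstrap standard deviation.  Invariant to rescaling all sizes by a
    positive constant.  Degenerate size variance falls back to the raw Fano
    factor with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if counts.shape != sizes.shape or counts.ndim != 1:
        raise ValueError("counts and sizes must be 1D arrays of equal length")
    n = counts.size
    if n < 30:
        warnings.warn(f"only {n} cells; size-corrected Fano is unreliable below 30",
                      UserWarning, stacklevel=2)
    raw = float(counts.var(ddof=1) / counts.mean())
    if sizes.var(ddof=1) <= 0 or np.allclose(sizes, sizes[0]):
        warnings.warn("degenerate size variance; returning raw Fano factor",
                      UserWarning, stacklevel=2)
        return SizeCorrectedFano(raw, (np.nan, np.nan), np.nan, raw, 0.0, n)

    value, slope = _fano_corrected(counts, sizes)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    done = 0
    for idx in _boot_indices(rng, n, n_boot):
        cb = counts[idx]
        sb = sizes[idx]
        mc = cb.mean(axis=1)
        ms = sb.mean(axis=1)
        var_c = cb.var(axis=1, ddof=1)
        var_s = sb.var(axis=1, ddof=1)
        cov = ((cb - mc[:, None]) * (sb - ms[:, None])).sum(axis=1) / (cb.shape[1] - 1)
        var_s = np.where(var_s > 0, var_s, np.nan)
        slope_b = cov / var_s
        boots[done: done + idx.shape[0]] = (var_c - slope_b**2 * var_s) / mc
        done += idx.shape[0]
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return SizeCorrectedFano(value, (float(lo), float(hi)), float(boots.std(ddof=1)),
                             raw, slope, n)


def sliding_window_fano(
    counts,
    lengths,
    window: float = 1.0,
    step: float = 0.1,
    population: str = "pooled",
    nucleation: str = "all",
) -> pd.DataFrame:
    """Fano-factor profile in a sliding cell-length window.

    Cells within a ``window`` um length window are combined; the window moves
    by ``step`` um across the full size range.  Windows are retained only when
    they hold at least the stratum's minimum number of cells (pooled or
    single-replicate threshold per ``population``) for at least the stratum's
    minimum run of consecutive windows; everything else is dropped.  Retention
    thresholds per nucleation stratum (pooled, replicate, consecutive):
    all = (50, 40, 20), mono = (40, 30, 10), bi = (30, 20, 6).
    """
    if population not in ("pooled", "replicate"):
        raise ValueError("population must be 'pooled' or 'replicate'")
    if nucleation not in WINDOW_THRESHOLDS:
        raise ValueError(f"nucleation must be one of {sorted(WINDOW_THRESHOLDS)}")
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths must be aligned")
    pooled_min, rep_min, consec = WINDOW_THRESHOLDS[nucleation]
    min_cells = pooled_min if population == "pooled" else rep_min

    empty = pd.DataFrame(columns=["center", "n_cells", "mean", "variance", "fano"])
    if counts.size == 0:
        return empty
    left = np.arange(lengths.min(), lengths.max() - window + step / 2, step)
    if left.size == 0:
        left = np.array([lengths.min()])
    rows = []
    for lo in left:
        in_win = (lengths >= lo) & (lengths < lo + window)
        sub = counts[in_win]
        n = int(sub.size)
        mean = sub.mean() if n else np.nan
        var = sub.var(ddof=1) if n > 1 else np.nan
        rows.append((lo + window / 2, n, mean, var, var / mean if n > 1 and mean > 0 else np.nan))
    prof = pd.DataFrame(rows, columns=["center", "n_cells", "mean", "variance", "fano"])

    ok = (prof["n_cells"] >= min_cells).to_numpy()
    keep = np.zeros_like(ok)
    i = 0
    while i < ok.size:
        if ok[i]:
            j = i
            while j < ok.size and ok[j]:
                j += 1
            if j - i >= consec:
                keep[i:j] = True
            i = j
        else:
            i += 1
    return prof.loc[keep].reset_index(drop=True)


@dataclass(frozen=True)
class CovarianceResult:
    covariance: float
    ci: tuple[float, float]
    se: float
    partial_covariance: float | None  # size-partialled (residual) covariance
    partial_ci: tuple[float, float] | None
    n: int
    low_n: bool


def nuc_cyto_covariance(
    nuclear_counts,
    cytoplasmic_counts,
    sizes=None,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> CovarianceResult:
    """Sample covariance of paired per-cell (nuclear, cytoplasmic) counts.

    Negative covariance is the signature of sub-Poissonian expression, zero of
    Poissonian, positive of super-Poissonian.  When ``sizes`` is given, a
    size-partialled covariance (covariance of the residuals of both counts
    regressed on size) is reported alongside, flagged separately since it is
    not the plain estimator.  CIs are percentile bootstrap.
    """
    nuc = np.asarray(nuclear_counts, dtype=float)
    cyt = np.asarray(cytoplasmic_counts, dtype=float)
    if nuc.shape != cyt.shape or nuc.ndim != 1:
        raise ValueError("paired 1D count vectors required")
    n = nuc.size
    low_n = n < 30
    if low_n:
        warnings.warn(f"n={n} < 30 cells: covariance estimate is low-precision",
                      UserWarning, stacklevel=2)

    def _cov(a, b):
        return ((a - a.mean()) * (b - b.mean())).sum() / (a.size - 1)

    value = float(_cov(nuc, cyt))
    rng = np.random.default_rng(seed)

    def _boot_cov(a, b):
        boots = np.empty(n_boot)
        done = 0
        for idx in _boot_indices(rng, n, n_boot):
            ab, bb = a[idx], b[idx]
            boots[done: done + idx.shape[0]] = (
                (ab - ab.mean(axis=1, keepdims=True)) * (bb - bb.mean(axis=1, keepdims=True))
            ).sum(axis=1) / (n - 1)
            done += idx.shape[0]
        return boots

    boots = _boot_cov(nuc, cyt)
    lo, hi = np.percentile(boots, [2.5, 97.5])

    partial = partial_ci = None
    if sizes is not None:
        s = np.asarray(sizes, dtype=float)
        resid_n = nuc - np.polyval(np.polyfit(s, nuc, 1), s)
        resid_c = cyt - np.polyval(np.polyfit(s, cyt, 1), s)
        partial = float(_cov(resid_n, resid_c))
        pboots = _boot_cov(resid_n, resid_c)
        plo, phi = np.percentile(pboots, [2.5, 97.5])
        partial_ci = (float(plo), float(phi))

    return CovarianceResult(
        covariance=value, ci=(float(lo), float(hi)), se=float(boots.std(ddof=1)),
        partial_covariance=partial, partial_ci=partial_ci, n=n, low_n=low_n,
    )


@dataclass(frozen=True)
class NoiseSummary:
    """Per-gene/condition, per-compartment noise summary."""

    label: str
    compartment: str
    n_cells: int
    mean_count: float
    size_corrected_fano: float
    fano_ci: tuple[float, float]
    raw_fano: float
    cov_nuc_cyto: float | None = None
    cov_ci: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.label, "compartment": self.compartment,
            "n_cells": self.n_cells, "mean_count": self.mean_count,
            "size_corrected_fano": self.size_corrected_fano,
            "fano_ci_low": self.fano_ci[0], "fano_ci_high": self.fano_ci[1],
            "raw_fano": self.raw_fano,
            "cov_nuc_cyto": self.cov_nuc_cyto,
            "cov_ci_low": None if self.cov_ci is None else self.cov_ci[0],
            "cov_ci_high": None if self.cov_ci is None else self.cov_ci[1],
        }


def noise_summary(
    label: str,
    compartment: str,
    counts,
    sizes,
    paired_counts=None,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> NoiseSummary:
    """Bundle mean, size-corrected Fano (with CI) and optional covariance."""
    counts = np.asarray(counts, dtype=float)
    fano = size_corrected_fano(counts, sizes, n_boot=n_boot, seed=seed)
    cov = cov_ci = None
    if paired_counts is not None:
        res = nuc_cyto_covariance(counts, paired_counts, sizes=None,
                                  n_boot=n_boot, seed=seed)
        cov, cov_ci = res.covariance, res.ci
    return NoiseSummary(
        label=label, compartment=compartment, n_cells=counts.size,
        mean_count=float(counts.mean()), size_corrected_fano=fano.value,
        fano_ci=fano.ci, raw_fano=fano.raw_fano,
        cov_nuc_cyto=cov, cov_ci=cov_ci,
    )
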