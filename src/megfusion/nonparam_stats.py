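"""Nonparametric inference: d', signed-rank, bootstrap latencies, FDR,
and sign-permutation cluster-size inference.

All resampling operations are driven by an explicit seed and are fully
deterministic given it. Permutation p-values use the +1 convention (the
observed statistic counts as one permutation), so no p-value is ever 0
and the smallest attainable value is 1/(n_perm+1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LatencyEstimate",
    "ClusterResult",
    "dprime",
    "signed_rank_test",
    "bootstrap_latency",
    "bootstrap_latency_difference",
    "fdr_correct",
    "sign_permutation_clusters",
]


# ---------------------------------------------------------------------------
# signal detection & rank tests


def dprime(n_hits: int, n_misses: int, n_fas: int, n_crs: int) -> float:
    """Signal-detection sensitivity d' = z(hit rate) - z(false-alarm rate).

    Extreme rates of 0 and 1 are replaced by 1/(2N) and 1 - 1/(2N) of the
    corresponding trial count before the inverse-normal transform, the
    standard correction keeping d' finite.
    """
    n_signal = n_hits + n_misses
    n_noise = n_fas + n_crs
    if n_signal <= 0 or n_noise <= 0:
        raise ValueError("need at least one signal and one noise trial")

    def _rate(k: int, n: int) -> float:
        r = k / n
        if r <= 0.0:
            return 1.0 / (2 * n)
        if r >= 1.0:
            return 1.0 - 1.0 / (2 * n)
        return r

    return float(
        stats.norm.ppf(_rate(n_hits, n_signal)) - stats.norm.ppf(_rate(n_fas, n_noise))
    )


def signed_rank_test(paired_a, paired_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 without ties in the absolute differences, otherwise the
    normal approximation with tie correction. Returns p = 1 when every
    difference is zero.
    """
    a = np.asarray(paired_a, dtype=np.float64)
    b = np.asarray(paired_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    diff = a - b
    diff = diff[diff != 0]
    if diff.size == 0:
        return 1.0
    has_ties = np.unique(np.abs(diff)).size < diff.size
    method = "exact" if (diff.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(diff, alternative="two-sided", method=method)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# bootstrap latency


@dataclass
class LatencyEstimate:
    """Peak or onset latency with a bootstrap percentile 95% CI.

    The CI is the 2.5/97.5 percentile band of the bootstrap latency
    distribution; the point estimate comes from the original subject
    average, so the band is not forced to bracket it. Replicates where
    the latency is undefined (flat series, or no sustained threshold
    crossing for onsets) are excluded and counted in `n_undefined`.
    """

    kind: str
    point_ms: float
    ci_low_ms: float
    ci_high_ms: float
    n_boot: int
    search_window: tuple[float, float]
    n_undefined: int = 0

    def __post_init__(self) -> None:
        if not np.isnan(self.ci_low_ms) and self.ci_low_ms > self.ci_high_ms:
            raise ValueError("ci_low_ms must not exceed ci_high_ms")

    def to_record(self) -> dict:
        return {
            "kind": self.kind,
            "point_ms": self.point_ms,
            "ci_low_ms": self.ci_low_ms,
            "ci_high_ms": self.ci_high_ms,
            "n_boot": self.n_boot,
            "search_window": list(self.search_window),
            "n_undefined": self.n_undefined,
        }


def _window_mask(time_axis, window):
    lo, hi = window
    mask = (time_axis >= lo) & (time_axis <= hi)
    if not mask.any():
        raise ValueError("search window contains no time points")
    return mask


def _peak_latency(series: np.ndarray, times: np.ndarray) -> float:
    if np.all(series == series[0]):
        return np.nan  # flat: peak undefined
    return float(times[int(np.argmax(series))])


def _onset_latency(
    series: np.ndarray,
    times: np.ndarray,
    threshold: np.ndarray,
    min_consecutive: int,
) -> float:
    above = series > threshold
    run = 0
    for idx, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= min_consecutive:
            return float(times[idx - min_consecutive + 1])
    return np.nan


def bootstrap_latency(
    subject_series: np.ndarray,
    time_axis: np.ndarray,
    kind: str = "peak",
    window: tuple[float, float] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    onset_threshold: np.ndarray | float | None = None,
    min_consecutive: int = 5,
) -> LatencyEstimate:
    """Bootstrap the latency of the subject-averaged time series.

    Subjects (rows of `subject_series`) are resampled with replacement
    `n_boot` times; the latency of each resampled average within `window`
    forms the empirical distribution whose 2.5/97.5 percentiles give the
    95% CI. `kind="peak"` takes the argmax. `kind="onset"` takes the
    first of at least `min_consecutive` consecutive samples exceeding
    `onset_threshold` (a scalar or per-time array, e.g. the point-wise
    threshold from sign-permutation inference on the original data; for
    onsets the series should already be centered on its null value).
    """
    series = np.atleast_2d(np.asarray(subject_series, dtype=np.float64))
    time_axis = np.asarray(time_axis, dtype=np.float64)
    if series.shape[0] < 2:
        raise ValueError("need at least 2 subjects to bootstrap")
    if series.shape[1] != time_axis.size:
        raise ValueError("series and time axis must align")
    if kind not in ("peak", "onset"):
        raise ValueError("kind must be 'peak' or 'onset'")
    if window is None:
        window = (float(time_axis[0]), float(time_axis[-1]))
    mask = _window_mask(time_axis, window)
    times = time_axis[mask]
    data = series[:, mask]

    if kind == "onset":
        if onset_threshold is None:
            raise ValueError("onset latency requires onset_threshold")
        thr = np.broadcast_to(
            np.asarray(onset_threshold, dtype=np.float64), times.shape
        )

        def extract(avg):
            return _onset_latency(avg, times, thr, min_consecutive)

    else:

        def extract(avg):
            return _peak_latency(avg, times)

    point = extract(data.mean(axis=0))
    rng = np.random.default_rng(seed)
    n_sub = data.shape[0]
    draws = rng.integers(0, n_sub, size=(n_boot, n_sub))
    boots = np.array([extract(data[idx].mean(axis=0)) for idx in draws])
    defined = boots[~np.isnan(boots)]
    n_undef = n_boot - defined.size
    if defined.size == 0:
        lo = hi = np.nan
    else:
        lo, hi = np.percentile(defined, [2.5, 97.5])
    return LatencyEstimate(
        kind=kind,
        point_ms=point,
        ci_low_ms=float(lo),
        ci_high_ms=float(hi),
        n_boot=n_boot,
        search_window=(float(window[0]), float(window[1])),
        n_undefined=int(n_undef),
    )


def bootstrap_latency_difference(
    series_a: np.ndarray,
    series_b: np.ndarray,
    time_axis: np.ndarray,
    kind: str = "peak",
    window: tuple[float, float] | None = None,
    n_boot: int = 1000,
    paired: bool = False,
    seed: int = 0,
    **latency_kwargs,
) -> tuple[float, np.ndarray]:
    """Two-sided bootstrap p-value for a latency difference (A - B).

    Each replicate resamples subjects with replacement — jointly for
    paired cohorts, independently otherwise — and records the latency
    difference of the resampled averages. The p-value is twice the
    smaller tail mass of the difference distribution around zero, floored
    at 1/n_boot. Returns (p, difference distribution); undefined
    replicates are dropped.
    """
    a = np.atleast_2d(np.asarray(series_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(series_b, dtype=np.float64))
    time_axis = np.asarray(time_axis, dtype=np.float64)
    if paired and a.shape[0] != b.shape[0]:
        raise ValueError("paired cohorts must have equal subject counts")
    if min(a.shape[0], b.shape[0]) < 2:
        raise ValueError("need at least 2 subjects per cohort")
    if window is None:
        window = (float(time_axis[0]), float(time_axis[-1]))
    mask = _window_mask(time_axis, window)
    times = time_axis[mask]
    da, db = a[:, mask], b[:, mask]

    if kind == "onset":
        thr = latency_kwargs.get("onset_threshold")
        if thr is None:
            raise ValueError("onset latency requires onset_threshold")
        thr = np.broadcast_to(np.asarray(thr, dtype=np.float64), times.shape)
        mc = latency_kwargs.get("min_consecutive", 5)

        def extract(avg):
            return _onset_latency(avg, times, thr, mc)

    elif kind == "peak":

        def extract(avg):
            return _peak_latency(avg, times)

    else:
        raise ValueError("kind must be 'peak' or 'onset'")

    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        if paired:
            idx = rng.integers(0, a.shape[0], size=a.shape[0])
            la = extract(da[idx].mean(axis=0))
            lb = extract(db[idx].mean(axis=0))
        else:
            ia = rng.integers(0, a.shape[0], size=a.shape[0])
            ib = rng.integers(0, b.shape[0], size=b.shape[0])
            la = extract(da[ia].mean(axis=0))
            lb = extract(db[ib].mean(axis=0))
        diffs[i] = la - lb
    defined = diffs[~np.isnan(diffs)]
    if defined.size == 0:
        return 1.0, diffs
    frac_le = np.mean(defined <= 0)
    frac_ge = np.mean(defined >= 0)
    p = 2.0 * min(frac_le, frac_ge)
    p = float(np.clip(p, 1.0 / n_boot, 1.0))
    return p, diffs


# ---------------------------------------------------------------------------
# multiple comparisons


def fdr_correct(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level q."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)


# ---------------------------------------------------------------------------
# sign-permutation cluster inference


@dataclass
class ClusterResult:
    """Cluster-size inference output for a 1-D series or 2-D map.

    `sig_mask` marks cells belonging to clusters surviving the corrected
    threshold; `clusters` lists every candidate cluster with its cell
    index array, size, and corrected p-value. `pointwise_threshold` is
    the per-cell cluster-defining threshold (useful downstream, e.g. as
    the onset-latency criterion).
    """

    sig_mask: np.ndarray
    clusters: list[dict]
    pointwise_threshold: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_significant(self) -> int:
        return sum(1 for c in self.clusters if c["significant"])


def sign_permutation_clusters(
    subject_effects: np.ndarray,
    n_perm: int = 1000,
    cdt: float = 0.05,
    alpha: float = 0.05,
    tail: str = "greater",
    seed: int = 0,
) -> ClusterResult:
    """Cluster-size inference by randomly sign-flipping subject effects.

    `subject_effects` is subjects x cells where cells form a 1-D time
    series or a 2-D (e.g. train x test time) map, already centered on the
    null value (accuracy - 50, rho - 0, ...). Under the null of a
    symmetric effect distribution the subject signs are exchangeable, so
    the permutation distribution of the across-subject mean is obtained
    by random +/-1 multiplication. Per cell, the cluster-defining
    threshold is the (1 - cdt) permutation quantile of the mean
    (one-sided `tail="greater"`; `"less"` mirrors it); observed
    supra-threshold cells are grouped into connected clusters (1-D
    adjacency, 4-connectivity for maps) and each cluster's size in cells
    is compared against the permutation distribution of the maximum
    cluster size, with the observed data included (+1 convention).
    Clusters with corrected p <= alpha are significant.
    """
    effects = np.asarray(subject_effects, dtype=np.float64)
    if effects.ndim < 2:
        raise ValueError("subject_effects must be subjects x cells")
    n_sub = effects.shape[0]
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives a coarse permutation distribution",
            stacklevel=2,
        )
    if tail not in ("greater", "less"):
        raise ValueError("tail must be 'greater' or 'less'")
    cell_shape = effects.shape[1:]
    if len(cell_shape) > 2:
        raise ValueError("only 1-D series and 2-D maps are supported")
    flat = effects.reshape(n_sub, -1)
    if tail == "less":
        flat = -flat

    observed = flat.mean(axis=0)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    perm_means = (signs @ flat) / n_sub  # (n_perm, n_cells)

    threshold = np.quantile(perm_means, 1.0 - cdt, axis=0)

    def _label(mask_flat: np.ndarray):
        mask = mask_flat.reshape(cell_shape)
        labeled, n_clu = ndimage.label(mask)  # 1-D chain / 2-D 4-connectivity
        return labeled, n_clu

    # null distribution of the maximum cluster size
    max_sizes = np.zeros(n_perm)
    for p_idx in range(n_perm):
        labeled, n_clu = _label(perm_means[p_idx] > threshold)
        if n_clu:
            max_sizes[p_idx] = ndimage.sum_labels(
                np.ones(cell_shape), labeled, index=range(1, n_clu + 1)
            ).max()

    labeled_obs, n_obs = _label(observed > threshold)
    clusters = []
    sig_mask = np.zeros(cell_shape, dtype=bool)
    for lab in range(1, n_obs + 1):
        cells = np.flatnonzero(labeled_obs.ravel() == lab)
        size = cells.size
        p_val = (1 + np.sum(max_sizes >= size)) / (n_perm + 1)
        significant = bool(p_val <= alpha)
        clusters.append(
            {
                "cells": cells,
                "size": int(size),
                "p": float(p_val),
                "significant": significant,
            }
        )
        if significant:
            sig_mask.ravel()[cells] = True

    thr_out = threshold.reshape(cell_shape)
    if tail == "less":
        thr_out = -thr_out
    return ClusterResult(
        sig_mask=sig_mask,
        clusters=clusters,
        pointwise_threshold=thr_out,
        params={
            "n_perm": n_perm,
            "cdt": cdt,
            "alpha": alpha,
            "tail": tail,
            "seed": seed,
        },
    )
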