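"""Five between-array normalization strategies for bead-summary signals.

Strategies: ``none``, ``average`` (scale to the grand mean of sample
means), ``quantile`` (classical order-statistic averaging), ``cubic_spline``
(monotone spline through quantile anchors onto the per-rank mean curve) and
``rank_invariant`` (monotone scaling curve fitted through probes whose rank
is stable against a reference sample).

All strategies operate on whatever probes are present — no pre-filtering —
and preserve within-sample rank order.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.stats import rankdata

from .io_bead import BeadSummaryMatrix

__all__ = [
    "NormalizationResult",
    "normalize_none",
    "normalize_average",
    "normalize_quantile",
    "normalize_cubic_spline",
    "normalize_rank_invariant",
    "normalize",
    "STRATEGIES",
]


@dataclass
class NormalizationResult:
    """Normalized signal plus per-strategy diagnostics.

    ``matrix`` keeps the input (for bead SEs and negative controls);
    ``signal`` is the normalized probe x sample matrix.
    """

    matrix: BeadSummaryMatrix
    signal: np.ndarray
    strategy: str
    diagnostics: dict = field(default_factory=dict)

    @property
    def probe_ids(self) -> list[str]:
        return self.matrix.probe_ids

    @property
    def sample_ids(self) -> list[str]:
        return self.matrix.sample_ids

    def scale_factors(self) -> np.ndarray:
        """Effective per-sample multiplicative factor (normalized/raw mean)."""
        raw = self.matrix.signal.mean(axis=0)
        out = np.ones(len(self.sample_ids))
        nonzero = raw != 0
        out[nonzero] = self.signal.mean(axis=0)[nonzero] / raw[nonzero]
        return out


def normalize_none(m: BeadSummaryMatrix) -> NormalizationResult:
    """Identity: signal passed through untouched."""
    return NormalizationResult(matrix=m, signal=m.signal.copy(), strategy="none")


def normalize_average(m: BeadSummaryMatrix) -> NormalizationResult:
    """Rescale each sample so its mean equals the grand mean of sample means."""
    if m.n_samples < 1:
        raise ValueError("need at least one sample")
    means = m.signal.mean(axis=0)
    if np.any(means <= 0):
        bad = [m.sample_ids[j] for j in np.flatnonzero(means <= 0)]
        raise ValueError(f"sample mean <= 0, cannot scale: {bad}")
    grand = means.mean()
    factors = grand / means
    return NormalizationResult(
        matrix=m,
        signal=m.signal * factors[None, :],
        strategy="average",
        diagnostics={"scale_factors": dict(zip(m.sample_ids, factors.tolist()))},
    )


def _rank_mean_reference(signal: np.ndarray) -> np.ndarray:
    """Per-rank mean of the samples' order statistics (ascending)."""
    return np.sort(signal, axis=0).mean(axis=1)


def normalize_quantile(m: BeadSummaryMatrix) -> NormalizationResult:
    """Classical quantile normalization; ties get the mean of covered ranks."""
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    ref = _rank_mean_reference(m.signal)
    out = np.empty_like(m.signal)
    ranks_grid = np.arange(1, m.n_probes + 1, dtype=float)
    for j in range(m.n_samples):
        ranks = rankdata(m.signal[:, j], method="average")
        out[:, j] = np.interp(ranks, ranks_grid, ref)
    return NormalizationResult(matrix=m, signal=out, strategy="quantile")


def _anchor_pairs(col: np.ndarray, ref: np.ndarray, n_anchors: int) -> tuple[np.ndarray, np.ndarray]:
    probs = np.linspace(0.0, 1.0, n_anchors)
    x = np.quantile(col, probs)
    y = np.quantile(ref, probs)
    # collapse duplicate x anchors (ties in the data) to keep x strictly increasing
    ux, inverse = np.unique(x, return_inverse=True)
    uy = np.zeros_like(ux)
    counts = np.zeros_like(ux)
    np.add.at(uy, inverse, y)
    np.add.at(counts, inverse, 1)
    return ux, uy / counts


def _monotone_map(x: np.ndarray, y: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """Monotone cubic through (x, y) with linear extension of boundary segments."""
    y = np.maximum.accumulate(y)
    spline = PchipInterpolator(x, y, extrapolate=False)
    lo_slope = (y[1] - y[0]) / (x[1] - x[0]) if x[1] > x[0] else 0.0
    hi_slope = (y[-1] - y[-2]) / (x[-1] - x[-2]) if x[-1] > x[-2] else 0.0

    def apply(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        out = spline(v)
        below = v < x[0]
        above = v > x[-1]
        out[below] = y[0] + lo_slope * (v[below] - x[0])
        out[above] = y[-1] + hi_slope * (v[above] - x[-1])
        return out

    return apply


def normalize_cubic_spline(m: BeadSummaryMatrix, n_anchors: int = 16) -> NormalizationResult:
    """Monotone spline through evenly spaced quantile anchors onto the
    per-rank mean reference curve."""
    if m.n_samples < 2:
        raise ValueError("cubic-spline normalization needs >= 2 samples")
    if n_anchors < 4:
        raise ValueError("need n_anchors >= 4")
    ref = _rank_mean_reference(m.signal)
    out = np.empty_like(m.signal)
    anchors: dict[str, list[list[float]]] = {}
    for j, s in enumerate(m.sample_ids):
        col = m.signal[:, j]
        n_distinct = np.unique(col).size
        k = n_anchors
        if n_distinct < k:
            if n_distinct < 4:
                raise ValueError(
                    f"sample {s!r} has only {n_distinct} distinct values; "
                    "cannot anchor a cubic spline"
                )
            warnings.warn(
                f"sample {s!r}: reducing anchors {k} -> {n_distinct} "
                "(too few distinct values)", stacklevel=2,
            )
            k = n_distinct
        x, y = _anchor_pairs(col, ref, k)
        while x.size < 4 and k < m.n_probes:
            k += 4
            x, y = _anchor_pairs(col, ref, k)
        if x.size < 2:
            raise ValueError(f"sample {s!r}: cannot build spline anchors")
        out[:, j] = _monotone_map(x, y)(col)
        anchors[s] = [x.tolist(), y.tolist()]
    return NormalizationResult(
        matrix=m, signal=out, strategy="cubic_spline", diagnostics={"anchors": anchors}
    )


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        out[i] = np.median(x[lo:hi])
    return out


def normalize_rank_invariant(
    m: BeadSummaryMatrix, rank_tol: float = 0.05, min_set: int = 50
) -> NormalizationResult:
    """Scale each sample onto a reference through its rank-invariant probes.

    The reference is the sample whose mean is the median of sample means.
    A probe is rank-invariant for a (sample, reference) pair when its
    normalized-rank difference is at most ``rank_tol``.  Samples with fewer
    than ``min_set`` invariant probes fall back to average scaling.
    """
    if m.n_samples < 2:
        raise ValueError("rank-invariant normalization needs >= 2 samples")
    means = m.signal.mean(axis=0)
    ref_j = int(np.argsort(means, kind="stable")[(m.n_samples - 1) // 2])
    ref_col = m.signal[:, ref_j]
    ref_ranks = rankdata(ref_col, method="average") / m.n_probes

    out = m.signal.copy()
    invariant_sets: dict[str, list[str]] = {}
    fallbacks: list[str] = []
    for j, s in enumerate(m.sample_ids):
        if j == ref_j:
            invariant_sets[s] = list(m.probe_ids)
            continue
        col = m.signal[:, j]
        ranks = rankdata(col, method="average") / m.n_probes
        inv = np.abs(ranks - ref_ranks) <= rank_tol
        invariant_sets[s] = [m.probe_ids[i] for i in np.flatnonzero(inv)]
        if inv.sum() < min_set:
            warnings.warn(
                f"sample {s!r}: only {int(inv.sum())} rank-invariant probes "
                f"(< {min_set}); falling back to average scaling", stacklevel=2,
            )
            fallbacks.append(s)
            if means[j] > 0:
                out[:, j] = col * (means[ref_j] / means[j])
            continue
        order = np.argsort(col[inv], kind="stable")
        x = col[inv][order]
        y = ref_col[inv][order]
        window = max(3, 2 * (min(51, x.size // 10) // 2) + 1)
        xs = _running_median(x, window)
        ys = _running_median(y, window)
        # downsample to well-separated anchors: near-coincident x anchors
        # make the boundary-extension slopes explode
        n_anchor = min(32, xs.size)
        pick = np.unique(np.linspace(0, xs.size - 1, n_anchor).round().astype(int))
        ux, idx = np.unique(xs[pick], return_index=True)
        uy = ys[pick][idx]
        if ux.size < 4:
            fallbacks.append(s)
            if means[j] > 0:
                out[:, j] = col * (means[ref_j] / means[j])
            continue
        out[:, j] = _monotone_map(ux, uy)(col)
    return NormalizationResult(
        matrix=m,
        signal=out,
        strategy="rank_invariant",
        diagnostics={
            "reference_sample": m.sample_ids[ref_j],
            "invariant_set_sizes": {s: len(v) for s, v in invariant_sets.items()},
            "invariant_sets": invariant_sets,
            "fallback_samples": fallbacks,
        },
    )


STRATEGIES: dict[str, Callable[..., NormalizationResult]] = {
    "none": normalize_none,
    "average": normalize_average,
    "quantile": normalize_quantile,
    "cubic_spline": normalize_cubic_spline,
    "rank_invariant": normalize_rank_invariant,
}


def normalize(m: BeadSummaryMatrix, strategy: str, **kwargs) -> NormalizationResult:
    """Dispatch to one of the five strategies by name."""
    try:
        fn = STRATEGIES[strategy]
    except KeyError:
        raise ValueError(
            f"unknown strategy {strategy!r}; choose from {sorted(STRATEGIES)}"
        ) from None
    return fn(m, **kwargs)
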