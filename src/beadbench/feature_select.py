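"""Max Cover (alpha,beta)-k feature selection on discretized expression data.

Stage 1 binarizes each probe with an entropy-minimizing single split and
keeps only probes passing the minimum-description-length acceptance test.
Stage 2 compares every pair of samples: a retained feature covers an
inter-class pair when its binary values differ across the pair, and an
intra-class pair when they agree.  A feature set is feasible at (alpha,
beta) when every inter-class pair is covered by at least alpha selected
features and every intra-class pair by at least beta.  A greedy multicover
solver is the workhorse; an exhaustive solver (guarded to small instances)
serves as an exact oracle.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .diffexp import ProbeScore, ProbeSet
from .io_bead import ClassLabels
from .normalize import NormalizationResult

__all__ = [
    "DiscretizationResult",
    "DiscretizedMatrix",
    "PairCoverage",
    "FeatureSetParams",
    "FeatureSetSolution",
    "InfeasibleError",
    "fayyad_irani_discretize",
    "discretize_matrix",
    "build_coverage",
    "max_alpha_beta",
    "solve_feature_set",
    "maxcover_de",
]

EXACT_MAX_FEATURES = 20
EXACT_MAX_SAMPLES = 10


class InfeasibleError(ValueError):
    """Requested (alpha, beta) cannot be met by the available features."""


class DiscretizationResult(NamedTuple):
    threshold: float | None
    accepted: bool
    gain: float


def _entropy(labels: Sequence[str]) -> float:
    """Class-information entropy in bits."""
    n = len(labels)
    if n == 0:
        return 0.0
    _, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    p = counts / n
    return float(-(p * np.log2(p)).sum())


def fayyad_irani_discretize(
    values: Sequence[float], classes: Sequence[str]
) -> DiscretizationResult:
    """Entropy-minimizing binary split with MDL accept/reject.

    Candidate cuts are midpoints between consecutive distinct sorted values
    that are class-boundary points.  The cut minimizing the weighted
    class-information entropy is chosen (lowest cut on ties) and accepted
    iff  Gain > log2(N-1)/N + Delta/N  with
    Delta = log2(3^c - 2) - [c*Ent(S) - c1*Ent(S1) - c2*Ent(S2)].
    Constant features have no candidate cut and are rejected, not raised.
    """
    values = np.asarray(values, dtype=float)
    classes = list(classes)
    n = values.size
    if n != len(classes):
        raise ValueError("values and classes must have equal length")
    if n < 2 or len(set(classes)) < 2:
        return DiscretizationResult(None, False, 0.0)

    order = np.argsort(values, kind="stable")
    v = values[order]
    y = [classes[i] for i in order]

    # group by distinct value; record the class set at each distinct value
    distinct: list[float] = []
    class_sets: list[set[str]] = []
    i = 0
    while i < n:
        j = i
        while j < n and v[j] == v[i]:
            j += 1
        distinct.append(float(v[i]))
        class_sets.append(set(y[i:j]))
        i = j
    if len(distinct) < 2:
        return DiscretizationResult(None, False, 0.0)

    ent_s = _entropy(y)
    c = len(set(y))
    best: tuple[float, float] | None = None  # (weighted entropy, cut)
    best_parts: tuple[list[str], list[str]] | None = None
    for t in range(len(distinct) - 1):
        left_set, right_set = class_sets[t], class_sets[t + 1]
        # boundary point: not both sides the same pure class
        if len(left_set) == 1 and left_set == right_set:
            continue
        cut = (distinct[t] + distinct[t + 1]) / 2.0
        mask = v <= cut
        s1 = [y[i] for i in range(n) if mask[i]]
        s2 = [y[i] for i in range(n) if not mask[i]]
        e = (len(s1) / n) * _entropy(s1) + (len(s2) / n) * _entropy(s2)
        if best is None or e < best[0] - 1e-15 or (abs(e - best[0]) <= 1e-15 and cut < best[1]):
            best = (e, cut)
            best_parts = (s1, s2)
    if best is None:
        return DiscretizationResult(None, False, 0.0)

    e_best, cut = best
    s1, s2 = best_parts
    gain = ent_s - e_best
    c1, c2 = len(set(s1)), len(set(s2))
    delta = math.log2(3**c - 2) - (
        c * ent_s - c1 * _entropy(s1) - c2 * _entropy(s2)
    )
    bound = math.log2(n - 1) / n + delta / n
    return DiscretizationResult(cut, gain > bound, gain)


@dataclass
class DiscretizedMatrix:
    """Binary features x samples matrix surviving the MDL filter."""

    feature_ids: list[str]  # retained, in input order
    sample_ids: list[str]
    binary: np.ndarray  # len(feature_ids) x len(sample_ids), entries {0,1}
    thresholds: dict[str, float]
    gains: dict[str, float]
    dropped: set[str] = field(default_factory=set)

    @property
    def retained(self) -> set[str]:
        return set(self.feature_ids)

    def __post_init__(self) -> None:
        self.binary = np.asarray(self.binary, dtype=np.int8)
        if self.binary.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("binary matrix shape mismatch")
        if self.binary.size and not np.isin(self.binary, (0, 1)).all():
            raise ValueError("binary matrix entries must be 0/1")


def discretize_matrix(
    norm: NormalizationResult, labels: ClassLabels
) -> DiscretizedMatrix:
    """Apply the entropy/MDL binarization to every probe."""
    labels.validate_for(norm.matrix)
    classes = labels.label_vector(norm.sample_ids)
    feature_ids: list[str] = []
    rows: list[np.ndarray] = []
    thresholds: dict[str, float] = {}
    gains: dict[str, float] = {}
    dropped: set[str] = set()
    for i, probe in enumerate(norm.probe_ids):
        res = fayyad_irani_discretize(norm.signal[i, :], classes)
        if res.accepted:
            feature_ids.append(probe)
            thresholds[probe] = float(res.threshold)
            gains[probe] = res.gain
            rows.append((norm.signal[i, :] > res.threshold).astype(np.int8))
        else:
            dropped.add(probe)
    binary = np.vstack(rows) if rows else np.empty((0, len(norm.sample_ids)), dtype=np.int8)
    return DiscretizedMatrix(
        feature_ids=feature_ids,
        sample_ids=list(norm.sample_ids),
        binary=binary,
        thresholds=thresholds,
        gains=gains,
        dropped=dropped,
    )


Pair = tuple[int, int]


@dataclass
class PairCoverage:
    """Which features discriminate (inter) or agree on (intra) each sample pair."""

    sample_ids: list[str]
    inter_pairs: list[Pair]
    intra_pairs: list[Pair]
    covers: dict[str, set[Pair]]
    feature_ids: list[str]  # deterministic feature order


def build_coverage(d: DiscretizedMatrix, labels: ClassLabels) -> PairCoverage:
    """Enumerate all C(n,2) sample pairs and each feature's covered pairs."""
    classes = labels.label_vector(d.sample_ids)
    n = len(d.sample_ids)
    inter: list[Pair] = []
    intra: list[Pair] = []
    for i, j in itertools.combinations(range(n), 2):
        (inter if classes[i] != classes[j] else intra).append((i, j))
    covers: dict[str, set[Pair]] = {}
    for f_idx, feature in enumerate(d.feature_ids):
        row = d.binary[f_idx]
        cov: set[Pair] = set()
        for i, j in inter:
            if row[i] != row[j]:
                cov.add((i, j))
        for i, j in intra:
            if row[i] == row[j]:
                cov.add((i, j))
        covers[feature] = cov
    return PairCoverage(
        sample_ids=list(d.sample_ids),
        inter_pairs=inter,
        intra_pairs=intra,
        covers=covers,
        feature_ids=list(d.feature_ids),
    )


@dataclass
class FeatureSetParams:
    alpha: int
    beta: int
    k: int

    def __post_init__(self) -> None:
        if self.beta < 0 or self.k < 0:
            raise ValueError("beta and k must be >= 0")


@dataclass
class FeatureSetSolution:
    features: list[str]
    params: FeatureSetParams
    total_coverage: int
    feasible: bool
    solver: str  # "greedy" | "exact"


def _cover_counts(cov: PairCoverage, features: Sequence[str] | None = None) -> dict[Pair, int]:
    feats = cov.feature_ids if features is None else features
    counts: dict[Pair, int] = {p: 0 for p in cov.inter_pairs + cov.intra_pairs}
    for f in feats:
        for pair in cov.covers[f]:
            counts[pair] += 1
    return counts


def max_alpha_beta(cov: PairCoverage) -> FeatureSetParams:
    """(alpha, beta) ceiling achievable using all retained features."""
    counts = _cover_counts(cov)
    alpha_max = min((counts[p] for p in cov.inter_pairs), default=0)
    beta_max = min((counts[p] for p in cov.intra_pairs), default=0)
    return FeatureSetParams(alpha=alpha_max, beta=beta_max, k=len(cov.feature_ids))


def _demands(cov: PairCoverage, alpha: int, beta: int) -> dict[Pair, int]:
    d = {p: alpha for p in cov.inter_pairs}
    d.update({p: beta for p in cov.intra_pairs})
    return d


def _is_feasible(cov: PairCoverage, features: Sequence[str], alpha: int, beta: int) -> bool:
    counts = _cover_counts(cov, features)
    return all(counts[p] >= alpha for p in cov.inter_pairs) and all(
        counts[p] >= beta for p in cov.intra_pairs
    )


def _total_coverage(cov: PairCoverage, features: Sequence[str], alpha: int, beta: int) -> int:
    """Met demand plus surplus coverage (= total covers by selected features)."""
    counts = _cover_counts(cov, features)
    needed = _demands(cov, alpha, beta)
    met = sum(min(c, needed[p]) for p, c in counts.items())
    surplus = sum(max(0, c - needed[p]) for p, c in counts.items())
    return met + surplus


def _greedy(cov: PairCoverage, alpha: int, beta: int, k: int | None) -> list[str]:
    remaining = {p: d for p, d in _demands(cov, alpha, beta).items() if d > 0}
    selected: list[str] = []
    available = list(cov.feature_ids)  # ascending id order = tie-break order
    while any(remaining.values()):
        best_f, best_score = None, -1
        for f in available:
            score = sum(1 for pair in cov.covers[f] if remaining.get(pair, 0) > 0)
            if score > best_score:
                best_f, best_score = f, score
        if best_f is None or best_score == 0:
            raise InfeasibleError("greedy cannot meet remaining pair demands")
        selected.append(best_f)
        available.remove(best_f)
        for pair in cov.covers[best_f]:
            if remaining.get(pair, 0) > 0:
                remaining[pair] -= 1
    if k is not None:
        if k < len(selected):
            raise InfeasibleError(
                f"k={k} below minimal feasible greedy size {len(selected)}"
            )
        while len(selected) < k and available:
            best_f, best_score = None, -1
            for f in available:
                score = len(cov.covers[f])
                if score > best_score:
                    best_f, best_score = f, score
            selected.append(best_f)
            available.remove(best_f)
    return selected


def _exact_min_k(cov: PairCoverage, alpha: int, beta: int) -> list[str]:
    feats = cov.feature_ids
    for k in range(0, len(feats) + 1):
        for subset in itertools.combinations(feats, k):
            if _is_feasible(cov, subset, alpha, beta):
                return list(subset)
    raise InfeasibleError("no feasible subset")  # pragma: no cover


def _exact_max_cover(cov: PairCoverage, alpha: int, beta: int, k: int) -> list[str]:
    best: tuple[int, tuple[str, ...]] | None = None
    for subset in itertools.combinations(cov.feature_ids, k):
        if not _is_feasible(cov, subset, alpha, beta):
            continue
        tc = _total_coverage(cov, subset, alpha, beta)
        if best is None or tc > best[0]:
            best = (tc, subset)
    if best is None:
        raise InfeasibleError(f"no feasible subset of size {k}")
    return list(best[1])


def solve_feature_set(
    cov: PairCoverage,
    params: FeatureSetParams,
    mode: str = "min_k",
    solver: str = "greedy",
) -> FeatureSetSolution:
    """Select a feature set meeting the (alpha, beta) pair-coverage demands.

    ``min_k`` finds a small feasible set; ``max_cover`` extends to exactly
    ``params.k`` features maximizing surplus coverage.  The exact solver is
    an exhaustive oracle guarded to small instances.
    """
    if mode not in ("min_k", "max_cover"):
        raise ValueError(f"unknown mode {mode!r}")
    ceiling = max_alpha_beta(cov)
    if params.alpha > ceiling.alpha or params.beta > ceiling.beta:
        raise InfeasibleError(
            f"requested (alpha={params.alpha}, beta={params.beta}) exceeds "
            f"achievable (alpha={ceiling.alpha}, beta={ceiling.beta})"
        )
    if solver == "exact":
        if len(cov.feature_ids) > EXACT_MAX_FEATURES or len(cov.sample_ids) > EXACT_MAX_SAMPLES:
            raise ValueError(
                "exact solver guarded to <= "
                f"{EXACT_MAX_FEATURES} features / {EXACT_MAX_SAMPLES} samples"
            )
        if mode == "min_k":
            features = _exact_min_k(cov, params.alpha, params.beta)
        else:
            features = _exact_max_cover(cov, params.alpha, params.beta, params.k)
    elif solver == "greedy":
        features = _greedy(cov, params.alpha, params.beta,
                           params.k if mode == "max_cover" else None)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    feasible = _is_feasible(cov, features, params.alpha, params.beta)
    return FeatureSetSolution(
        features=features,
        params=FeatureSetParams(alpha=params.alpha, beta=params.beta, k=len(features)),
        total_coverage=_total_coverage(cov, features, params.alpha, params.beta),
        feasible=feasible,
        solver=solver,
    )


def maxcover_de(
    norm: NormalizationResult,
    labels: ClassLabels,
    alpha: int | None = None,
    beta: int | None = None,
    k: int | None = None,
    mode: str = "max_cover",
    solver: str = "greedy",
) -> ProbeSet:
    """Full pipeline: discretize -> coverage -> (alpha,beta) -> solve.

    Defaults target the (alpha, beta) ceiling of the retained features; the
    resulting feature set becomes the ProbeSet (score = discretization
    gain, no p-values).
    """
    d = discretize_matrix(norm, labels)
    provenance = {
        "strategy": norm.strategy,
        "approach": "maxcover",
        "background_corrected": norm.matrix.background_corrected,
        "n_retained": len(d.feature_ids),
        "n_dropped": len(d.dropped),
    }
    if not d.feature_ids:
        warnings.warn("no features survived MDL discretization; empty solution",
                      stacklevel=2)
        return ProbeSet(probe_ids=[], scores={}, provenance=provenance)
    cov = build_coverage(d, labels)
    ceiling = max_alpha_beta(cov)
    a = ceiling.alpha if alpha is None else alpha
    b = ceiling.beta if beta is None else beta
    if k is None:
        # without a target k the max-cover extension adds nothing beyond
        # the greedy-minimal feasible set
        sol = solve_feature_set(cov, FeatureSetParams(a, b, 0), mode="min_k",
                                solver=solver)
    else:
        sol = solve_feature_set(cov, FeatureSetParams(a, b, k), mode=mode,
                                solver=solver)
    provenance.update({"alpha": a, "beta": b, "k": sol.params.k,
                       "mode": mode, "solver": sol.solver})

    idx_c, idx_t = labels.group_indices(norm.sample_ids)
    probe_index = {p: i for i, p in enumerate(norm.probe_ids)}
    probe_ids = sorted(sol.features)
    scores: dict[str, ProbeScore] = {}
    for p in probe_ids:
        i = probe_index[p]
        diff = norm.signal[i, idx_t].mean() - norm.signal[i, idx_c].mean()
        direction = "up" if diff > 0 else ("down" if diff < 0 else "none")
        scores[p] = ProbeScore(float(d.gains[p]), None, direction)
    return ProbeSet(probe_ids=probe_ids, scores=scores, provenance=provenance)
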