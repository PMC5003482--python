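"""Statistical differential-expression tests producing probe sets.

Two approaches are provided: a pooled-variance unpaired t-test (Welch by
flag) and a surrogate three-component error-model z-test combining
across-replicate biological variance, bead-level technical variance and a
non-specific floor estimated from negative controls.  The surrogate honors
the three-component structure of the proprietary original but makes no
claim of numerical equivalence; its provenance is tagged accordingly.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .io_bead import ClassLabels
from .normalize import NormalizationResult

__all__ = ["ProbeScore", "ProbeSet", "TestResult", "ttest_de", "illumina_custom_de",
           "bh_adjust"]


class ProbeScore(NamedTuple):
    statistic: float
    p_value: float | None
    direction: str  # "up" | "down" | "none" (test relative to control)


@dataclass
class TestResult:
    """Full per-probe test record (kept for diagnostics)."""

    statistic: float
    p_value: float
    mean_control: float
    mean_test: float
    var_control: float
    var_test: float
    tech_var: float = 0.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class ProbeSet:
    """An identified set of probes with per-probe scores and provenance."""

    probe_ids: list[str]
    scores: dict[str, ProbeScore] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe in ProbeSet")

    def __len__(self) -> int:
        return len(self.probe_ids)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self._member_set()

    def _member_set(self) -> set[str]:
        cache = getattr(self, "_members", None)
        if cache is None or len(cache) != len(self.probe_ids):
            cache = set(self.probe_ids)
            object.__setattr__(self, "_members", cache)
        return cache

    @property
    def members(self) -> set[str]:
        return set(self.probe_ids)

    def write_table(self, path: str | Path) -> None:
        lines = [f"# provenance {json.dumps(self.provenance, sort_keys=True)}"]
        lines.append("probe_id\tstatistic\tp_value\tdirection")
        for p in self.probe_ids:
            sc = self.scores.get(p, ProbeScore(float("nan"), None, "none"))
            pv = "" if sc.p_value is None else repr(float(sc.p_value))
            lines.append(f"{p}\t{repr(float(sc.statistic))}\t{pv}\t{sc.direction}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_table(cls, path: str | Path) -> "ProbeSet":
        provenance: dict = {}
        rows: list[str] = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("# provenance "):
                provenance = json.loads(line[len("# provenance "):])
            elif line.strip() and not line.startswith("#"):
                rows.append(line)
        probe_ids: list[str] = []
        scores: dict[str, ProbeScore] = {}
        for line in rows[1:]:  # skip header
            probe, stat, pv, direction = line.split("\t")
            probe_ids.append(probe)
            scores[probe] = ProbeScore(
                float(stat), None if pv == "" else float(pv), direction
            )
        return cls(probe_ids=probe_ids, scores=scores, provenance=provenance)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _directions(diff: np.ndarray) -> list[str]:
    return ["up" if d > 0 else ("down" if d < 0 else "none") for d in diff]


def _build_probe_set(
    norm: NormalizationResult,
    p: np.ndarray,
    stat: np.ndarray,
    diff: np.ndarray,
    alpha: float,
    approach: str,
    fdr: str | None,
    extra_provenance: dict | None = None,
) -> ProbeSet:
    p_sel = bh_adjust(p) if fdr == "bh" else p
    keep = np.flatnonzero(p_sel < alpha)
    dirs = _directions(diff)
    probe_ids = [norm.probe_ids[i] for i in keep]
    scores = {
        norm.probe_ids[i]: ProbeScore(float(stat[i]), float(p[i]), dirs[i])
        for i in keep
    }
    provenance = {
        "strategy": norm.strategy,
        "approach": approach,
        "alpha": alpha,
        "fdr": fdr,
        "background_corrected": norm.matrix.background_corrected,
    }
    if extra_provenance:
        provenance.update(extra_provenance)
    return ProbeSet(probe_ids=probe_ids, scores=scores, provenance=provenance)


def ttest_de(
    norm: NormalizationResult,
    labels: ClassLabels,
    alpha: float = 0.05,
    welch: bool = False,
    fdr: str | None = None,
) -> ProbeSet:
    """Two-sided unpaired t-test per probe; inclusion at p < alpha.

    Pooled-variance Student by default; no multiple-testing correction
    unless ``fdr='bh'``.  Zero pooled variance yields p=1 for equal means
    and p=0 (flagged degenerate) otherwise.
    """
    labels.validate_for(norm.matrix)
    idx_c, idx_t = labels.group_indices(norm.sample_ids)
    if idx_c.size < 2 or idx_t.size < 2:
        raise ValueError("need >= 2 samples per class for a t-test")
    xc = norm.signal[:, idx_c]
    xt = norm.signal[:, idx_t]
    nc, nt = idx_c.size, idx_t.size
    mc, mt = xc.mean(axis=1), xt.mean(axis=1)
    vc, vt = xc.var(axis=1, ddof=1), xt.var(axis=1, ddof=1)
    diff = mt - mc

    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se2 = vc / nc + vt / nt
            t = diff / np.sqrt(se2)
            df = se2**2 / ((vc / nc) ** 2 / (nc - 1) + (vt / nt) ** 2 / (nt - 1))
        else:
            sp2 = ((nc - 1) * vc + (nt - 1) * vt) / (nc + nt - 2)
            t = diff / np.sqrt(sp2 * (1 / nc + 1 / nt))
            df = np.full_like(t, float(nc + nt - 2))
        p = 2.0 * stats.t.sf(np.abs(t), df)

    degenerate = ~np.isfinite(t)
    zero_var_equal = degenerate & (diff == 0)
    zero_var_diff = degenerate & (diff != 0)
    t[zero_var_equal], p[zero_var_equal] = 0.0, 1.0
    t[zero_var_diff] = np.sign(diff[zero_var_diff]) * np.inf
    p[zero_var_diff] = 0.0
    if np.any(zero_var_diff):
        warnings.warn(
            f"{int(zero_var_diff.sum())} probe(s) with zero pooled variance "
            "and unequal means: p set to 0", stacklevel=2,
        )

    return _build_probe_set(
        norm, p, t, diff, alpha, "ttest", fdr,
        {"variant": "welch" if welch else "pooled"},
    )


def illumina_custom_de(
    norm: NormalizationResult,
    labels: ClassLabels,
    alpha: float = 0.05,
    fdr: str | None = None,
) -> ProbeSet:
    """Surrogate three-component error-model z-test.

    Per group: var = biological (across-replicate) variance + mean squared
    bead SE (rescaled by each sample's effective normalization factor) + a
    non-specific floor (variance of negative-control means across samples).
    """
    labels.validate_for(norm.matrix)
    idx_c, idx_t = labels.group_indices(norm.sample_ids)
    if idx_c.size < 2 or idx_t.size < 2:
        raise ValueError("need >= 2 samples per class")
    xc = norm.signal[:, idx_c]
    xt = norm.signal[:, idx_t]
    nc, nt = idx_c.size, idx_t.size
    mc, mt = xc.mean(axis=1), xt.mean(axis=1)
    diff = mt - mc

    m = norm.matrix
    if m.bead_se is None:
        warnings.warn("no bead SEs available; technical component set to 0",
                      stacklevel=2)
        tech_c = tech_t = np.zeros(m.n_probes)
    else:
        factors = norm.scale_factors()
        se_scaled = m.bead_se * factors[None, :]
        tech_c = (se_scaled[:, idx_c] ** 2).mean(axis=1)
        tech_t = (se_scaled[:, idx_t] ** 2).mean(axis=1)

    if m.neg_control and len(m.neg_control) > 1:
        neg_means = np.array([m.neg_control[s].mean for s in m.sample_ids
                              if s in m.neg_control])
        floor = float(np.var(neg_means, ddof=1)) if neg_means.size > 1 else 0.0
    else:
        floor = 0.0

    var_c = xc.var(axis=1, ddof=1) + tech_c + floor
    var_t = xt.var(axis=1, ddof=1) + tech_t + floor
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / np.sqrt(var_t / nt + var_c / nc)
        p = 2.0 * stats.norm.sf(np.abs(z))
    degenerate = ~np.isfinite(z)
    zero_eq = degenerate & (diff == 0)
    zero_ne = degenerate & (diff != 0)
    z[zero_eq], p[zero_eq] = 0.0, 1.0
    z[zero_ne] = np.sign(diff[zero_ne]) * np.inf
    p[zero_ne] = 0.0

    return _build_probe_set(
        norm, p, z, diff, alpha, "illumina", fdr,
        {"variant": "surrogate_three_component", "floor_var": floor},
    )
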