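"""Synthetic two-class bead-summary experiments with planted truth.

The generative model is multiplicative on the intensity scale: per-probe
log-normal baselines, log-normal biological replicate noise, a per-array
technical scale factor (optionally an intensity-dependent power distortion),
and additive bead-averaging error with a per-cell standard error.  A chosen
fraction of probes is "unexpressed" and drawn from the same distribution as
the negative-control beads.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_bead import BeadSummaryMatrix, ClassLabels, NegControlSummary, PathwayAnnotation

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "simulate_experiment",
    "simulate_pathways",
    "PRESETS",
]

# Tail-mass presets for the fraction of planted changes above 2-fold,
# emulating tissues where >2-fold changes are rare.
PRESETS = {"heart": 0.021, "brain": 0.004}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic bead-summary generator.

    Defaults are plausibility presets for a low-fold-change two-class
    design; none of them is a measured fact about any real array.
    """

    n_probes: int = 1000
    n_neg_controls: int = 100
    n_per_group: tuple[int, int] = (5, 5)  # (control, test)
    frac_de: float = 0.1
    frac_unexpressed: float = 0.2
    fold_range: tuple[float, float] = (1.1, 2.5)
    fold_gt2_frac: float = PRESETS["heart"]  # tail mass of folds > 2
    frac_up: float = 0.5  # planted changes are up in the test group with this prob.
    baseline_log_mean: float = math.log(2000.0)
    baseline_log_sd: float = 0.5
    bio_cv: float = 0.2
    array_scale_cv: float = 0.1
    array_power_sd: float = 0.0  # per-array power-law distortion exponent sd
    bead_count_mean: float = 30.0
    bead_cv: float = 0.2  # bead-level CV; per-cell SE = bead_cv*value/sqrt(n_beads)
    neg_mean: float = 100.0
    neg_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_de", "frac_unexpressed", "fold_gt2_frac", "frac_up"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_probes", "n_neg_controls"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if min(self.n_per_group) < 1:
            raise ValueError("n_per_group entries must be >= 1")
        for name in ("bio_cv", "array_scale_cv", "bead_cv", "array_power_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.fold_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid fold_range {self.fold_range}")


@dataclass
class PlantedTruth:
    """Ground truth of a simulated experiment.

    ``de_probes`` maps probe id to the realized test/control mean ratio
    (below 1 for down-regulated probes).
    """

    de_probes: dict[str, float]
    expressed_probes: set[str]

    def __post_init__(self) -> None:
        stray = set(self.de_probes) - self.expressed_probes
        if stray:
            raise ValueError(f"DE probes not expressed: {sorted(stray)[:5]}")
        if any(f <= 0 for f in self.de_probes.values()):
            raise ValueError("fold changes must be > 0")


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Log-normal multiplier with mean 1 and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _sample_folds(rng: np.random.Generator, cfg: SimulationConfig, n: int) -> np.ndarray:
    """Log-uniform folds on fold_range with a controlled tail mass above 2."""
    lo, hi = cfg.fold_range
    split = 2.0
    if hi <= split or lo >= split:
        return np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    in_tail = rng.random(n) < cfg.fold_gt2_frac
    folds = np.empty(n)
    folds[~in_tail] = np.exp(rng.uniform(math.log(lo), math.log(split), size=int((~in_tail).sum())))
    folds[in_tail] = np.exp(rng.uniform(math.log(split), math.log(hi), size=int(in_tail.sum())))
    return folds


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[BeadSummaryMatrix, ClassLabels, PlantedTruth]:
    """Generate one two-class experiment; the same seed is bit-reproducible."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_ctrl, n_test = cfg.n_per_group
    n_samples = n_ctrl + n_test
    n_expressed = round(cfg.n_probes * (1.0 - cfg.frac_unexpressed))
    n_de = round(n_expressed * cfg.frac_de)
    if n_de > 0 and n_de >= n_expressed:
        raise ValueError(
            "frac_de leaves no non-DE expressed probes; reduce frac_de or raise n_probes"
        )

    probe_ids = [f"P{i:05d}" for i in range(cfg.n_probes)]
    sample_ids = [f"C{i + 1}" for i in range(n_ctrl)] + [f"T{i + 1}" for i in range(n_test)]
    labels = ClassLabels(
        assignment={s: ("control" if s.startswith("C") else "test") for s in sample_ids}
    )

    expressed_mask = np.zeros(cfg.n_probes, dtype=bool)
    expressed_idx = rng.choice(cfg.n_probes, size=n_expressed, replace=False)
    expressed_mask[expressed_idx] = True
    de_idx = rng.choice(expressed_idx, size=n_de, replace=False) if n_de else np.array([], dtype=int)

    baselines = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=cfg.n_probes)
    folds = _sample_folds(rng, cfg, n_de)
    up = rng.random(n_de) < cfg.frac_up
    ratios = np.where(up, folds, 1.0 / folds)

    # per-probe, per-sample target means
    mu = np.tile(baselines[:, None], (1, n_samples))
    test_cols = np.arange(n_ctrl, n_samples)
    mu[np.ix_(de_idx, test_cols)] *= ratios[:, None]

    scale = _lognormal_unit_mean(rng, cfg.array_scale_cv, n_samples)
    gamma = 1.0 + (rng.normal(0.0, cfg.array_power_sd, n_samples) if cfg.array_power_sd else np.zeros(n_samples))
    pivot = math.exp(cfg.baseline_log_mean)

    bio = _lognormal_unit_mean(rng, cfg.bio_cv, (cfg.n_probes, n_samples))
    values = mu * bio
    if cfg.array_power_sd:
        values = pivot * (values / pivot) ** gamma[None, :]
    values = values * scale[None, :]

    # unexpressed probes mirror the negative-control distribution exactly
    n_unexpr = cfg.n_probes - n_expressed
    unexpr_idx = np.flatnonzero(~expressed_mask)
    values[unexpr_idx, :] = rng.normal(cfg.neg_mean, cfg.neg_sd, size=(n_unexpr, n_samples)) * scale[None, :]

    bead_counts = np.maximum(rng.poisson(cfg.bead_count_mean, size=(cfg.n_probes, n_samples)), 1)
    cell_sd = np.empty_like(values)
    cell_sd[expressed_mask] = cfg.bead_cv * np.abs(values[expressed_mask])
    cell_sd[~expressed_mask] = cfg.neg_sd * scale[None, :]
    bead_se = cell_sd / np.sqrt(bead_counts)
    # bead-averaging noise is added to expressed probes only; unexpressed
    # cells already ARE draws from the (bead-averaged) control distribution
    if cfg.bead_cv > 0:
        noise = rng.normal(0.0, 1.0, size=values.shape) * bead_se
        values[expressed_mask] += noise[expressed_mask]

    neg_values = rng.normal(cfg.neg_mean, cfg.neg_sd, size=(cfg.n_neg_controls, n_samples)) * scale[None, :]
    neg_control = {
        s: NegControlSummary(
            count=cfg.n_neg_controls,
            mean=float(np.mean(neg_values[:, j])),
            sd=float(np.std(neg_values[:, j], ddof=1)) if cfg.n_neg_controls > 1 else 0.0,
            values=neg_values[:, j].copy(),
        )
        for j, s in enumerate(sample_ids)
    }

    matrix = BeadSummaryMatrix(
        probe_ids=probe_ids,
        sample_ids=sample_ids,
        signal=values,
        bead_se=bead_se,
        neg_control=neg_control,
    )
    truth = PlantedTruth(
        de_probes={probe_ids[i]: float(r) for i, r in zip(de_idx, ratios)},
        expressed_probes={probe_ids[i] for i in expressed_idx},
    )
    return matrix, labels, truth


def simulate_pathways(
    truth: PlantedTruth,
    n_pathways: int = 20,
    pathway_size: int = 30,
    enriched_frac: float = 0.25,
    seed: int = 0,
    enriched_de_frac: float = 0.5,
    probe_to_gene: dict[str, str] | None = None,
    background_probes: set[str] | None = None,
) -> PathwayAnnotation:
    """Build a pathway annotation with a planted enrichment signal.

    A fraction ``enriched_frac`` of pathways is composed so that
    ``enriched_de_frac`` of its genes are DE (the rest drawn from non-DE
    genes); the remaining pathways are uniform draws from the background.
    """
    rng = np.random.default_rng(seed)
    if probe_to_gene is None:
        probes = background_probes or truth.expressed_probes
        probe_to_gene = {p: f"g_{p}" for p in sorted(probes)}
    background = set(probe_to_gene.values())
    if pathway_size > len(background):
        raise ValueError(
            f"pathway_size {pathway_size} exceeds background size {len(background)}"
        )
    de_genes = sorted({probe_to_gene[p] for p in truth.de_probes if p in probe_to_gene})
    other_genes = sorted(background - set(de_genes))
    all_genes = sorted(background)

    n_enriched = round(n_pathways * enriched_frac)
    pathways: dict[str, set[str]] = {}
    for i in range(n_pathways):
        pid = f"PW{i:03d}"
        if i < n_enriched and de_genes:
            n_de = min(round(pathway_size * enriched_de_frac), len(de_genes))
            n_other = min(pathway_size - n_de, len(other_genes))
            members = list(rng.choice(de_genes, size=n_de, replace=False))
            members += list(rng.choice(other_genes, size=n_other, replace=False))
        else:
            members = list(rng.choice(all_genes, size=pathway_size, replace=False))
        pathways[pid] = set(members)
    return PathwayAnnotation(
        pathways=pathways, probe_to_gene=dict(probe_to_gene), background=background
    )
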