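"""Background correction, detection p-values, and the expressed-probe filter.

Detection p-values are empirical (add-one) rank probabilities of a probe's
signal against the raw negative-control bead values of the same array:

    p = (#{controls >= signal} + 1) / (N + 1)

They are always computed on uncorrected signals, so background correction
cannot flip detection calls.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .io_bead import BeadSummaryMatrix, ClassLabels

__all__ = [
    "DetectionMatrix",
    "background_correct",
    "detection_pvalues",
    "filter_unexpressed",
]


@dataclass
class DetectionMatrix:
    """Per-cell and per-group detection p-values."""

    probe_ids: list[str]
    sample_ids: list[str]
    detection_p: np.ndarray  # probe x sample
    group_detection_p: np.ndarray  # probe x 2
    group_names: tuple[str, str]
    method: str = "empirical_add_one"

    def __post_init__(self) -> None:
        if self.group_detection_p.shape[1] != 2:
            raise ValueError("group detection matrix must have exactly 2 columns")
        for mat in (self.detection_p, self.group_detection_p):
            if np.any((mat < 0) | (mat > 1)):
                raise ValueError("detection p-values outside [0, 1]")
        self._index = {p: i for i, p in enumerate(self.probe_ids)}

    def group_p(self, probe_id: str) -> tuple[float, float]:
        i = self._index[probe_id]
        return float(self.group_detection_p[i, 0]), float(self.group_detection_p[i, 1])

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self._index


def background_correct(matrix: BeadSummaryMatrix) -> BeadSummaryMatrix:
    """Subtract each array's mean negative-control signal from every probe.

    Negative results are retained as-is; bead SEs are unchanged.  Applying
    the correction twice is an error.
    """
    if matrix.background_corrected:
        raise ValueError("matrix is already background-corrected")
    missing = [s for s in matrix.sample_ids if s not in matrix.neg_control]
    if missing:
        raise ValueError(f"no negative controls for samples {missing}")
    means = np.array([matrix.neg_control[s].mean for s in matrix.sample_ids])
    return replace(
        matrix,
        signal=matrix.signal - means[None, :],
        background_corrected=True,
    )


def detection_pvalues(
    matrix: BeadSummaryMatrix,
    labels: ClassLabels,
    aggregate: str = "mean",
) -> DetectionMatrix:
    """Empirical detection p-values against raw negative-control values.

    ``aggregate`` selects how per-sample p-values combine into a per-group
    value ("mean" or "min").
    """
    if aggregate not in ("mean", "min"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    labels.validate_for(matrix)
    missing = [
        s for s in matrix.sample_ids
        if s not in matrix.neg_control or matrix.neg_control[s].values is None
    ]
    if missing:
        raise ValueError(f"raw negative-control values unavailable for {missing}")

    signal = matrix.signal
    if matrix.background_corrected:
        # undo the mean-subtraction so detection is computed on raw scale
        means = np.array([matrix.neg_control[s].mean for s in matrix.sample_ids])
        signal = signal + means[None, :]

    p = np.empty_like(signal)
    for j, s in enumerate(matrix.sample_ids):
        ctrl = np.sort(matrix.neg_control[s].values)
        n = ctrl.size
        if n < 10:
            warnings.warn(
                f"sample {s!r} has only {n} negative controls; detection "
                "p-values will be coarse", stacklevel=2,
            )
        # #{controls >= x} = n - searchsorted(ctrl, x, side="left")
        ge = n - np.searchsorted(ctrl, signal[:, j], side="left")
        p[:, j] = (ge + 1) / (n + 1)

    idx_c, idx_t = labels.group_indices(matrix.sample_ids)
    agg = np.mean if aggregate == "mean" else np.min
    group = np.column_stack([agg(p[:, idx_c], axis=1), agg(p[:, idx_t], axis=1)])
    return DetectionMatrix(
        probe_ids=list(matrix.probe_ids),
        sample_ids=list(matrix.sample_ids),
        detection_p=p,
        group_detection_p=group,
        group_names=labels.classes,
        method=f"empirical_add_one/{aggregate}",
    )


def filter_unexpressed(probe_set, det: DetectionMatrix, threshold: float = 0.01):
    """Drop probes whose group detection p exceeds ``threshold`` in BOTH groups.

    Applied after differential-expression analysis; returns a new ProbeSet.
    """
    from .diffexp import ProbeSet  # local import avoids a cycle

    missing = [p for p in probe_set.probe_ids if p not in det]
    if missing:
        raise ValueError(f"probes absent from detection matrix: {missing[:5]}")
    kept = [
        p for p in probe_set.probe_ids
        if not all(g > threshold for g in det.group_p(p))
    ]
    provenance = dict(probe_set.provenance)
    provenance["detection_filter"] = threshold
    return ProbeSet(
        probe_ids=kept,
        scores={p: probe_set.scores[p] for p in kept},
        provenance=provenance,
    )
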