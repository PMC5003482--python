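"""Reading and writing bead-summary expression tables and their side files.

The on-disk dialect follows the GenomeStudio "Sample Probe Profile" export
convention: one probe per row, with per-sample column triplets named
``AVG_Signal.<sample>``, ``BEAD_STDERR.<sample>`` and
``Detection Pval.<sample>``.  The statistic/sample separator and the
statistic names themselves can be remapped through a dialect dictionary to
accommodate other export layouts.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BeadFileError",
    "NegControlSummary",
    "BeadSummaryMatrix",
    "ClassLabels",
    "PathwayAnnotation",
    "DEFAULT_DIALECT",
    "read_bead_summary",
    "write_bead_summary",
    "read_neg_controls",
    "write_neg_controls",
    "read_class_labels",
    "write_class_labels",
    "read_gmt",
    "write_gmt",
    "read_probe_gene_map",
    "write_probe_gene_map",
]

DEFAULT_DIALECT: dict[str, str] = {
    "probe_id": "ProbeID",
    "signal": "AVG_Signal",
    "bead_se": "BEAD_STDERR",
    "detection": "Detection Pval",
    "sep": ".",
}


class BeadFileError(ValueError):
    """Raised for malformed bead-summary files or side tables."""


@dataclass
class NegControlSummary:
    """Per-sample summary of negative-control bead signals."""

    count: int
    mean: float
    sd: float
    values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("negative-control count must be >= 1")
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)
            if self.values.size != self.count:
                raise ValueError("neg-control value vector length != count")

    def __eq__(self, other: object) -> bool:  # ndarray needs special-casing
        if not isinstance(other, NegControlSummary):
            return NotImplemented
        same_vals = (self.values is None) == (other.values is None) and (
            self.values is None or np.array_equal(self.values, other.values)
        )
        return (
            self.count == other.count
            and self.mean == other.mean
            and self.sd == other.sd
            and same_vals
        )


@dataclass
class BeadSummaryMatrix:
    """Probes x samples signal matrix with optional bead SE / detection p.

    ``signal`` may contain negative values after background correction;
    ``detection_p`` entries, where present, lie in [0, 1].
    """

    probe_ids: list[str]
    sample_ids: list[str]
    signal: np.ndarray
    bead_se: np.ndarray | None = None
    detection_p: np.ndarray | None = None
    neg_control: dict[str, NegControlSummary] = field(default_factory=dict)
    background_corrected: bool = False

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.probe_ids)) != len(self.probe_ids):
            dup = _first_duplicate(self.probe_ids)
            raise BeadFileError(f"duplicate probe ID: {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise BeadFileError(f"duplicate sample ID: {dup!r}")
        shape = (len(self.probe_ids), len(self.sample_ids))
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.shape != shape:
            raise BeadFileError(
                f"signal shape {self.signal.shape} != (probes, samples) {shape}"
            )
        for name in ("bead_se", "detection_p"):
            mat = getattr(self, name)
            if mat is not None:
                mat = np.asarray(mat, dtype=float)
                if mat.shape != shape:
                    raise BeadFileError(f"{name} shape {mat.shape} != {shape}")
                setattr(self, name, mat)
        if self.detection_p is not None:
            bad = (self.detection_p < 0) | (self.detection_p > 1)
            if np.any(bad):
                raise BeadFileError("detection p-values outside [0, 1]")
        extra = set(self.neg_control) - set(self.sample_ids)
        if extra:
            raise BeadFileError(f"negative controls for unknown samples: {sorted(extra)}")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_index(self, probe_id: str) -> int:
        return self._probe_lookup()[probe_id]

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def _probe_lookup(self) -> dict[str, int]:
        cache = getattr(self, "_probe_lookup_cache", None)
        if cache is None or len(cache) != len(self.probe_ids):
            cache = {p: i for i, p in enumerate(self.probe_ids)}
            object.__setattr__(self, "_probe_lookup_cache", cache)
        return cache

    def with_signal(self, signal: np.ndarray, *, background_corrected: bool | None = None) -> "BeadSummaryMatrix":
        """Copy of this matrix with a replaced signal matrix."""
        corrected = self.background_corrected if background_corrected is None else background_corrected
        return replace(self, signal=np.asarray(signal, dtype=float),
                       background_corrected=corrected)

    def equals(self, other: "BeadSummaryMatrix") -> bool:
        if self.probe_ids != other.probe_ids or self.sample_ids != other.sample_ids:
            return False
        if not np.array_equal(self.signal, other.signal):
            return False
        for name in ("bead_se", "detection_p"):
            a, b = getattr(self, name), getattr(other, name)
            if (a is None) != (b is None):
                return False
            if a is not None and not np.array_equal(a, b):
                return False
        return self.neg_control == other.neg_control


@dataclass
class ClassLabels:
    """Two-class sample assignment (control vs test)."""

    assignment: dict[str, str]
    control_class: str | None = None

    def __post_init__(self) -> None:
        classes = sorted(set(self.assignment.values()))
        if len(classes) != 2:
            raise BeadFileError(f"expected exactly 2 classes, got {classes}")
        if self.control_class is None:
            self.control_class = "control" if "control" in classes else classes[0]
        if self.control_class not in classes:
            raise BeadFileError(f"control class {self.control_class!r} not in {classes}")
        for cls in classes:
            n = sum(1 for v in self.assignment.values() if v == cls)
            if n < 2:
                raise BeadFileError(f"class {cls!r} has {n} sample(s); need >= 2")
            if n < 4:
                warnings.warn(
                    f"class {cls!r} has only {n} replicates; designs with >= 4 "
                    "biological replicates per group are recommended",
                    stacklevel=2,
                )

    @property
    def classes(self) -> tuple[str, str]:
        """(control class, test class)."""
        other = next(c for c in sorted(set(self.assignment.values()))
                     if c != self.control_class)
        return (self.control_class, other)

    @property
    def test_class(self) -> str:
        return self.classes[1]

    def validate_for(self, matrix: BeadSummaryMatrix) -> None:
        missing = [s for s in matrix.sample_ids if s not in self.assignment]
        if missing:
            raise BeadFileError(f"samples without class assignment: {missing}")

    def group_indices(self, sample_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Column indices of (control, test) samples in ``sample_ids`` order."""
        ctrl, test = self.classes
        idx_c = [i for i, s in enumerate(sample_ids) if self.assignment.get(s) == ctrl]
        idx_t = [i for i, s in enumerate(sample_ids) if self.assignment.get(s) == test]
        return np.asarray(idx_c, dtype=int), np.asarray(idx_t, dtype=int)

    def label_vector(self, sample_ids: Sequence[str]) -> list[str]:
        missing = [s for s in sample_ids if s not in self.assignment]
        if missing:
            raise BeadFileError(f"samples without class assignment: {missing}")
        return [self.assignment[s] for s in sample_ids]


@dataclass
class PathwayAnnotation:
    """Gene-set annotation mapped to the array through a probe->gene map."""

    pathways: dict[str, set[str]]
    probe_to_gene: dict[str, str]
    background: set[str]

    def __post_init__(self) -> None:
        for pid, genes in self.pathways.items():
            if not genes:
                raise BeadFileError(f"pathway {pid!r} is empty")
            stray = genes - self.background
            if stray:
                raise BeadFileError(
                    f"pathway {pid!r} has genes outside the background: {sorted(stray)[:5]}"
                )


# ---------------------------------------------------------------------------
# bead-summary profile IO


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    raise ValueError("no duplicate found")


def _fmt(x: float) -> str:
    return repr(float(x))


def _parse_numeric_column(series: pd.Series, column: str, probe_ids: Sequence[str]) -> np.ndarray:
    # float()/np.astype parse correctly rounded; pd.to_numeric does not
    raw = series.to_numpy(dtype=object)
    try:
        return np.array([float(v) for v in raw], dtype=float)
    except (TypeError, ValueError):
        for row, v in enumerate(raw):
            try:
                float(v)
            except (TypeError, ValueError):
                raise BeadFileError(
                    f"non-numeric value {v!r} in column {column!r}, "
                    f"probe {probe_ids[row]!r} (row {row + 2})"
                ) from None
        raise  # pragma: no cover


def read_bead_summary(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    controls_path: str | Path | None = None,
    control_probe_ids: set[str] | None = None,
) -> BeadSummaryMatrix:
    """Parse a tab-delimited bead-summary profile.

    Negative controls are attached either from a per-sample summary table
    (``controls_path``) or by flagging designated probe rows
    (``control_probe_ids``), which are removed from the matrix.
    """
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    sep = d["sep"]
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if d["probe_id"] not in df.columns:
        raise BeadFileError(f"missing probe-ID column {d['probe_id']!r}")
    probe_ids = df[d["probe_id"]].tolist()
    if len(set(probe_ids)) != len(probe_ids):
        raise BeadFileError(f"duplicate probe ID: {_first_duplicate(probe_ids)!r}")

    per_stat: dict[str, dict[str, str]] = {"signal": {}, "bead_se": {}, "detection": {}}
    sample_order: list[str] = []
    for col in df.columns:
        if col == d["probe_id"]:
            continue
        matched = False
        for stat in ("signal", "bead_se", "detection"):
            prefix = d[stat] + sep
            if col == d[stat] or col == prefix:
                raise BeadFileError(f"column {col!r} has no sample name")
            if col.startswith(prefix):
                sample = col[len(prefix):]
                per_stat[stat][sample] = col
                if stat == "signal":
                    sample_order.append(sample)
                matched = True
                break
        if not matched:
            warnings.warn(f"ignoring unrecognized column {col!r}", stacklevel=2)
    if not sample_order:
        raise BeadFileError(f"no {d['signal']!r} columns found")
    for stat in ("bead_se", "detection"):
        stray = set(per_stat[stat]) - set(sample_order)
        if stray:
            raise BeadFileError(
                f"{d[stat]!r} columns for samples without signal: {sorted(stray)}"
            )
        if per_stat[stat] and set(per_stat[stat]) != set(sample_order):
            missing = sorted(set(sample_order) - set(per_stat[stat]))
            raise BeadFileError(f"{d[stat]!r} columns missing for samples {missing}")

    def build(stat: str) -> np.ndarray | None:
        if not per_stat[stat]:
            return None
        cols = [
            _parse_numeric_column(df[per_stat[stat][s]], per_stat[stat][s], probe_ids)
            for s in sample_order
        ]
        return np.column_stack(cols)

    signal = build("signal")
    matrix = BeadSummaryMatrix(
        probe_ids=probe_ids,
        sample_ids=sample_order,
        signal=signal,
        bead_se=build("bead_se"),
        detection_p=build("detection"),
    )
    if control_probe_ids:
        matrix = _split_control_probes(matrix, control_probe_ids)
    if controls_path is not None:
        matrix.neg_control.update(read_neg_controls(controls_path))
        stray = set(matrix.neg_control) - set(matrix.sample_ids)
        if stray:
            raise BeadFileError(f"negative controls for unknown samples: {sorted(stray)}")
    return matrix


def _split_control_probes(matrix: BeadSummaryMatrix, control_ids: set[str]) -> BeadSummaryMatrix:
    missing = control_ids - set(matrix.probe_ids)
    if missing:
        raise BeadFileError(f"control probes not in matrix: {sorted(missing)}")
    keep = np.array([p not in control_ids for p in matrix.probe_ids])
    ctrl_rows = matrix.signal[~keep]
    neg = {
        s: NegControlSummary(
            count=ctrl_rows.shape[0],
            mean=float(np.mean(ctrl_rows[:, j])),
            sd=float(np.std(ctrl_rows[:, j], ddof=1)) if ctrl_rows.shape[0] > 1 else 0.0,
            values=ctrl_rows[:, j].copy(),
        )
        for j, s in enumerate(matrix.sample_ids)
    }
    return BeadSummaryMatrix(
        probe_ids=[p for p in matrix.probe_ids if p not in control_ids],
        sample_ids=matrix.sample_ids,
        signal=matrix.signal[keep],
        bead_se=None if matrix.bead_se is None else matrix.bead_se[keep],
        detection_p=None if matrix.detection_p is None else matrix.detection_p[keep],
        neg_control=neg,
        background_corrected=matrix.background_corrected,
    )


def write_bead_summary(
    matrix: BeadSummaryMatrix,
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    controls_path: str | Path | None = None,
) -> None:
    """Write a bead-summary profile; exact inverse of :func:`read_bead_summary`."""
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    sep = d["sep"]
    header = [d["probe_id"]]
    for s in matrix.sample_ids:
        header.append(f"{d['signal']}{sep}{s}")
        if matrix.bead_se is not None:
            header.append(f"{d['bead_se']}{sep}{s}")
        if matrix.detection_p is not None:
            header.append(f"{d['detection']}{sep}{s}")
    lines = ["\t".join(header)]
    for i, probe in enumerate(matrix.probe_ids):
        row = [probe]
        for j in range(matrix.n_samples):
            row.append(_fmt(matrix.signal[i, j]))
            if matrix.bead_se is not None:
                row.append(_fmt(matrix.bead_se[i, j]))
            if matrix.detection_p is not None:
                row.append(_fmt(matrix.detection_p[i, j]))
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
    if controls_path is not None and matrix.neg_control:
        write_neg_controls(matrix.neg_control, controls_path)


def read_neg_controls(path: str | Path) -> dict[str, NegControlSummary]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "count", "mean", "sd"}
    if not required.issubset(df.columns):
        raise BeadFileError(f"controls table needs columns {sorted(required)}")
    out: dict[str, NegControlSummary] = {}
    for _, row in df.iterrows():
        values = None
        if "values" in df.columns and row["values"].strip():
            values = np.array([float(v) for v in row["values"].split(",")])
        out[row["sample_id"]] = NegControlSummary(
            count=int(row["count"]),
            mean=float(row["mean"]),
            sd=float(row["sd"]),
            values=values,
        )
    return out


def write_neg_controls(neg: Mapping[str, NegControlSummary], path: str | Path) -> None:
    lines = ["sample_id\tcount\tmean\tsd\tvalues"]
    for sample, nc in neg.items():
        vals = "" if nc.values is None else ",".join(_fmt(v) for v in nc.values)
        lines.append(f"{sample}\t{nc.count}\t{_fmt(nc.mean)}\t{_fmt(nc.sd)}\t{vals}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# side tables


def read_class_labels(path: str | Path, control_class: str | None = None) -> ClassLabels:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise BeadFileError("class table needs two columns: sample_id, class")
    assignment = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if len(assignment) != len(df):
        raise BeadFileError("duplicate sample in class table")
    return ClassLabels(assignment=assignment, control_class=control_class)


def write_class_labels(labels: ClassLabels, path: str | Path) -> None:
    lines = ["sample_id\tclass"]
    lines += [f"{s}\t{c}" for s, c in labels.assignment.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path, background: set[str] | None = None,
             probe_to_gene: Mapping[str, str] | None = None) -> PathwayAnnotation:
    """Read a GMT gene-set file (pathway_id, description, genes...)."""
    pathways: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise BeadFileError(f"GMT line has fewer than 3 fields: {line[:60]!r}")
        pathways[parts[0]] = set(g for g in parts[2:] if g)
    p2g = dict(probe_to_gene) if probe_to_gene else {}
    if background is None:
        background = set(p2g.values()) if p2g else set().union(*pathways.values())
    return PathwayAnnotation(pathways=pathways, probe_to_gene=p2g, background=background)


def write_gmt(ann: PathwayAnnotation, path: str | Path) -> None:
    lines = []
    for pid, genes in ann.pathways.items():
        lines.append("\t".join([pid, "na"] + sorted(genes)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_probe_gene_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise BeadFileError("probe->gene map needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_probe_gene_map(p2g: Mapping[str, str], path: str | Path) -> None:
    lines = ["probe_id\tgene_id"]
    lines += [f"{p}\t{g}" for p, g in p2g.items()]
    Path(path).write_text("\n".join(lines) + "\n")
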