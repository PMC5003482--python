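"""Concordance statistics across probe sets and enriched-pathway sets.

NOG is the count of probes shared by two sets; POG is that count as a
percentage of each set's own size.  Across analytical approaches a probe is
fully concordant when every approach found it, partially concordant when at
least two but not all did, and discordant ("none") when only one did.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "OverlapStat",
    "pairwise_overlap",
    "strategy_concordance",
    "approach_concordance",
    "pathway_concordance",
]


@dataclass
class OverlapStat:
    nog: int
    pog_a: float | None  # percent of |A|; None when A is empty
    pog_b: float | None

    def __post_init__(self) -> None:
        for v in (self.pog_a, self.pog_b):
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValueError("POG outside [0, 100]")


def _as_set(s) -> set[str]:
    if isinstance(s, (set, frozenset)):
        return set(s)
    return set(s.probe_ids) if hasattr(s, "probe_ids") else set(s)


def pairwise_overlap(a, b) -> OverlapStat:
    """NOG/POG between two probe sets (ProbeSet objects or plain sets)."""
    sa, sb = _as_set(a), _as_set(b)
    nog = len(sa & sb)
    return OverlapStat(
        nog=nog,
        pog_a=100.0 * nog / len(sa) if sa else None,
        pog_b=100.0 * nog / len(sb) if sb else None,
    )


def strategy_concordance(
    sets: Mapping[str, object], exclude: Iterable[str] = ()
) -> dict[str, dict[str, float]]:
    """Mean NOG / mean POG per strategy over all pairwise comparisons.

    For strategy s, the mean POG uses the percentage attributed to s's own
    set size in each of its pairs.  Empty sets (and explicitly excluded
    strategies) are dropped from all comparisons with a warning.
    """
    usable: dict[str, set[str]] = {}
    for name, s in sets.items():
        if name in exclude:
            continue
        members = _as_set(s)
        if not members:
            warnings.warn(
                f"strategy {name!r} produced an empty set; excluded from "
                "concordance to avoid bias", stacklevel=2,
            )
            continue
        usable[name] = members
    if len(usable) < 2:
        raise ValueError("need >= 2 non-empty strategies for concordance")
    names = sorted(usable)
    out: dict[str, dict[str, float]] = {}
    for s in names:
        nogs: list[int] = []
        pogs: list[float] = []
        for t in names:
            if t == s:
                continue
            ov = pairwise_overlap(usable[s], usable[t])
            nogs.append(ov.nog)
            pogs.append(ov.pog_a)
        out[s] = {
            "mean_nog": sum(nogs) / len(nogs),
            "mean_pog": sum(pogs) / len(pogs),
            "set_size": len(usable[s]),
        }
    return out


def approach_concordance(sets: Mapping[str, object]) -> dict:
    """Classify each probe as full / partial / none across approaches.

    With m approaches: full = found by all m, none = found by exactly one,
    partial = anything in between.
    """
    members = {name: _as_set(s) for name, s in sets.items()}
    m = len(members)
    if m < 2:
        raise ValueError("need >= 2 approaches")
    universe: set[str] = set().union(*members.values())
    multiplicity = {p: sum(p in s for s in members.values()) for p in universe}

    def classify(count: int) -> str:
        if count == m:
            return "full"
        return "none" if count == 1 else "partial"

    probe_class = {p: classify(c) for p, c in multiplicity.items()}
    per_approach: dict[str, dict[str, int]] = {}
    for name, s in members.items():
        counts = {"full": 0, "partial": 0, "none": 0}
        for p in s:
            counts[probe_class[p]] += 1
        counts["total"] = len(s)
        per_approach[name] = counts
    totals = {
        "full": sum(1 for c in multiplicity.values() if classify(c) == "full"),
        "partial": sum(1 for c in multiplicity.values() if classify(c) == "partial"),
        "none": sum(1 for c in multiplicity.values() if classify(c) == "none"),
    }
    return {"per_probe": probe_class, "per_approach": per_approach, "totals": totals}


def pathway_concordance(
    path_sets: Mapping[str, Iterable[str]]
) -> dict[str, dict[str, int]]:
    """Per approach: total enriched pathways and how many are shared with
    at least one other approach."""
    sets = {name: set(s) for name, s in path_sets.items()}
    out: dict[str, dict[str, int]] = {}
    for name, s in sets.items():
        others: set[str] = set().union(
            *(t for n, t in sets.items() if n != name)
        ) if len(sets) > 1 else set()
        out[name] = {
            "total": len(s),
            "concordant": len(s & others),
        }
    return out
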