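"""Hypergeometric pathway over-representation against the array background.

Probes are mapped to genes and de-duplicated (a gene counts once no matter
how many probes hit it); the gene universe is the array background, not the
genome.  An EASE-style variant (k reduced by one in the tail) is available
by flag.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy.stats import hypergeom

from .io_bead import PathwayAnnotation

__all__ = ["EnrichmentResult", "enrich_pathways", "probes_to_genes"]


@dataclass
class EnrichmentResult:
    pathway_id: str
    k: int  # DE genes in pathway
    n: int  # DE genes total
    K: int  # background genes in pathway
    N: int  # background size
    fold_enrichment: float
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.K):
            raise ValueError("k exceeds min(n, K)")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p outside [0, 1]")
        if self.fold_enrichment < 0:
            raise ValueError("fold enrichment < 0")


def probes_to_genes(probes, ann: PathwayAnnotation) -> set[str]:
    """Map a probe collection to background genes, de-duplicated."""
    ids = probes.probe_ids if hasattr(probes, "probe_ids") else probes
    genes = {ann.probe_to_gene[p] for p in ids if p in ann.probe_to_gene}
    return genes & ann.background


def enrich_pathways(
    probes,
    ann: PathwayAnnotation,
    p_threshold: float = 0.05,
    fold_threshold: float | None = None,
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment per pathway, sorted by p.

    p = P[X >= k] for X ~ Hypergeom(N, K, n); with ``ease`` the tail is
    evaluated at max(k-1, 0) for a more conservative score.
    """
    genes = probes_to_genes(probes, ann)
    if not genes:
        warnings.warn("no probes mapped to background genes; empty enrichment",
                      stacklevel=2)
        return []
    n = len(genes)
    N = len(ann.background)
    results: list[EnrichmentResult] = []
    for pid, members in ann.pathways.items():
        in_bg = members & ann.background
        K = len(in_bg)
        k = len(genes & in_bg)
        k_eff = max(k - 1, 0) if ease else k
        p = float(hypergeom.sf(k_eff - 1, N, K, n))  # P[X >= k_eff]
        fold = (k / n) / (K / N) if k else 0.0
        significant = p < p_threshold and (
            fold_threshold is None or fold > fold_threshold
        )
        results.append(
            EnrichmentResult(
                pathway_id=pid, k=k, n=n, K=K, N=N,
                fold_enrichment=fold, p_value=p, significant=significant,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results
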