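"""Hypergeometric over-representation analysis against pathway collections.

A gene list (e.g. the anti-correlated targets of therapy-responsive
miRNAs) is tested one pathway at a time: with a universe of N genes of
which K belong to the pathway and a list of n genes hitting k of them,
the over-representation p-value is the hypergeometric upper tail
P(X >= k).  P-values across the whole multi-source collection are
BH-adjusted jointly and the report keeps pathways with FDR below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

PATHWAY_SOURCES = ("B", "K", "N", "P", "R")  # BioCarta, KEGG, NCI, PANTHER, Reactome

ENRICHMENT_COLUMNS = ["pathway_id", "name", "source", "n_pathway", "n_hits", "p", "fdr", "hit_genes"]


@dataclass
class Pathway:
    pathway_id: str
    name: str
    source: str
    genes: frozenset

    def __post_init__(self) -> None:
        if self.source not in PATHWAY_SOURCES:
            raise ValueError(f"unknown pathway source tag: {self.source!r}")
        if not self.genes:
            raise ValueError(f"pathway {self.pathway_id!r} has an empty gene set")
        self.genes = frozenset(self.genes)


@dataclass
class PathwayCollection:
    """Multi-source pathway gene sets plus the background universe.

    The default universe is the union of all pathway genes — the most
    conservative choice when the assay background is unknown; pass
    ``universe`` explicitly to use the measured gene space instead.
    """

    pathways: list[Pathway]
    universe: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.pathways:
            raise ValueError("empty pathway collection")
        ids = [p.pathway_id for p in self.pathways]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate pathway ids")
        union = frozenset().union(*(p.genes for p in self.pathways))
        if not self.universe:
            self.universe = union
        else:
            self.universe = frozenset(self.universe)
            stray = union - self.universe
            if stray:
                raise ValueError(
                    f"pathway genes outside the universe: {sorted(stray)[:5]}"
                )


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: N={N}, K={K}, n={n}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


class EnrichmentAnalysis:
    """Over-representation model of a gene list against a pathway collection."""

    def __init__(self, gene_list, collection: PathwayCollection, alpha: float = 0.05):
        self.gene_list = set(gene_list)
        self.collection = collection
        self.alpha = float(alpha)
        self.hits_in_universe = self.gene_list & collection.universe
        if not self.hits_in_universe:
            raise ValueError("gene list does not intersect the universe")

    def fit(self) -> "EnrichmentResults":
        N = len(self.collection.universe)
        n = len(self.hits_in_universe)
        rows = []
        for pw in self.collection.pathways:
            hit = sorted(self.hits_in_universe & pw.genes)
            k, K = len(hit), len(pw.genes)
            rows.append(
                {
                    "pathway_id": pw.pathway_id,
                    "name": pw.name,
                    "source": pw.source,
                    "n_pathway": K,
                    "n_hits": k,
                    "p": hypergeom_upper(N, K, n, k),
                    "hit_genes": hit,
                }
            )
        full = pd.DataFrame(rows)
        full["fdr"] = bh_adjust(full["p"].to_numpy())
        full = full[ENRICHMENT_COLUMNS]
        return EnrichmentResults(self, full)


class EnrichmentResults:
    """Full per-pathway table; ``table`` is the FDR-filtered, p-sorted report."""

    def __init__(self, model: EnrichmentAnalysis, full_table: pd.DataFrame):
        self.model = model
        self.full_table = full_table

    @property
    def table(self) -> pd.DataFrame:
        t = self.full_table[self.full_table["fdr"] < self.model.alpha]
        return t.sort_values(["p", "name"]).reset_index(drop=True)

    def summary(self, top: int = 15) -> str:
        t = self.table.head(top).copy()
        t["hit_genes"] = t["hit_genes"].map(lambda g: ",".join(g))
        lines = [
            "Pathway over-representation (hypergeometric upper tail, BH-FDR "
            f"< {self.model.alpha:g})",
            f"universe: {len(self.model.collection.universe)} genes   "
            f"list in universe: {len(self.model.hits_in_universe)}   "
            f"pathways tested: {len(self.full_table)}   "
            f"enriched: {len(self.table)}",
            "",
            t.to_string(index=False, float_format=lambda v: f"{v:.3g}")
            if len(t) else "(no enriched pathway)",
        ]
        return "\n".join(lines)


def enrich(gene_list, collection: PathwayCollection, alpha: float = 0.05) -> pd.DataFrame:
    """Functional wrapper returning the filtered enrichment report table."""
    return EnrichmentAnalysis(gene_list, collection, alpha).fit().table
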