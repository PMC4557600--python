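"""miRNA-mRNA anti-correlation network construction.

Because a miRNA represses its targets, a candidate regulatory interaction
is a miRNA-mRNA pair whose expression profiles anti-correlate across
samples: Pearson r in [-1, -0.5] flags an edge.  The resulting binary
matrix carries a network-level false detection rate estimated by a
permutation test (mRNA sample columns shuffled relative to the miRNA
columns), and edges are restricted to interactions validated with strong
or NGS-level experimental evidence in an interaction database.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .design import ExpressionMatrix, SampleDesign

EVIDENCE_LEVELS = ("strong", "NGS", "weak")
ADMITTED_EVIDENCE = ("strong", "NGS")

EDGE_COLUMNS = [
    "miRNA_id", "gene_id", "r", "miRNA_direction", "gene_direction", "validated",
]


@dataclass
class InteractionDB:
    """Validated miRNA-target records with an evidence annotation.

    Emulates a curated interaction database: one row per (miRNA_id,
    gene_id) with ``evidence`` in {strong, NGS, weak}; only strong/NGS
    records admit a network edge.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        need = ["miRNA_id", "gene_id", "evidence"]
        missing = [c for c in need if c not in self.records.columns]
        if missing:
            raise ValueError(f"interaction DB missing columns: {missing}")
        r = self.records.reset_index(drop=True).copy()
        if r[["miRNA_id", "gene_id"]].duplicated().any():
            raise ValueError("duplicate (miRNA_id, gene_id) record")
        bad = set(r["evidence"]) - set(EVIDENCE_LEVELS)
        if bad:
            raise ValueError(f"unknown evidence levels: {sorted(bad)}")
        self.records = r

    def __len__(self) -> int:
        return len(self.records)

    def admitted_pairs(self) -> set[tuple[str, str]]:
        ok = self.records["evidence"].isin(ADMITTED_EVIDENCE)
        return set(map(tuple, self.records.loc[ok, ["miRNA_id", "gene_id"]].to_numpy()))


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    """Row-standardize; rows with zero variance become all-NaN."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mu) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = np.nan
    return z


def correlation_matrix(
    mi: ExpressionMatrix,
    mr: ExpressionMatrix,
    features_mi=None,
    features_mr=None,
) -> pd.DataFrame:
    """Pearson correlation of each miRNA (rows) with each mRNA (columns).

    Both matrices must share the same ordered sample set (all samples of
    one cell line, both conditions).  Zero-variance features yield NaN
    entries, signalling an undefined correlation for those pairs.
    """
    if list(mi.sample_ids) != list(mr.sample_ids):
        raise ValueError("miRNA and mRNA matrices must share an identical ordered sample set")
    if features_mi is not None:
        mi = mi.subset_features(features_mi)
    if features_mr is not None:
        mr = mr.subset_features(features_mr)
    if not mi.feature_ids or not mr.feature_ids:
        raise ValueError("feature sets must be nonempty")
    n = len(mi.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 shared samples")
    X = _zscore_rows(mi.values.to_numpy())
    Y = _zscore_rows(mr.values.to_numpy())
    C = X @ Y.T / n
    return pd.DataFrame(np.clip(C, -1.0, 1.0), index=mi.feature_ids, columns=mr.feature_ids)


def binarize(corr: pd.DataFrame, threshold: float = -0.5) -> pd.DataFrame:
    """1 where the correlation is defined and <= threshold, else 0.

    The edge criterion is inclusive at the threshold (-1 <= r <= -0.5 by
    default); undefined (NaN) entries never become edges.
    """
    if not -1.0 <= threshold < 0.0:
        raise ValueError(f"threshold must lie in [-1, 0): {threshold}")
    vals = corr.to_numpy() if isinstance(corr, pd.DataFrame) else np.asarray(corr, dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (np.abs(finite) > 1 + 1e-12).any():
        raise ValueError("correlation entries must lie in [-1, 1]")
    b = np.where(np.isfinite(vals) & (vals <= threshold), 1, 0)
    if isinstance(corr, pd.DataFrame):
        return pd.DataFrame(b, index=corr.index, columns=corr.columns)
    return b


def edges_from_correlation(corr: pd.DataFrame, threshold: float = -0.5) -> pd.DataFrame:
    """Edge list (miRNA_id, gene_id, r) for entries passing the threshold."""
    b = binarize(corr, threshold).to_numpy().astype(bool)
    ii, jj = np.nonzero(b)
    return pd.DataFrame(
        {
            "miRNA_id": corr.index.to_numpy()[ii],
            "gene_id": corr.columns.to_numpy()[jj],
            "r": corr.to_numpy()[ii, jj],
        }
    )


def permutation_fdr(
    mi: ExpressionMatrix,
    mr: ExpressionMatrix,
    threshold: float = -0.5,
    n_permutations: int = 1000,
    seed: int = 0,
    features_mi=None,
    features_mr=None,
    groups=None,
) -> tuple[float | None, np.ndarray]:
    """Network-level false detection rate from a sample-permutation null.

    For each of B permutations the mRNA matrix's sample columns are
    shuffled relative to the miRNA columns (preserving each layer's
    internal covariance while destroying the cross-layer alignment) and
    the binarized edge count is recomputed.  The FDR is the mean null
    edge count divided by the observed count; ``None`` when no edge is
    observed.

    ``groups`` optionally assigns each sample (in column order) to an
    exchangeable block — e.g. the biological replicate, whose technical
    replicates are correlated and must travel together.  Blocks must be
    equally sized; whole blocks are then permuted, keeping the null
    distribution comparable to the observed one under nested replication.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if list(mi.sample_ids) != list(mr.sample_ids):
        raise ValueError("miRNA and mRNA matrices must share an identical ordered sample set")
    if features_mi is not None:
        mi = mi.subset_features(features_mi)
    if features_mr is not None:
        mr = mr.subset_features(features_mr)
    n = len(mi.sample_ids)
    X = _zscore_rows(mi.values.to_numpy())
    Y = _zscore_rows(mr.values.to_numpy())

    if groups is not None:
        groups = np.asarray(groups)
        if groups.shape != (n,):
            raise ValueError("groups must assign one block per sample")
        uniq, inv = np.unique(groups, return_inverse=True)
        block_cols = [np.flatnonzero(inv == i) for i in range(len(uniq))]
        sizes = {len(c) for c in block_cols}
        if len(sizes) != 1:
            raise ValueError("permutation blocks must be equally sized")

    def edge_count(Yp: np.ndarray) -> int:
        C = X @ Yp.T / n
        return int(np.nansum(np.where(np.isfinite(C) & (C <= threshold), 1, 0)))

    observed = edge_count(Y)
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_permutations, dtype=int)
    for b in range(n_permutations):
        if groups is None:
            order = rng.permutation(n)
        else:
            # positions of block j receive the columns of a permuted block i
            order = np.empty(n, dtype=int)
            for j, i in enumerate(rng.permutation(len(block_cols))):
                order[block_cols[j]] = block_cols[i]
        null_counts[b] = edge_count(Y[:, order])
    if observed == 0:
        return None, null_counts
    return float(null_counts.mean() / observed), null_counts


def filter_validated(edges: pd.DataFrame, db: InteractionDB) -> pd.DataFrame:
    """Keep edges recorded in the DB with strong or NGS evidence."""
    if edges.empty:
        out = edges.copy()
        out["validated"] = pd.Series(dtype=bool)
        return out
    admitted = db.admitted_pairs()
    keep = [
        (m, g) in admitted
        for m, g in zip(edges["miRNA_id"], edges["gene_id"])
    ]
    out = edges[keep].reset_index(drop=True).copy()
    out["validated"] = True
    return out


def annotate_directions(
    edges: pd.DataFrame, de_mi: pd.DataFrame, de_mr: pd.DataFrame
) -> pd.DataFrame:
    """Tag each edge with the regulation direction (up/down) of both ends.

    Directions come from the sign of the DE tables' log2 fold change.
    """
    de_mi = de_mi.table if hasattr(de_mi, "table") else de_mi
    de_mr = de_mr.table if hasattr(de_mr, "table") else de_mr
    out = edges.copy()
    for col, ids, de, name in (
        ("miRNA_direction", edges["miRNA_id"], de_mi, "miRNA"),
        ("gene_direction", edges["gene_id"], de_mr, "mRNA"),
    ):
        missing = set(ids) - set(de.index)
        if missing:
            raise KeyError(f"{name} endpoints missing from DE table: {sorted(missing)[:5]}")
        lfc = de["log2fc"].reindex(ids).to_numpy()
        out[col] = np.where(lfc > 0, "up", "down")
    return out


class AntiCorrelationNetwork:
    """Treatment-response miRNA-mRNA network model for one cell culture.

    Candidate edges are anti-correlated (r <= threshold) pairs of
    DE-significant miRNAs and mRNAs across all samples of the culture;
    edges must be validated interactions (strong/NGS evidence) and carry
    the regulation direction of both endpoints.  ``fit`` also estimates a
    network-level permutation FDR for the unfiltered binary matrix.

    Parameters
    ----------
    mi, mr : ExpressionMatrix
        miRNA and mRNA matrices over the same ordered samples.
    de_mi, de_mr : DEResults or DataFrame
        Differential-expression tables selecting the significant features
        and providing directions.
    db : InteractionDB
        Evidence-annotated interaction records.
    threshold : float
        Edge criterion, inclusive (default -0.5).
    n_permutations : int
        Permutations for the network FDR (default 1000).
    design : SampleDesign, optional
        When given, the permutation null shuffles biological-replicate
        blocks (technical replicates travel together) instead of single
        samples, respecting the nested replicate correlation.
    """

    def __init__(
        self,
        mi: ExpressionMatrix,
        mr: ExpressionMatrix,
        de_mi,
        de_mr,
        db: InteractionDB,
        cell_line: str = "",
        threshold: float = -0.5,
        n_permutations: int = 1000,
        design: SampleDesign | None = None,
    ):
        self.mi, self.mr = mi, mr
        self.de_mi = de_mi.table if hasattr(de_mi, "table") else de_mi
        self.de_mr = de_mr.table if hasattr(de_mr, "table") else de_mr
        self.db = db
        self.cell_line = cell_line
        self.threshold = float(threshold)
        self.n_permutations = int(n_permutations)
        self.groups = None
        if design is not None:
            key = design.table.set_index("sample_id")
            self.groups = [
                f"{key.loc[s, 'condition']}|{key.loc[s, 'bio_rep']}"
                for s in mi.sample_ids
            ]

    def fit(self, seed: int = 0) -> "NetworkResults":
        sig_mi = list(self.de_mi.index[self.de_mi["significant"]])
        sig_mr = list(self.de_mr.index[self.de_mr["significant"]])
        if not sig_mi or not sig_mr:
            raise ValueError(
                f"no significant features to correlate "
                f"(miRNAs={len(sig_mi)}, mRNAs={len(sig_mr)})"
            )
        corr = correlation_matrix(self.mi, self.mr, sig_mi, sig_mr)
        edges = edges_from_correlation(corr, self.threshold)
        n_candidate = len(edges)
        edges = filter_validated(edges, self.db)
        edges = annotate_directions(edges, self.de_mi, self.de_mr)
        edges.insert(0, "cell_line", self.cell_line)
        fdr, null_counts = permutation_fdr(
            self.mi, self.mr, self.threshold, self.n_permutations, seed,
            features_mi=sig_mi, features_mr=sig_mr, groups=self.groups,
        )
        return NetworkResults(
            model=self,
            edges=edges,
            n_candidate_edges=n_candidate,
            network_fdr=fdr,
            null_edge_counts=null_counts,
            seed=seed,
        )


class NetworkResults:
    """Edge table plus the permutation-null diagnostics of a fitted network."""

    def __init__(self, model, edges, n_candidate_edges, network_fdr,
                 null_edge_counts, seed):
        self.model = model
        self.edges = edges
        self.n_candidate_edges = n_candidate_edges
        self.network_fdr = network_fdr
        self.null_edge_counts = null_edge_counts
        self.seed = seed

    @property
    def cell_line(self) -> str:
        return self.model.cell_line

    @property
    def threshold(self) -> float:
        return self.model.threshold

    @property
    def mirna_nodes(self) -> set[str]:
        return set(self.edges["miRNA_id"])

    @property
    def gene_nodes(self) -> set[str]:
        return set(self.edges["gene_id"])

    def to_networkx(self) -> nx.DiGraph:
        """Directed bipartite graph, edges always miRNA -> gene."""
        g = nx.DiGraph()
        for row in self.edges.itertuples(index=False):
            g.add_node(row.miRNA_id, type="miRNA", direction=row.miRNA_direction,
                       cell_line=str(row.cell_line))
            g.add_node(row.gene_id, type="gene", direction=row.gene_direction,
                       cell_line=str(row.cell_line))
            g.add_edge(row.miRNA_id, row.gene_id, r=float(row.r),
                       validated=bool(row.validated), cell_line=str(row.cell_line))
        return g

    def summary(self) -> str:
        fdr = "n/a (no edges)" if self.network_fdr is None else f"{self.network_fdr:.4g}"
        note = ""
        if self.model.n_permutations < 10:
            note = "  [low-confidence: <10 permutations]"
        lines = [
            f"Anti-correlation network (cell line {self.cell_line or '?'})",
            f"threshold: r <= {self.threshold}   candidate edges: "
            f"{self.n_candidate_edges}   validated edges: {len(self.edges)}",
            f"miRNA nodes: {len(self.mirna_nodes)}   gene nodes: {len(self.gene_nodes)}",
            f"permutation FDR (B={self.model.n_permutations}): {fdr}{note}",
        ]
        return "\n".join(lines)


class CombinedNetwork:
    """Cross-culture network: shared miRNAs, edges tagged by culture of origin."""

    def __init__(self, edges: pd.DataFrame, cell_lines: tuple[str, str]):
        self.edges = edges
        self.cell_lines = cell_lines

    @property
    def mirna_nodes(self) -> set[str]:
        return set(self.edges["miRNA_id"])

    @property
    def gene_nodes(self) -> set[str]:
        return set(self.edges["gene_id"])

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for row in self.edges.itertuples(index=False):
            g.add_node(row.miRNA_id, type="miRNA", direction=row.miRNA_direction,
                       cell_line="both")
            g.add_node(row.gene_id, type="gene", direction=row.gene_direction,
                       cell_line=str(row.cell_line))
            g.add_edge(row.miRNA_id, row.gene_id, r=float(row.r),
                       validated=bool(row.validated), cell_line=str(row.cell_line))
        return g

    def summary(self) -> str:
        return (
            f"Combined network ({' + '.join(self.cell_lines)})\n"
            f"shared miRNA nodes: {len(self.mirna_nodes)}   "
            f"gene nodes: {len(self.gene_nodes)}   edges: {len(self.edges)}"
        )


def combine_networks(a: NetworkResults, b: NetworkResults) -> CombinedNetwork:
    """Edges of both cultures restricted to miRNAs present in each network."""
    if a.cell_line == b.cell_line:
        raise ValueError(f"both networks come from cell line {a.cell_line!r}")
    common = a.mirna_nodes & b.mirna_nodes
    edges = pd.concat([a.edges, b.edges], ignore_index=True)
    edges = edges[edges["miRNA_id"].isin(common)].reset_index(drop=True)
    return CombinedNetwork(edges, (a.cell_line, b.cell_line))


def combine_edge_tables(a: pd.DataFrame, b: pd.DataFrame) -> CombinedNetwork:
    """Combine two per-culture edge tables (``cell_line`` column required)."""
    cls = []
    for t in (a, b):
        if t.empty:
            cls.append("")
            continue
        lines = set(t["cell_line"])
        if len(lines) != 1:
            raise ValueError("each edge table must come from a single cell line")
        cls.append(lines.pop())
    if cls[0] and cls[0] == cls[1]:
        raise ValueError(f"both edge tables come from cell line {cls[0]!r}")
    common = set(a["miRNA_id"]) & set(b["miRNA_id"])
    edges = pd.concat([a, b], ignore_index=True)
    edges = edges[edges["miRNA_id"].isin(common)].reset_index(drop=True)
    return CombinedNetwork(edges, (cls[0], cls[1]))
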