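"""Differential expression and sample-cluster association.

Treated-vs-control contrasts are scored per feature with a moderated
two-sample t-statistic: the pooled per-feature variance is shrunk toward
the median feature variance with a fixed prior (default 4 degrees of
freedom), stabilizing small-replicate designs in the spirit of
empirical-Bayes microarray analysis.  Multiple testing is controlled by
Benjamini-Hochberg step-up FDR.  Unsupervised structure is assessed by
agglomerative clustering of sample profiles (correlation distance,
average linkage) followed by a two-sided Fisher's exact test of the
cluster x label 2x2 table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .design import ExpressionMatrix, SampleDesign


def collapse_technical_replicates(
    matrix: ExpressionMatrix, design: SampleDesign
) -> tuple[ExpressionMatrix, SampleDesign]:
    """Average technical replicates (log2 scale) into one column per bio-rep.

    The collapsed sample id is ``{cell_line}_{C|T}{bio_rep}``; the returned
    design has ``tech_rep = 1`` throughout.
    """
    matrix.check_design(design)
    groups = design.table.groupby(["cell_line", "condition", "bio_rep"], sort=True)
    cols, rows = {}, []
    for (cl, cond, b), g in groups:
        tag = "C" if cond == "control" else "T"
        new_id = f"{cl}_{tag}{b}"
        cols[new_id] = matrix.values[list(g["sample_id"])].mean(axis=1)
        rows.append(
            {"sample_id": new_id, "cell_line": cl, "condition": cond,
             "bio_rep": b, "tech_rep": 1}
        )
    collapsed = ExpressionMatrix(pd.DataFrame(cols), matrix.kind)
    return collapsed, SampleDesign(pd.DataFrame(rows))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class DifferentialExpression:
    """Moderated-t treated-vs-control model for one cell culture.

    Parameters
    ----------
    matrix, design :
        Expression matrix and matching sample sheet.  If the design spans
        several cell lines, `cell_line` selects one.
    alpha : float
        BH-FDR significance cutoff (default 0.05).
    prior_df : float
        Prior degrees of freedom for the variance shrinkage (default 4);
        the prior variance is the median pooled feature variance.
    collapse_tech : bool
        Average technical replicates before testing (default True), so the
        test sees biological replicates only.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        design: SampleDesign,
        alpha: float = 0.05,
        prior_df: float = 4.0,
        collapse_tech: bool = True,
        cell_line: str | None = None,
    ):
        if cell_line is not None:
            design = design.subset(cell_line)
            matrix = matrix.subset_samples(design.sample_ids)
        elif len(design.cell_lines) > 1:
            raise ValueError(
                "design spans several cell lines; pass cell_line= to select one"
            )
        matrix.check_design(design)
        if collapse_tech:
            matrix, design = collapse_technical_replicates(matrix, design)
        self.matrix = matrix
        self.design = design
        self.alpha = float(alpha)
        self.prior_df = float(prior_df)
        self.cell_line = design.cell_lines[0]

    def fit(self) -> "DEResults":
        labels = self.design.labels("condition")
        treated = [s for s in self.matrix.sample_ids if labels[s] == "treated"]
        control = [s for s in self.matrix.sample_ids if labels[s] == "control"]
        n1, n2 = len(treated), len(control)
        if n1 < 2 or n2 < 2:
            raise ValueError(
                f"need >=2 replicates per condition (treated={n1}, control={n2})"
            )
        X1 = self.matrix.values[treated].to_numpy()
        X2 = self.matrix.values[control].to_numpy()
        log2fc = X1.mean(axis=1) - X2.mean(axis=1)
        s1 = X1.var(axis=1, ddof=1)
        s2 = X2.var(axis=1, ddof=1)
        df = n1 + n2 - 2
        s2_pooled = ((n1 - 1) * s1 + (n2 - 1) * s2) / df
        if np.all(s2_pooled == 0):
            raise ValueError("zero total variance matrix: no within-condition variation")
        s2_prior = float(np.median(s2_pooled))
        d0 = self.prior_df
        s2_tilde = (d0 * s2_prior + df * s2_pooled) / (d0 + df)
        se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
        df_total = df + d0
        p = np.ones_like(log2fc)
        ok = se > 0
        t = np.zeros_like(log2fc)
        t[ok] = log2fc[ok] / se[ok]
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df_total)
        # features with no variance anywhere (se == 0) keep p = 1 by convention
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        fdr = bh_adjust(p)
        table = pd.DataFrame(
            {
                "log2fc": log2fc,
                "fc": 2.0 ** log2fc,
                "t": t,
                "p": p,
                "fdr": fdr,
                "significant": fdr < self.alpha,
            },
            index=pd.Index(self.matrix.feature_ids, name="feature_id"),
        )
        return DEResults(self, table, df_resid=df, df_prior=d0, s2_prior=s2_prior)


class DEResults:
    """Per-feature fold changes, moderated-t p-values and BH-FDR flags."""

    def __init__(self, model, table: pd.DataFrame, df_resid: int,
                 df_prior: float, s2_prior: float):
        self.model = model
        self.table = table
        self.df_resid = df_resid
        self.df_prior = df_prior
        self.s2_prior = s2_prior

    @property
    def significant_features(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def summary(self, top: int = 10) -> str:
        m = self.model
        head = self.table.sort_values("p").head(top)
        lines = [
            f"Differential expression ({m.matrix.kind}, cell line {m.cell_line})",
            f"features: {len(self.table)}   significant at FDR<{m.alpha:g}: "
            f"{self.n_significant}",
            f"moderated t: df={self.df_resid}+{self.df_prior:g} prior, "
            f"prior variance={self.s2_prior:.4g}",
            "",
            head.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


def differential_expression(
    matrix: ExpressionMatrix, design: SampleDesign, alpha: float = 0.05, **kwargs
) -> pd.DataFrame:
    """Functional wrapper returning the DE result table."""
    return DifferentialExpression(matrix, design, alpha=alpha, **kwargs).fit().table


def top_k_features(
    matrix: ExpressionMatrix,
    de: pd.DataFrame | None,
    k: int,
    by: str = "p_value",
) -> list[str]:
    """Top-k features by cross-sample variance or ascending raw p-value.

    Ties are broken lexicographically by feature id so the selection is
    deterministic.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(matrix.feature_ids):
        raise ValueError(f"k={k} exceeds feature count {len(matrix.feature_ids)}")
    if by == "variance":
        score = matrix.values.var(axis=1, ddof=1)
        order = pd.DataFrame({"score": -score, "fid": score.index}).sort_values(
            ["score", "fid"]
        )
    elif by == "p_value":
        if de is None:
            raise ValueError("p_value ranking requires a DE result table")
        table = de.table if isinstance(de, DEResults) else de
        p = table["p"].reindex(matrix.feature_ids)
        order = pd.DataFrame({"score": p.to_numpy(), "fid": p.index}).sort_values(
            ["score", "fid"]
        )
    else:
        raise ValueError("by must be 'variance' or 'p_value'")
    return list(order["fid"].head(k))


def overlap(a, b) -> tuple[set, int]:
    """Exact intersection of two feature sets and its size."""
    inter = set(a) & set(b)
    return inter, len(inter)


class ClusterAssociation:
    """Hierarchical clustering of samples + Fisher's exact label association.

    Samples are clustered on 1 - Pearson correlation between their
    expression profiles with average linkage; the tree is cut into
    `k_clusters` groups and association with a binary sample label
    (condition or cell_line) is tested with a two-sided Fisher's exact
    test on the 2x2 contingency table.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        design: SampleDesign,
        label: str = "condition",
        k_clusters: int = 2,
        distance: str = "correlation",
        linkage: str = "average",
    ):
        matrix.check_design(design)
        if len(matrix.sample_ids) < k_clusters:
            raise ValueError("fewer samples than requested clusters")
        self.matrix = matrix
        self.design = design
        self.label = label
        self.k_clusters = int(k_clusters)
        self.distance = distance
        self.linkage = linkage

    def fit(self) -> "ClusterResults":
        X = self.matrix.values.to_numpy().T  # samples x features
        if self.distance == "correlation":
            sds = X.std(axis=1)
            if np.any(sds == 0):
                bad = self.matrix.sample_ids[int(np.argmax(sds == 0))]
                raise ValueError(
                    f"sample {bad!r} has a constant profile; "
                    "correlation distance is undefined"
                )
        D = pdist(X, metric=self.distance)
        Z = hierarchy.linkage(D, method=self.linkage)
        assign = hierarchy.fcluster(Z, t=self.k_clusters, criterion="maxclust")
        clusters = pd.Series(assign, index=self.matrix.sample_ids, name="cluster")
        labels = self.design.labels(self.label).reindex(clusters.index)
        table = pd.crosstab(clusters, labels)
        if table.shape != (2, 2):
            raise ValueError(
                f"Fisher's exact test needs a 2x2 table, got {table.shape} "
                f"(clusters x {self.label})"
            )
        p = fisher_exact_2x2(table.to_numpy())
        return ClusterResults(self, clusters, table, p, Z)


class ClusterResults:
    def __init__(self, model, clusters, contingency, fisher_p, linkage_matrix):
        self.model = model
        self.clusters = clusters
        self.contingency = contingency
        self.fisher_p = fisher_p
        self.linkage_matrix = linkage_matrix

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Hierarchical clustering ({m.distance} distance, {m.linkage} linkage)",
            f"samples: {len(self.clusters)}   clusters: {m.k_clusters}   "
            f"label: {m.label}",
            "",
            self.contingency.to_string(),
            "",
            f"Fisher's exact test (two-sided): p = {self.fisher_p:.4g}",
        ]
        return "\n".join(lines)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 contingency table."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def cluster_and_associate(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    label: str = "condition",
    k_clusters: int = 2,
    **kwargs,
) -> tuple[pd.Series, pd.DataFrame, float]:
    """Functional wrapper: (cluster assignment, 2x2 contingency, Fisher p)."""
    res = ClusterAssociation(matrix, design, label, k_clusters, **kwargs).fit()
    return res.clusters, res.contingency, res.fisher_p
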