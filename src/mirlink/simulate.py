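"""Synthetic experiment generator with planted ground truth.

Emulates a two-culture radiochemotherapy expression study: log2-scale
miRNA and mRNA intensities for {control, treated} x 3 biological x 2
technical replicates per culture, with

* planted differentially expressed features (additive log2 shift under
  treatment),
* planted repressive miRNA->mRNA dependencies — the target mRNA is a
  negative linear transform of its miRNA plus noise calibrated so the
  population Pearson correlation across a culture's samples equals a
  requested value in [-1, -0.5],
* a validated-interaction table (planted edges annotated strong/NGS plus
  random decoys with a configurable evidence mix), and
* qPCR Ct plates whose expected ddCt equals -log2(fold change).

Biological noise is shared by the technical replicates of a biological
replicate; technical noise is independent per array — the nested design
induces the realistic within-bio-rep correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ExpressionMatrix, SampleDesign
from .enrich import PATHWAY_SOURCES, Pathway, PathwayCollection
from .network import EVIDENCE_LEVELS, InteractionDB
from .qpcr import CtTable


@dataclass
class SimConfig:
    """Stated world for the synthetic experiment.

    Defaults: 50 miRNAs x 500 mRNAs over two cultures x {control,
    treated} x 3 bio x 2 tech replicates (24 arrays, 12 per culture);
    planted DE shifts of 2.0 log2 units against biological/technical
    noise SDs of 0.25/0.10; 20 planted repressive edges targeting a
    population Pearson correlation of -0.8 within each culture.
    """

    n_mirna: int = 50
    n_mrna: int = 500
    cell_lines: tuple[str, ...] = ("HN1957", "HN2092")
    n_bio: int = 3
    n_tech: int = 2
    n_de_mirna: int = 10
    n_de_mrna: int = 50
    n_edges: int = 20
    target_correlation: float = -0.8
    de_shift: float = 2.0
    edge_shift: float = 2.0
    sigma_bio: float = 0.25
    sigma_tech: float = 0.10
    baseline_range: tuple[float, float] = (6.0, 12.0)

    def validate(self) -> None:
        if min(self.n_mirna, self.n_mrna, self.n_bio, self.n_tech) <= 0:
            raise ValueError("matrix and replicate dimensions must be positive")
        if not self.cell_lines:
            raise ValueError("need at least one cell line")
        if self.n_edges < 0 or self.n_de_mirna < 0 or self.n_de_mrna < 0:
            raise ValueError("planted feature counts must be non-negative")
        if self.n_edges and not -1.0 <= self.target_correlation <= -0.5:
            raise ValueError(
                f"target_correlation must lie in [-1, -0.5]: {self.target_correlation}"
            )
        if self.sigma_bio < 0 or self.sigma_tech < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.n_edges > min(self.n_mirna, self.n_mrna):
            raise ValueError("more planted edges than available features")
        if self.n_edges + self.n_de_mirna > self.n_mirna:
            raise ValueError("planted DE miRNAs + edge miRNAs exceed n_mirna")
        if self.n_edges + self.n_de_mrna > self.n_mrna:
            raise ValueError("planted DE mRNAs + edge targets exceed n_mrna")


@dataclass
class SyntheticTruth:
    """Planted structure against which recovery is scored."""

    planted_edges: list = field(default_factory=list)     # (miRNA_id, gene_id, target_r)
    de_features: list = field(default_factory=list)       # (feature_id, log2_shift)
    decoy_db_edges: list = field(default_factory=list)    # (miRNA_id, gene_id)

    @property
    def edge_pairs(self) -> set:
        return {(m, g) for m, g, _ in self.planted_edges}

    def to_dict(self) -> dict:
        return {
            "planted_edges": [[m, g, r] for m, g, r in self.planted_edges],
            "de_features": [[f, s] for f, s in self.de_features],
            "decoy_db_edges": [[m, g] for m, g in self.decoy_db_edges],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            planted_edges=[(m, g, float(r)) for m, g, r in d["planted_edges"]],
            de_features=[(f, float(s)) for f, s in d["de_features"]],
            decoy_db_edges=[(m, g) for m, g in d["decoy_db_edges"]],
        )


def _feature_ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def simulate_experiment(
    config: SimConfig, seed: int
) -> tuple[ExpressionMatrix, ExpressionMatrix, SampleDesign, SyntheticTruth]:
    """Generate miRNA and mRNA matrices, the sample sheet and the truth.

    Planted-edge miRNAs always receive the treatment shift
    (``edge_shift``, random sign) so that both interaction endpoints are
    genuinely treatment-responsive; their targets inherit the opposite
    shift through the repressive linear map ``mRNA = a - miRNA + eps``
    with eps calibrated from the miRNA's total cross-design variance so
    the population Pearson correlation equals ``target_correlation``.
    Identical (config, seed) yields bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    design = SampleDesign.default_layout(config.cell_lines, config.n_bio, config.n_tech)
    dtab = design.table
    n_samples = len(dtab)
    treated = (dtab["condition"] == "treated").to_numpy(dtype=float)

    mirna_ids = _feature_ids("miR-", config.n_mirna)
    gene_ids = _feature_ids("gene-", config.n_mrna)

    # planted assignments: edge miRNAs/targets first, then extra DE features
    edge_mirnas = mirna_ids[: config.n_edges]
    edge_genes = gene_ids[: config.n_edges]
    de_mirnas = mirna_ids[config.n_edges : config.n_edges + config.n_de_mirna]
    de_mrnas = gene_ids[config.n_edges : config.n_edges + config.n_de_mrna]

    def shifts(features, ids, magnitude):
        out = np.zeros(len(ids))
        idx = {f: i for i, f in enumerate(ids)}
        signs = rng.choice([-1.0, 1.0], size=len(features))
        for f, s in zip(features, signs):
            out[idx[f]] = s * magnitude
        return out

    mi_shift = shifts(edge_mirnas, mirna_ids, config.edge_shift) + shifts(
        de_mirnas, mirna_ids, config.de_shift
    )
    mr_shift = shifts(de_mrnas, gene_ids, config.de_shift)

    lo, hi = config.baseline_range
    base_mi = rng.uniform(lo, hi, size=config.n_mirna)
    base_mr = rng.uniform(lo, hi, size=config.n_mrna)

    # nested noise: one biological draw per (feature, cell, condition, bio_rep),
    # broadcast to its technical replicates; technical noise per array
    bio_key = dtab.groupby(["cell_line", "condition", "bio_rep"], sort=True).ngroup().to_numpy()
    n_bio_groups = bio_key.max() + 1

    def noise_matrix(n_features: int) -> np.ndarray:
        bio = rng.normal(0.0, config.sigma_bio, size=(n_features, n_bio_groups))
        tech = rng.normal(0.0, config.sigma_tech, size=(n_features, n_samples))
        return bio[:, bio_key] + tech

    M = base_mi[:, None] + mi_shift[:, None] * treated[None, :] + noise_matrix(config.n_mirna)
    G = base_mr[:, None] + mr_shift[:, None] * treated[None, :] + noise_matrix(config.n_mrna)

    # planted repressive edges: overwrite the target rows
    truth_edges = []
    mi_index = {f: i for i, f in enumerate(mirna_ids)}
    mr_index = {f: i for i, f in enumerate(gene_ids)}
    de_records = {}
    for f, s in zip(mirna_ids, mi_shift):
        if s != 0:
            de_records[f] = float(s)
    for f, s in zip(gene_ids, mr_shift):
        if s != 0:
            de_records[f] = float(s)
    for m_id, g_id in zip(edge_mirnas, edge_genes):
        r_t = config.target_correlation
        i, j = mi_index[m_id], mr_index[g_id]
        # total population variance of the miRNA across a culture's samples:
        # half the samples are shifted, so the shift contributes shift^2/4
        var_x = (
            (config.edge_shift ** 2) / 4.0
            + config.sigma_bio ** 2
            + config.sigma_tech ** 2
        )
        if var_x == 0:
            raise ValueError(
                f"planted edge ({m_id}, {g_id}) has zero miRNA variance; "
                "set a nonzero edge_shift or noise SD"
            )
        eps_var = var_x * (1.0 / r_t ** 2 - 1.0)
        eps = rng.normal(0.0, np.sqrt(eps_var), size=n_samples) if eps_var > 0 else 0.0
        x = M[i]
        center = base_mi[i] + mi_shift[i] / 2.0
        G[j] = base_mr[j] - (x - center) + eps
        truth_edges.append((m_id, g_id, float(r_t)))
        de_records[g_id] = -de_records.get(m_id, 0.0)

    truth = SyntheticTruth(
        planted_edges=truth_edges,
        de_features=sorted(de_records.items()),
    )
    mi = ExpressionMatrix(
        pd.DataFrame(M, index=mirna_ids, columns=design.sample_ids), "miRNA"
    )
    mr = ExpressionMatrix(
        pd.DataFrame(G, index=gene_ids, columns=design.sample_ids), "mRNA"
    )
    return mi, mr, design, truth


def simulate_interaction_db(
    truth: SyntheticTruth,
    n_decoys: int,
    evidence_mix: dict | None = None,
    seed: int = 0,
    mirna_ids: list[str] | None = None,
    gene_ids: list[str] | None = None,
) -> InteractionDB:
    """Interaction table: all planted edges (strong/NGS) plus random decoys.

    ``evidence_mix`` gives the decoy evidence proportions over
    {strong, NGS, weak} (default: 0.5/0.3/0.2).  Decoys never duplicate a
    planted edge; the drawn decoys are recorded in
    ``truth.decoy_db_edges``.  The id pools default to the features
    appearing in the truth.
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    evidence_mix = dict(evidence_mix) if evidence_mix else {"strong": 0.5, "NGS": 0.3, "weak": 0.2}
    bad = set(evidence_mix) - set(EVIDENCE_LEVELS)
    if bad:
        raise ValueError(f"unknown evidence levels in mix: {sorted(bad)}")
    probs = np.array([evidence_mix.get(e, 0.0) for e in EVIDENCE_LEVELS], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"evidence_mix must sum to 1, got {probs.sum()}")

    rng = np.random.default_rng(seed)
    planted = truth.edge_pairs
    rows = [
        {"miRNA_id": m, "gene_id": g,
         "evidence": "strong" if rng.random() < 0.5 else "NGS"}
        for m, g, _ in truth.planted_edges
    ]
    if mirna_ids is None:
        mirna_ids = sorted({m for m, _, _ in truth.planted_edges})
    if gene_ids is None:
        gene_ids = sorted({g for _, g, _ in truth.planted_edges})
    if n_decoys and (not mirna_ids or not gene_ids):
        raise ValueError("decoys requested but no feature id pools available")
    decoys: list[tuple[str, str]] = []
    seen = set(planted)
    guard = 0
    while len(decoys) < n_decoys:
        guard += 1
        if guard > 1000 * (n_decoys + 1):
            raise ValueError("unable to draw enough unique decoy pairs")
        m = mirna_ids[rng.integers(len(mirna_ids))]
        g = gene_ids[rng.integers(len(gene_ids))]
        if (m, g) in seen:
            continue
        seen.add((m, g))
        decoys.append((m, g))
        rows.append(
            {"miRNA_id": m, "gene_id": g,
             "evidence": EVIDENCE_LEVELS[rng.choice(len(EVIDENCE_LEVELS), p=probs)]}
        )
    truth.decoy_db_edges = decoys
    return InteractionDB(pd.DataFrame(rows, columns=["miRNA_id", "gene_id", "evidence"]))


def simulate_pathways(
    gene_ids,
    n_pathways: int = 40,
    size_range: tuple[int, int] = (10, 60),
    seed: int = 0,
    enriched_genes=None,
    enriched_fraction: float = 0.5,
) -> PathwayCollection:
    """Random multi-source pathway collection over a gene universe.

    Pathways draw genes uniformly from ``gene_ids`` with sizes in
    ``size_range`` and cycle through the five source tags.  When
    ``enriched_genes`` is given, the first pathway is planted to contain
    ``enriched_fraction`` of that list (plus random padding), giving the
    over-representation test a known positive.
    """
    gene_ids = list(gene_ids)
    if n_pathways <= 0 or not gene_ids:
        raise ValueError("need a positive pathway count and a nonempty universe")
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(gene_ids):
        raise ValueError(f"invalid size range {size_range} for universe of {len(gene_ids)}")
    rng = np.random.default_rng(seed)
    pathways = []
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        genes = set(rng.choice(gene_ids, size=size, replace=False))
        if i == 0 and enriched_genes:
            planted = list(enriched_genes)
            take = max(1, int(round(enriched_fraction * len(planted))))
            genes |= set(planted[:take])
        pathways.append(
            Pathway(
                pathway_id=f"PW{i + 1:04d}",
                name=f"synthetic pathway {i + 1}",
                source=PATHWAY_SOURCES[i % len(PATHWAY_SOURCES)],
                genes=frozenset(genes),
            )
        )
    return PathwayCollection(pathways, frozenset(gene_ids))


def simulate_qpcr(
    fold_changes: dict,
    n_bio_reps: int = 3,
    ct_noise_sd: float = 0.1,
    seed: int = 0,
    reference_targets: tuple[str, ...] = ("U6",),
    base_ct: float = 25.0,
) -> tuple[CtTable, SampleDesign]:
    """Ct plate whose expected ddCt equals -log2(fold change) per target.

    Treated samples of a target with true fold change ``fc`` run
    log2(fc) cycles earlier than controls; reference targets are flat
    (fold change 1).  With ``ct_noise_sd = 0`` the ddCt computation
    recovers every fold change exactly.
    """
    if n_bio_reps < 2:
        raise ValueError("need at least 2 biological replicates per condition")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    fold_changes = dict(fold_changes)
    for ref in reference_targets:
        fc_ref = fold_changes.setdefault(ref, 1.0)
        if fc_ref != 1.0:
            raise ValueError(f"reference target {ref!r} must have fold change 1")
    for t, fc in fold_changes.items():
        if not fc > 0:
            raise ValueError(f"fold change must be positive ({t!r}: {fc})")

    rng = np.random.default_rng(seed)
    rows, drows = [], []
    conditions = ["control"] * n_bio_reps + ["treated"] * n_bio_reps
    sample_ids = [
        f"q_{'C' if c == 'control' else 'T'}{i % n_bio_reps + 1}"
        for i, c in enumerate(conditions)
    ]
    for s, c, b in zip(sample_ids, conditions, list(range(1, n_bio_reps + 1)) * 2):
        drows.append({"sample_id": s, "cell_line": "qpcr", "condition": c,
                      "bio_rep": b, "tech_rep": 1})
    for t in sorted(fold_changes):
        fc = fold_changes[t]
        for s, c in zip(sample_ids, conditions):
            shift = -np.log2(fc) if c == "treated" else 0.0
            noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
            rows.append(
                {"target_id": t, "sample_id": s, "replicate": 1,
                 "ct": base_ct + shift + noise}
            )
    table = CtTable(pd.DataFrame(rows), reference_targets=list(reference_targets))
    return table, SampleDesign(pd.DataFrame(drows))
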