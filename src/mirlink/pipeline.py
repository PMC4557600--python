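"""End-to-end orchestration: DE -> clustering -> network -> combine -> enrich.

``run_all`` chains the stages per cell culture over file-based inputs (or
a fresh simulation), writing a deterministic artifact set stamped with
the config hash and seed, plus a machine-readable run manifest.  Re-running
with an identical config and seed reproduces every artifact byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import io as mio
from .diffexpr import ClusterAssociation, DifferentialExpression, top_k_features
from .enrich import EnrichmentAnalysis
from .network import AntiCorrelationNetwork, combine_networks
from .simulate import (
    SimConfig,
    simulate_experiment,
    simulate_interaction_db,
    simulate_pathways,
)

log = logging.getLogger("mirlink")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[mirlink] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Run settings; defaults follow the study's stated constants
    (DE FDR cutoff 0.05, edge criterion r <= -0.5, top-50 heatmap features).
    """

    seed: int = 0
    alpha_de: float = 0.05
    corr_threshold: float = -0.5
    n_permutations: int = 1000
    top_k: int = 50
    clustering: dict = field(default_factory=lambda: {"distance": "correlation",
                                                      "linkage": "average"})
    # inputs: either file paths ...
    mirna_expression: str | None = None
    mrna_expression: str | None = None
    sample_sheet: str | None = None
    interaction_db: str | None = None
    gmt: str | None = None
    # ... or a simulation that generates them
    simulate: SimConfig | None = None
    n_decoys: int = 200
    outdir: str = "mirlink_run"

    def validate(self) -> None:
        if not 0 < self.alpha_de <= 1:
            raise ValueError(f"alpha_de outside (0, 1]: {self.alpha_de}")
        if not -1.0 <= self.corr_threshold < 0.0:
            raise ValueError(f"corr_threshold outside [-1, 0): {self.corr_threshold}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        have_paths = all(
            p is not None
            for p in (self.mirna_expression, self.mrna_expression,
                      self.sample_sheet, self.interaction_db)
        )
        if self.simulate is None and not have_paths:
            raise ValueError("config needs either input paths or a simulate block")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.simulate is not None:
            d["simulate"] = asdict(self.simulate)
            d["simulate"]["cell_lines"] = list(self.simulate.cell_lines)
            d["simulate"]["baseline_range"] = list(self.simulate.baseline_range)
        return d

    def config_hash(self) -> str:
        # outdir is excluded: the same analysis in two directories is the same run
        d = self.to_dict()
        d.pop("outdir", None)
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> Path:
    """Run every stage; returns the run directory containing the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"mirlink config={config.config_hash()} seed={config.seed}"
    report: dict = {"cell_lines": {}}
    t0 = time.perf_counter()

    def stage(name):
        log.info("stage %-12s t=%.1fs", name, time.perf_counter() - t0)

    try:
        stage("inputs")
        if config.simulate is not None:
            mi, mr, design, truth = simulate_experiment(config.simulate, config.seed)
            db = simulate_interaction_db(
                truth, n_decoys=config.n_decoys, seed=config.seed + 1,
                mirna_ids=mi.feature_ids, gene_ids=mr.feature_ids,
            )
            coll = simulate_pathways(
                mr.feature_ids, seed=config.seed + 2,
                enriched_genes=[g for _, g, _ in truth.planted_edges],
            )
            indir = outdir / "inputs"
            mio.write_expression(mi, indir / "mirna_expression.tsv", stamp)
            mio.write_expression(mr, indir / "mrna_expression.tsv", stamp)
            mio.write_sample_sheet(design, indir / "sample_sheet.tsv", stamp)
            mio.write_interaction_db(db, indir / "interaction_db.tsv", stamp)
            mio.write_gmt(coll, indir / "pathways.gmt")
            mio.write_truth(truth, indir / "truth.json")
        else:
            mi = mio.read_expression(config.mirna_expression, "miRNA")
            mr = mio.read_expression(config.mrna_expression, "mRNA")
            design = mio.read_sample_sheet(config.sample_sheet)
            db = mio.read_interaction_db(config.interaction_db)
            coll = mio.read_gmt(config.gmt) if config.gmt else None
    except Exception as e:
        raise PipelineError(f"stage inputs: {e}") from e

    networks = {}
    for cl in design.cell_lines:
        sub = design.subset(cl)
        mi_cl = mi.subset_samples(sub.sample_ids)
        mr_cl = mr.subset_samples(sub.sample_ids)
        cl_report: dict = {}

        try:
            stage(f"de[{cl}]")
            de_mi = DifferentialExpression(mi_cl, sub, alpha=config.alpha_de).fit()
            de_mr = DifferentialExpression(mr_cl, sub, alpha=config.alpha_de).fit()
            mio.write_de_table(de_mi, outdir / f"de_mirna_{cl}.tsv", stamp)
            mio.write_de_table(de_mr, outdir / f"de_mrna_{cl}.tsv", stamp)
            cl_report["n_significant_mirna"] = de_mi.n_significant
            cl_report["n_significant_mrna"] = de_mr.n_significant
        except Exception as e:
            raise PipelineError(f"stage de[{cl}]: {e}") from e

        try:
            stage(f"cluster[{cl}]")
            # technical replicates kept as individual samples for clustering
            k_mi = min(config.top_k, len(mi_cl.feature_ids))
            k_mr = min(config.top_k, len(mr_cl.feature_ids))
            top_mi = top_k_features(mi_cl, de_mi, k_mi, by="p_value")
            top_mr = top_k_features(mr_cl, None, k_mr, by="variance")
            cl_report["clustering"] = {}
            for tag, mat, feats in (
                ("mirna_top_p", mi_cl, top_mi),
                ("mrna_top_variance", mr_cl, top_mr),
            ):
                res = ClusterAssociation(
                    mat.subset_features(feats), sub, label="condition",
                    distance=config.clustering["distance"],
                    linkage=config.clustering["linkage"],
                ).fit()
                cl_report["clustering"][tag] = {
                    "fisher_p": res.fisher_p,
                    "contingency": res.contingency.to_numpy().tolist(),
                }
        except Exception as e:
            raise PipelineError(f"stage cluster[{cl}]: {e}") from e

        try:
            stage(f"network[{cl}]")
            net = AntiCorrelationNetwork(
                mi_cl, mr_cl, de_mi, de_mr, db, cell_line=cl,
                threshold=config.corr_threshold,
                n_permutations=config.n_permutations,
                design=sub,
            ).fit(seed=config.seed + 10)
            mio.write_edge_table(net, outdir / f"network_{cl}.tsv", stamp)
            mio.write_graphml(net, outdir / f"network_{cl}.graphml")
            mio.write_sif(net, outdir / f"network_{cl}.sif")
            cl_report["network"] = {
                "n_candidate_edges": net.n_candidate_edges,
                "n_validated_edges": len(net.edges),
                "network_fdr": net.network_fdr,
                "n_permutations": config.n_permutations,
                "low_confidence": config.n_permutations < 10,
            }
            networks[cl] = net
        except Exception as e:
            raise PipelineError(f"stage network[{cl}]: {e}") from e

        if coll is not None:
            try:
                stage(f"enrich[{cl}]")
                genes = sorted(net.gene_nodes) or de_mr.significant_features
                res = EnrichmentAnalysis(genes, coll, alpha=config.alpha_de).fit()
                mio.write_enrichment(res, outdir / f"enrichment_{cl}.tsv", stamp)
                cl_report["enrichment"] = {
                    "n_tested": len(res.full_table),
                    "n_enriched": len(res.table),
                }
            except Exception as e:
                raise PipelineError(f"stage enrich[{cl}]: {e}") from e

        report["cell_lines"][cl] = cl_report

    if len(networks) == 2:
        try:
            stage("combine")
            a, b = (networks[cl] for cl in sorted(networks))
            combined = combine_networks(a, b)
            mio.write_edge_table(combined, outdir / "network_combined.tsv", stamp)
            mio.write_graphml(combined, outdir / "network_combined.graphml")
            mio.write_sif(combined, outdir / "network_combined.sif")
            report["combined_network"] = {
                "n_edges": len(combined.edges),
                "n_shared_mirnas": len(combined.mirna_nodes),
            }
        except Exception as e:
            raise PipelineError(f"stage combine: {e}") from e

    try:
        stage("manifest")
        import networkx
        import numpy
        import pandas
        import scipy

        from . import __version__

        artifacts = {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        }
        manifest = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "versions": {
                "mirlink": __version__,
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "pandas": pandas.__version__,
                "networkx": networkx.__version__,
            },
            "report": report,
            "artifacts": artifacts,
        }
        mio.write_json(manifest, outdir / "manifest.json")
    except Exception as e:
        raise PipelineError(f"stage manifest: {e}") from e

    stage("done")
    return outdir
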