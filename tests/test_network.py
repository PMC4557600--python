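"""Anti-correlation network: correlation, binarization, permutation FDR,
evidence filtering, direction annotation and cross-culture combination."""

import numpy as np
import pandas as pd
import pytest

import mirlink as ml


def matrices_from(rows_mi, rows_mr, sample_ids=None):
    n = len(next(iter(rows_mi.values())))
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    mi = ml.ExpressionMatrix(pd.DataFrame(rows_mi, index=sample_ids).T, "miRNA")
    mr = ml.ExpressionMatrix(pd.DataFrame(rows_mr, index=sample_ids).T, "mRNA")
    return mi, mr


def db_from(pairs, evidence="strong"):
    return ml.InteractionDB(pd.DataFrame(
        [{"miRNA_id": m, "gene_id": g,
          "evidence": evidence if isinstance(evidence, str) else e}
         for (m, g), e in zip(pairs, evidence if not isinstance(evidence, str)
                              else [evidence] * len(pairs))]
    ))


class TestCorrelationMatrix:
    def test_exact_negative_affine_is_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        mi, mr = matrices_from({"m": x}, {"g": 10 - 2 * x, "h": x.copy()})
        C = ml.correlation_matrix(mi, mr)
        assert C.loc["m", "g"] == pytest.approx(-1.0)
        assert C.loc["m", "h"] == pytest.approx(1.0)

    def test_planted_pair_within_fisher_interval(self):
        """Sample r of a 12-sample pair at population -0.8 stays in [-0.99, -0.3]."""
        cfg = ml.SimConfig(n_mirna=10, n_mrna=30, n_edges=5, n_de_mirna=2,
                           n_de_mrna=5, cell_lines=("CL",))
        hits = total = 0
        for seed in range(60):
            mi, mr, d, truth = ml.simulate_experiment(cfg, seed)
            C = ml.correlation_matrix(mi, mr)
            for m, g, _ in truth.planted_edges:
                total += 1
                hits += -0.99 <= C.loc[m, g] <= -0.3
        assert hits / total >= 0.95

    def test_zero_variance_feature_is_nan(self):
        mi, mr = matrices_from({"m": [1.0, 2.0, 3.0]}, {"g": [5.0, 5.0, 5.0]})
        C = ml.correlation_matrix(mi, mr)
        assert np.isnan(C.loc["m", "g"])

    def test_sample_mismatch_raises(self):
        mi, _ = matrices_from({"m": [1.0, 2.0, 3.0]}, {"g": [1.0, 2.0, 3.0]})
        _, mr = matrices_from({"m": [1.0, 2.0, 3.0]}, {"g": [1.0, 2.0, 3.0]},
                              sample_ids=["a", "b", "c"])
        with pytest.raises(ValueError, match="sample set"):
            ml.correlation_matrix(mi, mr)


class TestBinarize:
    def test_boundary_inclusive_at_threshold(self):
        c = pd.DataFrame([[-0.6, -0.5, -0.49, 0.7]])
        assert list(ml.binarize(c).to_numpy()[0]) == [1, 1, 0, 0]

    def test_positive_matrix_all_zero_and_nan_never_edge(self):
        c = pd.DataFrame([[0.3, 0.9], [np.nan, -0.7]])
        b = ml.binarize(c)
        assert b.to_numpy().tolist() == [[0, 0], [0, 1]]

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(8)
        c = pd.DataFrame(rng.uniform(-1, 1, (3, 3)))
        b = ml.binarize(c, threshold=-0.4).to_numpy()
        for i in range(3):
            for j in range(3):
                assert b[i, j] == (1 if c.iloc[i, j] <= -0.4 else 0)

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            ml.binarize(pd.DataFrame([[0.0]]), threshold=0.2)
        with pytest.raises(ValueError):
            ml.binarize(pd.DataFrame([[0.0]]), threshold=-1.5)


class TestPermutationFdr:
    def test_no_observed_edges_is_undefined(self):
        x = np.linspace(0, 1, 6)
        mi, mr = matrices_from({"m": x}, {"g": x + 0.01 * x**2})
        fdr, counts = ml.permutation_fdr(mi, mr, n_permutations=10, seed=0)
        assert fdr is None and len(counts) == 10

    def test_null_calibration_block_permutation(self):
        """Pure-null pipeline: observed edges match the permutation null
        within Monte-Carlo error (ratio in [0.5, 2] over 50 seeds)."""
        cfg = ml.SimConfig(n_mirna=20, n_mrna=100, n_edges=0, n_de_mirna=0,
                           n_de_mrna=0, cell_lines=("CL",))
        obs_tot, null_tot = 0, 0.0
        for seed in range(50):
            mi, mr, d, _ = ml.simulate_experiment(cfg, seed)
            key = d.table.set_index("sample_id")
            groups = [f"{key.loc[s, 'condition']}|{key.loc[s, 'bio_rep']}"
                      for s in mi.sample_ids]
            _, counts = ml.permutation_fdr(mi, mr, n_permutations=20,
                                           seed=seed + 500, groups=groups)
            C = ml.correlation_matrix(mi, mr)
            obs_tot += int((C.to_numpy() <= -0.5).sum())
            null_tot += counts.mean()
        assert 0.5 <= null_tot / obs_tot <= 2.0

    def test_planted_signal_inflates_observed_over_null(self):
        cfg = ml.SimConfig(n_mirna=25, n_mrna=520, n_edges=20, n_de_mirna=0,
                           n_de_mrna=0, target_correlation=-0.9,
                           cell_lines=("CL",))
        mi, mr, d, truth = ml.simulate_experiment(cfg, seed=3)
        fdr, counts = ml.permutation_fdr(mi, mr, n_permutations=50, seed=3)
        C = ml.correlation_matrix(mi, mr)
        observed = int((C.to_numpy() <= -0.5).sum())
        assert observed > counts.mean()
        assert fdr is not None and fdr < 1.0

    def test_seeded_and_reproducible(self, small_sim):
        _, mi, mr, design, _ = small_sim
        a = ml.permutation_fdr(mi, mr, n_permutations=20, seed=7)
        b = ml.permutation_fdr(mi, mr, n_permutations=20, seed=7)
        assert a[0] == b[0] and (a[1] == b[1]).all()

    def test_bad_b(self, small_sim):
        _, mi, mr, *_ = small_sim
        with pytest.raises(ValueError):
            ml.permutation_fdr(mi, mr, n_permutations=0)


class TestFilterAndAnnotate:
    def setup_method(self):
        self.edges = pd.DataFrame(
            {"miRNA_id": ["m1", "m1", "m2"], "gene_id": ["g1", "g2", "g3"],
             "r": [-0.8, -0.6, -0.55]}
        )

    def test_absent_and_weak_removed(self):
        db = ml.InteractionDB(pd.DataFrame(
            [{"miRNA_id": "m1", "gene_id": "g1", "evidence": "strong"},
             {"miRNA_id": "m1", "gene_id": "g2", "evidence": "weak"}]
        ))
        out = ml.filter_validated(self.edges, db)
        assert list(zip(out["miRNA_id"], out["gene_id"])) == [("m1", "g1")]
        assert out["validated"].all()

    def test_planted_set_fully_retained_with_decoy_free_db(self):
        db = db_from([("m1", "g1"), ("m1", "g2"), ("m2", "g3")], "NGS")
        out = ml.filter_validated(self.edges, db)
        assert len(out) == 3

    def test_filter_binarize_order_independent(self, small_sim):
        """Filtering before or after thresholding yields the same edge set."""
        cfg, mi, mr, design, truth = small_sim
        db = ml.simulate_interaction_db(truth, n_decoys=40, seed=2,
                                        mirna_ids=mi.feature_ids,
                                        gene_ids=mr.feature_ids)
        C = ml.correlation_matrix(mi, mr)
        after = ml.filter_validated(ml.edges_from_correlation(C, -0.5), db)
        admitted = db.admitted_pairs()
        Cpre = C.copy()
        for i in C.index:
            for j in C.columns:
                if (i, j) not in admitted:
                    Cpre.loc[i, j] = np.nan
        before = ml.edges_from_correlation(Cpre, -0.5)
        key = lambda df: set(zip(df["miRNA_id"], df["gene_id"]))
        assert key(after) == key(before)

    def test_direction_annotation(self):
        de_mi = pd.DataFrame({"log2fc": [0.4, -0.2]}, index=["m1", "m2"])
        de_mr = pd.DataFrame({"log2fc": [-0.6, -0.1, 0.9]}, index=["g1", "g2", "g3"])
        out = ml.annotate_directions(self.edges, de_mi, de_mr)
        assert list(out["miRNA_direction"]) == ["up", "up", "down"]
        assert list(out["gene_direction"]) == ["down", "down", "up"]

    def test_published_up_down_pair(self):
        """An FC-1.31 miRNA with an FC-0.69 target annotates as (up, down)."""
        edges = pd.DataFrame({"miRNA_id": ["miR-181b-5p"], "gene_id": ["ASB13"],
                              "r": [-0.8]})
        de_mi = pd.DataFrame({"log2fc": [np.log2(1.31)]}, index=["miR-181b-5p"])
        de_mr = pd.DataFrame({"log2fc": [np.log2(0.69)]}, index=["ASB13"])
        out = ml.annotate_directions(edges, de_mi, de_mr)
        assert out.loc[0, "miRNA_direction"] == "up"
        assert out.loc[0, "gene_direction"] == "down"

    def test_missing_endpoint_raises(self):
        de_mi = pd.DataFrame({"log2fc": [0.4]}, index=["m1"])
        de_mr = pd.DataFrame({"log2fc": [-0.6, 0.1, 0.2]}, index=["g1", "g2", "g3"])
        with pytest.raises(KeyError, match="m2"):
            ml.annotate_directions(self.edges, de_mi, de_mr)


def fitted_network(seed, cell_line="HN1957", cfg=None, n_decoys=100):
    cfg = cfg or ml.SimConfig()
    mi, mr, d, truth = ml.simulate_experiment(cfg, seed)
    db = ml.simulate_interaction_db(truth, n_decoys=n_decoys, seed=seed + 1,
                                    mirna_ids=mi.feature_ids,
                                    gene_ids=mr.feature_ids)
    sub = d.subset(cell_line)
    mi1, mr1 = mi.subset_samples(sub.sample_ids), mr.subset_samples(sub.sample_ids)
    de_mi = ml.DifferentialExpression(mi1, sub).fit()
    de_mr = ml.DifferentialExpression(mr1, sub).fit()
    net = ml.AntiCorrelationNetwork(mi1, mr1, de_mi, de_mr, db,
                                    cell_line=cell_line, n_permutations=20,
                                    design=sub).fit(seed=seed)
    return net, truth


class TestNetworkModel:
    def test_edges_respect_contract(self):
        net, truth = fitted_network(1)
        assert (net.edges["r"] <= net.threshold).all()
        assert net.edges["validated"].all()
        assert set(net.edges["miRNA_direction"]) <= {"up", "down"}

    def test_pipeline_regime_fdr_below_half(self):
        """DE-filtered networks with planted structure beat the null clearly."""
        for seed in (1, 2, 3):
            net, _ = fitted_network(seed)
            assert net.network_fdr is not None and net.network_fdr < 0.5

    def test_decoy_rejection_rate_consistent_with_null(self):
        """Null decoy pairs become final edges about as often as chance."""
        from scipy import stats

        cfg = ml.SimConfig()
        hits = total = 0
        for seed in range(30):
            net, truth = fitted_network(seed, cfg=cfg, n_decoys=200)
            edge_set = set(zip(net.edges["miRNA_id"], net.edges["gene_id"]))
            planted_feats = {f for m, g, _ in truth.planted_edges for f in (m, g)}
            de_feats = {f for f, _ in truth.de_features}
            for m, g in truth.decoy_db_edges:
                if m in planted_feats | de_feats or g in planted_feats | de_feats:
                    continue  # only pairs of genuinely null features
                total += 1
                hits += (m, g) in edge_set
        # null features rarely reach DE significance, so decoys almost never
        # survive; bound by the no-DE-filter anti-correlation rate itself
        p0 = stats.t.cdf(-0.5 * np.sqrt(10) / np.sqrt(0.75), 10)
        assert hits / total <= p0

    def test_end_to_end_recall(self):
        """Planted edges (r=-0.8, n=12) recovered with recall >= 0.8."""
        recalls = []
        for seed in range(40):
            net, truth = fitted_network(seed, n_decoys=0)
            found = set(zip(net.edges["miRNA_id"], net.edges["gene_id"]))
            recalls.append(len(found & truth.edge_pairs) / len(truth.edge_pairs))
        assert np.mean(recalls) >= 0.8


class TestCombine:
    def test_same_cell_line_rejected(self):
        a, _ = fitted_network(1)
        with pytest.raises(ValueError, match="cell line"):
            ml.combine_networks(a, a)

    def test_shared_mirnas_union_edges(self):
        a, truth = fitted_network(4)
        mi, mr, d, _ = ml.simulate_experiment(ml.SimConfig(), 4)
        b, _ = fitted_network(4, cell_line="HN2092")
        combined = ml.combine_networks(a, b)
        assert combined.mirna_nodes == a.mirna_nodes & b.mirna_nodes
        assert set(combined.edges["cell_line"]) <= {"HN1957", "HN2092"}

    def test_set_algebra_on_edge_tables(self):
        cols = ["cell_line", "miRNA_id", "gene_id", "r", "miRNA_direction",
                "gene_direction", "validated"]
        a = pd.DataFrame([["A", "m1", "g1", -0.7, "up", "down", True],
                          ["A", "m2", "g2", -0.6, "up", "down", True]], columns=cols)
        b = pd.DataFrame([["B", "m2", "g3", -0.9, "down", "up", True],
                          ["B", "m3", "g4", -0.8, "up", "down", True]], columns=cols)
        combined = ml.combine_edge_tables(a, b)
        assert combined.mirna_nodes == {"m2"}
        assert sorted(combined.edges["gene_id"]) == ["g2", "g3"]

    def test_disjoint_mirnas_empty(self):
        cols = ["cell_line", "miRNA_id", "gene_id", "r", "miRNA_direction",
                "gene_direction", "validated"]
        a = pd.DataFrame([["A", "m1", "g1", -0.7, "up", "down", True]], columns=cols)
        b = pd.DataFrame([["B", "m2", "g2", -0.9, "down", "up", True]], columns=cols)
        assert len(ml.combine_edge_tables(a, b).edges) == 0

    def test_graph_export_shapes(self, tmp_path):
        net, _ = fitted_network(5)
        g = net.to_networkx()
        assert g.number_of_edges() == len(net.edges)
        import mirlink.io as mio

        mio.write_graphml(net, tmp_path / "n.graphml")
        mio.write_sif(net, tmp_path / "n.sif")
        sif = (tmp_path / "n.sif").read_text().strip().splitlines()
        assert len(sif) == len(net.edges)
        assert all(line.split("\t")[1] == "represses" for line in sif)
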