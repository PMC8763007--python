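import numpy as np
import pandas as pd
import pytest

import stromascope as ss


class TestCellQC:
    def test_hand_arithmetic(self, tiny_counts):
        qc = ss.compute_cell_qc(tiny_counts, ["MT-1"])
        # c1: geneA=3, MT-1=1 → 2 genes, 4 UMIs, mito 0.25
        assert qc.loc["c1", "n_genes_detected"] == 2
        assert qc.loc["c1", "n_umi"] == 4
        assert qc.loc["c1", "mito_fraction"] == 0.25

    def test_all_zero_cell_conventions(self, tiny_counts):
        qc = ss.compute_cell_qc(tiny_counts, ["MT-1"])
        assert qc.loc["c3", "n_genes_detected"] == 0
        assert qc.loc["c3", "mito_fraction"] == 0.0

    def test_no_mito_genes_warns_and_zeroes(self, tiny_counts, caplog):
        with caplog.at_level("WARNING", logger="stromascope"):
            qc = ss.compute_cell_qc(tiny_counts, [])
        assert (qc["mito_fraction"] == 0).all()
        assert "mito" in caplog.text


class TestFilterCells:
    @pytest.mark.parametrize(
        "n_genes,n_umi,mito,platform,kept",
        [
            (201, 401, 0.249, "umi", True),     # interior cell on all bounds
            (200, 10000, 0.0, "umi", False),    # gene floor is exclusive
            (6000, 10000, 0.0, "umi", False),   # gene ceiling is exclusive
            (5000, 500, 0.25, "umi", False),    # mito bound is exclusive
            (5000, 400, 0.1, "umi", False),     # UMI floor is exclusive
            (5000, 400, 0.1, "full_length", True),  # UMI rule skipped off-UMI
            (201, 0, 0.2, "full_length", True),
        ],
    )
    def test_boundary_semantics(self, n_genes, n_umi, mito, platform, kept):
        qc = pd.DataFrame({"n_genes_detected": [n_genes], "n_umi": [n_umi],
                           "mito_fraction": [mito]}, index=["c"])
        assert ss.filter_cells(qc, platform=platform)[0] == kept

    def test_relaxing_thresholds_is_monotone(self):
        rng = np.random.default_rng(0)
        qc = pd.DataFrame({
            "n_genes_detected": rng.integers(0, 8000, 500),
            "n_umi": rng.integers(0, 3000, 500),
            "mito_fraction": rng.random(500) * 0.5,
        })
        strict = ss.filter_cells(qc, ss.QCThresholds(), "umi")
        relaxed = ss.filter_cells(
            qc, ss.QCThresholds(min_genes=100, max_genes=7000, max_mito=0.4,
                                min_umi=200), "umi")
        assert not np.any(strict & ~relaxed)

    def test_kept_plus_removed_equals_input(self):
        rng = np.random.default_rng(1)
        qc = pd.DataFrame({"n_genes_detected": rng.integers(0, 8000, 200),
                           "n_umi": rng.integers(0, 3000, 200),
                           "mito_fraction": rng.random(200)})
        keep = ss.filter_cells(qc)
        assert keep.sum() + (~keep).sum() == len(qc)


class TestLognormalize:
    def test_two_equal_counts(self):
        cm = ss.CountMatrix(np.array([[5], [5]]), ["g1", "g2"], ["c1"])
        expr = ss.lognormalize(cm)
        np.testing.assert_allclose(expr.values, np.log(1 + 5000), rtol=1e-12)

    def test_zero_count_maps_to_zero_exactly(self):
        cm = ss.CountMatrix(np.array([[3], [0]]), ["g1", "g2"], ["c1"])
        assert ss.lognormalize(cm).values[1, 0] == 0.0

    def test_single_gene_cell_scale_invariance(self):
        for c in (1, 7, 500):
            cm = ss.CountMatrix(np.array([[c], [0]]), ["g1", "g2"], ["c1"])
            np.testing.assert_allclose(ss.lognormalize(cm).values[0, 0],
                                       np.log(1 + 10000), rtol=1e-12)

    def test_per_cell_identity(self, umi_dataset):
        counts, *_ = umi_dataset
        expr = ss.lognormalize(counts)
        back = np.expm1(expr.values).sum(axis=0)
        np.testing.assert_allclose(back, 10000.0, rtol=1e-6)

    def test_all_zero_cell_error_names_cell(self):
        cm = ss.CountMatrix(np.array([[1, 0], [0, 0]]), ["g1", "g2"], ["good", "bad"])
        with pytest.raises(ValueError, match="bad"):
            ss.lognormalize(cm)


class TestTpmTransform:
    def test_zero_and_ten(self):
        em = ss.ExpressionMatrix(np.array([[0.0], [10.0], [999990.0]]), "raw_tpm",
                                 ["g1", "g2", "g3"], ["c1"])
        out = ss.tpm_transform(em)
        assert out.values[0, 0] == 0.0
        np.testing.assert_allclose(out.values[1, 0], 1.0, rtol=1e-12)
        assert out.transform_tag == "log2tpm10"

    def test_fpkm_cell_hand_oracle(self):
        em = ss.ExpressionMatrix(np.array([[1.0], [1.0], [2.0]]), "raw_tpm",
                                 ["g1", "g2", "g3"], ["c1"])
        out = ss.tpm_transform(em)
        expected = [np.log2(25001), np.log2(25001), np.log2(50001)]
        np.testing.assert_allclose(out.values[:, 0], expected, rtol=1e-12)

    def test_zero_total_cell_raises(self):
        em = ss.ExpressionMatrix(np.zeros((2, 1)), "raw_tpm", ["g1", "g2"], ["c1"])
        with pytest.raises(ValueError, match="zero total"):
            ss.tpm_transform(em)


class TestCellCycleScores:
    def test_identical_expression_scores_zero(self):
        # program genes and controls all identically expressed → score 0
        genes = [f"g{i}" for i in range(30)]
        em = ss.ExpressionMatrix(np.ones((30, 8)), "lognorm10k", genes,
                                 [f"c{i}" for i in range(8)])
        sc = ss.cell_cycle_scores(em, genes[:5], genes[5:10], n_bins=3, seed=0)
        assert np.allclose(sc.to_numpy(), 0.0, atol=1e-12)

    def test_planted_s_program_detected(self):
        cfg = ss.SimConfig(n_cells=1000, n_genes=900, seed=9,
                           cell_cycle_fraction=0.3, n_signature_genes_per_subtype=10)
        counts, truth, sigs = ss.simulate_tme_counts(cfg)
        expr = ss.lognormalize(counts)
        sc = ss.cell_cycle_scores(expr, sigs.s_genes, sigs.g2m_genes, seed=0)
        s_cells = truth.cells.index[truth.cells["cc_phase"] == "S"]
        frac = (sc.loc[s_cells, "s_score"] > sc.loc[s_cells, "g2m_score"]).mean()
        assert frac >= 0.95

    def test_fixed_seed_reproducible(self, umi_lognorm):
        expr, truth, sigs = umi_lognorm
        a = ss.cell_cycle_scores(expr, sigs.s_genes, sigs.g2m_genes, seed=4)
        b = ss.cell_cycle_scores(expr, sigs.s_genes, sigs.g2m_genes, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_intersection_raises(self, umi_lognorm):
        expr, *_ = umi_lognorm
        with pytest.raises(ValueError, match="no program genes"):
            ss.cell_cycle_scores(expr, ["NOT-A-GENE"], expr.gene_ids[:3])


def brute_force_vst_selection(counts, n, loess_span):
    """Direct per-gene reimplementation of VST ranking (loop-based oracle)."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    x = counts.dense().astype(float)
    n_cells = x.shape[1]
    clip = np.sqrt(n_cells)
    means = [row.mean() for row in x]
    variances = [row.var(ddof=1) for row in x]
    keep = [i for i, v in enumerate(variances) if v > 0]
    fitted = lowess([np.log10(variances[i]) for i in keep],
                    [np.log10(means[i]) for i in keep],
                    frac=loess_span, return_sorted=False)
    scores = {}
    for pos, i in enumerate(keep):
        sd = np.sqrt(10 ** fitted[pos])
        z = [(v - means[i]) / sd for v in x[i]]
        z = [max(-clip, min(clip, val)) for val in z]
        zm = sum(z) / len(z)
        scores[counts.gene_ids[i]] = sum((v - zm) ** 2 for v in z) / (len(z) - 1)
    ranked = sorted(scores, key=lambda g: -scores[g])
    return ranked[:n]


class TestHvgVst:
    def test_matches_brute_force_on_toy(self):
        cfg = ss.SimConfig(n_cells=120, n_genes=200, seed=17,
                           n_signature_genes_per_subtype=5,
                           n_marker_genes_per_major_type=5,
                           n_cell_cycle_genes=5)
        counts, *_ = ss.simulate_tme_counts(cfg)
        res = ss.select_hvg_vst(counts, n=40)
        oracle = brute_force_vst_selection(counts, 40, 0.3)
        assert set(res.selected) == set(oracle)

    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(3, (50, 30))
        x[7, :] = 4  # constant gene
        cm = ss.CountMatrix(x, [f"g{i}" for i in range(50)],
                            [f"c{i}" for i in range(30)])
        res = ss.select_hvg_vst(cm, n=50)
        assert res.stats.loc["g7", "standardized_variance"] == 0.0
        assert "g7" not in res.selected

    def test_planted_overdispersed_genes_recovered(self):
        rng = np.random.default_rng(21)
        n_genes, n_cells = 400, 300
        mean = 5.0
        x = rng.poisson(mean, (n_genes, n_cells)).astype(float)
        hot = rng.choice(n_genes, 30, replace=False)
        # overdispersed: gamma-poisson with 10x the background variance
        lam = rng.gamma(shape=0.5, scale=mean / 0.5, size=(30, n_cells))
        x[hot] = rng.poisson(lam)
        cm = ss.CountMatrix(x.astype(int), [f"g{i}" for i in range(n_genes)],
                            [f"c{i}" for i in range(n_cells)])
        res = ss.select_hvg_vst(cm, n=30)
        sens = len(set(res.selected) & {f"g{i}" for i in hot}) / 30
        assert sens >= 0.95

    def test_fewer_genes_than_requested_warns(self, caplog):
        rng = np.random.default_rng(2)
        cm = ss.CountMatrix(rng.poisson(2, (20, 15)), [f"g{i}" for i in range(20)],
                            [f"c{i}" for i in range(15)])
        with caplog.at_level("WARNING", logger="stromascope"):
            res = ss.select_hvg_vst(cm, n=100)
        assert len(res.selected) <= 20
        assert "nonconstant" in caplog.text

    def test_selected_sorted_by_standardized_variance(self, umi_dataset):
        counts, *_ = umi_dataset
        res = ss.select_hvg_vst(counts, n=100)
        sv = res.stats.loc[res.selected, "standardized_variance"].to_numpy()
        assert np.all(np.diff(sv) <= 1e-12)


class TestRegressAndScale:
    def _expr(self, vals, cells=None):
        g = [f"g{i}" for i in range(vals.shape[0])]
        c = cells or [f"c{i}" for i in range(vals.shape[1])]
        return ss.ExpressionMatrix(vals, "lognorm10k", g, c)

    def test_orthogonal_covariate_leaves_centered_expression(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=40)
        cov_vec = rng.normal(size=40)
        cov_vec -= cov_vec.mean()
        y_c = y - y.mean()
        y_orth = y_c - (y_c @ cov_vec) / (cov_vec @ cov_vec) * cov_vec
        expr = self._expr(y_orth[None, :])
        cov = pd.DataFrame({"v": cov_vec}, index=expr.cell_ids)
        out = ss.regress_and_scale(expr, cov)
        expected = (y_orth - y_orth.mean()) / y_orth.std()
        np.testing.assert_allclose(out.values[0], expected, atol=1e-8)

    def test_gene_equal_to_covariate_residual_zero(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=30)
        expr = self._expr(v[None, :])
        cov = pd.DataFrame({"v": v}, index=expr.cell_ids)
        out = ss.regress_and_scale(expr, cov)
        assert np.max(np.abs(out.values)) < 1e-8

    def test_mean_zero_variance_one(self, umi_lognorm):
        expr, truth, _ = umi_lognorm
        sub = expr.subset_genes(expr.gene_ids[100:150])
        cov = pd.DataFrame({"sample_id": truth.cells["sample_id"]},
                           index=truth.cells.index)
        out = ss.regress_and_scale(sub, cov)
        nondeg = out.values.std(axis=1) > 0
        np.testing.assert_allclose(out.values[nondeg].mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(out.values[nondeg].var(axis=1), 1, atol=1e-6)

    def test_collinear_design_no_error(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=20)
        expr = self._expr(rng.normal(size=(3, 20)))
        cov = pd.DataFrame({"a": v, "b": 2 * v}, index=expr.cell_ids)
        out = ss.regress_and_scale(expr, cov)
        assert np.isfinite(out.values).all()

    def test_mismatched_cell_count_raises(self):
        expr = self._expr(np.random.default_rng(6).normal(size=(2, 10)))
        cov = pd.DataFrame({"v": np.arange(5.0)}, index=[f"c{i}" for i in range(5)])
        with pytest.raises(ValueError, match="covariates"):
            ss.regress_and_scale(expr, cov)

    def test_constant_gene_maps_to_zero_row(self):
        expr = self._expr(np.vstack([np.full(10, 3.0),
                                     np.random.default_rng(7).normal(size=10)]))
        cov = pd.DataFrame(index=expr.cell_ids)
        out = ss.regress_and_scale(expr, cov)
        assert np.all(out.values[0] == 0.0)
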