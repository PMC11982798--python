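import warnings

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from scipy import sparse

from fixcurate._utils import FixcurateError, NormalizationError
from fixcurate import cell_score
from fixcurate.cell_score import (
    EscapeScorer,
    composition_table,
    curate,
    digestion_score,
    gene_filter,
    log_normalize,
    module_score,
    qc_filter,
)


def _adata(X, obs=None, gene_prefix="g"):
    X = np.asarray(X)
    obs = obs if obs is not None else pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])])
    var = pd.DataFrame(index=[f"{gene_prefix}{j}" for j in range(X.shape[1])])
    return AnnData(X=sparse.csr_matrix(X), obs=obs, var=var)


class TestQcFilter:
    def test_strict_threshold_semantics(self):
        # cell 0: 999 genes detected, plenty of UMIs -> removed
        # cell 1: exactly 1000 genes and exactly 1250 UMIs -> retained
        n_genes = 1100
        row0 = np.zeros(n_genes)
        row0[:999] = 6  # 999 genes, 5994 UMIs
        row1 = np.zeros(n_genes)
        row1[:999] = 1
        row1[999] = 251  # 1000 genes, 1250 UMIs
        filtered = qc_filter(_adata([row0, row1]))
        assert list(filtered.obs_names) == ["c1"]

    def test_empty_table_errors(self):
        empty = AnnData(X=sparse.csr_matrix((0, 5)))
        with pytest.raises(FixcurateError):
            qc_filter(empty)

    def test_all_removed_errors_with_counts(self):
        with pytest.raises(FixcurateError, match="2 cells"):
            qc_filter(_adata([[1, 0], [0, 1]]))

    def test_idempotent(self, small_cells):
        cells, _ = small_cells
        once = qc_filter(cells, 50, 100)
        twice = qc_filter(once, 50, 100)
        assert list(once.obs_names) == list(twice.obs_names)


class TestGeneFilter:
    def test_detection_count_rule(self):
        # detection counts across 100 cells: [0, 1, 4, 5, 6, 100]
        X = np.zeros((100, 6))
        for j, k in enumerate([0, 1, 4, 5, 6, 100]):
            X[:k, j] = 1
        kept = gene_filter(_adata(X), min_cells=5, sample_key=None)
        assert list(kept.var_names) == ["g3", "g4", "g5"]

    def test_per_sample_keeps_gene_passing_in_any_sample(self):
        X = np.zeros((10, 1))
        X[:5, 0] = 1  # 5 detections, all in sample A
        obs = pd.DataFrame({"sample": ["A"] * 5 + ["B"] * 5},
                           index=[f"c{i}" for i in range(10)])
        kept = gene_filter(_adata(X, obs=obs), min_cells=5)
        assert list(kept.var_names) == ["g0"]

    def test_idempotent(self, small_cells):
        cells, _ = small_cells
        once = gene_filter(cells)
        twice = gene_filter(once)
        assert list(once.var_names) == list(twice.var_names)


class TestLogNormalize:
    def test_already_at_scale_is_log1p(self):
        out = log_normalize(_adata([[1, 1, 2]]), scale=4)
        np.testing.assert_allclose(np.asarray(out.todense()), np.log1p([[1, 1, 2]]))

    def test_equal_counts_stay_equal(self):
        out = np.asarray(log_normalize(_adata([[3, 3, 3, 3]]), scale=100).todense())
        assert np.unique(out).size == 1

    def test_roundtrip_sum_equals_scale(self, small_cells):
        cells, _ = small_cells
        out = log_normalize(cells, scale=10_000)
        sums = np.asarray(np.expm1(out.todense())).sum(axis=1)
        np.testing.assert_allclose(sums, 10_000, rtol=1e-6)

    def test_zero_count_cell_errors(self):
        with pytest.raises(NormalizationError):
            log_normalize(_adata([[0, 0], [1, 2]]))


class TestModuleScore:
    def test_controls_equal_to_signature_give_zero(self):
        rng = np.random.default_rng(0)
        expr = rng.random((30, 20))
        ids = [f"g{j}" for j in range(20)]
        sig = ids[:5]
        scores = module_score(expr, ids, sig, n_bins=1, n_controls=5,
                              control_pool=sig, seed=0)
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_single_bin_all_controls_direct_value(self):
        # signature mean 2.0, non-signature mean 0.5 in every cell -> score 1.5
        expr = np.column_stack([np.full((10, 4), 2.0), np.full((10, 12), 0.5)])
        ids = [f"g{j}" for j in range(16)]
        scores = module_score(expr, ids, ids[:4], n_bins=1, n_controls=12, seed=0)
        np.testing.assert_allclose(scores, 1.5)

    def test_seed_reproducibility_and_stability(self, small_cells):
        cells, truth = small_cells
        expr = log_normalize(cells)
        sig = truth.genes_with("digestion_up")
        s1 = module_score(expr, cells.var_names, sig, seed=3)
        s2 = module_score(expr, cells.var_names, sig, seed=3)
        s3 = module_score(expr, cells.var_names, sig, seed=4)
        np.testing.assert_array_equal(s1, s2)
        assert np.corrcoef(s1, s3)[0, 1] > 0.9

    def test_invariant_to_gene_order_and_zero_genes(self, small_cells):
        cells, truth = small_cells
        expr = np.asarray(log_normalize(cells).todense())
        sig = truth.genes_with("digestion_up")
        base = module_score(expr, cells.var_names, sig, seed=5)
        perm = np.random.default_rng(1).permutation(cells.n_vars)
        permuted = module_score(expr[:, perm], cells.var_names[perm], sig, seed=5)
        np.testing.assert_allclose(base, permuted)
        padded = np.column_stack([expr, np.zeros((cells.n_obs, 7))])
        ids = list(cells.var_names) + [f"zero{k}" for k in range(7)]
        np.testing.assert_allclose(base, module_score(padded, ids, sig, seed=5))

    def test_missing_signature_errors(self):
        with pytest.raises(FixcurateError):
            module_score(np.ones((5, 3)), ["a", "b", "c"], ["nope"], seed=0)


class TestEscapeScorer:
    def test_bimodal_scores_split_at_boundary(self):
        rng = np.random.default_rng(0)
        scores = np.concatenate([rng.normal(0, 0.05, 100), rng.normal(1, 0.05, 100)])
        est = EscapeScorer(random_state=0).fit(scores)
        assert 0.2 < est.threshold_ < 0.8
        np.testing.assert_array_equal(est.predict(scores), scores >= est.threshold_)
        assert est.predict(scores).sum() == 100

    def test_unimodal_scores_flag_nothing(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(0.3, 0.1, 500)
        with pytest.warns(UserWarning, match="unimodal"):
            est = EscapeScorer(random_state=0).fit(scores)
        assert est.degenerate_
        assert est.threshold_ == np.inf
        assert est.predict(scores).sum() == 0

    def test_sklearn_params_roundtrip(self):
        est = EscapeScorer(min_separation=1.5, random_state=7)
        assert EscapeScorer(**est.get_params()).get_params() == est.get_params()


class TestDigestionScore:
    def test_escape_recovery_on_planted_data(self, small_cells):
        cells, truth = small_cells
        signature = truth.genes_with("digestion_up") + truth.genes_with("digestion_amplified")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sv = digestion_score(cells, signature, seed=2)
        flags = sv.flagged.to_numpy()
        escape = cells.obs["truth_escape"].to_numpy(dtype=bool)
        assert 0.19 <= flags.mean() <= 0.29
        tp = (flags & escape).sum()
        assert tp / escape.sum() >= 0.9
        assert tp / flags.sum() >= 0.8
        # escape scores stochastically dominate
        from scipy.stats import mannwhitneyu

        p = mannwhitneyu(sv.score[escape], sv.score[~escape], alternative="greater").pvalue
        assert p < 1e-6

    def test_no_escape_data_flags_below_5pct(self):
        from conftest import small_config
        from fixcurate.simdata import simulate_cells

        cells, truth = simulate_cells(small_config(seed=13, sc_params={"escape_fraction": 0.0}))
        signature = truth.genes_with("digestion_up")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sv = digestion_score(cells, signature, seed=2)
        assert sv.flagged.mean() < 0.05


class TestCurate:
    def test_printed_bookkeeping(self):
        X = sparse.csr_matrix((66_904, 1))
        cells = AnnData(X=X, obs=pd.DataFrame(index=[f"c{i}" for i in range(66_904)]))
        flags = pd.Series([True] * 16_107 + [False] * 50_797, index=cells.obs_names)
        curated, report = curate(cells, flags)
        assert report["n_after"] == 50_797
        assert report["pct_flagged"] == 24
        assert curated.n_obs == 50_797

    def test_no_flags_is_identity(self, small_cells):
        cells, _ = small_cells
        flags = pd.Series(False, index=cells.obs_names)
        curated, report = curate(cells, flags)
        assert curated.n_obs == cells.n_obs
        assert report["pct_flagged"] == 0

    def test_conservation_and_misalignment(self, small_cells):
        cells, _ = small_cells
        rng = np.random.default_rng(0)
        flags = pd.Series(rng.random(cells.n_obs) < 0.3, index=cells.obs_names)
        _, report = curate(cells, flags)
        assert report["n_after"] + report["n_flagged"] == report["n_before"]
        with pytest.raises(FixcurateError):
            curate(cells, flags.iloc[:-1])


class TestCompositionTable:
    def test_fractions_sum_to_one_per_condition(self, small_cells):
        cells, _ = small_cells
        cells = cells.copy()
        cells.obs["cluster"] = cells.obs["tissue"]
        tab = composition_table(cells)
        np.testing.assert_allclose(tab.sum(axis=0), 1.0, atol=1e-9)

    def test_simple_fraction(self):
        obs = pd.DataFrame(
            {"cluster": ["A"] * 50 + ["B"] * 50, "condition": ["WW"] * 100},
            index=[f"c{i}" for i in range(100)],
        )
        cells = AnnData(X=sparse.csr_matrix((100, 1)), obs=obs)
        tab = composition_table(cells)
        assert tab.loc["A", "WW"] == pytest.approx(0.5)

    def test_missing_labels_error(self, small_cells):
        cells, _ = small_cells
        with pytest.raises(FixcurateError):
            composition_table(cells, cluster_key="not_there")
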