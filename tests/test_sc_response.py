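import warnings

import numpy as np
import pandas as pd
import pytest

from fixcurate._utils import FixcurateError
from fixcurate import cell_score, sc_response
from fixcurate.sc_response import (
    apply_response_cuts,
    coexpression_fraction,
    dual_program_detection,
    marker_filter_for_regulons,
    pseudobulk_aggregate,
    pseudobulk_de,
    tissue_drought_response,
    wilcoxon_rank_sum,
)

from oracles import wilcoxon_exact_oracle


class TestWilcoxon:
    def test_fully_separated_small_samples(self):
        stat, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert stat == 0
        assert p == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_exact_branch_matches_enumeration_and_asymptotic_close(self):
        rng = np.random.default_rng(2)
        from scipy.stats import mannwhitneyu

        for _ in range(5):
            values = rng.permutation(np.arange(14, dtype=float))
            a, b = values[:7], values[7:]
            p_exact = wilcoxon_exact_oracle(a, b)
            _, p_ours = wilcoxon_rank_sum(a, b)
            assert p_ours == pytest.approx(p_exact, rel=1e-9)
            p_asym = mannwhitneyu(a, b, method="asymptotic").pvalue
            if 0.005 < p_exact < 0.9:
                assert p_asym == pytest.approx(p_exact, rel=0.10)

    def test_empty_group_errors(self):
        with pytest.raises(FixcurateError):
            wilcoxon_rank_sum([], [1.0])


class TestResponseCuts:
    def test_threshold_boundaries_are_strict(self):
        tbl = pd.DataFrame(
            {
                "log2fc": [0.80, 0.75, -0.80, 0.80, 0.80],
                "p": [0.01, 0.01, 0.01, 0.05, 0.01],
                "pct": [0.06, 0.06, 0.06, 0.06, 0.04],
            },
            index=["keep_up", "lfc_at_cut", "keep_down", "p_at_cut", "low_pct"],
        )
        up, down = apply_response_cuts(tbl, 0.05, 0.75, 0.05)
        assert up == ["keep_up"]
        assert down == ["keep_down"]


@pytest.fixture(scope="module")
def response(small_cells):
    cells, truth = small_cells
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tissue_drought_response(cells), truth


@pytest.fixture(scope="module")
def md_mesophyll(small_cells):
    cells, truth = small_cells
    mes = cells[(cells.obs["tissue"] == "mesophyll") & (cells.obs["condition"] == "MD")].copy()
    return mes, truth


class TestTissueResponse:

    def test_planted_drought_genes_recovered_in_mesophyll(self, response):
        resp, truth = response
        planted_up = set(truth.genes_with("drought_up"))
        found = set(resp.up_genes["mesophyll"])
        assert len(found & planted_up) / len(planted_up) >= 0.8

    def test_up_down_disjoint_and_thresholds_enforced(self, response):
        resp, _ = response
        for tissue in resp.tables:
            assert not set(resp.up_genes[tissue]) & set(resp.down_genes[tissue])
            tbl = resp.tables[tissue].loc[resp.up_genes[tissue]]
            assert (tbl["p"] < resp.p_cut).all()
            assert (tbl["log2fc"] > resp.lfc_cut).all()
            assert (tbl["pct"] >= resp.pct_cut).all()

    def test_invariant_to_cell_and_gene_order(self, small_cells):
        cells, _ = small_cells
        rng = np.random.default_rng(0)
        shuffled = cells[rng.permutation(cells.n_obs), rng.permutation(cells.n_vars)].copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = tissue_drought_response(cells)
            perm = tissue_drought_response(shuffled)
        for tissue in base.up_genes:
            assert sorted(base.up_genes[tissue]) == sorted(perm.up_genes[tissue])
            assert sorted(base.down_genes[tissue]) == sorted(perm.down_genes[tissue])

    def test_small_tissue_skipped_with_warning(self, small_cells):
        cells, _ = small_cells
        cells = cells.copy()
        labels = cells.obs["tissue"].astype(str)
        labels.iloc[:5] = "rare"
        cells.obs["tissue"] = labels
        with pytest.warns(UserWarning, match="rare"):
            resp = tissue_drought_response(cells)
        assert "rare" in resp.skipped


class TestPseudobulk:
    def test_mean_aggregation(self):
        from anndata import AnnData
        from scipy import sparse

        obs = pd.DataFrame(
            {"cluster": ["A", "A", "B"], "sample": ["s1", "s1", "s1"]},
            index=["c1", "c2", "c3"],
        )
        cells = AnnData(X=sparse.csr_matrix(np.array([[1.0], [3.0], [5.0]])), obs=obs)
        prof = pseudobulk_aggregate(cells, expr=cells.X)
        assert prof.loc[prof.index[0], "A|s1"] == pytest.approx(2.0)
        assert prof.loc[prof.index[0], "B|s1"] == pytest.approx(5.0)
        assert prof.shape[1] == 2  # one column per non-empty (cluster, sample)

    def test_identical_profiles_yield_no_hits(self):
        profiles = pd.DataFrame(
            np.tile(np.log1p([5.0, 10.0, 40.0]), (4, 1)).T,
            index=["g1", "g2", "g3"],
            columns=["a1", "a2", "b1", "b2"],
        )
        _, sig = pseudobulk_de(profiles, ["a1", "a2"], ["b1", "b2"])
        assert sig == []

    def test_planted_fold_changes_recovered(self, small_cells):
        cells, truth = small_cells
        cells = cells.copy()
        cells.obs["cluster"] = cells.obs["tissue"]
        # split each sample into two pseudo-replicates for replicate-aware DE
        half = np.arange(cells.n_obs) % 2
        cells.obs["sample"] = cells.obs["sample"].astype(str) + np.where(half == 0, "_r1", "_r2")
        mes = cells[cells.obs["cluster"] == "mesophyll"].copy()
        prof = pseudobulk_aggregate(mes)
        ww = [c for c in prof.columns if "_WW" in c]
        md = [c for c in prof.columns if "_MD" in c]
        de, sig = pseudobulk_de(prof, ww, md)
        planted = set(truth.genes_with("drought_up")) | set(truth.genes_with("drought_down"))
        assert len(set(sig) & planted) / len(planted) >= 0.9

    def test_too_few_replicates_error(self):
        profiles = pd.DataFrame(np.ones((3, 2)), columns=["a1", "b1"])
        with pytest.raises(FixcurateError):
            pseudobulk_de(profiles, ["a1"], ["b1"])


class TestDualPrograms:
    def test_label_recall_against_truth(self, md_mesophyll):
        mes, truth = md_mesophyll
        can = truth.genes_with("canonical_drought")
        iron = truth.genes_with("iron_starvation")
        dual = dual_program_detection(mes, can, iron, seed=0)
        labels = dual.table["label"].to_numpy()
        truth_labels = mes.obs["truth_subpopulation"].to_numpy()
        for program in ("canonical", "iron"):
            mask = truth_labels == program
            hit = np.isin(labels[mask], [program, "shared"]).sum()
            assert hit / mask.sum() >= 0.85

    def test_label_conservation(self, md_mesophyll):
        mes, truth = md_mesophyll
        dual = dual_program_detection(
            mes, truth.genes_with("canonical_drought"), truth.genes_with("iron_starvation"), seed=0
        )
        counts = dual.counts()
        assert sum(counts.values()) == mes.n_obs

    def test_swapping_programs_swaps_labels_exactly(self, md_mesophyll):
        mes, truth = md_mesophyll
        can = truth.genes_with("canonical_drought")
        iron = truth.genes_with("iron_starvation")
        fwd = dual_program_detection(mes, can, iron, seed=0)
        rev = dual_program_detection(mes, iron, can, seed=0)
        swap = {"canonical": "iron", "iron": "canonical", "shared": "shared", "none": "none"}
        assert (rev.table["label"].map(swap) == fwd.table["label"]).all()

    def test_well_watered_cells_mostly_none(self, small_cells):
        cells, truth = small_cells
        ww = cells[(cells.obs["tissue"] == "mesophyll") & (cells.obs["condition"] == "WW")].copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dual = dual_program_detection(
                ww, truth.genes_with("canonical_drought"), truth.genes_with("iron_starvation"), seed=0
            )
        assert (dual.table["label"] == "none").mean() >= 0.9

    def test_absent_program_errors(self, md_mesophyll):
        mes, truth = md_mesophyll
        with pytest.raises(FixcurateError):
            dual_program_detection(mes, ["missing1"], truth.genes_with("iron_starvation"), seed=0)


class TestCoexpression:
    def test_worked_examples(self):
        expr = np.array(
            # cells c1..c3, genes a, b
            [[1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]
        )
        assert coexpression_fraction(expr, ["a", "b"], "a", "b") == pytest.approx(1 / 3)
        ident = np.array([[1.0, 1.0], [0.0, 0.0], [2.0, 2.0]])
        assert coexpression_fraction(ident, ["a", "b"], "a", "b") == pytest.approx(1.0)
        disjoint = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert coexpression_fraction(disjoint, ["a", "b"], "a", "b") == 0.0

    def test_undetected_pair_warns_and_returns_zero(self):
        expr = np.zeros((4, 2))
        with pytest.warns(UserWarning):
            assert coexpression_fraction(expr, ["a", "b"], "a", "b") == 0.0

    def test_program_exclusivity_on_planted_cells(self, small_cells):
        cells, truth = small_cells
        mes = cells[(cells.obs["tissue"] == "mesophyll") & (cells.obs["condition"] == "MD")].copy()
        expr = cell_score.log_normalize(mes)
        can = truth.genes_with("canonical_drought")
        iron = truth.genes_with("iron_starvation")
        cross = coexpression_fraction(expr, mes.var_names, can[0], iron[0])
        within = coexpression_fraction(expr, mes.var_names, can[0], can[1])
        assert cross < 0.1
        assert within > 0.5


class TestMarkerFilter:
    def test_threshold_semantics(self):
        markers = pd.DataFrame(
            {
                "pct": [0.11, 0.10, 0.50, 0.50],
                "log2fc": [0.2, 0.2, 0.1, 0.2],
                "padj": [0.01, 0.01, 0.01, 0.05],
            },
            index=["kept", "pct_at_cut", "lfc_at_cut", "padj_at_cut"],
        )
        out = marker_filter_for_regulons(markers)
        assert list(out.index) == ["kept"]

    def test_empty_input_empty_output(self):
        markers = pd.DataFrame(columns=["pct", "log2fc", "padj"])
        assert marker_filter_for_regulons(markers).empty

    def test_missing_columns_error(self):
        with pytest.raises(FixcurateError, match="padj"):
            marker_filter_for_regulons(pd.DataFrame({"pct": [0.5], "log2fc": [1.0]}))
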