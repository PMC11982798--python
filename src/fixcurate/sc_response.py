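"""Drought-response inference on the curated single-cell atlas.

Per-tissue mild-drought (MD vs WW) differential expression by Wilcoxon
rank-sum with the detection-fraction and fold-change cuts, pseudobulk
aggregation and replicate-aware DE, detection of the two mutually exclusive
mesophyll drought programs (canonical/ABA vs iron starvation), detection-set
coexpression, and the marker filter that prepares regulon-inference input.

Single-cell log2 fold changes follow the common convention
log2((mean(expm1(x_b)) + 1) / (mean(expm1(x_a)) + 1)) on log-normalized data.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse, stats

from ._utils import FixcurateError
from .bulk_de import BulkCounts, nb_wald
from .cell_score import EscapeScorer, log_normalize, module_score
from .signature import intersections

TISSUE_P_CUT = 0.05
TISSUE_LFC_CUT = 0.75
TISSUE_PCT_CUT = 0.05
PSEUDOBULK_P_CUT = 0.05
PSEUDOBULK_LFC_CUT = 0.5
MIN_CELLS_PER_SIDE = 10


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Rank-sum (Mann-Whitney U) test, two-sided.

    Exact enumeration for small tie-free samples (both n <= 20), otherwise the
    tie-corrected normal approximation. Returns (U for sample a, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise FixcurateError("empty group in rank-sum test")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _ranksum_pvalues(x: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Vectorized tie-corrected normal-approximation rank-sum p per column
    (group b vs rest), with continuity correction."""
    n = x.shape[0]
    n1 = int(mask_b.sum())
    n2 = n - n1
    ranks = stats.rankdata(x, axis=0)
    r1 = ranks[mask_b].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    # tie correction per column
    tie_term = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        _, counts = np.unique(x[:, j], return_counts=True)
        tie_term[j] = (counts**3 - counts).sum()
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sd = np.sqrt(np.maximum(var_u, 1e-300))
    z = (np.abs(u1 - mean_u) - 0.5) / sd
    z = np.maximum(z, 0.0)
    p = 2.0 * stats.norm.sf(z)
    p[var_u <= 0] = 1.0
    return np.clip(p, 0.0, 1.0)


def sc_log2fc(expr_a: np.ndarray, expr_b: np.ndarray) -> np.ndarray:
    """log2((mean expm1 b + 1) / (mean expm1 a + 1)) per gene."""
    mean_a = np.expm1(expr_a).mean(axis=0)
    mean_b = np.expm1(expr_b).mean(axis=0)
    return np.log2((mean_b + 1.0) / (mean_a + 1.0))


def apply_response_cuts(
    tbl: pd.DataFrame, p_cut: float, lfc_cut: float, pct_cut: float
) -> tuple[list[str], list[str]]:
    """Split a per-gene table (columns log2fc, p, pct) into up/down responsive
    sets: p < p_cut, |log2fc| strictly above lfc_cut, detection fraction at
    least pct_cut in the induced-side population."""
    passing = (tbl["p"] < p_cut) & (tbl["log2fc"].abs() > lfc_cut) & (tbl["pct"] >= pct_cut)
    up = list(tbl.index[passing & (tbl["log2fc"] > 0)])
    down = list(tbl.index[passing & (tbl["log2fc"] < 0)])
    return up, down


@dataclass
class TissueResponse:
    """Per-tissue MD-responsive gene sets with the thresholds applied."""

    tables: dict[str, pd.DataFrame]
    up_genes: dict[str, list[str]]
    down_genes: dict[str, list[str]]
    p_cut: float
    lfc_cut: float
    pct_cut: float
    skipped: list[str] = field(default_factory=list)

    def shared_unique(self, direction: str = "up") -> dict[frozenset, int]:
        """UpSet decomposition of the per-tissue responsive sets."""
        sets = self.up_genes if direction == "up" else self.down_genes
        nonempty = {t: set(g) for t, g in sets.items() if g}
        return intersections(nonempty) if nonempty else {}


def tissue_drought_response(
    cells: AnnData,
    tissue_key: str = "tissue",
    condition_key: str = "condition",
    p_cut: float = TISSUE_P_CUT,
    lfc_cut: float = TISSUE_LFC_CUT,
    pct_cut: float = TISSUE_PCT_CUT,
    expr=None,
) -> TissueResponse:
    """Per-tissue drought response: MD vs WW Wilcoxon per gene on
    log-normalized expression.

    A gene is reported when p < p_cut, |log2fc| > lfc_cut (strict), and it is
    detected in at least ``pct_cut`` of the cells of the condition where it is
    induced (the higher-mean side). Tissues with fewer than 10 cells in either
    condition are skipped with a warning.
    """
    if expr is None:
        expr = log_normalize(cells)
    dense = np.asarray(expr.todense()) if sparse.issparse(expr) else np.asarray(expr)
    genes = cells.var_names
    cond = cells.obs[condition_key].to_numpy()
    tables: dict[str, pd.DataFrame] = {}
    up: dict[str, list[str]] = {}
    down: dict[str, list[str]] = {}
    skipped: list[str] = []
    for tissue in pd.unique(cells.obs[tissue_key]):
        t_mask = (cells.obs[tissue_key] == tissue).to_numpy()
        md = t_mask & (cond == "MD")
        ww = t_mask & (cond == "WW")
        if md.sum() < MIN_CELLS_PER_SIDE or ww.sum() < MIN_CELLS_PER_SIDE:
            warnings.warn(f"tissue {tissue!r} has <{MIN_CELLS_PER_SIDE} cells in a condition; skipped")
            skipped.append(str(tissue))
            continue
        sub = dense[md | ww]
        p = _ranksum_pvalues(sub, md[md | ww])
        lfc = sc_log2fc(dense[ww], dense[md])
        pct_md = (dense[md] > 0).mean(axis=0)
        pct_ww = (dense[ww] > 0).mean(axis=0)
        pct_induced = np.where(lfc >= 0, pct_md, pct_ww)
        tbl = pd.DataFrame(
            {"log2fc": lfc, "p": p, "pct": pct_induced}, index=genes
        )
        tables[str(tissue)] = tbl
        up[str(tissue)], down[str(tissue)] = apply_response_cuts(tbl, p_cut, lfc_cut, pct_cut)
    return TissueResponse(
        tables=tables, up_genes=up, down_genes=down,
        p_cut=p_cut, lfc_cut=lfc_cut, pct_cut=pct_cut, skipped=skipped,
    )


def pseudobulk_aggregate(
    cells: AnnData,
    by: tuple[str, str] = ("cluster", "sample"),
    expr=None,
) -> pd.DataFrame:
    """Genes x groups matrix of mean log-normalized expression per
    (cluster, sample) group; empty groups do not appear."""
    for key in by:
        if key not in cells.obs:
            raise FixcurateError(f"missing obs column {key!r}")
    if expr is None:
        expr = log_normalize(cells)
    dense = np.asarray(expr.todense()) if sparse.issparse(expr) else np.asarray(expr)
    cols = {}
    n_cells = {}
    for keys, idx in sorted(cells.obs.groupby(list(by), observed=True).indices.items()):
        name = "|".join(str(k) for k in (keys if isinstance(keys, tuple) else (keys,)))
        cols[name] = dense[idx].mean(axis=0)
        n_cells[name] = int(len(idx))
    out = pd.DataFrame(cols, index=cells.var_names)
    out.attrs["n_cells"] = n_cells
    return out


def pseudobulk_de(
    profiles: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    p_cut: float = PSEUDOBULK_P_CUT,
    lfc_cut: float = PSEUDOBULK_LFC_CUT,
    cell_scale: int = 50,
) -> tuple[pd.DataFrame, list[str]]:
    """Replicate-aware DE on pseudobulk profiles (group_b vs group_a).

    The log-scale profiles are rescaled to pseudo-counts — expm1, multiplied
    by the number of cells behind each group (recorded by
    ``pseudobulk_aggregate``; falls back to ``cell_scale``) so the values
    carry the depth a summed pseudobulk library would have — then fed through
    the NB Wald test. Returns the full table and the significant set
    {p < p_cut and |log2fc| > lfc_cut} (strict on the fold change).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise FixcurateError("pseudobulk DE needs >= 2 groups per side")
    sub = profiles[list(group_a) + list(group_b)]
    n_cells = profiles.attrs.get("n_cells", {})
    scale = np.array([n_cells.get(c, cell_scale) for c in sub.columns], dtype=float)
    pseudo = np.rint(np.expm1(sub.to_numpy()) * scale).astype(np.int64)
    design = pd.DataFrame(
        {
            "sample": sub.columns,
            "digestion": "U",
            "condition": ["WW"] * len(group_a) + ["MD"] * len(group_b),
            "replicate": list(range(1, len(group_a) + 1)) + list(range(1, len(group_b) + 1)),
        }
    ).set_index("sample")
    bulk = BulkCounts(
        counts=pd.DataFrame(pseudo, index=profiles.index, columns=sub.columns),
        design=design,
    )
    de = nb_wald(bulk, {"condition": "WW"}, {"condition": "MD"})
    sig = list(de.index[(de["p"] < p_cut) & (de["log2fc"].abs() > lfc_cut)])
    return de, sig


@dataclass
class DualAssignment:
    """Per-cell canonical vs iron-starvation drought-program assignment."""

    table: pd.DataFrame  # columns score_canonical, score_iron, label
    canonical_genes: list[str]
    iron_genes: list[str]
    threshold_canonical: float
    threshold_iron: float

    def counts(self) -> dict[str, int]:
        return self.table["label"].value_counts().reindex(
            ["canonical", "iron", "shared", "none"], fill_value=0
        ).to_dict()


def _program_seed(seed: int, genes) -> int:
    """Seed derived from the gene list content so scoring a program does not
    depend on argument position (swapping programs swaps labels exactly)."""
    digest = zlib.crc32(",".join(sorted(genes)).encode())
    return int((seed + digest) % (2**31 - 1))


def dual_program_detection(
    cells: AnnData,
    canonical_genes,
    iron_genes,
    seed: int = 0,
    tissue: str | None = None,
    tissue_key: str = "tissue",
    expr=None,
) -> DualAssignment:
    """Score each (mesophyll) cell against the two drought programs and label
    it canonical / iron / shared / none.

    Each program's score is a binned-control module score; each cutoff comes
    from the same 2-component-mixture rule used for the digestion score. A
    cell above both cutoffs is ``shared``, above one is that program's label,
    above neither is ``none``.
    """
    if tissue is not None:
        cells = cells[cells.obs[tissue_key] == tissue].copy()
        expr = None
    canonical_genes = list(canonical_genes)
    iron_genes = list(iron_genes)
    for name, prog in (("canonical", canonical_genes), ("iron", iron_genes)):
        if not any(g in cells.var_names for g in prog):
            raise FixcurateError(f"{name} program absent from the expression matrix")
    if expr is None:
        expr = log_normalize(cells)

    def score_and_cut(genes):
        s = module_score(expr, cells.var_names, genes, seed=_program_seed(seed, genes))
        est = EscapeScorer(random_state=_program_seed(seed, genes))
        flags = est.fit_predict(s)
        return s, flags, float(est.threshold_)

    s_can, f_can, t_can = score_and_cut(canonical_genes)
    s_iron, f_iron, t_iron = score_and_cut(iron_genes)
    label = np.where(
        f_can & f_iron, "shared",
        np.where(f_can, "canonical", np.where(f_iron, "iron", "none")),
    )
    table = pd.DataFrame(
        {"score_canonical": s_can, "score_iron": s_iron, "label": label},
        index=cells.obs_names,
    )
    return DualAssignment(
        table=table,
        canonical_genes=canonical_genes,
        iron_genes=iron_genes,
        threshold_canonical=t_can,
        threshold_iron=t_iron,
    )


def coexpression_fraction(expr, gene_ids, gene_a: str, gene_b: str, detect_cut: float = 0.0) -> float:
    """Jaccard coexpression of two genes: cells expressing both over cells
    expressing either (expression above ``detect_cut``)."""
    gene_ids = pd.Index(gene_ids)
    for g in (gene_a, gene_b):
        if g not in gene_ids:
            raise FixcurateError(f"gene {g!r} not in the matrix")
    dense = np.asarray(expr.todense()) if sparse.issparse(expr) else np.asarray(expr)
    det_a = dense[:, gene_ids.get_loc(gene_a)] > detect_cut
    det_b = dense[:, gene_ids.get_loc(gene_b)] > detect_cut
    union = (det_a | det_b).sum()
    if union == 0:
        warnings.warn(f"neither {gene_a} nor {gene_b} is detected in any cell")
        return 0.0
    return float((det_a & det_b).sum() / union)


def marker_filter_for_regulons(
    markers: pd.DataFrame,
    pct_cut: float = 0.10,
    lfc_cut: float = 0.1,
    padj_cut: float = 0.05,
) -> pd.DataFrame:
    """Filter a per-cluster marker table to the regulon-inference input:
    genes expressed in more than ``pct_cut`` of cells (strict >), log2 fold
    change above ``lfc_cut`` (strict >) and adjusted p below ``padj_cut``."""
    required = {"pct", "log2fc", "padj"}
    missing = required - set(markers.columns)
    if missing:
        raise FixcurateError(f"marker table missing columns {sorted(missing)}")
    keep = (
        (markers["pct"] > pct_cut)
        & (markers["log2fc"] > lfc_cut)
        & (markers["padj"] < padj_cut)
    )
    return markers[keep].copy()
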