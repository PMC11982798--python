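"""Single-cell QC, normalization, digestion-response scoring and curation.

Cells are held in an AnnData (cells x genes raw counts in ``.X``, per-cell
metadata in ``.obs``). The digestion-response score is a per-cell module
score: mean log-normalized expression of the signature genes minus the mean
of expression-matched control genes drawn from abundance bins. Cells from
fixed samples whose score clears a data-driven threshold (equal-posterior
boundary of a 2-component Gaussian mixture) are flagged as having escaped
fixation and removed to curate the atlas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse, stats
from scipy.optimize import brentq
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from ._utils import FixcurateError, NormalizationError, pct
from .signature import SignatureSet

QC_MIN_GENES = 1000
QC_MIN_UMIS = 1250
GENE_MIN_CELLS = 5
NORM_SCALE = 10_000
SCORE_BINS = 25
SCORE_CONTROLS = 50


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)


def qc_filter(cells: AnnData, min_genes: int = QC_MIN_GENES, min_umis: int = QC_MIN_UMIS) -> AnnData:
    """Drop cells expressing fewer than ``min_genes`` genes or with fewer than
    ``min_umis`` UMIs (strict-< exclusion: a cell at exactly the cut stays)."""
    if cells.n_obs == 0:
        raise FixcurateError("QC filter applied to an empty cell table")
    X = cells.X
    if sparse.issparse(X):
        n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
        n_umis = np.asarray(X.sum(axis=1)).ravel()
    else:
        n_genes = (X > 0).sum(axis=1)
        n_umis = X.sum(axis=1)
    keep = (n_genes >= min_genes) & (n_umis >= min_umis)
    if not keep.any():
        raise FixcurateError(
            f"QC removed all {cells.n_obs} cells (min_genes={min_genes}, min_umis={min_umis})"
        )
    return cells[keep].copy()


def gene_filter(cells: AnnData, min_cells: int = GENE_MIN_CELLS, sample_key: str | None = "sample") -> AnnData:
    """Drop low-abundance genes detected in fewer than ``min_cells`` cells.

    The filter is evaluated per sample (as samples are processed before
    merging): a gene is kept if it reaches the cut in at least one sample.
    Pass ``sample_key=None`` to evaluate on the pooled table.
    """
    det = cells.X > 0
    if sample_key is not None and sample_key in cells.obs:
        keep = np.zeros(cells.n_vars, dtype=bool)
        for _, idx in cells.obs.groupby(sample_key, observed=True).indices.items():
            counts = np.asarray(det[idx].sum(axis=0)).ravel()
            keep |= counts >= min_cells
    else:
        keep = np.asarray(det.sum(axis=0)).ravel() >= min_cells
    return cells[:, keep].copy()


def log_normalize(cells: AnnData, scale: int = NORM_SCALE):
    """Depth-normalize each cell to ``scale`` total counts, then log1p.

    Returns a cells x genes matrix (sparse if the input is sparse) satisfying
    sum(expm1(row)) == scale for every cell.
    """
    X = cells.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise NormalizationError(f"{int((totals == 0).sum())} cells have zero counts")
    if sparse.issparse(X):
        out = X.multiply(scale / totals[:, None]).tocsr()
        out.data = np.log1p(out.data)
        return out
    return np.log1p(X * (scale / totals[:, None]))


def _expression_bins(gene_means: np.ndarray, gene_ids: pd.Index, n_bins: int) -> np.ndarray:
    """Equal-size abundance bins by average expression; -1 marks undetected
    genes, which take no part in binning or control pools. Ties are broken by
    gene id so the binning does not depend on column order."""
    bins = np.full(gene_means.size, -1, dtype=int)
    detected = np.flatnonzero(gene_means > 0)
    if detected.size == 0:
        return bins
    order = detected[np.lexsort((np.asarray(gene_ids)[detected], gene_means[detected]))]
    labels = pd.qcut(
        np.arange(order.size), q=min(n_bins, order.size), labels=False, duplicates="drop"
    )
    bins[order] = labels
    return bins


def module_score(
    expr,
    gene_ids,
    genes,
    n_bins: int = SCORE_BINS,
    n_controls: int = SCORE_CONTROLS,
    seed: int = 0,
    control_pool=None,
) -> np.ndarray:
    """Per-cell module score of a gene set with binned control genes.

    Genes are binned into ``n_bins`` abundance bins by average expression
    across cells. For each signature gene, ``n_controls`` control genes are
    drawn without replacement from its bin, excluding signature genes (or
    from ``control_pool`` if given); a bin with too few candidates is sampled
    with replacement with a warning. The score is mean signature expression
    minus mean control expression, per cell.
    """
    gene_ids = pd.Index(gene_ids)
    sig_pos = gene_ids.get_indexer([g for g in genes if g in gene_ids])
    sig_pos = sig_pos[sig_pos >= 0]
    if sig_pos.size == 0:
        raise FixcurateError("no signature gene present in the expression matrix")
    dense = _dense(expr)
    gene_means = dense.mean(axis=0)
    bins = _expression_bins(gene_means, gene_ids, n_bins)
    sig_set = set(sig_pos.tolist())
    if control_pool is not None:
        pool_pos = set(gene_ids.get_indexer([g for g in control_pool if g in gene_ids]).tolist())
        pool_pos.discard(-1)
    else:
        pool_pos = None

    # iterate signature genes and candidates in gene-id order so the draws
    # depend only on (gene ids, seed), never on column order
    rng = np.random.default_rng(seed)
    control_idx: list[np.ndarray] = []
    id_order = np.argsort(np.asarray(gene_ids)[sig_pos])
    for g in sig_pos[id_order]:
        if bins[g] < 0:  # undetected signature gene: constant 0 contribution
            continue
        same_bin = np.flatnonzero(bins == bins[g])
        if pool_pos is not None:
            candidates = np.array([i for i in same_bin if i in pool_pos], dtype=int)
        else:
            candidates = np.array([i for i in same_bin if i not in sig_set], dtype=int)
        if candidates.size == 0:
            warnings.warn("empty control pool for a signature gene's bin; gene skipped in controls")
            continue
        candidates = candidates[np.argsort(np.asarray(gene_ids)[candidates])]
        if candidates.size >= n_controls:
            control_idx.append(rng.choice(candidates, size=n_controls, replace=False))
        else:
            warnings.warn("control bin smaller than n_controls; sampling with replacement")
            control_idx.append(rng.choice(candidates, size=n_controls, replace=True))
    controls = np.concatenate(control_idx) if control_idx else np.array([], dtype=int)
    sig_mean = dense[:, sig_pos].mean(axis=1)
    ctrl_mean = dense[:, controls].mean(axis=1) if controls.size else np.zeros(dense.shape[0])
    return sig_mean - ctrl_mean


class EscapeScorer(BaseEstimator):
    """Data-driven threshold on a per-cell score via a 2-component Gaussian
    mixture; the boundary is the equal-posterior point between the components.

    The mixture is accepted only when it beats a single Gaussian by
    likelihood ratio and the components are genuinely separated (Ashman's
    D > ``min_separation``); otherwise the score distribution is treated as
    unimodal, the threshold is +inf and nothing is flagged.

    Attributes (after fit): ``threshold_``, ``degenerate_``, ``means_``,
    ``lrt_stat_``, ``ashman_d_``.
    """

    def __init__(self, min_separation: float = 2.0, lrt_crit: float = 16.27,
                 random_state: int | None = 0):
        self.min_separation = min_separation
        self.lrt_crit = lrt_crit  # chi-square(3) 0.999 quantile
        self.random_state = random_state

    def fit(self, scores, y=None):
        x = np.asarray(scores, dtype=float).reshape(-1, 1)
        if x.shape[0] < 10:
            raise FixcurateError("need at least 10 scores to fit the mixture")
        gm = GaussianMixture(n_components=2, n_init=5, random_state=self.random_state)
        gm.fit(x)
        ll2 = gm.score(x) * x.shape[0]
        mu0, sd0 = x.mean(), max(x.std(), 1e-12)
        ll1 = stats.norm.logpdf(x.ravel(), mu0, sd0).sum()
        self.lrt_stat_ = float(2.0 * (ll2 - ll1))
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        lo, hi = np.argsort(means)
        self.means_ = means[[lo, hi]]
        self.ashman_d_ = float(
            abs(means[hi] - means[lo]) * np.sqrt(2.0 / (sds[lo] ** 2 + sds[hi] ** 2))
        )
        self.degenerate_ = (self.lrt_stat_ < self.lrt_crit) or (self.ashman_d_ < self.min_separation)
        if self.degenerate_:
            warnings.warn("score distribution is unimodal; no cells will be flagged")
            self.threshold_ = np.inf
            return self

        w = gm.weights_

        def post_diff(v: float) -> float:
            return (
                np.log(w[hi]) + stats.norm.logpdf(v, means[hi], sds[hi])
                - np.log(w[lo]) - stats.norm.logpdf(v, means[lo], sds[lo])
            )

        a, b = means[lo], means[hi]
        if post_diff(a) * post_diff(b) < 0:
            self.threshold_ = float(brentq(post_diff, a, b))
        else:  # posterior never crosses between the means; fall back to midpoint
            self.threshold_ = float((a + b) / 2.0)
        return self

    def predict(self, scores) -> np.ndarray:
        x = np.asarray(scores, dtype=float)
        return x >= self.threshold_

    def fit_predict(self, scores, y=None) -> np.ndarray:
        return self.fit(scores).predict(scores)


@dataclass
class ScoreVector:
    """Per-cell digestion-response scores with the escape flags."""

    score: pd.Series
    threshold: float
    flagged: pd.Series
    signature_used: SignatureSet | list
    control_bins: int
    controls_per_gene: int
    seed: int

    def __post_init__(self) -> None:
        if not self.score.index.equals(self.flagged.index):
            raise ValueError("score and flag indices differ")


def digestion_score(
    cells: AnnData,
    signature: SignatureSet | list,
    n_bins: int = SCORE_BINS,
    n_controls: int = SCORE_CONTROLS,
    seed: int = 0,
    expr=None,
    scorer: EscapeScorer | None = None,
) -> ScoreVector:
    """Score every cell against the digestion signature and flag escape cells.

    ``expr`` may carry a precomputed log-normalized matrix; otherwise it is
    computed here. Scores are pooled across the table's samples (pooling
    stabilizes the abundance bins); flagging is per cell.
    """
    genes = signature.genes if isinstance(signature, SignatureSet) else list(signature)
    if expr is None:
        expr = log_normalize(cells)
    scores = module_score(expr, cells.var_names, genes, n_bins=n_bins,
                          n_controls=n_controls, seed=seed)
    scorer = scorer if scorer is not None else EscapeScorer(random_state=seed)
    flags = scorer.fit_predict(scores)
    return ScoreVector(
        score=pd.Series(scores, index=cells.obs_names, name="score_digestion"),
        threshold=float(scorer.threshold_),
        flagged=pd.Series(flags, index=cells.obs_names, name="flag_escape"),
        signature_used=signature,
        control_bins=n_bins,
        controls_per_gene=n_controls,
        seed=seed,
    )


def curate(cells: AnnData, flags: ScoreVector | pd.Series) -> tuple[AnnData, dict]:
    """Remove flagged escape cells; report the curation bookkeeping."""
    flagged = flags.flagged if isinstance(flags, ScoreVector) else flags
    if list(flagged.index) != list(cells.obs_names):
        raise FixcurateError("flags are not aligned to the cell table")
    mask = flagged.to_numpy(dtype=bool)
    n_before = cells.n_obs
    n_flagged = int(mask.sum())
    curated = cells[~mask].copy()
    report = {
        "n_before": n_before,
        "n_flagged": n_flagged,
        "n_after": n_before - n_flagged,
        "pct_flagged": pct(n_flagged, n_before) if n_before else 0,
    }
    return curated, report


def composition_table(cells: AnnData, cluster_key: str = "cluster",
                      condition_key: str = "condition") -> pd.DataFrame:
    """Within-condition normalized cluster composition: per condition, the
    fraction of that condition's cells in each cluster (columns sum to 1)."""
    for key in (cluster_key, condition_key):
        if key not in cells.obs or cells.obs[key].isna().any():
            raise FixcurateError(f"missing labels in obs[{key!r}]")
    tab = pd.crosstab(cells.obs[cluster_key], cells.obs[condition_key])
    return tab / tab.sum(axis=0)
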