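"""Differential expression for the bulk digestion x drought factorial.

Implements median-of-ratios normalization, a minimal negative-binomial Wald
test (method-of-moments dispersion with a small floor, no shrinkage trend, no
outlier handling), a likelihood-ratio test for the digestion:condition
interaction, Benjamini-Hochberg adjustment, Z-scoring, and clustering of gene
response profiles on Kendall-correlation distance.

Group profile ordering is fixed to (U,WW), (U,MD), (D,WW), (D,MD), (FD,WW),
(FD,MD) for any levels present, in that convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score
from sklearn.utils.validation import check_random_state
from statsmodels.stats.multitest import multipletests

from ._utils import ConfigError, NormalizationError

DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5

GROUP_ORDER = [(d, c) for d in ("U", "D", "FD") for c in ("WW", "MD")]


@dataclass
class BulkCounts:
    """Genes x samples integer counts plus the factorial sample design.

    ``design`` is indexed by sample and has columns digestion (U/D/FD),
    condition (WW/MD) and replicate.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ConfigError("duplicate gene ids in counts")
        if list(self.counts.columns) != list(self.design.index):
            raise ConfigError("counts columns and design rows do not match")
        if not np.isfinite(self.counts.to_numpy()).all():
            raise ConfigError("counts contain non-finite values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def mask(self, **levels: str) -> np.ndarray:
        """Boolean sample mask, e.g. mask(digestion="U", condition="MD")."""
        m = np.ones(len(self.design), dtype=bool)
        for col, val in levels.items():
            m &= (self.design[col] == val).to_numpy()
        return m

    def groups(self) -> list[tuple[str, str]]:
        present = set(zip(self.design["digestion"], self.design["condition"]))
        return [g for g in GROUP_ORDER if g in present]

    def group_means(self, normalized: bool = True) -> pd.DataFrame:
        """Per-gene mean expression per (digestion, condition) group, in the
        fixed group-order convention; size-factor normalized by default."""
        mat = self.counts.to_numpy(dtype=float)
        if normalized:
            mat = mat / size_factors(self)
        cols = {}
        for dig, cond in self.groups():
            m = self.mask(digestion=dig, condition=cond)
            cols[f"{dig}_{cond}"] = mat[:, m].mean(axis=1)
        return pd.DataFrame(cols, index=self.counts.index)


def size_factors(counts: BulkCounts | pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Per sample: the median over all-positive genes of count / geometric mean
    of that gene across samples.
    """
    mat = (counts.counts if isinstance(counts, BulkCounts) else counts).to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "size factors undefined: no gene has positive counts in every sample"
        )
    sub = mat[positive]
    log_geo = np.log(sub).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(sub) - log_geo, axis=0))
    return factors / np.exp(np.mean(np.log(factors)))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def z_score(x: np.ndarray) -> np.ndarray:
    """(x - mean) / sample SD (n-1 denominator), the scale() convention."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("z_score needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("z_score undefined for a constant vector")
    return (x - x.mean()) / sd


def kendall_tau(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall tau-b (tie-corrected) correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(stats.kendalltau(x, y, variant="b").statistic)


def _moment_dispersion(norm: np.ndarray, masks: list[np.ndarray]) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion pooled over within-group
    residual variation, floored at DISPERSION_FLOOR."""
    n_genes = norm.shape[0]
    ss = np.zeros(n_genes)
    mu_w = np.zeros(n_genes)
    df = 0
    n_tot = 0
    for m in masks:
        sub = norm[:, m]
        n = sub.shape[1]
        mean = sub.mean(axis=1)
        ss += ((sub - mean[:, None]) ** 2).sum(axis=1)
        mu_w += mean * n
        df += n - 1
        n_tot += n
    var = ss / max(df, 1)
    mu = mu_w / n_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (var - mu) / mu**2
    disp = np.where(np.isfinite(disp), disp, 0.0)
    return np.maximum(disp, DISPERSION_FLOOR)


def _shrink_dispersion(disp: np.ndarray, weight: float = 0.5) -> np.ndarray:
    """Shrink noisy per-gene dispersions toward the across-gene median; with a
    handful of replicates the raw moment estimate is too variable to use as-is."""
    if disp.size == 0:
        return disp
    target = np.median(disp)
    return weight * disp + (1.0 - weight) * target


def nb_wald(counts: BulkCounts, group_a: dict, group_b: dict) -> pd.DataFrame:
    """Two-group NB Wald test of group_b vs group_a.

    Groups are selected by design levels, e.g. ``{"digestion": "U",
    "condition": "WW"}``. Per gene the groups' means are fitted on
    size-factor-normalized counts, log2fc = log2((mean_b + pc)/(mean_a + pc)),
    and the Wald statistic log2fc/se is referred to a standard normal. The
    per-group variance of the mean uses the plug-in NB variance with a
    moment dispersion shrunk toward the across-gene median.

    Returns a DataFrame indexed by gene with columns base_mean, log2fc, se,
    stat, p, fdr. All-zero genes are reported with log2fc 0 and p 1.
    """
    mask_a = counts.mask(**group_a)
    mask_b = counts.mask(**group_b)
    for name, m in (("a", mask_a), ("b", mask_b)):
        if m.sum() < 2:
            raise ConfigError(f"group {name} has {m.sum()} samples; need >= 2 replicates")
    sf = size_factors(counts)
    norm = counts.counts.to_numpy(dtype=float) / sf
    mean_a = norm[:, mask_a].mean(axis=1)
    mean_b = norm[:, mask_b].mean(axis=1)
    disp = _shrink_dispersion(_moment_dispersion(norm, [mask_a, mask_b]))

    # pseudocount only where a group mean is zero, so clean fold changes stay exact
    pc = np.where((mean_a == 0) | (mean_b == 0), PSEUDOCOUNT, 0.0)
    log2fc = np.log2((mean_b + pc) / np.where(mean_a + pc > 0, mean_a + pc, 1.0))

    def mean_var(mu: np.ndarray, m: np.ndarray) -> np.ndarray:
        # var of (count/s) is mu/s + disp*mu^2; average over the group's samples
        per_sample = mu[:, None] / sf[m][None, :] + disp[:, None] * mu[:, None] ** 2
        return per_sample.sum(axis=1) / m.sum() ** 2

    ln2 = np.log(2.0)
    denom_a = np.maximum(mean_a, PSEUDOCOUNT)
    denom_b = np.maximum(mean_b, PSEUDOCOUNT)
    se2 = mean_var(denom_a, mask_a) / (denom_a * ln2) ** 2
    se2 += mean_var(denom_b, mask_b) / (denom_b * ln2) ** 2
    se = np.sqrt(np.maximum(se2, 1e-300))
    stat = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(stat))

    zero = (mean_a == 0) & (mean_b == 0)
    log2fc[zero] = 0.0
    stat[zero] = 0.0
    p[zero] = 1.0
    p = np.clip(p, 0.0, 1.0)

    return pd.DataFrame(
        {
            "base_mean": (mean_a + mean_b) / 2.0,
            "log2fc": log2fc,
            "se": se,
            "stat": stat,
            "p": p,
            "fdr": bh_adjust(p),
        },
        index=counts.gene_ids,
    )


def _nb_loglik(y: np.ndarray, mu: np.ndarray, disp: float) -> float:
    size = 1.0 / max(disp, DISPERSION_FLOOR)
    mu = np.clip(mu, 1e-10, None)
    return float(stats.nbinom.logpmf(y, size, size / (size + mu)).sum())


def _fit_nb_glm(y: np.ndarray, X: np.ndarray, offset: np.ndarray, disp: float) -> float:
    """Log-likelihood of an NB GLM with log link and fixed dispersion."""
    import statsmodels.api as sm

    fam = sm.families.NegativeBinomial(alpha=max(disp, DISPERSION_FLOOR))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100, tol=1e-8)
            mu = res.predict(X, offset=offset)
        except Exception:
            mu = np.full_like(offset, y.mean() if y.mean() > 0 else 1e-10)
    return _nb_loglik(y, mu, disp)


def lrt_interaction(counts: BulkCounts, p_cut: float = 0.05) -> pd.DataFrame:
    """Likelihood-ratio test for the digestion:condition interaction.

    Per gene, an NB GLM with digestion + condition + digestion:condition is
    compared against the additive digestion + condition model; the statistic
    2*(logL_full - logL_reduced) is referred to chi-square with df equal to
    the parameter-count difference. Dispersion per gene is the shrunken
    moment estimate from within-group variation, shared between the two fits
    so the models are nested.

    Returns a DataFrame with columns stat, df, p, fdr, significant (p < p_cut).
    """
    design = counts.design
    digestion = pd.Categorical(design["digestion"], categories=["U", "D", "FD"])
    condition = pd.Categorical(design["condition"], categories=["WW", "MD"])
    present_d = [l for l in digestion.categories if (digestion == l).any()]
    present_c = [l for l in condition.categories if (condition == l).any()]
    if len(present_d) < 2 or len(present_c) < 2:
        raise ConfigError("interaction LRT needs both factors with >= 2 levels")

    D = pd.get_dummies(pd.Series(digestion).astype(str), dtype=float)[present_d[1:]]
    C = pd.get_dummies(pd.Series(condition).astype(str), dtype=float)[present_c[1:]]
    X_red = np.column_stack([np.ones(len(design)), D.to_numpy(), C.to_numpy()])
    inter = np.einsum("ij,ik->ijk", D.to_numpy(), C.to_numpy()).reshape(len(design), -1)
    X_full = np.column_stack([X_red, inter])
    df_diff = X_full.shape[1] - X_red.shape[1]

    sf = size_factors(counts)
    offset = np.log(sf)
    norm = counts.counts.to_numpy(dtype=float) / sf
    masks = [
        counts.mask(digestion=d, condition=c) for d, c in counts.groups()
    ]
    disp = _shrink_dispersion(_moment_dispersion(norm, masks))

    raw = counts.counts.to_numpy(dtype=float)
    stat = np.zeros(raw.shape[0])
    for i in range(raw.shape[0]):
        y = raw[i]
        if y.sum() == 0:
            continue
        ll_full = _fit_nb_glm(y, X_full, offset, disp[i])
        ll_red = _fit_nb_glm(y, X_red, offset, disp[i])
        stat[i] = max(0.0, 2.0 * (ll_full - ll_red))
    p = stats.chi2.sf(stat, df_diff)
    p[raw.sum(axis=1) == 0] = 1.0
    return pd.DataFrame(
        {
            "stat": stat,
            "df": df_diff,
            "p": p,
            "fdr": bh_adjust(p),
            "significant": p < p_cut,
        },
        index=counts.gene_ids,
    )


def _kendall_distance_matrix(profiles: np.ndarray) -> np.ndarray:
    n = profiles.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            tau = stats.kendalltau(profiles[i], profiles[j], variant="b").statistic
            if not np.isfinite(tau):
                tau = 0.0
            d[i, j] = d[j, i] = 1.0 - tau
    return d


class KendallProfileClusterer(BaseEstimator, ClusterMixin):
    """k-medoids clustering of expression response profiles on Kendall distance.

    Profiles (per-gene mean expression across sample groups, original scale)
    are clustered with distance d = 1 - tau_b; the number of clusters is
    chosen from ``k_range`` by maximal mean silhouette on the precomputed
    distances. Medoid initialization ties are broken by ``random_state``.

    Attributes
    ----------
    labels_ : ndarray of cluster ids per profile
    k_ : chosen number of clusters
    silhouette_ : mean silhouette at k_
    medoid_indices_ : row indices of the medoids
    degenerate_ : True when all profiles are identical (one cluster, warned)
    """

    def __init__(self, k_range: tuple[int, int] = (2, 8), n_init: int = 5, random_state: int | None = 0):
        self.k_range = k_range
        self.n_init = n_init
        self.random_state = random_state

    def _kmedoids(self, d: np.ndarray, k: int, rng: np.random.RandomState) -> tuple[np.ndarray, np.ndarray]:
        n = d.shape[0]
        best_cost, best = np.inf, None
        for _ in range(self.n_init):
            medoids = rng.choice(n, size=k, replace=False)
            for _ in range(100):
                labels = np.argmin(d[:, medoids], axis=1)
                new_medoids = medoids.copy()
                for c in range(k):
                    members = np.flatnonzero(labels == c)
                    if members.size == 0:
                        new_medoids[c] = rng.randint(n)
                        continue
                    within = d[np.ix_(members, members)].sum(axis=1)
                    new_medoids[c] = members[np.argmin(within)]
                if np.array_equal(new_medoids, medoids):
                    break
                medoids = new_medoids
            labels = np.argmin(d[:, medoids], axis=1)
            cost = d[np.arange(n), medoids[labels]].sum()
            if cost < best_cost:
                best_cost, best = cost, (labels, medoids)
        return best

    def fit(self, X: np.ndarray, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("need profiles over >= 2 sample groups")
        rng = check_random_state(self.random_state)
        d = _kendall_distance_matrix(X)
        self.distances_ = d
        if np.allclose(d, 0.0):
            warnings.warn("all profiles are identical; returning a single cluster")
            self.labels_ = np.zeros(X.shape[0], dtype=int)
            self.k_ = 1
            self.silhouette_ = float("nan")
            self.medoid_indices_ = np.array([0])
            self.degenerate_ = True
            return self
        self.degenerate_ = False
        ks = [k for k in range(self.k_range[0], self.k_range[1] + 1) if k < X.shape[0]]
        if not ks:
            raise ValueError(f"need more than max(k_range) profiles, got {X.shape[0]}")
        best_sil, best = -np.inf, None
        for k in ks:
            labels, medoids = self._kmedoids(d, k, rng)
            if len(np.unique(labels)) < 2:
                continue
            sil = silhouette_score(d, labels, metric="precomputed")
            if sil > best_sil:
                best_sil, best = sil, (k, labels, medoids)
        if best is None:  # all candidate k collapsed
            self.labels_ = np.zeros(X.shape[0], dtype=int)
            self.k_, self.silhouette_ = 1, float("nan")
            self.medoid_indices_ = np.array([0])
            self.degenerate_ = True
            return self
        self.k_, self.labels_, self.medoid_indices_ = best
        self.silhouette_ = float(best_sil)
        return self


@dataclass
class ProfileClustering:
    """Gene -> cluster assignments with Z-scored centroid profiles."""

    assignments: pd.Series
    centroids: pd.DataFrame
    k: int
    silhouette: float
    degenerate: bool = False
    group_order: list = field(default_factory=list)

    def cluster_genes(self, cluster_id: int) -> list[str]:
        return list(self.assignments.index[self.assignments == cluster_id])


def cluster_profiles(
    de_genes,
    counts: BulkCounts,
    k_range: tuple[int, int] = (2, 8),
    random_state: int | None = 0,
) -> ProfileClustering:
    """Cluster differentially expressed genes by response profile.

    Profiles are per-group normalized mean expression on the original scale;
    clustering distance is 1 - Kendall tau_b; k is chosen by silhouette.
    Centroids are reported as Z-scored cluster-mean profiles (visualization
    convention); the Z-scoring plays no role in the clustering itself.
    """
    de_genes = [g for g in de_genes if g in counts.gene_ids]
    means = counts.group_means().loc[de_genes]
    est = KendallProfileClusterer(k_range=k_range, random_state=random_state)
    est.fit(means.to_numpy())
    assignments = pd.Series(est.labels_, index=means.index, name="cluster")
    cent_rows = {}
    for c in np.unique(est.labels_):
        prof = means.to_numpy()[est.labels_ == c].mean(axis=0)
        sd = prof.std(ddof=1)
        cent_rows[int(c)] = (prof - prof.mean()) / sd if sd > 0 else prof * 0.0
    centroids = pd.DataFrame(cent_rows, index=means.columns).T
    return ProfileClustering(
        assignments=assignments,
        centroids=centroids,
        k=est.k_,
        silhouette=est.silhouette_,
        degenerate=est.degenerate_,
        group_order=list(means.columns),
    )
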