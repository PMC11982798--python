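"""Digestion-response gene signature and cross-sample audit statistics.

The signature is the ranked membership of the induced digestion-response
cluster, after removal of drought-responsive/interacting genes, truncated to a
requested size (default 250). Audit operations count directional agreement of
drought responses across isolation methods, test overlap enrichment of DEG
sets, and decompose named gene sets into exclusive UpSet intersections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from ._utils import pct
from .bulk_de import ProfileClustering

DEFAULT_SIGNATURE_SIZE = 250


@dataclass
class SignatureSet:
    """Ordered signature genes with their provenance."""

    genes: list[str]
    source_cluster: int
    excluded: set[str] = field(default_factory=set)
    requested_size: int = DEFAULT_SIGNATURE_SIZE
    truncated: bool = True  # False when fewer survivors than requested

    def __post_init__(self) -> None:
        if set(self.genes) & self.excluded:
            raise ValueError("signature genes overlap the exclusion set")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class DirectionalAudit:
    """Directional agreement of a reference DEG set in a target contrast."""

    n_reference: int
    n_same: int
    n_opposite: int
    n_missing: int

    def __post_init__(self) -> None:
        if self.n_same + self.n_opposite + self.n_missing != self.n_reference:
            raise ValueError("audit counts do not conserve")

    @property
    def pct_same(self) -> int:
        return pct(self.n_same, self.n_reference)

    @property
    def pct_opposite(self) -> int:
        return pct(self.n_opposite, self.n_reference)


def induced_cluster(clustering: ProfileClustering, reference_group: str = "U_WW",
                    induced_group: str = "D_WW") -> int:
    """Pick the cluster most strongly induced by digestion: the one whose
    centroid rises most from the undigested to the digested group."""
    delta = clustering.centroids[induced_group] - clustering.centroids[reference_group]
    return int(delta.idxmax())


def derive_signature(
    clustering: ProfileClustering,
    ranking: pd.DataFrame,
    exclusions: set[str],
    size: int = DEFAULT_SIGNATURE_SIZE,
    source_cluster: int | None = None,
) -> SignatureSet:
    """Top genes of the digestion-induced cluster, exclusions removed.

    Cluster members are ranked by ascending fdr, ties broken by descending
    |log2fc| then lexicographic gene id, and truncated to ``size``. If fewer
    genes survive exclusion than requested, all survivors are returned with a
    warning.
    """
    if size <= 0:
        raise ValueError(f"signature size must be positive, got {size}")
    if source_cluster is None:
        source_cluster = induced_cluster(clustering)
    members = clustering.cluster_genes(source_cluster)
    if not members:
        raise ValueError(f"cluster {source_cluster} is empty")
    survivors = [g for g in members if g not in exclusions]
    tbl = ranking.loc[[g for g in survivors if g in ranking.index]].copy()
    tbl["_abs_lfc"] = tbl["log2fc"].abs()
    tbl = tbl.sort_values(
        by=["fdr", "_abs_lfc"], ascending=[True, False], kind="mergesort"
    )
    # mergesort is stable; pre-sort by gene id for the lexicographic tie-break
    tbl = tbl.loc[sorted(tbl.index)].sort_values(
        by=["fdr", "_abs_lfc"], ascending=[True, False], kind="mergesort"
    )
    ordered = list(tbl.index)
    truncated = len(ordered) >= size
    if not truncated:
        warnings.warn(
            f"only {len(ordered)} genes survive exclusion; requested {size}"
        )
    return SignatureSet(
        genes=ordered[:size],
        source_cluster=source_cluster,
        excluded=set(exclusions),
        requested_size=size,
        truncated=truncated,
    )


def directional_counts(de: pd.DataFrame, fdr_cut: float = 0.05) -> tuple[int, int, int]:
    """(n_up, n_down, n_total) among genes with fdr < cut.

    Significant genes with log2fc exactly 0 belong to neither direction and
    are excluded from the total (with a warning).
    """
    sig = de[de["fdr"] < fdr_cut]
    n_up = int((sig["log2fc"] > 0).sum())
    n_down = int((sig["log2fc"] < 0).sum())
    n_zero = len(sig) - n_up - n_down
    if n_zero:
        warnings.warn(f"{n_zero} significant genes with log2fc == 0 counted in neither direction")
    return n_up, n_down, n_up + n_down


def opposite_direction_audit(
    reference: pd.DataFrame, target: pd.DataFrame, fdr_cut: float = 0.05
) -> DirectionalAudit:
    """Classify each reference-significant gene by its fold-change sign in the
    target contrast: same direction, opposite, or missing from the target."""
    ref_sig = reference[(reference["fdr"] < fdr_cut) & (reference["log2fc"] != 0)]
    if ref_sig.empty:
        raise ValueError("reference significant set is empty")
    n_same = n_opp = n_missing = 0
    tgt_lfc = target["log2fc"]
    for gene, row in ref_sig.iterrows():
        if gene not in tgt_lfc.index:
            n_missing += 1
            continue
        prod = np.sign(row["log2fc"]) * np.sign(tgt_lfc.loc[gene])
        if prod < 0:
            n_opp += 1
        else:  # zero target fold change is not an opposite response
            n_same += 1
    return DirectionalAudit(
        n_reference=len(ref_sig), n_same=n_same, n_opposite=n_opp, n_missing=n_missing
    )


def overlap_enrichment(set_a, set_b, universe: int) -> tuple[float, float]:
    """Fold enrichment of the overlap of two gene sets over chance, with a
    continuity-corrected chi-square p-value on the 2x2 contingency table."""
    a, b = set(set_a), set(set_b)
    if universe <= 0:
        raise ValueError("universe must be positive")
    if not a or not b:
        raise ValueError("empty gene set")
    if len(a) > universe or len(b) > universe:
        raise ValueError("set larger than universe")
    k = len(a & b)
    expected = len(a) * len(b) / universe
    fold = k / expected
    table = np.array(
        [
            [k, len(a) - k],
            [len(b) - k, universe - len(a) - len(b) + k],
        ]
    )
    if (table < 0).any():
        raise ValueError("sets are inconsistent with the stated universe")
    chi2_p = chi2_contingency(table, correction=True).pvalue
    return float(fold), float(chi2_p)


def intersections(sets: dict[str, set]) -> dict[frozenset, int]:
    """Exclusive (UpSet-style) intersection sizes for named gene sets.

    Every element of the union is counted in exactly one combination — the
    full set of names containing it — so the sizes sum to the union size.
    Only non-empty combinations are returned.
    """
    if not sets:
        raise ValueError("need at least one set")
    names = list(sets)
    out: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(set(sets[n]) for n in combo))
            outside = set.union(set(), *(set(sets[n]) for n in names if n not in combo))
            size = len(inside - outside)
            if size:
                out[frozenset(combo)] = size
    return out
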