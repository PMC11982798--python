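"""Synthetic bulk and single-cell count data with planted digestion/drought structure.

The generator emulates the design of the study this package supports: bulk
RNA-seq of undigested (U), digested (D) and fixed-digested (FD) leaf samples
under well-watered (WW) and mild-drought (MD) conditions, and single-cell
RNA-seq of the fixed-digested samples. Planted gene programs:

* a cell-wall-digestion program (up and down components) whose response is
  attenuated under fixation,
* an "amplified" program whose digestion response is larger under fixation,
* a drought program shared across isolation methods,
* digestion x drought interaction genes whose drought response flips sign in
  digested material,
* tissue marker programs,
* two mutually exclusive drought programs (canonical/ABA vs iron starvation)
  gated on a latent per-cell drought gradient in the mesophyll,

plus escape cells in fixed-digested samples that retain the full digestion
program. Ground-truth labels for every planted gene and cell are returned so
parameter recovery can be measured.

Counts are negative binomial with mean 2**(baseline + sum of active log2
effects) and a shared dispersion; identical configs (including seed) produce
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from anndata import AnnData

from ._utils import ConfigError, derive_rng
from .bulk_de import BulkCounts

DIGESTION_LEVELS = ("U", "D", "FD")
CONDITIONS = ("WW", "MD")

# log2 boost of a tissue's marker genes in that tissue, and the factor by
# which the "amplified" program's digestion response grows under fixation.
MARKER_EFFECT_LFC = 3.0
FD_AMPLIFICATION = 1.5


@dataclass
class DigestionProgram:
    n_up: int = 100
    n_down: int = 100
    effect_lfc: float = 2.0
    fixation_attenuation: float = 0.8


@dataclass
class AmplifiedProgram:
    n_genes: int = 50
    effect_lfc: float = 2.0


@dataclass
class DroughtProgram:
    n_up: int = 60
    n_down: int = 60
    effect_lfc: float = 2.0


@dataclass
class InteractionProgram:
    n_genes: int = 50
    flip: bool = True


@dataclass
class ScParams:
    n_cells_per_sample: int = 500
    tissue_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"mesophyll": 0.5, "epidermis": 0.3, "vasculature": 0.2}
    )
    n_marker_genes_per_tissue: int = 30
    escape_fraction: float = 0.24
    canonical_program_genes: int = 30
    iron_program_genes: int = 30
    gradient_tip_fraction: float = 0.2
    depth_mean: int = 3000
    depth_sigma: float = 0.3
    dispersion: float = 0.3
    # the two drought programs are induced stress genes: near-silent at
    # baseline, strongly activated in the cells where the program fires
    program_baseline_drop: float = 6.0
    program_effect_lfc: float = 9.0


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study design: a 3 (digestion) x 2 (condition) bulk
    factorial with 3 replicates per cell, strong (2 log2FC) planted effects,
    and fixed-digested single-cell samples in which 24% of cells escape
    fixation.
    """

    n_genes: int = 2000
    n_bulk_replicates: int = 3
    bulk_design: tuple = tuple((d, c) for d in DIGESTION_LEVELS for c in CONDITIONS)
    baseline_mean_log: float = 5.0
    baseline_sd_log: float = 2.0
    dispersion: float = 0.05
    digestion_program: DigestionProgram = field(default_factory=DigestionProgram)
    amplified_program: AmplifiedProgram = field(default_factory=AmplifiedProgram)
    drought_program: DroughtProgram = field(default_factory=DroughtProgram)
    interaction_program: InteractionProgram = field(default_factory=InteractionProgram)
    sc_params: ScParams = field(default_factory=ScParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.digestion_program, dict):
            self.digestion_program = DigestionProgram(**self.digestion_program)
        if isinstance(self.amplified_program, dict):
            self.amplified_program = AmplifiedProgram(**self.amplified_program)
        if isinstance(self.drought_program, dict):
            self.drought_program = DroughtProgram(**self.drought_program)
        if isinstance(self.interaction_program, dict):
            self.interaction_program = InteractionProgram(**self.interaction_program)
        if isinstance(self.sc_params, dict):
            self.sc_params = ScParams(**self.sc_params)
        self.bulk_design = tuple(tuple(pair) for pair in self.bulk_design)
        self.validate()

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_bulk_replicates <= 0:
            raise ConfigError("n_genes and n_bulk_replicates must be positive")
        if not np.isfinite(self.dispersion) or self.dispersion <= 0:
            raise ConfigError(f"dispersion must be a positive real, got {self.dispersion}")
        sc = self.sc_params
        if not np.isfinite(sc.dispersion) or sc.dispersion <= 0:
            raise ConfigError("sc dispersion must be positive")
        for eff in (
            self.digestion_program.effect_lfc,
            self.amplified_program.effect_lfc,
            self.drought_program.effect_lfc,
        ):
            if not np.isfinite(eff):
                raise ConfigError(f"non-finite effect size {eff}")
        if not 0.0 <= self.digestion_program.fixation_attenuation <= 1.0:
            raise ConfigError("fixation_attenuation must lie in [0, 1]")
        if not 0.0 <= sc.escape_fraction <= 1.0:
            raise ConfigError("escape_fraction must lie in [0, 1]")
        if not 0.0 < sc.gradient_tip_fraction < 1.0:
            raise ConfigError("gradient_tip_fraction must lie in (0, 1)")
        total = sum(sc.tissue_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"tissue_proportions sum to {total}, expected 1")
        for pair in self.bulk_design:
            d, c = pair
            if d not in DIGESTION_LEVELS or c not in CONDITIONS:
                raise ConfigError(f"unknown design cell {pair}")
        n_planted = self._n_planted()
        if n_planted > self.n_genes:
            raise ConfigError(
                f"{n_planted} planted genes exceed n_genes={self.n_genes}"
            )

    def _n_planted(self) -> int:
        sc = self.sc_params
        return (
            self.digestion_program.n_up
            + self.digestion_program.n_down
            + self.amplified_program.n_genes
            + self.drought_program.n_up
            + self.drought_program.n_down
            + self.interaction_program.n_genes
            + sc.n_marker_genes_per_tissue * len(sc.tissue_proportions)
            + sc.canonical_program_genes
            + sc.iron_program_genes
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bulk_design"] = [list(p) for p in self.bulk_design]
        d["sc_params"]["tissue_proportions"] = dict(self.sc_params.tissue_proportions)
        return d


@dataclass
class GroundTruth:
    """Planted structure: per-gene tag sets and per-cell latent labels."""

    gene_labels: dict[str, set[str]]
    cell_labels: pd.DataFrame | None = None

    def genes_with(self, tag: str) -> list[str]:
        return [g for g, tags in self.gene_labels.items() if tag in tags]


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def _assign_programs(config: SimConfig) -> dict[str, np.ndarray]:
    """Deterministic disjoint index blocks for every planted program."""
    sc = config.sc_params
    blocks: dict[str, int] = {
        "digestion_up": config.digestion_program.n_up,
        "digestion_down": config.digestion_program.n_down,
        "digestion_amplified": config.amplified_program.n_genes,
        "drought_up": config.drought_program.n_up,
        "drought_down": config.drought_program.n_down,
        "interacting": config.interaction_program.n_genes,
    }
    for tissue in sc.tissue_proportions:
        blocks[f"tissue_marker:{tissue}"] = sc.n_marker_genes_per_tissue
    blocks["canonical_drought"] = sc.canonical_program_genes
    blocks["iron_starvation"] = sc.iron_program_genes
    out: dict[str, np.ndarray] = {}
    start = 0
    for tag, size in blocks.items():
        out[tag] = np.arange(start, start + size)
        start += size
    return out


def _gene_truth(config: SimConfig, programs: dict[str, np.ndarray]) -> dict[str, set[str]]:
    ids = _gene_ids(config.n_genes)
    labels: dict[str, set[str]] = {g: set() for g in ids}
    for tag, idx in programs.items():
        for i in idx:
            labels[ids[i]].add(tag)
    return labels


def _baselines(config: SimConfig, programs: dict[str, np.ndarray], key: int) -> np.ndarray:
    """Per-gene baseline log2 mean; planted genes floored one log2 unit below
    the global mean so the programs sit in the reliably detected expression
    range, as curated signature genes do in real data."""
    rng = derive_rng(config.seed, key)
    base = rng.normal(config.baseline_mean_log, config.baseline_sd_log, config.n_genes)
    planted = np.concatenate(list(programs.values()))
    base[planted] = np.maximum(base[planted], config.baseline_mean_log - 1.0)
    low = config.baseline_mean_log - config.sc_params.program_baseline_drop
    base[programs["canonical_drought"]] = low
    base[programs["iron_starvation"]] = low
    return base


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    size = 1.0 / dispersion
    mean = np.clip(mean, 1e-12, None)
    return rng.negative_binomial(size, size / (size + mean))


def _digestion_effect(config: SimConfig, programs: dict[str, np.ndarray], digestion: str) -> np.ndarray:
    """Per-gene log2 shift caused by cell-wall digestion at a given fixation state."""
    eff = np.zeros(config.n_genes)
    if digestion == "U":
        return eff
    dp, ap = config.digestion_program, config.amplified_program
    scale = 1.0 if digestion == "D" else 1.0 - dp.fixation_attenuation
    eff[programs["digestion_up"]] += dp.effect_lfc * scale
    eff[programs["digestion_down"]] -= dp.effect_lfc * scale
    amp = 1.0 if digestion == "D" else FD_AMPLIFICATION
    eff[programs["digestion_amplified"]] += ap.effect_lfc * amp
    return eff


def _drought_effect(config: SimConfig, programs: dict[str, np.ndarray], digestion: str) -> np.ndarray:
    """Per-gene log2 shift of MD vs WW, including the interaction flip.

    Interacting genes respond +e in undigested tissue and -e in digested
    protoplasts; under fixation the digestion-induced deviation from the
    undigested response is attenuated, so the FD effect is
    e - 2e*(1 - attenuation).
    """
    eff = np.zeros(config.n_genes)
    dr = config.drought_program
    eff[programs["drought_up"]] += dr.effect_lfc
    eff[programs["drought_down"]] -= dr.effect_lfc
    e = dr.effect_lfc
    inter = programs["interacting"]
    if not config.interaction_program.flip:
        eff[inter] += e
        return eff
    if digestion == "U":
        eff[inter] += e
    elif digestion == "D":
        eff[inter] -= e
    else:  # FD: attenuated flip
        atten = config.digestion_program.fixation_attenuation
        eff[inter] += e - 2.0 * e * (1.0 - atten)
    return eff


def simulate_bulk(config: SimConfig) -> tuple[BulkCounts, GroundTruth]:
    """Simulate the bulk factorial experiment.

    Returns a genes x samples count matrix with its design table, and the
    ground-truth gene tags. NB mean of gene g in sample (digestion, condition)
    is 2**(baseline_g + digestion effect + drought effect) times a mild
    lognormal per-sample library factor.
    """
    config.validate()
    programs = _assign_programs(config)
    base = _baselines(config, programs, 0)
    rng = derive_rng(config.seed, 1)
    ids = _gene_ids(config.n_genes)

    sample_names, digestion_col, condition_col, replicate_col = [], [], [], []
    cols = []
    for digestion, condition in config.bulk_design:
        log_mu = base + _digestion_effect(config, programs, digestion)
        if condition == "MD":
            log_mu = log_mu + _drought_effect(config, programs, digestion)
        mu = np.exp2(log_mu)
        for rep in range(1, config.n_bulk_replicates + 1):
            lib = rng.lognormal(0.0, 0.1)
            cols.append(_nb_sample(rng, mu * lib, config.dispersion))
            sample_names.append(f"{digestion}_{condition}_r{rep}")
            digestion_col.append(digestion)
            condition_col.append(condition)
            replicate_col.append(rep)

    counts = pd.DataFrame(
        np.column_stack(cols), index=ids, columns=sample_names, dtype=np.int64
    )
    design = pd.DataFrame(
        {
            "sample": sample_names,
            "digestion": digestion_col,
            "condition": condition_col,
            "replicate": replicate_col,
        }
    ).set_index("sample")
    truth = GroundTruth(gene_labels=_gene_truth(config, programs))
    return BulkCounts(counts=counts, design=design), truth


def simulate_cells(config: SimConfig) -> tuple[AnnData, GroundTruth]:
    """Simulate fixed-digested single-cell samples with escape cells and the
    dual mesophyll drought programs.

    Cells are assigned tissues by ``tissue_proportions``; a cell's gene means
    add the tissue marker program, the full digestion program if the cell
    escaped fixation, the bulk drought program if from an MD sample, and one
    of the two mutually exclusive drought programs for MD mesophyll cells
    gated on a latent drought gradient: the canonical/ABA program fires only
    at the very tip of the gradient (gradient > 1 - tip fraction), the
    iron-starvation program only in the mid/high band below the tip. Library
    sizes are lognormal around ``depth_mean``; counts are NB (genes x cells
    stored cells x genes in the returned AnnData).
    """
    config.validate()
    sc = config.sc_params
    sc_digestions = [d for d in DIGESTION_LEVELS if d != "U" and any(p[0] == d for p in config.bulk_design)]
    if sc.escape_fraction > 0 and "FD" not in sc_digestions:
        raise ConfigError("escape_fraction > 0 requires a FixedDigested sample in the design")
    # single-cell profiling is done on the fixed-digested material only
    sc_digestions = [d for d in sc_digestions if d == "FD"] or sc_digestions

    programs = _assign_programs(config)
    base = _baselines(config, programs, 0)
    rng = derive_rng(config.seed, 2)
    ids = _gene_ids(config.n_genes)
    tissues = list(sc.tissue_proportions)
    props = np.array([sc.tissue_proportions[t] for t in tissues])

    rows = []
    meta_rows = []
    cell_ids = []
    for digestion in sc_digestions:
        for condition in CONDITIONS:
            sample = f"sc_{digestion}_{condition}"
            n = sc.n_cells_per_sample
            tissue_idx = rng.choice(len(tissues), size=n, p=props)
            escape = (
                rng.random(n) < sc.escape_fraction
                if digestion == "FD"
                else np.zeros(n, dtype=bool)
            )
            polarity = rng.random(n)
            gradient = np.zeros(n)
            mes = np.array([tissues[i] == "mesophyll" for i in tissue_idx])
            if condition == "MD":
                gradient[mes] = rng.random(mes.sum())
            else:
                gradient[mes] = rng.random(mes.sum()) * 0.3
            tip = gradient > 1.0 - sc.gradient_tip_fraction
            mid = (gradient > 0.5) & ~tip
            canonical = mes & (condition == "MD") & tip
            iron = mes & (condition == "MD") & mid

            dig_eff = _digestion_effect(config, programs, "D")  # full program
            dr_eff_bulk = np.zeros(config.n_genes)
            dr_eff_bulk[programs["drought_up"]] += config.drought_program.effect_lfc
            dr_eff_bulk[programs["drought_down"]] -= config.drought_program.effect_lfc

            depth = rng.lognormal(np.log(sc.depth_mean), sc.depth_sigma, n)
            for i in range(n):
                log_mu = base.copy()
                tname = tissues[tissue_idx[i]]
                log_mu[programs[f"tissue_marker:{tname}"]] += MARKER_EFFECT_LFC
                if escape[i]:
                    log_mu = log_mu + dig_eff
                if condition == "MD":
                    log_mu = log_mu + dr_eff_bulk
                if canonical[i]:
                    log_mu[programs["canonical_drought"]] += sc.program_effect_lfc
                if iron[i]:
                    log_mu[programs["iron_starvation"]] += sc.program_effect_lfc
                rel = np.exp2(log_mu)
                mu = rel / rel.sum() * depth[i]
                rows.append(_nb_sample(rng, mu, sc.dispersion))
                cid = f"{sample}_c{i:05d}"
                cell_ids.append(cid)
                sub = "canonical" if canonical[i] else ("iron" if iron[i] else "none")
                meta_rows.append(
                    {
                        "sample": sample,
                        "condition": condition,
                        "fixation": digestion,
                        "tissue": tname,
                        "truth_escape": bool(escape[i]),
                        "truth_polarity": polarity[i],
                        "truth_drought_gradient": gradient[i],
                        "truth_subpopulation": sub,
                    }
                )

    from scipy import sparse

    X = sparse.csr_matrix(np.vstack(rows).astype(np.int64))
    obs = pd.DataFrame(meta_rows, index=cell_ids)
    adata = AnnData(X=X, obs=obs, var=pd.DataFrame(index=ids))
    cell_truth = obs[
        ["tissue", "condition", "fixation", "truth_escape", "truth_polarity",
         "truth_drought_gradient", "truth_subpopulation"]
    ].rename(
        columns={
            "truth_escape": "escape",
            "truth_polarity": "polarity",
            "truth_drought_gradient": "drought_gradient",
            "truth_subpopulation": "subpopulation",
        }
    )
    truth = GroundTruth(gene_labels=_gene_truth(config, programs), cell_labels=cell_truth)
    return adata, truth
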