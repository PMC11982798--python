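import warnings

import numpy as np
import pandas as pd
import pytest

from fixcurate.bulk_de import BulkCounts
from fixcurate.simdata import SimConfig, simulate_bulk, simulate_cells


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """Reduced-size study (600 genes, 250 cells/sample) for unit tests."""
    params = dict(
        n_genes=600,
        digestion_program={"n_up": 40, "n_down": 40},
        amplified_program={"n_genes": 20},
        drought_program={"n_up": 30, "n_down": 30},
        interaction_program={"n_genes": 20},
        sc_params={
            "n_cells_per_sample": 250,
            "n_marker_genes_per_tissue": 15,
            "canonical_program_genes": 20,
            "iron_program_genes": 20,
            "depth_mean": 1000,  # keeps depth per gene at the default ratio
        },
        seed=seed,
    )
    for key, value in overrides.items():
        if isinstance(params.get(key), dict) and isinstance(value, dict):
            params[key] = {**params[key], **value}
        else:
            params[key] = value
    return SimConfig(**params)


def null_config(seed: int = 0, n_genes: int = 2000) -> SimConfig:
    """All planted effects removed: pure NB noise around the baselines."""
    return SimConfig(
        seed=seed,
        n_genes=n_genes,
        digestion_program={"n_up": 0, "n_down": 0},
        amplified_program={"n_genes": 0},
        drought_program={"n_up": 0, "n_down": 0},
        interaction_program={"n_genes": 0},
        sc_params={
            "n_marker_genes_per_tissue": 0,
            "canonical_program_genes": 0,
            "iron_program_genes": 0,
        },
    )


@pytest.fixture(scope="session")
def small_bulk():
    return simulate_bulk(small_config(seed=11))


@pytest.fixture(scope="session")
def small_cells():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cells(small_config(seed=11))


def toy_bulk(counts_by_gene: dict, groups: list[tuple[str, str]]) -> BulkCounts:
    """Hand-built BulkCounts: counts_by_gene maps gene -> list of counts, one
    per sample; groups gives (digestion, condition) per sample."""
    samples = [f"s{i}" for i in range(len(groups))]
    counts = pd.DataFrame(counts_by_gene, index=samples).T
    counts.columns = samples
    design = pd.DataFrame(
        {
            "sample": samples,
            "digestion": [g[0] for g in groups],
            "condition": [g[1] for g in groups],
            "replicate": list(range(1, len(groups) + 1)),
        }
    ).set_index("sample")
    return BulkCounts(counts=counts.astype(np.int64), design=design)
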