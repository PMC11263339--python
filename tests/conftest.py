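import numpy as np
import pandas as pd
import pytest

from intersexpr.design import DesignSpec, Sample, default_design
from intersexpr.simulate import TRUTH_COLUMNS, TruthTable, default_truth, simulate_counts


def flat_truth(n_genes: int, baseline: float = 100.0, dispersion: float = 0.1,
               fold: float = 1.0) -> TruthTable:
    """A truth table of identical unbiased genes (null simulation input)."""
    rows = {
        f"g{i:05d}": dict(
            sex_class="none", sex_high="", species_class="none", species_high="",
            tissue_class="none", tissue_high="", baseline_fpkm=baseline,
            specific_fpkm=0.05, fold_change=fold, dispersion=dispersion,
            intersex_behavior="no_change", intersex_reference="female",
        )
        for i in range(n_genes)
    }
    table = pd.DataFrame(rows).T[TRUTH_COLUMNS]
    for c in ("baseline_fpkm", "specific_fpkm", "fold_change", "dispersion"):
        table[c] = table[c].astype(float)
    table.index.name = "gene_id"
    return TruthTable(table)


def two_group_design(n_reps: int = 3) -> DesignSpec:
    """Male vs female reproductive samples of one pure species."""
    samples = [
        Sample(f"U_{sex}_reproductive_r{r}", "U", sex, "reproductive", r)
        for sex in ("male", "female")
        for r in range(1, n_reps + 1)
    ]
    return DesignSpec(samples)


@pytest.fixture(scope="session")
def full_design() -> DesignSpec:
    return default_design()


@pytest.fixture(scope="session")
def strong_truth() -> TruthTable:
    """Default planted truth under the strong-effect regime."""
    return default_truth(n_genes=1000, seed=20)


@pytest.fixture(scope="session")
def strong_counts(full_design, strong_truth):
    return simulate_counts(full_design, strong_truth, seed=21)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
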