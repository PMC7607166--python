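import numpy as np
import pandas as pd
import pytest

from raceqtl.sim import (
    PlantedDriver,
    PlantedShift,
    SimConfig,
    SurvivalGene,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def driver_config() -> SimConfig:
    """A cohort with one genotype-mediated driver, one plain DE gene, and a
    survival-linked gene, at the study's 1:1:4 race ratio."""
    return SimConfig(
        n_per_population={"AS": 100, "AA": 100, "CA": 400},
        n_genes=120,
        n_snps=6,
        planted_drivers=[
            PlantedDriver(
                "rs_driver", "GENE_DRV",
                {"AS": 0.0744, "AA": 0.2247, "CA": 0.5149}, 1.0,
            )
        ],
        planted_de_only=[PlantedShift("GENE_DE", {"AS": -1.6, "AA": -0.63, "CA": 0.0})],
        survival_genes=[SurvivalGene("GENE_DRV", 0.8)],
        seed=11,
    )


@pytest.fixture(scope="session")
def driver_dataset(driver_config):
    return simulate_dataset(driver_config)


@pytest.fixture()
def tiny_counts() -> pd.DataFrame:
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        rng.poisson(50, size=(5, 6)),
        index=[f"g{i}" for i in range(5)],
        columns=[f"s{i}" for i in range(6)],
    )
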