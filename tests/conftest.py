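import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from seedmqtl import (
    GeneticMap,
    GenotypeMatrix,
    PhenotypeTable,
    RilDesign,
    ScanConfig,
    calc_genoprob,
    default_map_template,
    simulate_ril_population,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gmap_small() -> GeneticMap:
    """Two chromosomes, four markers, with bp anchors."""
    df = pd.DataFrame(
        {
            "chrom": ["1", "1", "2", "2"],
            "pos_cm": [0.0, 10.0, 0.0, 8.0],
            "pos_bp": [1.0, 3_000_000.0, 1.0, 2_400_000.0],
        },
        index=pd.Index(["m1", "m2", "m3", "m4"], name="marker"),
    )
    return GeneticMap(df)


@pytest.fixture(scope="session")
def study_map() -> GeneticMap:
    return default_map_template()


@pytest.fixture(scope="session")
def study_pop(study_map):
    """One study-scale RIL population shared across tests (seed fixed)."""
    _, geno = simulate_ril_population(RilDesign(), seed=101)
    return geno


@pytest.fixture(scope="session")
def study_genoprob(study_pop, study_map):
    return calc_genoprob(study_pop, study_map, ScanConfig())


def toy_pheno(values: dict, index=None, meta: pd.DataFrame | None = None):
    df = pd.DataFrame(values)
    if index is not None:
        df.index = pd.Index(index, name="id")
    else:
        df.index = pd.Index([f"i{k}" for k in range(len(df))], name="id")
    return PhenotypeTable(df, meta)
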