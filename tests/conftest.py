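import numpy as np
import pandas as pd
import pytest

from diffcornet import (
    FactorRegistry,
    MetaboliteRegistry,
    MetaboliteTable,
    PlantedChange,
    simulate_table,
    study_spec,
)
from diffcornet.synthetic import DesignCell, SyntheticSpec, study_design


def make_table(values: np.ndarray, metabolites, genotypes=None, mulches=None):
    """Handcrafted table helper: values row-per-sample, study factor levels."""
    n = len(values)
    genotypes = genotypes or ["2", "8", "5", "10", "12", "4", "20"] * (n // 7 + 1)
    mulches = mulches or ["BP", "HV", "RY", "BS"] * (n // 4 + 1)
    idx = [f"s{i:03d}" for i in range(n)]
    factors = pd.DataFrame(
        {
            "genotype": genotypes[:n],
            "mulch": mulches[:n],
            "year": ["2006"] * n,
            "stage": ["red"] * n,
            "replicate": [str(i) for i in range(n)],
        },
        index=idx,
    )
    frame = pd.DataFrame(values, index=idx, columns=list(metabolites))
    return MetaboliteTable(
        frame, factors,
        MetaboliteRegistry.minimal(list(metabolites)),
        FactorRegistry.study_default(),
    )


@pytest.fixture(scope="session")
def study_table():
    """Small study-shaped simulated table (no planted changes)."""
    return simulate_table(study_spec(seed=11, replicates=2))


@pytest.fixture(scope="session")
def planted_spec():
    """Study-shaped spec with one strong planted polyamine change."""
    return study_spec(
        seed=23, replicates=3,
        planted=[PlantedChange(("ALA", "CIT"), 0.1, 0.7, "polyamine")],
    )


@pytest.fixture(scope="session")
def planted_table(planted_spec):
    return simulate_table(planted_spec)


@pytest.fixture()
def fixture_run_dir(tmp_path):
    """Bundled-style toy fixture: small table + pipeline config on disk."""
    spec = SyntheticSpec(
        metabolites=tuple(sorted(study_spec().groups)),
        groups=study_spec().groups,
        design=tuple(study_design(replicates=1, years=("2007",), stages=("red",))),
        base_correlation=study_spec().base_correlation,
        seed=5,
    )
    table = simulate_table(spec)
    from diffcornet import write_metabolite_table

    table_path = tmp_path / "table.csv"
    write_metabolite_table(table, table_path)
    config_path = tmp_path / "config.yaml"
    config_path.write_text(
        "io:\n  table: table.csv\n"
        "analysis:\n  partitions: [polyamine, mejas, mulch]\n  alpha: 0.05\n"
    )
    return tmp_path
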