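import numpy as np
import pandas as pd
import pytest

import musclenet as mn
from musclenet.design import BREEDS, STAGES


def make_means(rows: dict[str, list[float]]) -> pd.DataFrame:
    """Hand-built treatment-mean table; values in breed-major (BA 110..260,
    CH 110..260) order, None for missing."""
    cols = pd.MultiIndex.from_tuples([(b, s) for b in BREEDS for s in STAGES],
                                     names=["breed", "stage"])
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    df.columns = cols
    df.index.name = "gene"
    return df


def run_chain(cfg: mn.SimulationConfig):
    """simulate -> average -> means -> filter -> map -> diff, with truth."""
    matrix, design, pmap, truth = mn.simulate_dataset(cfg)
    collapsed, cdesign = mn.average_technical_replicates(matrix, design)
    means = mn.filter_expressed(mn.compute_treatment_means(collapsed, cdesign))
    gene_means = mn.map_to_genes(means, pmap)
    return {
        "matrix": matrix, "design": design, "pmap": pmap, "truth": truth,
        "gene_means": gene_means, "diff": mn.compute_diff(gene_means),
    }


@pytest.fixture(scope="session")
def default_run():
    """One default-condition synthetic dataset, shared across tests."""
    return run_chain(mn.SimulationConfig(seed=1213))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
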