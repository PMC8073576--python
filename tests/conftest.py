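import numpy as np
import pandas as pd
import pytest

from prxmap.containers import ExperimentDesign, IntensityMatrix
from prxmap.synthetic import (
    DropoutSpec,
    TruthConfig,
    generate_interactome_truth,
    simulate_lfq_experiment,
)


@pytest.fixture(scope="session")
def two_condition_design() -> ExperimentDesign:
    """One isoform, WT vs catalytic-dead, 3 replicates each."""
    return ExperimentDesign.full_design(isoforms=["PRDX1"], genotypes=["WT", "CPRS"])


@pytest.fixture(scope="session")
def full_design() -> ExperimentDesign:
    return ExperimentDesign.full_design()


@pytest.fixture(scope="session")
def null_experiment(two_condition_design):
    """1000 background proteins, no planted effects, ~34% dropout."""
    cfg = TruthConfig(
        seed=3,
        n_background=1000,
        n_interactors=0,
        n_reverse_decoys=0,
        n_contaminants=0,
        low_peptide_fraction=0.0,
    )
    truths = generate_interactome_truth(cfg)
    matrix, ptable = simulate_lfq_experiment(
        truths,
        two_condition_design,
        DropoutSpec(target_missing_fraction=0.34),
        noise_sd=0.5,
        seed=3,
    )
    return truths, matrix, ptable


@pytest.fixture()
def tiny_matrix():
    """3 proteins x 4 samples log2 matrix with one missing cell."""
    values = pd.DataFrame(
        [
            [20.0, 21.0, 20.5, 20.8],
            [25.0, np.nan, 25.5, 24.9],
            [30.0, 30.2, 29.8, 30.1],
        ],
        index=["P1", "P2", "P3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return IntensityMatrix(values, scale="log2")
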