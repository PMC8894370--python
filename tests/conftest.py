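import numpy as np
import pytest

from kinomeprofiler.array_io import ExposureStack
from kinomeprofiler.preprocess import PhosphoMatrix
from kinomeprofiler.synthetic import (
    SyntheticTruth,
    default_fixture_layout,
    default_substrate_map,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def layout():
    return default_fixture_layout()


@pytest.fixture(scope="session")
def substrate_map(layout):
    return default_substrate_map(layout=layout)


@pytest.fixture
def small_stack():
    """2 samples x 3 peptides x 3 exposures with exactly linear signals."""
    exposures = np.array([10.0, 50.0, 200.0])
    slopes = np.array([[2.0, 0.5, 10.0], [1.0, 4.0, 0.0]])  # per (sample, peptide)
    intensity = slopes[:, :, None] * exposures[None, None, :]
    return ExposureStack(
        samples=["s1", "s2"],
        group_of={"s1": "A", "s2": "B"},
        peptide_ids=["PEP1_1_10", "PEP2_5_20", "PEP3_2_14"],
        exposure_times_ms=exposures,
        intensity=intensity,
    )


def make_matrix(values, groups, peptides=None):
    values = np.asarray(values, dtype=float)
    samples = [f"s{i}" for i in range(values.shape[0])]
    if peptides is None:
        peptides = [f"P{j}_1_10" for j in range(values.shape[1])]
    return PhosphoMatrix(
        samples=samples,
        peptides=list(peptides),
        values=values,
        group_of=dict(zip(samples, groups)),
    )


@pytest.fixture(scope="session")
def planted_noiseless(layout, substrate_map):
    """Noise-free experiment with PKG1 doubled in rd1."""
    truth = SyntheticTruth(
        seed=11,
        groups={"WT": 5, "rd1": 8},
        active_kinases={("PKG1", "rd1"): 2.0},
        noise_sd_log2=0.0,
        exposure_noise_cv=0.0,
    )
    return simulate_experiment(truth, layout, substrate_map)
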