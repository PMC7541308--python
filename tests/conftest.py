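import numpy as np
import pytest

from protnet import SimConfig, simulate
from protnet.types import AbundanceMatrix, SampleMeta


def make_samples(n_per_group: int = 4) -> list[SampleMeta]:
    samples = []
    for age in ("young", "old"):
        for geno in ("WT", "KO"):
            for r in range(1, n_per_group + 1):
                samples.append(
                    SampleMeta(f"{geno}_{age}_{r}", geno, age, batch=age, replicate=r)
                )
    return samples


def make_matrix(values: np.ndarray, mask: np.ndarray | None = None,
                proteins: list[str] | None = None) -> AbundanceMatrix:
    values = np.asarray(values, float)
    n_p, n_s = values.shape
    assert n_s == 16, "helper builds the standard 16-sample design"
    if proteins is None:
        proteins = [f"P{i}" for i in range(n_p)]
    if mask is None:
        mask = np.ones_like(values, dtype=bool)
    return AbundanceMatrix(proteins, make_samples(), values, mask)


@pytest.fixture(scope="session")
def default_sim():
    """One default simulation with ground truth, shared across tests."""
    return simulate(SimConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
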