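import numpy as np
import pytest

from ampeff.gam import fit_gam
from ampeff.simulate import SimulationConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic study: 60 pairs x 8 replicates = 480 reactions."""
    return generate_dataset(SimulationConfig(seed=42, n_pairs=60, n_replicates=8))


@pytest.fixture(scope="session")
def fitted_model(small_dataset):
    model, summary = fit_gam(small_dataset)
    return model, summary


def brute_force_triplet_overlap(a: str, b: str) -> int:
    """Independent oracle: exhaustive triplet-by-triplet matching.

    Walks every 3-mer of *a*, consuming at most one matching 3-mer of *b*
    per hit, without any Counter machinery.
    """
    ta = [a[i : i + 3] for i in range(len(a) - 2)]
    tb = [b[i : i + 3] for i in range(len(b) - 2)]
    hits = 0
    for t in ta:
        for j, u in enumerate(tb):
            if t == u:
                hits += 1
                del tb[j]
                break
    return hits


def brute_force_revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[c] for c in reversed(seq))
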