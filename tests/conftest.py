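import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from rristack.dataset import featurize_complex
from rristack.synthgen import SynthParams, generate_complex


@pytest.fixture(scope="session")
def small_complex():
    """A small synthetic two-chain complex with its generator truth."""
    record, positives = generate_complex(
        SynthParams(n_residues=30, target_pairs=15, seed=7), "SMALL"
    )
    return record, positives


@pytest.fixture(scope="session")
def small_featurized(small_complex):
    record, _ = small_complex
    return featurize_complex(record)


def rigid_motion(rng: np.random.Generator):
    """A random rotation matrix + translation vector."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.normal(scale=20.0, size=3)


def transform_record(record, rot, shift):
    """Apply a rigid motion to every atom of a complex (in place copy)."""
    import copy

    moved = copy.deepcopy(record)
    for chain in moved.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.coords = rot @ atom.coords + shift
    return moved
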