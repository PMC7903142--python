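"""Shared fixtures: tiny seeded synthetic datasets and models.

BLAS thread pools are pinned to one thread before numpy loads so test
timings and histories are stable across machines.
"""

import os

for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from cathseg.synthgen import SynthgenConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_config():
    return SynthgenConfig(
        n_samples=12, frame_size=64, n_backgrounds=4, n_shapes=8, seed=11
    )


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory, tiny_config):
    """12 synthetic 64x64 image/mask pairs with manifest, on disk."""
    out = tmp_path_factory.mktemp("tiny_ds")
    manifest = generate_dataset(tiny_config.n_samples, tiny_config, 11, out)
    return out, manifest


@pytest.fixture(scope="session")
def tiny_arrays(tiny_dataset):
    from cathseg.training import load_manifest_arrays

    out, _ = tiny_dataset
    return load_manifest_arrays(out / "manifest.csv")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
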