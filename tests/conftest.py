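import numpy as np
import pytest

from sononet.datapipe import build_clip_index, make_splits
from sononet.synthdata import ProtocolSpec, generate_dataset


@pytest.fixture(scope="session")
def small_protocol():
    """Compact 5-scan protocol: scan 3 alternates heart/other, the rest carry
    one static class each."""
    return ProtocolSpec(
        scans=(
            ((0, 20),),
            ((1, 20), (2, 20)),
            ((3, 20), (6, 20), (3, 20), (6, 20)),
            ((4, 20),),
            ((5, 20),),
        )
    )


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory, small_protocol):
    """6 synthetic patients written to disk: (manifest, priors, frames)."""
    out = tmp_path_factory.mktemp("synth")
    return generate_dataset(6, small_protocol, seed=3, size=64, out_dir=out)


@pytest.fixture(scope="session")
def small_split(small_dataset):
    manifest, _, _ = small_dataset
    return make_splits(manifest, test_fraction=0.4, val_fraction=0.25, seed=0, test_seed=5)


@pytest.fixture(scope="session")
def small_clip_index(small_dataset):
    manifest, _, _ = small_dataset
    return build_clip_index(manifest, 10)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
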