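import os

# pin BLAS threading before numpy loads so training runs are bit-identical
# regardless of host core count
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from keloidscope.perfusion import default_lut
from keloidscope.synthetic import SceneSpec, generate_dataset


@pytest.fixture(scope="session")
def lut():
    return default_lut()


@pytest.fixture(scope="session")
def small_spec():
    # 128-px scenes keep unit tests fast; statistics are size-invariant
    return SceneSpec(image_height=128, image_width=128, seed=5)


@pytest.fixture(scope="session")
def small_dataset():
    """24 cases at 128 px with the default stage mix and site profiles."""
    records, manifest = generate_dataset(
        24, seed=42, base_spec=SceneSpec(image_height=128, image_width=128)
    )
    return records, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
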