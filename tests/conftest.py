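import numpy as np
import pytest

from compositedna.mapping import CodeConfig, preset
from compositedna.constellation import ALPHABET_2, ALPHABET_3, ALPHABET_4
from compositedna.pipeline import encode_bytes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def data_2355():
    return np.random.default_rng(99).integers(0, 256, 2355, dtype=np.uint8).tobytes()


@pytest.fixture(scope="session")
def encoded_8col(data_2355):
    """(frames, info) for the 126-strand column-synthesis preset."""
    cfg = preset("8col")
    frames, info = encode_bytes(data_2355, cfg)
    return cfg, frames, info, data_2355


def tiny_config(alphabet, name="tiny", **kw):
    """A 3-strand toy configuration for fast end-to-end tests."""
    field_bits = 15 if len(alphabet) == 15 else 12
    defaults = dict(
        name=name, alphabet=alphabet, rs_n=45, rs_k=30, field_bits=field_bits,
        n_blocks=1, index_len_5p=8, index_len_3p=8,
    )
    defaults.update(kw)
    return CodeConfig(**defaults)


@pytest.fixture(scope="session")
def small_15_config():
    """A 50-strand 15-letter configuration for detector-comparison tests."""
    return CodeConfig(
        name="small15", alphabet=ALPHABET_4, rs_n=750, rs_k=625, field_bits=15,
        n_blocks=1, index_len_5p=8, index_len_3p=8,
    )
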