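import numpy as np
import pytest

from wmsnorm.gc_model import GcBiasModel
from wmsnorm.synthetic import planted_bias_model


@pytest.fixture
def rng():
    return np.random.default_rng(20160)


@pytest.fixture
def planted_model() -> GcBiasModel:
    return planted_bias_model()


@pytest.fixture
def simple_model() -> GcBiasModel:
    """Flat bias surface (predicts 1 everywhere): weights are all 1."""
    return GcBiasModel(theta=(0.0, 50.0, 10.0, 1.0, 0.0, 0.0, 0.0, 0.0))


@pytest.fixture
def tiny_fasta(tmp_path):
    """Three 300 bp references with distinct GC compositions."""
    path = tmp_path / "refs.fasta"
    gc100 = "GGCC" * 75
    gc0 = "AATT" * 75
    gc50 = "ATGC" * 75
    path.write_text(f">high\n{gc100}\n>low\n{gc0}\n>mid\n{gc50}\n")
    return path
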