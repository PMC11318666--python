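import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture
def write_matrix(tmp_path):
    """Write a dense matrix text file and return its path."""

    def _write(text_or_array, name="mat.tsv"):
        p = tmp_path / name
        if isinstance(text_or_array, str):
            p.write_text(text_or_array)
        else:
            np.savetxt(p, np.asarray(text_or_array, dtype=float), delimiter="\t")
        return p

    return _write
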