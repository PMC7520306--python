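import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20200806)


@pytest.fixture
def gmt_file(tmp_path):
    """Write GMT lines to a temp file and return its path."""

    def _write(lines):
        path = tmp_path / "sets.gmt"
        path.write_text("".join(line + "\n" for line in lines))
        return path

    return _write
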