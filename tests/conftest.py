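import sys
from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cmakit import example_network


@pytest.fixture
def network():
    """Weighted example CMA network (two lamp2a paralogs, mixed families)."""
    return example_network()


@pytest.fixture
def fasta_file(tmp_path):
    def _write(text: str) -> Path:
        p = tmp_path / "proteins.fasta"
        p.write_text(text)
        return p

    return _write
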