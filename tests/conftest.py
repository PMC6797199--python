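import pytest

from httscan.core_io import Config, SequenceRecord


@pytest.fixture
def cfg():
    return Config()


@pytest.fixture
def write_text(tmp_path):
    def _write(name, content):
        p = tmp_path / name
        p.write_text(content)
        return p
    return _write


def rec(id, seq, species=None):
    """Shorthand SequenceRecord constructor with species parsed from the id."""
    if species is None:
        species = id.split("_")[0]
    return SequenceRecord(id=id, seq=seq, species=species)
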