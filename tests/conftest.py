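import pytest

from tcrscreen.germline import bundled_germline
from tcrscreen.readqc import SequencingRead


@pytest.fixture(scope="session")
def db():
    """Bundled synthetic germline database (17 segments)."""
    return bundled_germline()


def make_read(seq, quals, read_id="r1", mate="merged"):
    if isinstance(quals, int):
        quals = [quals] * len(seq)
    return SequencingRead(read_id=read_id, mate=mate, seq=seq, quals=list(quals))
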