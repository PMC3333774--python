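import gzip
from pathlib import Path

import pytest

from shscreen import HairpinLibrary, HairpinRecord


def make_fastq(path: Path, seqs: list[str], gz: bool = False) -> Path:
    opener = gzip.open if gz else open
    with opener(path, "wt") as fh:
        for i, seq in enumerate(seqs, 1):
            fh.write(f"@read{i}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


@pytest.fixture
def tiny_lib() -> HairpinLibrary:
    """Three well-separated hairpins plus a near-neighbour pair.

    h1/h3 differ at two positions (distance 2), h2 is 19 away from h1.
    """
    return HairpinLibrary(
        [
            HairpinRecord("h1", "GENE1", "AAAAAAAAAAAAAAAAAAA"),
            HairpinRecord("h2", "GENE2", "CCCCCCCCCCCCCCCCCCC"),
            HairpinRecord("h3", "GENE3", "AAAAAAAAAAAAAAAAACC"),
            HairpinRecord("h4", "GENE2", "GATCGATCGATCGATCGAT"),
        ],
        name="tiny",
    )


@pytest.fixture
def fastq_writer(tmp_path):
    def _write(seqs: list[str], name: str = "reads.fq", gz: bool = False) -> Path:
        return make_fastq(tmp_path / name, seqs, gz=gz)

    return _write
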