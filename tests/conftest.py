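import gzip
from pathlib import Path

import pytest

from adtcount import CellWhitelist, OligoReference


def write_fastq(path: Path, records: list[tuple[str, str]], gzipped: bool = False) -> Path:
    """Write (read_id, sequence) records as FASTQ with dummy qualities."""
    body = "".join(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n" for rid, seq in records)
    if gzipped:
        with gzip.open(path, "wt") as fh:
            fh.write(body)
    else:
        path.write_text(body)
    return path


@pytest.fixture
def small_whitelist() -> CellWhitelist:
    return CellWhitelist(
        (
            "AAAACCCCGGGGTTTT",
            "ACGTACGTACGTACGT",
            "TTTTGGGGCCCCAAAA",
            "GATCGATCGATCGATC",
        )
    )


@pytest.fixture
def small_reference() -> OligoReference:
    return OligoReference(
        names=("CD4", "CD8", "CD19"),
        sequences=(
            "AAAATTTTCCCCGGGG",
            "CGCGCGCGATATATAT",
            "TGCATGCATGCATGCA",
        ),
    )
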