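"""Reading and writing for antibody-tag counting runs.

Inputs are paired FASTQ files (one read of each pair carrying the cell
barcode + UMI, the other the antibody-oligo tag), a two-column oligo
reference table and a cell-barcode whitelist.  Output is a feature-by-
barcode count matrix written both as a CellRanger-style MatrixMarket
triplet (matrix.mtx.gz / barcodes.tsv.gz / features.tsv.gz) and,
optionally, as a dense CSV.

Coordinates are 0-based half-open everywhere in memory; MatrixMarket
indices are 1-based on disk as the format requires.
"""

from __future__ import annotations

import gzip
import itertools
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam
import scipy.io
import scipy.sparse

__all__ = [
    "ReadLayout",
    "ReadRecord",
    "OligoReference",
    "CellWhitelist",
    "CountMatrix",
    "PairedFastqStream",
    "load_oligo_reference",
    "load_whitelist",
    "write_mtx_triplet",
    "read_mtx_triplet",
    "write_dense_csv",
    "read_dense_csv",
    "FEATURE_TYPE",
]

_ACGT_RE = re.compile(r"^[ACGT]+$")

#: literal feature-type string CellRanger uses for antibody capture libraries
FEATURE_TYPE = "Antibody Capture"


@dataclass(frozen=True)
class ReadLayout:
    """Where the cell barcode, UMI and tag live inside the paired reads.

    Offsets are 0-based; windows are half-open.  The defaults assume a
    16-bp cell barcode at the start of the cell-ID read, a 12-bp UMI
    immediately after it, and a 16-bp antibody tag at the start of the
    oligo read — the prevailing droplet-chemistry geometry.
    """

    barcode_start: int = 0
    barcode_len: int = 16
    umi_start: int = 16
    umi_len: int = 12
    tag_start: int = 0
    tag_len: int = 16

    def __post_init__(self) -> None:
        for name in ("barcode_start", "umi_start", "tag_start"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("barcode_len", "umi_len", "tag_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")

    @property
    def cellid_read_min_len(self) -> int:
        return max(self.barcode_start + self.barcode_len, self.umi_start + self.umi_len)

    @property
    def oligo_read_min_len(self) -> int:
        return self.tag_start + self.tag_len


class ReadRecord(NamedTuple):
    """One sequenced molecule's extracted sub-sequences."""

    read_id: str
    cell_seq: str
    umi_seq: str
    tag_seq: str


def _validate_sequences(seqs: Sequence[str], what: str) -> None:
    if not seqs:
        raise ValueError(f"{what}: empty list")
    bad = [s for s in seqs if not _ACGT_RE.match(s)]
    if bad:
        raise ValueError(f"{what}: non-ACGT sequences: {bad[:5]}")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"{what}: ragged sequence lengths {sorted(lengths)}")


@dataclass(frozen=True)
class OligoReference:
    """The antibody-oligo panel: ordered (marker name, tag sequence) pairs."""

    names: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise ValueError("names and sequences differ in length")
        _validate_sequences(self.sequences, "oligo reference")
        dup_names = [n for n, c in _counts(self.names).items() if c > 1]
        if dup_names:
            raise ValueError(f"duplicate marker names: {dup_names}")
        dup_seqs = [s for s, c in _counts(self.sequences).items() if c > 1]
        if dup_seqs:
            raise ValueError(f"duplicate oligo sequences: {dup_seqs}")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def width(self) -> int:
        return len(self.sequences[0])


@dataclass(frozen=True)
class CellWhitelist:
    """Ordered list of valid cell barcodes."""

    barcodes: tuple[str, ...]

    def __post_init__(self) -> None:
        _validate_sequences(self.barcodes, "cell whitelist")
        dups = [b for b, c in _counts(self.barcodes).items() if c > 1]
        if dups:
            raise ValueError(f"duplicate barcodes after suffix stripping: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.barcodes)

    @property
    def width(self) -> int:
        return len(self.barcodes[0])


def _counts(items: Sequence[str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for x in items:
        out[x] = out.get(x, 0) + 1
    return out


@dataclass
class CountMatrix:
    """Deduplicated feature-by-barcode integer matrix.

    Rows are oligo-reference entries in reference order, columns are
    whitelist barcodes in whitelist order — the full cross product, so
    the dimensions never depend on which entries happen to be nonzero.
    """

    counts: np.ndarray
    row_names: tuple[str, ...]
    col_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.row_names), len(self.col_names)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.row_names)} features x {len(self.col_names)} barcodes"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.row_names = tuple(self.row_names)
        self.col_names = tuple(self.col_names)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.row_names == other.row_names
            and self.col_names == other.col_names
            and np.array_equal(self.counts, other.counts)
        )


# ---------------------------------------------------------------------------
# FASTQ input
# ---------------------------------------------------------------------------

def _strip_mate_suffix(name: str) -> str:
    return re.sub(r"/[123]$", "", name)


class PairedFastqStream:
    """Iterate paired FASTQ lanes as :class:`ReadRecord` objects.

    One cell-ID file and one oligo file per lane; lanes are concatenated in
    the given order.  Reads too short for the layout windows are skipped
    and tallied in :attr:`n_skipped_short`, never truncated or padded.
    Gzip is handled transparently.
    """

    def __init__(
        self,
        cellid_paths: Sequence[str | Path],
        oligo_paths: Sequence[str | Path],
        layout: ReadLayout | None = None,
    ) -> None:
        if len(cellid_paths) != len(oligo_paths):
            raise ValueError(
                f"{len(cellid_paths)} cell-ID files vs {len(oligo_paths)} oligo files: "
                "one pair per lane required"
            )
        if not cellid_paths:
            raise ValueError("no input FASTQ files given")
        self.cellid_paths = [Path(p) for p in cellid_paths]
        self.oligo_paths = [Path(p) for p in oligo_paths]
        self.layout = layout or ReadLayout()
        self.n_pairs = 0
        self.n_skipped_short = 0

    def __iter__(self) -> Iterator[ReadRecord]:
        lay = self.layout
        for lane, (cpath, opath) in enumerate(zip(self.cellid_paths, self.oligo_paths)):
            with pysam.FastxFile(str(cpath)) as cf, pysam.FastxFile(str(opath)) as of:
                for idx, (crec, orec) in enumerate(itertools.zip_longest(cf, of)):
                    if crec is None or orec is None:
                        short = cpath if crec is None else opath
                        raise ValueError(
                            f"lane {lane} ({cpath.name} / {opath.name}): unequal record "
                            f"counts — {short.name} ended at record {idx}"
                        )
                    cid = _strip_mate_suffix(crec.name)
                    oid = _strip_mate_suffix(orec.name)
                    if cid != oid:
                        raise ValueError(
                            f"lane {lane}, record {idx}: paired read ids differ "
                            f"({crec.name!r} vs {orec.name!r})"
                        )
                    self.n_pairs += 1
                    cseq = crec.sequence.upper()
                    tseq = orec.sequence.upper()
                    if len(cseq) < lay.cellid_read_min_len or len(tseq) < lay.oligo_read_min_len:
                        self.n_skipped_short += 1
                        continue
                    yield ReadRecord(
                        read_id=cid,
                        cell_seq=cseq[lay.barcode_start : lay.barcode_start + lay.barcode_len],
                        umi_seq=cseq[lay.umi_start : lay.umi_start + lay.umi_len],
                        tag_seq=tseq[lay.tag_start : lay.tag_start + lay.tag_len],
                    )
        if self.n_pairs == 0:
            raise ValueError("empty FASTQ input: no records found in any lane")


# ---------------------------------------------------------------------------
# Reference tables
# ---------------------------------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_oligo_reference(path: str | Path) -> OligoReference:
    """Load a two-column (marker name, tag sequence) delimited table.

    Comma, tab or whitespace delimited; an optional header row is detected
    by its second column not being a plain ACGT sequence.
    """
    names: list[str] = []
    seqs: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = re.split(r"[,\t ]+", line)
            if len(parts) < 2:
                raise ValueError(f"oligo reference {path}: expected 2 columns, got {line!r}")
            names.append(parts[0])
            seqs.append(parts[1].upper())
    if not names:
        raise ValueError(f"oligo reference {path}: empty file")
    if len(names) > 1 and not _ACGT_RE.match(seqs[0]):
        # header row; a lone malformed row falls through to sequence validation
        names, seqs = names[1:], seqs[1:]
    if not names:
        raise ValueError(f"oligo reference {path}: no data rows")
    return OligoReference(names=tuple(names), sequences=tuple(seqs))


def load_whitelist(path: str | Path) -> CellWhitelist:
    """Load a one-barcode-per-line whitelist, optionally gzipped.

    Trailing suffixes after a dash (CellRanger's ``-1`` GEM-well suffix)
    are stripped before validation.
    """
    barcodes: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            bc = line.strip()
            if not bc:
                continue
            bc = bc.split("-", 1)[0].upper()
            barcodes.append(bc)
    if not barcodes:
        raise ValueError(f"whitelist {path}: empty file")
    return CellWhitelist(barcodes=tuple(barcodes))


# ---------------------------------------------------------------------------
# Matrix output
# ---------------------------------------------------------------------------

def _gzip_out(path: Path):
    # mtime=0 so identical content gives byte-identical files across runs
    return gzip.GzipFile(str(path), "wb", mtime=0)


def write_mtx_triplet(matrix: CountMatrix, outdir: str | Path) -> tuple[Path, Path, Path]:
    """Write a CellRanger-style gzipped MTX triplet.

    ``matrix.mtx.gz`` uses the MatrixMarket ``coordinate integer general``
    header with 1-based indices, features as rows and barcodes as columns,
    listing only nonzero entries in column-major order; ``barcodes.tsv.gz``
    has one barcode per line in whitelist order; ``features.tsv.gz`` has
    (id, name, "Antibody Capture") per line in reference order.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mtx_path = outdir / "matrix.mtx.gz"
    bc_path = outdir / "barcodes.tsv.gz"
    ft_path = outdir / "features.tsv.gz"

    coo = scipy.sparse.csc_matrix(matrix.counts).tocoo()
    with _gzip_out(mtx_path) as fh:
        scipy.io.mmwrite(fh, coo, field="integer")
    with _gzip_out(bc_path) as fh:
        fh.write(("".join(f"{bc}\n" for bc in matrix.col_names)).encode())
    with _gzip_out(ft_path) as fh:
        fh.write(
            ("".join(f"{n}\t{n}\t{FEATURE_TYPE}\n" for n in matrix.row_names)).encode()
        )
    return mtx_path, bc_path, ft_path


def read_mtx_triplet(outdir: str | Path) -> CountMatrix:
    """Read back a triplet written by :func:`write_mtx_triplet`."""
    outdir = Path(outdir)
    with gzip.open(outdir / "matrix.mtx.gz", "rb") as fh:
        counts = scipy.io.mmread(fh).toarray().astype(np.int64)
    with gzip.open(outdir / "barcodes.tsv.gz", "rt") as fh:
        col_names = tuple(line.strip() for line in fh if line.strip())
    with gzip.open(outdir / "features.tsv.gz", "rt") as fh:
        row_names = tuple(line.split("\t")[0] for line in fh if line.strip())
    return CountMatrix(counts=counts, row_names=row_names, col_names=col_names)


def write_dense_csv(matrix: CountMatrix, path: str | Path) -> Path:
    """Write the full dense matrix as CSV, markers as row labels."""
    path = Path(path)
    df = pd.DataFrame(matrix.counts, index=list(matrix.row_names), columns=list(matrix.col_names))
    df.to_csv(path, index_label="marker")
    return path


def read_dense_csv(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, index_col=0)
    return CountMatrix(
        counts=df.to_numpy(dtype=np.int64),
        row_names=tuple(df.index.astype(str)),
        col_names=tuple(df.columns.astype(str)),
    )
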