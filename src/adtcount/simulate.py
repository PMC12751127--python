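"""Synthetic paired-FASTQ generator with exact ground truth.

Emulates the read structure of a droplet feature-barcoding experiment:
each original molecule is a (cell barcode, antibody oligo, UMI) triple;
the cell-ID read carries barcode + UMI, the oligo read carries the tag.
Configurable corruptions mirror the failure modes the counting pipeline
must survive:

* per-base substitution errors in barcode / UMI / tag windows,
* PCR re-emission with an identical UMI (exact duplicates),
* PCR re-emission with a single-base UMI error (fuzzy duplicates),
* ambient reads whose barcode is on no whitelist entry,
* an optional "ambiguity bait": a whitelist pair at Hamming distance 2
  plus reads equidistant between them, which a 1-mismatch matcher must
  drop as ambiguous.

The ground-truth matrix counts distinct molecules (duplicates collapse),
so for error-free or one-substitution regimes with well-separated
references it is the exact oracle for the pipeline's output.  Molecule
UMIs are drawn at pairwise Hamming distance >= 3 within each cell, so
neither exact collisions nor one-base duplicate twins can ever bridge
two true molecules.  Errors are substitutions by default; a tag indel
rate exists for stress-testing the edit-ratio metric.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .formats_io import CellWhitelist, CountMatrix, OligoReference, write_mtx_triplet

__all__ = [
    "SimParams",
    "SimulationTruth",
    "SimulatedDataset",
    "make_references",
    "emit_reads",
    "simulate_dataset",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults model a small, clean bench experiment.

    Rates are probabilities in [0, 1].  ``mean_reads_per_pair`` is the
    Poisson mean of molecules per (cell, oligo) combination.
    ``pcr_dup_rate`` / ``fuzzy_dup_rate`` are per-read re-emission
    probabilities (identical UMI / one-base-off UMI).  ``ambient_rate``
    adds off-whitelist reads in proportion to the molecule read count.
    ``max_subs_per_window`` optionally caps injected substitutions per
    barcode/UMI/tag window, for controlled-error recovery experiments.
    """

    n_cells: int = 200
    n_oligos: int = 20
    barcode_len: int = 16
    umi_len: int = 12
    tag_len: int = 16
    mean_reads_per_pair: float = 5.0
    barcode_sub_rate: float = 0.0
    umi_sub_rate: float = 0.0
    tag_sub_rate: float = 0.0
    tag_indel_rate: float = 0.0
    pcr_dup_rate: float = 0.0
    fuzzy_dup_rate: float = 0.0
    ambient_rate: float = 0.0
    ambiguous_bait: bool = False
    n_bait_reads: int = 0
    max_subs_per_window: int | None = None
    min_pairwise_distance: int = 3

    def __post_init__(self) -> None:
        for name in (
            "barcode_sub_rate",
            "umi_sub_rate",
            "tag_sub_rate",
            "tag_indel_rate",
            "pcr_dup_rate",
            "fuzzy_dup_rate",
            "ambient_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_cells", "n_oligos", "barcode_len", "umi_len", "tag_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.mean_reads_per_pair < 0:
            raise ValueError("mean_reads_per_pair must be >= 0")


@dataclass
class SimulationTruth:
    """Ground truth: post-dedup molecule counts and per-read provenance."""

    matrix: CountMatrix
    provenance: pd.DataFrame


@dataclass
class SimulatedDataset:
    cellid_fastq: Path
    oligo_fastq: Path
    whitelist_path: Path
    reference_path: Path
    truth: SimulationTruth


def _random_distinct_seqs(
    rng: np.random.Generator,
    n: int,
    length: int,
    min_dist: int,
    max_tries_factor: int = 2000,
) -> list[str]:
    """Rejection-sample sequences with pairwise Hamming distance >= min_dist."""
    if 4**length < n:
        raise ValueError(
            f"cannot draw {n} distinct sequences of length {length}: alphabet too small"
        )
    chosen: list[np.ndarray] = []
    tries = 0
    max_tries = max_tries_factor * n
    while len(chosen) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n} sequences of length {length} at pairwise "
                f"distance >= {min_dist} after {max_tries} draws"
            )
        cand = rng.integers(0, 4, size=length)
        if all(int((cand != c).sum()) >= min_dist for c in chosen):
            chosen.append(cand)
    return ["".join(_BASES[c]) for c in chosen]


def make_references(
    params: SimParams, seed: int
) -> tuple[CellWhitelist, OligoReference]:
    """Draw a whitelist and oligo panel with pairwise Hamming distance >= 3.

    With the ambiguity bait enabled, two extra whitelist barcodes at
    Hamming distance 2 from each other are appended; they deliberately
    violate the separation invariant so that midpoint reads become
    ambiguous under a 1-mismatch cutoff.
    """
    rng = np.random.default_rng(seed)
    barcodes = _random_distinct_seqs(
        rng, params.n_cells, params.barcode_len, params.min_pairwise_distance
    )
    oligos = _random_distinct_seqs(
        rng, params.n_oligos, params.tag_len, params.min_pairwise_distance
    )
    if params.ambiguous_bait:
        b1, b2 = _make_bait_pair(rng, barcodes, params)
        barcodes = barcodes + [b1, b2]
    names = tuple(f"ADT{i + 1:03d}" for i in range(params.n_oligos))
    return CellWhitelist(tuple(barcodes)), OligoReference(names, tuple(oligos))


def _make_bait_pair(
    rng: np.random.Generator, existing: list[str], params: SimParams
) -> tuple[str, str]:
    enc = np.frombuffer("".join(existing).encode(), dtype=np.uint8).reshape(
        len(existing), -1
    )
    for _ in range(10_000):
        cand = rng.integers(0, 4, size=params.barcode_len)
        b1 = "".join(_BASES[cand])
        b1_enc = np.frombuffer(b1.encode(), dtype=np.uint8)
        if ((enc != b1_enc).sum(axis=1) < params.min_pairwise_distance).any():
            continue
        pos = rng.choice(params.barcode_len, size=2, replace=False)
        cand2 = cand.copy()
        for p in pos:
            cand2[p] = (cand2[p] + 1 + rng.integers(0, 3)) % 4
        b2 = "".join(_BASES[cand2])
        b2_enc = np.frombuffer(b2.encode(), dtype=np.uint8)
        if ((enc != b2_enc).sum(axis=1) < params.min_pairwise_distance).any():
            continue
        return b1, b2
    raise ValueError("could not place an ambiguity-bait barcode pair")


def _bait_midpoint(b1: str, b2: str) -> str:
    """A barcode at Hamming distance 1 from each of two distance-2 barcodes."""
    diff = [i for i in range(len(b1)) if b1[i] != b2[i]]
    mid = list(b1)
    mid[diff[0]] = b2[diff[0]]
    return "".join(mid)


def _substitute(
    rng: np.random.Generator, seq: str, rate: float, cap: int | None
) -> tuple[str, int]:
    if rate <= 0.0:
        return seq, 0
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if cap is not None and len(hits) > cap:
        hits = rng.choice(hits, size=cap, replace=False)
    if len(hits) == 0:
        return seq, 0
    chars = list(seq)
    for i in hits:
        old = chars[i]
        choices = [b for b in "ACGT" if b != old]
        chars[i] = choices[rng.integers(0, 3)]
    return "".join(chars), len(hits)


def _indel(rng: np.random.Generator, seq: str) -> str:
    # single-base deletion or insertion, keeping the read non-empty
    pos = int(rng.integers(0, len(seq)))
    if rng.random() < 0.5 and len(seq) > 1:
        return seq[:pos] + seq[pos + 1 :]
    base = "ACGT"[rng.integers(0, 4)]
    return seq[:pos] + base + seq[pos:]


def _new_umi(rng: np.random.Generator, used: set[str], length: int) -> str:
    # molecule UMIs within a cell keep pairwise Hamming distance >= 3, so a
    # one-base duplicate twin can only ever connect to its own parent and the
    # truth matrix stays an exact oracle for fuzzy dedup
    while True:
        u = "".join(_BASES[rng.integers(0, 4, size=length)])
        if all(sum(1 for x, y in zip(u, v) if x != y) >= 3 for v in used):
            used.add(u)
            return u


def _one_off_umi(rng: np.random.Generator, umi: str, used: set[str]) -> str:
    for _ in range(100):
        pos = int(rng.integers(0, len(umi)))
        base = "ACGT"[rng.integers(0, 4)]
        if base == umi[pos]:
            continue
        cand = umi[:pos] + base + umi[pos + 1 :]
        if cand not in used:
            used.add(cand)
            return cand
    raise RuntimeError("could not draw a one-off UMI")


def emit_reads(
    params: SimParams,
    whitelist: CellWhitelist,
    reference: OligoReference,
    outdir: str | Path,
    seed: int,
) -> SimulatedDataset:
    """Emit a shuffled, gzipped FASTQ pair plus ground truth.

    Molecule counts per (cell, oligo) are Poisson with the configured
    mean; duplicates and errors are injected per read at the configured
    rates.  The truth matrix counts distinct molecules for whitelist
    cells only — ambient and bait reads never enter it.  Output is
    byte-reproducible for a fixed (params, seed).
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    n_truth_cells = params.n_cells  # bait barcodes sit at the end, always zero
    truth_counts = np.zeros((len(reference), len(whitelist)), dtype=np.int64)

    # reads as (cell_read_seq, tag_read_seq, provenance dict)
    reads: list[tuple[str, str, dict]] = []
    umis_per_cell: list[set[str]] = [set() for _ in range(len(whitelist))]

    n_mols = rng.poisson(
        params.mean_reads_per_pair, size=(len(reference), n_truth_cells)
    )
    for o in range(len(reference)):
        for c in range(n_truth_cells):
            k = int(n_mols[o, c])
            if k == 0:
                continue
            truth_counts[o, c] += k
            for _ in range(k):
                umi = _new_umi(rng, umis_per_cell[c], params.umi_len)
                emissions = [(umi, False, False)]
                if rng.random() < params.pcr_dup_rate:
                    emissions.append((umi, True, False))
                if rng.random() < params.fuzzy_dup_rate:
                    emissions.append(
                        (_one_off_umi(rng, umi, umis_per_cell[c]), True, True)
                    )
                for read_umi, is_dup, is_fuzzy in emissions:
                    bc_seq, n_bc = _substitute(
                        rng,
                        whitelist.barcodes[c],
                        params.barcode_sub_rate,
                        params.max_subs_per_window,
                    )
                    umi_seq, n_um = _substitute(
                        rng, read_umi, params.umi_sub_rate, params.max_subs_per_window
                    )
                    tag_seq, n_tg = _substitute(
                        rng,
                        reference.sequences[o],
                        params.tag_sub_rate,
                        params.max_subs_per_window,
                    )
                    if params.tag_indel_rate > 0 and rng.random() < params.tag_indel_rate:
                        tag_seq = _indel(rng, tag_seq)
                    reads.append(
                        (
                            bc_seq + umi_seq,
                            tag_seq,
                            {
                                "true_cell": whitelist.barcodes[c],
                                "true_oligo": reference.names[o],
                                "true_umi": read_umi,
                                "is_duplicate": is_dup,
                                "is_fuzzy_duplicate": is_fuzzy,
                                "is_ambient": False,
                                "is_bait": False,
                                "n_sub_barcode": n_bc,
                                "n_sub_umi": n_um,
                                "n_sub_tag": n_tg,
                            },
                        )
                    )

    # ambient reads: off-whitelist barcode (distance >= 2 from every entry)
    n_ambient = rng.poisson(params.ambient_rate * max(1, len(reads)))
    wl_enc = np.frombuffer("".join(whitelist.barcodes).encode(), dtype=np.uint8).reshape(
        len(whitelist), -1
    )
    for _ in range(n_ambient):
        while True:
            cand = rng.integers(0, 4, size=params.barcode_len)
            bc = "".join(_BASES[cand])
            bc_enc = np.frombuffer(bc.encode(), dtype=np.uint8)
            if ((wl_enc != bc_enc).sum(axis=1) >= 2).all():
                break
        o = int(rng.integers(0, len(reference)))
        umi = "".join(_BASES[rng.integers(0, 4, size=params.umi_len)])
        reads.append(
            (
                bc + umi,
                reference.sequences[o],
                {
                    "true_cell": "",
                    "true_oligo": reference.names[o],
                    "true_umi": umi,
                    "is_duplicate": False,
                    "is_fuzzy_duplicate": False,
                    "is_ambient": True,
                    "is_bait": False,
                    "n_sub_barcode": 0,
                    "n_sub_umi": 0,
                    "n_sub_tag": 0,
                },
            )
        )

    if params.ambiguous_bait and params.n_bait_reads > 0:
        b1, b2 = whitelist.barcodes[-2], whitelist.barcodes[-1]
        mid = _bait_midpoint(b1, b2)
        for _ in range(params.n_bait_reads):
            o = int(rng.integers(0, len(reference)))
            umi = "".join(_BASES[rng.integers(0, 4, size=params.umi_len)])
            reads.append(
                (
                    mid + umi,
                    reference.sequences[o],
                    {
                        "true_cell": "",
                        "true_oligo": reference.names[o],
                        "true_umi": umi,
                        "is_duplicate": False,
                        "is_fuzzy_duplicate": False,
                        "is_ambient": False,
                        "is_bait": True,
                        "n_sub_barcode": 0,
                        "n_sub_umi": 0,
                        "n_sub_tag": 0,
                    },
                )
            )

    order = rng.permutation(len(reads))
    cell_fastq = outdir / "sim_cellid.fastq.gz"
    tag_fastq = outdir / "sim_oligo.fastq.gz"
    prov_rows: list[dict] = []
    with gzip.GzipFile(str(cell_fastq), "wb", mtime=0) as cf, gzip.GzipFile(
        str(tag_fastq), "wb", mtime=0
    ) as tf:
        for out_i, idx in enumerate(order):
            cseq, tseq, prov = reads[idx]
            rid = f"sim:{out_i:08d}"
            cf.write(f"@{rid}\n{cseq}\n+\n{'I' * len(cseq)}\n".encode())
            tf.write(f"@{rid}\n{tseq}\n+\n{'I' * len(tseq)}\n".encode())
            prov_rows.append({"read_id": rid, **prov})

    provenance = pd.DataFrame(
        prov_rows,
        columns=[
            "read_id",
            "true_cell",
            "true_oligo",
            "true_umi",
            "is_duplicate",
            "is_fuzzy_duplicate",
            "is_ambient",
            "is_bait",
            "n_sub_barcode",
            "n_sub_umi",
            "n_sub_tag",
        ],
    )
    truth = SimulationTruth(
        matrix=CountMatrix(
            counts=truth_counts,
            row_names=reference.names,
            col_names=whitelist.barcodes,
        ),
        provenance=provenance,
    )
    return SimulatedDataset(
        cellid_fastq=cell_fastq,
        oligo_fastq=tag_fastq,
        whitelist_path=outdir / "whitelist.txt",
        reference_path=outdir / "oligo_reference.csv",
        truth=truth,
    )


def simulate_dataset(
    params: SimParams, outdir: str | Path, seed: int
) -> SimulatedDataset:
    """Generate references, reads and truth files under ``outdir``.

    Writes ``sim_cellid.fastq.gz`` / ``sim_oligo.fastq.gz``,
    ``whitelist.txt``, ``oligo_reference.csv``, the truth matrix as an
    MTX triplet under ``truth/`` and ``provenance.csv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    whitelist, reference = make_references(params, seed)
    # emission gets its own stream so reference growth never shifts read noise
    ds = emit_reads(params, whitelist, reference, outdir, seed + 1_000_003)

    with open(ds.whitelist_path, "w") as fh:
        for bc in whitelist.barcodes:
            fh.write(bc + "\n")
    with open(ds.reference_path, "w") as fh:
        fh.write("marker,sequence\n")
        for name, seq in zip(reference.names, reference.sequences):
            fh.write(f"{name},{seq}\n")
    write_mtx_triplet(ds.truth.matrix, outdir / "truth")
    ds.truth.provenance.to_csv(outdir / "provenance.csv", index=False)
    return ds
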