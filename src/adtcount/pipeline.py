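"""End-to-end counting run: FASTQ pairs in, count matrix + report out.

Stages, in order: extract barcode/UMI/tag windows from each read pair;
match the cell barcode against the whitelist (Hamming, cutoff
``cell_max_mismatch``) and the tag against the oligo panel (normalized
edit ratio, cutoff ``oligo_min_ratio``) — the two matches are
independent; keep only reads unique in both; collapse UMI duplicates;
increment ``counts[oligo, cell]`` once per surviving read; write the
MTX triplet, an optional dense CSV, a per-UMI duplication table and a
plain-text run report.

Reads hitting two or more whitelist barcodes or two or more oligos are
ambiguous and dropped; the report tallies them both as reads and as
distinct offending sequences.  The matrix always spans the full
|reference| x |whitelist| grid.  An empty matrix is a valid result;
errors are reserved for malformed inputs, and a failed run leaves no
partial matrix behind.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .dedup import AssignedRead, DedupParams, DedupReport, dedup_reads
from .formats_io import (
    CellWhitelist,
    CountMatrix,
    OligoReference,
    PairedFastqStream,
    ReadLayout,
    load_oligo_reference,
    load_whitelist,
    write_dense_csv,
    write_mtx_triplet,
)
from .matching import MatchParams, match_batch

__all__ = ["RunConfig", "RunReport", "run_count", "count_from_files"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class RunConfig:
    """Everything a counting run needs."""

    cellid_fastqs: Sequence[str | Path]
    oligo_fastqs: Sequence[str | Path]
    oligo_reference: str | Path
    whitelist: str | Path
    outdir: str | Path
    layout: ReadLayout = field(default_factory=ReadLayout)
    match_params: MatchParams = field(default_factory=MatchParams)
    dedup_params: DedupParams = field(default_factory=DedupParams)
    csv_out: str | Path | None = None
    revcomp_whitelist: bool = False


@dataclass
class RunReport:
    """Per-stage tallies plus a parameter echo; all invariants are checked.

    ``reads_total = reads_skipped_short + reads_with_both_matched +
    everything filtered``; ``reads_in_matrix = reads_assigned −
    umi_duplicates_removed`` and equals the matrix grand total.
    """

    reads_total: int = 0
    reads_skipped_short: int = 0
    cell_unique: int = 0
    cell_none: int = 0
    cell_ambiguous: int = 0
    oligo_unique: int = 0
    oligo_none: int = 0
    oligo_ambiguous: int = 0
    distinct_ambiguous_cell_seqs: int = 0
    distinct_ambiguous_oligo_seqs: int = 0
    reads_assigned: int = 0
    umi_duplicates_removed: int = 0
    reads_in_matrix: int = 0
    parameters: dict = field(default_factory=dict)

    def to_text(self) -> str:
        lines = ["# antibody-tag counting run report", ""]
        for k, v in asdict(self).items():
            if k == "parameters":
                continue
            lines.append(f"{k}\t{v}")
        lines.append("")
        lines.append("# parameters")
        for k, v in self.parameters.items():
            lines.append(f"{k}\t{v}")
        lines.append("")
        return "\n".join(lines)

    def validate(self) -> None:
        matched = self.reads_total - self.reads_skipped_short
        for side in ("cell", "oligo"):
            parts = sum(
                getattr(self, f"{side}_{s}") for s in ("unique", "none", "ambiguous")
            )
            if parts != matched:
                raise AssertionError(
                    f"{side} status partition {parts} != matched reads {matched}"
                )
        if self.reads_in_matrix != self.reads_assigned - self.umi_duplicates_removed:
            raise AssertionError("reads_in_matrix != reads_assigned - duplicates")


def _echo_params(config: RunConfig) -> dict:
    out: dict = {}
    for prefix, obj in (
        ("layout", config.layout),
        ("match", config.match_params),
        ("dedup", config.dedup_params),
    ):
        for k, v in asdict(obj).items():
            out[f"{prefix}.{k}"] = v
    out["revcomp_whitelist"] = config.revcomp_whitelist
    return out


def run_count(
    config: RunConfig,
    log: Callable[[str], None] | None = None,
) -> tuple[CountMatrix, RunReport, DedupReport]:
    """Execute a full counting run and write all outputs to ``config.outdir``."""
    emit = log or (lambda msg: None)
    reference = load_oligo_reference(config.oligo_reference)
    whitelist = load_whitelist(config.whitelist)
    if config.revcomp_whitelist:
        whitelist = CellWhitelist(
            tuple(bc.translate(_COMPLEMENT)[::-1] for bc in whitelist.barcodes)
        )
    emit(f"[load] {len(reference)} oligos, {len(whitelist)} whitelist barcodes")

    matrix, report, dreport = _count_stream(
        PairedFastqStream(config.cellid_fastqs, config.oligo_fastqs, config.layout),
        reference,
        whitelist,
        config.match_params,
        config.dedup_params,
        emit,
    )
    report.parameters = _echo_params(config)
    report.validate()

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        written.extend(write_mtx_triplet(matrix, outdir))
        report_path = outdir / "run_report.txt"
        report_path.write_text(report.to_text())
        written.append(report_path)
        json_path = outdir / "run_report.json"
        json_path.write_text(json.dumps(asdict(report), indent=2, default=str))
        written.append(json_path)
        umi_path = outdir / "umi_duplication.csv"
        dreport.per_key.to_csv(umi_path, index=False)
        written.append(umi_path)
        if config.csv_out is not None:
            written.append(write_dense_csv(matrix, config.csv_out))
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    emit(f"[write] matrix and report in {outdir}")
    return matrix, report, dreport


def _count_stream(
    stream: PairedFastqStream,
    reference: OligoReference,
    whitelist: CellWhitelist,
    match_params: MatchParams,
    dedup_params: DedupParams,
    emit: Callable[[str], None],
) -> tuple[CountMatrix, RunReport, DedupReport]:
    report = RunReport()
    assigned: list[AssignedRead] = []
    amb_cells: set[str] = set()
    amb_oligos: set[str] = set()

    chunk: list = []
    it = iter(stream)

    def flush() -> None:
        if not chunk:
            return
        cell_res = match_batch(
            [r.cell_seq for r in chunk], whitelist, "hamming", match_params
        )
        oligo_res = match_batch(
            [r.tag_seq for r in chunk], reference, "ratio", match_params
        )
        for rec, cr, orr in zip(chunk, cell_res, oligo_res):
            _tally(report, "cell", cr.status)
            _tally(report, "oligo", orr.status)
            if cr.status == "ambiguous":
                amb_cells.add(rec.cell_seq)
            if orr.status == "ambiguous":
                amb_oligos.add(rec.tag_seq)
            if cr.status == "unique" and orr.status == "unique":
                assigned.append(
                    AssignedRead(
                        cell_index=cr.ref_index,
                        oligo_index=orr.ref_index,
                        umi_seq=rec.umi_seq,
                    )
                )
        chunk.clear()

    for rec in it:
        chunk.append(rec)
        if len(chunk) >= match_params.chunk_size:
            flush()
    flush()

    report.reads_total = stream.n_pairs
    report.reads_skipped_short = stream.n_skipped_short
    report.reads_assigned = len(assigned)
    report.distinct_ambiguous_cell_seqs = len(amb_cells)
    report.distinct_ambiguous_oligo_seqs = len(amb_oligos)
    emit(
        f"[match] {report.reads_total} pairs: {report.reads_assigned} assigned, "
        f"{report.cell_ambiguous} cell-ambiguous, {report.oligo_ambiguous} oligo-ambiguous"
    )

    survivors, dreport = dedup_reads(assigned, dedup_params)
    report.umi_duplicates_removed = dreport.n_removed
    report.reads_in_matrix = len(survivors)
    emit(f"[dedup] {dreport.n_removed} duplicate reads removed ({dedup_params.mode})")

    counts = np.zeros((len(reference), len(whitelist)), dtype=np.int64)
    if survivors:
        o_idx = np.fromiter((s.oligo_index for s in survivors), dtype=np.int64)
        c_idx = np.fromiter((s.cell_index for s in survivors), dtype=np.int64)
        np.add.at(counts, (o_idx, c_idx), 1)
    matrix = CountMatrix(
        counts=counts, row_names=reference.names, col_names=whitelist.barcodes
    )
    if matrix.total != report.reads_in_matrix:
        raise AssertionError("matrix grand total != surviving reads")
    return matrix, report, dreport


def _tally(report: RunReport, side: str, status: str) -> None:
    setattr(report, f"{side}_{status}", getattr(report, f"{side}_{status}") + 1)


def count_from_files(
    cellid_fastqs: Sequence[str | Path],
    oligo_fastqs: Sequence[str | Path],
    oligo_reference: str | Path,
    whitelist: str | Path,
    outdir: str | Path,
    **kwargs,
) -> tuple[CountMatrix, RunReport, DedupReport]:
    """Convenience wrapper building a :class:`RunConfig` from paths."""
    config = RunConfig(
        cellid_fastqs=cellid_fastqs,
        oligo_fastqs=oligo_fastqs,
        oligo_reference=oligo_reference,
        whitelist=whitelist,
        outdir=outdir,
        **kwargs,
    )
    return run_count(config)
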