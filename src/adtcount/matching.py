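"""Tolerant assignment of sequences to reference lists.

Two metrics, following the division of labour standard for feature
barcoding: Hamming distance for fixed-width cell barcodes (default
cutoff 1 mismatch) and a normalized edit-distance similarity,
``1 - levenshtein(q, ref) / len(ref)``, for antibody-oligo tags
(default cutoff 0.93 — one substitution in a 16-bp tag scores 0.9375
and passes, two score 0.875 and fail).

A sequence meeting the cutoff for two or more references is *ambiguous*
and is never rescued by best-score tie-breaking: such reads are dropped
and reported.  ``N`` never matches any base, including another ``N``.

Batches are processed in chunks (optionally across threads); results are
defined by, and bit-identical to, the brute-force all-pairs scan
regardless of chunking or thread count.
"""

from __future__ import annotations

import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import edlib
import numpy as np

from .formats_io import CellWhitelist, OligoReference

__all__ = [
    "MatchParams",
    "MatchResult",
    "hamming_distance",
    "normalized_similarity",
    "match_one",
    "match_batch",
]

Metric = Literal["hamming", "ratio"]


@dataclass(frozen=True)
class MatchParams:
    """Cutoffs and batching knobs for reference matching.

    cell_max_mismatch
        Maximum Hamming distance for a cell barcode to hit a whitelist
        entry.  Default 1; larger values recover few extra reads.
    oligo_min_ratio
        Minimum normalized similarity for a tag to hit an oligo.
        Default 0.93, i.e. one mismatch against a 16-bp tag.
    chunk_size
        Sequences per batch handed to the matcher.  Default 100,000.
    threads
        Worker threads for chunk processing; defaults to all available.
    """

    cell_max_mismatch: int = 1
    oligo_min_ratio: float = 0.93
    chunk_size: int = 100_000
    threads: int = field(default_factory=lambda: os.cpu_count() or 1)

    def __post_init__(self) -> None:
        if self.cell_max_mismatch < 0:
            raise ValueError("cell_max_mismatch must be >= 0")
        if not 0.0 <= self.oligo_min_ratio <= 1.0:
            raise ValueError("oligo_min_ratio must be in [0, 1]")
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")


class MatchResult(NamedTuple):
    """Outcome of matching one sequence against a reference list."""

    status: str  # "unique" | "none" | "ambiguous"
    ref_index: int | None
    n_hits: int


_NONE = MatchResult("none", None, 0)


def _result(n_hits: int, ref_index: int) -> MatchResult:
    if n_hits == 0:
        return _NONE
    if n_hits == 1:
        return MatchResult("unique", ref_index, 1)
    return MatchResult("ambiguous", None, n_hits)


def hamming_distance(a: str, b: str) -> int:
    """Positionwise mismatch count; ``N`` differs from everything, itself included."""
    if len(a) != len(b):
        raise ValueError(f"hamming_distance requires equal lengths ({len(a)} vs {len(b)})")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def _mask_n(query: str) -> str:
    # lowercase n never equals A/C/G/T or an uppercase reference N, so an
    # ambiguous base in the read can match nothing
    return query.replace("N", "n")


def normalized_similarity(query: str, ref: str) -> float:
    """``1 - levenshtein(query, ref) / len(ref)``, clipped below at 0."""
    if not ref:
        raise ValueError("normalized_similarity: empty reference")
    if not query:
        raise ValueError("normalized_similarity: empty query")
    d = edlib.align(_mask_n(query), ref, task="distance")["editDistance"]
    return max(0.0, 1.0 - d / len(ref))


def _ref_seqs(refs: OligoReference | CellWhitelist | Sequence[str]) -> list[str]:
    if isinstance(refs, OligoReference):
        return list(refs.sequences)
    if isinstance(refs, CellWhitelist):
        return list(refs.barcodes)
    return list(refs)


def match_one(
    seq: str,
    refs: OligoReference | CellWhitelist | Sequence[str],
    metric: Metric,
    params: MatchParams | None = None,
) -> MatchResult:
    """Match a single sequence against every reference entry.

    Hamming mode with a sequence length different from the reference
    width tallies the read as ``none`` rather than raising: the I/O
    layer already rejected reads too short for the extraction windows,
    so a width clash can only mean the whitelist disagrees with the
    layout for this read.
    """
    params = params or MatchParams()
    seqs = _ref_seqs(refs)
    if not seqs:
        raise ValueError("empty reference list")
    n_hits = 0
    hit_index = -1
    if metric == "hamming":
        if len(seq) != len(seqs[0]):
            return _NONE
        for i, r in enumerate(seqs):
            if hamming_distance(seq, r) <= params.cell_max_mismatch:
                n_hits += 1
                hit_index = i
    elif metric == "ratio":
        for i, r in enumerate(seqs):
            if normalized_similarity(seq, r) >= params.oligo_min_ratio:
                n_hits += 1
                hit_index = i
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return _result(n_hits, hit_index)


# ---------------------------------------------------------------------------
# batched matching
# ---------------------------------------------------------------------------

def _encode(seqs: Sequence[str], mask_query_n: bool) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), -1
    )
    if mask_query_n:
        arr = arr.copy()
        arr[arr == ord("N")] = ord("n")
    return arr


def _match_chunk_hamming(
    seqs: Sequence[str], ref_arr: np.ndarray, max_mm: int
) -> list[MatchResult]:
    width = ref_arr.shape[1]
    out: list[MatchResult] = [_NONE] * len(seqs)
    ok_idx = [i for i, s in enumerate(seqs) if len(s) == width]
    if not ok_idx:
        return out
    q_arr = _encode([seqs[i] for i in ok_idx], mask_query_n=True)
    # block the query axis so the Q x R x L boolean tensor stays small
    block = max(1, 32_000_000 // (ref_arr.shape[0] * width))
    for start in range(0, len(ok_idx), block):
        qb = q_arr[start : start + block]
        dist = (qb[:, None, :] != ref_arr[None, :, :]).sum(axis=2)
        hits = dist <= max_mm
        n_hits = hits.sum(axis=1)
        first = hits.argmax(axis=1)
        for j in range(qb.shape[0]):
            out[ok_idx[start + j]] = _result(int(n_hits[j]), int(first[j]))
    return out


def _match_chunk_ratio(
    seqs: Sequence[str],
    refs: Sequence[str],
    min_ratio: float,
    cache: dict[str, MatchResult],
) -> list[MatchResult]:
    out: list[MatchResult] = []
    for s in seqs:
        res = cache.get(s)
        if res is None:
            n_hits = 0
            hit_index = -1
            q = _mask_n(s)
            for i, r in enumerate(refs):
                d = edlib.align(q, r, task="distance")["editDistance"]
                if max(0.0, 1.0 - d / len(r)) >= min_ratio:
                    n_hits += 1
                    hit_index = i
            res = _result(n_hits, hit_index)
            cache[s] = res
        out.append(res)
    return out


def match_batch(
    seqs: Sequence[str],
    refs: OligoReference | CellWhitelist | Sequence[str],
    metric: Metric,
    params: MatchParams | None = None,
) -> list[MatchResult]:
    """Elementwise :func:`match_one` over a batch, chunked and threaded.

    The result is independent of ``chunk_size`` and ``threads``.
    """
    params = params or MatchParams()
    ref_list = _ref_seqs(refs)
    if not ref_list:
        raise ValueError("empty reference list")
    if metric not in ("hamming", "ratio"):
        raise ValueError(f"unknown metric {metric!r}")
    seqs = list(seqs)
    if not seqs:
        return []

    chunks = [
        seqs[i : i + params.chunk_size] for i in range(0, len(seqs), params.chunk_size)
    ]
    if metric == "hamming":
        ref_arr = _encode(ref_list, mask_query_n=False)

        def work(chunk: list[str]) -> list[MatchResult]:
            return _match_chunk_hamming(chunk, ref_arr, params.cell_max_mismatch)

    else:
        cache: dict[str, MatchResult] = {}

        def work(chunk: list[str]) -> list[MatchResult]:
            return _match_chunk_ratio(chunk, ref_list, params.oligo_min_ratio, cache)

    if params.threads > 1 and len(chunks) > 1:
        with ThreadPoolExecutor(max_workers=params.threads) as pool:
            results = list(pool.map(work, chunks))
    else:
        results = [work(c) for c in chunks]
    out: list[MatchResult] = []
    for r in results:
        out.extend(r)
    return out
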