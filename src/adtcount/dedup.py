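"""UMI deduplication for assigned reads.

After a read pair has been uniquely assigned to a cell and an oligo, PCR
copies of the same original molecule must be collapsed.  Two modes:

``exact``
    The default.  Within each deduplication key (cell + UMI, or
    cell + oligo + UMI) the first occurrence in input order survives and
    every later occurrence is removed.

``fuzzy``
    Within each cell (and oligo, if included in the key scope) build a
    graph on the distinct UMIs with an edge wherever the Hamming
    distance is at most ``umi_max_mismatch``; each connected component
    keeps exactly one representative — its most frequent UMI, ties
    broken lexicographically — and only the first input occurrence of
    that UMI survives.  This collapses PCR copies that picked up a
    sequencing error in the UMI itself.

Both modes preserve input order among survivors, are idempotent, and
satisfy ``n_input == n_survivors + n_removed``.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .matching import hamming_distance

__all__ = [
    "AssignedRead",
    "DedupParams",
    "DedupReport",
    "dedup_exact",
    "dedup_fuzzy",
    "dedup_reads",
    "compare_dedup_modes",
]


class AssignedRead(NamedTuple):
    """A read resolved to (cell, oligo, UMI), before deduplication."""

    cell_index: int
    oligo_index: int
    umi_seq: str


@dataclass(frozen=True)
class DedupParams:
    """Mode and key scope for UMI collapsing.

    ``key_scope`` defaults to ``cell_umi`` (duplicates are copies of the
    same cell-barcode + UMI combination regardless of tag); the
    ``cell_oligo_umi`` scope, the convention most tag-counting tools
    use, additionally requires the oligo to agree.
    """

    mode: str = "exact"  # "exact" | "fuzzy"
    umi_max_mismatch: int = 1
    key_scope: str = "cell_umi"  # "cell_umi" | "cell_oligo_umi"

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "fuzzy"):
            raise ValueError(f"unknown dedup mode {self.mode!r}")
        if self.key_scope not in ("cell_umi", "cell_oligo_umi"):
            raise ValueError(f"unknown key scope {self.key_scope!r}")
        if self.mode == "fuzzy" and self.umi_max_mismatch < 1:
            raise ValueError("umi_max_mismatch must be >= 1 in fuzzy mode")


@dataclass
class DedupReport:
    """Duplication statistics for one dedup run (or a mode comparison).

    ``per_key`` has one row per surviving key (exact mode: distinct
    dedup key; fuzzy mode: UMI component) with its total read count,
    reads removed and duplicate fraction ``removed / total``.  For
    :func:`compare_dedup_modes` the comparison columns give, per UMI
    component, duplicates identified by each mode and the normalized
    difference (the extra duplicates fuzzy finds, weighted by the
    component's total count).
    """

    n_input: int
    n_survivors: int
    n_removed: int
    per_key: pd.DataFrame
    zero_change_fraction: float | None = None

    @property
    def duplicate_fractions(self) -> np.ndarray:
        return self.per_key["duplicate_fraction"].to_numpy()


def _key(read: AssignedRead, scope: str) -> tuple:
    if scope == "cell_umi":
        return (read.cell_index, read.umi_seq)
    return (read.cell_index, read.oligo_index, read.umi_seq)


def _group_key(read: AssignedRead, scope: str) -> tuple:
    if scope == "cell_umi":
        return (read.cell_index,)
    return (read.cell_index, read.oligo_index)


def dedup_exact(
    reads: Sequence[AssignedRead], params: DedupParams | None = None
) -> tuple[list[AssignedRead], DedupReport]:
    """Keep the first occurrence of each dedup key, in input order."""
    params = params or DedupParams()
    seen: set[tuple] = set()
    survivors: list[AssignedRead] = []
    counts: Counter[tuple] = Counter()
    first_read: dict[tuple, AssignedRead] = {}
    for r in reads:
        k = _key(r, params.key_scope)
        counts[k] += 1
        if k not in seen:
            seen.add(k)
            first_read[k] = r
            survivors.append(r)
    rows = [
        {
            "cell_index": first_read[k].cell_index,
            "oligo_index": first_read[k].oligo_index,
            "umi": k[-1],
            "total": c,
            "removed": c - 1,
            "duplicate_fraction": (c - 1) / c,
        }
        for k, c in counts.items()
    ]
    report = DedupReport(
        n_input=len(reads),
        n_survivors=len(survivors),
        n_removed=len(reads) - len(survivors),
        per_key=_per_key_frame(rows),
    )
    return survivors, report


def _per_key_frame(rows: list[dict]) -> pd.DataFrame:
    cols = ["cell_index", "oligo_index", "umi", "total", "removed", "duplicate_fraction"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _umi_components(
    umis: list[str], max_mismatch: int
) -> list[list[int]]:
    """Connected components over distinct UMIs under a Hamming threshold."""
    uf = _UnionFind(len(umis))
    for i in range(len(umis)):
        for j in range(i + 1, len(umis)):
            if hamming_distance(umis[i], umis[j]) <= max_mismatch:
                uf.union(i, j)
    comps: dict[int, list[int]] = defaultdict(list)
    for i in range(len(umis)):
        comps[uf.find(i)].append(i)
    return list(comps.values())


def dedup_fuzzy(
    reads: Sequence[AssignedRead], params: DedupParams | None = None
) -> tuple[list[AssignedRead], DedupReport]:
    """Collapse UMI components; one survivor per component.

    The representative is the component's most frequent UMI (ties broken
    lexicographically) and the survivor is that UMI's first occurrence in
    input order — deterministic and independent of read order up to which
    duplicate copy survives.
    """
    params = params or DedupParams(mode="fuzzy")
    groups: dict[tuple, list[int]] = defaultdict(list)
    for i, r in enumerate(reads):
        groups[_group_key(r, params.key_scope)].append(i)

    survivor_idx: list[int] = []
    rows: list[dict] = []
    for g_indices in groups.values():
        umi_counts: Counter[str] = Counter(reads[i].umi_seq for i in g_indices)
        distinct = sorted(umi_counts)  # deterministic component ordering
        comp_sets = _umi_components(distinct, params.umi_max_mismatch)
        first_occurrence: dict[str, int] = {}
        for i in g_indices:
            first_occurrence.setdefault(reads[i].umi_seq, i)
        for comp in comp_sets:
            members = [distinct[c] for c in comp]
            rep = min(members, key=lambda u: (-umi_counts[u], u))
            keep = first_occurrence[rep]
            survivor_idx.append(keep)
            total = sum(umi_counts[u] for u in members)
            rows.append(
                {
                    "cell_index": reads[keep].cell_index,
                    "oligo_index": reads[keep].oligo_index,
                    "umi": rep,
                    "total": total,
                    "removed": total - 1,
                    "duplicate_fraction": (total - 1) / total,
                    "n_distinct_umis": len(members),
                }
            )
    survivor_idx.sort()
    survivors = [reads[i] for i in survivor_idx]
    per_key = pd.DataFrame(
        rows,
        columns=[
            "cell_index",
            "oligo_index",
            "umi",
            "total",
            "removed",
            "duplicate_fraction",
            "n_distinct_umis",
        ],
    )
    report = DedupReport(
        n_input=len(reads),
        n_survivors=len(survivors),
        n_removed=len(reads) - len(survivors),
        per_key=per_key,
    )
    return survivors, report


def dedup_reads(
    reads: Sequence[AssignedRead], params: DedupParams | None = None
) -> tuple[list[AssignedRead], DedupReport]:
    """Dispatch on ``params.mode``."""
    params = params or DedupParams()
    if params.mode == "fuzzy":
        return dedup_fuzzy(reads, params)
    return dedup_exact(reads, params)


def compare_dedup_modes(
    reads: Sequence[AssignedRead], params: DedupParams | None = None
) -> DedupReport:
    """Run exact and fuzzy dedup and report their per-UMI disagreement.

    For each fuzzy UMI component: exact removes ``total - n_distinct``
    reads, fuzzy removes ``total - 1``; the normalized difference is the
    extra duplicates fuzzy identifies divided by the component's total
    count.  ``zero_change_fraction`` is the fraction of components where
    both modes agree (single-UMI components).
    """
    params = params or DedupParams()
    fuzzy_params = DedupParams(
        mode="fuzzy", umi_max_mismatch=params.umi_max_mismatch, key_scope=params.key_scope
    )
    _, fuzzy_report = dedup_fuzzy(reads, fuzzy_params)
    per = fuzzy_report.per_key.copy()
    if per.empty:
        per = per.assign(exact_removed=[], fuzzy_removed=[], normalized_difference=[])
        return DedupReport(
            n_input=len(reads),
            n_survivors=0,
            n_removed=0,
            per_key=per,
            zero_change_fraction=None,
        )
    per["exact_removed"] = per["total"] - per["n_distinct_umis"]
    per["fuzzy_removed"] = per["total"] - 1
    per["normalized_difference"] = (per["fuzzy_removed"] - per["exact_removed"]) / per[
        "total"
    ]
    zero_change = float((per["normalized_difference"] == 0).mean())
    return DedupReport(
        n_input=fuzzy_report.n_input,
        n_survivors=fuzzy_report.n_survivors,
        n_removed=fuzzy_report.n_removed,
        per_key=per,
        zero_change_fraction=zero_change,
    )
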