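"""Exact (0-mismatch) assignment of reads to the miRNA reference.

A read counts toward a mature miRNA iff it is an exact contiguous
substring of the mature sequence — no mismatches, no indels, no
soft-clipping.  Reads matching k matures are split fractionally (1/k
each) by default so total counts are conserved; a deterministic
"first" policy (lexicographically smallest id) is available instead.
Reads containing N can never match: N is not a reference base.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .mirref import HairpinRecord, MatureRecord
from .readprep import Read

log = logging.getLogger(__name__)

MULTIMAP_POLICIES = ("fractional", "first")


@dataclass
class MatureHit:
    read_id: str
    mirna_id: str
    offset: int  # 0-based start of the read within the mature sequence
    weight: float  # fractional count in (0, 1]


@dataclass
class PoolCounts:
    """Per-miRNA read counts for one library."""

    pool: str
    counts: dict[str, float] = field(default_factory=dict)
    total_aligned: float = 0.0
    unaligned: float = 0.0


def _matching_ids(seq: str, matures: Sequence[MatureRecord]) -> list[tuple[str, int]]:
    hits = []
    for m in matures:
        off = m.seq.find(seq)
        if off != -1:
            hits.append((m.id, off))
    return hits


def match_mature(
    read: Union[Read, str],
    matures: Sequence[MatureRecord],
    policy: str = "fractional",
) -> list[MatureHit]:
    """All matures containing the read as an exact substring.

    Returns one hit per matching mature at its left-most offset, weighted
    1/k for k matches (``policy="fractional"``) or a single hit to the
    lexicographically first id (``policy="first"``).
    """
    if policy not in MULTIMAP_POLICIES:
        raise ValueError(f"unknown multi-mapping policy {policy!r}")
    seq = read.seq if isinstance(read, Read) else read
    read_id = read.id if isinstance(read, Read) else ""
    hits = _matching_ids(seq, matures)
    if not hits:
        return []
    if policy == "first":
        hits = [min(hits)]
    w = 1.0 / len(hits)
    return [MatureHit(read_id, mid, off, w) for mid, off in sorted(hits)]


def match_hairpin(read: Union[Read, str], hairpins: Sequence[HairpinRecord]) -> bool:
    """True iff the read is an exact substring of at least one hairpin."""
    seq = read.seq if isinstance(read, Read) else read
    return any(seq in h.seq for h in hairpins)


def count_pool(
    reads: Iterable[Read],
    matures: Sequence[MatureRecord],
    pool: str,
    policy: str = "fractional",
) -> PoolCounts:
    """Count reads against the mature library for one pool.

    Identical sequences are matched once and weighted by multiplicity.
    Unmatched reads are excluded from ``total_aligned`` but tallied in
    ``unaligned``, so aligned + unaligned equals the input read count.
    """
    if policy not in MULTIMAP_POLICIES:
        raise ValueError(f"unknown multi-mapping policy {policy!r}")
    by_seq = Counter(r.seq for r in reads)
    pc = PoolCounts(pool=pool)
    for seq, n in by_seq.items():
        hits = _matching_ids(seq, matures)
        if not hits:
            pc.unaligned += n
            continue
        if policy == "first":
            hits = [min(hits)]
        w = n / len(hits)
        for mid, _off in hits:
            pc.counts[mid] = pc.counts.get(mid, 0.0) + w
    pc.total_aligned = sum(pc.counts.values())
    if pc.unaligned:
        log.info("count_pool(%s): %.0f reads unaligned to the mature library",
                 pool, pc.unaligned)
    return pc


def counts_to_frame(pc: PoolCounts) -> pd.DataFrame:
    """Count table with per-miRNA percent shares of aligned reads."""
    rows = sorted(pc.counts.items())
    df = pd.DataFrame(rows, columns=["mirna_id", "count"])
    df.insert(1, "pool", pc.pool)
    df["share_percent"] = 100.0 * df["count"] / pc.total_aligned if len(df) else []
    return df


def write_counts_tsv(pc: PoolCounts, path: str | Path) -> None:
    counts_to_frame(pc).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> PoolCounts:
    df = pd.read_csv(path, sep="\t")
    pools = df["pool"].unique()
    if len(pools) != 1:
        raise ValueError(f"{path}: expected one pool per counts file, got {list(pools)}")
    counts = dict(zip(df["mirna_id"], df["count"].astype(float)))
    return PoolCounts(pool=str(pools[0]), counts=counts,
                      total_aligned=float(sum(counts.values())))
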