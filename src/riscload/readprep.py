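"""FASTQ input, 3' adapter trimming and the minimum-length filter.

Small-RNA library reads run through the insert into the 3' sequencing
adapter, so the insert is whatever lies 5' of the adapter.  Trimming
looks for the left-most full occurrence of the adapter; failing that, a
read suffix equal to an adapter prefix of at least ``min_overlap`` nt is
removed (the adapter ran off the end of the read).  The rule is applied
to a fixpoint so trimming is idempotent.  Reads shorter than 15 nt after
trimming are discarded, the conventional floor for a mature miRNA.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .mirref import canonicalize

log = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 15
DEFAULT_MIN_OVERLAP = 5


@dataclass
class Read:
    id: str
    seq: str
    pool: str  # "total" or "IP"


@dataclass
class TrimStats:
    n_input: int = 0
    n_trimmed: int = 0
    n_no_adapter: int = 0
    n_short: int = 0

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_no_adapter - self.n_short


def read_fastq(path: str | Path, pool: str) -> Iterator[Read]:
    """Stream reads from a (possibly gzipped) 4-line FASTQ file.

    Qualities are checked for length but ignored thereafter — the
    downstream pipeline is exact-match only.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "rt") as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"{path}: malformed FASTQ record {n + 1}: {exc}") from exc
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}: FASTQ record {n + 1}: sequence and quality lengths differ"
                )
            n += 1
            yield Read(id=title.split()[0], seq=canonicalize(seq), pool=pool)
    if n == 0:
        log.warning("%s: empty FASTQ file", path)


def _trim_once(seq: str, adapter: str, min_overlap: int) -> tuple[str, bool]:
    i = seq.find(adapter)
    if i != -1:
        return seq[:i], True
    # partial adapter at the 3' end: longest read suffix == adapter prefix
    for k in range(min(len(seq), len(adapter) - 1), min_overlap - 1, -1):
        if seq.endswith(adapter[:k]):
            return seq[: len(seq) - k], True
    return seq, False


def trim_adapter(
    read: Read,
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    keep_untrimmed: bool = False,
) -> Optional[Read]:
    """Remove the 3' adapter from a read.

    Returns the trimmed read, or ``None`` when no adapter evidence is
    found and ``keep_untrimmed`` is false (the default: a genuine short
    insert must exhibit the adapter).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    seq = read.seq
    any_trim = False
    while True:
        seq, trimmed = _trim_once(seq, adapter, min_overlap)
        any_trim |= trimmed
        if not trimmed or not seq:
            break
    if not any_trim:
        return read if keep_untrimmed else None
    return Read(id=read.id, seq=seq, pool=read.pool)


def length_filter(reads: Iterable[Read], min_len: int = DEFAULT_MIN_LEN) -> list[Read]:
    """Keep reads of at least ``min_len`` nt; log how many were dropped."""
    kept, dropped = [], 0
    for r in reads:
        if len(r.seq) >= min_len:
            kept.append(r)
        else:
            dropped += 1
    if dropped:
        log.info("length_filter: dropped %d reads shorter than %d nt", dropped, min_len)
    return kept


def prepare_reads(
    reads: Iterable[Read],
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_len: int = DEFAULT_MIN_LEN,
    keep_untrimmed: bool = False,
) -> tuple[list[Read], TrimStats]:
    """Trim and length-filter a read stream; the usual entry point."""
    stats = TrimStats()
    out: list[Read] = []
    for r in reads:
        stats.n_input += 1
        t = trim_adapter(r, adapter, min_overlap, keep_untrimmed)
        if t is None:
            stats.n_no_adapter += 1
            continue
        if t.seq != r.seq:
            stats.n_trimmed += 1
        if len(t.seq) < min_len:
            stats.n_short += 1
            continue
        out.append(t)
    return out, stats
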