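"""Non-templated 3' tail classification and tailing summaries.

A read carries a *non-templated tail* when it extends 3' past a mature
miRNA with sequence that no generating hairpin encodes.  Classification
mirrors exact-match pipeline logic:

1. Reads that align (exactly, 0 mismatch) anywhere within a hairpin are
   templated by definition — at most they are templated-extension
   isomiRs, never tails.
2. A hairpin-unaligned read is assigned to a mature miRNA only when the
   full mature sequence is an exact prefix of the read (a discrete,
   shared 5' start site), choosing the mature of length closest to the
   read length (minimal extension; ties broken by lexicographic id).
3. The 3' extension beyond the mature is compared against the sequence
   immediately downstream of the mature in every hairpin able to
   generate it; if any hairpin continues with the extension the read is
   a templated isomiR, otherwise it is tailed.

Matures with no generating hairpin carry no templated context and are
excluded from calling.  Extensions containing N cannot be adjudicated by
exact matching and are reported undetermined, outside the percent-tailed
denominators.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .mirref import HairpinRecord, MatureRecord
from .readprep import Read

log = logging.getLogger(__name__)

EXTENSION_CHECKS = ("positional", "anywhere_in_hairpin")

#: reporting bins for tail length
TAIL_LENGTH_BINS = ("1", "2", "3", "4+")


@dataclass
class TailCall:
    read_id: str
    pool: str
    mirna_id: str
    tail_seq: str  # the 3' extension (empty for exact mature reads)
    tailed: bool
    templated: bool  # extension explained by >= 1 generating hairpin
    undetermined: bool = False  # N in the extension; outside denominators


@dataclass
class TailSummary:
    mirna_id: str
    pool: str
    n_reads: int
    n_tailed: int
    pct_tailed: float
    tail_composition: dict[str, int] = field(default_factory=dict)


class TailClassifier:
    """Classify reads for non-templated 3' tails against a linked reference."""

    def __init__(
        self,
        matures: Sequence[MatureRecord],
        hairpins: Sequence[HairpinRecord],
        extension_check: str = "positional",
    ) -> None:
        if extension_check not in EXTENSION_CHECKS:
            raise ValueError(f"unknown extension_check {extension_check!r}")
        self.extension_check = extension_check
        unlinked = [m.id for m in matures if not m.hairpin_ids]
        if unlinked:
            log.info(
                "tail calling excludes %d matures with no generating hairpin: %s",
                len(unlinked), ", ".join(sorted(unlinked)),
            )
        self.matures = sorted((m for m in matures if m.hairpin_ids), key=lambda m: m.id)
        self.hairpin_by_id = {h.id: h for h in hairpins}
        self._hairpin_seqs = [h.seq for h in hairpins]

    def _assign(self, seq: str) -> Optional[MatureRecord]:
        # discrete 5' start: the full mature must be a prefix of the read
        candidates = [m for m in self.matures if seq.startswith(m.seq)]
        if not candidates:
            return None
        return min(candidates, key=lambda m: (len(seq) - len(m.seq), m.id))

    def _extension_is_templated(self, m: MatureRecord, ext: str) -> bool:
        for hid in sorted(m.hairpin_ids):
            h = self.hairpin_by_id.get(hid)
            if h is None:
                continue
            if self.extension_check == "anywhere_in_hairpin":
                if ext in h.seq:
                    return True
                continue
            start = h.seq.find(m.seq)
            while start != -1:
                end = start + len(m.seq)
                if h.seq[end : end + len(ext)] == ext:
                    return True
                start = h.seq.find(m.seq, start + 1)
        return False

    def classify(self, read: Read) -> Optional[TailCall]:
        seq = read.seq
        if any(seq in h for h in self._hairpin_seqs):
            # whole read is hairpin-templated; never a tail
            m = self._assign(seq)
            if m is None:
                return None
            ext = seq[len(m.seq):]
            return TailCall(read.id, read.pool, m.id, ext,
                            tailed=False, templated=bool(ext))
        m = self._assign(seq)
        if m is None:
            return None
        ext = seq[len(m.seq):]
        if not ext:
            return TailCall(read.id, read.pool, m.id, "", tailed=False, templated=False)
        if "N" in ext:
            return TailCall(read.id, read.pool, m.id, ext,
                            tailed=False, templated=False, undetermined=True)
        templated = self._extension_is_templated(m, ext)
        return TailCall(read.id, read.pool, m.id, ext,
                        tailed=not templated, templated=templated)

    def classify_all(self, reads: Iterable[Read]) -> list[TailCall]:
        calls = []
        for r in reads:
            c = self.classify(r)
            if c is not None:
                calls.append(c)
        return calls


def classify_read(
    read: Read,
    matures: Sequence[MatureRecord],
    hairpins: Sequence[HairpinRecord],
    extension_check: str = "positional",
) -> Optional[TailCall]:
    """One-shot form of :meth:`TailClassifier.classify`."""
    return TailClassifier(matures, hairpins, extension_check).classify(read)


def summarize_tails(calls: Iterable[TailCall]) -> list[TailSummary]:
    """Per-(miRNA, pool) tailing summary.

    ``pct_tailed`` is tailed reads over all determined reads assigned to
    the miRNA (tailed + untailed); undetermined calls are excluded from
    the denominator.
    """
    groups: dict[tuple[str, str], list[TailCall]] = {}
    for c in calls:
        if c.undetermined:
            continue
        groups.setdefault((c.mirna_id, c.pool), []).append(c)
    out = []
    for (mid, pool), cs in sorted(groups.items()):
        n_tailed = sum(1 for c in cs if c.tailed)
        comp = Counter(c.tail_seq for c in cs if c.tailed)
        out.append(TailSummary(
            mirna_id=mid, pool=pool, n_reads=len(cs), n_tailed=n_tailed,
            pct_tailed=100.0 * n_tailed / len(cs),
            tail_composition=dict(comp),
        ))
    return out


def summaries_to_frames(
    summaries: Iterable[TailSummary],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-miRNA tailing table, tail-composition table) as DataFrames."""
    summaries = list(summaries)
    s3 = pd.DataFrame(
        [(s.mirna_id, s.pool, s.n_reads, s.n_tailed, s.pct_tailed) for s in summaries],
        columns=["mirna_id", "pool", "n_reads", "n_tailed", "pct_tailed"],
    )
    rows = []
    for s in summaries:
        for tail, n in sorted(s.tail_composition.items()):
            rows.append((s.mirna_id, s.pool, tail, n))
    s4 = pd.DataFrame(rows, columns=["mirna_id", "pool", "tail_seq", "count"])
    return s3, s4


def tail_ratio(pct_total: float, pct_ip: float) -> Optional[float]:
    """Percent tailed in the total pool over percent tailed in the IP pool.

    Values > 1 mean tailing is enriched in the total (free) pool.  When
    the IP percentage is 0 the ratio is undefined and ``None`` is
    returned (excluded from summaries), except the 0/0-free case (0, x)
    which is a genuine 0.
    """
    if pct_ip == 0:
        return None
    return pct_total / pct_ip


def tail_length_distribution(calls: Iterable[TailCall]) -> dict[str, int]:
    """Tailed-read counts binned by tail length: 1, 2, 3, >= 4 nt."""
    dist = {b: 0 for b in TAIL_LENGTH_BINS}
    for c in calls:
        if not c.tailed:
            continue
        n = len(c.tail_seq)
        dist["4+" if n >= 4 else str(n)] += 1
    return dist


def tail_enrichment_by_sequence(
    calls_total: Iterable[TailCall], calls_ip: Iterable[TailCall]
) -> dict[str, float]:
    """Fold prevalence of each tail sequence, total pool versus IP pool.

    Prevalence is the fraction of *tailed* reads in a pool carrying that
    exact tail; the fold is total over IP.  Tails absent from the IP
    pool map to ``inf``.
    """
    ct = Counter(c.tail_seq for c in calls_total if c.tailed)
    ci = Counter(c.tail_seq for c in calls_ip if c.tailed)
    nt, ni = sum(ct.values()), sum(ci.values())
    if nt == 0 or ni == 0:
        raise ValueError("both pools need at least one tailed read")
    out = {}
    for tail in sorted(set(ct) | set(ci)):
        ft = ct.get(tail, 0) / nt
        fi = ci.get(tail, 0) / ni
        out[tail] = ft / fi if fi > 0 else float("inf")
    return out
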