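"""miRNA reference handling: mature and hairpin sequence catalogues.

Mature miRNAs and the pre-miRNA hairpins that can generate them are read
from miRBase-style FASTA (RNA alphabet, free-text description after the
identifier).  Everything is stored in a single uppercase DNA alphabet
(U -> T) so that sequencing reads and reference sequences live in one
comparison domain.

A mature miRNA is *generated by* a hairpin when its sequence occurs as a
contiguous substring of the hairpin sequence; :func:`link_matures` fills
those links, which the tail classifier later uses as the templated 3'
context.  The seed — the main determinant of target recognition — is the
7-nt window at positions 2–8 (1-based) of the mature sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: shortest mature miRNA accepted; also the read-length cutoff downstream
MIN_MATURE_LEN = 15

#: 1-based inclusive seed window on the mature sequence
SEED_START, SEED_END = 2, 8


def canonicalize(seq: str) -> str:
    """Uppercase a sequence and map the RNA alphabet onto DNA (U -> T)."""
    return seq.upper().replace("U", "T")


@dataclass
class MatureRecord:
    """A mature miRNA (or passenger strand) from the reference catalogue."""

    id: str
    seq: str
    hairpin_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"mature record {self.id!r}: invalid characters {sorted(bad)}"
            )
        if len(self.seq) < MIN_MATURE_LEN:
            raise ValueError(
                f"mature record {self.id!r}: length {len(self.seq)} < {MIN_MATURE_LEN}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def seed(self) -> str:
        """Positions 2–8 (1-based, inclusive) of the mature sequence."""
        return self.seq[SEED_START - 1 : SEED_END]


@dataclass
class HairpinRecord:
    """A pre-miRNA hairpin sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"hairpin record {self.id!r}: invalid characters {sorted(bad)}"
            )


def load_fasta(path: str | Path, kind: str) -> list[MatureRecord] | list[HairpinRecord]:
    """Load a mature or hairpin FASTA file.

    Sequences are canonicalized (uppercase DNA); the record id is the
    header token before the first whitespace.  Duplicate ids, non-ACGTU
    characters and empty files are rejected.
    """
    if kind not in ("mature", "hairpin"):
        raise ValueError(f"kind must be 'mature' or 'hairpin', got {kind!r}")
    path = Path(path)

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: not FASTA — first non-blank line {lineno} "
                        f"does not start with '>'"
                    )
                break

    cls = MatureRecord if kind == "mature" else HairpinRecord
    records: list = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(cls(id=rec.id, seq=canonicalize(str(rec.seq))))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def link_matures(
    matures: Iterable[MatureRecord], hairpins: Iterable[HairpinRecord]
) -> list[MatureRecord]:
    """Attach to each mature the set of hairpins able to generate it.

    A hairpin generates a mature iff the mature sequence is a contiguous
    substring of the hairpin sequence.  Matures with no generating hairpin
    are retained (they can still be quantified) but a warning is logged,
    as they carry no templated context for tail calling.
    """
    hairpins = list(hairpins)
    out: list[MatureRecord] = []
    for m in matures:
        ids = {h.id for h in hairpins if m.seq in h.seq}
        if not ids:
            log.warning("mature %s has no generating hairpin in the reference", m.id)
        out.append(MatureRecord(id=m.id, seq=m.seq, hairpin_ids=ids))
    return out


def gc_content(seq: str) -> float:
    """Fraction of G+C bases in ``seq`` (in [0, 1])."""
    if not seq:
        raise ValueError("gc_content of empty sequence is undefined")
    return (seq.count("G") + seq.count("C")) / len(seq)


def at_content(seq: str) -> float:
    """Fraction of A+T bases in ``seq``; complements :func:`gc_content`."""
    if not seq:
        raise ValueError("at_content of empty sequence is undefined")
    return (seq.count("A") + seq.count("T")) / len(seq)
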