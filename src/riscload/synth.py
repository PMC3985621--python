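"""Synthetic references and paired small-RNA libraries with ground truth.

The generator emulates the design of a paired total / Ago-IP small-RNA
sequencing experiment.  Both libraries draw from one per-miRNA abundance
vector a_i; the IP library reweights each miRNA by its RISC-loading
fraction L_i, so under the model the expected association ratio is

    R_i = L_i * sum_j(a_j) / sum_j(a_j * L_j),

i.e. the share ratio estimates L_i up to one global constant.  Reads are
the mature sequence, optionally carrying a templated 3' extension (drawn
from the hairpin downstream context), a short non-templated tail (1–3
nt, A/T-rich by default), or a 5'-end shift of one nt, followed by the
3' sequencing adapter.  A non-templated tail is never allowed to equal
the hairpin's templated continuation, so truth labels are unambiguous by
construction.  Every read's origin is recorded in a truth table.

All randomness flows from one integer seed; the same seed yields
byte-identical FASTA/FASTQ output.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .mirref import HairpinRecord, MatureRecord, link_matures
from .readprep import Read

#: Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: tail base composition: short A/T-rich tails with occasional C, rare G
DEFAULT_TAIL_WEIGHTS = {"A": 0.4, "T": 0.4, "C": 0.15, "G": 0.05}

BASES = "ACGT"


@dataclass
class TruthManifest:
    """Ground-truth generative parameters for one simulated experiment."""

    abundance: dict[str, float]
    loading_fraction: dict[str, float]  # L_i in (0, 1]
    tail_rate: dict[str, float]  # per-miRNA non-templated tailing probability
    tail_alphabet_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TAIL_WEIGHTS)
    )
    templated_ext_rate: float = 0.05
    fiveprime_jitter_rate: float = 0.02
    depth: int = 100_000  # reads per pool
    adapter: str = DEFAULT_ADAPTER
    seed: int = 0

    def expected_ratios(self) -> dict[str, float]:
        """Model expectation R_i = L_i * sum(a) / sum(a * L)."""
        ids = sorted(self.abundance)
        a = np.array([self.abundance[m] for m in ids])
        L = np.array([self.loading_fraction[m] for m in ids])
        scale = a.sum() / (a * L).sum()
        return {m: float(l * scale) for m, l in zip(ids, L)}

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "abundance": {k: float(v) for k, v in self.abundance.items()},
                    "loading_fraction": {k: float(v) for k, v in self.loading_fraction.items()},
                    "tail_rate": {k: float(v) for k, v in self.tail_rate.items()},
                    "tail_alphabet_weights": {k: float(v) for k, v in self.tail_alphabet_weights.items()},
                    "templated_ext_rate": float(self.templated_ext_rate),
                    "fiveprime_jitter_rate": float(self.fiveprime_jitter_rate),
                    "depth": int(self.depth),
                    "adapter": self.adapter,
                    "seed": int(self.seed),
                },
                fh,
                sort_keys=True,
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def simulate_reference(
    n_mirnas: int,
    mature_len_range: tuple[int, int] = (19, 23),
    hairpin_len_range: tuple[int, int] = (65, 90),
    shared_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[MatureRecord], list[HairpinRecord]]:
    """Random mature/hairpin reference with controlled embedding.

    Every mature is embedded in >= 1 hairpin with >= 4 nt of templated
    3' context; the first ``round(shared_fraction * n)`` matures get a
    second, independent hairpin (multi-precursor miRNAs).  Rejection
    sampling guarantees no mature occurs in an unrelated hairpin and no
    mature is a substring of another.
    """
    if mature_len_range[0] < 15:
        raise ValueError("mature length must be >= 15")
    if hairpin_len_range[0] < mature_len_range[1] + 10:
        raise ValueError("hairpins must exceed matures by >= 10 nt")
    rng = np.random.default_rng(seed)

    mature_seqs: list[str] = []
    while len(mature_seqs) < n_mirnas:
        mlen = int(rng.integers(mature_len_range[0], mature_len_range[1] + 1))
        s = _random_seq(rng, mlen)
        if any(s in t or t in s for t in mature_seqs):
            continue
        mature_seqs.append(s)

    matures = [
        MatureRecord(id=f"syn-miR-{i + 1:04d}", seq=s)
        for i, s in enumerate(mature_seqs)
    ]

    n_shared = int(round(shared_fraction * n_mirnas))
    hairpins: list[HairpinRecord] = []

    def embed(m: MatureRecord, hid: str) -> HairpinRecord:
        for _ in range(200):
            hlen = int(rng.integers(hairpin_len_range[0], hairpin_len_range[1] + 1))
            # keep >= 4 nt of 3' context downstream of the mature
            offset = int(rng.integers(0, hlen - len(m.seq) - 4 + 1))
            seq = (
                _random_seq(rng, offset)
                + m.seq
                + _random_seq(rng, hlen - offset - len(m.seq))
            )
            if any(o.seq in seq for o in matures if o.id != m.id):
                continue
            return HairpinRecord(id=hid, seq=seq)
        raise RuntimeError(f"could not embed mature {m.id} without collisions")

    for i, m in enumerate(matures):
        hairpins.append(embed(m, f"syn-mir-{i + 1:04d}"))
        if i < n_shared:
            hairpins.append(embed(m, f"syn-mir-{i + 1:04d}-2"))
    return matures, hairpins


def default_manifest(
    matures: Sequence[MatureRecord],
    seed: int = 0,
    depth: int = 100_000,
    abundance_sigma: float = 2.9,
    loading_decades: float = 3.0,
    tail_rate_range: tuple[float, float] = (0.002, 0.2),
    templated_ext_rate: float = 0.05,
    fiveprime_jitter_rate: float = 0.02,
    adapter: str = DEFAULT_ADAPTER,
) -> TruthManifest:
    """Draw per-miRNA truth parameters for a realistic experiment.

    Abundances are lognormal (sigma 2.9, so a handful of miRNAs dominate
    and roughly 7–8% of them clear a 0.1% share gate); loading fractions
    are log-uniform across 3 decades; per-miRNA tail rates are
    log-uniform between 0.2% and 20%.
    """
    rng = np.random.default_rng([seed, 97])
    ids = [m.id for m in matures]
    n = len(ids)
    a = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=n)
    L = 10.0 ** rng.uniform(-loading_decades, 0.0, size=n)
    lo, hi = np.log10(tail_rate_range[0]), np.log10(tail_rate_range[1])
    t = 10.0 ** rng.uniform(lo, hi, size=n)
    return TruthManifest(
        abundance=dict(zip(ids, map(float, a))),
        loading_fraction=dict(zip(ids, map(float, L))),
        tail_rate=dict(zip(ids, map(float, t))),
        templated_ext_rate=templated_ext_rate,
        fiveprime_jitter_rate=fiveprime_jitter_rate,
        depth=depth,
        adapter=adapter,
        seed=seed,
    )


@dataclass
class SimulatedLibraries:
    reads_total: list[Read]  # insert + adapter, as sequenced
    reads_ip: list[Read]
    truth: pd.DataFrame  # read_id, pool, mirna_id, tailed, tail_seq, jitter, templated_ext
    tail_collisions: int  # tails resampled because they matched the hairpin


def _draw_tail(
    rng: np.random.Generator,
    weights: dict[str, float],
    continuations: list[str],
) -> tuple[str, int]:
    bases = sorted(weights)
    p = np.array([weights[b] for b in bases], dtype=float)
    p = p / p.sum()
    collisions = 0
    for _ in range(100):
        n = int(rng.integers(1, 4))  # 1-3 nt
        tail = "".join(rng.choice(bases, size=n, p=p))
        if any(c[: len(tail)] == tail for c in continuations):
            collisions += 1
            continue
        return tail, collisions
    raise RuntimeError("could not draw a collision-free tail")


def simulate_libraries(
    matures: Sequence[MatureRecord],
    hairpins: Sequence[HairpinRecord],
    manifest: TruthManifest,
) -> SimulatedLibraries:
    """Sample the total and IP read pools with per-read ground truth."""
    linked = link_matures(matures, hairpins)
    by_hid = {h.id: h for h in hairpins}
    ids = sorted(manifest.abundance)
    by_mid = {m.id: m for m in linked}
    missing = [m for m in ids if m not in by_mid]
    if missing:
        raise ValueError(f"manifest names unknown miRNAs: {missing}")

    a = np.array([manifest.abundance[m] for m in ids], dtype=float)
    L = np.array([manifest.loading_fraction[m] for m in ids], dtype=float)
    if a.sum() <= 0 or (a * L).sum() <= 0:
        raise ValueError("zero-probability pool")
    p_total = a / a.sum()
    p_ip = (a * L) / (a * L).sum()

    # per-mature hairpin occurrence and 3' continuation context
    context: dict[str, list[tuple[str, str, str]]] = {}  # mid -> [(hid, left, cont)]
    for mid in ids:
        m = by_mid[mid]
        ctx = []
        for hid in sorted(m.hairpin_ids):
            h = by_hid[hid].seq
            start = h.find(m.seq)
            while start != -1:
                left = h[start - 1] if start > 0 else ""
                ctx.append((hid, left, h[start + len(m.seq):]))
                start = h.find(m.seq, start + 1)
        if not ctx:
            raise ValueError(f"mature {mid} has no generating hairpin")
        context[mid] = ctx

    collisions = 0
    rows: list[tuple] = []

    def make_pool(pool: str, probs: np.ndarray, stream: int) -> list[Read]:
        nonlocal collisions
        rng = np.random.default_rng([manifest.seed, stream])
        idx = rng.choice(len(ids), size=manifest.depth, p=probs)
        reads = []
        for k, i in enumerate(idx):
            mid = ids[i]
            m = by_mid[mid]
            ctx = context[mid]
            hid, left, cont = ctx[int(rng.integers(0, len(ctx)))]
            seq = m.seq
            jitter = 0
            if rng.random() < manifest.fiveprime_jitter_rate:
                if rng.random() < 0.5 and left:
                    seq = left + seq  # templated 5' extension
                    jitter = 1
                else:
                    seq = seq[1:]  # 5' truncation
                    jitter = -1
            tail, text = "", ""
            u = rng.random()
            t_i = manifest.tail_rate[mid]
            if u < t_i:
                all_conts = [c for _h, _l, c in ctx]
                tail, ncoll = _draw_tail(rng, manifest.tail_alphabet_weights, all_conts)
                collisions += ncoll
                seq = seq + tail
            elif u < t_i + manifest.templated_ext_rate and cont:
                elen = int(rng.integers(1, min(3, len(cont)) + 1))
                text = cont[:elen]
                seq = seq + text
            rid = f"{pool}-{k:07d}"
            reads.append(Read(id=rid, seq=seq + manifest.adapter, pool=pool))
            rows.append((rid, pool, mid, bool(tail), tail, jitter, text))
        return reads

    reads_total = make_pool("total", p_total, 0)
    reads_ip = make_pool("IP", p_ip, 1)
    truth = pd.DataFrame(
        rows,
        columns=["read_id", "pool", "mirna_id", "tailed", "tail_seq", "jitter",
                 "templated_ext"],
    )
    return SimulatedLibraries(reads_total, reads_ip, truth, collisions)


def write_fasta(records: Sequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.seq}\n")


def write_fastq(reads: Sequence[Read], path: str | Path) -> None:
    """Write FASTQ (gzipped when the name ends in .gz, mtime pinned to 0
    so identical simulations are byte-identical)."""
    path = Path(path)
    if path.suffix == ".gz":
        with open(path, "wb") as raw, gzip.GzipFile(
            filename="", mode="wb", fileobj=raw, mtime=0
        ) as fh:
            for r in reads:
                fh.write(f"@{r.id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n".encode())
    else:
        with open(path, "w") as fh:
            for r in reads:
                fh.write(f"@{r.id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_simulation(
    outdir: str | Path,
    matures: Sequence[MatureRecord],
    hairpins: Sequence[HairpinRecord],
    sim: SimulatedLibraries,
    manifest: TruthManifest,
) -> dict[str, Path]:
    """Emit mature.fa, hairpin.fa, total/ip FASTQ, truth.tsv, manifest.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mature": outdir / "mature.fa",
        "hairpin": outdir / "hairpin.fa",
        "total": outdir / "total.fastq.gz",
        "ip": outdir / "ip.fastq.gz",
        "truth": outdir / "truth.tsv",
        "manifest": outdir / "manifest.yaml",
    }
    write_fasta(matures, paths["mature"])
    write_fasta(hairpins, paths["hairpin"])
    write_fastq(sim.reads_total, paths["total"])
    write_fastq(sim.reads_ip, paths["ip"])
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    manifest.to_yaml(paths["manifest"])
    return paths
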