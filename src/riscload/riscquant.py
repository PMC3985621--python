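"""RISC-association statistics from paired total / IP count tables.

Each miRNA's abundance is expressed as its percent share of the
miRNA-aligned reads in its library, so both pools sum to 100%.  The
RISC-association ratio R = share_IP / share_total then measures loading
relative to the *average* miRNA: because both share vectors are
normalized, R = 1 is the mean line, R > 1 means over-representation in
RISC and R < 1 under-representation.  On top of the per-miRNA table sit
the expression gate (>= 0.1% of either pool by default), the 2-fold
over/under classification, seed-family pooling, the extreme spread
(max/min ratio) and the implied absolute RISC fraction under the
assumption that the most-loaded miRNA is 100% RISC-bound.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .matcher import PoolCounts

DEFAULT_GATE_THRESHOLD = 0.1  # percent of a pool
DEFAULT_FOLD_THRESHOLD = 2.0
DEFAULT_PSEUDOCOUNT = 0.5  # reads added to the empty pool of one-sided miRNAs

GATE_MODES = ("either_pool", "total")

#: seed families pooled for the sensor analyses: miR-92a/92b/25 share a
#: seed; miR-30a-3p/30e-3p and miR-125a-5p/125b-5p are sensed jointly.
DEFAULT_FAMILIES: dict[str, list[str]] = {
    "miR-92-3p": ["hsa-miR-92a-3p", "hsa-miR-92b-3p", "hsa-miR-25-3p"],
    "miR-30-3p": ["hsa-miR-30a-3p", "hsa-miR-30e-3p"],
    "miR-125-5p": ["hsa-miR-125a-5p", "hsa-miR-125b-5p"],
}


def shares(counts: PoolCounts) -> dict[str, float]:
    """Percent share of each miRNA among the pool's aligned reads."""
    if counts.total_aligned <= 0:
        raise ValueError(f"pool {counts.pool!r} has no aligned reads")
    return {m: 100.0 * c / counts.total_aligned for m, c in counts.counts.items()}


def risc_ratio(share_ip: float, share_total: float) -> tuple[float, float]:
    """(ratio, log2 ratio) of IP share over total share.

    One-sided detections return signed-infinite markers; both-zero is
    undefined and raises.
    """
    if share_ip < 0 or share_total < 0:
        raise ValueError("shares must be non-negative")
    if share_ip == 0 and share_total == 0:
        raise ValueError("ratio undefined when both shares are zero")
    if share_total == 0:
        return math.inf, math.inf
    if share_ip == 0:
        return 0.0, -math.inf
    r = share_ip / share_total
    return r, math.log2(r)


def quantify(
    total: PoolCounts,
    ip: PoolCounts,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    gate_threshold: float = DEFAULT_GATE_THRESHOLD,
    gate_mode: str = "either_pool",
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> pd.DataFrame:
    """Build the per-miRNA quantification table from the two count pools.

    miRNAs detected in only one pool receive ``pseudocount`` reads in the
    empty pool before shares are computed (keeping log2 ratios finite)
    and are flagged ``pseudocounted``; they are excluded from the extreme
    spread downstream.  Shares are recomputed after the pseudocounts so
    each column still sums to 100.
    """
    ids = sorted(set(total.counts) | set(ip.counts))
    if not ids:
        raise ValueError("no miRNAs detected in either pool")
    ct = {m: total.counts.get(m, 0.0) for m in ids}
    ci = {m: ip.counts.get(m, 0.0) for m in ids}
    pseudo = {m: (ct[m] == 0.0) != (ci[m] == 0.0) for m in ids}
    for m in ids:
        if pseudo[m]:
            if ct[m] == 0.0:
                ct[m] = pseudocount
            else:
                ci[m] = pseudocount
    tot_sum = sum(ct.values())
    ip_sum = sum(ci.values())
    if tot_sum <= 0 or ip_sum <= 0:
        raise ValueError("a pool has no reads after pseudocounting")
    df = pd.DataFrame({
        "mirna_id": ids,
        "share_total": [100.0 * ct[m] / tot_sum for m in ids],
        "share_ip": [100.0 * ci[m] / ip_sum for m in ids],
        "pseudocounted": [pseudo[m] for m in ids],
    })
    df["ratio"] = df["share_ip"] / df["share_total"]
    df["log2_ratio"] = np.log2(df["ratio"])
    df = expression_gate(df, gate_threshold, gate_mode)
    df = classify(df, fold_threshold)
    return df


def quantify_from_shares(
    share_total: Mapping[str, float],
    share_ip: Mapping[str, float],
    gate_threshold: float = DEFAULT_GATE_THRESHOLD,
    gate_mode: str = "either_pool",
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> pd.DataFrame:
    """Quantification table from precomputed percent shares.

    Entry point for re-deriving gate / classification / discrepancy
    statistics from a published per-miRNA share table instead of raw
    reads.  Shares are taken as given (not renormalized); one-sided
    entries get infinite / zero ratios.
    """
    ids = sorted(set(share_total) | set(share_ip))
    st = np.array([float(share_total.get(m, 0.0)) for m in ids])
    si = np.array([float(share_ip.get(m, 0.0)) for m in ids])
    both_zero = (st == 0) & (si == 0)
    if both_zero.any():
        keep = ~both_zero
        ids = [m for m, k in zip(ids, keep) if k]
        st, si = st[keep], si[keep]
    with np.errstate(divide="ignore"):
        ratio = np.where(st > 0, si / np.where(st > 0, st, 1.0), np.inf)
        log2r = np.log2(ratio, out=np.full_like(ratio, -np.inf), where=ratio > 0)
    df = pd.DataFrame({
        "mirna_id": ids,
        "share_total": st,
        "share_ip": si,
        "pseudocounted": False,
        "ratio": ratio,
        "log2_ratio": log2r,
    })
    df = expression_gate(df, gate_threshold, gate_mode)
    df = classify(df, fold_threshold)
    return df


def load_share_tsv(
    path: str | Path,
    id_col: str = "mirna_id",
    total_col: str = "share_total",
    ip_col: str = "share_ip",
) -> tuple[dict[str, float], dict[str, float]]:
    """Read a per-miRNA percent-share TSV into (total, IP) share maps."""
    df = pd.read_csv(path, sep="\t")
    for col in (id_col, total_col, ip_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return (
        dict(zip(df[id_col], df[total_col].astype(float))),
        dict(zip(df[id_col], df[ip_col].astype(float))),
    )


def expression_gate(
    df: pd.DataFrame,
    threshold: float = DEFAULT_GATE_THRESHOLD,
    mode: str = "either_pool",
) -> pd.DataFrame:
    """Flag miRNAs at or above ``threshold`` percent of a pool.

    ``mode="either_pool"`` (default) gates on the total and/or the IP
    share; ``mode="total"`` on the total share only.  The gate is
    inclusive (at or above).
    """
    if mode not in GATE_MODES:
        raise ValueError(f"unknown gate mode {mode!r}")
    df = df.copy()
    if mode == "total":
        df["expressed"] = df["share_total"] >= threshold
    else:
        df["expressed"] = (df["share_total"] >= threshold) | (df["share_ip"] >= threshold)
    return df


def classify(df: pd.DataFrame, fold_threshold: float = DEFAULT_FOLD_THRESHOLD) -> pd.DataFrame:
    """Assign over / under / average classes at strict 2-fold lines."""
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    df = df.copy()
    df["assoc_class"] = np.select(
        [df["ratio"] > fold_threshold, df["ratio"] < 1.0 / fold_threshold],
        ["over", "under"],
        default="average",
    )
    return df


def pool_families(
    df: pd.DataFrame, families: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Pool member shares per seed family and recompute the ratio.

    The pooled ratio is sum(IP shares)/sum(total shares) — the ratio of
    pooled shares, not the mean of member ratios.
    """
    by_id = df.set_index("mirna_id")
    rows = []
    for fam, members in families.items():
        missing = [m for m in members if m not in by_id.index]
        if missing:
            raise KeyError(f"family {fam!r}: unknown member ids {missing}")
        st = float(by_id.loc[list(members), "share_total"].sum())
        si = float(by_id.loc[list(members), "share_ip"].sum())
        ratio, log2r = risc_ratio(si, st)
        rows.append({
            "family_id": fam,
            "member_ids": ",".join(members),
            "share_total": st,
            "share_ip": si,
            "ratio": ratio,
            "log2_ratio": log2r,
        })
    return pd.DataFrame(rows)


def extreme_spread(
    quants: Union[pd.DataFrame, Mapping[str, float], Sequence[float]],
) -> tuple[float, str, str]:
    """Max/min RISC-association ratio over expressed miRNAs.

    Accepts the quantification table (expressed, non-pseudocounted rows
    with finite ratios are used) or a plain mapping/sequence of ratios.
    Returns (spread, id of the most-associated, id of the least).
    """
    if isinstance(quants, pd.DataFrame):
        sel = quants
        if "expressed" in sel.columns:
            sel = sel[sel["expressed"]]
        if "pseudocounted" in sel.columns:
            sel = sel[~sel["pseudocounted"]]
        series = pd.Series(sel["ratio"].values, index=sel["mirna_id"].values, dtype=float)
    elif isinstance(quants, Mapping):
        series = pd.Series(dict(quants), dtype=float)
    else:
        series = pd.Series(list(quants), dtype=float)
    series = series[np.isfinite(series) & (series > 0)]
    if len(series) < 2:
        raise ValueError("extreme_spread needs >= 2 finite positive ratios")
    return float(series.max() / series.min()), str(series.idxmax()), str(series.idxmin())


def implied_risc_fraction(ratio_i: float, ratio_max: float) -> float:
    """Percent of a miRNA in RISC if the most-associated one is 100% bound.

    With the top miRNA pinned at 100%, a miRNA whose fold-over-average
    ratio is ratio_i is implied to be 100 * ratio_i / ratio_max percent
    RISC-bound.
    """
    if ratio_i <= 0 or ratio_max <= 0:
        raise ValueError("ratios must be positive")
    if ratio_i > ratio_max:
        raise ValueError("ratio_i must not exceed ratio_max")
    return 100.0 * ratio_i / ratio_max


def scatter_table(df: pd.DataFrame) -> pd.DataFrame:
    """log2 share pairs for expressed miRNAs (two-library scatter export)."""
    sel = df[df["expressed"]] if "expressed" in df.columns else df
    sel = sel[(sel["share_total"] > 0) & (sel["share_ip"] > 0)]
    return pd.DataFrame({
        "mirna_id": sel["mirna_id"].values,
        "log2_share_total": np.log2(sel["share_total"].values),
        "log2_share_ip": np.log2(sel["share_ip"].values),
    })
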