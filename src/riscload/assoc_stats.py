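"""Downstream statistics: correlations, discrepancy counts, qPCR and
luciferase-sensor normalizations.

These are the readouts that connect RISC association to function: the
count of miRNAs whose detection differs >2-fold between pools, relative
sensor expression (RLuc/FLuc against an empty control set to 1), qPCR
values normalized to a neutrally-loaded reference miRNA, the change in
a miRNA's RISC share after target overexpression, and the Pearson
correlation between sensor repression and a miRNA's share of either the
RISC-associated or the total pool.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as _stats


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("pearson needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson undefined for zero-variance input")
    r, p = _stats.pearsonr(x, y)
    return float(r), float(p)


def discrepancy_count(
    quants: Union[pd.DataFrame, Sequence[float]], fold: float = 2.0
) -> tuple[int, int]:
    """(n with a >fold discrepancy between pools, n analysed).

    Given the quantification table, only expressed miRNAs are analysed;
    a plain sequence of ratios is used as-is.
    """
    if isinstance(quants, pd.DataFrame):
        sel = quants[quants["expressed"]] if "expressed" in quants.columns else quants
        ratios = np.asarray(sel["ratio"], dtype=float)
    else:
        ratios = np.asarray(list(quants), dtype=float)
    disc = int(np.sum((ratios > fold) | (ratios < 1.0 / fold)))
    return disc, int(len(ratios))


def normalize_qpcr(
    values: Mapping[str, float], reference_id: str, mode: str = "linear"
) -> dict[str, float]:
    """Normalize qPCR abundances to a reference miRNA (reference -> 1).

    ``mode="ct"`` treats inputs as Ct cycle values and maps them through
    2^-Ct to the linear scale first.
    """
    if mode not in ("linear", "ct"):
        raise ValueError(f"unknown qPCR mode {mode!r}")
    if reference_id not in values:
        raise ValueError(f"reference {reference_id!r} missing from qPCR values")
    if mode == "ct":
        lin = {k: 2.0 ** (-float(v)) for k, v in values.items()}
    else:
        lin = {k: float(v) for k, v in values.items()}
    ref = lin[reference_id]
    if ref <= 0:
        raise ValueError("reference value must be positive")
    return {k: v / ref for k, v in lin.items()}


def relative_risc_change(
    sensor_ip: float, sensor_total: float, control_ip: float, control_total: float
) -> float:
    """Fold change of a miRNA's RISC share (IP/total) versus control cells.

    All four inputs are reference-normalized qPCR abundances; the
    control condition's IP/total contribution defines 1.0.
    """
    for v in (sensor_ip, sensor_total, control_ip, control_total):
        if v <= 0:
            raise ValueError("all normalized values must be positive")
    return (sensor_ip / sensor_total) / (control_ip / control_total)


def sensor_relative_expression(
    rluc: float, fluc: float, control_rluc: float, control_fluc: float
) -> float:
    """RLuc/FLuc of a sensor relative to the empty control construct (== 1)."""
    for v in (rluc, fluc, control_rluc, control_fluc):
        if v <= 0:
            raise ValueError("luciferase activities must be positive")
    return (rluc / fluc) / (control_rluc / control_fluc)


def function_correlation(
    shares: Mapping[str, float],
    sensors: Mapping[str, float],
    log2_shares: bool = False,
) -> tuple[float, float]:
    """Pearson (r, p) between miRNA pool shares and sensor repression.

    ``shares`` maps each sensed target (miRNA or pooled seed family) to
    its percent share of the chosen pool (RISC-associated or total);
    ``sensors`` maps targets to relative sensor expression.  Only shared
    targets enter; fewer than 3 is an error.
    """
    targets = sorted(set(shares) & set(sensors))
    if len(targets) < 3:
        raise ValueError(f"need >= 3 shared targets, have {len(targets)}")
    x = np.array([shares[t] for t in targets], dtype=float)
    if log2_shares:
        if np.any(x <= 0):
            raise ValueError("log2 scale requires positive shares")
        x = np.log2(x)
    y = np.array([sensors[t] for t in targets], dtype=float)
    return pearson(x, y)
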