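"""Blocked method comparison (Quade test) and information transfer rate."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist
from scipy.stats import rankdata

from .recording import ValidationError


@dataclass(frozen=True)
class QuadeResult:
    """Outcome of the Quade test on a blocks x treatments table."""

    statistic: float  # F
    pvalue: float
    df_num: int
    df_den: int
    degenerate: bool = False  # every block internally tied: no variance to rank


def quade_test(table: np.ndarray) -> QuadeResult:
    """Quade's weighted-rank test for k treatments observed in b blocks.

    ``table`` has one row per block (e.g. subject) and one column per
    treatment (e.g. decoding method).  Within-block ranks use mid-ranks for
    ties; blocks are weighted by the rank of their sample range.  The
    statistic is F = (b-1) * B / (A - B) with A = sum of S_ij^2 and
    B = sum_j S_j^2 / b, referred to an F(k-1, (b-1)(k-1)) distribution.

    A table whose every block is internally tied carries no rank information;
    it is reported as a degenerate no-variance case (NaN statistic, p = 1)
    rather than raising.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValidationError("Quade test needs >= 2 blocks and >= 2 treatments")
    b, k = tab.shape
    ranks = np.apply_along_axis(rankdata, 1, tab)  # mid-ranks within block
    block_range = tab.max(axis=1) - tab.min(axis=1)
    q = rankdata(block_range)  # block weights: ranks of the ranges
    s = q[:, None] * (ranks - (k + 1) / 2.0)
    a2 = float((s**2).sum())
    s_j = s.sum(axis=0)
    bb = float((s_j**2).sum()) / b
    df_num, df_den = k - 1, (b - 1) * (k - 1)
    if a2 <= bb + 1e-12 * max(a2, 1.0):
        if a2 == 0.0:  # all blocks fully tied
            return QuadeResult(float("nan"), 1.0, df_num, df_den, degenerate=True)
        return QuadeResult(float("inf"), 0.0, df_num, df_den)
    stat = (b - 1) * bb / (a2 - bb)
    pvalue = float(f_dist.sf(stat, df_num, df_den))
    return QuadeResult(stat, pvalue, df_num, df_den)


def wolpaw_bits_per_selection(accuracy: float, n_choices: int = 36) -> float:
    """Bits conveyed by one N-way selection at a given accuracy (Wolpaw).

    B = log2 N + P log2 P + (1-P) log2((1-P)/(N-1)); the P = 0 and P = 1
    limits are handled analytically.  At chance (P = 1/N) this is 0.
    """
    p = float(accuracy)
    n = int(n_choices)
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"accuracy must be in [0, 1], got {p}")
    if n < 2:
        raise ValidationError("n_choices must be >= 2")
    bits = math.log2(n)
    if p > 0.0:
        bits += p * math.log2(p)
    if p < 1.0:
        bits += (1.0 - p) * math.log2((1.0 - p) / (n - 1))
    return bits


def selection_time_s(
    n_intensifications: int,
    flash_s: float = 0.125,
    pause_s: float = 0.125,
    inter_trial_s: float = 0.0,
) -> float:
    """Time to spell one letter: n repetitions of 12 flash+pause periods.

    The inter-trial pause between letters is excluded by default (pass it to
    include it in the rate).
    """
    if n_intensifications < 1:
        raise ValidationError("need at least one intensification")
    return n_intensifications * 12 * (flash_s + pause_s) + inter_trial_s


def information_transfer_rate(
    accuracy: float, n_choices: int = 36, selection_time: float | None = None
) -> float:
    """Information transfer rate in bits per second.

    ``selection_time`` is the seconds spent per selection; if omitted the
    value is bits per selection.
    """
    bits = wolpaw_bits_per_selection(accuracy, n_choices)
    if selection_time is None:
        return bits
    if selection_time <= 0:
        raise ValidationError("selection time must be positive")
    return bits / selection_time
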