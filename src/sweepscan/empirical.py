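"""Genome-wide empirical ranking, empirical p-values and significance flags.

The empirical p-value of a statistic is (rank - 1)/N — the fraction of
the genome-wide distribution strictly more extreme than it (autosomes and
X ranked separately upstream).  This form reproduces every printed
worked-example p-value in the source tables; rank/N differs in the fourth
decimal for large ranks and does not.  Ties receive the
maximum (most conservative) rank of their tied block.  The number of values
flagged at level alpha is round-half-up(alpha * N), which makes the flag set
an exact prefix of the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import rankdata

UPPER = "upper"
LOWER = "lower"


@dataclass
class EmpiricalRanks:
    """Ranks and empirical p-values for one value vector.

    ``rank`` and ``p_e`` are NaN at positions whose input was undefined;
    ``n`` counts the defined (ranked) values only.
    """

    rank: np.ndarray
    p_e: np.ndarray
    n: int
    tail: str


def rank_and_p(values: np.ndarray, tail: str) -> EmpiricalRanks:
    """Rank values by decreasing extremity in the stated tail.

    P_E = (rank - 1)/N, the fraction of ranked values strictly more
    extreme.  ``tail="upper"`` ranks the largest value first (LSBL);
    ``tail="lower"`` the smallest (lnRH, standardized difference of D).
    NaN values are excluded from N and receive NaN rank.
    """
    if tail not in (UPPER, LOWER):
        raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")
    values = np.asarray(values, dtype=float)
    defined = np.isfinite(values)
    n = int(defined.sum())
    if n == 0:
        raise ValueError("no defined values to rank")
    v = values[defined]
    ranks = rankdata(-v if tail == UPPER else v, method="max")
    rank = np.full(values.shape, np.nan)
    rank[defined] = ranks
    return EmpiricalRanks(rank=rank, p_e=(rank - 1) / n, n=n, tail=tail)


def round_half_up(x: float, digits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def significant_count(n: int, alpha: float) -> int:
    """Number of values flagged at level alpha: round-half-up(alpha * N)."""
    if n < 1:
        raise ValueError("N must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    count = Decimal(str(alpha)) * Decimal(n)
    return int(count.quantize(Decimal(1), rounding=ROUND_HALF_UP))


def flag_significant(ranks: EmpiricalRanks | np.ndarray, alpha: float,
                     n: int | None = None) -> np.ndarray:
    """Boolean flags: rank <= round-half-up(alpha * N). NaN ranks are False."""
    if isinstance(ranks, EmpiricalRanks):
        rank, n = ranks.rank, ranks.n
    else:
        rank = np.asarray(ranks, dtype=float)
        if n is None:
            raise ValueError("n is required when passing a raw rank array")
    cutoff = significant_count(n, alpha)
    with np.errstate(invalid="ignore"):
        return np.where(np.isfinite(rank), rank <= cutoff, False)


def format_p(p: float) -> str:
    """Empirical p formatted at 4 decimals (half-up), as reported in output files."""
    return str(Decimal(repr(float(p))).quantize(Decimal("0.0001"),
                                         rounding=ROUND_HALF_UP))


def empirical_table(values: np.ndarray, tail: str, chromosome_class: str):
    """TSV-ready table: value, rank, N, P_E (4 dp), 5% / 1% flags."""
    import pandas as pd

    res = rank_and_p(values, tail)
    return pd.DataFrame({
        "value": values,
        "rank": res.rank,
        "n": res.n,
        "p_e": [format_p(p) if np.isfinite(p) else "NA" for p in res.p_e],
        "flag_05": flag_significant(res, 0.05),
        "flag_01": flag_significant(res, 0.01),
        "chromosome_class": chromosome_class,
    })
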