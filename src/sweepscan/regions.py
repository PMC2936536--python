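"""Clustering of significant markers/windows into 1-Mb regions.

Each non-overlapping megabase region is tested with the hypergeometric upper
tail (observing at least k significant items among its n, given K of N
genome-wide), Bonferroni-corrected over the tested (non-empty) regions.
Regions jointly significant for the standardized difference of D and either
LSBL or lnRH are nominated as candidate regions and merged into runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

DEFAULT_REGION_SIZE = 1_000_000
#: Operational per-region significance threshold on the corrected p-value.
DEFAULT_REGION_ALPHA = 0.004


def hypergeom_tail(k: int, big_k: int, n: int, big_n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= n <= big_n) or not (0 <= big_k <= big_n) or k > big_k:
        raise ValueError(
            f"invalid hypergeometric bounds k={k} K={big_k} n={n} N={big_n}")
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, big_n, big_k, n))
    return min(max(p, 0.0), 1.0)


def scan_megabase_regions(chrom: np.ndarray, pos: np.ndarray,
                          flags: np.ndarray,
                          region_size: int = DEFAULT_REGION_SIZE,
                          region_alpha: float = DEFAULT_REGION_ALPHA,
                          statistic_name: str = "") -> pd.DataFrame:
    """Hypergeometric scan of non-overlapping regions anchored at position 1.

    ``chrom``/``pos`` locate each item (marker position or window midpoint)
    and ``flags`` is its genome-wide significance call at alpha = 0.05.
    Regions without items are excluded from testing and from the Bonferroni
    denominator.  Returns one row per tested region with columns
    chrom, start, end (half-open bound start + region_size), n, k, N, K, p,
    p_bonf, significant, statistic.
    """
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    flags = np.asarray(flags, dtype=bool)
    if not (chrom.shape == pos.shape == flags.shape):
        raise ValueError("chrom, pos and flags must be aligned")
    big_n = int(len(pos))
    big_k = int(flags.sum())
    region_index = (pos - 1) // region_size
    rows = []
    for c in sorted(set(chrom.tolist())):
        on_c = chrom == c
        for r in np.unique(region_index[on_c]):
            in_region = on_c & (region_index == r)
            n = int(in_region.sum())
            k = int(flags[in_region].sum())
            rows.append({
                "chrom": c,
                "start": int(r) * region_size + 1,
                "end": (int(r) + 1) * region_size,
                "n": n, "k": k, "N": big_n, "K": big_k,
                "p": hypergeom_tail(k, big_k, n, big_n),
            })
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n", "k",
                                     "N", "K", "p"])
    n_tested = len(df)
    df["p_bonf"] = np.minimum(1.0, df["p"] * n_tested)
    df["significant"] = df["p_bonf"] <= region_alpha
    df["statistic"] = statistic_name
    return df


def nominate_regions(lsbl_regions: pd.DataFrame, lnrh_regions: pd.DataFrame,
                     delta_d_regions: pd.DataFrame,
                     region_size: int = DEFAULT_REGION_SIZE) -> pd.DataFrame:
    """Candidate regions: significant for delta-D and for LSBL or lnRH.

    Adjacent nominated megabases on the same chromosome merge into runs;
    the returned table has one row per run with its length in regions.
    """
    def sig_set(df):
        return {(r.chrom, int(r.start)) for r in df.itertuples()
                if bool(r.significant)}

    lsbl_sig = sig_set(lsbl_regions)
    lnrh_sig = sig_set(lnrh_regions)
    dd_sig = sig_set(delta_d_regions)
    nominated = sorted(dd_sig & (lsbl_sig | lnrh_sig))
    runs = []
    for chrom, start in nominated:
        if runs and runs[-1]["chrom"] == chrom \
                and runs[-1]["end"] + 1 == start:
            runs[-1]["end"] = start + region_size - 1
            runs[-1]["n_regions"] += 1
        else:
            runs.append({"chrom": chrom, "start": start,
                         "end": start + region_size - 1, "n_regions": 1})
    return pd.DataFrame(runs, columns=["chrom", "start", "end", "n_regions"])


def overlap_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Any-base-overlap join of two 1-based inclusive interval tables.

    Both inputs need chrom/start/end columns; abutting intervals
    (a.end + 1 == b.start) do not overlap.  Each overlapping pair is
    reported with both source rows (prefixed ``a_`` and ``b_``).
    """
    rows = []
    for ra in a.itertuples(index=False):
        for rb in b.itertuples(index=False):
            if ra.chrom != rb.chrom:
                continue
            if ra.start <= rb.end and ra.end >= rb.start:
                row = {f"a_{k}": v for k, v in ra._asdict().items()}
                row.update({f"b_{k}": v for k, v in rb._asdict().items()})
                rows.append(row)
    return pd.DataFrame(rows)


def write_regions_bed(path, regions: pd.DataFrame) -> None:
    """Write nominated regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tn_regions\n")
        for r in regions.itertuples(index=False):
            n = getattr(r, "n_regions", 1)
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{n}\n")
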