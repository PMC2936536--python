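"""Sliding-window statistics: lnRH, Tajima's D, standardized D and the
standardized difference of D.

Windows are 100 kb wide with a 25 kb step by default, anchored at position 1
of each chromosome.  Undefined window values (no markers, zero
heterozygosity, no segregating sites) are NaN throughout and are excluded
from standardization and ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .data_model import GenotypePanel, MarkerTable
from .diversity import allele_counts_all, expected_heterozygosity_all

DEFAULT_WINDOW_SIZE = 100_000
DEFAULT_WINDOW_STEP = 25_000


@dataclass
class WindowGrid:
    """Per-window (chrom, start, end) spans, 1-based inclusive."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    size: int
    step: int

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)

    def __len__(self) -> int:
        return int(self.start.shape[0])

    @property
    def n_windows(self) -> int:
        return len(self)


def make_windows(chrom_lengths: Mapping[str, int],
                 size: int = DEFAULT_WINDOW_SIZE,
                 step: int = DEFAULT_WINDOW_STEP) -> WindowGrid:
    """Build the overlapping window grid over each chromosome.

    The first window starts at position 1 and windows are emitted while
    ``start <= length - size + 1`` (every window spans exactly ``size`` bp).
    """
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    if size % step != 0:
        warnings.warn(f"window size {size} is not a multiple of step {step}")
    chroms, starts = [], []
    for chrom, length in chrom_lengths.items():
        s = np.arange(1, int(length) - size + 2, step, dtype=np.int64)
        starts.append(s)
        chroms.extend([chrom] * len(s))
    start = np.concatenate(starts) if starts else np.empty(0, dtype=np.int64)
    return WindowGrid(chrom=np.asarray(chroms, dtype=object), start=start,
                      end=start + size - 1, size=size, step=step)


def window_marker_indices(grid: WindowGrid,
                          markers: MarkerTable) -> list[np.ndarray]:
    """Marker indices falling in each window (markers may hit several windows)."""
    out: list[np.ndarray] = []
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in set(grid.chrom.tolist()):
        by_chrom[chrom] = np.flatnonzero(markers.chrom == chrom)
    for w in range(len(grid)):
        idx = by_chrom.get(grid.chrom[w], np.empty(0, dtype=np.int64))
        pos = markers.pos[idx]
        out.append(idx[(pos >= grid.start[w]) & (pos <= grid.end[w])])
    return out


def window_heterozygosity(panel: GenotypePanel, grid: WindowGrid,
                          markers: MarkerTable,
                          window_markers: list[np.ndarray] | None = None,
                          ) -> np.ndarray:
    """Mean unbiased expected heterozygosity over the markers in each window."""
    if window_markers is None:
        window_markers = window_marker_indices(grid, markers)
    n_chrom, alt, _ = allele_counts_all(panel)
    h = expected_heterozygosity_all(n_chrom, alt)
    out = np.full(len(grid), np.nan)
    for w, idx in enumerate(window_markers):
        vals = h[idx]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            out[w] = vals.mean()
    return out


def window_lnrh(panel_focal: GenotypePanel, panel_ref: GenotypePanel,
                grid: WindowGrid, markers: MarkerTable,
                window_markers: list[np.ndarray] | None = None) -> np.ndarray:
    """Per-window ln(H_focal / H_ref); NaN where either H is 0 or undefined."""
    if window_markers is None:
        window_markers = window_marker_indices(grid, markers)
    h_f = window_heterozygosity(panel_focal, grid, markers, window_markers)
    h_r = window_heterozygosity(panel_ref, grid, markers, window_markers)
    with np.errstate(divide="ignore", invalid="ignore"):
        lnrh = np.log(h_f / h_r)
    lnrh[~np.isfinite(lnrh)] = np.nan
    return lnrh


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalizing constants for n sampled chromosomes."""
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4 chromosomes")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i ** 2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d_from_counts(s: int, pi: float, n: int) -> float:
    """Tajima's D from segregating sites S and mean pairwise diversity pi."""
    if s == 0:
        return float("nan")
    k = tajima_constants(n)
    var = k["e1"] * s + k["e2"] * s * (s - 1)
    return float((pi - s / k["a1"]) / np.sqrt(var))


def tajimas_d(panel: GenotypePanel, grid: WindowGrid, markers: MarkerTable,
              window_markers: list[np.ndarray] | None = None) -> np.ndarray:
    """Per-window Tajima's D for one panel.

    S counts window markers polymorphic within the panel; pi sums the
    per-site unbiased heterozygosity 2*p*(1-p)*n/(n-1).  Constants use the
    full panel chromosome count n = 2 * samples (per-site missingness beyond
    the upstream call-rate filter is ignored).  Windows with S = 0 are NaN.
    """
    n = 2 * panel.n_samples
    consts = tajima_constants(n)
    if window_markers is None:
        window_markers = window_marker_indices(grid, markers)
    n_chrom, alt, _ = allele_counts_all(panel)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / n_chrom
    poly = (alt > 0) & (alt < n_chrom)
    pi_site = np.where(poly, 2.0 * p * (1.0 - p) * n / (n - 1.0), 0.0)
    out = np.full(len(grid), np.nan)
    for w, idx in enumerate(window_markers):
        s = int(poly[idx].sum())
        if s == 0:
            continue
        pi = float(pi_site[idx].sum())
        var = consts["e1"] * s + consts["e2"] * s * (s - 1)
        out[w] = (pi - s / consts["a1"]) / np.sqrt(var)
    return out


def _zscore(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    defined = np.isfinite(values)
    if defined.sum() < 2:
        raise ValueError("need >= 2 defined windows to standardize")
    mu = values[defined].mean()
    sd = values[defined].std(ddof=1)
    out = np.full_like(values, np.nan)
    if sd == 0:
        warnings.warn("zero standard deviation; standardized values set to 0")
        out[defined] = 0.0
        return out
    out[defined] = (values[defined] - mu) / sd
    return out


def standardize_d(d_values: np.ndarray) -> np.ndarray:
    """(D_i - mean) / sample SD over all defined windows."""
    return _zscore(d_values)


def std_diff_d(d_focal: np.ndarray, d_ref: np.ndarray) -> np.ndarray:
    """Standardized per-window difference D_focal - D_ref.

    The mean and sample SD are those of the differences themselves over all
    windows where both inputs are defined.
    """
    d_focal = np.asarray(d_focal, dtype=float)
    d_ref = np.asarray(d_ref, dtype=float)
    if d_focal.shape != d_ref.shape:
        raise ValueError("window tracks are not aligned")
    delta = d_focal - d_ref
    return _zscore(delta)


def flag_negative_focal(d_std_focal: np.ndarray, delta_d_std: np.ndarray,
                        mode: str = "tail_only") -> np.ndarray:
    """Per-window eligibility mask for the standardized-difference ranking.

    ``tail_only`` (default): every window where both tracks are defined is
    eligible.  ``two_stage``: additionally require a negative standardized
    focal D, mirroring the narrative two-step screen.
    """
    d_std_focal = np.asarray(d_std_focal, dtype=float)
    delta_d_std = np.asarray(delta_d_std, dtype=float)
    if d_std_focal.shape != delta_d_std.shape:
        raise ValueError("window tracks are not aligned")
    defined = np.isfinite(d_std_focal) & np.isfinite(delta_d_std)
    if mode == "tail_only":
        return defined
    if mode == "two_stage":
        return defined & (d_std_focal < 0)
    raise ValueError(f"unknown mode {mode!r}")


def window_stat_track(panel_focal: GenotypePanel, panel_ref: GenotypePanel,
                      grid: WindowGrid, markers: MarkerTable):
    """Full per-window table: marker counts, H, lnRH, D tracks and z-scores."""
    import pandas as pd

    wm = window_marker_indices(grid, markers)
    h_f = window_heterozygosity(panel_focal, grid, markers, wm)
    h_r = window_heterozygosity(panel_ref, grid, markers, wm)
    with np.errstate(divide="ignore", invalid="ignore"):
        lnrh = np.log(h_f / h_r)
    lnrh[~np.isfinite(lnrh)] = np.nan
    d_f = tajimas_d(panel_focal, grid, markers, wm)
    d_r = tajimas_d(panel_ref, grid, markers, wm)
    return pd.DataFrame({
        "chrom": grid.chrom,
        "start": grid.start,
        "end": grid.end,
        "n_markers": [len(ix) for ix in wm],
        "h_focal": h_f,
        "h_ref": h_r,
        "lnrh": lnrh,
        "d_focal": d_f,
        "d_ref": d_r,
        "d_std_focal": standardize_d(d_f),
        "delta_d_std": std_diff_d(d_f, d_r),
    })
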