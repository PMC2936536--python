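"""Per-marker allele frequencies, heterozygosity, Weir-Cockerham FST and
locus-specific branch lengths (LSBL).

The FST estimator is the two-population Weir & Cockerham (1984) moment
estimator theta-hat with the full genotype-level heterozygosity term.  An
allele-count ("haploid") variant that ignores observed heterozygosity is
available for sensitivity checks.  Undefined estimates (monomorphic in both
populations, or too few called chromosomes) are returned as NaN and carry
through all downstream arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import MISSING, GenotypePanel, MarkerTable


@dataclass(frozen=True)
class AlleleCounts:
    """Called-chromosome, alternate-allele and heterozygote counts at a marker."""

    n_chrom: int
    alt_count: int
    het_count: int

    @property
    def p_alt(self) -> float:
        return self.alt_count / self.n_chrom if self.n_chrom else float("nan")


@dataclass
class PairwiseFst:
    """Weir-Cockerham theta with its a (among), b (between-individual) and
    c (within-individual) variance components."""

    theta: float
    a: float
    b: float
    c: float


@dataclass
class LsblTriplet:
    """Branch lengths for populations A, B, C of one triangulation."""

    d_a: float
    d_b: float
    d_c: float


def allele_counts_all(panel: GenotypePanel):
    """Vectorized per-marker (n_chrom, alt_count, het_count) for a panel."""
    g = panel.genotypes
    called = g != MISSING
    n_chrom = 2 * called.sum(axis=0).astype(np.int64)
    alt = np.where(called, g, 0).sum(axis=0).astype(np.int64)
    het = (g == 1).sum(axis=0).astype(np.int64)
    return n_chrom, alt, het


def allele_counts(panel: GenotypePanel, marker_index: int) -> AlleleCounts:
    """Allele counts at one marker; missing genotypes are excluded."""
    if not 0 <= marker_index < panel.n_markers:
        raise IndexError(f"marker index {marker_index} out of range")
    g = panel.genotypes[:, marker_index]
    called = g != MISSING
    return AlleleCounts(
        n_chrom=int(2 * called.sum()),
        alt_count=int(g[called].sum()),
        het_count=int((g == 1).sum()),
    )


def expected_heterozygosity(counts: AlleleCounts) -> float:
    """Unbiased expected heterozygosity 2*p*(1-p)*n/(n-1); NaN if n_chrom < 2."""
    n = counts.n_chrom
    if n < 2:
        return float("nan")
    p = counts.alt_count / n
    return 2.0 * p * (1.0 - p) * n / (n - 1)


def expected_heterozygosity_all(n_chrom: np.ndarray,
                                alt: np.ndarray) -> np.ndarray:
    n = np.asarray(n_chrom, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.asarray(alt, dtype=float) / n
        h = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    h[n < 2] = np.nan
    return h


def _wc_components(n1, p1, h1, n2, p2, h2):
    """Weir-Cockerham (1984) a, b, c variance components for r = 2 samples.

    n_i are diploid sample sizes, p_i alternate-allele frequencies, h_i
    observed heterozygote proportions.  All arguments broadcast.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
            / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
    return a, b, c


def wc_fst(counts_pop1: AlleleCounts, counts_pop2: AlleleCounts,
           method: str = "genotype") -> PairwiseFst:
    """Two-population Weir-Cockerham theta-hat at one marker.

    Returns NaN components when either population has fewer than 2 called
    chromosomes or the marker is monomorphic in both populations combined.
    Negative estimates are reported as computed (clipping is deferred to
    :func:`lsbl`).
    """
    theta, a, b, c = wc_fst_arrays(
        np.array([counts_pop1.n_chrom]), np.array([counts_pop1.alt_count]),
        np.array([counts_pop1.het_count]),
        np.array([counts_pop2.n_chrom]), np.array([counts_pop2.alt_count]),
        np.array([counts_pop2.het_count]), method=method)
    return PairwiseFst(float(theta[0]), float(a[0]), float(b[0]), float(c[0]))


def wc_fst_arrays(n_chrom1, alt1, het1, n_chrom2, alt2, het2,
                  method: str = "genotype"):
    """Vectorized Weir-Cockerham theta over markers.

    ``method="genotype"`` uses diploid sample sizes and the observed
    heterozygosity term; ``method="haploid"`` treats chromosomes as haploid
    individuals (no heterozygosity term).
    """
    n_chrom1 = np.asarray(n_chrom1, dtype=float)
    n_chrom2 = np.asarray(n_chrom2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.asarray(alt1, dtype=float) / n_chrom1
        p2 = np.asarray(alt2, dtype=float) / n_chrom2
    if method == "genotype":
        n1 = n_chrom1 / 2.0
        n2 = n_chrom2 / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            h1 = np.asarray(het1, dtype=float) / n1
            h2 = np.asarray(het2, dtype=float) / n2
        a, b, c = _wc_components(n1, p1, h1, n2, p2, h2)
    elif method == "haploid":
        a, b, c = _wc_components(n_chrom1, p1, 0.0, n_chrom2, p2, 0.0)
        c = np.zeros_like(a)
    else:
        raise ValueError(f"unknown method {method!r}")
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = a / denom
    undefined = (n_chrom1 < 2) | (n_chrom2 < 2) | ~np.isfinite(denom) \
        | np.isclose(denom, 0.0)
    theta = np.where(undefined, np.nan, theta)
    a = np.where(undefined, np.nan, a)
    b = np.where(undefined, np.nan, b)
    c = np.where(undefined, np.nan, c)
    return theta, a, b, c


def wc_fst_panels(panel1: GenotypePanel, panel2: GenotypePanel,
                  method: str = "genotype"):
    """Per-marker theta (and components) between two aligned panels."""
    n1, alt1, het1 = allele_counts_all(panel1)
    n2, alt2, het2 = allele_counts_all(panel2)
    return wc_fst_arrays(n1, alt1, het1, n2, alt2, het2, method=method)


def global_fst(panel1: GenotypePanel, panel2: GenotypePanel,
               method: str = "genotype") -> float:
    """Multi-locus ratio-of-sums Weir-Cockerham theta: sum(a)/sum(a+b+c)."""
    _, a, b, c = wc_fst_panels(panel1, panel2, method=method)
    ok = np.isfinite(a)
    denom = (a[ok] + b[ok] + c[ok]).sum()
    if denom == 0:
        return float("nan")
    return float(a[ok].sum() / denom)


def lsbl(fst_ab, fst_ac, fst_bc):
    """Locus-specific branch lengths from three pairwise theta values.

    Negative pairwise estimates are floored at 0 before triangulation:
    d_A = (F_AB + F_AC - F_BC) / 2 and cyclic permutations.  NaN inputs
    propagate to an undefined triplet.  Accepts scalars or arrays.
    """
    scalar = np.isscalar(fst_ab) or (np.ndim(fst_ab) == 0)
    ab = np.maximum(np.asarray(fst_ab, dtype=float), 0.0)
    ac = np.maximum(np.asarray(fst_ac, dtype=float), 0.0)
    bc = np.maximum(np.asarray(fst_bc, dtype=float), 0.0)
    d_a = (ab + ac - bc) / 2.0
    d_b = (ab + bc - ac) / 2.0
    d_c = (ac + bc - ab) / 2.0
    if scalar:
        return LsblTriplet(float(d_a), float(d_b), float(d_c))
    return d_a, d_b, d_c


def region_mean_fst(markers: MarkerTable, fst_track: np.ndarray, chrom: str,
                    span: tuple[int, int], radius: int) -> float:
    """Unweighted mean of defined per-marker theta within span +/- radius bp."""
    start, end = span
    if start > end:
        raise ValueError("span start > end")
    sel = (markers.chrom == chrom) \
        & (markers.pos >= start - radius) & (markers.pos <= end + radius)
    vals = np.asarray(fst_track, dtype=float)[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def lsbl_table(markers: MarkerTable, theta_ab, theta_ac, theta_bc,
               labels: Sequence[str] = ("A", "B", "C")):
    """Per-marker TSV-ready table of pairwise theta and branch lengths."""
    import pandas as pd

    d_a, d_b, d_c = lsbl(theta_ab, theta_ac, theta_bc)
    la, lb, lc = labels
    return pd.DataFrame({
        "marker_id": markers.marker_id,
        "chrom": markers.chrom,
        "pos": markers.pos,
        f"fst_{la}{lb}": theta_ab,
        f"fst_{la}{lc}": theta_ac,
        f"fst_{lb}{lc}": theta_bc,
        f"d_{la}": d_a,
        f"d_{lb}": d_b,
        f"d_{lc}": d_c,
    })
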