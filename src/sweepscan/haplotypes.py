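"""Long-range-haplotype scan: core haplotypes, EHH/REHH, gamma-tail
significance with FDR control, and derived-allele filtering.

Cores are distinct allelic strings over non-overlapping spans of consecutive
markers.  EHH at a distance is the probability that two random carriers of
the core are identical over all markers within that distance of the core
span; REHH compares a core's EHH to the pooled homozygosity of the grouped
competing haplotypes on the same span.  REHH values are tested against a per-
frequency-bin gamma null fitted by maximum likelihood, with Benjamini-
Hochberg FDR control, and the reported significant set is restricted to
cores carrying a high-frequency (> 0.85) derived allele.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy.special import digamma, polygamma
from scipy.stats import gamma as gamma_dist

from .data_model import MISSING, GenotypePanel, HaplotypePanel, MarkerTable

logger = logging.getLogger(__name__)

DEFAULT_CORE_SIZE = 7
DEFAULT_MIN_CARRIERS = 3
DEFAULT_EVAL_DISTANCE = 500_000
DEFAULT_BIN_WIDTH = 0.05
DEFAULT_MIN_PER_BIN = 30
DEFAULT_FDR_Q = 0.05
DERIVED_FREQ_THRESHOLD = 0.85


@dataclass
class CoreHaplotype:
    """A distinct allelic string over a span of consecutive markers."""

    chrom: str
    start_index: int  # first marker index of the span (inclusive)
    end_index: int    # last marker index of the span (inclusive)
    alleles: tuple
    carriers: np.ndarray  # haplotype row indices
    frequency: float

    @property
    def n_carriers(self) -> int:
        return int(len(self.carriers))


@dataclass
class EhhCurve:
    distances: np.ndarray
    values: np.ndarray


@dataclass
class RehhResult:
    core: CoreHaplotype
    ehh: float
    rehh: float
    distance: int
    frequency_bin: int = -1
    gamma_shape: float = float("nan")
    gamma_scale: float = float("nan")
    p: float = float("nan")
    fdr_flag: bool = False
    derived_pass: bool = False
    significant: bool = False


@dataclass
class WglrhConfig:
    core_size: int = DEFAULT_CORE_SIZE
    min_carriers: int = DEFAULT_MIN_CARRIERS
    distance: int = DEFAULT_EVAL_DISTANCE
    bin_width: float = DEFAULT_BIN_WIDTH
    min_per_bin: int = DEFAULT_MIN_PER_BIN
    fdr_q: float = DEFAULT_FDR_Q
    derived_freq_threshold: float = DERIVED_FREQ_THRESHOLD


# ---------------------------------------------------------------------------
# derived alleles
# ---------------------------------------------------------------------------


def derived_allele_frequency(panel: GenotypePanel | HaplotypePanel,
                             marker_index: int,
                             markers: MarkerTable) -> float:
    """Frequency of the derived allele among called chromosomes.

    NaN when the ancestral state is unknown (such markers are excluded from
    the haplotype scan).
    """
    ancestral = markers.ancestral[marker_index]
    if ancestral == "unknown":
        return float("nan")
    if isinstance(panel, HaplotypePanel):
        col = panel.haplotypes[:, marker_index]
    else:
        col = panel.genotypes[:, marker_index]
    called = col != MISSING
    n = called.sum() * (1 if isinstance(panel, HaplotypePanel) else 2)
    if n == 0:
        return float("nan")
    alt = col[called].sum()
    p_alt = alt / n
    return float(p_alt if ancestral == "ref" else 1.0 - p_alt)


def passes_derived_filter(freq: float,
                          threshold: float = DERIVED_FREQ_THRESHOLD) -> bool:
    """Strictly greater-than comparison: 0.85 exactly fails, 0.86 passes."""
    return bool(np.isfinite(freq) and freq > threshold)


# ---------------------------------------------------------------------------
# cores and EHH
# ---------------------------------------------------------------------------


def define_cores(panel: HaplotypePanel, markers: MarkerTable,
                 core_size: int = DEFAULT_CORE_SIZE,
                 min_carriers: int = DEFAULT_MIN_CARRIERS,
                 ) -> list[CoreHaplotype]:
    """Distinct core haplotypes over non-overlapping spans of core_size markers.

    Haplotype rows with a missing allele inside a span are dropped for that
    span; core frequencies are relative to the retained rows.  Cores with
    fewer than ``min_carriers`` carriers are dropped.  Spans never cross a
    chromosome boundary.
    """
    cores: list[CoreHaplotype] = []
    haps = panel.haplotypes
    for chrom in dict.fromkeys(markers.chrom.tolist()):
        idx = np.flatnonzero(markers.chrom == chrom)
        for s in range(0, len(idx) - core_size + 1, core_size):
            span = idx[s:s + core_size]
            sub = haps[:, span]
            keep = ~(sub == MISSING).any(axis=1)
            rows = np.flatnonzero(keep)
            if rows.size == 0:
                continue
            strings, inverse = np.unique(sub[rows], axis=0,
                                         return_inverse=True)
            for g in range(strings.shape[0]):
                carriers = rows[inverse == g]
                if carriers.size < min_carriers:
                    continue
                cores.append(CoreHaplotype(
                    chrom=str(chrom),
                    start_index=int(span[0]),
                    end_index=int(span[-1]),
                    alleles=tuple(int(a) for a in strings[g]),
                    carriers=carriers,
                    frequency=float(carriers.size / rows.size),
                ))
    return cores


def _extension_columns(core: CoreHaplotype, markers: MarkerTable,
                       distance: int,
                       exclude_span: tuple[int, int] | None = None,
                       ) -> np.ndarray:
    """Marker indices within `distance` bp of the core span, outside the core.

    ``exclude_span`` removes markers within a (start, end) bp interval, used
    for markers falling inside a copy-number polymorphism.
    """
    lo = markers.pos[core.start_index] - distance
    hi = markers.pos[core.end_index] + distance
    sel = (markers.chrom == core.chrom) & (markers.pos >= lo) \
        & (markers.pos <= hi)
    sel[core.start_index:core.end_index + 1] = False
    if exclude_span is not None:
        sel &= ~((markers.pos >= exclude_span[0])
                 & (markers.pos <= exclude_span[1]))
    return np.flatnonzero(sel)


def _ehh_rows(rows: np.ndarray, cols: np.ndarray,
              haps: np.ndarray) -> float:
    """Homozygosity of a row set over the given columns.

    Rows with missing alleles in the columns are dropped; NaN when fewer
    than 2 usable rows remain.
    """
    sub = haps[np.asarray(rows)][:, cols]
    keep = ~(sub == MISSING).any(axis=1)
    sub = sub[keep]
    c = sub.shape[0]
    if c < 2:
        return float("nan")
    if sub.shape[1] == 0:
        return 1.0
    _, counts = np.unique(sub, axis=0, return_counts=True)
    return float(sum(comb(int(k), 2) for k in counts) / comb(c, 2))


def ehh(core: CoreHaplotype, panel: HaplotypePanel, markers: MarkerTable,
        distance: int,
        exclude_span: tuple[int, int] | None = None) -> float:
    """Extended haplotype homozygosity of a core at a physical distance.

    EHH = sum_h C(c_h, 2) / C(c, 2) over distinct extensions h of the core
    among its carriers.  Carrier rows with missing alleles in the extension
    are dropped at this distance; NaN when fewer than 2 usable carriers
    remain.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    cols = _extension_columns(core, markers, distance, exclude_span)
    return _ehh_rows(core.carriers, cols, panel.haplotypes)


def ehh_curve(core: CoreHaplotype, panel: HaplotypePanel,
              markers: MarkerTable, distances) -> EhhCurve:
    values = np.asarray([ehh(core, panel, markers, int(d))
                         for d in distances], dtype=float)
    return EhhCurve(distances=np.asarray(distances, dtype=np.int64),
                    values=values)


def rehh(core: CoreHaplotype, span_cores: list[CoreHaplotype],
         panel: HaplotypePanel, markers: MarkerTable,
         distance: int = DEFAULT_EVAL_DISTANCE,
         exclude_span: tuple[int, int] | None = None) -> float:
    """EHH of the core relative to the pooled EHH of all competing cores.

    The denominator is the homozygosity of the grouped complement: all
    carriers of the other cores on the span pooled into one set, so that
    pairs drawn from different competing haplotypes count as non-identical
    (the relative-EHH definition of the cited long-range-haplotype method).
    NaN if there is no competing core or the complement EHH is zero or
    undefined.
    """
    others = [c for c in span_cores if c is not core
              and (c.start_index, c.end_index, c.alleles)
              != (core.start_index, core.end_index, core.alleles)]
    if not others:
        return float("nan")
    ehh_core = ehh(core, panel, markers, distance, exclude_span)
    cols = _extension_columns(core, markers, distance, exclude_span)
    # the complement comparison includes the core columns, so carriers of
    # different competing haplotypes never count as an identical pair
    cols_with_core = np.union1d(
        cols, np.arange(core.start_index, core.end_index + 1))
    rest = np.concatenate([np.asarray(c.carriers) for c in others])
    ehh_others = _ehh_rows(rest, cols_with_core, panel.haplotypes)
    if not np.isfinite(ehh_core) or not np.isfinite(ehh_others) \
            or ehh_others == 0.0:
        return float("nan")
    return float(ehh_core / ehh_others)


# ---------------------------------------------------------------------------
# gamma null and FDR
# ---------------------------------------------------------------------------


def fit_gamma_mle(values, tol: float = 1e-8,
                  max_iter: int = 200) -> tuple[float, float]:
    """Maximum-likelihood gamma (shape, scale) via Newton iteration on the
    digamma equation log(k) - psi(k) = log(mean) - mean(log)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if np.any(x <= 0):
        raise ValueError("gamma fit requires strictly positive values")
    s = float(np.log(x.mean()) - np.log(x).mean())
    if s <= 0:
        raise ValueError("zero-variance input: gamma MLE undefined")
    k = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(max_iter):
        f = np.log(k) - digamma(k) - s
        fprime = 1.0 / k - polygamma(1, k)
        step = f / fprime
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) <= tol * abs(k):
            k = k_new
            break
        k = k_new
    scale = float(x.mean() / k)
    return float(k), scale


def gamma_tail_p(x: float, shape: float, scale: float) -> float:
    """Upper-tail gamma probability, floored into (0, 1]."""
    p = float(gamma_dist.sf(x, shape, scale=scale))
    return min(1.0, max(p, np.finfo(float).tiny))


def bh_fdr(p_values, q: float = DEFAULT_FDR_Q) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    below = sorted_p <= (np.arange(1, m + 1) * q / m)
    if not below.any():
        return np.zeros(m, dtype=bool)
    cutoff = sorted_p[np.flatnonzero(below).max()]
    return p <= cutoff


# ---------------------------------------------------------------------------
# whole-genome scan
# ---------------------------------------------------------------------------


def _core_derived_pass(core: CoreHaplotype, panel: HaplotypePanel,
                       markers: MarkerTable, threshold: float) -> bool:
    """True if the core carries a derived allele whose panel frequency
    strictly exceeds the threshold at some marker of its span."""
    for offset, j in enumerate(range(core.start_index, core.end_index + 1)):
        ancestral = markers.ancestral[j]
        if ancestral == "unknown":
            continue
        derived_code = 1 if ancestral == "ref" else 0
        if core.alleles[offset] != derived_code:
            continue
        freq = derived_allele_frequency(panel, j, markers)
        if passes_derived_filter(freq, threshold):
            return True
    return False


def wglrh_scan(panel: HaplotypePanel, markers: MarkerTable,
               config: WglrhConfig | None = None) -> list[RehhResult]:
    """Full long-range-haplotype scan of a phased panel.

    Cores are built genome-wide, REHH evaluated at the configured distance,
    a gamma null fitted per core-frequency bin (bins with fewer than
    ``min_per_bin`` REHH values fall back to a pooled genome-wide fit),
    upper-tail p-values corrected by Benjamini-Hochberg, and the reported
    significant set restricted to cores passing the derived-allele filter.
    """
    cfg = config or WglrhConfig()
    cores = define_cores(panel, markers, cfg.core_size, cfg.min_carriers)
    by_span: dict[tuple, list[CoreHaplotype]] = {}
    for c in cores:
        by_span.setdefault((c.chrom, c.start_index, c.end_index),
                           []).append(c)
    results: list[RehhResult] = []
    for span_cores in by_span.values():
        if len(span_cores) < 2:
            continue
        for core in span_cores:
            e = ehh(core, panel, markers, cfg.distance)
            r = rehh(core, span_cores, panel, markers, cfg.distance)
            if not np.isfinite(r):
                continue
            results.append(RehhResult(core=core, ehh=e, rehh=r,
                                      distance=cfg.distance))
    any_ancestral = bool(np.any(markers.ancestral != "unknown"))
    if not any_ancestral:
        warnings.warn("no ancestral states available: "
                      "significant set is empty")
    usable = [r for r in results if np.isfinite(r.rehh) and r.rehh > 0]
    n_dropped = len(results) - len(usable)
    if n_dropped:
        logger.info("dropped %d cores with undefined/zero REHH", n_dropped)
    if not usable:
        return results
    n_bins = int(np.ceil(1.0 / cfg.bin_width))
    for r in usable:
        r.frequency_bin = min(int(r.core.frequency / cfg.bin_width),
                              n_bins - 1)
    values_by_bin: dict[int, list[RehhResult]] = {}
    for r in usable:
        values_by_bin.setdefault(r.frequency_bin, []).append(r)
    pooled_fit = None
    try:
        pooled_fit = fit_gamma_mle([r.rehh for r in usable])
    except ValueError:
        pass
    for b, rs in values_by_bin.items():
        fit = pooled_fit
        if len(rs) >= cfg.min_per_bin:
            try:
                fit = fit_gamma_mle([r.rehh for r in rs])
            except ValueError:
                fit = pooled_fit
        if fit is None:
            continue
        shape, scale = fit
        for r in rs:
            r.gamma_shape, r.gamma_scale = shape, scale
            r.p = gamma_tail_p(r.rehh, shape, scale)
    for r in usable:
        r.derived_pass = any_ancestral and _core_derived_pass(
            r.core, panel, markers, cfg.derived_freq_threshold)
    # the derived-allele restriction defines the candidate set; FDR is the
    # last step, applied across the restricted tests only
    tested = [r for r in usable if np.isfinite(r.p) and r.derived_pass]
    if tested:
        flags = bh_fdr([r.p for r in tested], cfg.fdr_q)
        for r, f in zip(tested, flags):
            r.fdr_flag = bool(f)
    for r in usable:
        r.significant = r.fdr_flag and r.derived_pass
    return results


def cnp_rehh_at_boundary(cnp_index: int, panel: HaplotypePanel,
                         markers: MarkerTable,
                         distance: int = DEFAULT_EVAL_DISTANCE,
                         cnp_span: tuple[int, int] | None = None,
                         min_carriers: int = 2) -> list[RehhResult]:
    """REHH for a biallelic CNP treated as a single-marker core at its
    boundary; markers inside ``cnp_span`` (bp interval) are excluded from
    the extension.  Returns one result per allele class present (a fixed
    CNP yields a single core with undefined REHH)."""
    col = panel.haplotypes[:, cnp_index]
    chrom = str(markers.chrom[cnp_index])
    cores = []
    for allele in (0, 1):
        carriers = np.flatnonzero(col == allele)
        if carriers.size < min_carriers:
            continue
        called = int((col != MISSING).sum())
        cores.append(CoreHaplotype(
            chrom=chrom, start_index=cnp_index, end_index=cnp_index,
            alleles=(allele,), carriers=carriers,
            frequency=float(carriers.size / called)))
    out = []
    for core in cores:
        e = ehh(core, panel, markers, distance, exclude_span=cnp_span)
        r = rehh(core, cores, panel, markers, distance,
                 exclude_span=cnp_span)
        out.append(RehhResult(core=core, ehh=e, rehh=r, distance=distance))
    return out
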