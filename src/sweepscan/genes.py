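"""Candidate-gene scoring against a genome-wide per-gene null, and
pathway-level one-sided Kolmogorov-Smirnov enrichment.

Each gene is assigned the markers (or windows) within 50 kb of its span and
scored by the most extreme assigned value.  The per-gene null is the
distribution of those extreme scores over every annotated gene; pathway
genes are flagged when their score falls in the alpha prefix of that
genome-wide per-gene ranking (same round-half-up prefix rule and
block-maximum tie handling as the marker-level empirical ranking).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .data_model import GeneRecord, MarkerTable
from .empirical import LOWER, UPPER, significant_count
from .windows import WindowGrid

DEFAULT_FLANK = 50_000


@dataclass
class GeneScore:
    """Most extreme statistic among the items assigned to one gene."""

    gene_id: str
    statistic_name: str
    extreme_value: float
    n_items: int
    flag_05: bool = False
    flag_01: bool = False
    null_quantile: float = float("nan")


def assign_markers_to_gene(gene: GeneRecord, markers: MarkerTable,
                           flank: int = DEFAULT_FLANK) -> np.ndarray:
    """Indices of markers with pos in [start - flank, end + flank] (inclusive)."""
    sel = (markers.chrom == gene.chrom) \
        & (markers.pos >= gene.start - flank) \
        & (markers.pos <= gene.end + flank)
    return np.flatnonzero(sel)


def assign_windows_to_gene(gene: GeneRecord, grid: WindowGrid,
                           flank: int = DEFAULT_FLANK) -> np.ndarray:
    """Indices of windows overlapping the flanked gene span by >= 1 bp."""
    sel = (grid.chrom == gene.chrom) \
        & (grid.end >= gene.start - flank) \
        & (grid.start <= gene.end + flank)
    return np.flatnonzero(sel)


def gene_extreme_statistic(gene: GeneRecord, assigned: np.ndarray,
                           values: np.ndarray, tail: str,
                           statistic_name: str = "") -> GeneScore | None:
    """Max (upper tail) or min (lower tail) defined value among assigned items.

    Returns None when the gene has no defined assigned item (such genes are
    excluded from the per-gene null).
    """
    vals = np.asarray(values, dtype=float)[assigned]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return None
    extreme = float(vals.max() if tail == UPPER else vals.min())
    return GeneScore(gene_id=gene.gene_id, statistic_name=statistic_name,
                     extreme_value=extreme, n_items=int(vals.size))


def score_genes(genes: Sequence[GeneRecord], markers_or_grid,
                values: np.ndarray, tail: str, statistic_name: str = "",
                flank: int = DEFAULT_FLANK) -> list[GeneScore]:
    """Score every gene; items are markers or windows depending on the track."""
    scores = []
    for gene in genes:
        if isinstance(markers_or_grid, WindowGrid):
            assigned = assign_windows_to_gene(gene, markers_or_grid, flank)
        else:
            assigned = assign_markers_to_gene(gene, markers_or_grid, flank)
        score = gene_extreme_statistic(gene, assigned, values, tail,
                                       statistic_name)
        if score is not None:
            scores.append(score)
    return scores


def _gene_ranks(values: np.ndarray, tail: str) -> np.ndarray:
    return rankdata(-values if tail == UPPER else values, method="max")


def gene_null_cutoffs(scores: Sequence[GeneScore], tail: str,
                      ) -> tuple[float, float]:
    """Empirical 5% and 1% tail cutoffs of the per-gene extreme-score null."""
    values = np.asarray([s.extreme_value for s in scores], dtype=float)
    n = values.size
    if n < 20:
        raise ValueError(f"need >= 20 scored genes, got {n}")
    order = np.sort(values)[::-1] if tail == UPPER else np.sort(values)

    def cutoff(alpha: float) -> float:
        count = significant_count(n, alpha)
        if count == 0:
            return float("inf") if tail == UPPER else float("-inf")
        return float(order[count - 1])

    return cutoff(0.05), cutoff(0.01)


def flag_gene_scores(scores: Sequence[GeneScore], tail: str,
                     ) -> list[GeneScore]:
    """Set flag_05/flag_01 and null quantiles from the genome-wide ranking.

    A gene is flagged at alpha when its block-maximum rank lies within the
    round-half-up(alpha * N) prefix of the per-gene ranking.
    """
    values = np.asarray([s.extreme_value for s in scores], dtype=float)
    n = values.size
    if n == 0:
        return []
    ranks = _gene_ranks(values, tail)
    c05 = significant_count(n, 0.05)
    c01 = significant_count(n, 0.01)
    for s, r in zip(scores, ranks):
        s.flag_05 = bool(r <= c05)
        s.flag_01 = bool(r <= c01)
        s.null_quantile = float(r / n)
    return list(scores)


def nominate_candidate_genes(pathway_gene_ids: Sequence[str],
                             scores: Sequence[GeneScore], tail: str,
                             alpha: float = 0.05) -> list[GeneScore]:
    """Pathway genes whose score sits in the alpha prefix of the genome null.

    ``scores`` must cover the genome-wide gene set (pathway genes included);
    pathway genes absent from it are unscored and silently omitted.
    """
    flagged = flag_gene_scores(list(scores), tail)
    wanted = set(pathway_gene_ids)
    attr = "flag_05" if alpha == 0.05 else "flag_01"
    return [s for s in flagged if s.gene_id in wanted and getattr(s, attr)]


def ks_pathway_test(pathway_values: np.ndarray, background_values: np.ndarray,
                    direction: str = "high") -> tuple[float, float]:
    """One-sided two-sample K-S test for a pathway shift toward extreme values.

    ``direction="high"`` computes D+ = sup_x [F_background(x) - F_pathway(x)]
    (pathway stochastically larger); ``direction="low"`` the mirror.  The
    p-value uses the asymptotic one-sided form exp(-2 D^2 nm/(n+m)), capped
    at 1.
    """
    pathway = np.asarray(pathway_values, dtype=float)
    background = np.asarray(background_values, dtype=float)
    pathway = pathway[np.isfinite(pathway)]
    background = background[np.isfinite(background)]
    if pathway.size == 0 or background.size == 0:
        raise ValueError("both samples must be non-empty")
    if direction == "low":
        pathway, background = -pathway, -background
    elif direction != "high":
        raise ValueError(f"unknown direction {direction!r}")
    grid = np.concatenate([pathway, background])
    f_path = np.searchsorted(np.sort(pathway), grid, side="right") / pathway.size
    f_bg = np.searchsorted(np.sort(background), grid, side="right") \
        / background.size
    d = float(max(0.0, (f_bg - f_path).max()))
    n, m = background.size, pathway.size
    p = float(min(1.0, np.exp(-2.0 * d * d * n * m / (n + m))))
    return d, p


def gene_score_table(scores: Sequence[GeneScore]):
    import pandas as pd

    return pd.DataFrame([{
        "gene_id": s.gene_id,
        "statistic": s.statistic_name,
        "extreme_value": s.extreme_value,
        "n_items": s.n_items,
        "null_quantile": s.null_quantile,
        "flag_05": s.flag_05,
        "flag_01": s.flag_01,
    } for s in scores])
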