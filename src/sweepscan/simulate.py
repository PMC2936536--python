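"""Forward-time three-population Wright-Fisher simulator on a marker lattice.

The root population is an ancestral haplotype pool whose derived-allele
frequencies follow a neutral-SFS-shaped (density proportional to 1/x,
truncated) distribution.  The outgroup splits ``split_outgroup`` generations
before present and the highland/lowland pair ``split_highland`` generations
before present; every branch drifts with recombination, and an additive
selection coefficient ``s`` can act on one focal marker in the highland
branch only.  Outputs are phased haplotype panels, collapsed genotype
panels with injected missingness, a marker table with known ancestral
states, and a truth record for recovery tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import (MISSING, GeneRecord, GenotypePanel, HaplotypePanel,
                         MarkerTable, write_gene_bed, write_genotypes_tsv,
                         write_sample_map, write_vcf)

logger = logging.getLogger(__name__)

HIGHLAND = "highland"
LOWLAND = "lowland"
OUTGROUP = "outgroup"


@dataclass
class SimulationConfig:
    """Parameters of the three-population sweep simulation."""

    n_e: int = 500
    split_outgroup: int = 200   # generations before present (t1)
    split_highland: int = 100   # generations before present (t2 < t1)
    s: float = 0.0              # additive selection coefficient, highland only
    chrom_length: int = 2_000_000
    marker_spacing: int = 3_000  # ~1 marker per 3 kb
    recomb_rate: float = 1e-8    # per bp per generation
    n_highland: int = 50
    n_lowland: int = 50
    n_outgroup: int = 50
    missing_rate: float = 0.01
    seed: int = 0
    chrom_name: str = "chr1"
    # symmetric per-haplotype per-marker flip rate; replenishes rare variants
    # so the site frequency spectrum stays near neutral expectations
    mutation_rate: float = 2e-4
    # initial derived-frequency distribution (density ~ 1/x, truncated)
    freq_min: float = 0.0005
    freq_max: float = 0.98
    # focal marker is drawn from this standing-frequency band at the split
    focal_freq_band: tuple[float, float] = (0.05, 0.25)
    # "standing": select on a variant segregating at sweep onset (the band
    # above); "de_novo": place a single new mutation on one haplotype at
    # onset, giving a single-origin hard sweep
    sweep_origin: str = "standing"
    sweep_min_final: float = 0.85
    # selection acts only over the last sweep_duration generations of the
    # highland branch (None: the whole branch); sweep_max_final < 1 retries
    # runs that fix, leaving a partial sweep
    sweep_duration: int | None = None
    sweep_max_final: float = 1.0
    max_retries: int = 20
    ancestral_unknown_rate: float = 0.0
    maf_ascertainment: bool = False  # mimic array SNP discovery (MAF >= 0.05)
    # synthetic gene annotation geometry and pathway sizes
    gene_length: int = 20_000
    gene_gap: int = 30_000
    n_hif: int = 6
    n_ras: int = 2
    n_globin: int = 3

    def validate(self) -> None:
        if self.split_highland >= self.split_outgroup:
            raise ValueError("split_highland (t2) must be < split_outgroup (t1)")
        if self.n_e < 2 or self.chrom_length <= 0 or self.marker_spacing <= 0:
            raise ValueError("population size / lengths must be positive")
        if self.recomb_rate < 0 or self.s < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    focal_marker_id: str | None
    focal_position: int | None
    sweep_frequency: dict = field(default_factory=dict)
    target_gene_id: str | None = None


# ---------------------------------------------------------------------------
# Wright-Fisher machinery
# ---------------------------------------------------------------------------


def _initial_frequencies(n: int, rng: np.random.Generator,
                         fmin: float, fmax: float) -> np.ndarray:
    """Inverse-CDF draws from density proportional to 1/x on [fmin, fmax]."""
    u = rng.random(n)
    return fmin * (fmax / fmin) ** u


def _evolve(pop: np.ndarray, n_gen: int, gap_rec: np.ndarray,
            rng: np.random.Generator, focal: int | None = None,
            s: float = 0.0, mutation_rate: float = 0.0) -> np.ndarray:
    """Evolve a haplotype population (2*N_e rows) for n_gen generations.

    Random union of gametes; crossover counts per gamete are Poisson with
    the summed per-gap recombination probability and crossover gaps drawn
    proportionally to gap length.  When ``focal`` is set, parents are drawn
    with additive fitness 1 + s * (derived copies at the focal marker).
    """
    n_hap, m = pop.shape
    n_e = n_hap // 2
    lam = float(gap_rec.sum())
    gap_p = gap_rec / lam if lam > 0 else None
    for _ in range(n_gen):
        if focal is not None and s > 0:
            g = pop[0::2, focal].astype(float) + pop[1::2, focal]
            w = 1.0 + s * g
            parents = rng.choice(n_e, size=n_hap, p=w / w.sum())
        else:
            parents = rng.integers(0, n_e, size=n_hap)
        start = rng.integers(0, 2, size=n_hap)
        children = pop[2 * parents + start]
        if lam > 0:
            n_x = rng.poisson(lam, size=n_hap)
            rec = np.flatnonzero(n_x)
            if rec.size:
                counts = n_x[rec]
                gaps = rng.choice(m - 1, size=int(counts.sum()), p=gap_p)
                rows = np.repeat(np.arange(rec.size), counts)
                switch = np.zeros((rec.size, m - 1), dtype=np.int32)
                np.add.at(switch, (rows, gaps), 1)
                phase = np.empty((rec.size, m), dtype=np.int32)
                phase[:, 0] = start[rec]
                np.cumsum(switch, axis=1, out=phase[:, 1:])
                phase[:, 1:] += start[rec, None]
                phase %= 2
                children[rec] = np.where(phase == 0, pop[2 * parents[rec]],
                                         pop[2 * parents[rec] + 1])
        if mutation_rate > 0:
            n_mut = rng.poisson(mutation_rate * n_hap * m)
            if n_mut:
                mr = rng.integers(0, n_hap, size=n_mut)
                mc = rng.integers(0, m, size=n_mut)
                children[mr, mc] ^= 1
        pop = children
    return pop


def _sample_panels(pop: np.ndarray, n_samples: int, label: str,
                   missing_rate: float, rng: np.random.Generator,
                   ) -> tuple[HaplotypePanel, GenotypePanel]:
    n_e = pop.shape[0] // 2
    if n_samples > n_e:
        raise ValueError(f"cannot sample {n_samples} of {n_e} individuals")
    chosen = rng.choice(n_e, size=n_samples, replace=False)
    rows = np.asarray([r for i in chosen for r in (2 * i, 2 * i + 1)])
    haps = pop[rows].astype(np.int8)
    sample_ids = [f"{label}_{k:03d}" for k in range(n_samples)]
    if missing_rate > 0:
        mask = rng.random((n_samples, pop.shape[1])) < missing_rate
        hap_mask = np.repeat(mask, 2, axis=0)
        haps = haps.copy()
        haps[hap_mask] = MISSING
    hap_panel = HaplotypePanel(label, sample_ids, haps)
    return hap_panel, hap_panel.collapse()


def _derived_frequency(pop: np.ndarray, j: int) -> float:
    return float(pop[:, j].mean())


def simulate_three_populations(config: SimulationConfig):
    """Run the simulation.

    Returns ``(markers, genotype_panels, haplotype_panels, truth)`` with
    panels ordered (highland, lowland, outgroup).  Under selection the
    highland branch is re-drawn (bounded retries) if the focal derived
    allele fails to exceed ``sweep_min_final``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.chrom_length // config.marker_spacing
    if m < 2:
        raise ValueError("chromosome too short for two markers")
    pos = (np.arange(m, dtype=np.int64) * config.marker_spacing
           + config.marker_spacing // 2)
    gap_rec = config.recomb_rate * np.diff(pos).astype(float)
    freqs = _initial_frequencies(m, rng, config.freq_min, config.freq_max)
    pool = (rng.random((2 * config.n_e, m)) < freqs).astype(np.uint8)

    t1, t2 = config.split_outgroup, config.split_highland
    pop_out = _evolve(pool.copy(), t1, gap_rec, rng,
                      mutation_rate=config.mutation_rate)
    pop_anc = _evolve(pool.copy(), t1 - t2, gap_rec, rng,
                      mutation_rate=config.mutation_rate)

    focal: int | None = None
    if config.s == 0:
        pop_high = _evolve(pop_anc.copy(), t2, gap_rec, rng,
                           mutation_rate=config.mutation_rate)
        pop_low = _evolve(pop_anc.copy(), t2, gap_rec, rng,
                          mutation_rate=config.mutation_rate)
    else:
        pop_low = _evolve(pop_anc.copy(), t2, gap_rec, rng,
                          mutation_rate=config.mutation_rate)
        duration = t2 if config.sweep_duration is None \
            else min(config.sweep_duration, t2)
        lo, hi = config.focal_freq_band
        center = config.chrom_length // 2
        pop_high = None
        n_outer = 5
        inner = max(1, (config.max_retries + 1) // n_outer)
        attempts = 0
        for _ in range(n_outer):
            # the standing-frequency band applies at sweep onset
            prefix = _evolve(pop_anc.copy(), t2 - duration, gap_rec, rng,
                             mutation_rate=config.mutation_rate)
            freqs_at_onset = prefix.mean(axis=0)
            if config.sweep_origin == "de_novo":
                candidates = np.flatnonzero(freqs_at_onset == 0.0)
            else:
                candidates = np.flatnonzero((freqs_at_onset >= lo)
                                            & (freqs_at_onset <= hi))
            if candidates.size == 0:
                continue
            focal = int(candidates[np.argmin(
                np.abs(pos[candidates] - center))])
            for _ in range(inner):
                attempts += 1
                onset = prefix.copy()
                if config.sweep_origin == "de_novo":
                    onset[rng.integers(0, onset.shape[0]), focal] = 1
                cand = _evolve(onset, duration, gap_rec, rng,
                               focal=focal, s=config.s,
                               mutation_rate=config.mutation_rate)
                freq = _derived_frequency(cand, focal)
                if config.sweep_min_final < freq <= config.sweep_max_final:
                    pop_high = cand
                    break
            if pop_high is not None:
                break
            logger.info("sweep not established after %d attempts; "
                        "re-drawing the pre-sweep branch", attempts)
        if pop_high is None:
            raise RuntimeError(
                f"focal allele failed to reach "
                f"({config.sweep_min_final}, {config.sweep_max_final}] "
                f"in {attempts} attempts")

    ancestral = np.full(m, "ref", dtype=object)
    if config.ancestral_unknown_rate > 0:
        unknown = rng.random(m) < config.ancestral_unknown_rate
        if focal is not None:
            unknown[focal] = False
        ancestral[unknown] = "unknown"
    markers = MarkerTable(
        marker_id=np.asarray([f"m{j:06d}" for j in range(m)], dtype=object),
        chrom=np.asarray([config.chrom_name] * m, dtype=object),
        pos=pos,
        allele_ref=np.asarray(["A"] * m, dtype=object),
        allele_alt=np.asarray(["G"] * m, dtype=object),
        ancestral=ancestral,
        marker_class=np.asarray(["snp"] * m, dtype=object),
    )

    panels = []
    for pop, n, label in ((pop_high, config.n_highland, HIGHLAND),
                          (pop_low, config.n_lowland, LOWLAND),
                          (pop_out, config.n_outgroup, OUTGROUP)):
        panels.append(_sample_panels(pop, n, label, config.missing_rate, rng))
    hap_panels = [p[0] for p in panels]
    geno_panels = [p[1] for p in panels]

    if config.maf_ascertainment:
        pooled = np.concatenate([g.genotypes for g in geno_panels], axis=0)
        called = pooled != MISSING
        with np.errstate(invalid="ignore"):
            p = np.where(called, pooled, 0).sum(0) / (2.0 * called.sum(0))
        maf = np.minimum(p, 1 - p)
        keep = maf >= 0.05
        if focal is not None:
            keep[focal] = True
        index = np.flatnonzero(keep)
        markers = markers.subset(index)
        hap_panels = [h.subset_markers(index) for h in hap_panels]
        geno_panels = [g.subset_markers(index) for g in geno_panels]
        if focal is not None:
            focal = int(np.flatnonzero(index == focal)[0])

    truth = SimulationTruth(focal_marker_id=None, focal_position=None)
    if focal is not None:
        truth.focal_marker_id = str(markers.marker_id[focal])
        truth.focal_position = int(markers.pos[focal])
        truth.sweep_frequency = {
            HIGHLAND: _derived_frequency(pop_high, focal),
            LOWLAND: _derived_frequency(pop_low, focal),
            OUTGROUP: _derived_frequency(pop_out, focal),
        }
    return markers, geno_panels, hap_panels, truth


# ---------------------------------------------------------------------------
# synthetic annotation
# ---------------------------------------------------------------------------


def generate_annotation_track(markers: MarkerTable, config: SimulationConfig,
                              truth: SimulationTruth | None = None,
                              ) -> list[GeneRecord]:
    """Tile the chromosome with synthetic genes and assign pathway tags.

    Genes are ``gene_length`` bp with ``gene_gap`` bp gaps.  When the truth
    record carries a focal marker, the tiling phase is shifted so that
    exactly one gene contains it, and that gene is tagged HIF (and recorded
    as ``truth.target_gene_id``).  Remaining pathway tags are assigned to
    random genes, deterministically from the configuration seed.
    """
    period = config.gene_length + config.gene_gap
    length = config.chrom_length
    if length < config.gene_length:
        raise ValueError("chromosome too short for a single gene")
    offset = 1
    focal_pos = truth.focal_position if truth is not None else None
    if focal_pos is not None:
        offset = (focal_pos - config.gene_length // 2) % period
        if offset == 0:
            offset = period
    starts = np.arange(offset, length - config.gene_length + 2, period,
                       dtype=np.int64)
    if starts.size == 0:
        raise ValueError("chromosome too short for a single gene")
    genes = [GeneRecord(gene_id=f"G{k:04d}", chrom=config.chrom_name,
                        start=int(s0), end=int(s0 + config.gene_length - 1))
             for k, s0 in enumerate(starts)]
    target_index = None
    if focal_pos is not None:
        for k, g in enumerate(genes):
            if g.start <= focal_pos <= g.end:
                target_index = k
                break
        if target_index is None:
            raise RuntimeError("focal marker not contained in any gene")
    rng = np.random.default_rng(config.seed + 104729)
    # the focal-containing gene consumes one HIF slot
    n_hif = config.n_hif - 1 if target_index is not None and config.n_hif \
        else config.n_hif
    tags = ([("HIF", n_hif), ("RAS", config.n_ras),
             ("globin", config.n_globin)])
    wanted = sum(n for _, n in tags)
    pool = [k for k in range(len(genes)) if k != target_index]
    if wanted > len(pool):
        raise ValueError("more pathway genes requested than genes available")
    chosen = list(rng.choice(len(pool), size=wanted, replace=False)) \
        if wanted else []
    flat = []
    for tag, n in tags:
        flat.extend([tag] * n)
    for slot, tag in zip(chosen, flat):
        genes[pool[slot]].pathway_tag = tag
    if target_index is not None:
        genes[target_index].pathway_tag = "HIF"
        if truth is not None:
            truth.target_gene_id = genes[target_index].gene_id
    return genes


# ---------------------------------------------------------------------------
# fixture writer
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_set(markers: MarkerTable, geno_panels, hap_panels,
                      genes, truth: SimulationTruth,
                      config: SimulationConfig, directory: str | Path,
                      overwrite: bool = False) -> dict:
    """Write the complete pipeline input set plus a checksum manifest.

    Files: phased VCF, genotype TSV, sample map, gene BED, truth JSON and a
    copy of the configuration.  Refuses to overwrite an existing manifest
    unless ``overwrite`` is set.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True")
    files = {
        "haplotypes.vcf": lambda p: write_vcf(p, markers, hap_panels,
                                              phased=True),
        "genotypes.tsv": lambda p: write_genotypes_tsv(p, markers,
                                                       geno_panels),
        "sample_map.tsv": lambda p: write_sample_map(p, geno_panels),
        "genes.bed": lambda p: write_gene_bed(p, genes),
        "truth.json": lambda p: Path(p).write_text(
            json.dumps(dataclasses.asdict(truth), indent=2) + "\n"),
        "config.json": lambda p: Path(p).write_text(
            json.dumps(dataclasses.asdict(config), indent=2) + "\n"),
    }
    manifest = {}
    for name, writer in files.items():
        path = directory / name
        writer(path)
        manifest[name] = _sha256(path)
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
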