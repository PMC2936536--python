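"""Typed containers and readers/writers for markers, genotypes, haplotypes and genes.

Internal coordinates are 1-based inclusive (VCF convention); BED input is
converted on read and BED output converted back on write.  Missing genotype
and haplotype calls use the :data:`MISSING` sentinel and are never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype (0/1/2 scale) or haplotype allele (0/1 scale).
MISSING = -9

PATHWAY_TAGS = ("HIF", "RAS", "globin", "none")
ANCESTRAL_STATES = ("ref", "alt", "unknown")
MARKER_CLASSES = ("snp", "cnp")


class DataModelError(ValueError):
    """Raised for malformed input files or contract violations."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class MarkerTable:
    """Per-marker map: id, chromosome, 1-based position, alleles, ancestral state.

    ``ancestral`` entries are one of ``{"ref", "alt", "unknown"}`` and
    ``marker_class`` entries one of ``{"snp", "cnp"}``.
    """

    marker_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    allele_ref: np.ndarray
    allele_alt: np.ndarray
    ancestral: np.ndarray
    marker_class: np.ndarray

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.allele_ref = np.asarray(self.allele_ref, dtype=object)
        self.allele_alt = np.asarray(self.allele_alt, dtype=object)
        self.ancestral = np.asarray(self.ancestral, dtype=object)
        self.marker_class = np.asarray(self.marker_class, dtype=object)

    def __len__(self) -> int:
        return int(self.pos.shape[0])

    @property
    def n_markers(self) -> int:
        return len(self)

    def validate(self) -> None:
        """Check table invariants; raise :class:`DataModelError` on violation."""
        n = len(self)
        for name in ("marker_id", "chrom", "allele_ref", "allele_alt",
                     "ancestral", "marker_class"):
            if getattr(self, name).shape[0] != n:
                raise DataModelError(f"field {name} length mismatch")
        if len(set(self.marker_id.tolist())) != n:
            raise DataModelError("duplicate marker ids")
        for chrom in set(self.chrom.tolist()):
            p = self.pos[self.chrom == chrom]
            if np.any(np.diff(p) <= 0):
                raise DataModelError(
                    f"positions not strictly increasing on {chrom}")
        if np.any(self.allele_ref == self.allele_alt):
            raise DataModelError("identical ref/alt alleles")
        bad = set(self.ancestral.tolist()) - set(ANCESTRAL_STATES)
        if bad:
            raise DataModelError(f"unknown ancestral states: {sorted(bad)}")
        bad = set(self.marker_class.tolist()) - set(MARKER_CLASSES)
        if bad:
            raise DataModelError(f"unknown marker classes: {sorted(bad)}")

    def subset(self, index: np.ndarray) -> "MarkerTable":
        index = np.asarray(index)
        return MarkerTable(
            marker_id=self.marker_id[index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            allele_ref=self.allele_ref[index],
            allele_alt=self.allele_alt[index],
            ancestral=self.ancestral[index],
            marker_class=self.marker_class[index],
        )


@dataclass
class GenotypePanel:
    """Diploid genotype matrix for one population (samples x markers).

    Entries count alternate alleles: 0, 1, 2, or :data:`MISSING`.
    """

    population_label: str
    sample_ids: list[str]
    genotypes: np.ndarray
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return int(self.genotypes.shape[1])

    def validate(self, markers: MarkerTable | None = None) -> None:
        if self.genotypes.shape[0] != self.n_samples:
            raise DataModelError("genotype row count != sample count")
        allowed = {0, 1, 2, MISSING}
        if not set(np.unique(self.genotypes).tolist()) <= allowed:
            raise DataModelError("genotype entries outside {0,1,2,missing}")
        if markers is not None and self.n_markers != len(markers):
            raise DataModelError("genotype column count != marker count")

    def subset_markers(self, index: np.ndarray) -> "GenotypePanel":
        return replace(self, genotypes=self.genotypes[:, np.asarray(index)])


@dataclass
class HaplotypePanel:
    """Phased haplotype matrix for one population (2*samples x markers).

    Row ``2*i`` and ``2*i + 1`` are the two haplotypes of sample ``i``;
    entries are 0, 1, or :data:`MISSING`.
    """

    population_label: str
    sample_ids: list[str]
    haplotypes: np.ndarray
    phased: bool = True

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return int(self.haplotypes.shape[0])

    @property
    def n_markers(self) -> int:
        return int(self.haplotypes.shape[1])

    def validate(self, markers: MarkerTable | None = None) -> None:
        if self.n_haplotypes != 2 * self.n_samples:
            raise DataModelError("haplotype row count != 2 * sample count")
        allowed = {0, 1, MISSING}
        if not set(np.unique(self.haplotypes).tolist()) <= allowed:
            raise DataModelError("haplotype entries outside {0,1,missing}")
        if markers is not None and self.n_markers != len(markers):
            raise DataModelError("haplotype column count != marker count")

    def collapse(self) -> GenotypePanel:
        """Collapse haplotype pairs back into a diploid genotype panel."""
        h0 = self.haplotypes[0::2]
        h1 = self.haplotypes[1::2]
        geno = h0 + h1
        geno[(h0 == MISSING) | (h1 == MISSING)] = MISSING
        return GenotypePanel(self.population_label, list(self.sample_ids), geno)

    def subset_markers(self, index: np.ndarray) -> "HaplotypePanel":
        return replace(self, haplotypes=self.haplotypes[:, np.asarray(index)])


@dataclass
class GeneRecord:
    """Gene span (1-based inclusive) with an optional pathway tag."""

    gene_id: str
    chrom: str
    start: int
    end: int
    pathway_tag: str = "none"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataModelError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.pathway_tag not in PATHWAY_TAGS:
            raise DataModelError(
                f"gene {self.gene_id}: unknown pathway tag {self.pathway_tag!r}")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _chrom_sort_key(label: str):
    name = label[3:] if label.lower().startswith("chr") else label
    if name.isdigit():
        return (0, int(name), "")
    return (1, 0, name)


def read_sample_map(path: str | Path) -> dict[str, str]:
    """Read a two-column sample -> population TSV map."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataModelError(
                    f"{path}:{lineno}: expected 2 tab-separated columns")
            mapping[parts[0]] = parts[1]
    if not mapping:
        raise DataModelError(f"{path}: empty sample map")
    return mapping


def _populations_in_order(sample_map: Mapping[str, str]) -> list[str]:
    seen: list[str] = []
    for pop in sample_map.values():
        if pop not in seen:
            seen.append(pop)
    return seen


def _split_panels(sample_ids: Sequence[str], genotypes: np.ndarray,
                  sample_map: Mapping[str, str]) -> list[GenotypePanel]:
    missing = [s for s in sample_map if s not in set(sample_ids)]
    if missing:
        raise DataModelError(
            f"samples in map absent from file: {', '.join(sorted(missing))}")
    panels = []
    for pop in _populations_in_order(sample_map):
        idx = [i for i, s in enumerate(sample_ids) if sample_map.get(s) == pop]
        panels.append(GenotypePanel(
            population_label=pop,
            sample_ids=[sample_ids[i] for i in idx],
            genotypes=genotypes[idx],
        ))
    return panels


def _sort_markers(markers: MarkerTable, matrices: list[np.ndarray]):
    order = sorted(range(len(markers)),
                   key=lambda i: (_chrom_sort_key(markers.chrom[i]),
                                  int(markers.pos[i])))
    order = np.asarray(order)
    return markers.subset(order), [m[:, order] for m in matrices]


# ---------------------------------------------------------------------------
# genotype readers
# ---------------------------------------------------------------------------


def _read_vcf_records(path: str | Path, require_phased: bool):
    """Parse a VCF into marker fields plus a per-sample allele-pair matrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows = []
    pairs = []  # (n_markers, n_samples, 2) allele indices, -1 missing
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        aa = var.INFO.get("AA")
        if aa is None:
            ancestral = "unknown"
        elif aa == var.REF:
            ancestral = "ref"
        elif aa == var.ALT[0]:
            ancestral = "alt"
        else:
            ancestral = "unknown"
        mclass = var.INFO.get("MC") or "snp"
        gts = var.genotypes  # [a0, a1, phased] per sample
        site = np.full((len(sample_ids), 2), -1, dtype=np.int8)
        for j, gt in enumerate(gts):
            alleles = gt[:-1]
            phased = bool(gt[-1])
            if len(alleles) != 2:
                raise DataModelError(
                    f"{path}: sample {sample_ids[j]} at {var.CHROM}:{var.POS} "
                    f"is not diploid")
            a0, a1 = int(alleles[0]), int(alleles[1])
            # homozygous and fully missing calls carry no phase information
            if require_phased and not phased and a0 != a1:
                raise DataModelError(
                    f"{path}: unphased heterozygote for sample "
                    f"{sample_ids[j]} at {var.CHROM}:{var.POS}")
            site[j, 0] = a0 if a0 >= 0 else -1
            site[j, 1] = a1 if a1 >= 0 else -1
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM,
                     int(var.POS), var.REF, var.ALT[0], ancestral, mclass))
        pairs.append(site)
    if n_skipped:
        logger.info("skipped %d multi-allelic records in %s", n_skipped, path)
    if not rows:
        raise DataModelError(f"{path}: no biallelic records")
    markers = MarkerTable(
        marker_id=[r[0] for r in rows], chrom=[r[1] for r in rows],
        pos=[r[2] for r in rows], allele_ref=[r[3] for r in rows],
        allele_alt=[r[4] for r in rows], ancestral=[r[5] for r in rows],
        marker_class=[r[6] for r in rows])
    return markers, sample_ids, np.stack(pairs), n_skipped


def _read_genotypes_vcf(path, sample_map):
    markers, sample_ids, pairs, _ = _read_vcf_records(path, require_phased=False)
    geno = pairs.sum(axis=2).T.astype(np.int8)  # samples x markers
    geno[(pairs[:, :, 0] < 0).T | (pairs[:, :, 1] < 0).T] = MISSING
    return markers, sample_ids, geno


def _read_genotypes_tsv(path, sample_map):
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        fixed = ["marker_id", "chrom", "pos", "ref", "alt", "ancestral", "class"]
        if header[: len(fixed)] != fixed:
            raise DataModelError(
                f"{path}:1: expected header starting with {fixed}")
        sample_ids = header[len(fixed):]
        rows, geno_rows = [], []
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise DataModelError(
                    f"{path}:{lineno}: expected {len(header)} columns, "
                    f"got {len(parts)}")
            try:
                pos = int(parts[2])
            except ValueError as exc:
                raise DataModelError(
                    f"{path}:{lineno}: bad position {parts[2]!r}") from exc
            codes = []
            for val in parts[len(fixed):]:
                if val == "NA":
                    codes.append(MISSING)
                elif val in ("0", "1", "2"):
                    codes.append(int(val))
                else:
                    raise DataModelError(
                        f"{path}:{lineno}: bad genotype code {val!r}")
            rows.append((parts[0], parts[1], pos, parts[3], parts[4],
                         parts[5], parts[6]))
            geno_rows.append(codes)
    markers = MarkerTable(
        marker_id=[r[0] for r in rows], chrom=[r[1] for r in rows],
        pos=[r[2] for r in rows], allele_ref=[r[3] for r in rows],
        allele_alt=[r[4] for r in rows], ancestral=[r[5] for r in rows],
        marker_class=[r[6] for r in rows])
    geno = np.asarray(geno_rows, dtype=np.int8).T  # samples x markers
    return markers, sample_ids, geno


def read_genotypes(path: str | Path, format: str,
                   sample_map: str | Path | Mapping[str, str],
                   ) -> tuple[MarkerTable, list[GenotypePanel]]:
    """Read diploid genotypes from a VCF or genotype-matrix TSV.

    ``sample_map`` assigns samples to populations (path to a two-column TSV
    or an in-memory mapping); one panel is returned per population, in map
    order.  Multi-allelic VCF records are skipped with a logged count, and
    markers are sorted by (chromosome, position).
    """
    if not isinstance(sample_map, Mapping):
        sample_map = read_sample_map(sample_map)
    if format == "vcf":
        markers, sample_ids, geno = _read_genotypes_vcf(path, sample_map)
    elif format == "tsv":
        markers, sample_ids, geno = _read_genotypes_tsv(path, sample_map)
    else:
        raise DataModelError(f"unknown genotype format {format!r}")
    markers, (geno,) = _sort_markers(markers, [geno])
    markers.validate()
    panels = _split_panels(sample_ids, geno, sample_map)
    for p in panels:
        p.validate(markers)
    return markers, panels


def read_haplotypes(path: str | Path,
                    sample_map: str | Path | Mapping[str, str],
                    ) -> tuple[MarkerTable, list[HaplotypePanel]]:
    """Read phased haplotypes from a VCF; unphased heterozygotes are rejected."""
    if not isinstance(sample_map, Mapping):
        sample_map = read_sample_map(sample_map)
    markers, sample_ids, pairs, _ = _read_vcf_records(path, require_phased=True)
    # pairs: markers x samples x 2 -> haplotype rows (2*samples) x markers
    n_samples = len(sample_ids)
    haps = np.empty((2 * n_samples, len(markers)), dtype=np.int8)
    haps[0::2] = pairs[:, :, 0].T
    haps[1::2] = pairs[:, :, 1].T
    haps[haps < 0] = MISSING
    markers, (haps,) = _sort_markers(markers, [haps])
    markers.validate()
    missing_from_file = [s for s in sample_map if s not in set(sample_ids)]
    if missing_from_file:
        raise DataModelError(
            "samples in map absent from file: "
            + ", ".join(sorted(missing_from_file)))
    panels = []
    for pop in _populations_in_order(sample_map):
        idx = [i for i, s in enumerate(sample_ids) if sample_map.get(s) == pop]
        rows = np.asarray([r for i in idx for r in (2 * i, 2 * i + 1)])
        panels.append(HaplotypePanel(
            population_label=pop,
            sample_ids=[sample_ids[i] for i in idx],
            haplotypes=haps[rows],
        ))
    for p in panels:
        p.validate(markers)
    return markers, panels


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------


def read_gene_annotations(path: str | Path) -> list[GeneRecord]:
    """Read a BED-like gene file (4th column id, optional 5th column tag).

    BED 0-based half-open coordinates are converted to 1-based inclusive.
    """
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise DataModelError(
                    f"{path}:{lineno}: expected at least 4 BED columns")
            chrom, start_s, end_s, gene_id = parts[:4]
            try:
                bed_start, bed_end = int(start_s), int(end_s)
            except ValueError as exc:
                raise DataModelError(
                    f"{path}:{lineno}: bad coordinates") from exc
            if bed_start >= bed_end:
                raise DataModelError(
                    f"{path}:{lineno}: start {bed_start} >= end {bed_end}")
            tag = parts[4] if len(parts) > 4 and parts[4] else "none"
            genes.append(GeneRecord(gene_id=gene_id, chrom=chrom,
                                    start=bed_start + 1, end=bed_end,
                                    pathway_tag=tag))
    return genes


def write_gene_bed(path: str | Path, genes: Iterable[GeneRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tgene_id\tpathway_tag\n")
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t"
                     f"{g.pathway_tag}\n")


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_TSV_HEADER = ["marker_id", "chrom", "pos", "ref", "alt", "ancestral", "class"]


def write_genotypes_tsv(path: str | Path, markers: MarkerTable,
                        panels: Sequence[GenotypePanel]) -> None:
    """Write markers-as-rows genotype matrix with per-sample 0/1/2/NA codes."""
    sample_ids = [s for p in panels for s in p.sample_ids]
    geno = np.concatenate([p.genotypes for p in panels], axis=0)
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_HEADER + sample_ids) + "\n")
        for i in range(len(markers)):
            codes = ["NA" if g == MISSING else str(int(g)) for g in geno[:, i]]
            fh.write("\t".join([
                str(markers.marker_id[i]), str(markers.chrom[i]),
                str(int(markers.pos[i])), str(markers.allele_ref[i]),
                str(markers.allele_alt[i]), str(markers.ancestral[i]),
                str(markers.marker_class[i])] + codes) + "\n")


def write_sample_map(path: str | Path,
                     panels: Sequence[GenotypePanel | HaplotypePanel]) -> None:
    with open(path, "w") as fh:
        fh.write("#sample\tpopulation\n")
        for p in panels:
            for s in p.sample_ids:
                fh.write(f"{s}\t{p.population_label}\n")


def _gt_string(a0: int, a1: int, sep: str) -> str:
    left = "." if a0 == MISSING else str(int(a0))
    right = "." if a1 == MISSING else str(int(a1))
    return f"{left}{sep}{right}"


def write_vcf(path: str | Path, markers: MarkerTable,
              panels: Sequence[GenotypePanel] | Sequence[HaplotypePanel],
              phased: bool | None = None) -> None:
    """Write a minimal VCF 4.2 with GT and AA/MC INFO fields.

    Haplotype panels are written phased (``|``); genotype panels unphased.
    """
    if phased is None:
        phased = isinstance(panels[0], HaplotypePanel)
    sep = "|" if phased else "/"
    sample_ids = [s for p in panels for s in p.sample_ids]
    contigs = []
    for c in markers.chrom.tolist():
        if c not in contigs:
            contigs.append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for c in contigs:
            length = int(markers.pos[markers.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,'
                 'Description="Ancestral allele">\n')
        fh.write('##INFO=<ID=MC,Number=1,Type=String,'
                 'Description="Marker class (snp or cnp)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for i in range(len(markers)):
            anc = markers.ancestral[i]
            info = [f"MC={markers.marker_class[i]}"]
            if anc == "ref":
                info.insert(0, f"AA={markers.allele_ref[i]}")
            elif anc == "alt":
                info.insert(0, f"AA={markers.allele_alt[i]}")
            gts = []
            for p in panels:
                if isinstance(p, HaplotypePanel):
                    h = p.haplotypes[:, i]
                    for s in range(p.n_samples):
                        gts.append(_gt_string(h[2 * s], h[2 * s + 1], sep))
                else:
                    for g in p.genotypes[:, i]:
                        if g == MISSING:
                            gts.append(_gt_string(MISSING, MISSING, sep))
                        else:
                            gts.append(_gt_string(0 if g < 2 else 1,
                                                  0 if g < 1 else 1, sep))
            fh.write("\t".join([
                str(markers.chrom[i]), str(int(markers.pos[i])),
                str(markers.marker_id[i]), str(markers.allele_ref[i]),
                str(markers.allele_alt[i]), ".", "PASS", ";".join(info),
                "GT"] + gts) + "\n")


# ---------------------------------------------------------------------------
# filters and partitions
# ---------------------------------------------------------------------------


def call_rates(panel: GenotypePanel) -> np.ndarray:
    """Per-marker fraction of called (non-missing) genotypes."""
    return (panel.genotypes != MISSING).mean(axis=0)


def filter_by_call_rate(
    markers: MarkerTable,
    panels: Sequence[GenotypePanel],
    threshold: float = 0.95,
    population_set: Sequence[str] | None = None,
) -> tuple[MarkerTable, list[GenotypePanel], np.ndarray]:
    """Keep markers whose call rate is >= threshold in every listed population.

    Returns the filtered marker table, all panels restricted to the kept
    markers, and the kept-marker index into the input table.  The threshold
    comparison is inclusive (a call rate of exactly ``threshold`` is kept).
    """
    if not 0 < threshold <= 1:
        raise DataModelError("threshold must be in (0, 1]")
    if population_set is not None and len(population_set) == 0:
        raise DataModelError("population_set must not be empty")
    labels = {p.population_label: p for p in panels}
    if population_set is None:
        selected = list(panels)
    else:
        unknown = set(population_set) - set(labels)
        if unknown:
            raise DataModelError(f"unknown populations: {sorted(unknown)}")
        selected = [labels[name] for name in population_set]
    keep = np.ones(len(markers), dtype=bool)
    for p in selected:
        keep &= call_rates(p) >= threshold
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("call-rate filter removed %d of %d markers",
                    n_removed, len(markers))
    index = np.flatnonzero(keep)
    return (markers.subset(index),
            [p.subset_markers(index) for p in panels], index)


def split_by_chromosome_class(
    markers: MarkerTable,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition marker indices into (autosomal, X, dropped) sets.

    Y and mitochondrial markers are dropped with a log message; any other
    unrecognized chromosome label raises an error.
    """
    auto, x_set, dropped, bad = [], [], [], []
    for i, label in enumerate(markers.chrom.tolist()):
        name = label[3:] if label.lower().startswith("chr") else label
        name = name.upper()
        if name.isdigit():
            auto.append(i)
        elif name == "X":
            x_set.append(i)
        elif name in ("Y", "M", "MT"):
            dropped.append(i)
        else:
            bad.append(label)
    if bad:
        raise DataModelError(
            f"unrecognized chromosome labels: {sorted(set(bad))}")
    if dropped:
        logger.info("dropped %d Y/mitochondrial markers", len(dropped))
    return (np.asarray(auto, dtype=np.int64),
            np.asarray(x_set, dtype=np.int64),
            np.asarray(dropped, dtype=np.int64))
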