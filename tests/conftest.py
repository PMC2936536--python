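import numpy as np
import pytest

from sweepscan.data_model import (MISSING, GenotypePanel, HaplotypePanel,
                                  MarkerTable)


def make_markers(positions, chrom="chr1", ancestral=None):
    n = len(positions)
    return MarkerTable(
        marker_id=[f"m{i}" for i in range(n)],
        chrom=[chrom] * n,
        pos=list(positions),
        allele_ref=["A"] * n,
        allele_alt=["G"] * n,
        ancestral=list(ancestral) if ancestral is not None else ["ref"] * n,
        marker_class=["snp"] * n,
    )


def make_panel(label, genotypes):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    return GenotypePanel(
        population_label=label,
        sample_ids=[f"{label}_{i}" for i in range(genotypes.shape[0])],
        genotypes=genotypes,
    )


def make_hap_panel(label, haplotypes):
    haplotypes = np.asarray(haplotypes, dtype=np.int8)
    assert haplotypes.shape[0] % 2 == 0
    return HaplotypePanel(
        population_label=label,
        sample_ids=[f"{label}_{i}" for i in range(haplotypes.shape[0] // 2)],
        haplotypes=haplotypes,
    )


@pytest.fixture
def toy_markers():
    return make_markers([100, 200, 300, 400, 500])


TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000>
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4\ts5\ts6
chr1\t100\trs1\tA\tG\t.\tPASS\tAA=A\tGT\t0|0\t0|1\t1|1\t0|0\t0|1\t1|1
chr1\t200\trs2\tC\tT\t.\tPASS\tAA=T\tGT\t0|1\t0|1\t0|0\t1|1\t0|0\t0|1
chr1\t300\trs3\tG\tA\t.\tPASS\t.\tGT\t1|1\t1|1\t0|1\t0|0\t.|.\t0|0
chr1\t400\trs4\tT\tC\t.\tPASS\tAA=T\tGT\t0|0\t0|0\t0|0\t0|1\t1|1\t0|0
chr1\t500\trs5\tA\tC\t.\tPASS\tAA=A\tGT\t0|1\t1|1\t0|0\t0|0\t0|1\t1|1
"""

TOY_SAMPLE_MAP = """\
#sample\tpopulation
s1\tpopA
s2\tpopA
s3\tpopB
s4\tpopB
s5\tpopC
s6\tpopC
"""


@pytest.fixture
def toy_vcf(tmp_path):
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(TOY_VCF)
    smap = tmp_path / "samples.tsv"
    smap.write_text(TOY_SAMPLE_MAP)
    return vcf, smap


@pytest.fixture
def triallelic_vcf(tmp_path):
    lines = TOY_VCF.splitlines()
    lines.insert(8, "chr1\t250\trs_tri\tA\tG,T\t.\tPASS\t.\tGT"
                 + "\t0|1" * 6)
    vcf = tmp_path / "tri.vcf"
    vcf.write_text("\n".join(lines) + "\n")
    smap = tmp_path / "samples.tsv"
    smap.write_text(TOY_SAMPLE_MAP)
    return vcf, smap
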