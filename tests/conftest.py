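"""Shared fixtures: tiny hand-built inputs and reusable simulated panels."""

import numpy as np
import pytest

from chlamypop.datatypes import GenotypeMatrix
from chlamypop.simulate import SimulationConfig, simulate_panel

INTERGENIC_ONLY = {"exon": 0.0, "intron": 0.0, "utr5": 0.0, "utr3": 0.0,
                   "intergenic": 1.0}


def neutral_config(chromosome_lengths, theta=0.002, rho=0.0, seed=0,
                   n=12) -> SimulationConfig:
    """Single panmictic population, no thinning, no masking, no dropout."""
    return SimulationConfig(
        n_per_group=n, two_groups=False, split_depth=0.0,
        theta_per_base=theta, rho_per_base=rho,
        chromosome_lengths=list(chromosome_lengths),
        class_layout=[INTERGENIC_ONLY] * len(chromosome_lengths),
        intergenic_diversity_scale=1.0, ambiguous_tract_rate=0.0,
        missing_rate=0.0, indel_rate=0.0, seed=seed)


def make_matrix(calls, positions=None, chromosomes=None) -> GenotypeMatrix:
    """GenotypeMatrix from a plain (n_strains, n_sites) array of calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n, s = calls.shape
    if positions is None:
        positions = np.arange(1, s + 1)
    if chromosomes is None:
        chromosomes = np.full(s, "chr01", dtype=object)
    return GenotypeMatrix(
        strain_ids=[f"S{i + 1:02d}" for i in range(n)],
        chromosomes=np.asarray(chromosomes, dtype=object),
        positions=np.asarray(positions),
        ref=np.full(s, "A", dtype="<U1"),
        alt=np.full(s, "G", dtype="<U1"),
        calls=calls)


@pytest.fixture(scope="session")
def two_group_panel():
    """One default-style two-group panel on a reduced (6-chromosome) genome."""
    config = SimulationConfig(chromosome_lengths=[100_000] * 6, seed=11)
    return simulate_panel(config)


@pytest.fixture(scope="session")
def annotation_files(tmp_path_factory):
    """Hand-built single-chromosome GFF3 + FASTA with known codon structure.

    Gene A (+ strand): 5'UTR 11-16, CDS 17-23 + 34-38 (codon split across
    the intron 24-33), 3'UTR 39-44; coding sequence ATG GGA GAA TGA.
    Gene B (- strand): 3'UTR 61-66, CDS 67-78, 5'UTR 79-84; coding
    sequence ATG TCC GGG TAA (genomic = its reverse complement).
    """
    root = tmp_path_factory.mktemp("annotation")
    seq = list("A" * 120)
    seq[16:23] = "ATGGGAG"   # gene A CDS part 1 (coding 1-7)
    seq[33:38] = "AATGA"     # gene A CDS part 2 (coding 8-12)
    seq[66:78] = "TTACCCGGACAT"  # revcomp(ATGTCCGGGTAA)
    fasta = root / "ref.fa"
    fasta.write_text(">chrT\n" + "".join(seq) + "\n")

    gff = root / "models.gff3"
    gff.write_text("\n".join([
        "##gff-version 3",
        "chrT\ttest\tgene\t11\t44\t.\t+\t.\tID=geneA",
        "chrT\ttest\tmRNA\t11\t44\t.\t+\t.\tID=geneA.t1;Parent=geneA",
        "chrT\ttest\texon\t11\t23\t.\t+\t.\tID=geneA.e1;Parent=geneA.t1",
        "chrT\ttest\texon\t34\t44\t.\t+\t.\tID=geneA.e2;Parent=geneA.t1",
        "chrT\ttest\tfive_prime_UTR\t11\t16\t.\t+\t.\tID=geneA.u5;Parent=geneA.t1",
        "chrT\ttest\tCDS\t17\t23\t.\t+\t0\tID=geneA.c1;Parent=geneA.t1",
        "chrT\ttest\tCDS\t34\t38\t.\t+\t2\tID=geneA.c2;Parent=geneA.t1",
        "chrT\ttest\tthree_prime_UTR\t39\t44\t.\t+\t.\tID=geneA.u3;Parent=geneA.t1",
        "chrT\ttest\tgene\t61\t84\t.\t-\t.\tID=geneB",
        "chrT\ttest\tmRNA\t61\t84\t.\t-\t.\tID=geneB.t1;Parent=geneB",
        "chrT\ttest\texon\t61\t84\t.\t-\t.\tID=geneB.e1;Parent=geneB.t1",
        "chrT\ttest\tthree_prime_UTR\t61\t66\t.\t-\t.\tID=geneB.u3;Parent=geneB.t1",
        "chrT\ttest\tCDS\t67\t78\t.\t-\t0\tID=geneB.c1;Parent=geneB.t1",
        "chrT\ttest\tfive_prime_UTR\t79\t84\t.\t-\t.\tID=geneB.u5;Parent=geneB.t1",
        "",
    ]))
    return gff, fasta


@pytest.fixture()
def tiny_vcf(tmp_path):
    """Four records: triallelic, low QUAL, passing SNP, boundary QUAL, indel."""
    path = tmp_path / "tiny.vcf"
    path.write_text("\n".join([
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr01,length=1000>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsA\tsB\tsC",
        "chr01\t10\t.\tA\tC,T\t50\tPASS\t.\tGT\t0\t1\t2",
        "chr01\t20\t.\tG\tA\t20\tPASS\t.\tGT\t0\t1\t1",
        "chr01\t30\t.\tT\tC\t45\tPASS\t.\tGT\t0\t.\t1",
        "chr01\t40\t.\tC\tG\t30\tPASS\t.\tGT\t1\t1\t0",
        "chr01\t50\t.\tA\tAT\t50\tPASS\t.\tGT\t0\t1\t1",
        "",
    ]))
    return path
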