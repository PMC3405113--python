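"""Input parsing, SNP filtering, functional site classification and QC.

Variants come in as VCF (haploid or homozygous-diploid-coded genotypes),
gene models as GFF3, the reference as FASTA (ambiguous bases allowed).
Every genomic position is assigned exactly one primary class —
coding exon, intron, 5'/3' UTR or intergenic — with coding positions
additionally flagged fourfold-degenerate when all four bases at that
codon position encode the same amino acid.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
import gffutils
from Bio import SeqIO
from Bio.Data import CodonTable
from skbio import TreeNode

from .datatypes import (
    EXON,
    INTERGENIC,
    INTRON,
    MISSING,
    SITE_CLASSES,
    UTR3,
    UTR5,
    CallableMask,
    CodonMap,
    GenotypeMatrix,
    SiteAnnotation,
    VCFParseError,
)

_BASES = ("A", "C", "G", "T")
_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _translate(codon: str) -> str:
    if codon in _STANDARD.stop_codons:
        return "*"
    return _STANDARD.forward_table[codon]


def _fourfold_table() -> dict[tuple[str, int], bool]:
    """(codon, offset) -> True when every base at offset keeps the amino acid."""
    table = {}
    for b0 in _BASES:
        for b1 in _BASES:
            for b2 in _BASES:
                codon = b0 + b1 + b2
                for off in range(3):
                    aas = {
                        _translate(codon[:off] + b + codon[off + 1:])
                        for b in _BASES
                    }
                    table[(codon, off)] = len(aas) == 1
    return table


_FOURFOLD = _fourfold_table()


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _haploid_call(gt: tuple) -> int:
    """Collapse a GT tuple to a haploid code; reject heterozygotes."""
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return MISSING
    if len(set(alleles)) > 1:
        raise VCFParseError(
            "heterozygous genotype in a haploid panel (mixed ploidy)")
    return int(alleles[0])


def read_genotype_table(vcf_path: str | os.PathLike,
                        quality_threshold: float = 30.0) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix` of filtered biallelic SNPs.

    Only biallelic SNP records with QUAL strictly greater than
    ``quality_threshold`` are retained; records with indel alleles are
    counted on the returned matrix's ``n_indels`` attribute and records
    with more than one alternate allele are dropped.  Genotypes must be
    haploid or homozygous-diploid-coded; heterozygotes raise
    :class:`VCFParseError`.
    """
    try:
        vcf = pysam.VariantFile(os.fspath(vcf_path))
    except (OSError, ValueError) as exc:
        raise VCFParseError(f"cannot parse VCF {vcf_path}: {exc}") from exc
    strain_ids = list(vcf.header.samples)
    chroms, positions, refs, alts = [], [], [], []
    columns = []
    n_indels = 0
    record_no = 0
    try:
        for rec in vcf:
            record_no += 1
            if rec.alts is None:
                continue
            if len(rec.ref) > 1 or any(len(a) != 1 for a in rec.alts):
                n_indels += 1
                continue
            if len(rec.alts) != 1:
                continue  # multiallelic SNP: outside the biallelic matrix
            if rec.qual is None or not rec.qual > quality_threshold:
                continue
            calls = [_haploid_call(rec.samples[s]["GT"]) for s in strain_ids]
            chroms.append(rec.chrom)
            positions.append(rec.pos)
            refs.append(rec.ref)
            alts.append(rec.alts[0])
            columns.append(calls)
    except VCFParseError:
        raise
    except Exception as exc:  # malformed record mid-file
        raise VCFParseError(
            f"malformed VCF record #{record_no} in {vcf_path}: {exc}") from exc
    calls = (np.array(columns, dtype=np.int8).T if columns
             else np.empty((len(strain_ids), 0), dtype=np.int8))
    matrix = GenotypeMatrix(
        strain_ids=strain_ids,
        chromosomes=np.array(chroms, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype="<U1"),
        alt=np.array(alts, dtype="<U1"),
        calls=calls,
    )
    matrix.n_indels = n_indels
    return matrix


# ---------------------------------------------------------------------------
# FASTA / callable mask
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, np.ndarray]:
    """Reference sequences as per-chromosome arrays of single characters."""
    seqs = {}
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        seqs[rec.id] = np.frombuffer(
            str(rec.seq).upper().encode(), dtype="S1").astype("<U1")
    return seqs


def read_callable_mask(path: str | os.PathLike,
                       chromosome_lengths: dict[str, int]) -> CallableMask:
    """Read a BED (0-based, half-open) of fully sequenced intervals."""
    mask = {c: np.zeros(n, dtype=bool) for c, n in chromosome_lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split()[:3]
            mask[chrom][int(start):int(end)] = True
    return CallableMask(mask=mask)


def write_callable_mask(mask: CallableMask, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, arr in mask.mask.items():
            padded = np.concatenate(([False], arr, [False]))
            edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
            for start, end in zip(edges[::2], edges[1::2]):
                fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Gene models and site classification
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One transcript's worth of features in 0-based half-open coordinates."""

    gene_id: str
    chromosome: str
    strand: str
    start0: int
    end0: int
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    exons: list[tuple[int, int]] = field(default_factory=list)


def parse_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Load gene models (CDS/UTR/exon blocks per gene) from GFF3."""
    db = gffutils.create_db(os.fspath(path), dbfn=":memory:",
                            merge_strategy="create_unique", keep_order=True)
    models = []
    for gene in db.features_of_type("gene"):
        model = GeneModel(
            gene_id=gene.id,
            chromosome=gene.seqid,
            strand=gene.strand,
            start0=gene.start - 1,
            end0=gene.end,
        )
        for ftype, dest in (("CDS", model.cds),
                            ("five_prime_UTR", model.utr5),
                            ("three_prime_UTR", model.utr3),
                            ("exon", model.exons)):
            for feat in db.children(gene, featuretype=ftype, order_by="start"):
                dest.append((feat.start - 1, feat.end))
        models.append(model)
    models.sort(key=lambda m: (m.chromosome, m.start0, m.gene_id))
    return models


def annotate_models(models: list[GeneModel],
                    reference: dict[str, np.ndarray]) -> SiteAnnotation:
    """Paint per-position classes and codon bookkeeping from gene models.

    Precedence CDS > UTR > intron > intergenic is realised by painting
    the classes in ascending rank, so the strongest label wins at
    overlaps.  Where two genes' CDS overlap, codon identity is taken
    from the first gene by coordinate then id (first writer wins).
    """
    classes = {c: np.full(len(seq), INTERGENIC, dtype=np.uint8)
               for c, seq in reference.items()}
    fourfold = {c: np.zeros(len(s), dtype=bool) for c, s in reference.items()}
    codon_maps = {c: CodonMap.empty(len(s)) for c, s in reference.items()}

    for model in models:
        classes[model.chromosome][model.start0:model.end0] = INTRON
    for model in models:
        for s, e in model.utr5:
            classes[model.chromosome][s:e] = UTR5
        for s, e in model.utr3:
            classes[model.chromosome][s:e] = UTR3
    for model in models:
        for s, e in model.cds:
            classes[model.chromosome][s:e] = EXON

    for model in sorted(models, key=lambda m: (m.chromosome, m.start0,
                                               m.gene_id)):
        _paint_codons(model, reference[model.chromosome],
                      codon_maps[model.chromosome],
                      fourfold[model.chromosome])
    return SiteAnnotation(classes=classes, fourfold=fourfold,
                          codon_maps=codon_maps)


def _paint_codons(model: GeneModel, seq: np.ndarray, cmap: CodonMap,
                  fourfold: np.ndarray) -> None:
    if not model.cds:
        return
    coords = np.concatenate(
        [np.arange(s, e) for s, e in sorted(model.cds)])
    if model.strand == "-":
        coords = coords[::-1]
    if coords.size % 3:
        warnings.warn(
            f"CDS length of {model.gene_id} not divisible by 3; "
            "codon subclassing skipped for this model")
        return
    for k in range(coords.size // 3):
        triplet = coords[3 * k:3 * k + 3]
        codon = _coding_bases(seq, triplet, model.strand)
        if "N" in codon:
            continue
        for off, p in enumerate(triplet):
            if cmap.offset[p] != -1:
                continue  # earlier gene already owns this position
            cmap.base0[p], cmap.base1[p], cmap.base2[p] = triplet
            cmap.offset[p] = off
            cmap.strand[p] = model.strand
            fourfold[p] = _FOURFOLD[(codon, off)]


def _coding_bases(seq: np.ndarray, coords: np.ndarray, strand: str) -> str:
    bases = [str(seq[p]) for p in coords]
    if strand == "-":
        bases = [_COMPLEMENT.get(b, "N") for b in bases]
    return "".join(bases)


def classify_sites(annotation_path: str | os.PathLike,
                   reference_path: str | os.PathLike) -> SiteAnnotation:
    """Assign every reference position to a functional class.

    Reads gene models from GFF3 and the genome from FASTA; see
    :func:`annotate_models` for the painting rules.
    """
    reference = read_fasta(reference_path)
    models = parse_gff3(annotation_path)
    return annotate_models(models, reference)


def classify_snp_effect(ref_codon: str, alt_codon: str) -> str:
    """'synonymous' or 'nonsynonymous' for a single-base codon change."""
    ref_codon, alt_codon = ref_codon.upper(), alt_codon.upper()
    for codon in (ref_codon, alt_codon):
        if len(codon) != 3 or any(b not in _BASES for b in codon):
            raise ValueError(f"not an unambiguous codon: {codon!r}")
    diffs = sum(a != b for a, b in zip(ref_codon, alt_codon))
    if diffs == 0:
        raise ValueError("codons are identical: no SNP to classify")
    if diffs > 1:
        raise ValueError("codons differ at more than one position")
    return ("synonymous" if _translate(ref_codon) == _translate(alt_codon)
            else "nonsynonymous")


def classify_variants(matrix: GenotypeMatrix, annotation: SiteAnnotation,
                      reference: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-SNP primary class plus coding subclass.

    Returns a frame with columns chromosome, position, site_class,
    subclass (synonymous / nonsynonymous / '' outside CDS) and a
    fourfold flag for SNPs at fourfold-degenerate positions.
    """
    codes = annotation.site_class_codes(matrix.chromosomes, matrix.positions)
    fourfold = annotation.fourfold_at(matrix.chromosomes, matrix.positions)
    subclass = []
    for i in range(matrix.n_sites):
        if codes[i] != EXON:
            subclass.append("")
            continue
        chrom = str(matrix.chromosomes[i])
        cmap = annotation.codon_maps.get(chrom)
        p = int(matrix.positions[i]) - 1
        if cmap is None or cmap.offset[p] == -1:
            subclass.append("")
            continue
        triplet = np.array([cmap.base0[p], cmap.base1[p], cmap.base2[p]])
        strand = str(cmap.strand[p])
        ref_codon = _coding_bases(reference[chrom], triplet, strand)
        alt = str(matrix.alt[i])
        coding_alt = alt if strand == "+" else _COMPLEMENT[alt]
        off = int(cmap.offset[p])
        alt_codon = ref_codon[:off] + coding_alt + ref_codon[off + 1:]
        if "N" in ref_codon:
            subclass.append("")
            continue
        subclass.append(classify_snp_effect(ref_codon, alt_codon))
    return pd.DataFrame({
        "chromosome": matrix.chromosomes.astype(str),
        "position": matrix.positions,
        "site_class": [SITE_CLASSES[c] for c in codes],
        "subclass": subclass,
        "fourfold": fourfold,
    })


# ---------------------------------------------------------------------------
# Window QC
# ---------------------------------------------------------------------------

def window_qc(reference: dict[str, np.ndarray], annotation: SiteAnnotation,
              mask: CallableMask, window_size: int) -> pd.DataFrame:
    """Per-window intergenic, ambiguous-reference and callability fractions.

    Windows tile each chromosome from position 1 in non-overlapping
    blocks of ``window_size``; a final partial window keeps its true
    length as denominator.  Reported coordinates are 1-based with an
    exclusive end.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    rows = []
    for chrom, seq in reference.items():
        codes = annotation.classes[chrom]
        callable_arr = mask.mask[chrom]
        for start0 in range(0, len(seq), window_size):
            end0 = min(start0 + window_size, len(seq))
            window = slice(start0, end0)
            rows.append({
                "chromosome": chrom,
                "start": start0 + 1,
                "end": end0 + 1,
                "length": end0 - start0,
                "fraction_intergenic": float(
                    (codes[window] == INTERGENIC).mean()),
                "fraction_ambiguous_reference": float(
                    (seq[window] == "N").mean()),
                "fraction_fully_sequenced": float(callable_arr[window].mean()),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree: TreeNode, path: str | os.PathLike) -> None:
    """Serialize a tree to Newick; round-trips through :func:`read_newick`."""
    if tree is None or (tree.is_tip() and tree.name is None):
        raise ValueError("cannot serialize an empty tree")
    tree.write(os.fspath(path), format="newick")


def read_newick(path: str | os.PathLike) -> TreeNode:
    return TreeNode.read(os.fspath(path), format="newick")
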