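"""Synthetic haploid resequencing panels with known truth.

The generator emulates a 12-strain haploid panel of a unicellular alga:
two diverged subpopulations (Groups I and II), species-wide diversity
around theta = 0.002/base, recombination, a gene/intron/UTR/intergenic
genome layout, lowered intergenic diversity, and reference
incompleteness (ambiguous tracts) concentrated where intergenic DNA is
— one chromosome is laid out intergenic-rich to reproduce the
ascertainment signature such regions create.  Outputs can be emitted as
VCF + GFF3 + FASTA + metadata + truth files that parse back through
:mod:`chlamypop.io_annotation` into an identical panel.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import _coalescent
from .datatypes import (
    CLASS_CODE,
    INTERGENIC,
    MISSING,
    CallableMask,
    GenotypeMatrix,
    SiteAnnotation,
)
from .io_annotation import GeneModel, annotate_models, write_callable_mask

_DEF_GENIC = {"exon": 0.28, "intron": 0.30, "utr5": 0.09, "utr3": 0.13}


def default_class_layout(n_chromosomes: int = 17,
                         intergenic: float = 0.20,
                         intergenic_rich: dict[int, float] | None = None
                         ) -> list[dict[str, float]]:
    """Per-chromosome class fractions; chromosome 15 is intergenic-rich.

    Genic classes keep their relative proportions as the intergenic
    share varies, mirroring the contrast between a typical chromosome
    (~12-28% intergenic) and the intergenic-rich one (~48%).
    """
    if intergenic_rich is None:
        intergenic_rich = {14: 0.48} if n_chromosomes >= 15 else {}
    layout = []
    for i in range(n_chromosomes):
        ig = intergenic_rich.get(i, intergenic)
        scale = (1.0 - ig) / sum(_DEF_GENIC.values())
        fractions = {k: v * scale for k, v in _DEF_GENIC.items()}
        fractions["intergenic"] = ig
        layout.append(fractions)
    return layout


@dataclass
class SimulationConfig:
    """Generating parameters of a synthetic panel.

    Defaults describe the study conditions the analyses target: a
    12-strain panel split into two groups of six, theta = 0.002/base,
    rho = 2.18e-4/base, 17 chromosomes with one intergenic-rich outlier,
    halved intergenic diversity, ambiguous reference tracts inside
    intergenic DNA and a small per-call dropout rate.
    """

    n_per_group: int = 6
    theta_per_base: float = 0.002
    rho_per_base: float = 2.18e-4
    split_depth: float = 0.35
    chromosome_lengths: list[int] = field(
        default_factory=lambda: [100_000] * 17)
    class_layout: list[dict[str, float]] | None = None
    intergenic_diversity_scale: float = 0.5
    ambiguous_tract_rate: float = 0.15
    missing_rate: float = 0.02
    indel_rate: float = 0.01
    seed: int = 0
    two_groups: bool = True

    def __post_init__(self) -> None:
        if self.class_layout is None:
            self.class_layout = default_class_layout(
                len(self.chromosome_lengths))
        if len(self.class_layout) != len(self.chromosome_lengths):
            raise ValueError("class_layout must match chromosome_lengths")
        for rate in (self.theta_per_base, self.rho_per_base,
                     self.split_depth, self.ambiguous_tract_rate,
                     self.missing_rate, self.indel_rate):
            if rate < 0:
                raise ValueError("rates must be non-negative")
        if not 0 <= self.intergenic_diversity_scale <= 1:
            raise ValueError("intergenic_diversity_scale must be in [0, 1]")
        for fr in self.class_layout:
            if abs(sum(fr.values()) - 1.0) > 1e-6:
                raise ValueError("class fractions must sum to 1")

    @property
    def n_samples(self) -> int:
        return 2 * self.n_per_group if self.two_groups else self.n_per_group

    def chromosome_names(self) -> list[str]:
        return [f"chr{i + 1:02d}" for i in range(len(self.chromosome_lengths))]


@dataclass
class SimulationTruth:
    """What the generator actually realized, for recovery tests."""

    config: SimulationConfig
    groups: dict[str, str]
    n_snps: int
    snps_per_chromosome: dict[str, int]
    snps_per_class: dict[str, int]
    callable_per_class: dict[str, int]


@dataclass
class SimulatedPanel:
    matrix: GenotypeMatrix
    annotation: SiteAnnotation
    mask: CallableMask
    truth: SimulationTruth
    reference: dict[str, np.ndarray]
    models: list[GeneModel]
    metadata: pd.DataFrame


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

_CASSETTE = 6000  # one gene plus its intergenic spacer


def _cassette_blocks(fractions: dict[str, float]) -> list[tuple[str, int]]:
    """Block layout (class label, length) of one plus-strand cassette."""
    ig = round(_CASSETTE * fractions["intergenic"])
    u5 = round(_CASSETTE * fractions["utr5"])
    u3 = round(_CASSETTE * fractions["utr3"])
    introns = round(_CASSETTE * fractions["intron"])
    coding = _CASSETTE - ig - u5 - u3 - introns
    ig += coding % 3  # keep the CDS a whole number of codons
    coding -= coding % 3
    e = coding // 3
    exon_lengths = [e, e, coding - 2 * e]  # codons split across introns
    i = introns // 2
    intron_lengths = [i, introns - i]
    return [
        ("intergenic", ig),
        ("utr5", u5),
        ("exon", exon_lengths[0]),
        ("intron", intron_lengths[0]),
        ("exon", exon_lengths[1]),
        ("intron", intron_lengths[1]),
        ("exon", exon_lengths[2]),
        ("utr3", u3),
    ]


def build_gene_models(chromosome_names: list[str],
                      chromosome_lengths: list[int],
                      class_layout: list[dict[str, float]]
                      ) -> list[GeneModel]:
    """Deterministic repeating gene cassettes matching the class fractions.

    Gene strand alternates along each chromosome; leftover bases at the
    chromosome end stay intergenic.
    """
    models = []
    for ci, (chrom, length) in enumerate(zip(chromosome_names,
                                             chromosome_lengths)):
        blocks = _cassette_blocks(class_layout[ci])
        start = 0
        gi = 0
        while start + _CASSETTE <= length:
            strand = "+" if gi % 2 == 0 else "-"
            ordered = blocks if strand == "+" else (
                [blocks[0]] + [b for b in reversed(blocks[1:])])
            pos = start
            cds, utr5, utr3 = [], [], []
            gene_start = None
            for label, blen in ordered:
                if blen == 0:
                    continue
                block = (pos, pos + blen)
                if label != "intergenic" and gene_start is None:
                    gene_start = pos
                if label == "exon":
                    cds.append(block)
                elif label == "utr5":
                    utr5.append(block)
                elif label == "utr3":
                    utr3.append(block)
                pos += blen
            gi += 1
            model = GeneModel(
                gene_id=f"{chrom}.g{gi}",
                chromosome=chrom,
                strand=strand,
                start0=gene_start,
                end0=pos,
                cds=sorted(cds),
                utr5=sorted(utr5),
                utr3=sorted(utr3),
            )
            # exons = maximal runs of UTR+CDS
            featured = sorted(cds + utr5 + utr3)
            exons: list[tuple[int, int]] = []
            for s, e in featured:
                if exons and exons[-1][1] == s:
                    exons[-1] = (exons[-1][0], e)
                else:
                    exons.append((s, e))
            model.exons = exons
            models.append(model)
            start += _CASSETTE
    return models


def _reference_sequences(config: SimulationConfig,
                         annotation_classes: dict[str, np.ndarray],
                         rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Random reference with N tracts centred in intergenic runs."""
    reference = {}
    for chrom, codes in annotation_classes.items():
        seq = rng.choice(np.array(list("ACGT")), size=codes.size)
        if config.ambiguous_tract_rate > 0:
            inter = np.concatenate(
                ([False], codes == INTERGENIC, [False]))
            edges = np.flatnonzero(np.diff(inter.astype(np.int8)))
            for s, e in zip(edges[::2], edges[1::2]):
                tract = int(round((e - s) * config.ambiguous_tract_rate))
                if tract:
                    mid = (s + e) // 2
                    seq[mid - tract // 2: mid - tract // 2 + tract] = "N"
        reference[chrom] = seq
    return reference


# ---------------------------------------------------------------------------
# panel simulation
# ---------------------------------------------------------------------------

def simulate_panel(config: SimulationConfig) -> SimulatedPanel:
    """Generate a haploid panel under the configured coalescent model.

    Each chromosome is an independent coalescent-with-recombination
    realization; mutations follow infinite sites on the integer grid.
    Intergenic mutations are thinned by ``intergenic_diversity_scale``,
    mutations falling in ambiguous (N) reference tracts are removed as
    uncallable, and per-call dropout produces missing genotypes.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    names = config.chromosome_names()
    models = build_gene_models(names, config.chromosome_lengths,
                               config.class_layout)

    # layout first (deterministic), then sequence, then genealogy
    placeholder = {c: np.full(L, "A", dtype="<U1")
                   for c, L in zip(names, config.chromosome_lengths)}
    class_only = annotate_models(models, placeholder)
    reference = _reference_sequences(config, class_only.classes, rng)
    annotation = annotate_models(models, reference)

    group_sizes = ((config.n_per_group, config.n_per_group)
                   if config.two_groups else None)
    strain_ids = [f"S{i + 1:02d}" for i in range(n)]
    groups = {s: ("I" if config.two_groups and i < config.n_per_group
                  else "II" if config.two_groups else "I")
              for i, s in enumerate(strain_ids)}

    chroms_col, pos_col, ref_col, alt_col, call_cols = [], [], [], [], []
    callable_mask = {}
    p_invariant_callable = (1.0 - config.missing_rate) ** n
    base_set = np.array(list("ACGT"))

    for chrom, length in zip(names, config.chromosome_lengths):
        mutations = _coalescent.simulate_mutations(
            n, length, config.theta_per_base, config.rho_per_base, rng,
            group_sizes=group_sizes, split_depth=config.split_depth)
        positions, masks = _coalescent.assign_integer_positions(
            mutations, length)
        codes = annotation.classes[chrom][positions]
        seq = reference[chrom]

        keep = np.ones(positions.size, dtype=bool)
        if config.intergenic_diversity_scale < 1.0:
            inter = codes == INTERGENIC
            keep[inter] = (rng.random(int(inter.sum()))
                           < config.intergenic_diversity_scale)
        keep &= seq[positions] != "N"
        positions, masks = positions[keep], masks[keep]

        calls = np.zeros((n, positions.size), dtype=np.int8)
        for j, m in enumerate(masks):
            for s in range(n):
                if (int(m) >> s) & 1:
                    calls[s, j] = 1
        if config.missing_rate > 0:
            calls[rng.random(calls.shape) < config.missing_rate] = MISSING

        observed = ((calls == 1).sum(axis=0) > 0)
        positions, calls = positions[observed], calls[:, observed]

        chrom_callable = (seq != "N") & (
            rng.random(length) < p_invariant_callable)
        chrom_callable[positions] = (calls != MISSING).all(axis=0)
        callable_mask[chrom] = chrom_callable

        ref_bases = seq[positions]
        alt_bases = np.empty(positions.size, dtype="<U1")
        for j, rb in enumerate(ref_bases):
            choices = base_set[base_set != rb]
            alt_bases[j] = choices[rng.integers(3)]

        chroms_col.append(np.full(positions.size, chrom, dtype=object))
        pos_col.append(positions + 1)
        ref_col.append(ref_bases)
        alt_col.append(alt_bases)
        call_cols.append(calls)

    matrix = GenotypeMatrix(
        strain_ids=strain_ids,
        chromosomes=np.concatenate(chroms_col),
        positions=np.concatenate(pos_col),
        ref=np.concatenate(ref_col),
        alt=np.concatenate(alt_col),
        calls=np.concatenate(call_cols, axis=1),
    )
    mask = CallableMask(mask=callable_mask)

    # latitude with a monotone link to Group II ancestry plus noise
    latitude = np.array([
        46.0 - (9.0 if groups[s] == "II" else 0.0) for s in strain_ids
    ]) + rng.normal(0.0, 1.0, size=n)
    metadata = pd.DataFrame({
        "strain": strain_ids,
        "group": [groups[s] for s in strain_ids],
        "latitude": np.round(latitude, 4),
    })

    class_codes = annotation.site_class_codes(matrix.chromosomes,
                                              matrix.positions)
    snps_per_class = {name: int((class_codes == code).sum())
                      for name, code in CLASS_CODE.items()}
    truth = SimulationTruth(
        config=config,
        groups=groups,
        n_snps=matrix.n_sites,
        snps_per_chromosome={c: int((matrix.chromosomes == c).sum())
                             for c in names},
        snps_per_class=snps_per_class,
        callable_per_class=mask.counts_by_class(annotation),
    )
    return SimulatedPanel(matrix=matrix, annotation=annotation, mask=mask,
                          truth=truth, reference=reference, models=models,
                          metadata=metadata)


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def emit_files(panel: SimulatedPanel, out_dir: str | os.PathLike) -> dict:
    """Write VCF, GFF3, FASTA, metadata TSV, callable BED and truth JSON.

    The VCF round-trips through
    :func:`chlamypop.io_annotation.read_genotype_table` into a matrix
    equal to ``panel.matrix``; a few indel records are interleaved to
    exercise the reader's indel routing.
    """
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    paths = {
        "vcf": os.path.join(out, "panel.vcf"),
        "gff3": os.path.join(out, "annotation.gff3"),
        "fasta": os.path.join(out, "reference.fa"),
        "metadata": os.path.join(out, "metadata.tsv"),
        "callable": os.path.join(out, "callable.bed"),
        "truth": os.path.join(out, "truth.json"),
    }
    _write_vcf(panel, paths["vcf"])
    _write_gff3(panel.models, paths["gff3"])
    _write_fasta(panel.reference, paths["fasta"])
    panel.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    write_callable_mask(panel.mask, paths["callable"])
    truth = asdict(panel.truth)
    truth["config"] = asdict(panel.truth.config)
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def _write_vcf(panel: SimulatedPanel, path: str) -> None:
    config = panel.truth.config
    rng = np.random.default_rng(config.seed + 1_000_003)
    matrix = panel.matrix
    n_indels_target = int(round(config.indel_rate * matrix.n_sites))
    indels = _draw_indels(panel, n_indels_target, rng)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=chlamypop-simulate\n")
        for chrom, seq in panel.reference.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description='
                 '"Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.strain_ids) + "\n")
        rows = []
        for i in range(matrix.n_sites):
            gts = "\t".join(
                "." if c == MISSING else str(int(c))
                for c in matrix.calls[:, i])
            rows.append((str(matrix.chromosomes[i]), int(matrix.positions[i]),
                         f"{matrix.ref[i]}\t{matrix.alt[i]}\t45\tPASS\t.\tGT\t"
                         + gts))
        rows.extend(indels)
        order = {c: k for k, c in enumerate(panel.reference)}
        rows.sort(key=lambda r: (order[r[0]], r[1]))
        for chrom, pos, rest in rows:
            fh.write(f"{chrom}\t{pos}\t.\t{rest}\n")


def _draw_indels(panel: SimulatedPanel, count: int,
                 rng: np.random.Generator) -> list[tuple[str, int, str]]:
    rows = []
    n = panel.matrix.n_strains
    snp_positions = {
        (str(c), int(p))
        for c, p in zip(panel.matrix.chromosomes, panel.matrix.positions)}
    chroms = list(panel.reference)
    for _ in range(count):
        chrom = chroms[rng.integers(len(chroms))]
        seq = panel.reference[chrom]
        for _attempt in range(20):
            p = int(rng.integers(len(seq)))
            if seq[p] != "N" and (chrom, p + 1) not in snp_positions:
                break
        else:
            continue
        ref = str(seq[p])
        alt = ref + "ACGT"[rng.integers(4)]
        gts = "\t".join(str(int(b)) for b in rng.integers(2, size=n))
        rows.append((chrom, p + 1, f"{ref}\t{alt}\t45\tPASS\t.\tGT\t{gts}"))
    return rows


def _write_gff3(models: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gid = m.gene_id
            fh.write(f"{m.chromosome}\tchlamypop\tgene\t{m.start0 + 1}\t"
                     f"{m.end0}\t.\t{m.strand}\t.\tID={gid}\n")
            fh.write(f"{m.chromosome}\tchlamypop\tmRNA\t{m.start0 + 1}\t"
                     f"{m.end0}\t.\t{m.strand}\t.\tID={gid}.t1;Parent={gid}\n")
            for k, (s, e) in enumerate(m.exons, 1):
                fh.write(f"{m.chromosome}\tchlamypop\texon\t{s + 1}\t{e}\t.\t"
                         f"{m.strand}\t.\tID={gid}.e{k};Parent={gid}.t1\n")
            cds_order = m.cds if m.strand == "+" else list(reversed(m.cds))
            coding_seen = 0
            phases = {}
            for s, e in cds_order:
                phases[(s, e)] = (3 - coding_seen % 3) % 3
                coding_seen += e - s
            for k, (s, e) in enumerate(m.cds, 1):
                fh.write(f"{m.chromosome}\tchlamypop\tCDS\t{s + 1}\t{e}\t.\t"
                         f"{m.strand}\t{phases[(s, e)]}\t"
                         f"ID={gid}.c{k};Parent={gid}.t1\n")
            for label, blocks in (("five_prime_UTR", m.utr5),
                                  ("three_prime_UTR", m.utr3)):
                for k, (s, e) in enumerate(blocks, 1):
                    fh.write(f"{m.chromosome}\tchlamypop\t{label}\t{s + 1}\t"
                             f"{e}\t.\t{m.strand}\t.\t"
                             f"ID={gid}.u{label[0]}{k};Parent={gid}.t1\n")


def _write_fasta(reference: dict[str, np.ndarray], path: str,
                 width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            s = "".join(seq)
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")
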