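"""Core in-memory containers for the haploid panel analyses.

The panel is held as a strains x sites matrix of haploid 0/1 calls
(``MISSING`` = -1 marks a dropped call), together with per-site
chromosome, position and allele metadata.  Functional annotation and
callability are held as dense per-chromosome arrays so that window and
site-class summaries are simple vectorised reductions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

MISSING: int = -1

#: primary functional site classes, in paint precedence order
#: (exon strongest, intergenic background)
SITE_CLASSES = ("exon", "intron", "utr5", "utr3", "intergenic")
CLASS_CODE = {name: i for i, name in enumerate(SITE_CLASSES)}
EXON, INTRON, UTR5, UTR3, INTERGENIC = range(5)


class VCFParseError(ValueError):
    """Raised when a variant record cannot be parsed or violates ploidy."""


@dataclass
class GenotypeMatrix:
    """Biallelic haploid SNP calls for a panel of strains.

    Attributes
    ----------
    strain_ids : list of str
        Panel member labels, one per matrix row.
    chromosomes : ndarray of str
        Per-site chromosome identifier.
    positions : ndarray of int
        Per-site 1-based coordinate, strictly increasing within a
        chromosome.
    ref, alt : ndarray of single characters
        Reference and alternate alleles per site.
    calls : ndarray, shape (n_strains, n_sites), int8
        0 = reference allele, 1 = alternate allele, -1 = missing.
    """

    strain_ids: list[str]
    chromosomes: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.chromosomes = np.asarray(self.chromosomes)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref)
        self.alt = np.asarray(self.alt)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2 or self.calls.shape[0] != len(self.strain_ids):
            raise ValueError("calls must be (n_strains, n_sites)")
        if self.calls.shape[1] != self.positions.size:
            raise ValueError("site metadata does not match calls matrix")
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            raise ValueError("calls may only contain 0, 1 or the missing sentinel")
        for chrom in self.chromosome_order():
            pos = self.positions[self.chromosomes == chrom]
            if pos.size > 1 and not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {chrom}")

    # -- basic shape --------------------------------------------------
    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def chromosome_order(self) -> list[str]:
        """Chromosome ids in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.chromosomes:
            seen.setdefault(str(c), None)
        return list(seen)

    # -- subsetting ---------------------------------------------------
    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            strain_ids=list(self.strain_ids),
            chromosomes=self.chromosomes[index],
            positions=self.positions[index],
            ref=self.ref[index],
            alt=self.alt[index],
            calls=self.calls[:, index],
        )

    def take_strains(self, strains: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.strain_ids.index(s) for s in strains]
        return GenotypeMatrix(
            strain_ids=[self.strain_ids[i] for i in idx],
            chromosomes=self.chromosomes,
            positions=self.positions,
            ref=self.ref,
            alt=self.alt,
            calls=self.calls[idx, :],
        )

    def sites_on(self, chromosome: str) -> np.ndarray:
        return np.flatnonzero(self.chromosomes == chromosome)

    # -- masks --------------------------------------------------------
    def complete_sites(self) -> np.ndarray:
        """Boolean mask of sites called in every strain (strict mode)."""
        return (self.calls != MISSING).all(axis=0)

    def alt_counts(self) -> np.ndarray:
        """Per-site count of alternate alleles among called strains."""
        return (self.calls == 1).sum(axis=0)

    def called_counts(self) -> np.ndarray:
        return (self.calls != MISSING).sum(axis=0)

    def segregating_sites(self) -> np.ndarray:
        """Mask of sites polymorphic among the called strains."""
        ac = self.alt_counts()
        an = self.called_counts()
        return (ac > 0) & (ac < an)

    def __eq__(self, other: object) -> bool:  # round-trip checks
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.strain_ids == other.strain_ids
            and np.array_equal(self.chromosomes, other.chromosomes)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class CodonMap:
    """Per-position codon bookkeeping for CDS sites of one chromosome.

    ``base0/1/2`` give the genomic 0-based coordinates of the codon's
    three bases in coding order (so they decrease along minus-strand
    genes); ``offset`` is the within-codon index of the position itself
    and ``strand`` the coding strand.  Non-CDS positions carry -1.
    """

    base0: np.ndarray
    base1: np.ndarray
    base2: np.ndarray
    offset: np.ndarray
    strand: np.ndarray  # '+', '-' or ' '

    @classmethod
    def empty(cls, length: int) -> "CodonMap":
        m1 = np.full(length, -1, dtype=np.int64)
        return cls(m1, m1.copy(), m1.copy(),
                   np.full(length, -1, dtype=np.int8),
                   np.full(length, " ", dtype="<U1"))


@dataclass
class SiteAnnotation:
    """Dense per-chromosome functional class labels.

    ``classes[chrom]`` is a uint8 array (codes in :data:`CLASS_CODE`)
    covering every base of the chromosome; ``fourfold[chrom]`` flags CDS
    positions at which all four bases encode the same amino acid.
    """

    classes: dict[str, np.ndarray]
    fourfold: dict[str, np.ndarray]
    codon_maps: dict[str, CodonMap] = field(default_factory=dict)

    def class_at(self, chromosome: str, position: int) -> str:
        """Primary class of a 1-based position."""
        return SITE_CLASSES[int(self.classes[chromosome][position - 1])]

    def chromosome_length(self, chromosome: str) -> int:
        return int(self.classes[chromosome].size)

    def site_class_codes(self, chromosomes: np.ndarray,
                         positions: np.ndarray) -> np.ndarray:
        """Vectorised class codes for (chromosome, 1-based position) pairs."""
        out = np.empty(positions.size, dtype=np.uint8)
        for chrom in np.unique(chromosomes):
            sel = chromosomes == chrom
            out[sel] = self.classes[str(chrom)][positions[sel] - 1]
        return out

    def fourfold_at(self, chromosomes: np.ndarray,
                    positions: np.ndarray) -> np.ndarray:
        out = np.zeros(positions.size, dtype=bool)
        for chrom in np.unique(chromosomes):
            sel = chromosomes == chrom
            out[sel] = self.fourfold[str(chrom)][positions[sel] - 1]
        return out


@dataclass
class CallableMask:
    """Positions sequenced in every strain, per chromosome.

    The boolean arrays are dense over the chromosome (index = 0-based
    position).  These sites are the denominator of every per-base
    diversity estimate.
    """

    mask: dict[str, np.ndarray]

    def n_callable(self, chromosome: str | None = None) -> int:
        if chromosome is not None:
            return int(self.mask[chromosome].sum())
        return int(sum(arr.sum() for arr in self.mask.values()))

    def counts_by_class(self, annotation: SiteAnnotation) -> dict[str, int]:
        """Callable site count per functional class; values sum to total."""
        counts = dict.fromkeys(SITE_CLASSES, 0)
        for chrom, m in self.mask.items():
            codes = annotation.classes[chrom][: m.size]
            for name, code in CLASS_CODE.items():
                counts[name] += int((m & (codes == code)).sum())
        return counts

    def window_fraction(self, chromosome: str, start0: int, end0: int) -> float:
        m = self.mask[chromosome][start0:end0]
        return float(m.mean()) if m.size else float("nan")


@dataclass
class DiversityEstimate:
    """Watterson and pairwise diversity for one slice of the data."""

    S: int
    n: int
    L: int
    a_n: float
    theta_w_per_base: float
    theta_pi_per_base: float


@dataclass
class FixedDifferenceSummary:
    """Count of SNPs whose alleles sort completely between two groups."""

    n_fixed: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_fixed / self.n_total if self.n_total else float("nan")


@dataclass
class OutcrossingEstimate:
    """Effective generations of outcrossing from rho and the map rate.

    ``generations`` solves N_e = rho / (2 r) where rho = 2 N_e r is the
    population recombination rate per base and r the per-generation
    recombination fraction per base (Morgans/base).
    """

    rho_per_base: float
    r_per_base: float
    generations: float
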