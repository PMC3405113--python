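"""Linkage disequilibrium, recombination detection and rate estimation.

r-squared between two biallelic haploid sites is D^2 / (pA(1-pA)pB(1-pB))
with D = pAB - pA*pB from haplotype counts, which for 0/1 haploid calls
equals the squared Pearson correlation of the two call vectors.  Decay
curves average r^2 in non-overlapping physical-distance bins (25 kb by
default).  Recombination is detected by the four-gamete test and the
population recombination rate rho = 2*N_e*r is estimated per chromosome
by fitting the drift-recombination expectation

    E[r^2](d) ~ 1/(1 + rho*d) + 1/n

to the binned decay curve; the genome-wide rho is the average of the
per-chromosome estimates.  Solving N_e = rho/(2r) converts rho to the
effective number of generations of outcrossing, and a four-parameter
logistic Marey map (genetic vs physical position) gives local
recombination rates from cross marker data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .datatypes import MISSING, GenotypeMatrix, OutcrossingEstimate

__all__ = [
    "r_squared", "ld_pairs", "ld_decay", "ld_matrix", "four_gamete_pairs",
    "RhoEstimate", "estimate_rho", "genome_rho", "outcrossing_generations",
    "MareyFit", "marey_fit",
]


def r_squared(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    """LD r^2 between two haploid sites from jointly-called strains."""
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    both = (a != MISSING) & (b != MISSING)
    a, b = a[both].astype(float), b[both].astype(float)
    if a.size < 2:
        raise ValueError("need at least two jointly-called strains")
    pA, pB = a.mean(), b.mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic site in slice: r^2 undefined")
    pAB = (a * b).mean()
    D = pAB - pA * pB
    return float(D * D / (pA * (1 - pA) * pB * (1 - pB)))


def _complete_chromosome_slice(matrix: GenotypeMatrix, chromosome: str
                               ) -> tuple[np.ndarray, np.ndarray]:
    """(positions, calls) of fully-called polymorphic sites on a chromosome."""
    idx = matrix.sites_on(chromosome)
    sub = matrix.take_sites(idx)
    keep = sub.complete_sites() & sub.segregating_sites()
    return sub.positions[keep], sub.calls[:, keep]


def _r2_grid(calls: np.ndarray) -> np.ndarray:
    """All-pairs r^2 for complete 0/1 calls (squared Pearson correlation)."""
    with np.errstate(invalid="ignore"):
        grid = np.corrcoef(calls.T.astype(float)) ** 2
    np.fill_diagonal(grid, 1.0)
    return grid


def ld_pairs(matrix: GenotypeMatrix, chromosome: str,
             max_distance: int | None = None) -> pd.DataFrame:
    """r^2 for intra-chromosomal SNP pairs in strict (complete-call) mode."""
    pos, calls = _complete_chromosome_slice(matrix, chromosome)
    S = pos.size
    if S < 2:
        return pd.DataFrame(columns=["pos_a", "pos_b", "distance",
                                     "r_squared"])
    grid = _r2_grid(calls)
    ia, ib = np.triu_indices(S, k=1)
    dist = pos[ib] - pos[ia]
    if max_distance is not None:
        keep = dist <= max_distance
        ia, ib, dist = ia[keep], ib[keep], dist[keep]
    return pd.DataFrame({
        "pos_a": pos[ia], "pos_b": pos[ib],
        "distance": dist, "r_squared": grid[ia, ib],
    })


def ld_decay(matrix: GenotypeMatrix, bin_width: int = 25_000,
             max_distance: int | None = None,
             scope: str = "genome") -> pd.DataFrame:
    """Mean r^2 in non-overlapping distance bins.

    scope='genome' pools all intra-chromosomal pairs; scope='chromosome'
    returns one curve per chromosome.  Empty bins are reported with a
    zero pair count and a NaN mean.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    per_chrom = {}
    for chrom in matrix.chromosome_order():
        pairs = ld_pairs(matrix, chrom, max_distance=max_distance)
        if len(pairs):
            per_chrom[chrom] = pairs
    if not per_chrom:
        return pd.DataFrame(columns=["scope", "bin_start", "bin_end",
                                     "mean_r2", "n_pairs"])
    frames = []
    if scope == "genome":
        pooled = pd.concat(per_chrom.values(), ignore_index=True)
        frames.append(_bin_curve(pooled, bin_width, "genome"))
    elif scope == "chromosome":
        for chrom, pairs in per_chrom.items():
            frames.append(_bin_curve(pairs, bin_width, chrom))
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return pd.concat(frames, ignore_index=True)


def _bin_curve(pairs: pd.DataFrame, bin_width: int,
               label: str) -> pd.DataFrame:
    top = int(pairs["distance"].max())
    n_bins = top // bin_width + 1
    idx = (pairs["distance"].to_numpy() // bin_width).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=pairs["r_squared"].to_numpy(),
                       minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({
        "scope": label,
        "bin_start": np.arange(n_bins) * bin_width,
        "bin_end": (np.arange(n_bins) + 1) * bin_width,
        "mean_r2": means,
        "n_pairs": counts,
    })


def ld_matrix(matrix: GenotypeMatrix, chromosome: str,
              block_threshold: float | None = None,
              block_min_sites: int = 3):
    """Full symmetric r^2 grid for one chromosome (diagonal = 1).

    With ``block_threshold`` also returns runs of consecutive SNPs whose
    adjacent-pair r^2 stays above the threshold for at least
    ``block_min_sites`` sites — a simple haplotype-block heuristic.
    """
    pos, calls = _complete_chromosome_slice(matrix, chromosome)
    if pos.size < 2:
        raise ValueError("chromosome needs at least two usable SNPs")
    grid = _r2_grid(calls)
    if block_threshold is None:
        return pos, grid
    adjacent = np.diag(grid, k=1)
    blocks = []
    run_start = None
    for k, v in enumerate(adjacent):
        if v >= block_threshold:
            if run_start is None:
                run_start = k
        else:
            if run_start is not None and k - run_start + 1 >= block_min_sites:
                blocks.append((int(pos[run_start]), int(pos[k])))
            run_start = None
    if run_start is not None and len(adjacent) - run_start + 1 >= block_min_sites:
        blocks.append((int(pos[run_start]), int(pos[-1])))
    return pos, grid, blocks


# ---------------------------------------------------------------------------
# four-gamete test
# ---------------------------------------------------------------------------

def four_gamete_pairs(matrix: GenotypeMatrix) -> dict:
    """Count intra-chromosomal SNP pairs showing all four haplotypes.

    Under infinite sites, observing gametes 00, 01, 10 and 11 at a pair
    of linked sites requires a recombination event between them.
    Complete-call polymorphic sites only (strict mode).
    """
    per_chrom = {}
    for chrom in matrix.chromosome_order():
        pos, calls = _complete_chromosome_slice(matrix, chromosome=chrom)
        S = pos.size
        if S < 2:
            per_chrom[chrom] = 0
            continue
        # pack each site's calls into one integer bitmask per site
        weights = 1 << np.arange(calls.shape[0], dtype=np.uint64)
        packed = (calls.astype(np.uint64).T * weights).sum(axis=1)
        full = np.uint64((1 << calls.shape[0]) - 1)
        a = packed[:, None]
        b = packed[None, :]
        has11 = (a & b) != 0
        has10 = (a & ~b & full) != 0
        has01 = (~a & full & b) != 0
        has00 = (~a & ~b & full) != 0
        viol = has11 & has10 & has01 & has00
        per_chrom[chrom] = int(np.triu(viol, k=1).sum())
    return {"total": sum(per_chrom.values()), "per_chromosome": per_chrom}


# ---------------------------------------------------------------------------
# rho estimation and outcrossing
# ---------------------------------------------------------------------------

@dataclass
class RhoEstimate:
    """Moment-fit population recombination rate for one chromosome."""

    chromosome: str
    rho_per_base: float
    amplitude: float
    n: int
    n_bins: int
    rss: float

    @property
    def rho_per_mb(self) -> float:
        return self.rho_per_base * 1e6


def estimate_rho(matrix: GenotypeMatrix, chromosome: str,
                 bin_width: int = 2_000,
                 max_distance: int | None = None) -> RhoEstimate:
    """Fit E[r^2](d) = a/(1 + rho*d) + 1/n to the binned decay curve.

    Pair-count-weighted least squares over rho >= 0 at the bin
    midpoints.  The amplitude ``a`` is profiled out in closed form at
    each candidate rho; it absorbs the genealogy-to-genealogy baseline
    of r^2 (which in coalescent samples sits well below 1 even at zero
    distance), leaving rho to be identified from the decay shape.  A
    curve with fewer than two populated bins is an error; a curve with
    no decay signal returns the rho = 0 boundary.
    """
    n = matrix.n_strains
    pairs = ld_pairs(matrix, chromosome, max_distance=max_distance)
    if not len(pairs):
        raise ValueError(f"no usable SNP pairs on {chromosome}")
    curve = _bin_curve(pairs, bin_width, chromosome)
    curve = curve[curve["n_pairs"] > 0]
    if len(curve) < 2:
        raise ValueError("decay curve has fewer than two populated bins")
    d = (curve["bin_start"].to_numpy()
         + curve["bin_end"].to_numpy()) / 2.0
    y = curve["mean_r2"].to_numpy() - 1.0 / n
    w = curve["n_pairs"].to_numpy().astype(float)

    def profiled(log_rho: float) -> tuple[float, float]:
        u = 1.0 / (1.0 + 10.0 ** log_rho * d)
        denom = float(np.sum(w * u * u))
        a = max(float(np.sum(w * u * y)) / denom, 0.0)
        return float(np.sum(w * (y - a * u) ** 2)), a

    grid = np.linspace(-9.0, -1.0, 33)
    losses = [profiled(g)[0] for g in grid]
    g0 = grid[int(np.argmin(losses))]
    res = optimize.minimize_scalar(
        lambda g: profiled(g)[0], bounds=(g0 - 0.5, g0 + 0.5),
        method="bounded")
    rho = 10.0 ** float(res.x)
    rss, amplitude = profiled(float(res.x))
    flat_rss, flat_a = profiled(-30.0)  # rho -> 0 limit: constant curve
    if flat_rss <= rss:
        rho, rss, amplitude = 0.0, flat_rss, flat_a
    return RhoEstimate(chromosome=chromosome, rho_per_base=rho,
                       amplitude=amplitude, n=n, n_bins=len(curve),
                       rss=rss)


def genome_rho(matrix: GenotypeMatrix, bin_width: int = 2_000,
               max_distance: int | None = None
               ) -> tuple[float, list[RhoEstimate]]:
    """Per-chromosome rho estimates and their plain average."""
    estimates = []
    for chrom in matrix.chromosome_order():
        try:
            estimates.append(estimate_rho(matrix, chrom, bin_width=bin_width,
                                          max_distance=max_distance))
        except ValueError as exc:
            warnings.warn(f"{chrom}: {exc}")
    if not estimates:
        raise ValueError("no chromosome yielded a rho estimate")
    return float(np.mean([e.rho_per_base for e in estimates])), estimates


def outcrossing_generations(rho_per_base: float,
                            r_per_base: float) -> OutcrossingEstimate:
    """Effective outcrossing generations N_e = rho / (2 r).

    ``r_per_base`` is the per-generation recombination fraction in
    Morgans per base (1e-7 corresponds to the canonical 0.01 cM/kb map).
    """
    if r_per_base <= 0:
        raise ValueError("r_per_base must be positive")
    if rho_per_base < 0:
        raise ValueError("rho_per_base must be non-negative")
    return OutcrossingEstimate(
        rho_per_base=rho_per_base, r_per_base=r_per_base,
        generations=rho_per_base / (2.0 * r_per_base))


# ---------------------------------------------------------------------------
# Marey map
# ---------------------------------------------------------------------------

@dataclass
class MareyFit:
    """Four-parameter logistic genetic-vs-physical map for one chromosome.

    cM(x) = lower + (upper - lower) / (1 + exp(-slope * (x - midpoint)))
    with upper >= lower and slope >= 0, so the fitted map never
    decreases; the local recombination rate is the analytic derivative.
    """

    chromosome: str
    lower: float
    upper: float
    midpoint: float
    slope: float
    rss: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.lower + (self.upper - self.lower) / (
            1.0 + np.exp(-self.slope * (x - self.midpoint)))

    def local_rate_cm_per_kb(self, x) -> np.ndarray:
        """Derivative of the fitted map, converted to cM per kb."""
        x = np.asarray(x, dtype=float)
        z = np.exp(-self.slope * (x - self.midpoint))
        deriv = (self.upper - self.lower) * self.slope * z / (1.0 + z) ** 2
        return deriv * 1_000.0


def marey_fit(markers: pd.DataFrame | list[tuple[float, float]],
              chromosome: str = "") -> MareyFit:
    """Least-squares logistic fit of cM against physical position.

    ``markers`` is a frame with columns (bp, cM) or a list of (bp, cM)
    tuples; at least five markers are required.  Non-monotone marker
    pairs are tolerated as noise — monotonicity is enforced on the fit,
    not the data.
    """
    if isinstance(markers, pd.DataFrame):
        bp = markers["bp"].to_numpy(dtype=float)
        cm = markers["cM"].to_numpy(dtype=float)
    else:
        arr = np.asarray(markers, dtype=float)
        bp, cm = arr[:, 0], arr[:, 1]
    if bp.size < 5:
        raise ValueError("need at least five markers for the Marey fit")
    span = bp.max() - bp.min()
    rise = cm.max() - cm.min()

    def model(params: np.ndarray) -> np.ndarray:
        lower, d_upper, midpoint, slope = params
        return lower + d_upper / (1.0 + np.exp(-slope * (bp - midpoint)))

    def residual(params: np.ndarray) -> np.ndarray:
        return model(params) - cm

    x0 = np.array([cm.min(), max(rise, 1e-9), bp.mean(),
                   4.0 / max(span, 1.0)])
    res = optimize.least_squares(
        residual, x0,
        bounds=([-np.inf, 0.0, -np.inf, 0.0],
                [np.inf, np.inf, np.inf, np.inf]))
    lower, d_upper, midpoint, slope = res.x
    return MareyFit(chromosome=chromosome, lower=float(lower),
                    upper=float(lower + d_upper), midpoint=float(midpoint),
                    slope=float(slope), rss=float(2 * res.cost))
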