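"""Nucleotide diversity estimation: theta_W, theta_pi, windows, contrasts.

Watterson's estimator theta_W = S / (a_n * L) counts segregating sites,
with a_n the (n-1)th harmonic number and L the callable length; theta_pi
is the mean number of pairwise differences per base.  Both are reported
per site class and in non-overlapping genomic windows, normalised by
the callable length of the slice being summarised.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    CLASS_CODE,
    MISSING,
    CallableMask,
    DiversityEstimate,
    GenotypeMatrix,
    SiteAnnotation,
)

__all__ = [
    "harmonic_number",
    "watterson_theta",
    "pi_theta",
    "site_pi_sum",
    "diversity_estimate",
    "class_diversity",
    "windowed_diversity",
    "chromosome_contrast",
    "spearman_correlation",
]


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i, the Watterson normaliser."""
    return float(np.sum(1.0 / np.arange(1, n)))


def watterson_theta(S: int, n: int, L: int) -> float:
    """Per-base Watterson estimator S / (a_n * L)."""
    if n < 2:
        raise ValueError("Watterson's estimator needs n >= 2")
    if S < 0:
        raise ValueError("negative segregating-site count")
    if L == 0:
        return float("nan")  # undefined, not zero
    return S / (harmonic_number(n) * L)


def site_pi_sum(calls: np.ndarray) -> float:
    """Sum over sites of the mean pairwise difference, complete calls.

    At a site with j alternate alleles out of n, the mean difference
    over the C(n, 2) strain pairs is j*(n-j)/C(n, 2).
    """
    n = calls.shape[0]
    if n < 2:
        raise ValueError("pairwise diversity needs n >= 2")
    j = (calls == 1).sum(axis=0)
    return float(np.sum(j * (n - j)) / (n * (n - 1) / 2))


def pi_theta(matrix_or_calls, L: int, mode: str = "strict") -> float:
    """Per-base mean pairwise difference.

    mode='strict' (default, mirroring analyses restricted to sites
    called in every strain): sites with any missing call are dropped and
    the per-pair denominator is the shared callable length ``L``.
    mode='pairwise' averages d_ij / L_ij over pairs, where L_ij counts
    the sites called in both strains, rescaled to per-base units; pairs
    sharing zero called sites are excluded with a warning.
    """
    calls = (matrix_or_calls.calls
             if isinstance(matrix_or_calls, GenotypeMatrix)
             else np.asarray(matrix_or_calls))
    n = calls.shape[0]
    if n < 2:
        raise ValueError("pairwise diversity needs n >= 2")
    if L == 0:
        return float("nan")
    if mode == "strict":
        complete = (calls != MISSING).all(axis=0)
        return site_pi_sum(calls[:, complete]) / L
    if mode != "pairwise":
        raise ValueError(f"unknown mode {mode!r}")
    per_pair = []
    snp_sites = calls.shape[1]
    for i in range(n):
        for j in range(i + 1, n):
            both = (calls[i] != MISSING) & (calls[j] != MISSING)
            co_called = int(both.sum())
            # shared length = shared invariant sites + co-called SNPs
            L_ij = L - snp_sites + co_called
            if L_ij <= 0:
                warnings.warn(f"pair ({i},{j}) shares no called sites; "
                              "excluded from theta_pi")
                continue
            d_ij = int((calls[i, both] != calls[j, both]).sum())
            per_pair.append(d_ij / L_ij)
    if not per_pair:
        return float("nan")
    return float(np.mean(per_pair))


def diversity_estimate(matrix: GenotypeMatrix, L: int,
                       mode: str = "strict") -> DiversityEstimate:
    """theta_W and theta_pi for one slice of sites over callable length L."""
    n = matrix.n_strains
    if mode == "strict":
        keep = matrix.complete_sites()
        calls = matrix.calls[:, keep]
        ac = (calls == 1).sum(axis=0)
        S = int(((ac > 0) & (ac < n)).sum())
    else:
        S = int(matrix.segregating_sites().sum())
    return DiversityEstimate(
        S=S, n=n, L=int(L), a_n=harmonic_number(n),
        theta_w_per_base=watterson_theta(S, n, L) if L else float("nan"),
        theta_pi_per_base=pi_theta(matrix, L, mode=mode),
    )


def class_diversity(matrix: GenotypeMatrix, annotation: SiteAnnotation,
                    mask: CallableMask, mode: str = "strict") -> pd.DataFrame:
    """Per-site-class diversity table; S and L partition the totals.

    SNPs at unannotated positions are counted as intergenic (the
    annotator labels everything, so this only triggers on foreign
    annotations) and classes without callable sites are flagged by a
    NaN theta.
    """
    codes = annotation.site_class_codes(matrix.chromosomes, matrix.positions)
    callable_counts = mask.counts_by_class(annotation)
    rows = []
    for name, code in CLASS_CODE.items():
        sub = matrix.take_sites(np.flatnonzero(codes == code))
        L = callable_counts[name]
        est = diversity_estimate(sub, L, mode=mode)
        rows.append({
            "site_class": name, "S": est.S, "n": est.n, "L": L,
            "theta_w": est.theta_w_per_base,
            "theta_pi": est.theta_pi_per_base,
        })
    total_L = mask.n_callable()
    est = diversity_estimate(matrix, total_L, mode=mode)
    rows.append({"site_class": "all", "S": est.S, "n": est.n, "L": total_L,
                 "theta_w": est.theta_w_per_base,
                 "theta_pi": est.theta_pi_per_base})
    return pd.DataFrame(rows)


def windowed_diversity(matrix: GenotypeMatrix, mask: CallableMask,
                       window_size: int = 100_000,
                       exclude_intergenic: bool = False,
                       annotation: SiteAnnotation | None = None,
                       mode: str = "strict") -> pd.DataFrame:
    """Non-overlapping window diversity with a 10-window moving average.

    Windows tile each chromosome from position 1; the final partial
    window keeps its true extent.  With ``exclude_intergenic`` both the
    segregating sites and the callable length drop intergenic positions
    (requires ``annotation``).  The moving average is a trailing mean
    over up to 10 windows of the same chromosome.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if exclude_intergenic and annotation is None:
        raise ValueError("exclude_intergenic requires an annotation")
    n = matrix.n_strains
    if mode == "strict":
        usable = matrix.complete_sites() & matrix.segregating_sites()
    else:
        usable = matrix.segregating_sites()
    codes = (annotation.site_class_codes(matrix.chromosomes, matrix.positions)
             if annotation is not None else None)
    rows = []
    for chrom, call_arr in mask.mask.items():
        length = call_arr.size
        on_chrom = matrix.chromosomes == chrom
        inter_code = CLASS_CODE["intergenic"]
        if exclude_intergenic:
            chrom_classes = annotation.classes[chrom]
        for start0 in range(0, length, window_size):
            end0 = min(start0 + window_size, length)
            in_window = (on_chrom & usable
                         & (matrix.positions >= start0 + 1)
                         & (matrix.positions <= end0))
            callable_window = call_arr[start0:end0]
            if exclude_intergenic:
                in_window &= codes != inter_code
                callable_window = (callable_window
                                   & (chrom_classes[start0:end0] != inter_code))
            S = int(in_window.sum())
            L = int(callable_window.sum())
            window_calls = matrix.calls[:, in_window]
            theta_w = watterson_theta(S, n, L) if L else float("nan")
            theta_pi = (site_pi_sum(window_calls) / L) if L else float("nan")
            rows.append({
                "chromosome": chrom, "start": start0 + 1, "end": end0 + 1,
                "S": S, "L": L, "theta_w": theta_w, "theta_pi": theta_pi,
            })
    frame = pd.DataFrame(rows)
    frame["theta_w_ma10"] = (
        frame.groupby("chromosome", sort=False)["theta_w"]
        .transform(lambda s: s.rolling(10, min_periods=1).mean()))
    return frame


def chromosome_contrast(windows: pd.DataFrame,
                        chromosome: str) -> dict[str, float]:
    """One-way ANOVA of window theta_W: one chromosome against the rest."""
    on = windows.loc[windows["chromosome"] == chromosome, "theta_w"].dropna()
    off = windows.loc[windows["chromosome"] != chromosome, "theta_w"].dropna()
    if len(on) < 2 or len(off) < 2:
        raise ValueError("need at least two windows in each group")
    values = np.concatenate([on.to_numpy(), off.to_numpy()])
    if np.allclose(on.var(ddof=1), 0) and np.allclose(off.var(ddof=1), 0):
        if np.isclose(on.mean(), off.mean()):
            return {"F": 0.0, "df1": 1, "df2": len(values) - 2, "p": 1.0}
        return {"F": float("inf"), "df1": 1, "df2": len(values) - 2, "p": 0.0}
    F, p = stats.f_oneway(on.to_numpy(), off.to_numpy())
    return {"F": float(F), "df1": 1, "df2": len(values) - 2, "p": float(p)}


def spearman_correlation(x, y) -> dict[str, float]:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        warnings.warn("constant input; Spearman correlation undefined")
        return {"rho": float("nan"), "p": float("nan")}
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p)}
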