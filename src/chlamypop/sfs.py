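"""Folded (minor-allele-frequency) spectra and the neutral expectation.

Without a close outgroup alleles cannot be polarized, so spectra are
folded: a site's class is min(alt count, n - alt count).  The neutral,
constant-size expectation for class i of a sample of n follows from
folding the 1/i unfolded spectrum:

    E[eta_i] is proportional to (1/i + 1/(n-i)) / (1 + [i == n-i])

for i = 1..floor(n/2), normalised to the observed number of SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import GenotypeMatrix, SiteAnnotation, SITE_CLASSES

__all__ = ["FoldedSFS", "folded_sfs", "folded_sfs_by_class",
           "neutral_folded_expectation", "spectrum_skew"]


@dataclass
class FoldedSFS:
    """Histogram over minor-allele count classes 1..floor(n/2)."""

    n: int
    counts: np.ndarray
    class_label: str = "all"

    @property
    def S(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def folded_sfs(matrix: GenotypeMatrix, class_label: str = "all",
               site_mask: np.ndarray | None = None) -> FoldedSFS:
    """Fold the allele counts of the complete-call segregating sites.

    Sites with any missing call are dropped (strict mode) so every site
    contributes at the full sample size; monomorphic sites are excluded.
    """
    n = matrix.n_strains
    if n < 4:
        warnings.warn("folded spectrum with n < 4 is uninformative")
    keep = matrix.complete_sites()
    if site_mask is not None:
        keep = keep & site_mask
    ac = (matrix.calls[:, keep] == 1).sum(axis=0)
    ac = ac[(ac > 0) & (ac < n)]
    minor = np.minimum(ac, n - ac)
    n_classes = n // 2
    counts = np.bincount(minor, minlength=n_classes + 1)[1:n_classes + 1]
    return FoldedSFS(n=n, counts=counts.astype(np.int64),
                     class_label=class_label)


def folded_sfs_by_class(matrix: GenotypeMatrix, annotation: SiteAnnotation,
                        variant_classes=None) -> dict[str, FoldedSFS]:
    """One folded spectrum per primary site class plus coding subclasses.

    ``variant_classes`` is the frame from
    :func:`chlamypop.io_annotation.classify_variants`; when given,
    synonymous / nonsynonymous / fourfold spectra are added.
    """
    codes = annotation.site_class_codes(matrix.chromosomes, matrix.positions)
    out = {"all": folded_sfs(matrix)}
    for ci, name in enumerate(SITE_CLASSES):
        out[name] = folded_sfs(matrix, class_label=name,
                               site_mask=codes == ci)
    if variant_classes is not None:
        sub = variant_classes["subclass"].to_numpy()
        out["synonymous"] = folded_sfs(matrix, "synonymous",
                                       sub == "synonymous")
        out["nonsynonymous"] = folded_sfs(matrix, "nonsynonymous",
                                          sub == "nonsynonymous")
        four = variant_classes["fourfold"].to_numpy(dtype=bool)
        out["fourfold"] = folded_sfs(matrix, "fourfold", four)
    return out


def neutral_folded_expectation(n: int, S: int | float) -> np.ndarray:
    """Expected folded class counts for a neutral constant-size sample."""
    if n < 4:
        raise ValueError("need n >= 4")
    if S < 0:
        raise ValueError("negative SNP count")
    i = np.arange(1, n // 2 + 1)
    weights = (1.0 / i + 1.0 / (n - i)) / (1.0 + (i == n - i))
    return S * weights / weights.sum()


def spectrum_skew(observed: FoldedSFS,
                  expected: np.ndarray | None = None) -> dict:
    """Low-frequency skew of an observed spectrum against the expectation.

    Returns the singleton excess (observed minus expected proportion in
    class 1), per-class residuals, and a chi-square over classes after
    pooling adjacent high-frequency classes (from the top down) until
    every pooled expectation reaches 5.
    """
    if observed.S == 0:
        raise ValueError("empty spectrum")
    if expected is None:
        expected = neutral_folded_expectation(observed.n, observed.S)
    expected = np.asarray(expected, dtype=float)
    if expected.size != observed.counts.size:
        raise ValueError("class count mismatch between observed and expected")
    obs = observed.counts.astype(float)
    exp_prop = expected / expected.sum()
    singleton_excess = float(observed.proportions[0] - exp_prop[0])
    residuals = (obs - expected) / np.sqrt(np.where(expected > 0, expected, 1))

    pooled_obs, pooled_exp = _pool_tail(obs, expected, minimum=5.0)
    if pooled_obs.size >= 2:
        # condition on the total: expected re-scaled to the observed sum
        pooled_exp = pooled_exp * pooled_obs.sum() / pooled_exp.sum()
        chi2, p = stats.chisquare(pooled_obs, pooled_exp)
    else:
        chi2, p = float("nan"), float("nan")
    return {
        "singleton_excess": singleton_excess,
        "chi_square": float(chi2),
        "p": float(p),
        "df": int(pooled_obs.size - 1) if pooled_obs.size >= 2 else 0,
        "residuals": residuals,
    }


def _pool_tail(obs: np.ndarray, exp: np.ndarray,
               minimum: float) -> tuple[np.ndarray, np.ndarray]:
    """Pool classes from the high-frequency end until expectations >= minimum."""
    obs_out = list(obs)
    exp_out = list(exp)
    while len(exp_out) > 1 and exp_out[-1] < minimum:
        exp_out[-2] += exp_out.pop()
        obs_out[-2] += obs_out.pop()
    return np.asarray(obs_out), np.asarray(exp_out)
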