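"""Genotype-level support: Hardy-Weinberg tests, heterozygosity, two-locus
EM haplotype frequencies, and linkage disequilibrium statistics.

The two loci here are the SIRPB1 intron-1 copy-number variant (alleles Sin,
the ancestral single copy, and Dup, the duplication) and the tagging SNP
rs2209313 (alleles C and T).  Unphased genotypes leave the double
heterozygote's phase ambiguous (Sin-C/Dup-T vs Sin-T/Dup-C); the EM
algorithm resolves it by maximum likelihood under random mating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .popdata import GenotypeTable

__all__ = [
    "HweResult",
    "HaplotypeEstimate",
    "LdStats",
    "HAPLOTYPE_LABELS",
    "hwe_chi2",
    "expected_heterozygosity",
    "em_haplotypes",
    "ld_stats",
]

#: Fixed haplotype order: (CNV allele)-(SNP allele).
HAPLOTYPE_LABELS = ("Sin-C", "Sin-T", "Dup-C", "Dup-T")


@dataclass(frozen=True)
class HweResult:
    """Pearson 1-df chi-square test of Hardy-Weinberg proportions."""

    n_AA: int
    n_Aa: int
    n_aa: int
    p_hat: float
    chi2: float
    pvalue: float


def hwe_chi2(n_AA: int, n_Aa: int, n_aa: int) -> HweResult:
    """Hardy-Weinberg chi-square (1 df, no continuity correction).

    Expected counts are (n p^2, 2 n p (1-p), n (1-p)^2) with p estimated by
    the allele count.  A monomorphic sample is returned as chi2 = 0 with a
    warning rather than an error.
    """
    from scipy.stats import chi2 as chi2_dist

    n = n_AA + n_Aa + n_aa
    if n <= 0:
        raise ValueError("empty sample")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        warnings.warn("monomorphic sample: HWE chi-square defined as 0")
        return HweResult(n_AA, n_Aa, n_aa, p, 0.0, 1.0)
    expected = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return HweResult(n_AA, n_Aa, n_aa, p, chi2, float(chi2_dist.sf(chi2, 1)))


def expected_heterozygosity(p: float) -> float:
    """Expected heterozygosity 2 p (1-p) of a biallelic locus."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("allele proportion outside [0, 1]")
    return 2.0 * p * (1.0 - p)


@dataclass(frozen=True)
class HaplotypeEstimate:
    """EM-estimated two-locus haplotype frequencies, ordered as HAPLOTYPE_LABELS."""

    h: np.ndarray  # (Sin-C, Sin-T, Dup-C, Dup-T)
    loglik: float
    iterations: int
    converged: bool

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        object.__setattr__(self, "h", h)
        if np.any(h < -1e-12) or abs(h.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies are not a probability vector")

    def frequency(self, label: str) -> float:
        return float(self.h[HAPLOTYPE_LABELS.index(label)])


def _loglik(h: np.ndarray, counts: np.ndarray) -> float:
    """Multinomial log-likelihood (constant dropped) of the 3x3 genotype counts.

    counts[i, j]: i copies of Dup, j copies of T.  Haplotype order
    (Sin-C, Sin-T, Dup-C, Dup-T) = (h0, h1, h2, h3).
    """
    h0, h1, h2, h3 = h
    probs = np.array(
        [
            [h0 * h0, 2 * h0 * h1, h1 * h1],
            [2 * h0 * h2, 2 * (h0 * h3 + h1 * h2), 2 * h1 * h3],
            [h2 * h2, 2 * h2 * h3, h3 * h3],
        ]
    )
    mask = counts > 0
    with np.errstate(divide="ignore"):
        lp = np.where(probs > 0, np.log(np.maximum(probs, 1e-300)), -np.inf)
    return float(np.sum(counts[mask] * lp[mask]))


def em_haplotypes(
    g: GenotypeTable, tol: float = 1e-8, max_iter: int = 1000
) -> HaplotypeEstimate:
    """Two-locus haplotype frequencies by EM over the phase-ambiguity.

    All genotype classes except the double heterozygote determine their two
    gametes; the double heterozygote contributes (Sin-C, Dup-T) with
    posterior weight h0 h3 / (h0 h3 + h1 h2) and (Sin-T, Dup-C) otherwise.
    Initialization is the linkage-equilibrium product of observed allele
    frequencies; iteration stops when max |delta h| < tol.  The
    log-likelihood is checked to be non-decreasing every iteration.
    """
    counts = g.genotype_counts().astype(float)
    n = counts.sum()
    # unambiguous gamete counts per haplotype (double het handled in E-step)
    base = np.zeros(4)
    base[0] = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]  # Sin-C
    base[1] = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]  # Sin-T
    base[2] = 2 * counts[2, 0] + counts[1, 0] + counts[2, 1]  # Dup-C
    base[3] = 2 * counts[2, 2] + counts[1, 2] + counts[2, 1]  # Dup-T
    n_dh = counts[1, 1]

    p_dup = (2 * counts[2].sum() + counts[1].sum()) / (2 * n)
    p_t = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * n)
    h = np.array(
        [
            (1 - p_dup) * (1 - p_t),
            (1 - p_dup) * p_t,
            p_dup * (1 - p_t),
            p_dup * p_t,
        ]
    )
    if n_dh == 0:
        # no latent phase: direct gamete counting is the MLE in one step
        h = base / (2 * n)
        return HaplotypeEstimate(h, _loglik(h, counts), 1, True)

    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        cis = h[0] * h[3]
        trans = h[1] * h[2]
        w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        new = base.copy()
        new[0] += n_dh * w
        new[3] += n_dh * w
        new[1] += n_dh * (1 - w)
        new[2] += n_dh * (1 - w)
        new /= 2 * n
        ll = _loglik(new, counts)
        assert ll >= prev_ll - 1e-9, "EM log-likelihood decreased"
        delta = float(np.max(np.abs(new - h)))
        h, prev_ll = new, ll
        if delta < tol:
            return HaplotypeEstimate(h, ll, it, True)
    return HaplotypeEstimate(h, prev_ll, max_iter, False)


@dataclass(frozen=True)
class LdStats:
    """Two-locus linkage disequilibrium: D, D' and r^2."""

    D: float
    Dprime: float
    r2: float


def ld_stats(h) -> LdStats:
    """LD statistics from haplotype frequencies (Sin-C, Sin-T, Dup-C, Dup-T).

    With p_A = freq(Sin) and p_B = freq(C): D = h(Sin-C) - p_A p_B;
    D' = |D| / D_max where D_max = min(p_A (1-p_B), (1-p_A) p_B) for D > 0
    and min(p_A p_B, (1-p_A)(1-p_B)) for D < 0; r^2 = D^2 / (p_A (1-p_A)
    p_B (1-p_B)).
    """
    if isinstance(h, HaplotypeEstimate):
        h = h.h
    h = np.asarray(h, dtype=float)
    p_a = h[0] + h[1]  # Sin
    p_b = h[0] + h[2]  # C
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("monomorphic locus: LD undefined")
    D = float(h[0] - p_a * p_b)
    if D > 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    elif D < 0:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        dmax = 1.0
    dprime = abs(D) / dmax if dmax > 0 else 0.0
    r2 = D * D / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LdStats(D=D, Dprime=float(dprime), r2=float(r2))
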