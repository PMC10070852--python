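"""Population-genetic statistics: allele frequencies, Hardy-Weinberg
equilibrium tests, and Tajima's D with its full constant chain.

All operations work from explicit genotype counts or 0/1 haplotype
matrices so the arithmetic is auditable.  The chi-square HWE test uses
one degree of freedom and no continuity correction.  Tajima's D follows
the classical decomposition

    D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1))

with a1..e2 the sample-size constants, pi the mean number of pairwise
differences among haplotypes, and S the segregating-site count after
minor-allele-frequency filtering.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "MISSING",
    "GenotypeCounts",
    "AlleleFrequencies",
    "HWEResult",
    "HaplotypeMatrix",
    "TajimaComponents",
    "MonomorphicError",
    "allele_frequencies",
    "allele_freq_from_genotype_freqs",
    "counts_from_proportions",
    "hwe_expected",
    "hwe_chisq",
    "maf",
    "filter_by_maf",
    "drop_high_missing_sites",
    "tajima_constants",
    "pairwise_pi",
    "tajimas_d",
    "genotype_pi",
]

#: Allele code for a missing call in haplotype and dosage matrices.
MISSING = -1

#: Sites with more than this fraction of missing alleles are dropped
#: before diversity statistics are computed.
MAX_SITE_MISSINGNESS = 0.20


class MonomorphicError(ValueError):
    """The HWE test is undefined when only one allele is present."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeCounts:
    """Diploid genotype counts for one population at a biallelic site."""

    population: str
    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self) -> None:
        for name in ("n_hom_ref", "n_het", "n_hom_alt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt


@dataclass(frozen=True)
class AlleleFrequencies:
    """Reference (p) and alternate (q) allele frequencies, p + q = 1."""

    p: float
    q: float

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.p <= 1 + 1e-12 and -1e-12 <= self.q <= 1 + 1e-12):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if abs(self.p + self.q - 1.0) > 1e-12:
            raise ValueError("p + q must equal 1")


@dataclass
class HWEResult:
    """Chi-square Hardy-Weinberg test (df=1, no continuity correction).

    ``f_hat`` is the inbreeding-coefficient estimate
    1 - observed_het / expected_het; positive values mean a heterozygote
    deficit.
    """

    chi2: float
    df: int
    p_value: float
    expected: tuple[float, float, float]
    f_hat: float


@dataclass
class HaplotypeMatrix:
    """n haplotypes x S biallelic sites, coded 0/1 with -1 for missing.

    Positions are 1-based and strictly increasing.
    """

    positions: np.ndarray
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D (n x S) array")
        if self.positions.shape[0] != self.alleles.shape[1]:
            raise ValueError("positions length must match site count")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise ValueError("allele codes must be 0, 1 or -1 (missing)")

    @property
    def n(self) -> int:
        return self.alleles.shape[0]

    @property
    def S(self) -> int:
        return self.alleles.shape[1]

    def site(self, j: int) -> np.ndarray:
        return self.alleles[:, j]

    def take_sites(self, idx: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(self.positions[idx], self.alleles[:, idx])


@dataclass
class TajimaComponents:
    """Full decomposition of a Tajima's D computation."""

    n: int
    S: int
    pi: float
    theta_w: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    D: float


# ---------------------------------------------------------------------------
# Allele and genotype frequencies
# ---------------------------------------------------------------------------

def allele_frequencies(counts: GenotypeCounts) -> AlleleFrequencies:
    """Reference-allele frequency p = (2*hom_ref + het) / 2n by allele
    counting; q = 1 - p."""
    n = counts.n
    if n < 1:
        raise ValueError(f"population {counts.population!r} has no samples")
    p = (2 * counts.n_hom_ref + counts.n_het) / (2 * n)
    return AlleleFrequencies(p=p, q=1.0 - p)


def allele_freq_from_genotype_freqs(f_hom_ref: float, f_het: float) -> float:
    """Allele frequency from genotype *proportions*: p = f_hom + f_het/2.

    Useful when a published table reports genotype fractions but not raw
    counts.
    """
    if f_hom_ref < 0 or f_het < 0:
        raise ValueError("genotype frequencies must be non-negative")
    if f_hom_ref + f_het > 1 + 1e-9:
        raise ValueError("genotype frequencies must sum to at most 1")
    return f_hom_ref + f_het / 2.0


def counts_from_proportions(f_hom_ref: float, f_het: float, f_hom_alt: float,
                            n: int, population: str = "") -> GenotypeCounts:
    """Reconstruct integer genotype counts from published proportions.

    Each proportion is multiplied by n and rounded half away from zero.
    The reconstruction is not guaranteed to sum to n when the printed
    proportions are themselves rounded; callers should sanity-check.
    """
    def _round_half_away(x: float) -> int:
        return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))

    return GenotypeCounts(population,
                          _round_half_away(f_hom_ref * n),
                          _round_half_away(f_het * n),
                          _round_half_away(f_hom_alt * n))


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------

def hwe_expected(counts: GenotypeCounts) -> tuple[float, float, float]:
    """Expected genotype counts (n*p^2, 2npq, n*q^2) under Hardy-Weinberg."""
    n = counts.n
    if n < 1:
        raise ValueError("cannot compute HWE expectations for n = 0")
    freqs = allele_frequencies(counts)
    p, q = freqs.p, freqs.q
    return (n * p * p, 2 * n * p * q, n * q * q)


def hwe_chisq(counts: GenotypeCounts) -> HWEResult:
    """Chi-square goodness-of-fit test against Hardy-Weinberg proportions.

    Sums (obs - exp)^2 / exp over the three genotype classes with df = 1
    (three classes, one estimated allele frequency, one total constraint)
    and **no** continuity correction.

    Raises
    ------
    MonomorphicError
        Only one allele present; the test is undefined.
    """
    freqs = allele_frequencies(counts)
    if freqs.p == 0.0 or freqs.q == 0.0:
        raise MonomorphicError(
            f"population {counts.population!r} is monomorphic; "
            "HWE test undefined")
    expected = hwe_expected(counts)
    observed = (counts.n_hom_ref, counts.n_het, counts.n_hom_alt)
    chi2 = 0.0
    for obs, exp in zip(observed, expected):
        if exp == 0.0:
            if obs > 0:
                warnings.warn("zero expected count with nonzero observed; "
                              "statistic is infinite")
                chi2 = math.inf
                break
            continue
        chi2 += (obs - exp) ** 2 / exp
    p_value = float(stats.chi2.sf(chi2, df=1)) if math.isfinite(chi2) else 0.0
    f_hat = 1.0 - counts.n_het / expected[1]
    return HWEResult(chi2=chi2, df=1, p_value=p_value,
                     expected=expected, f_hat=f_hat)


# ---------------------------------------------------------------------------
# Site filters
# ---------------------------------------------------------------------------

def maf(column: np.ndarray) -> float:
    """Minor allele frequency of one site among non-missing haplotypes."""
    col = np.asarray(column)
    col = col[col != MISSING]
    if col.size < 2:
        raise ValueError("need at least 2 non-missing alleles for MAF")
    f1 = float(np.mean(col == 1))
    return min(f1, 1.0 - f1)


def filter_by_maf(hap: HaplotypeMatrix, threshold: float = 0.05) -> HaplotypeMatrix:
    """Retain sites whose minor allele frequency is strictly greater
    than ``threshold``; site order is preserved."""
    if hap.S == 0:
        return hap
    keep = np.array([maf(hap.site(j)) > threshold for j in range(hap.S)])
    out = hap.take_sites(np.where(keep)[0])
    log.info("MAF filter (> %.3g): %d sites before, %d after",
             threshold, hap.S, out.S)
    return out


def drop_high_missing_sites(hap: HaplotypeMatrix,
                            max_missing: float = MAX_SITE_MISSINGNESS,
                            ) -> HaplotypeMatrix:
    """Drop sites with more than ``max_missing`` fraction of missing calls."""
    if hap.S == 0:
        return hap
    miss_frac = np.mean(hap.alleles == MISSING, axis=0)
    keep = np.where(miss_frac <= max_missing)[0]
    dropped = hap.S - keep.size
    if dropped:
        log.info("dropped %d site(s) with > %.0f%% missingness",
                 dropped, 100 * max_missing)
    return hap.take_sites(keep)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> tuple[float, float, float, float, float,
                                      float, float, float]:
    """Sample-size constants (a1, a2, b1, b2, c1, c2, e1, e2) of the
    D statistic for n haplotypes."""
    if n < 2:
        raise ValueError(f"need at least 2 haplotypes, got {n}")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return a1, a2, b1, b2, c1, c2, e1, e2


def _segregating(hap: HaplotypeMatrix) -> np.ndarray:
    """Boolean mask of sites with both alleles present among non-missing."""
    a = hap.alleles
    has0 = ((a == 0).sum(axis=0)) > 0
    has1 = ((a == 1).sum(axis=0)) > 0
    return has0 & has1


def pairwise_pi(hap: HaplotypeMatrix) -> float:
    """Mean number of pairwise differences among haplotypes (pi).

    Averages, over all C(n,2) haplotype pairs, the count of sites at
    which the pair carries different non-missing alleles.  Equivalent to
    sum_j n0_j * n1_j / C(n,2) where n0_j, n1_j count the non-missing
    alleles at site j, which on complete data equals
    sum_j 2 p_j (1-p_j) n/(n-1).
    """
    if hap.n < 2:
        raise ValueError("need at least 2 haplotypes for pi")
    a = hap.alleles
    n0 = (a == 0).sum(axis=0).astype(float)
    n1 = (a == 1).sum(axis=0).astype(float)
    pairs = hap.n * (hap.n - 1) / 2.0
    return float(np.sum(n0 * n1) / pairs)


def tajimas_d(hap: HaplotypeMatrix,
              max_missing: float = MAX_SITE_MISSINGNESS) -> TajimaComponents:
    """Tajima's D with its full component decomposition.

    Sites above the missingness cap are dropped first.  With zero
    segregating sites, D is undefined and reported as NaN with a
    warning (the statistic's variance normalization vanishes).  A
    positive D marks an excess of intermediate-frequency variants
    (balancing selection); a negative D an excess of rare variants.
    """
    if hap.n < 2:
        raise ValueError("need at least 2 haplotypes for Tajima's D")
    if hap.n < 4:
        warnings.warn("Tajima's D is unreliable below 4 haplotypes")
    hap = drop_high_missing_sites(hap, max_missing)
    seg = _segregating(hap)
    seg_hap = hap.take_sites(np.where(seg)[0])
    S = seg_hap.S
    a1, a2, b1, b2, c1, c2, e1, e2 = tajima_constants(hap.n)
    pi = pairwise_pi(seg_hap) if S else 0.0
    theta_w = S / a1
    var = e1 * S + e2 * S * (S - 1)
    if S == 0:
        warnings.warn("no segregating sites: Tajima's D is undefined")
        D = math.nan
    elif var <= 0.0:
        # e1 = e2 = 0 at n = 3: the variance normalization vanishes.
        warnings.warn("zero variance normalization: Tajima's D is undefined")
        D = math.nan
    else:
        D = (pi - theta_w) / math.sqrt(var)
    return TajimaComponents(n=hap.n, S=S, pi=pi, theta_w=theta_w,
                            a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2,
                            e1=e1, e2=e2, D=D)


def genotype_pi(dosages: np.ndarray) -> float:
    """Per-site nucleotide-diversity sum from *unphased* diploid genotypes.

    ``dosages`` is an (n_samples x S) array of alternate-allele dosages
    (0, 1, 2; -1 for missing).  Each site's 2N non-missing allele copies
    form the sample: pi_site = 2 p (1-p) * 2N/(2N-1), summed over sites.
    This is the estimator to use when haplotype phase is unavailable; on
    phased data expanded to haplotypes it coincides with
    :func:`pairwise_pi`.
    """
    d = np.asarray(dosages)
    if d.ndim != 2 or d.shape[0] < 2:
        raise ValueError("need a 2-D dosage matrix with >= 2 samples")
    total = 0.0
    for j in range(d.shape[1]):
        col = d[:, j]
        col = col[col != MISSING]
        two_n = 2 * col.size
        if two_n < 2:
            continue
        p = float(col.sum()) / two_n
        total += 2.0 * p * (1.0 - p) * two_n / (two_n - 1)
    return total
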