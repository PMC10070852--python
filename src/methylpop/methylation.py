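"""Methylation-based genotype inference at a SNP-overlapping CpG probe.

A SNP that replaces the G of a CpG dinucleotide abolishes the methylation
substrate on that chromosome.  At such a probe the per-sample methylation
level is tripartite: homozygotes for the CpG-abolishing allele are
hypomethylated, heterozygotes hemimethylated, and homozygotes for the
CpG-preserving allele hypermethylated.  This module transforms array
beta-values to M-values, fits a one-dimensional Gaussian mixture to the
M-value distribution by expectation-maximization, and converts component
membership into diploid genotype calls.

Conventions
-----------
* beta is the fraction of methylated signal, in [0, 1].
* M = log2(beta / (1 - beta)); beta is clipped to [EPS, 1 - EPS] first so
  M stays finite at the boundaries.
* Mixture components are always reported sorted by ascending mean; the
  lowest-mean component maps to the homozygote for the CpG-abolishing
  (low-methylation) allele, "A" by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "EPS",
    "MethylationSample",
    "MixtureFit",
    "GenotypeCall",
    "ClassSummary",
    "beta_to_m",
    "m_to_beta",
    "fit_gaussian_mixture",
    "fit_three_class_mixture",
    "select_k_by_bic",
    "call_genotypes",
    "summarize_classes",
]

#: Clipping bound applied to beta before the log-ratio transform.
EPS = 1e-6

# EM settings: deterministic percentile initialization, log-likelihood
# tolerance, iteration cap, and a variance floor preventing component
# collapse onto a single observation.
EM_TOL = 1e-8
EM_MAX_ITER = 500
VAR_FLOOR = 1e-4


class DomainError(ValueError):
    """Input value outside the mathematical domain of an operation."""


class DegenerateDataError(ValueError):
    """Data carry no information for the requested fit (e.g. zero variance)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MethylationSample:
    """One sample's methylation level at a single probe.

    ``true_genotype`` is only populated by the synthetic generator and is
    used to score call accuracy against ground truth.
    """

    sample_id: str
    beta: float
    m_value: float
    true_genotype: Optional[str] = None

    @classmethod
    def from_beta(cls, sample_id: str, beta: float,
                  true_genotype: Optional[str] = None) -> "MethylationSample":
        return cls(sample_id, float(beta), beta_to_m(beta, sample_id=sample_id),
                   true_genotype)

    @classmethod
    def from_m(cls, sample_id: str, m_value: float,
               true_genotype: Optional[str] = None) -> "MethylationSample":
        return cls(sample_id, m_to_beta(m_value), float(m_value), true_genotype)


@dataclass
class MixtureFit:
    """A fitted 1-D Gaussian mixture, components sorted by ascending mean."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    converged: bool
    n_iter: int
    n_obs: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)

    @property
    def bic(self) -> float:
        """Bayesian information criterion: -2*logL + n_params*log(n)."""
        n_params = 3 * self.k - 1
        return -2.0 * self.log_likelihood + n_params * math.log(self.n_obs)

    def responsibilities(self, m_values: np.ndarray) -> np.ndarray:
        """Posterior component membership for each value (rows sum to 1)."""
        m = np.asarray(m_values, dtype=float)[:, None]
        dens = self.weights * _normal_pdf(m, self.means, self.sds)
        total = dens.sum(axis=1, keepdims=True)
        # A point infinitely far from every component gets uniform posteriors.
        total[total == 0.0] = 1.0
        out = dens / total
        zero_rows = dens.sum(axis=1) == 0.0
        out[zero_rows] = 1.0 / self.k
        return out


@dataclass
class GenotypeCall:
    """A diploid genotype call with its three-class posterior."""

    sample_id: str
    genotype: str
    posteriors: np.ndarray  # ordered (hom_low, het, hom_high)

    def __post_init__(self) -> None:
        self.posteriors = np.asarray(self.posteriors, dtype=float)


@dataclass
class ClassSummary:
    """Per-genotype-class M-value summary; ``sd`` is None for singletons."""

    genotype: str
    n: int
    mean_m: float
    sd_m: Optional[float]


# ---------------------------------------------------------------------------
# beta <-> M transforms
# ---------------------------------------------------------------------------

def beta_to_m(beta: float, sample_id: Optional[str] = None) -> float:
    """Convert a methylation beta-value to an M-value.

    M = log2(beta'/(1-beta')) where beta' is beta clipped to
    [EPS, 1-EPS].  Strictly increasing in beta on the clipped range.

    Raises
    ------
    DomainError
        If beta is outside [0, 1] (the offending sample is named when
        ``sample_id`` is given).
    """
    b = float(beta)
    if not (0.0 <= b <= 1.0) or math.isnan(b):
        who = f" for sample {sample_id!r}" if sample_id else ""
        raise DomainError(f"beta must lie in [0, 1], got {beta!r}{who}")
    b = min(max(b, EPS), 1.0 - EPS)
    return math.log2(b / (1.0 - b))


def m_to_beta(m: float) -> float:
    """Inverse of :func:`beta_to_m` (up to boundary clipping): 2^m/(1+2^m)."""
    m = float(m)
    if not math.isfinite(m):
        raise DomainError(f"M-value must be finite, got {m!r}")
    # Overflow-safe logistic in base 2.
    if m >= 0:
        return 1.0 / (1.0 + 2.0 ** (-m))
    x = 2.0 ** m
    return x / (1.0 + x)


def _normal_pdf(x: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    z = (x - mean) / sd
    return np.exp(-0.5 * z * z) / (sd * math.sqrt(2.0 * math.pi))


# ---------------------------------------------------------------------------
# Mixture fitting (EM)
# ---------------------------------------------------------------------------

# Percentile starting points per component count; k=3 brackets the
# hypo/hemi/hyper classes without depending on a random restart.
_INIT_PERCENTILES = {1: (50.0,), 2: (25.0, 75.0), 3: (10.0, 50.0, 90.0)}


def fit_gaussian_mixture(m_values: Sequence[float], k: int = 3,
                         seed: int = 0) -> MixtureFit:
    """Fit a k-component 1-D Gaussian mixture by EM.

    Initialization is deterministic (means at fixed data percentiles,
    equal weights, pooled variance), so ``seed`` does not change the
    result for a given data set; it is accepted so that callers can
    thread one seed through a whole pipeline uniformly.

    Raises
    ------
    ValueError
        Fewer than ``3*k`` observations, or non-finite input.
    DegenerateDataError
        All observations identical (zero variance).
    """
    x = np.asarray(list(m_values), dtype=float)
    if x.size < 3 * k:
        raise ValueError(
            f"need at least {3 * k} observations to fit k={k}, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("M-values must be finite")
    if np.ptp(x) == 0.0:
        raise DegenerateDataError(
            "all M-values identical: mixture variance is zero")
    if k not in _INIT_PERCENTILES:
        raise ValueError(f"k must be in {{1,2,3}}, got {k}")

    n = x.size
    means = np.percentile(x, _INIT_PERCENTILES[k]).astype(float)
    var = np.full(k, max(x.var(), VAR_FLOOR))
    weights = np.full(k, 1.0 / k)

    prev_ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, EM_MAX_ITER + 1):
        # E-step in log space is unnecessary in 1-D at these scales.
        dens = weights * _normal_pdf(x[:, None], means, np.sqrt(var))
        total = dens.sum(axis=1)
        total[total == 0.0] = np.finfo(float).tiny
        resp = dens / total[:, None]
        ll = float(np.log(total).sum())

        # M-step.
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, np.finfo(float).tiny)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
        var = np.maximum(var, VAR_FLOOR)

        if abs(ll - prev_ll) < EM_TOL:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll

    order = np.argsort(means)
    return MixtureFit(k=k, weights=weights[order], means=means[order],
                      sds=np.sqrt(var[order]), log_likelihood=prev_ll,
                      converged=converged, n_iter=n_iter, n_obs=n)


def fit_three_class_mixture(m_values: Sequence[float], seed: int = 0,
                            k: int = 3) -> MixtureFit:
    """Fit the tripartite (default k=3) M-value mixture. See
    :func:`fit_gaussian_mixture`."""
    return fit_gaussian_mixture(m_values, k=k, seed=seed)


def select_k_by_bic(m_values: Sequence[float], seed: int = 0,
                    candidates: Sequence[int] = (1, 2, 3)) -> MixtureFit:
    """Fit each candidate component count and return the fit with the
    lowest BIC. Ties break toward fewer components."""
    fits = []
    for k in candidates:
        try:
            fits.append(fit_gaussian_mixture(m_values, k=k, seed=seed))
        except ValueError:
            continue
    if not fits:
        raise ValueError("no candidate component count could be fitted")
    return min(fits, key=lambda f: (f.bic, f.k))


# ---------------------------------------------------------------------------
# Genotype calling
# ---------------------------------------------------------------------------

def _genotype_labels(low_allele: str, high_allele: str) -> tuple[str, str, str]:
    return (f"{low_allele}/{low_allele}",
            f"{low_allele}/{high_allele}",
            f"{high_allele}/{high_allele}")


def call_genotypes(samples: Sequence[MethylationSample], fit: Optional[MixtureFit],
                   low_allele: str = "A", high_allele: str = "G",
                   thresholds: Optional[tuple[float, float]] = None,
                   ) -> list[GenotypeCall]:
    """Call diploid genotypes from M-values via mixture posteriors.

    The lowest-mean component maps to the ``low_allele`` homozygote
    (by default "A", the CpG-abolishing allele: less CpG, less
    methylation), the middle to the heterozygote, the highest to the
    ``high_allele`` homozygote.  Swap the two allele arguments when the
    locus has the opposite orientation.

    If ``thresholds=(t1, t2)`` is given, hard M-value cutpoints are used
    instead of a mixture and posteriors are one-hot.

    Raises
    ------
    ValueError
        ``fit.k != 3`` and no thresholds supplied.
    """
    labels = _genotype_labels(low_allele, high_allele)
    calls: list[GenotypeCall] = []
    if thresholds is not None:
        t1, t2 = sorted(thresholds)
        for s in samples:
            idx = 0 if s.m_value < t1 else (1 if s.m_value < t2 else 2)
            post = np.zeros(3)
            post[idx] = 1.0
            calls.append(GenotypeCall(s.sample_id, labels[idx], post))
        return calls

    if fit is None or fit.k != 3:
        raise ValueError(
            "genotype calling needs a 3-component fit or explicit thresholds")
    m = np.array([s.m_value for s in samples], dtype=float)
    resp = fit.responsibilities(m)
    for s, post in zip(samples, resp):
        calls.append(GenotypeCall(s.sample_id, labels[int(np.argmax(post))],
                                  post))
    return calls


def summarize_classes(calls: Sequence[GenotypeCall],
                      samples: Sequence[MethylationSample],
                      ) -> dict[str, ClassSummary]:
    """Mean and sample SD (ddof=1) of M per called genotype class.

    Classes with no members are absent from the result; a single-member
    class reports ``sd_m=None``.
    """
    if not calls:
        raise ValueError("no genotype calls to summarize")
    m_by_id = {s.sample_id: s.m_value for s in samples}
    groups: dict[str, list[float]] = {}
    for c in calls:
        groups.setdefault(c.genotype, []).append(m_by_id[c.sample_id])
    out: dict[str, ClassSummary] = {}
    for g, vals in groups.items():
        arr = np.asarray(vals)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else None
        out[g] = ClassSummary(g, arr.size, float(arr.mean()), sd)
    return out
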