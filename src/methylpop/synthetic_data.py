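"""Synthetic-data generators for every pipeline input.

Three generators emulate the statistical structure the analysis
assumes:

* tripartite Gaussian methylation classes (one per diploid genotype at
  a CpG-disrupting SNP), sampled on the M-value scale;
* diploid genotype counts from a multinomial with an inbreeding
  coefficient F, so heterozygote deficits can be dialled in;
* haplotype samples from a standard neutral coalescent with
  infinite-sites mutation, and a "balanced polymorphism" variant in
  which two allelic classes are simulated as independent neutral
  samples separated by a set of fixed differences.  The two-class
  construction reproduces the site-frequency signature balancing
  selection leaves (an excess of intermediate-frequency variants that
  inflates pi) without a forward population model.

Time is in coalescent units (2N generations); theta is the scaled
mutation rate per *locus*, not per site.  Every generator takes a
:class:`numpy.random.Generator` or integer seed and is bit-reproducible
given (seed, config).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .methylation import MethylationSample, m_to_beta
from .popgen import GenotypeCounts, HaplotypeMatrix
from .seqio import AlignedSequences, write_fasta

__all__ = [
    "METHYLATION_PRESETS",
    "MethylationSimConfig",
    "HaplotypeSimConfig",
    "simulate_methylation",
    "simulate_genotype_counts",
    "simulate_neutral_haplotypes",
    "simulate_balanced_haplotypes",
    "coalescent_genealogy",
    "haplotypes_to_alignment",
    "write_sim_bundle",
]

#: Named parameter sets for the three methylation classes (means, sds),
#: ordered (hom_low, het, hom_high) on the M-value scale.  "paper96" and
#: "paper45" are the two published 450k-array parameterizations of the
#: same probe; "test" keeps the paper96 means but shrinks the spreads so
#: the classes are well separated and class assignment is assertable.
METHYLATION_PRESETS: dict[str, tuple[tuple[float, float, float],
                                     tuple[float, float, float]]] = {
    "paper96": ((-4.21, -0.51, 1.41), (1.96, 2.06, 0.97)),
    "paper45": ((-5.01, -0.11, 1.97), (0.67, 0.49, 0.36)),
    "test": ((-4.21, -0.51, 1.41), (0.3, 0.3, 0.3)),
}

_GENOTYPES = ("A/A", "A/G", "G/G")


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass
class MethylationSimConfig:
    """Three-class Gaussian methylation model at one probe."""

    n_per_genotype: tuple[int, int, int] = (32, 32, 32)
    class_means: tuple[float, float, float] = METHYLATION_PRESETS["paper96"][0]
    class_sds: tuple[float, float, float] = METHYLATION_PRESETS["paper96"][1]
    seed: int = 0

    def __post_init__(self) -> None:
        if any(sd <= 0 for sd in self.class_sds):
            raise ValueError("class sds must be positive")
        if any(n < 0 for n in self.n_per_genotype):
            raise ValueError("class sizes must be non-negative")

    @classmethod
    def from_preset(cls, name: str, n_per_genotype=(32, 32, 32),
                    seed: int = 0) -> "MethylationSimConfig":
        means, sds = METHYLATION_PRESETS[name]
        return cls(tuple(n_per_genotype), means, sds, seed)


@dataclass
class HaplotypeSimConfig:
    """Coalescent sample configuration.

    For the neutral generator only ``n`` and ``theta`` are used.  For
    the balanced generator ``n_per_class`` sizes the two allelic
    classes, ``theta`` is the within-class mutation rate and
    ``k_fixed`` the number of sites fixed between classes.
    """

    n: int = 20
    theta: float = 5.0
    n_per_class: tuple[int, int] = (12, 12)
    k_fixed: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 haplotypes")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.k_fixed < 0:
            raise ValueError("k_fixed must be >= 0")


# ---------------------------------------------------------------------------
# Methylation and genotype-count generators
# ---------------------------------------------------------------------------

def simulate_methylation(cfg: MethylationSimConfig,
                         rng: Optional[np.random.Generator] = None,
                         ) -> list[MethylationSample]:
    """Draw per-class Gaussian M-values and derive beta-values.

    Samples carry their generating genotype in ``true_genotype``.
    """
    rng = _as_rng(cfg.seed if rng is None else rng)
    out: list[MethylationSample] = []
    idx = 0
    for g, n, mu, sd in zip(_GENOTYPES, cfg.n_per_genotype,
                            cfg.class_means, cfg.class_sds):
        for m in rng.normal(mu, sd, size=n):
            out.append(MethylationSample(sample_id=f"S{idx:04d}",
                                         beta=m_to_beta(float(m)),
                                         m_value=float(m), true_genotype=g))
            idx += 1
    return out


def simulate_genotype_counts(n: int, p: float, f: float = 0.0,
                             seed=0, population: str = "sim",
                             ) -> GenotypeCounts:
    """Multinomial genotype counts under inbreeding coefficient F.

    Class probabilities are (p^2 + Fpq, 2pq(1-F), q^2 + Fpq): F > 0
    depletes heterozygotes, F < 0 enriches them.  F must satisfy
    F >= -min(p/q, q/p) for the probabilities to stay non-negative.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    q = 1.0 - p
    probs = np.array([p * p + f * p * q, 2 * p * q * (1 - f),
                      q * q + f * p * q])
    if np.any(probs < -1e-12) or np.any(probs > 1 + 1e-12):
        raise ValueError(f"F={f} gives genotype probabilities outside [0,1]")
    probs = np.clip(probs, 0.0, 1.0)
    probs /= probs.sum()
    rng = _as_rng(seed)
    counts = rng.multinomial(n, probs)
    return GenotypeCounts(population, int(counts[0]), int(counts[1]),
                          int(counts[2]))


# ---------------------------------------------------------------------------
# Coalescent
# ---------------------------------------------------------------------------

def coalescent_genealogy(n: int, rng: np.random.Generator,
                         ) -> list[tuple[float, list[np.ndarray]]]:
    """Simulate one n-sample coalescent genealogy.

    Returns one entry per epoch with k = n .. 2 active lineages:
    ``(t_k, descendant_sets)`` where ``t_k`` is the exponential epoch
    length (rate k(k-1)/2, coalescent units) and ``descendant_sets``
    lists, for each active lineage, the array of sample indices below
    it.  Total branch length is sum(k * t_k).
    """
    if n < 2:
        raise ValueError("need at least 2 lineages")
    lineages: list[np.ndarray] = [np.array([i]) for i in range(n)]
    epochs: list[tuple[float, list[np.ndarray]]] = []
    while len(lineages) > 1:
        k = len(lineages)
        t = rng.exponential(2.0 / (k * (k - 1)))
        epochs.append((float(t), list(lineages)))
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        merged = np.concatenate([lineages[i], lineages[j]])
        lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
    return epochs


def _drop_mutations(n: int, theta: float,
                    epochs: list[tuple[float, list[np.ndarray]]],
                    rng: np.random.Generator) -> list[np.ndarray]:
    """Poisson(theta/2 * L) infinite-sites mutations on the genealogy;
    returns the carrier index set of each mutation (one unique site
    each)."""
    branch = np.array([t * len(lin) for t, lin in epochs])
    L = float(branch.sum())
    if L == 0.0 or theta == 0.0:
        return []
    n_mut = int(rng.poisson(theta / 2.0 * L))
    carriers: list[np.ndarray] = []
    if n_mut == 0:
        return carriers
    probs = branch / L
    epoch_idx = rng.choice(len(epochs), size=n_mut, p=probs)
    for e in epoch_idx:
        _, lineages = epochs[int(e)]
        carriers.append(lineages[int(rng.integers(len(lineages)))])
    return carriers


def _matrix_from_carriers(n: int, carriers: list[np.ndarray],
                          ) -> np.ndarray:
    a = np.zeros((n, len(carriers)), dtype=np.int8)
    for j, c in enumerate(carriers):
        a[c, j] = 1
    return a


def simulate_neutral_haplotypes(cfg: HaplotypeSimConfig,
                                rng: Optional[np.random.Generator] = None,
                                ) -> HaplotypeMatrix:
    """Standard neutral coalescent sample under the infinite-sites model.

    Coalescence times are exponential with rate C(k,2); mutations fall
    as a Poisson process of rate theta/2 per unit branch length, each
    creating a unique segregating site.  E[S] = theta * sum_{i<n} 1/i.
    Sites that hit the root lineage set of all samples cannot occur
    (every epoch has >= 2 lineages), so all emitted sites segregate.
    """
    rng = _as_rng(cfg.seed if rng is None else rng)
    epochs = coalescent_genealogy(cfg.n, rng)
    carriers = _drop_mutations(cfg.n, cfg.theta, epochs, rng)
    alleles = _matrix_from_carriers(cfg.n, carriers)
    return HaplotypeMatrix(np.arange(1, alleles.shape[1] + 1), alleles)


def simulate_balanced_haplotypes(cfg: HaplotypeSimConfig,
                                 rng: Optional[np.random.Generator] = None,
                                 ) -> HaplotypeMatrix:
    """Two-class balanced-polymorphism haplotype sample.

    Each allelic class is an independent neutral coalescent sample with
    within-class rate ``cfg.theta``; ``cfg.k_fixed`` extra sites are
    fixed for class 2's allele.  Rows are class 1's haplotypes followed
    by class 2's.  This mimics an old balanced polymorphism: deep
    divergence between classes held at intermediate frequency.
    """
    n1, n2 = cfg.n_per_class
    if n1 < 1 or n2 < 1:
        raise ValueError("both allelic classes must be non-empty")
    if cfg.k_fixed == 0 and cfg.theta == 0:
        import warnings
        warnings.warn("k_fixed=0 and theta=0: simulated sample has no variation")
    rng = _as_rng(cfg.seed if rng is None else rng)

    def _class_matrix(n_class: int) -> np.ndarray:
        if n_class == 1 or cfg.theta == 0.0:
            return np.zeros((n_class, 0), dtype=np.int8)
        epochs = coalescent_genealogy(n_class, rng)
        carriers = _drop_mutations(n_class, cfg.theta, epochs, rng)
        return _matrix_from_carriers(n_class, carriers)

    a1 = _class_matrix(n1)
    a2 = _class_matrix(n2)
    n = n1 + n2
    fixed = np.zeros((n, cfg.k_fixed), dtype=np.int8)
    fixed[n1:, :] = 1
    left = np.vstack([a1, np.zeros((n2, a1.shape[1]), dtype=np.int8)])
    right = np.vstack([np.zeros((n1, a2.shape[1]), dtype=np.int8), a2])
    alleles = np.hstack([left, fixed, right])
    return HaplotypeMatrix(np.arange(1, alleles.shape[1] + 1), alleles)


# ---------------------------------------------------------------------------
# Haplotypes -> sequences, and the simulation bundle
# ---------------------------------------------------------------------------

def haplotypes_to_alignment(hap: HaplotypeMatrix, length: int = 2500,
                            low_allele: str = "A", high_allele: str = "G",
                            seed=0) -> AlignedSequences:
    """Embed a haplotype matrix in a monomorphic background sequence.

    A random background of the given length is shared by every
    haplotype; the S variant columns are placed at random distinct
    positions (allele 0 -> ``low_allele``, 1 -> ``high_allele``,
    missing -> N).  Extracting variants from the result recovers the
    matrix up to the ref-allele orientation at each site.
    """
    if length < hap.S:
        raise ValueError("alignment length shorter than the number of sites")
    rng = _as_rng(seed)
    background = rng.choice(list("ACGT"), size=length)
    cols = np.sort(rng.choice(length, size=hap.S, replace=False))
    seqs = []
    code = {0: low_allele, 1: high_allele}
    for i in range(hap.n):
        row = background.copy()
        for j, col in enumerate(cols):
            a = int(hap.alleles[i, j])
            row[col] = code.get(a, "N")
        seqs.append("".join(row))
    return AlignedSequences(ids=[f"hap{i:03d}" for i in range(hap.n)],
                            seqs=seqs)


def write_sim_bundle(outdir: str | Path, seed: int = 0,
                     preset: str = "test",
                     n_per_genotype: tuple[int, int, int] = (32, 32, 32),
                     n_hap: int = 20, theta: float = 5.0,
                     balanced: bool = False,
                     n_per_class: tuple[int, int] = (12, 12),
                     k_fixed: int = 16,
                     population: str = "sim") -> dict:
    """Write a complete synthetic input bundle to ``outdir``.

    Produces methylation.csv, genotypes.csv, haplotypes.fasta and
    truth.json (configs plus true class labels), all derived from one
    seeded generator.  Returns the truth dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    mcfg = MethylationSimConfig.from_preset(preset, n_per_genotype, seed=seed)
    samples = simulate_methylation(mcfg, rng)
    with open(outdir / "methylation.csv", "w") as fh:
        fh.write("sample_id,beta,population,true_genotype\n")
        for s in samples:
            fh.write(f"{s.sample_id},{s.beta:.10g},{population},"
                     f"{s.true_genotype}\n")
    with open(outdir / "genotypes.csv", "w") as fh:
        fh.write("sample_id,population,genotype\n")
        for s in samples:
            fh.write(f"{s.sample_id},{population},"
                     f"{s.true_genotype.replace('/', '')}\n")

    hcfg = HaplotypeSimConfig(n=n_hap, theta=theta,
                              n_per_class=tuple(n_per_class),
                              k_fixed=k_fixed, seed=seed)
    hap = (simulate_balanced_haplotypes(hcfg, rng) if balanced
           else simulate_neutral_haplotypes(hcfg, rng))
    aln = haplotypes_to_alignment(hap, seed=rng)
    write_fasta(aln, outdir / "haplotypes.fasta")

    truth = {
        "seed": seed,
        "methylation_config": {
            "preset": preset,
            "n_per_genotype": list(mcfg.n_per_genotype),
            "class_means": list(mcfg.class_means),
            "class_sds": list(mcfg.class_sds),
        },
        "haplotype_config": {
            "balanced": balanced, "n": n_hap, "theta": theta,
            "n_per_class": list(n_per_class), "k_fixed": k_fixed,
        },
        "true_genotypes": {s.sample_id: s.true_genotype for s in samples},
        "n_segregating_sites": int(hap.S),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth
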