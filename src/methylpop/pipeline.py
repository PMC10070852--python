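"""End-to-end orchestration: methylation -> genotype calls ->
population frequencies / HWE -> alignment variants -> Tajima's D ->
report.

The pipeline is deterministic: every stochastic step draws from a
generator seeded by ``AnalysisConfig.seed``, and re-running an
identical config produces byte-identical CSV/JSON outputs.  All
statistics in the report are produced by direct calls into the
`methylation`, `popgen` and `seqio` modules — the pipeline adds no
arithmetic of its own.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import methylation as meth
from . import popgen, seqio

log = logging.getLogger(__name__)

__all__ = [
    "SCHEMA_VERSION",
    "AnalysisConfig",
    "PopulationStats",
    "TajimaGroupResult",
    "PopulationReport",
    "load_methylation_csv",
    "load_genotype_csv",
    "counts_by_population",
    "run_population_scan",
    "compare_to_reference",
]

SCHEMA_VERSION = 1

#: Populations smaller than this skip the HWE test with a warning.
MIN_N_FOR_HWE = 5


def configure_logging(level: int = logging.INFO) -> None:
    """Structured, levelled log lines to standard error."""
    logging.basicConfig(
        level=level,
        format="%(levelname)s %(name)s: %(message)s",
        force=True,
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Everything a full run needs; any subset of inputs may be given,
    but at least one of methylation/genotype CSVs must be present."""

    methylation_csv: Optional[str] = None
    genotype_csv: Optional[str] = None
    fasta: Optional[str] = None
    population_map_csv: Optional[str] = None
    reference_csv: Optional[str] = None
    outdir: Optional[str] = None
    maf_threshold: float = 0.05
    pi_mode: str = "haplotype"  # or "unphased"
    balancing_threshold: float = 1.80
    grouping: str = "all"  # or "population"
    low_allele: str = "A"
    high_allele: str = "G"
    mixture_preset: str = "paper96"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pi_mode not in ("haplotype", "unphased"):
            raise ValueError("pi_mode must be 'haplotype' or 'unphased'")
        if self.grouping not in ("all", "population"):
            raise ValueError("grouping must be 'all' or 'population'")
        if not (0.0 <= self.maf_threshold < 0.5):
            raise ValueError("maf_threshold must lie in [0, 0.5)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load a YAML config; keyword overrides (e.g. CLI flags) win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Report types
# ---------------------------------------------------------------------------

@dataclass
class PopulationStats:
    population: str
    n: int
    freq_low: float   # frequency of the low-methylation (ref) allele
    freq_high: float
    f_hom_low: float
    f_het: float
    f_hom_high: float
    chi2: Optional[float]
    p_value: Optional[float]
    f_hat: Optional[float]


@dataclass
class TajimaGroupResult:
    group: str
    components: popgen.TajimaComponents
    sites_before_filter: int
    balancing_flag: bool


@dataclass
class PopulationReport:
    populations: list[PopulationStats]
    tajima: list[TajimaGroupResult]
    genotype_calls: Optional[pd.DataFrame]
    call_accuracy: Optional[float]
    provenance: dict

    def frequency_frame(self) -> pd.DataFrame:
        cfg = self.provenance.get("config", {})
        lo = cfg.get("low_allele", "A")
        hi = cfg.get("high_allele", "G")
        rows = []
        for s in self.populations:
            rows.append({
                "population": s.population, "n": s.n,
                f"{lo}_freq": s.freq_low, f"{hi}_freq": s.freq_high,
                f"{lo}{lo}_freq": s.f_hom_low, f"{lo}{hi}_freq": s.f_het,
                f"{hi}{hi}_freq": s.f_hom_high,
                "chi2": s.chi2, "p_value": s.p_value, "f_hat": s.f_hat,
            })
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        def _num(x):
            if x is None:
                return None
            return None if isinstance(x, float) and math.isnan(x) else x
        return {
            "schema_version": SCHEMA_VERSION,
            "provenance": self.provenance,
            "populations": [
                {**dataclasses.asdict(s),
                 "chi2": _num(s.chi2), "p_value": _num(s.p_value),
                 "f_hat": _num(s.f_hat)}
                for s in self.populations
            ],
            "tajima": [
                {"group": t.group,
                 "sites_before_filter": t.sites_before_filter,
                 "balancing_flag": t.balancing_flag,
                 **{k: _num(v) for k, v in
                    dataclasses.asdict(t.components).items()}}
                for t in self.tajima
            ],
            "call_accuracy": self.call_accuracy,
        }

    def write(self, outdir: str | Path) -> None:
        """Write report.json (full precision) and report.csv (p-values
        to 3 decimals) plus genotype_calls.csv when calls were made."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        df = self.frequency_frame()
        if not df.empty:
            df = df.copy()
            df["p_value"] = df["p_value"].map(
                lambda p: "" if p is None or (isinstance(p, float) and math.isnan(p))
                else f"{p:.3f}")
        df.to_csv(outdir / "report.csv", index=False)
        if self.genotype_calls is not None:
            self.genotype_calls.to_csv(outdir / "genotype_calls.csv",
                                       index=False)


# ---------------------------------------------------------------------------
# Input loading
# ---------------------------------------------------------------------------

def load_methylation_csv(path: str | Path) -> pd.DataFrame:
    """Read `sample_id,beta` (or `m_value`) with optional `population`
    and `true_genotype` columns; fills in the missing one of beta/M."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'sample_id'")
    if "beta" in df.columns:
        df["m_value"] = [meth.beta_to_m(b, sample_id=s)
                         for s, b in zip(df["sample_id"], df["beta"])]
    elif "m_value" in df.columns:
        df["beta"] = [meth.m_to_beta(m) for m in df["m_value"]]
    else:
        raise ValueError(f"{path}: need a 'beta' or 'm_value' column")
    return df


def load_genotype_csv(path: str | Path) -> pd.DataFrame:
    """Read `sample_id,population,genotype` (genotype like AA/AG/GG)."""
    df = pd.read_csv(path, dtype=str)
    missing = {"sample_id", "population", "genotype"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def counts_by_population(genotypes: pd.DataFrame, low_allele: str = "A",
                         high_allele: str = "G",
                         ) -> dict[str, popgen.GenotypeCounts]:
    """Tally AA/AG/GG-style genotype strings into per-population counts."""
    hom_low = low_allele + low_allele
    het = {low_allele + high_allele, high_allele + low_allele}
    hom_high = high_allele + high_allele
    out: dict[str, popgen.GenotypeCounts] = {}
    for pop, sub in genotypes.groupby("population", sort=True):
        g = sub["genotype"].str.replace("/", "", regex=False)
        unknown = set(g) - {hom_low, hom_high} - het
        if unknown:
            raise ValueError(
                f"population {pop!r}: unrecognized genotype(s) {sorted(unknown)}")
        out[str(pop)] = popgen.GenotypeCounts(
            str(pop), int((g == hom_low).sum()), int(g.isin(het).sum()),
            int((g == hom_high).sum()))
    return out


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def _call_genotypes_stage(cfg: AnalysisConfig, mdf: pd.DataFrame,
                          ) -> tuple[pd.DataFrame, pd.DataFrame, Optional[float]]:
    """Fit the M-value mixture and call genotypes; returns
    (genotype table, calls table, accuracy vs truth if available)."""
    samples = [meth.MethylationSample(sample_id=r.sample_id, beta=r.beta,
                                      m_value=r.m_value)
               for r in mdf.itertuples()]
    fit = meth.fit_three_class_mixture([s.m_value for s in samples],
                                       seed=cfg.seed)
    calls = meth.call_genotypes(samples, fit, low_allele=cfg.low_allele,
                                high_allele=cfg.high_allele)
    lo, hi = cfg.low_allele, cfg.high_allele
    calls_df = pd.DataFrame({
        "sample_id": [c.sample_id for c in calls],
        "genotype": [c.genotype for c in calls],
        f"posterior_{lo}{lo}": [c.posteriors[0] for c in calls],
        f"posterior_{lo}{hi}": [c.posteriors[1] for c in calls],
        f"posterior_{hi}{hi}": [c.posteriors[2] for c in calls],
        "m_value": [s.m_value for s in samples],
    })
    pops = (mdf["population"] if "population" in mdf.columns
            else pd.Series(["all"] * len(mdf)))
    gdf = pd.DataFrame({
        "sample_id": calls_df["sample_id"],
        "population": pops.values,
        "genotype": calls_df["genotype"].str.replace("/", "", regex=False),
    })
    accuracy = None
    if "true_genotype" in mdf.columns:
        truth = mdf.set_index("sample_id")["true_genotype"].str.replace(
            "/", "", regex=False)
        called = gdf.set_index("sample_id")["genotype"]
        accuracy = float((called == truth.loc[called.index]).mean())
    return gdf, calls_df, accuracy


def _sequence_groups(cfg: AnalysisConfig, sample_ids: Sequence[str],
                     pop_map: Optional[dict[str, str]]) -> dict[str, list[int]]:
    if cfg.grouping == "all" or not pop_map:
        if cfg.grouping == "population" and not pop_map:
            warnings.warn("grouping='population' but no population map for "
                          "sequences; falling back to a single group")
        return {"all": list(range(len(sample_ids)))}
    groups: dict[str, list[int]] = {}
    orphans = [sid for sid in sample_ids if sid not in pop_map]
    if orphans:
        raise ValueError(f"sequence ids missing from population map: {orphans}")
    for i, sid in enumerate(sample_ids):
        groups.setdefault(pop_map[sid], []).append(i)
    return groups


def _tajima_stage(cfg: AnalysisConfig,
                  records: list[seqio.VariantRecord],
                  sample_ids: list[str],
                  pop_map: Optional[dict[str, str]],
                  ) -> list[TajimaGroupResult]:
    results: list[TajimaGroupResult] = []
    for group, idx in sorted(_sequence_groups(cfg, sample_ids, pop_map).items()):
        sub = [dataclasses.replace(r, genotypes=[r.genotypes[i] for i in idx])
               for r in records]
        sub = [r for r in sub if r.is_biallelic_snp]
        if cfg.pi_mode == "haplotype":
            hap = seqio.haplotypes_from_variants(sub, phased=True)
            before = hap.S
            hap = popgen.filter_by_maf(hap, cfg.maf_threshold)
            comp = popgen.tajimas_d(hap)
        else:
            comp, before = _tajima_unphased(sub, cfg.maf_threshold)
        flag = bool(comp.D > cfg.balancing_threshold) if math.isfinite(comp.D) else False
        results.append(TajimaGroupResult(group, comp, before, flag))
        log.info("group %s: S=%d (of %d pre-filter), pi=%.4f, D=%.4f",
                 group, comp.S, before, comp.pi, comp.D)
    return results


def _tajima_unphased(records: list[seqio.VariantRecord], maf_threshold: float,
                     ) -> tuple[popgen.TajimaComponents, int]:
    """Tajima's D from unphased diploid dosages: the 2N allele copies
    per site are the sample; pi comes from the diploid estimator."""
    dosages = seqio.dosage_matrix(records)
    before = dosages.shape[1]
    if dosages.size:
        keep = []
        for j in range(dosages.shape[1]):
            col = dosages[:, j]
            col = col[col != popgen.MISSING]
            p = col.sum() / (2 * col.size) if col.size else 0.0
            if min(p, 1 - p) > maf_threshold:
                keep.append(j)
        dosages = dosages[:, keep]
    n = 2 * dosages.shape[0]
    a1, a2, b1, b2, c1, c2, e1, e2 = popgen.tajima_constants(n)
    pi = popgen.genotype_pi(dosages) if dosages.size else 0.0
    S = dosages.shape[1]
    theta_w = S / a1
    if S == 0:
        warnings.warn("no segregating sites after filtering: D undefined")
        D = math.nan
    else:
        D = (pi - theta_w) / math.sqrt(e1 * S + e2 * S * (S - 1))
    comp = popgen.TajimaComponents(n=n, S=S, pi=pi, theta_w=theta_w, a1=a1,
                                   a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1,
                                   e2=e2, D=D)
    return comp, before


# ---------------------------------------------------------------------------
# Main entry points
# ---------------------------------------------------------------------------

def run_population_scan(cfg: AnalysisConfig) -> PopulationReport:
    """Run the full analysis described by ``cfg`` and (optionally)
    write the report to ``cfg.outdir``.

    Stages: genotype calling from methylation (when no genotype CSV is
    given), per-population allele frequencies and HWE, variant
    extraction from the alignment, MAF filtering and Tajima's D per
    grouping, and the balancing-selection flag (D > threshold).
    """
    if cfg.methylation_csv is None and cfg.genotype_csv is None:
        raise ValueError("need a methylation CSV and/or a genotype CSV")

    calls_df: Optional[pd.DataFrame] = None
    accuracy: Optional[float] = None
    mdf: Optional[pd.DataFrame] = None

    if cfg.methylation_csv:
        mdf = load_methylation_csv(cfg.methylation_csv)
    if cfg.genotype_csv:
        gdf = load_genotype_csv(cfg.genotype_csv)
        if mdf is not None:
            m_ids, g_ids = set(mdf["sample_id"]), set(gdf["sample_id"])
            orphans = sorted(m_ids ^ g_ids)
            if orphans:
                raise ValueError(
                    "sample ids differ between methylation and genotype "
                    f"inputs; orphans: {orphans}")
    else:
        gdf, calls_df, accuracy = _call_genotypes_stage(cfg, mdf)

    pop_map: Optional[dict[str, str]] = None
    if cfg.population_map_csv:
        pm = pd.read_csv(cfg.population_map_csv, dtype=str)
        pop_map = dict(zip(pm["sample_id"], pm["population"]))
        gdf = gdf.copy()
        gdf["population"] = gdf["sample_id"].map(
            lambda s: pop_map.get(s, "unknown"))

    pop_stats: list[PopulationStats] = []
    for pop, counts in counts_by_population(gdf, cfg.low_allele,
                                            cfg.high_allele).items():
        freqs = popgen.allele_frequencies(counts)
        n = counts.n
        chi2 = p_value = f_hat = None
        if n < MIN_N_FOR_HWE:
            warnings.warn(f"population {pop!r} has n={n} < {MIN_N_FOR_HWE}; "
                          "HWE test skipped")
        else:
            try:
                hwe = popgen.hwe_chisq(counts)
                chi2, p_value, f_hat = hwe.chi2, hwe.p_value, hwe.f_hat
            except popgen.MonomorphicError:
                warnings.warn(f"population {pop!r} is monomorphic; "
                              "HWE test skipped")
        pop_stats.append(PopulationStats(
            pop, n, freqs.p, freqs.q, counts.n_hom_ref / n,
            counts.n_het / n, counts.n_hom_alt / n, chi2, p_value, f_hat))

    tajima_results: list[TajimaGroupResult] = []
    if cfg.fasta:
        aln = seqio.read_fasta_alignment(cfg.fasta)
        # Sequences carrying two-base IUPAC codes are unphased diploid
        # consensus sequences; without any such code each sequence is a
        # haplotype and diploid expansion would double-count it.
        diploid = any(ch in seqio.IUPAC_DIPLOID
                      for s in aln.seqs for ch in set(s))
        log.info("alignment interpreted as %s",
                 "diploid (IUPAC heterozygotes found)" if diploid
                 else "haploid (no IUPAC heterozygote codes)")
        records = seqio.variants_from_alignment(aln, diploid_iupac=diploid)
        tajima_results = _tajima_stage(cfg, records, aln.ids, pop_map)

    from . import __version__
    report = PopulationReport(
        populations=pop_stats,
        tajima=tajima_results,
        genotype_calls=calls_df,
        call_accuracy=accuracy,
        provenance={"config": cfg.to_dict(), "seed": cfg.seed,
                    "package_version": __version__,
                    "schema_version": SCHEMA_VERSION},
    )
    if cfg.outdir:
        report.write(cfg.outdir)
    return report


def compare_to_reference(report: PopulationReport | pd.DataFrame,
                         reference_csv: str | Path,
                         flip: bool = False) -> pd.DataFrame:
    """Merge the report's allele frequencies with a user-supplied
    reference table (columns ``population, allele, frequency``).

    The merged table is sorted by ascending low-allele frequency.  No
    statistical test is attached.  ``flip`` swaps the reference table's
    allele orientation; an allele-label mismatch raises with a hint to
    use it.
    """
    if isinstance(report, PopulationReport):
        cfg = report.provenance.get("config", {})
        lo = cfg.get("low_allele", "A")
        hi = cfg.get("high_allele", "G")
        df = report.frequency_frame()
    else:
        df = report
        lo, hi = "A", "G"  # plain frames use the default orientation
    sample = df[["population", f"{lo}_freq", f"{hi}_freq", "n"]].copy()
    sample["source"] = "sample"

    ref = pd.read_csv(reference_csv, dtype={"population": str, "allele": str})
    if ref.empty:
        warnings.warn("reference table is empty; report returned unchanged")
        return sample.sort_values(f"{lo}_freq", kind="stable").reset_index(drop=True)
    labels = set(ref["allele"])
    if flip:
        ref = ref.copy()
        ref["allele"] = ref["allele"].map({lo: hi, hi: lo})
        labels = set(ref["allele"])
    if not labels <= {lo, hi}:
        raise ValueError(
            f"reference allele labels {sorted(labels)} do not match "
            f"{{{lo},{hi}}}; if the orientation is reversed, pass flip=True")
    wide = ref.pivot_table(index="population", columns="allele",
                           values="frequency", aggfunc="first")
    out_rows = []
    for pop, row in wide.iterrows():
        f_lo = row.get(lo, np.nan)
        f_hi = row.get(hi, np.nan)
        if math.isnan(f_lo) and not math.isnan(f_hi):
            f_lo = 1.0 - f_hi
        if math.isnan(f_hi) and not math.isnan(f_lo):
            f_hi = 1.0 - f_lo
        n = ref.loc[ref["population"] == pop, "n"].iloc[0] if "n" in ref else np.nan
        out_rows.append({"population": pop, f"{lo}_freq": f_lo,
                         f"{hi}_freq": f_hi, "n": n, "source": "reference"})
    merged = pd.concat([sample, pd.DataFrame(out_rows)], ignore_index=True)
    return merged.sort_values(f"{lo}_freq", kind="stable").reset_index(drop=True)
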