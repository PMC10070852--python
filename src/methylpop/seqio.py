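"""Sequence and variant I/O: aligned FASTA in, VCF-style variant tables
out, and the bridge from variant records to haplotype matrices.

Coordinates are 1-based throughout: alignment columns and VCF POS both
count from 1.  Heterozygous positions in Sanger-style consensus
sequences are expected as two-base IUPAC ambiguity codes (R, Y, S, W,
K, M); with ``diploid_iupac`` enabled each aligned sequence is treated
as an unphased diploid and those codes expand to heterozygous
genotypes.  Three/four-base ambiguity codes (B, D, H, V), N and gaps
are treated as missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO

from .popgen import MISSING, HaplotypeMatrix

log = logging.getLogger(__name__)

__all__ = [
    "AlignedSequences",
    "VariantRecord",
    "FastaFormatError",
    "VcfFormatError",
    "PhaseError",
    "IUPAC_DIPLOID",
    "read_fasta_alignment",
    "write_fasta",
    "variants_from_alignment",
    "write_vcf",
    "read_vcf",
    "haplotypes_from_variants",
    "dosage_matrix",
]

#: Two-base IUPAC codes, i.e. the heterozygote-informative ones.
IUPAC_DIPLOID = {
    "R": ("A", "G"), "Y": ("C", "T"), "S": ("C", "G"),
    "W": ("A", "T"), "K": ("G", "T"), "M": ("A", "C"),
}
_BASES = frozenset("ACGT")
_MISSING_CHARS = frozenset("N-BDHV")


class FastaFormatError(ValueError):
    pass


class VcfFormatError(ValueError):
    pass


class PhaseError(ValueError):
    """Haplotype expansion requested for genotypes without phase."""


@dataclass
class AlignedSequences:
    """A multiple sequence alignment: unique ids, equal-length sequences."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise FastaFormatError("duplicate sequence ids in alignment")
        if self.seqs:
            L = len(self.seqs[0])
            bad = [self.ids[i] for i, s in enumerate(self.seqs) if len(s) != L]
            if bad:
                raise FastaFormatError(
                    f"sequences not all the same length; offending ids: {bad}")

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0


@dataclass
class VariantRecord:
    """One polymorphic alignment column as a VCF-style record.

    ``pos`` is the 1-based alignment column.  ``genotypes`` holds one
    call per sample: haploid "0"/"1"/"." or diploid "0/0", "0/1", "1/1",
    "./." (a "|" separator marks a phased diploid call).
    """

    chrom: str
    pos: int
    ref: str
    alt: list[str]
    genotypes: list[str]

    def __post_init__(self) -> None:
        if self.ref in self.alt:
            raise ValueError("ref allele must differ from every alt allele")

    @property
    def is_biallelic_snp(self) -> bool:
        return (len(self.alt) == 1 and len(self.ref) == 1
                and len(self.alt[0]) == 1)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta_alignment(path: str | Path) -> AlignedSequences:
    """Read an aligned FASTA file; sequences are uppercased and must be
    equal length."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    return AlignedSequences(ids=ids, seqs=seqs)


def write_fasta(aln: AlignedSequences, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# Variant extraction
# ---------------------------------------------------------------------------

def _column_alleles(chars: Sequence[str], diploid: bool) -> list[tuple[str, str] | None]:
    """Per-sample allele pair for one column (None = fully missing)."""
    out: list[tuple[str, str] | None] = []
    for ch in chars:
        if ch in _BASES:
            out.append((ch, ch))
        elif diploid and ch in IUPAC_DIPLOID:
            out.append(IUPAC_DIPLOID[ch])
        else:
            if ch not in _MISSING_CHARS and not (not diploid and ch in IUPAC_DIPLOID):
                log.warning("unrecognized character %r treated as missing", ch)
            out.append(None)
    return out


def variants_from_alignment(aln: AlignedSequences, diploid_iupac: bool = True,
                            chrom: str = "locus") -> list[VariantRecord]:
    """Extract one VariantRecord per polymorphic alignment column.

    With ``diploid_iupac`` each sequence is an unphased diploid: a
    two-base ambiguity code becomes a heterozygous genotype.  Without
    it sequences are haploid and ambiguity codes are missing.  The
    reference allele is the majority allele (alphabetical tie-break,
    which is stable under sequence reordering).  Columns with more than
    two alleles are emitted multi-allelic with a warning; all-gap/
    all-missing columns are skipped with a log entry.  Positions are
    1-based.
    """
    records: list[VariantRecord] = []
    for col in range(aln.length):
        chars = [s[col] for s in aln.seqs]
        pairs = _column_alleles(chars, diploid_iupac)
        counts: dict[str, int] = {}
        for pr in pairs:
            if pr is None:
                continue
            for a in pr:
                counts[a] = counts.get(a, 0) + 1
        if not counts:
            log.info("column %d is all-missing; skipped", col + 1)
            continue
        if len(counts) < 2:
            continue  # monomorphic
        # Majority ref, alphabetical tie-break; alts by descending count
        # then alphabetical.
        alleles = sorted(counts, key=lambda a: (-counts[a], a))
        ref, alts = alleles[0], alleles[1:]
        if len(alleles) > 2:
            log.warning("column %d has %d alleles; emitted multi-allelic",
                        col + 1, len(alleles))
        index = {a: i for i, a in enumerate([ref] + alts)}
        gts: list[str] = []
        for pr in pairs:
            if diploid_iupac:
                gts.append("./." if pr is None
                           else f"{index[pr[0]]}/{index[pr[1]]}")
            else:
                gts.append("." if pr is None else str(index[pr[0]]))
        records.append(VariantRecord(chrom=chrom, pos=col + 1, ref=ref,
                                     alt=alts, genotypes=gts))
    return records


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = "##fileformat=VCFv4.2"
_VCF_COLUMNS = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                "INFO", "FORMAT"]


def write_vcf(records: Sequence[VariantRecord], path: str | Path,
              sample_ids: Sequence[str]) -> None:
    """Write a minimal VCF v4.2 with a GT-only FORMAT column.

    Positions must be unique; records are written in the order given.
    """
    seen: set[tuple[str, int]] = set()
    for r in records:
        key = (r.chrom, r.pos)
        if key in seen:
            raise ValueError(f"duplicate position {r.chrom}:{r.pos}")
        seen.add(key)
        if len(r.genotypes) != len(sample_ids):
            raise ValueError(
                f"record at pos {r.pos} has {len(r.genotypes)} genotypes "
                f"for {len(sample_ids)} samples")
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER + "\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("\t".join(_VCF_COLUMNS + list(sample_ids)) + "\n")
        for r in records:
            fields = [r.chrom, str(r.pos), ".", r.ref, ",".join(r.alt),
                      ".", ".", ".", "GT"] + list(r.genotypes)
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Read biallelic SNP records (GT field) from a VCF.

    Non-SNP or multi-allelic records are skipped with a logged count.
    Phased "|" genotype separators are accepted and preserved.
    """
    records: list[VariantRecord] = []
    sample_ids: Optional[list[str]] = None
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if cols[:9] != _VCF_COLUMNS:
                    raise VcfFormatError("malformed #CHROM header line")
                sample_ids = cols[9:]
                continue
            if sample_ids is None:
                raise VcfFormatError("VCF data before #CHROM header")
            parts = line.split("\t")
            chrom, pos, _id, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            fmt = parts[8].split(":")
            if "GT" not in fmt:
                raise VcfFormatError(f"record at {chrom}:{pos} lacks GT")
            gt_idx = fmt.index("GT")
            alts = alt.split(",")
            if not (len(ref) == 1 and len(alts) == 1 and len(alts[0]) == 1
                    and alts[0] != "."):
                skipped += 1
                continue
            gts = [p.split(":")[gt_idx] for p in parts[9:]]
            records.append(VariantRecord(chrom=chrom, pos=pos, ref=ref,
                                         alt=alts, genotypes=gts))
    if sample_ids is None:
        raise VcfFormatError(f"missing #CHROM header in {path}")
    if skipped:
        log.info("skipped %d non-biallelic-SNP record(s)", skipped)
    return records, sample_ids


# ---------------------------------------------------------------------------
# Bridge to haplotype / dosage matrices
# ---------------------------------------------------------------------------

def _gt_alleles(gt: str) -> tuple[list[str], bool]:
    """Split a GT string into allele codes; the flag marks a phased call."""
    if "|" in gt:
        return gt.split("|"), True
    if "/" in gt:
        return gt.split("/"), False
    return [gt], True  # haploid calls carry no phase ambiguity


def haplotypes_from_variants(records: Sequence[VariantRecord],
                             phased: bool = True) -> HaplotypeMatrix:
    """Expand diploid variant records into a 0/1 haplotype matrix.

    Each diploid sample contributes two haplotype rows, column-
    consistently (first allele of every genotype -> haplotype 1).
    Haploid records pass through one row per sample.  Heterozygous
    unphased calls ("0/1") cannot be assigned to haplotypes; they raise
    :class:`PhaseError`.  With ``phased=False`` the expansion is
    refused outright — route unphased data through
    :func:`dosage_matrix` and the diploid diversity estimator instead.
    """
    if not phased:
        raise PhaseError(
            "unphased genotypes cannot be expanded to haplotypes; "
            "use dosage_matrix() with the unphased diversity estimator")
    recs = [r for r in records if r.is_biallelic_snp]
    if len(recs) != len(records):
        raise ValueError("haplotype expansion requires biallelic SNP records")
    if not recs:
        return HaplotypeMatrix(np.empty(0, dtype=int), np.empty((0, 0)))
    n_samples = len(recs[0].genotypes)
    ploidies = [len(_gt_alleles(recs[0].genotypes[i])[0]) for i in range(n_samples)]
    n_hap = sum(ploidies)
    alleles = np.full((n_hap, len(recs)), MISSING, dtype=np.int8)
    for j, r in enumerate(recs):
        row = 0
        for i, gt in enumerate(r.genotypes):
            codes, is_phased = _gt_alleles(gt)
            if len(codes) != ploidies[i]:
                raise ValueError(
                    f"sample {i} changes ploidy at position {r.pos}")
            if len(codes) == 2 and not is_phased and codes[0] != codes[1]:
                raise PhaseError(
                    f"unphased heterozygote at position {r.pos}, sample {i}; "
                    "cannot expand to haplotypes")
            for c in codes:
                alleles[row, j] = MISSING if c == "." else int(c)
                row += 1
    return HaplotypeMatrix(np.array([r.pos for r in recs]), alleles)


def dosage_matrix(records: Sequence[VariantRecord]) -> np.ndarray:
    """Alternate-allele dosage (0/1/2, -1 missing) per sample x site for
    unphased diploid records; haploid calls count as one allele copy
    scaled to dosage 0/2 so hom/het semantics stay comparable."""
    recs = [r for r in records if r.is_biallelic_snp]
    if not recs:
        return np.empty((0, 0), dtype=np.int8)
    n_samples = len(recs[0].genotypes)
    out = np.full((n_samples, len(recs)), MISSING, dtype=np.int8)
    for j, r in enumerate(recs):
        for i, gt in enumerate(r.genotypes):
            codes, _ = _gt_alleles(gt)
            if any(c == "." for c in codes):
                continue
            vals = [int(c) for c in codes]
            out[i, j] = sum(vals) if len(vals) == 2 else 2 * vals[0]
    return out
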