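"""Genotype input/output and quality control.

Reads multi-sample VCF files into an allele-dosage matrix, applies the
standard GBS marker filters (call rate, monomorphism, minor allele
frequency) with full per-category accounting, and summarises marker
density per chromosome.

Dosage coding: 0, 1, 2 copies of the alternate allele; ``MISSING`` (−1)
for uncalled or half-called genotypes. Coordinates are 1-based as in VCF;
all physical distances are base-pair differences of positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("gbspopgen")

#: dosage code for a missing (or half-called) genotype
MISSING: int = -1

_NUCLEOTIDES = frozenset("ACGT")


class GenotypeIOError(RuntimeError):
    """Fatal error while reading, writing or validating genotype data."""


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP: chromosome, 1-based position, ref and alt alleles."""

    chrom: str
    pos: int
    ref: str = "A"
    alt: str = "T"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise GenotypeIOError(f"variant position must be >= 1, got {self.pos}")


@dataclass
class FilterReport:
    """Accounting of the QC filter cascade.

    Each input variant is counted exactly once: under the first filter it
    fails (call rate, then monomorphism, then MAF) or under ``n_retained``.
    """

    n_input: int
    n_callrate_removed: int
    n_monomorphic_removed: int
    n_maf_removed: int
    n_retained: int

    def __post_init__(self) -> None:
        removals = (
            self.n_callrate_removed + self.n_monomorphic_removed + self.n_maf_removed
        )
        if self.n_input != self.n_retained + removals:
            raise GenotypeIOError(
                f"filter accounting does not balance: {self.n_input} != "
                f"{self.n_retained} + {removals}"
            )
        if min(
            self.n_input,
            self.n_callrate_removed,
            self.n_monomorphic_removed,
            self.n_maf_removed,
            self.n_retained,
        ) < 0:
            raise GenotypeIOError("filter counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_input": [self.n_input],
                "n_callrate_removed": [self.n_callrate_removed],
                "n_monomorphic_removed": [self.n_monomorphic_removed],
                "n_maf_removed": [self.n_maf_removed],
                "n_retained": [self.n_retained],
            }
        )


@dataclass
class GenotypeMatrix:
    """Samples × variants allele-dosage matrix with variant coordinates.

    Parameters
    ----------
    sample_ids
        Unique sample labels, one per matrix row.
    variants
        Ordered variant records, one per matrix column; positions must
        strictly increase within each chromosome.
    dosage
        ``int8`` array of shape ``(n_samples, n_variants)`` with entries in
        ``{0, 1, 2, MISSING}``.
    """

    sample_ids: list[str]
    variants: list[VariantRecord]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.validate()

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise GenotypeIOError("duplicated sample id")
        if self.dosage.shape != (len(self.sample_ids), len(self.variants)):
            raise GenotypeIOError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        valid = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.dosage[~valid])
            raise GenotypeIOError(f"invalid dosage codes: {bad.tolist()}")
        last: dict[str, int] = {}
        for v in self.variants:
            if v.chrom in last and v.pos <= last[v.chrom]:
                raise GenotypeIOError(
                    f"positions not strictly increasing on {v.chrom} at {v.pos}"
                )
            last[v.chrom] = v.pos

    # -- convenience accessors -------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=[self.variants[i] for i in keep],
            dosage=self.dosage[:, keep].copy(),
        )

    # -- per-site summaries ----------------------------------------------

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per site over non-missing calls (NaN if none)."""
        called = self.dosage != MISSING
        n_alleles = 2.0 * called.sum(axis=0)
        alt = np.where(called, self.dosage, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / n_alleles, np.nan)

    def call_rates(self) -> np.ndarray:
        return (self.dosage != MISSING).mean(axis=0)

    def maf(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)


@dataclass
class PopulationMap:
    """Assignment of samples to named populations."""

    assignments: dict[str, str]

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.assignments.values():
            seen.setdefault(pop, None)
        return list(seen)

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def validate_against(self, gm: GenotypeMatrix) -> None:
        known = set(gm.sample_ids)
        missing = [s for s in self.assignments if s not in known]
        if missing:
            raise GenotypeIOError(
                f"population map names samples absent from the matrix: {missing[:5]}"
            )
        if not self.assignments:
            raise GenotypeIOError("population map is empty")


def read_popmap(path: str | Path) -> PopulationMap:
    """Read a 2-column TSV (sample_id, population) with a header line."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise GenotypeIOError(f"population map {path} needs 2 columns")
    assignments = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if len(assignments) != len(df):
        raise GenotypeIOError(f"duplicated sample id in population map {path}")
    return PopulationMap(assignments)


def write_popmap(pm: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for sample, pop in pm.assignments.items():
            fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    region_filter: Iterable[str] | None = None,
) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are kept; multiallelic or non-SNP records are
    skipped and counted in the log. Unphased ``0/1`` and phased ``0|1`` both
    map to dosage 1; ``./.`` and half-calls such as ``0/.`` map to ``MISSING``.

    Parameters
    ----------
    path
        VCF v4.x file, plain or bgzip-compressed.
    region_filter
        Optional set of chromosome labels to retain.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise GenotypeIOError(f"cannot read VCF: {path} does not exist")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 raises various types
        raise GenotypeIOError(f"cannot read VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise GenotypeIOError(f"duplicated sample id in {path}")
    regions = set(region_filter) if region_filter is not None else None

    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if regions is not None and rec.CHROM not in regions:
            continue
        alts = rec.ALT
        if (
            len(alts) != 1
            or len(rec.REF) != 1
            or len(alts[0]) != 1
            or rec.REF.upper() not in _NUCLEOTIDES
            or alts[0].upper() not in _NUCLEOTIDES
        ):
            n_skipped += 1
            continue
        gts = rec.genotype.array()  # (n_samples, ploidy + 1); last col = phased
        alleles = gts[:, :2]
        col = alleles.sum(axis=1).astype(np.int8)
        col[(alleles < 0).any(axis=1)] = MISSING
        variants.append(VariantRecord(rec.CHROM, rec.POS, rec.REF, alts[0]))
        columns.append(col)
    vcf.close()

    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    if not variants:
        raise GenotypeIOError(f"no biallelic SNP records retained from {path}")
    dosage = np.stack(columns, axis=1)
    gm = GenotypeMatrix(samples, variants, dosage)
    logger.info(
        "read_vcf: %d samples x %d variants from %s", gm.n_samples, gm.n_variants, path
    )
    return gm


_GT_STRINGS_UNPHASED = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    gm: GenotypeMatrix,
    path: str | Path,
    haplotypes: np.ndarray | None = None,
) -> None:
    """Write a GenotypeMatrix as VCF v4.2.

    With ``haplotypes`` (shape ``(n_samples, 2, n_variants)``, entries 0/1)
    genotypes are written phased (``a|b``); cells that are MISSING in the
    dosage matrix are still written as ``./.``. Without, genotypes are
    unphased dosage transcriptions.
    """
    chrom_lengths: dict[str, int] = {}
    for v in gm.variants:
        chrom_lengths[v.chrom] = max(chrom_lengths.get(v.chrom, 0), v.pos)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gbspopgen\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j, v in enumerate(gm.variants):
            if haplotypes is not None:
                gts = [
                    "./."
                    if gm.dosage[i, j] == MISSING
                    else f"{haplotypes[i, 0, j]}|{haplotypes[i, 1, j]}"
                    for i in range(gm.n_samples)
                ]
            else:
                gts = [_GT_STRINGS_UNPHASED[int(d)] for d in gm.dosage[:, j]]
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def apply_qc_filters(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.95,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the marker QC cascade: call rate → monomorphism → MAF.

    Each variant is attributed to the first test it fails, so the report's
    categories are disjoint and sum (with retained) to the input count.
    A variant is monomorphic here when its non-missing calls show fewer
    than two distinct dosage values; MAF is computed on non-missing calls
    only, and a variant with zero calls falls under the call-rate filter.

    Returns the filtered matrix and a :class:`FilterReport`.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise GenotypeIOError(f"maf_min must be in [0, 0.5], got {maf_min}")
    if not 0.0 <= call_rate_min <= 1.0:
        raise GenotypeIOError(f"call_rate_min must be in [0, 1], got {call_rate_min}")
    if gm.n_samples == 0:
        raise GenotypeIOError("cannot filter a matrix with zero samples")

    call_rate = gm.call_rates()
    fail_cr = call_rate < call_rate_min

    called = gm.dosage != MISSING
    n_distinct = np.zeros(gm.n_variants, dtype=int)
    for code in (0, 1, 2):
        n_distinct += ((gm.dosage == code) & called).any(axis=0)
    fail_mono = (n_distinct < 2) & ~fail_cr

    maf = gm.maf()
    with np.errstate(invalid="ignore"):
        fail_maf = (np.nan_to_num(maf, nan=0.0) < maf_min) & ~fail_cr & ~fail_mono

    keep = ~(fail_cr | fail_mono | fail_maf)
    report = FilterReport(
        n_input=gm.n_variants,
        n_callrate_removed=int(fail_cr.sum()),
        n_monomorphic_removed=int(fail_mono.sum()),
        n_maf_removed=int(fail_maf.sum()),
        n_retained=int(keep.sum()),
    )
    logger.info(
        "QC: %d in, %d call-rate, %d monomorphic, %d MAF removed, %d retained",
        report.n_input,
        report.n_callrate_removed,
        report.n_monomorphic_removed,
        report.n_maf_removed,
        report.n_retained,
    )
    return gm.subset_variants(keep), report


def chromosome_summary(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-chromosome SNP count, mean MAF and largest inter-SNP gap (bp).

    Chromosomes appear in order of first occurrence; a chromosome with a
    single SNP reports a gap of 0.
    """
    if gm.n_variants == 0:
        raise GenotypeIOError("chromosome_summary requires a non-empty matrix")
    maf = gm.maf()
    chroms = gm.chroms
    positions = gm.positions
    rows = []
    seen: dict[str, None] = {}
    for c in chroms:
        seen.setdefault(c, None)
    for chrom in seen:
        mask = chroms == chrom
        pos = positions[mask]
        gap = int(np.diff(pos).max()) if pos.size > 1 else 0
        rows.append(
            {
                "chrom": chrom,
                "n_snps": int(mask.sum()),
                "mean_maf": float(np.nanmean(maf[mask])),
                "largest_gap_bp": gap,
            }
        )
    return pd.DataFrame(rows)
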