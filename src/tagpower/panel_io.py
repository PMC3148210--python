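"""Phased haplotype panel I/O, validation and subsetting.

The central data structure is :class:`HaplotypePanel`: a binary matrix with
one row per chromosome (two consecutive rows per sample) and one column per
biallelic SNP, plus per-variant metadata.  Panels are read from phased VCF
(via cyvcf2) or from IMPUTE-style ``.hap``/``.legend`` pairs, and written
back as plain text.  All internal coordinates are 1-based; BED input is
converted at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from cyvcf2 import VCF

from .errors import (
    DomainError,
    FormatError,
    LookupError_,
    MissingGenotypeError,
    PhasingError,
)

logger = logging.getLogger(__name__)

#: MAF boundaries: rare iff maf <= RARE_MAX, low-frequency iff
#: RARE_MAX < maf <= LOW_FREQUENCY_MAX, common otherwise.
RARE_MAX = 0.005
LOW_FREQUENCY_MAX = 0.05

_SNP_ALLELES = {"A", "C", "G", "T"}


class MafCategory(str, Enum):
    """Minor-allele-frequency class of a variant."""

    COMMON = "common"
    LOW_FREQUENCY = "low_frequency"
    RARE = "rare"


def compute_maf(column: Sequence[int] | np.ndarray) -> float:
    """Minor allele frequency of a 0/1 haplotype column.

    Returns ``min(f, 1 - f)`` where ``f`` is the mean of the column; the
    result is invariant under global relabeling of the two alleles.
    """
    col = np.asarray(column)
    if col.size == 0:
        raise DomainError("cannot compute MAF of an empty column")
    f = float(col.mean())
    return min(f, 1.0 - f)


def classify_maf_category(maf: float) -> MafCategory:
    """Classify a MAF as rare (<=0.5%), low-frequency (<=5%) or common."""
    if not 0.0 <= maf <= 0.5:
        raise DomainError(f"MAF must lie in [0, 0.5]; got {maf!r}")
    if maf <= RARE_MAX:
        return MafCategory.RARE
    if maf <= LOW_FREQUENCY_MAX:
        return MafCategory.LOW_FREQUENCY
    return MafCategory.COMMON


@dataclass(frozen=True)
class VariantRecord:
    """Metadata for one biallelic SNP column."""

    id: str
    chrom: str
    pos: int  # 1-based
    alleles: tuple[str, str]
    maf: float
    category: MafCategory


@dataclass(frozen=True)
class GeneRegion:
    """Half-open genomic interval (BED convention: 0-based start)."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise DomainError(
                f"region {self.name}: start must be < end ({self.start}, {self.end})"
            )

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        return chrom == self.chrom and self.start < pos <= self.end


@dataclass(frozen=True)
class ArrayManifest:
    """Fixed-content array: a named set of (chrom, pos) sites."""

    name: str
    sites: frozenset

    @classmethod
    def from_pairs(cls, name: str, pairs: Iterable[tuple[str, int]]) -> "ArrayManifest":
        return cls(name=name, sites=frozenset((str(c), int(p)) for c, p in pairs))

    def __len__(self) -> int:
        return len(self.sites)


class HaplotypePanel:
    """Phased binary haplotype matrix with variant metadata.

    Rows ``2k`` and ``2k + 1`` of :attr:`haplotypes` are the two chromosomes
    of sample ``k``.  Every column is polymorphic and variants are strictly
    sorted by ``(chrom, pos)``; the constructor enforces both.
    """

    def __init__(
        self,
        variants: Sequence[VariantRecord],
        haplotypes: np.ndarray,
        sample_ids: Sequence[str],
    ) -> None:
        haplotypes = np.asarray(haplotypes, dtype=np.uint8)
        if haplotypes.ndim != 2:
            raise FormatError("haplotypes must be a 2-D matrix")
        n_hap, n_var = haplotypes.shape
        if n_hap % 2 != 0:
            raise FormatError(f"haplotype row count must be even, got {n_hap}")
        if len(sample_ids) * 2 != n_hap:
            raise FormatError(
                f"{len(sample_ids)} samples require {2 * len(sample_ids)} rows, "
                f"got {n_hap}"
            )
        if len(variants) != n_var:
            raise FormatError(
                f"{len(variants)} variant records for {n_var} matrix columns"
            )
        if not np.isin(haplotypes, (0, 1)).all():
            raise FormatError("haplotype matrix entries must be 0 or 1")
        if n_var:
            counts = haplotypes.sum(axis=0)
            bad = np.flatnonzero((counts == 0) | (counts == n_hap))
            if bad.size:
                raise FormatError(
                    f"monomorphic columns present (first: {variants[bad[0]].id}); "
                    "drop them before constructing the panel"
                )
        keys = [(v.chrom, v.pos) for v in variants]
        if any(keys[i] >= keys[i + 1] for i in range(len(keys) - 1)):
            raise FormatError("variants must be strictly sorted by (chrom, pos)")
        if len(set(v.id for v in variants)) != len(variants):
            raise FormatError("duplicate variant ids")
        self.variants: tuple[VariantRecord, ...] = tuple(variants)
        self.haplotypes = haplotypes
        self.sample_ids: tuple[str, ...] = tuple(str(s) for s in sample_ids)
        self._id_index = {v.id: i for i, v in enumerate(self.variants)}

    # -- basic accessors -------------------------------------------------

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    @property
    def chroms(self) -> list[str]:
        return [v.chrom for v in self.variants]

    @property
    def mafs(self) -> np.ndarray:
        return np.array([v.maf for v in self.variants], dtype=float)

    @property
    def categories(self) -> list[MafCategory]:
        return [v.category for v in self.variants]

    def variant_index(self, variant_id: str) -> int:
        try:
            return self._id_index[variant_id]
        except KeyError:
            raise LookupError_(f"unknown variant id {variant_id!r}") from None

    def column(self, variant_id: str) -> np.ndarray:
        return self.haplotypes[:, self.variant_index(variant_id)]

    def genotypes(self) -> np.ndarray:
        """Per-sample genotype matrix (0/1/2), samples x variants."""
        return (self.haplotypes[0::2, :] + self.haplotypes[1::2, :]).astype(np.uint8)

    def sites(self) -> list[tuple[str, int]]:
        return [(v.chrom, v.pos) for v in self.variants]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypePanel):
            return NotImplemented
        return (
            self.variants == other.variants
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.haplotypes, other.haplotypes)
        )

    def __repr__(self) -> str:
        return (
            f"HaplotypePanel({self.n_variants} variants, "
            f"{self.n_samples} samples)"
        )


def build_panel(
    ids: Sequence[str],
    chroms: Sequence[str],
    positions: Sequence[int],
    alleles: Sequence[tuple[str, str]],
    haplotypes: np.ndarray,
    sample_ids: Sequence[str],
) -> HaplotypePanel:
    """Assemble a panel: sort variants, drop monomorphic columns, annotate MAF.

    The number of monomorphic columns removed is logged at INFO level.
    """
    haplotypes = np.asarray(haplotypes, dtype=np.uint8)
    n_hap = haplotypes.shape[0]
    order = sorted(range(len(ids)), key=lambda i: (str(chroms[i]), int(positions[i])))
    seen: set[tuple[str, int]] = set()
    records: list[VariantRecord] = []
    keep: list[int] = []
    n_mono = 0
    for i in order:
        key = (str(chroms[i]), int(positions[i]))
        col = haplotypes[:, i]
        count = int(col.sum())
        if count == 0 or count == n_hap:
            n_mono += 1
            continue
        if key in seen:
            raise FormatError(f"duplicate site {key[0]}:{key[1]}")
        seen.add(key)
        maf = compute_maf(col)
        records.append(
            VariantRecord(
                id=str(ids[i]),
                chrom=key[0],
                pos=key[1],
                alleles=(str(alleles[i][0]), str(alleles[i][1])),
                maf=maf,
                category=classify_maf_category(maf),
            )
        )
        keep.append(i)
    if n_mono:
        logger.info("dropped %d monomorphic column(s)", n_mono)
    matrix = haplotypes[:, keep] if keep else np.zeros((n_hap, 0), dtype=np.uint8)
    return HaplotypePanel(records, matrix, sample_ids)


# -- VCF ------------------------------------------------------------------


def read_phased_vcf(path: str | Path) -> HaplotypePanel:
    """Read a phased, biallelic-SNP VCF into a panel.

    Raises :class:`PhasingError` on any ``/``-separated genotype,
    :class:`FormatError` on multiallelic or non-SNP records, and
    :class:`MissingGenotypeError` on missing calls.  Monomorphic records
    are dropped (count logged), not treated as errors.
    """
    path = Path(path)
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    n_hap = 2 * len(sample_ids)
    ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    alleles: list[tuple[str, str]] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        label = f"{rec.CHROM}:{rec.POS}"
        if len(rec.ALT) != 1:
            raise FormatError(f"multiallelic record at {label}")
        ref, alt = rec.REF, rec.ALT[0]
        if ref not in _SNP_ALLELES or alt not in _SNP_ALLELES:
            raise FormatError(f"non-SNP record at {label} ({ref}>{alt})")
        col = np.empty(n_hap, dtype=np.uint8)
        for k, g in enumerate(rec.genotypes):
            if len(g) != 3:
                raise FormatError(
                    f"non-diploid genotype for sample {sample_ids[k]} at {label}"
                )
            a0, a1, phased = g
            if a0 < 0 or a1 < 0:
                raise MissingGenotypeError(
                    f"missing genotype for sample {sample_ids[k]} at {label}"
                )
            if not phased:
                raise PhasingError(
                    f"unphased genotype for sample {sample_ids[k]} at {label}"
                )
            col[2 * k] = a0
            col[2 * k + 1] = a1
        ids.append(rec.ID if rec.ID not in (None, ".") else label)
        chroms.append(str(rec.CHROM))
        positions.append(int(rec.POS))
        alleles.append((ref, alt))
        columns.append(col)
    matrix = (
        np.column_stack(columns) if columns else np.zeros((n_hap, 0), dtype=np.uint8)
    )
    return build_panel(ids, chroms, positions, alleles, matrix, sample_ids)


def write_phased_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a panel as an uncompressed VCF with phased GT fields.

    Round-trips exactly through :func:`read_phased_vcf`.
    """
    path = Path(path)
    contigs = sorted(set(panel.chroms))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=tagpower\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        H = panel.haplotypes
        for j, v in enumerate(panel.variants):
            gts = "\t".join(
                f"{H[2 * k, j]}|{H[2 * k + 1, j]}" for k in range(panel.n_samples)
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.alleles[0]}\t{v.alleles[1]}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# -- hap/legend dialect ---------------------------------------------------


def write_hap_legend(
    panel: HaplotypePanel, hap_path: str | Path, legend_path: str | Path
) -> None:
    """Write IMPUTE-style files: one variant per row, haplotypes as columns."""
    with open(legend_path, "w") as fh:
        fh.write("id position allele0 allele1\n")
        for v in panel.variants:
            fh.write(f"{v.id} {v.pos} {v.alleles[0]} {v.alleles[1]}\n")
    np.savetxt(hap_path, panel.haplotypes.T, fmt="%d", delimiter=" ")


def read_hap_legend(
    hap_path: str | Path,
    legend_path: str | Path,
    chrom: str = "1",
    sample_ids: Sequence[str] | None = None,
) -> HaplotypePanel:
    """Read an IMPUTE-style hap/legend pair (legend carries no chromosome)."""
    ids, positions, alleles = [], [], []
    with open(legend_path) as fh:
        header = fh.readline()
        if not header.lower().startswith("id"):
            raise FormatError("legend file must start with an 'id ...' header")
        for line in fh:
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"short legend line: {line.rstrip()!r}")
            ids.append(parts[0])
            positions.append(int(parts[1]))
            alleles.append((parts[2], parts[3]))
    matrix = np.loadtxt(hap_path, dtype=np.uint8, ndmin=2).T
    if matrix.shape[1] != len(ids):
        raise FormatError(
            f"hap file has {matrix.shape[1]} variants, legend has {len(ids)}"
        )
    n_hap = matrix.shape[0]
    if sample_ids is None:
        sample_ids = [f"sample{k}" for k in range(n_hap // 2)]
    return build_panel(ids, [chrom] * len(ids), positions, alleles, matrix, sample_ids)


# -- BED and manifests ----------------------------------------------------


def read_bed_regions(path: str | Path) -> list[GeneRegion]:
    """Read gene regions from BED (0-based half-open, name in column 4)."""
    regions: list[GeneRegion] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"BED line {i + 1} has fewer than 3 columns")
            name = parts[3] if len(parts) > 3 else f"region{len(regions)}"
            regions.append(
                GeneRegion(
                    name=name,
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                )
            )
    return regions


def write_bed_regions(regions: Sequence[GeneRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")


def read_manifest(path: str | Path, name: str | None = None) -> ArrayManifest:
    """Read an array manifest: two-column TSV of chrom, pos (1-based)."""
    pairs: list[tuple[str, int]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"manifest line {i + 1} has fewer than 2 columns")
            pairs.append((parts[0], int(parts[1])))
    return ArrayManifest.from_pairs(name or Path(path).stem, pairs)


def write_manifest(manifest: ArrayManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# chrom\tpos\n")
        for chrom, pos in sorted(manifest.sites):
            fh.write(f"{chrom}\t{pos}\n")


# -- subsetting -----------------------------------------------------------


def assign_regions(
    panel: HaplotypePanel, regions: Sequence[GeneRegion]
) -> np.ndarray:
    """Index of the first region containing each variant (-1 if none)."""
    out = np.full(panel.n_variants, -1, dtype=np.int64)
    for j, v in enumerate(panel.variants):
        for k, r in enumerate(regions):
            if r.contains(v.chrom, v.pos):
                out[j] = k
                break
    return out


def subset_panel(
    panel: HaplotypePanel,
    *,
    variant_ids: Iterable[str] | None = None,
    sample_ids: Iterable[str] | None = None,
    region: GeneRegion | None = None,
    manifest: ArrayManifest | None = None,
) -> HaplotypePanel:
    """Restrict a panel by variants, samples, a region, or an array manifest.

    Original variant order is kept; MAF and category are recomputed on the
    retained samples, and columns left monomorphic by sample subsetting are
    dropped (count logged).
    """
    keep = np.ones(panel.n_variants, dtype=bool)
    if variant_ids is not None:
        wanted = set(variant_ids)
        keep &= np.array([v.id in wanted for v in panel.variants], dtype=bool)
    if region is not None:
        keep &= np.array(
            [region.contains(v.chrom, v.pos) for v in panel.variants], dtype=bool
        )
    if manifest is not None:
        keep &= np.array(
            [(v.chrom, v.pos) in manifest.sites for v in panel.variants], dtype=bool
        )
    rows = np.arange(panel.n_haplotypes)
    samples = list(panel.sample_ids)
    if sample_ids is not None:
        wanted_samples = list(dict.fromkeys(sample_ids))  # preserve order, dedupe
        index = {s: k for k, s in enumerate(panel.sample_ids)}
        missing = [s for s in wanted_samples if s not in index]
        if missing:
            raise LookupError_(f"unknown sample id(s): {missing}")
        samples = [s for s in panel.sample_ids if s in set(wanted_samples)]
        rows = np.concatenate(
            [[2 * index[s], 2 * index[s] + 1] for s in samples]
        ).astype(np.int64) if samples else np.zeros(0, dtype=np.int64)
    idx = np.flatnonzero(keep)
    matrix = panel.haplotypes[np.ix_(rows, idx)]
    kept = [panel.variants[j] for j in idx]
    return build_panel(
        [v.id for v in kept],
        [v.chrom for v in kept],
        [v.pos for v in kept],
        [v.alleles for v in kept],
        matrix,
        samples,
    )
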