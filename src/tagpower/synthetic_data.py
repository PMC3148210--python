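"""Synthetic phased haplotype panels with a controllable frequency spectrum
and block-structured, distance-decaying LD.

The generator works frequencies-first: each variant's minor-allele count is
drawn from the configured folded site-frequency spectrum and then imposed on
the chromosomes.  LD comes from a founder-copying mosaic: every chromosome
copies one of a small number of founder lineages per block, switching
lineage between adjacent variants with probability proportional to the
inter-variant distance.  Carrier sets are built from whole lineages, with
the boundary lineage trimmed by a slowly evolving per-chromosome priority
field to hit the drawn count exactly, so nearby variants share carriers
and distant ones do not.
Minor-allele counts are drawn through a Gaussian-copula AR(1) field along
each block, which keeps the marginal spectrum exact while letting nearby
variants have similar frequencies (without which high r2 is unreachable).

A discovery-subsample ascertainment routine emulates fixed-content arrays
whose site list was frozen on a finite discovery cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DomainError, GenerationError
from .panel_io import (
    ArrayManifest,
    GeneRegion,
    HaplotypePanel,
    build_panel,
    subset_panel,
)

__all__ = [
    "SimulationConfig",
    "expected_folded_sfs",
    "generate_panel",
    "generate_gene_panels",
    "ascertain_discovery_panel",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the mosaic generator.

    ``sfs`` selects the target folded spectrum: ``"neutral_folded"`` (the
    1/i spectrum folded onto minor-allele counts), ``"uniform"``, or an
    explicit list of proportions over minor counts ``1..n_chromosomes//2``.
    """

    seed: int = 0
    n_samples: int = 55
    n_variants: int = 2000
    region_length: int = 1_000_000
    mode: str = "chromosome"  # "chromosome" | "genes"
    n_genes: int = 382
    block_length: int = 20_000
    founder_haplotypes_per_block: int = 8
    recombination_switch_rate: float = 1e-6  # per basepair
    sfs: str | tuple[float, ...] = "neutral_folded"
    chrom: str = "1"
    carrier_jitter: float = 0.2
    frequency_correlation_length: float = 10_000.0  # bp; 0 disables

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ConfigError("n_samples must be positive")
        if self.n_variants <= 0:
            raise ConfigError("n_variants must be positive")
        if self.region_length < self.n_variants:
            raise ConfigError(
                "region_length must be at least n_variants "
                "(positions are drawn without replacement)"
            )
        if self.mode not in ("chromosome", "genes"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "genes" and self.n_genes <= 0:
            raise ConfigError("n_genes must be positive in genes mode")
        if self.block_length <= 0:
            raise ConfigError("block_length must be positive")
        if self.founder_haplotypes_per_block < 1:
            raise ConfigError("founder_haplotypes_per_block must be >= 1")
        if not 0.0 <= self.recombination_switch_rate <= 1.0:
            raise ConfigError("recombination_switch_rate must lie in [0, 1]")
        if self.carrier_jitter < 0:
            raise ConfigError("carrier_jitter must be nonnegative")
        if self.frequency_correlation_length < 0:
            raise ConfigError("frequency_correlation_length must be nonnegative")
        if isinstance(self.sfs, str):
            if self.sfs not in ("neutral_folded", "uniform"):
                raise ConfigError(f"unknown sfs {self.sfs!r}")
        else:
            w = np.asarray(self.sfs, dtype=float)
            if w.ndim != 1 or w.size != self.n_samples:  # counts 1..n/2 = n_samples
                raise ConfigError(
                    "custom sfs must list one weight per minor count "
                    f"1..{self.n_samples} (n_chromosomes // 2)"
                )
            if (w < 0).any() or w.sum() <= 0:
                raise ConfigError("custom sfs weights must be nonnegative, sum > 0")


def expected_folded_sfs(n_chromosomes: int) -> np.ndarray:
    """Folded neutral spectrum over minor-allele counts ``1..n//2``.

    The unfolded standard-neutral spectrum is proportional to ``1/i``;
    folding adds the complementary class, so the weight of minor count
    ``i`` is ``1/i + 1/(n - i)`` for ``i < n/2`` and ``1/i`` at ``i = n/2``.
    Returns proportions summing to 1.
    """
    n = int(n_chromosomes)
    if n < 2:
        raise DomainError("need at least 2 chromosomes")
    half = n // 2
    counts = np.arange(1, half + 1, dtype=float)
    w = 1.0 / counts
    complement = n - counts
    fold = complement > counts  # strict: i = n - i contributes once
    w[fold] += 1.0 / complement[fold]
    return w / w.sum()


def _sfs_weights(config: SimulationConfig, n_chromosomes: int) -> np.ndarray:
    half = n_chromosomes // 2
    if isinstance(config.sfs, str):
        if config.sfs == "neutral_folded":
            return expected_folded_sfs(n_chromosomes)
        return np.full(half, 1.0 / half)
    w = np.asarray(config.sfs, dtype=float)
    return w / w.sum()


def _draw_positions(rng: np.random.Generator, n: int, start: int, length: int) -> np.ndarray:
    """``n`` distinct 1-based positions in ``(start, start + length]``, sorted."""
    pos = rng.choice(length, size=n, replace=False) + start + 1
    pos.sort()
    return pos.astype(np.int64)


def _mosaic_labels(
    rng: np.random.Generator,
    positions: np.ndarray,
    n_chromosomes: int,
    n_founders: int,
    switch_rate: float,
    block_length: int,
) -> np.ndarray:
    """Founder label per (chromosome, variant) under the copying process.

    Labels restart independently at every block boundary; within a block a
    chromosome switches to a fresh uniform founder between adjacent variants
    with probability ``min(1, switch_rate * distance)``.
    """
    n_var = positions.size
    labels = np.empty((n_chromosomes, n_var), dtype=np.int32)
    block_of = positions // block_length
    labels[:, 0] = rng.integers(n_founders, size=n_chromosomes)
    for j in range(1, n_var):
        if block_of[j] != block_of[j - 1]:
            labels[:, j] = rng.integers(n_founders, size=n_chromosomes)
            continue
        p_switch = min(1.0, switch_rate * float(positions[j] - positions[j - 1]))
        stay = rng.random(n_chromosomes) >= p_switch
        fresh = rng.integers(n_founders, size=n_chromosomes)
        labels[:, j] = np.where(stay, labels[:, j - 1], fresh)
    return labels


def _place_carriers(
    labels_col: np.ndarray,
    priority: np.ndarray,
    founder_order: np.ndarray,
    target_count: int,
) -> np.ndarray:
    """Carrier-chromosome index set of size ``target_count`` for one variant.

    Whole lineages are taken in the block's fixed founder order; the
    boundary lineage is trimmed to its lowest-priority chromosomes.  The
    priority field evolves along the chromosome at the copying switch
    rate, so nearby variants trim to (nearly) the same carriers while
    distant ones decorrelate.
    """
    carriers: list[np.ndarray] = []
    total = 0
    for f in founder_order:
        members = np.flatnonzero(labels_col == f)
        if total + members.size <= target_count:
            carriers.append(members)
            total += members.size
        else:
            need = target_count - total
            if need > 0:
                order = members[np.argsort(priority[members], kind="stable")]
                carriers.append(order[:need])
                total = target_count
        if total == target_count:
            break
    return np.concatenate(carriers) if carriers else np.zeros(0, dtype=np.int64)


def _draw_minor_counts(
    rng: np.random.Generator,
    positions: np.ndarray,
    weights: np.ndarray,
    block_length: int,
    correlation_length: float,
) -> np.ndarray:
    """Minor-allele counts with the configured marginal spectrum.

    A latent AR(1) Gaussian field (restarted at block boundaries, lag
    correlation ``exp(-distance / correlation_length)``) is pushed through
    the spectrum's inverse CDF, so the marginal law of every count is
    exactly ``weights`` while nearby variants get similar counts.  A zero
    correlation length reduces to i.i.d. draws.
    """
    n_var = positions.size
    z = np.empty(n_var)
    z[0] = rng.standard_normal()
    block_of = positions // block_length
    for j in range(1, n_var):
        if correlation_length <= 0 or block_of[j] != block_of[j - 1]:
            z[j] = rng.standard_normal()
            continue
        rho = math.exp(-float(positions[j] - positions[j - 1]) / correlation_length)
        z[j] = rho * z[j - 1] + math.sqrt(1.0 - rho * rho) * rng.standard_normal()
    u = 0.5 * (1.0 + np.array([math.erf(v / math.sqrt(2.0)) for v in z]))
    counts = np.searchsorted(np.cumsum(weights), u, side="left") + 1
    return np.clip(counts, 1, weights.size)


def _generate_block_columns(
    rng: np.random.Generator,
    positions: np.ndarray,
    n_chromosomes: int,
    config: SimulationConfig,
    minor_counts: np.ndarray,
) -> np.ndarray:
    matrix = np.zeros((n_chromosomes, positions.size), dtype=np.uint8)
    labels = _mosaic_labels(
        rng,
        positions,
        n_chromosomes,
        config.founder_haplotypes_per_block,
        config.recombination_switch_rate,
        config.block_length,
    )
    block_of = positions // config.block_length
    founder_orders: dict[int, np.ndarray] = {}
    priority = rng.random(n_chromosomes)
    for j in range(positions.size):
        b = int(block_of[j])
        if b not in founder_orders:
            founder_orders[b] = rng.permutation(config.founder_haplotypes_per_block)
            priority = rng.random(n_chromosomes)
        elif j > 0:
            p_switch = min(
                1.0,
                config.recombination_switch_rate
                * float(positions[j] - positions[j - 1]),
            )
            refresh = rng.random(n_chromosomes) < p_switch
            priority = np.where(refresh, rng.random(n_chromosomes), priority)
        noisy = priority + config.carrier_jitter * rng.random(n_chromosomes)
        carriers = _place_carriers(
            labels[:, j], noisy, founder_orders[b], int(minor_counts[j])
        )
        matrix[carriers, j] = 1
    return matrix


def generate_panel(
    config: SimulationConfig, *, start: int = 0, _prefix: str = "snp"
) -> HaplotypePanel:
    """Generate one chromosome-scale panel.

    Deterministic under ``config.seed``: two calls with the same config
    produce byte-identical panels.
    """
    config.validate()
    if config.founder_haplotypes_per_block < 2:
        raise GenerationError(
            "founder_haplotypes_per_block=1 makes every column monomorphic "
            "(all chromosomes copy the same lineage)"
        )
    rng = np.random.default_rng(config.seed)
    return _generate_region(rng, config, start=start, prefix=_prefix)


def _generate_region(
    rng: np.random.Generator,
    config: SimulationConfig,
    *,
    start: int,
    prefix: str,
    n_variants: int | None = None,
    region_length: int | None = None,
) -> HaplotypePanel:
    n_var = config.n_variants if n_variants is None else n_variants
    length = config.region_length if region_length is None else region_length
    n_chrom = 2 * config.n_samples
    positions = _draw_positions(rng, n_var, start, length)
    weights = _sfs_weights(config, n_chrom)
    minor_counts = _draw_minor_counts(
        rng, positions, weights, config.block_length,
        config.frequency_correlation_length,
    )
    matrix = _generate_block_columns(rng, positions, n_chrom, config, minor_counts)
    ids = [f"{prefix}_{config.chrom}_{p}" for p in positions]
    alleles = [("A", "G")] * n_var
    panel = build_panel(
        ids,
        [config.chrom] * n_var,
        positions,
        alleles,
        matrix,
        [f"sample{k}" for k in range(config.n_samples)],
    )
    if panel.n_variants == 0:
        raise GenerationError("no polymorphic column survived generation")
    return panel


def generate_gene_panels(
    config: SimulationConfig,
) -> tuple[HaplotypePanel, list[GeneRegion]]:
    """Generate a multi-gene panel plus its disjoint gene regions.

    Variants are split across ``n_genes`` equal-width, well-separated
    regions; the mean number of variants per gene is ``n_variants /
    n_genes`` (remainder spread over the first genes).
    """
    config.validate()
    if config.mode != "genes":
        raise ConfigError("generate_gene_panels requires mode='genes'")
    if config.founder_haplotypes_per_block < 2:
        raise GenerationError(
            "founder_haplotypes_per_block=1 makes every column monomorphic"
        )
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    base, extra = divmod(config.n_variants, n_genes)
    per_gene = [base + (1 if g < extra else 0) for g in range(n_genes)]
    gene_length = max(config.region_length // n_genes, max(base + 1, 2))
    gap = max(gene_length // 2, 1)
    regions: list[GeneRegion] = []
    panels: list[HaplotypePanel] = []
    cursor = 0
    for g, n_var in enumerate(per_gene):
        if n_var == 0:
            continue
        region = GeneRegion(
            name=f"gene{g}", chrom=config.chrom, start=cursor, end=cursor + gene_length
        )
        regions.append(region)
        panels.append(
            _generate_region(
                rng,
                config,
                start=cursor,
                prefix=f"g{g}",
                n_variants=n_var,
                region_length=gene_length,
            )
        )
        cursor += gene_length + gap
    merged = _concat_panels(panels)
    return merged, regions


def _concat_panels(panels: list[HaplotypePanel]) -> HaplotypePanel:
    first = panels[0]
    ids, chroms, positions, alleles = [], [], [], []
    for p in panels:
        for v in p.variants:
            ids.append(v.id)
            chroms.append(v.chrom)
            positions.append(v.pos)
            alleles.append(v.alleles)
    matrix = np.concatenate([p.haplotypes for p in panels], axis=1)
    return build_panel(ids, chroms, positions, alleles, matrix, first.sample_ids)


def ascertain_discovery_panel(
    panel: HaplotypePanel, discovery_sample_ids
) -> ArrayManifest:
    """Array manifest of sites polymorphic within a discovery subsample.

    Models a fixed-content chip whose site list was chosen from a finite
    discovery cohort: variants carried only outside the cohort are absent.
    An empty discovery set yields an empty manifest.
    """
    ids = list(discovery_sample_ids)
    if not ids:
        return ArrayManifest.from_pairs("discovery", [])
    sub = subset_panel(panel, sample_ids=ids)
    return ArrayManifest.from_pairs("discovery", sub.sites())
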