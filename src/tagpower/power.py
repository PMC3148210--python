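"""Case-control power engine for single-SNP 2-df chi-square tests.

Penetrances are solved from a prevalence and genotype relative risks under
Hardy-Weinberg genotype frequencies; case/control genotype distributions
follow by Bayes inversion.  Power is estimated three ways:

* :func:`simulate_power_direct` — genotype sampling straight from the
  case/control conditional distributions (fast, used for direct tests);
* :func:`estimate_power` — chromosome resampling from a finite haplotype
  panel with rejection sampling on disease status, supporting direct,
  best-proxy and array-restricted testing;
* :func:`analytic_power` — a noncentral chi-square approximation serving
  as the independent oracle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConsistencyError,
    DegenerateTableError,
    DomainError,
    InfeasibleModelError,
    SimulationError,
)
from .ld_analysis import _r2_one_vs_many
from .panel_io import ArrayManifest, HaplotypePanel, MafCategory

logger = logging.getLogger(__name__)

#: Published survey of common-disease susceptibility loci used to pick the
#: homozygous relative-risk defaults: mean and median reported risks.
SURVEY_MEAN_RR = 1.5
SURVEY_MEDIAN_RR = 1.183

#: Default homozygous relative risks: candidates for common variants, and
#: per-model values for low-frequency variants.
DEFAULT_RR_HOM_COMMON = (1.4, 1.8)
DEFAULT_RR_HOM_LOW_FREQUENCY = {"recessive": 3.2, "default": 1.8}

DEFAULT_PREVALENCE = 0.01
DEFAULT_ALPHA = 0.05
DEFAULT_REPLICATES = 1000

_REL_TOL = 1e-8


class ModelKind(str, Enum):
    DOMINANT = "dominant"
    ADDITIVE = "additive"
    MULTIPLICATIVE = "multiplicative"
    RECESSIVE = "recessive"


@dataclass(frozen=True)
class DiseaseModel:
    """Prevalence plus heterozygous/homozygous genotype relative risks."""

    kind: ModelKind
    prevalence: float
    rr_het: float
    rr_hom: float

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise DomainError(f"prevalence must lie in (0, 1); got {self.prevalence}")
        k, g1, g2 = self.kind, self.rr_het, self.rr_hom
        ok = {
            ModelKind.DOMINANT: math.isclose(g1, g2, rel_tol=_REL_TOL),
            ModelKind.RECESSIVE: math.isclose(g1, 1.0, rel_tol=_REL_TOL),
            ModelKind.ADDITIVE: math.isclose(g2, 2 * g1 - 1, rel_tol=_REL_TOL),
            ModelKind.MULTIPLICATIVE: math.isclose(g2, g1 * g1, rel_tol=_REL_TOL),
        }[ModelKind(k)]
        if not ok:
            raise DomainError(
                f"relative risks ({g1}, {g2}) violate the {ModelKind(k).value} "
                "model constraint"
            )

    @classmethod
    def from_rr_hom(
        cls, kind: ModelKind | str, rr_hom: float, prevalence: float = DEFAULT_PREVALENCE
    ) -> "DiseaseModel":
        """Build a model from its homozygous relative risk alone."""
        kind = ModelKind(kind)
        if kind is ModelKind.DOMINANT:
            rr_het = rr_hom
        elif kind is ModelKind.RECESSIVE:
            rr_het = 1.0
        elif kind is ModelKind.ADDITIVE:
            rr_het = (rr_hom + 1.0) / 2.0
        else:
            rr_het = math.sqrt(rr_hom)
        return cls(kind=kind, prevalence=prevalence, rr_het=rr_het, rr_hom=rr_hom)

    @classmethod
    def null(cls, kind: ModelKind | str = ModelKind.DOMINANT, prevalence: float = DEFAULT_PREVALENCE) -> "DiseaseModel":
        return cls(kind=ModelKind(kind), prevalence=prevalence, rr_het=1.0, rr_hom=1.0)

    @property
    def is_null(self) -> bool:
        return self.rr_het == 1.0 and self.rr_hom == 1.0


def default_rr_hom(kind: ModelKind | str, category: MafCategory) -> float:
    """Published homozygous relative-risk default for a variant class."""
    kind = ModelKind(kind)
    if category is MafCategory.COMMON:
        return DEFAULT_RR_HOM_COMMON[1]
    if kind is ModelKind.RECESSIVE:
        return DEFAULT_RR_HOM_LOW_FREQUENCY["recessive"]
    return DEFAULT_RR_HOM_LOW_FREQUENCY["default"]


@dataclass(frozen=True)
class PenetranceTriple:
    """P(disease | 0, 1, 2 risk alleles)."""

    f0: float
    f1: float
    f2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f0, self.f1, self.f2], dtype=float)


@dataclass(frozen=True)
class CaseControlCounts:
    case_counts: tuple[int, int, int]
    control_counts: tuple[int, int, int]

    @property
    def n_cases(self) -> int:
        return sum(self.case_counts)

    @property
    def n_controls(self) -> int:
        return sum(self.control_counts)


@dataclass(frozen=True)
class PowerEstimate:
    causal: str
    model: DiseaseModel
    n_cases: int
    n_controls: int
    alpha: float
    mode: str
    replicates: int
    power: float
    tested: str | None = None

    @property
    def mc_se(self) -> float:
        return math.sqrt(self.power * (1.0 - self.power) / self.replicates)


# -- penetrance algebra ---------------------------------------------------


def hwe_genotype_freqs(risk_allele_freq: float) -> np.ndarray:
    """((1-p)^2, 2p(1-p), p^2) under Hardy-Weinberg equilibrium."""
    p = float(risk_allele_freq)
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"allele frequency must lie in [0, 1]; got {p}")
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p], dtype=float)


def solve_penetrance(model: DiseaseModel, risk_allele_freq: float) -> PenetranceTriple:
    """Solve f0 from the prevalence identity; f1, f2 scale by the risks."""
    geno = hwe_genotype_freqs(risk_allele_freq)
    denom = geno[0] + model.rr_het * geno[1] + model.rr_hom * geno[2]
    f0 = model.prevalence / denom
    f1 = model.rr_het * f0
    f2 = model.rr_hom * f0
    if f1 > 1.0 or f2 > 1.0:
        raise InfeasibleModelError(
            f"penetrance exceeds 1 for {model.kind.value} model "
            f"(K={model.prevalence}, rr_het={model.rr_het}, rr_hom={model.rr_hom}, "
            f"p={risk_allele_freq}): f1={f1:.4g}, f2={f2:.4g}"
        )
    return PenetranceTriple(f0=f0, f1=f1, f2=f2)


def case_control_genotype_freqs(
    pen: PenetranceTriple, geno: Sequence[float], prevalence: float
) -> tuple[np.ndarray, np.ndarray]:
    """Bayes inversion: genotype distributions within cases and controls."""
    geno = np.asarray(geno, dtype=float)
    f = pen.as_array()
    if abs(float(f @ geno) - prevalence) > 1e-9:
        raise ConsistencyError(
            "penetrances, genotype frequencies and prevalence are inconsistent"
        )
    case = f * geno / prevalence
    control = (1.0 - f) * geno / (1.0 - prevalence)
    return case, control


# -- test statistic -------------------------------------------------------


def chi2_2df_test(counts: CaseControlCounts) -> tuple[float, float]:
    """Pearson chi-square on the 2x3 case/control-by-genotype table.

    Genotype columns with zero total are dropped and the degrees of
    freedom reduced accordingly.
    """
    table = np.array([counts.case_counts, counts.control_counts], dtype=float)
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        raise DegenerateTableError(
            "fewer than two genotype columns with nonzero totals"
        )
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def _chi2_batch(case_counts: np.ndarray, control_counts: np.ndarray) -> np.ndarray:
    """P-values of the 2x3 Pearson test for many replicates at once.

    Replicates with fewer than two informative columns get p = 1
    (no evidence either way).
    """
    O = np.stack([case_counts, control_counts], axis=1).astype(float)  # R x 2 x 3
    col = O.sum(axis=1)
    row = O.sum(axis=2)
    total = row.sum(axis=1)
    E = row[:, :, None] * col[:, None, :] / total[:, None, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(E > 0, (O - E) ** 2 / E, 0.0)
    stat = terms.sum(axis=(1, 2))
    df = (col > 0).sum(axis=1) - 1
    p = np.ones_like(stat)
    ok = df >= 1
    p[ok] = stats.chi2.sf(stat[ok], df[ok])
    return p


# -- panel-resampling simulator -------------------------------------------


def _rejection_sample_pairs(
    rng: np.random.Generator,
    causal_col: np.ndarray,
    accept_by_genotype: np.ndarray,
    n_needed: int,
    max_batches: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Chromosome-pair indices accepted with genotype-dependent probability."""
    n_hap = causal_col.size
    q = causal_col.mean()
    geno_probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
    mean_accept = float(geno_probs @ accept_by_genotype)
    if mean_accept <= 0.0:
        raise SimulationError("acceptance probability is zero for this stratum")
    first: list[np.ndarray] = []
    second: list[np.ndarray] = []
    remaining = n_needed
    for _ in range(max_batches):
        if remaining <= 0:
            break
        batch = int(min(5_000_000, max(1000, remaining / mean_accept * 1.3)))
        i1 = rng.integers(n_hap, size=batch)
        i2 = rng.integers(n_hap, size=batch)
        g = causal_col[i1] + causal_col[i2]
        accepted = np.flatnonzero(rng.random(batch) < accept_by_genotype[g])
        take = accepted[: min(accepted.size, remaining)]
        first.append(i1[take])
        second.append(i2[take])
        remaining -= take.size
    if remaining > 0:
        raise SimulationError(
            f"rejection sampling exhausted its budget with {remaining} "
            "individuals still required"
        )
    return np.concatenate(first), np.concatenate(second)


def simulate_case_control(
    panel: HaplotypePanel,
    causal: str,
    model: DiseaseModel,
    n_cases: int,
    n_controls: int,
    seed: int | np.random.Generator = 0,
    sites: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample chromosome pairs into a case-control genotype matrix.

    Individuals draw two chromosomes uniformly with replacement; a draw is
    accepted as a case with probability equal to its causal-genotype
    penetrance, and as a control with the complement.  Returns a genotype
    matrix (cases first, then controls; columns follow ``sites`` or the
    whole panel) and a 1/0 status vector.  Deterministic under the seed.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    j = panel.variant_index(causal)
    causal_col = panel.haplotypes[:, j]
    p_risk = float(causal_col.mean())  # risk allele = alternate allele
    pen = solve_penetrance(model, p_risk).as_array()
    site_idx = (
        np.arange(panel.n_variants)
        if sites is None
        else np.array([panel.variant_index(s) for s in sites], dtype=np.int64)
    )
    H = panel.haplotypes[:, site_idx]
    ca1, ca2 = _rejection_sample_pairs(rng, causal_col, pen, n_cases)
    co1, co2 = _rejection_sample_pairs(rng, causal_col, 1.0 - pen, n_controls)
    genotypes = np.concatenate(
        [
            H[ca1, :].astype(np.int16) + H[ca2, :],
            H[co1, :].astype(np.int16) + H[co2, :],
        ]
    )
    status = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    return genotypes, status


def _best_proxy(
    panel: HaplotypePanel,
    causal: str,
    mode: str,
    manifest: ArrayManifest | None,
) -> str | None:
    """Tested SNP per mode; ties on r2 break to the lowest (chrom, pos)."""
    j = panel.variant_index(causal)
    if mode == "all_snps":
        return causal
    if mode == "exclude_causal":
        candidates = np.array(
            [k for k in range(panel.n_variants) if k != j], dtype=np.int64
        )
    elif mode == "panel_restricted":
        if manifest is None:
            raise ConsistencyError("mode='panel_restricted' requires a manifest")
        candidates = np.array(
            [
                k
                for k, v in enumerate(panel.variants)
                if (v.chrom, v.pos) in manifest.sites
            ],
            dtype=np.int64,
        )
        if candidates.size and j in candidates:
            return causal  # causal directly typed on the array
    else:
        raise ConsistencyError(f"unknown mode {mode!r}")
    if candidates.size == 0:
        return None
    r2 = _r2_one_vs_many(panel.haplotypes, j, candidates)
    best = r2.max()
    tied = candidates[np.isclose(r2, best, rtol=0, atol=1e-12)]
    keyed = sorted(tied, key=lambda k: (panel.variants[k].chrom, panel.variants[k].pos))
    return panel.variants[keyed[0]].id


def estimate_power(
    panel: HaplotypePanel,
    causal: str,
    model: DiseaseModel,
    n_cases: int,
    n_controls: int,
    alpha: float = DEFAULT_ALPHA,
    replicates: int = DEFAULT_REPLICATES,
    mode: str = "all_snps",
    manifest: ArrayManifest | None = None,
    seed: int = 0,
) -> PowerEstimate:
    """Monte-Carlo power of the 2-df test at the causal or best-proxy SNP.

    ``mode`` selects the tested SNP: the causal itself (``all_snps``), the
    highest-r2 non-causal panel SNP (``exclude_causal``), or the highest-r2
    SNP among the manifest's sites (``panel_restricted``).  When no
    eligible SNP exists, power is reported as 0 with a logged warning.
    """
    if not 0.0 < alpha < 1.0:
        raise DomainError("alpha must lie in (0, 1)")
    tested = _best_proxy(panel, causal, mode, manifest)
    if tested is None:
        logger.warning(
            "no eligible SNP to test for causal %s under mode %s; power = 0",
            causal,
            mode,
        )
        return PowerEstimate(
            causal=causal,
            model=model,
            n_cases=n_cases,
            n_controls=n_controls,
            alpha=alpha,
            mode=mode,
            replicates=replicates,
            power=0.0,
            tested=None,
        )
    rng = np.random.default_rng(seed)
    case_counts = np.empty((replicates, 3), dtype=np.int64)
    control_counts = np.empty((replicates, 3), dtype=np.int64)
    for r in range(replicates):
        genotypes, status = simulate_case_control(
            panel, causal, model, n_cases, n_controls, seed=rng, sites=[tested]
        )
        g = genotypes[:, 0]
        case_counts[r] = np.bincount(g[status == 1], minlength=3)[:3]
        control_counts[r] = np.bincount(g[status == 0], minlength=3)[:3]
    pvals = _chi2_batch(case_counts, control_counts)
    power = float((pvals <= alpha).mean())
    return PowerEstimate(
        causal=causal,
        model=model,
        n_cases=n_cases,
        n_controls=n_controls,
        alpha=alpha,
        mode=mode,
        replicates=replicates,
        power=power,
        tested=tested,
    )


# -- direct (HWE) simulator and analytic oracle ---------------------------


def simulate_power_direct(
    model: DiseaseModel,
    risk_allele_freq: float,
    n_cases: int,
    n_controls: int,
    alpha: float = DEFAULT_ALPHA,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
) -> PowerEstimate:
    """Monte-Carlo direct-test power sampling genotypes from the solved
    case/control conditional distributions (HWE population)."""
    rng = np.random.default_rng(seed)
    pen = solve_penetrance(model, risk_allele_freq)
    geno = hwe_genotype_freqs(risk_allele_freq)
    case_p, control_p = case_control_genotype_freqs(pen, geno, model.prevalence)
    case_counts = rng.multinomial(n_cases, case_p, size=replicates)
    control_counts = rng.multinomial(n_controls, control_p, size=replicates)
    pvals = _chi2_batch(case_counts, control_counts)
    power = float((pvals <= alpha).mean())
    return PowerEstimate(
        causal="direct",
        model=model,
        n_cases=n_cases,
        n_controls=n_controls,
        alpha=alpha,
        mode="all_snps",
        replicates=replicates,
        power=power,
        tested="direct",
    )


def analytic_power(
    model: DiseaseModel,
    risk_allele_freq: float,
    n_cases: int,
    n_controls: int,
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Noncentral chi-square approximation to the direct 2-df test power.

    The noncentrality is ``n_eff * sum_g (case_g - control_g)^2 / pbar_g``
    with ``n_eff = n_cases n_controls / (n_cases + n_controls)`` and
    ``pbar`` the arm-size-weighted mean cell probability.
    """
    pen = solve_penetrance(model, risk_allele_freq)
    geno = hwe_genotype_freqs(risk_allele_freq)
    case_p, control_p = case_control_genotype_freqs(pen, geno, model.prevalence)
    n = n_cases + n_controls
    pbar = (n_cases * case_p + n_controls * control_p) / n
    mask = pbar > 0
    lam = (
        n_cases
        * n_controls
        / n
        * float(((case_p[mask] - control_p[mask]) ** 2 / pbar[mask]).sum())
    )
    crit = stats.chi2.ppf(1.0 - alpha, 2)
    if lam == 0.0:
        return float(alpha)
    return float(stats.ncx2.sf(crit, 2, lam))


def aggregate_power_by_maf(
    estimates: Sequence[PowerEstimate],
    panel: HaplotypePanel,
    bin_width: float = 0.01,
) -> pd.DataFrame:
    """Mean power per causal-MAF bin; bins with no causal SNPs are omitted."""
    if not estimates:
        raise ConsistencyError("no estimates to aggregate")
    head = estimates[0]
    for e in estimates[1:]:
        if (
            e.model != head.model
            or e.n_cases != head.n_cases
            or e.n_controls != head.n_controls
            or e.alpha != head.alpha
            or e.mode != head.mode
        ):
            raise ConsistencyError(
                "estimates mix models, sample sizes, alphas or modes"
            )
    rows = []
    for e in estimates:
        maf = panel.variants[panel.variant_index(e.causal)].maf
        rows.append({"maf": maf, "power": e.power})
    frame = pd.DataFrame(rows)
    frame["maf_bin"] = (frame["maf"] / bin_width).astype(int) * bin_width
    out = (
        frame.groupby("maf_bin")
        .agg(mean_power=("power", "mean"), n_causal=("power", "size"))
        .reset_index()
    )
    return out
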