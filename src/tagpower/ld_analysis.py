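"""Pairwise r-squared within distance windows or genes, stratified by
MAF-category pair, plus the dosage-accuracy metric.

r-squared is computed from phased haplotype gamete counts:
``r2 = D**2 / (pA (1 - pA) pB (1 - pB))`` with ``D = pAB - pA pB``, which
equals the squared Pearson correlation of the two 0/1 columns.  Profiles
summarize pairs into five left-closed r-squared intervals of width 0.2
(top bin closed at 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError
from .panel_io import GeneRegion, HaplotypePanel, MafCategory, assign_regions

#: Strata drawn in the figures (common/common, low-frequency/common,
#: low-frequency/low-frequency).  Pairs involving a rare-category variant
#: are reported under the RARE_STRATA labels instead.
FIGURE_STRATA = ("cc", "rc", "rr")
RARE_STRATA = ("rare_common", "rare_low", "rare_rare")
ALL_STRATA = FIGURE_STRATA + RARE_STRATA

R2_BIN_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
R2_BIN_LABELS = ("[0,0.2)", "[0.2,0.4)", "[0.4,0.6)", "[0.6,0.8)", "[0.8,1]")


def category_pair(a: MafCategory, b: MafCategory) -> str:
    """Stratum label for a pair of MAF categories."""
    cats = {a, b}
    if MafCategory.RARE in cats:
        other = (cats - {MafCategory.RARE}) or {MafCategory.RARE}
        o = next(iter(other))
        if o is MafCategory.RARE:
            return "rare_rare"
        return "rare_low" if o is MafCategory.LOW_FREQUENCY else "rare_common"
    if cats == {MafCategory.COMMON}:
        return "cc"
    if cats == {MafCategory.LOW_FREQUENCY}:
        return "rr"
    return "rc"


@dataclass(frozen=True)
class LDPair:
    left: str
    right: str
    distance: int
    r2: float
    category_pair: str


@dataclass(frozen=True)
class LDProfile:
    """Proportions of pairs in the five r-squared intervals for one stratum."""

    window: int
    stratum: str
    bins: tuple[float, float, float, float, float]
    n_pairs: int


def compute_r2(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Haplotype r-squared between two polymorphic 0/1 columns.

    Symmetric and invariant to relabeling the alleles at either site.
    """
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DomainError("columns must be 1-D and of equal length")
    pa, pb = a.mean(), b.mean()
    va, vb = pa * (1.0 - pa), pb * (1.0 - pb)
    if va == 0.0 or vb == 0.0:
        raise DomainError("r2 undefined for a monomorphic column")
    d = (a * b).mean() - pa * pb
    return float(min(1.0, d * d / (va * vb)))


def _r2_one_vs_many(H: np.ndarray, j: int, others: np.ndarray) -> np.ndarray:
    """Vectorized r2 between column ``j`` and each column index in ``others``."""
    a = H[:, j].astype(float)
    B = H[:, others].astype(float)
    n = a.size
    pa = a.mean()
    pb = B.mean(axis=0)
    d = (a @ B) / n - pa * pb
    denom = pa * (1.0 - pa) * pb * (1.0 - pb)
    return np.minimum(1.0, d * d / denom)


def iter_ld_pairs(
    panel: HaplotypePanel,
    window: int,
    scope: str = "distance",
    regions: Sequence[GeneRegion] | None = None,
) -> list[LDPair]:
    """All unordered in-scope pairs, each counted once.

    ``scope="distance"``: pairs on the same chromosome with
    ``|pos_left - pos_right| <= window``.  ``scope="gene"``: pairs within
    the same region (``regions`` required; the window is ignored).
    """
    if scope not in ("distance", "gene"):
        raise ConfigError(f"unknown scope {scope!r}")
    if scope == "distance" and window <= 0:
        raise DomainError("window must be positive")
    if scope == "gene" and regions is None:
        raise ConfigError("scope='gene' requires regions")
    H = panel.haplotypes
    pos = panel.positions
    chroms = panel.chroms
    cats = panel.categories
    ids = [v.id for v in panel.variants]
    if scope == "gene":
        member = assign_regions(panel, regions)
    pairs: list[LDPair] = []
    for j in range(panel.n_variants - 1):
        if scope == "distance":
            hi = int(np.searchsorted(pos, pos[j] + window, side="right"))
            others = np.arange(j + 1, hi)
            others = others[[chroms[k] == chroms[j] for k in others]]
        else:
            if member[j] < 0:
                continue
            others = np.array(
                [k for k in range(j + 1, panel.n_variants) if member[k] == member[j]],
                dtype=np.int64,
            )
        if others.size == 0:
            continue
        r2 = _r2_one_vs_many(H, j, others)
        for k, val in zip(others, r2):
            pairs.append(
                LDPair(
                    left=ids[j],
                    right=ids[int(k)],
                    distance=int(abs(pos[int(k)] - pos[j])),
                    r2=float(val),
                    category_pair=category_pair(cats[j], cats[int(k)]),
                )
            )
    return pairs


def bin_r2_proportions(r2_values: Sequence[float]) -> tuple[float, ...]:
    """Proportions over the five r-squared intervals; sums to 1."""
    vals = np.asarray(list(r2_values), dtype=float)
    if vals.size == 0:
        raise DomainError("cannot bin an empty list of r2 values")
    if (vals < 0).any() or (vals > 1).any():
        raise DomainError("r2 values must lie in [0, 1]")
    idx = np.minimum((vals / 0.2).astype(int), 4)
    counts = np.bincount(idx, minlength=5).astype(float)
    return tuple(counts / vals.size)


def pairwise_ld_profile(
    panel: HaplotypePanel,
    window: int,
    scope: str = "distance",
    regions: Sequence[GeneRegion] | None = None,
    strata: Sequence[str] = ALL_STRATA,
) -> list[LDProfile]:
    """Five-interval r-squared profiles per MAF-category stratum."""
    pairs = iter_ld_pairs(panel, window, scope=scope, regions=regions)
    by_stratum: dict[str, list[float]] = {s: [] for s in strata}
    for p in pairs:
        if p.category_pair in by_stratum:
            by_stratum[p.category_pair].append(p.r2)
    profiles = []
    for s in strata:
        vals = by_stratum[s]
        bins = bin_r2_proportions(vals) if vals else (0.0,) * 5
        profiles.append(
            LDProfile(window=window, stratum=s, bins=bins, n_pairs=len(vals))
        )
    return profiles


def dosage_r2(true_genotypes: Sequence[int], imputed_dosages: Sequence[float]) -> float:
    """Squared Pearson correlation between true genotypes and dosages.

    Constant dosages score 0; constant true genotypes are a caller error.
    """
    truth = np.asarray(true_genotypes, dtype=float)
    dose = np.asarray(imputed_dosages, dtype=float)
    if truth.shape != dose.shape or truth.ndim != 1 or truth.size < 2:
        raise DomainError("need two equal-length vectors of length >= 2")
    if np.ptp(truth) == 0:
        raise DomainError("true genotypes are constant")
    if np.ptp(dose) == 0:
        return 0.0
    r = np.corrcoef(truth, dose)[0, 1]
    return float(min(1.0, r * r))


def pairs_to_frame(pairs: Sequence[LDPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "left": p.left,
                "right": p.right,
                "distance": p.distance,
                "r2": p.r2,
                "category_pair": p.category_pair,
            }
            for p in pairs
        ],
        columns=["left", "right", "distance", "r2", "category_pair"],
    )


def profiles_to_frame(profiles: Sequence[LDProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"window": p.window, "stratum": p.stratum, "n_pairs": p.n_pairs}
        row.update({lab: b for lab, b in zip(R2_BIN_LABELS, p.bins)})
        rows.append(row)
    return pd.DataFrame(rows, columns=["window", "stratum", "n_pairs", *R2_BIN_LABELS])
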