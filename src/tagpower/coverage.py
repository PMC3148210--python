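"""Coverage of a target panel's variation by a fixed tag/array site set.

A target SNP counts as covered when its own site is on the array (direct
typing, r2 = 1 by convention) or when some array site on the same
chromosome within the window has haplotype r2 at or above the threshold
with it.  Array sites absent from the target panel, or monomorphic in the
target samples, capture nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .ld_analysis import _r2_one_vs_many
from .panel_io import ArrayManifest, HaplotypePanel, MafCategory

__all__ = ["CoverageReport", "coverage_at_threshold", "coverage_curve"]

DEFAULT_WINDOW = 200_000


@dataclass(frozen=True)
class CoverageReport:
    """Per-category and overall (n_target, n_covered, proportion)."""

    threshold: float
    tag_set_name: str
    per_category: dict
    n_target: int
    n_covered: int

    @property
    def proportion(self) -> float:
        return self.n_covered / self.n_target if self.n_target else 0.0

    def category_proportion(self, category: MafCategory) -> float:
        n, c = self.per_category.get(category.value, (0, 0))
        return c / n if n else 0.0


def _covered_mask(
    target: HaplotypePanel,
    tags: ArrayManifest,
    threshold: float,
    window: int,
    count_direct: bool,
) -> np.ndarray:
    if not 0.0 < threshold <= 1.0:
        raise DomainError(f"threshold must lie in (0, 1]; got {threshold}")
    if window <= 0:
        raise DomainError("window must be positive")
    sites = target.sites()
    direct = np.array([s in tags.sites for s in sites], dtype=bool)
    # tag columns usable for indirect capture: on the array AND polymorphic
    # in the target samples (panel columns are polymorphic by construction)
    tag_idx = np.flatnonzero(direct)
    covered = direct.copy() if count_direct else np.zeros(len(sites), dtype=bool)
    pos = target.positions
    chroms = target.chroms
    H = target.haplotypes
    if tag_idx.size == 0:
        return covered
    for j in range(target.n_variants):
        if covered[j]:
            continue
        near = tag_idx[
            (np.abs(pos[tag_idx] - pos[j]) <= window)
            & np.array([chroms[k] == chroms[j] for k in tag_idx], dtype=bool)
        ]
        near = near[near != j]
        if near.size == 0:
            continue
        r2 = _r2_one_vs_many(H, j, near)
        if (r2 >= threshold).any():
            covered[j] = True
    return covered


def coverage_at_threshold(
    target: HaplotypePanel,
    tags: ArrayManifest,
    threshold: float,
    window: int = DEFAULT_WINDOW,
    count_direct: bool = True,
) -> CoverageReport:
    """Coverage report at one r2 threshold, stratified by MAF category.

    ``count_direct=False`` restricts "covered" to indirect r2 capture,
    the switchable alternative reading of array content.
    """
    covered = _covered_mask(target, tags, threshold, window, count_direct)
    cats = np.array([v.category.value for v in target.variants])
    per_category = {}
    for cat in MafCategory:
        mask = cats == cat.value
        per_category[cat.value] = (int(mask.sum()), int(covered[mask].sum()))
    return CoverageReport(
        threshold=threshold,
        tag_set_name=tags.name,
        per_category=per_category,
        n_target=target.n_variants,
        n_covered=int(covered.sum()),
    )


def coverage_curve(
    target: HaplotypePanel,
    tags: ArrayManifest,
    thresholds: Sequence[float],
    window: int = DEFAULT_WINDOW,
    count_direct: bool = True,
) -> list[CoverageReport]:
    """One report per threshold; thresholds must be sorted ascending."""
    ts = list(thresholds)
    if ts != sorted(ts):
        raise DomainError("thresholds must be sorted ascending")
    return [
        coverage_at_threshold(target, tags, t, window=window, count_direct=count_direct)
        for t in ts
    ]


def reports_to_frame(reports: Sequence[CoverageReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {
            "threshold": r.threshold,
            "tag_set": r.tag_set_name,
            "n_target": r.n_target,
            "n_covered": r.n_covered,
            "overall": r.proportion,
        }
        for cat in MafCategory:
            n, c = r.per_category[cat.value]
            row[f"{cat.value}_n"] = n
            row[f"{cat.value}_covered"] = c
            row[cat.value] = c / n if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
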