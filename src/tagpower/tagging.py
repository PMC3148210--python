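"""Greedy pairwise tag-SNP selection with bins, and untaggable detection.

A SNP "qualifies" as a neighbor of another when the two are in scope (same
chromosome within the window, or same gene) and their haplotype r-squared
is at or above the threshold.  Selection is iterative: the SNP with the
most qualifying neighbors among the remaining SNPs becomes a tag and its
bin (itself plus those neighbors) is removed; neighbor counts are
recomputed each round.  SNPs with no qualifying neighbor in the full graph
are untaggable.  A SNP left with neighbors only outside the remaining set
still has a tagging certificate in principle but not to any selected tag;
by default it becomes a singleton tag so that the untaggable set coincides
exactly with the zero-degree SNPs (``singleton_policy="untaggable"``
reproduces the stricter reading where such leftovers are reported as
untaggable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import ConfigError, ConsistencyError, DomainError
from .ld_analysis import iter_ld_pairs
from .panel_io import GeneRegion, HaplotypePanel, MafCategory

__all__ = ["TagAssignment", "greedy_select_tags", "find_untaggable", "tag_summary"]


@dataclass(frozen=True)
class TagAssignment:
    """Partition of a panel into tags with bins and untaggable SNPs."""

    threshold: float
    scope: str
    window: int
    bins: tuple  # of (tag_id, frozenset of tagged member ids)
    untaggable: frozenset

    @property
    def tags(self) -> tuple:
        return tuple(tag for tag, _ in self.bins)

    def covered_ids(self) -> set:
        out: set = set()
        for tag, members in self.bins:
            out.add(tag)
            out.update(members)
        return out


def _qualifying_graph(
    panel: HaplotypePanel,
    threshold: float,
    scope: str,
    window: int,
    regions: Sequence[GeneRegion] | None,
) -> dict[str, set]:
    if not 0.0 < threshold <= 1.0:
        raise DomainError(f"threshold must lie in (0, 1]; got {threshold}")
    if scope == "gene" and regions is None:
        raise ConfigError("scope='gene' requires regions")
    adj: dict[str, set] = {v.id: set() for v in panel.variants}
    for p in iter_ld_pairs(panel, window, scope=scope, regions=regions):
        if p.r2 >= threshold:
            adj[p.left].add(p.right)
            adj[p.right].add(p.left)
    return adj


def greedy_select_tags(
    panel: HaplotypePanel,
    threshold: float,
    scope: str = "distance",
    window: int = 200_000,
    regions: Sequence[GeneRegion] | None = None,
    singleton_policy: str = "tag",
) -> TagAssignment:
    """Greedy maximum-neighbor tag selection.

    Ties on the neighbor count break to the lowest (chrom, pos).  Every
    panel variant ends up exactly once: as a tag, in a bin, or untaggable.
    """
    if singleton_policy not in ("tag", "untaggable"):
        raise ConfigError(f"unknown singleton_policy {singleton_policy!r}")
    adj = _qualifying_graph(panel, threshold, scope, window, regions)
    order = {v.id: (v.chrom, v.pos) for v in panel.variants}
    zero_degree = frozenset(i for i, nbrs in adj.items() if not nbrs)
    remaining = set(adj) - zero_degree
    bins: list[tuple[str, frozenset]] = []
    untaggable = set(zero_degree)
    while remaining:
        best = min(remaining, key=lambda i: (-len(adj[i] & remaining), order[i]))
        members = adj[best] & remaining
        if not members:
            # all remaining SNPs have zero live neighbors
            leftovers = sorted(remaining, key=lambda i: order[i])
            if singleton_policy == "tag":
                bins.extend((i, frozenset()) for i in leftovers)
            else:
                untaggable.update(leftovers)
            break
        bins.append((best, frozenset(members)))
        remaining -= members | {best}
    return TagAssignment(
        threshold=threshold,
        scope=scope,
        window=window,
        bins=tuple(bins),
        untaggable=frozenset(untaggable),
    )


def find_untaggable(
    panel: HaplotypePanel,
    threshold: float,
    scope: str = "distance",
    window: int = 200_000,
    regions: Sequence[GeneRegion] | None = None,
) -> frozenset:
    """SNPs with no in-scope partner at r2 >= threshold (greedy-independent)."""
    adj = _qualifying_graph(panel, threshold, scope, window, regions)
    return frozenset(i for i, nbrs in adj.items() if not nbrs)


def tag_summary(assignment: TagAssignment, panel: HaplotypePanel) -> pd.DataFrame:
    """Per-MAF-category proportions of tag, tagged and untaggable SNPs.

    Rows sum to 1 within each category present in the panel.
    """
    ids = {v.id for v in panel.variants}
    assigned = assignment.covered_ids() | set(assignment.untaggable)
    if assigned != ids:
        raise ConsistencyError("assignment does not match panel variants")
    role: dict[str, str] = {}
    for tag, members in assignment.bins:
        role[tag] = "tag"
        for m in members:
            role[m] = "tagged"
    for i in assignment.untaggable:
        role[i] = "untaggable"
    rows = []
    for cat in MafCategory:
        members = [v for v in panel.variants if v.category is cat]
        if not members:
            continue
        n = len(members)
        counts = {"tag": 0, "tagged": 0, "untaggable": 0}
        for v in members:
            counts[role[v.id]] += 1
        rows.append(
            {
                "category": cat.value,
                "n": n,
                "tag": counts["tag"] / n,
                "tagged": counts["tagged"] / n,
                "untaggable": counts["untaggable"] / n,
            }
        )
    return pd.DataFrame(rows, columns=["category", "n", "tag", "tagged", "untaggable"])


def assignment_to_frames(
    assignment: TagAssignment, panel: HaplotypePanel
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Tags, bin-membership (with certificate r2) and untaggable tables."""
    from .ld_analysis import compute_r2

    tag_rows = [{"tag": t} for t in assignment.tags]
    bin_rows = []
    for tag, members in assignment.bins:
        tcol = panel.column(tag)
        for m in sorted(members, key=panel.variant_index):
            bin_rows.append({"tag": tag, "member": m, "r2": compute_r2(tcol, panel.column(m))})
    unt_rows = [
        {"variant": i}
        for i in sorted(assignment.untaggable, key=panel.variant_index)
    ]
    return (
        pd.DataFrame(tag_rows, columns=["tag"]),
        pd.DataFrame(bin_rows, columns=["tag", "member", "r2"]),
        pd.DataFrame(unt_rows, columns=["variant"]),
    )
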