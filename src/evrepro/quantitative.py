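"""Abundance-level (quantitative) variability of replicate groups.

Operates on APEX-flavor tables: absolute per-protein abundances whose column
sums are placed on a common scale by the normalization constant C.  The
member-level statistic for the RSD is each replicate's total abundance (its
column sum); scheme assembly and interpretations are shared with the
qualitative module.  Also provides the pooled-abundance ranking used to lay
out quantitative heatmaps and the most-abundant-protein filter (mean across
all replicates above a fixed cutoff, 2.0E6 by default under C = 1.0E8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_design import AbundanceTable, Flavor, GroupingScheme
from .qualitative import Interpretation, RSDResult, compute_rsd

__all__ = [
    "AbundanceRanking",
    "TopAbundantSet",
    "abundance_rsd",
    "rank_for_heatmap",
    "top_abundant",
    "DEFAULT_ABUNDANCE_CUTOFF",
]

DEFAULT_ABUNDANCE_CUTOFF = 2.0e6


@dataclass(frozen=True)
class AbundanceRanking:
    """Proteins ordered by decreasing pooled abundance; columns in group order."""

    protein_ids: tuple[str, ...]
    pooled_abundance: tuple[float, ...]
    replicate_order: tuple[str, ...]
    values: np.ndarray  # reordered (ranked proteins x grouped replicates)

    def to_dict(self) -> dict:
        return {
            "protein_ids": list(self.protein_ids),
            "pooled_abundance": list(self.pooled_abundance),
            "replicate_order": list(self.replicate_order),
        }


@dataclass(frozen=True)
class TopAbundantSet:
    """Proteins whose mean abundance over all replicates reaches the cutoff."""

    cutoff: float
    protein_ids: tuple[str, ...]
    mean_abundance: dict[str, float]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.mean_abundance

    def __len__(self) -> int:
        return len(self.protein_ids)

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "n_proteins": len(self.protein_ids),
            "protein_ids": list(self.protein_ids),
            "mean_abundance": dict(self.mean_abundance),
        }


def _require_apex(table: AbundanceTable, op: str) -> None:
    if table.flavor is not Flavor.APEX:
        raise ValueError(f"{op} expects an APEX-flavor (absolute abundance) table")


def abundance_rsd(
    table: AbundanceTable,
    grouping: GroupingScheme,
    interpretation: Interpretation | str = Interpretation.WITHIN_GROUP_MEAN,
    proteins: str = "complete_cases",
) -> RSDResult:
    """RSD of total abundance per replicate under a grouping.

    The member value for replicate ``r`` is its column sum.  ``proteins``
    selects the rows contributing to the totals: ``"complete_cases"``
    (default; only proteins nonzero in every replicate of the grouping, the
    replicate-common set an absolute-abundance supplementary table lists) or
    ``"all"``.  On a table whose columns are each normalized to the constant
    C, the all-protein totals are constant by construction and the RSD
    degenerates to 0; the complete-case restriction is what makes the
    statistic informative there.
    """
    _require_apex(table, "abundance_rsd")
    if proteins not in {"all", "complete_cases"}:
        raise ValueError("proteins must be 'all' or 'complete_cases'")
    members = [m for g in grouping.groups for m in g]
    cols = {m: table.column(m) for m in members}
    if proteins == "complete_cases":
        mask = np.all(np.stack([cols[m] > 0 for m in members], axis=1), axis=1)
        cols = {m: cols[m][mask] for m in members}
    totals = {m: float(cols[m].sum()) for m in members}
    if any(v == 0 for v in totals.values()):
        zero = [m for m, v in totals.items() if v == 0]
        raise ValueError(f"replicate(s) with zero total abundance: {zero}")
    result = compute_rsd(
        grouping, totals, statistic_kind="abundance", interpretation=interpretation
    )
    return result


def rank_for_heatmap(table: AbundanceTable, grouping: GroupingScheme) -> AbundanceRanking:
    """Order proteins by decreasing abundance pooled over all replicates and
    reorder columns in the grouping's group-then-member order.

    Pooling is the per-protein sum across every replicate; ties are broken by
    lexicographic protein id so the layout is deterministic.
    """
    pooled = table.values.sum(axis=1)
    order = sorted(
        range(table.n_proteins), key=lambda i: (-pooled[i], table.protein_ids[i])
    )
    replicate_order = tuple(m for g in grouping.groups for m in g)
    col_idx = [table.replicate_ids.index(m) for m in replicate_order]
    values = table.values[np.ix_(order, col_idx)]
    return AbundanceRanking(
        protein_ids=tuple(table.protein_ids[i] for i in order),
        pooled_abundance=tuple(float(pooled[i]) for i in order),
        replicate_order=replicate_order,
        values=values,
    )


def top_abundant(
    table: AbundanceTable, cutoff: float = DEFAULT_ABUNDANCE_CUTOFF
) -> TopAbundantSet:
    """Proteins whose mean abundance across all replicate columns is at or
    above ``cutoff`` (boundary inclusive); zeros count toward the mean."""
    _require_apex(table, "top_abundant")
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    means = table.values.mean(axis=1) if table.n_replicates else np.array([])
    keep = [
        (p, float(m))
        for p, m in zip(table.protein_ids, means)
        if m >= cutoff
    ]
    return TopAbundantSet(
        cutoff=float(cutoff),
        protein_ids=tuple(p for p, _ in keep),
        mean_abundance={p: m for p, m in keep},
    )
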