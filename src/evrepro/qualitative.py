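"""Presence/absence (qualitative) variability across replicates.

A protein is *identified* in a replicate when its intensity exceeds a
threshold (0 by default, i.e. any nonzero LFQ intensity counts as presence).
From the resulting boolean matrix this module derives:

* occupancy classes — proteins seen in every replicate, in an intermediate
  number (>1 and < all), or in exactly one replicate (singletons);
* per-triad three-set Venn partitions (unique / shared-by-2 / common-to-3);
* the relative standard deviation (RSD) of identified-protein counts under
  the TR and BR groupings, the study's scale-free summary of qualitative
  technical vs biological variability.

Two RSD readings are supported (see :class:`Interpretation`): the per-group
RSD of the member counts averaged over groups, and the RSD of the three
group totals.  Both use the n-1 (sample) standard deviation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_design import AbundanceTable, GroupingScheme, Scheme

__all__ = [
    "PresenceMatrix",
    "OccupancyProfile",
    "VennPartition",
    "Interpretation",
    "GroupStats",
    "RSDResult",
    "presence_matrix",
    "occupancy_profile",
    "venn_partition",
    "count_rsd",
    "compute_rsd",
]


class Interpretation(str, enum.Enum):
    """How a scheme-level RSD is assembled from triad member values.

    WITHIN_GROUP_MEAN: RSD within each group over its member values, then the
    unweighted mean across groups.  BETWEEN_GROUP_SUMS: a single RSD over the
    per-group totals (sum of member values per group).
    """

    WITHIN_GROUP_MEAN = "within_group_mean"
    BETWEEN_GROUP_SUMS = "between_group_sums"


@dataclass(frozen=True)
class PresenceMatrix:
    """Boolean protein x replicate detection matrix with its threshold."""

    protein_ids: tuple[str, ...]
    replicate_ids: tuple[str, ...]
    present: np.ndarray
    threshold: float = 0.0

    def __post_init__(self) -> None:
        present = np.asarray(self.present, dtype=bool)
        object.__setattr__(self, "present", present)
        object.__setattr__(self, "protein_ids", tuple(self.protein_ids))
        object.__setattr__(self, "replicate_ids", tuple(self.replicate_ids))
        if present.shape != (len(self.protein_ids), len(self.replicate_ids)):
            raise ValueError("presence matrix shape mismatch")

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_ids)

    def column(self, replicate_id: str) -> np.ndarray:
        return self.present[:, self.replicate_ids.index(replicate_id)]

    def counts_per_replicate(self) -> dict[str, int]:
        return {
            r: int(self.present[:, j].sum()) for j, r in enumerate(self.replicate_ids)
        }


@dataclass(frozen=True)
class OccupancyProfile:
    """Partition of detected proteins by the number of replicates they occupy."""

    n_total: int
    n_all: int
    n_intermediate: int
    n_singleton: int
    n_replicates: int
    occupancy: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_all": self.n_all,
            "n_intermediate": self.n_intermediate,
            "n_singleton": self.n_singleton,
            "n_replicates": self.n_replicates,
        }


@dataclass(frozen=True)
class VennPartition:
    """Triad-wise 3-set Venn region counts collapsed to unique/shared2/common3."""

    scheme: Scheme
    per_triad: tuple[dict, ...]
    averages: dict
    percentages: dict
    n_total: int

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme.value,
            "per_triad": list(self.per_triad),
            "averages": self.averages,
            "percentages": self.percentages,
            "n_total": self.n_total,
        }


@dataclass(frozen=True)
class GroupStats:
    """Member values and dispersion summary for one replicate group."""

    group_label: str
    member_ids: tuple[str, ...]
    member_values: tuple[float, ...]
    mean: float
    sample_sd: float
    rsd_percent: float


@dataclass(frozen=True)
class RSDResult:
    """Scheme-level relative standard deviation with per-group detail."""

    scheme: Scheme
    statistic_kind: str  # "count" or "abundance"
    interpretation: Interpretation
    per_group: tuple[GroupStats, ...]
    scheme_rsd_percent: float

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme.value,
            "statistic_kind": self.statistic_kind,
            "interpretation": self.interpretation.value,
            "scheme_rsd_percent": self.scheme_rsd_percent,
            "per_group": [
                {
                    "group": g.group_label,
                    "members": list(g.member_ids),
                    "values": list(g.member_values),
                    "mean": g.mean,
                    "sample_sd": g.sample_sd,
                    "rsd_percent": g.rsd_percent,
                }
                for g in self.per_group
            ],
        }


# ---------------------------------------------------------------------------


def presence_matrix(table: AbundanceTable, threshold: float = 0.0) -> PresenceMatrix:
    """Binarize an abundance table: present <=> value > ``threshold``."""
    if threshold < 0:
        raise ValueError("presence threshold must be non-negative")
    return PresenceMatrix(
        protein_ids=table.protein_ids,
        replicate_ids=table.replicate_ids,
        present=table.values > threshold,
        threshold=float(threshold),
    )


def occupancy_profile(presence: PresenceMatrix) -> OccupancyProfile:
    """Classify proteins by occupancy: all replicates / intermediate / singleton.

    Proteins absent everywhere are excluded from ``n_total``; the
    conservation identity ``n_all + n_intermediate + n_singleton = n_total``
    holds on every input.
    """
    n_reps = presence.n_replicates
    if n_reps < 2:
        raise ValueError("occupancy classes need at least 2 replicates")
    occ = presence.present.sum(axis=1)
    n_total = int((occ >= 1).sum())
    n_all = int((occ == n_reps).sum())
    n_singleton = int((occ == 1).sum())
    n_intermediate = int(((occ > 1) & (occ < n_reps)).sum())
    return OccupancyProfile(
        n_total=n_total,
        n_all=n_all,
        n_intermediate=n_intermediate,
        n_singleton=n_singleton,
        n_replicates=n_reps,
        occupancy={p: int(o) for p, o in zip(presence.protein_ids, occ)},
    )


def venn_partition(presence: PresenceMatrix, grouping: GroupingScheme) -> VennPartition:
    """Collapse each triad's 3-set Venn diagram to unique / shared-by-2 /
    common-to-3 counts, plus averages over triads and percentages of the
    cell-line total (proteins present in >= 1 of all replicates)."""
    for g in grouping.groups:
        if len(g) != 3:
            raise ValueError(f"venn partition requires triads; group {g} has {len(g)} members")
    occ_total = int((presence.present.sum(axis=1) >= 1).sum())
    per_triad = []
    for label, members in zip(grouping.group_labels, grouping.groups):
        cols = np.stack([presence.column(m) for m in members], axis=1)
        k = cols.sum(axis=1)
        per_triad.append(
            {
                "group": label,
                "unique_to_one": int((k == 1).sum()),
                "shared_by_exactly_two": int((k == 2).sum()),
                "common_to_three": int((k == 3).sum()),
            }
        )
    keys = ("unique_to_one", "shared_by_exactly_two", "common_to_three")
    averages = {k: float(np.mean([t[k] for t in per_triad])) for k in keys}
    percentages = {
        k: (100.0 * averages[k] / occ_total if occ_total else 0.0) for k in keys
    }
    return VennPartition(
        scheme=grouping.scheme,
        per_triad=tuple(per_triad),
        averages=averages,
        percentages=percentages,
        n_total=occ_total,
    )


def compute_rsd(
    grouping: GroupingScheme,
    member_values: dict[str, float],
    statistic_kind: str,
    interpretation: Interpretation | str = Interpretation.WITHIN_GROUP_MEAN,
) -> RSDResult:
    """Assemble a scheme-level RSD from one value per replicate.

    ``rsd = sd / mean * 100`` with the sample (n-1) standard deviation; a
    zero mean is an error (RSD undefined), as is a group with fewer than two
    members.
    """
    interpretation = Interpretation(interpretation)
    per_group: list[GroupStats] = []
    for label, members in zip(grouping.group_labels, grouping.groups):
        if len(members) < 2:
            raise ValueError(f"group {label} has fewer than 2 members; RSD undefined")
        vals = np.array([float(member_values[m]) for m in members])
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if mean == 0:
            raise ValueError(f"group {label} has zero mean; RSD undefined")
        per_group.append(
            GroupStats(
                group_label=label,
                member_ids=tuple(members),
                member_values=tuple(float(v) for v in vals),
                mean=mean,
                sample_sd=sd,
                rsd_percent=100.0 * sd / mean,
            )
        )
    if interpretation is Interpretation.WITHIN_GROUP_MEAN:
        scheme_rsd = float(np.mean([g.rsd_percent for g in per_group]))
    else:
        totals = np.array([sum(g.member_values) for g in per_group])
        if len(totals) < 2:
            raise ValueError("between-group-sums RSD needs at least 2 groups")
        mean = float(totals.mean())
        if mean == 0:
            raise ValueError("group totals have zero mean; RSD undefined")
        scheme_rsd = 100.0 * float(totals.std(ddof=1)) / mean
    return RSDResult(
        scheme=grouping.scheme,
        statistic_kind=statistic_kind,
        interpretation=interpretation,
        per_group=tuple(per_group),
        scheme_rsd_percent=scheme_rsd,
    )


def count_rsd(
    presence: PresenceMatrix,
    grouping: GroupingScheme,
    interpretation: Interpretation | str = Interpretation.WITHIN_GROUP_MEAN,
) -> RSDResult:
    """RSD of identified-protein counts per replicate under a grouping.

    The member value for each replicate is the number of proteins present in
    it; this is the qualitative-variability statistic and depends only on the
    presence matrix, never on abundance magnitudes.
    """
    counts = presence.counts_per_replicate()
    missing = [m for g in grouping.groups for m in g if m not in counts]
    if missing:
        raise KeyError(f"grouping references unknown replicates: {missing}")
    return compute_rsd(
        grouping,
        {m: float(counts[m]) for g in grouping.groups for m in g},
        statistic_kind="count",
        interpretation=interpretation,
    )
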