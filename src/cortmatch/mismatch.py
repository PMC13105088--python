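"""Signed rank-difference mismatch maps and grouped summaries.

For a target map a and feature map m on the same parcellation, both are
rank-transformed (average ranks, 1 = lowest). If their Spearman
correlation is negative, the feature's ranks are reversed
(rank -> P + 1 - rank) so that all comparisons share a direction; the
per-parcel signed rank difference is then

    delta_r_i = rank(a)_i - rank(m)_i,

positive where the target sits higher in its own ranking than the feature
predicts. Parcels are aggregated into anatomical regions or functional
networks (assigned by majority voxel overlap) and summarised by the mean
absolute rank difference per group, sorted descending. These maps are
descriptive; no per-parcel inference is attached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import BrainMap, LabelVolume

__all__ = [
    "GroupAssignment",
    "MismatchResult",
    "signed_rank_difference",
    "assign_by_majority",
    "aggregate_mismatch",
    "resample_nearest",
]


@dataclass(frozen=True)
class GroupAssignment:
    """parcel id -> group label, with the assignment's provenance and any
    majority-vote ties (parcel id -> tied group labels)."""

    mapping: dict
    source: str
    ties: dict = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.ties is None:
            object.__setattr__(self, "ties", {})

    def group_of(self, parcel_id) -> object:
        return self.mapping[parcel_id]

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "GroupAssignment":
        if not {"parcel_id", "group"} <= set(df.columns):
            raise ValueError("assignment table needs parcel_id and group columns")
        dup = df["parcel_id"][df["parcel_id"].duplicated()]
        if len(dup):
            raise ValueError(f"parcel assigned more than once: {sorted(set(dup))}")
        return cls(
            mapping=dict(zip(df["parcel_id"], df["group"])), source="table"
        )


@dataclass(frozen=True)
class MismatchResult:
    delta_r: np.ndarray
    reversed: bool
    target: BrainMap
    feature_name: str
    group_means: pd.DataFrame | None = None  # group, mean_abs_delta_r, n_parcels


def signed_rank_difference(
    a: BrainMap, m: BrainMap, reverse_zero: bool = False
) -> MismatchResult:
    """Per-parcel signed rank difference with the sign-reversal convention.

    Feature ranks are reversed for strictly negative Spearman correlation;
    an exactly-zero correlation reverses only if ``reverse_zero`` is set
    (either direction is arbitrary for an uncorrelated map).
    """
    a.check_aligned(m)
    P = a.geometry.n_parcels
    if np.ptp(a.values) == 0 or np.ptp(m.values) == 0:
        raise ValueError("zero-variance input")
    ra = stats.rankdata(a.values)
    rm = stats.rankdata(m.values)
    rho = stats.spearmanr(a.values, m.values).statistic
    reversed_ = bool(rho < 0 or (reverse_zero and rho == 0))
    if reversed_:
        rm = (P + 1) - rm
    return MismatchResult(
        delta_r=ra - rm, reversed=reversed_, target=a, feature_name=m.name
    )


def resample_nearest(source: LabelVolume, grid: LabelVolume) -> LabelVolume:
    """Resample a label volume onto another volume's voxel grid by
    nearest-neighbour lookup through the affines (each grid voxel centre is
    mapped into source voxel space and rounded)."""
    shape = grid.labels.shape
    ijk = np.indices(shape).reshape(3, -1).T
    mm = grid.voxel_mm(ijk)
    inv = np.linalg.inv(source.affine)
    src_ijk = np.rint(mm @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    inside = np.all((src_ijk >= 0) & (src_ijk < source.labels.shape), axis=1)
    out = np.zeros(ijk.shape[0], dtype=source.labels.dtype)
    out[inside] = source.labels[tuple(src_ijk[inside].T)]
    return LabelVolume(labels=out.reshape(shape), affine=grid.affine)


def assign_by_majority(
    group_volume: LabelVolume, parcel_volume: LabelVolume
) -> GroupAssignment:
    """Assign each parcel to the group occupying most of its voxels.

    The group volume is first resampled to the parcel grid by
    nearest-neighbour interpolation if the grids differ. Background group
    voxels (label 0) are excluded from the count; ties go to the lowest
    group label and are recorded. A parcel overlapping no group at all is
    an error (callers may fall back to an explicit assignment table).
    """
    if group_volume.labels.shape != parcel_volume.labels.shape or not np.allclose(
        group_volume.affine, parcel_volume.affine
    ):
        group_volume = resample_nearest(group_volume, parcel_volume)
    mapping: dict[int, int] = {}
    ties: dict[int, tuple] = {}
    unassigned = []
    for pid in parcel_volume.parcel_labels():
        groups = group_volume.labels[parcel_volume.labels == pid]
        groups = groups[groups > 0]
        if groups.size == 0:
            unassigned.append(int(pid))
            continue
        labs, counts = np.unique(groups, return_counts=True)
        winners = labs[counts == counts.max()]
        mapping[int(pid)] = int(winners.min())
        if winners.size > 1:
            ties[int(pid)] = tuple(int(w) for w in winners)
    if unassigned:
        raise ValueError(
            f"parcels with no group overlap: {unassigned}; supply a fallback table"
        )
    return GroupAssignment(mapping=mapping, source="majority-vote volume", ties=ties)


def aggregate_mismatch(
    result: MismatchResult, assignment: GroupAssignment
) -> MismatchResult:
    """Mean absolute rank difference per group, sorted descending (ties in
    the mean are ordered by group label)."""
    ids = np.asarray(result.target.geometry.parcel_ids)
    missing = [i for i in ids if i not in assignment.mapping]
    if missing:
        raise ValueError(f"parcels without group assignment: {missing}")
    df = pd.DataFrame(
        {
            "group": [assignment.mapping[i] for i in ids],
            "abs_delta_r": np.abs(result.delta_r),
        }
    )
    grouped = (
        df.groupby("group")["abs_delta_r"]
        .agg(mean_abs_delta_r="mean", n_parcels="size")
        .reset_index()
        .sort_values(
            ["mean_abs_delta_r", "group"], ascending=[False, True], kind="stable"
        )
        .reset_index(drop=True)
    )
    return MismatchResult(
        delta_r=result.delta_r,
        reversed=result.reversed,
        target=result.target,
        feature_name=result.feature_name,
        group_means=grouped,
    )
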