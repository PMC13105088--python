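"""Parcel geometry and map containers.

The unit of analysis throughout the package is the *parcel*: an atlas label
covering a set of voxels. A :class:`BrainMap` holds one value per parcel,
aligned to a :class:`ParcelGeometry` that carries parcel identifiers,
centroids and a parcel-to-parcel distance matrix. Voxel-level statistical
maps enter the parcel world through :func:`parcellate` (nearest-neighbour
interpolation followed by within-parcel averaging), and bilateral atlases
are reduced to one map entry per area pair with :func:`merge_hemispheres`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "LabelVolume",
    "StatPointSet",
    "ParcelGeometry",
    "BrainMap",
    "AlignmentError",
    "parcellate",
    "merge_hemispheres",
    "build_geometry",
]


class AlignmentError(ValueError):
    """Raised when two parcel-level objects do not share a parcellation."""


@dataclass(frozen=True)
class LabelVolume:
    """Integer label image: 0 is background, k > 0 indexes a parcel.

    ``affine`` maps 0-based voxel indices to mm coordinates
    (voxel-centre convention).
    """

    labels: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels)
        affine = np.asarray(self.affine, dtype=float)
        if labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        if labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "affine", affine)

    def voxel_mm(self, ijk: np.ndarray) -> np.ndarray:
        """mm coordinates of 0-based voxel indices (N x 3)."""
        ijk = np.atleast_2d(ijk)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def parcel_labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the volume."""
        labs = np.unique(self.labels)
        return labs[labs > 0]

    def voxel_counts(self) -> dict[int, int]:
        labs, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(labs.tolist(), counts.tolist()))


@dataclass(frozen=True)
class StatPointSet:
    """Scattered statistical values at mm coordinates (e.g. a source grid)."""

    coords: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be N x 3")
        if values.shape != (coords.shape[0],):
            raise ValueError("values must match coords length")
        if coords.shape[0] < 1:
            raise ValueError("need at least one point")
        if not np.all(np.isfinite(coords)) or not np.all(np.isfinite(values)):
            raise ValueError("non-finite coordinates or values")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class ParcelGeometry:
    """Ordered parcel ids, centroids (mm) and a symmetric distance matrix."""

    parcel_ids: np.ndarray
    centroids: np.ndarray | None
    dist: np.ndarray

    def __post_init__(self):
        ids = np.asarray(self.parcel_ids)
        dist = np.asarray(self.dist, dtype=float)
        P = len(ids)
        if P < 3:
            raise ValueError("need at least 3 parcels")
        if len(np.unique(ids)) != P:
            raise ValueError("duplicate parcel ids")
        if dist.shape != (P, P):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(dist, dist.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(dist), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if dist.min() < 0:
            raise ValueError("distances must be non-negative")
        if self.centroids is not None:
            cen = np.asarray(self.centroids, dtype=float)
            if cen.shape != (P, 3):
                raise ValueError("centroids must be P x 3")
            object.__setattr__(self, "centroids", cen)
        object.__setattr__(self, "parcel_ids", ids)
        object.__setattr__(self, "dist", dist)

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    def same_parcellation(self, other: "ParcelGeometry") -> bool:
        return np.array_equal(self.parcel_ids, other.parcel_ids)


@dataclass(frozen=True)
class BrainMap:
    """One finite value per parcel, aligned to a :class:`ParcelGeometry`."""

    name: str
    values: np.ndarray
    geometry: ParcelGeometry

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.geometry.n_parcels,):
            raise AlignmentError(
                f"map {self.name!r} has {values.shape} values for "
                f"{self.geometry.n_parcels} parcels"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError(f"map {self.name!r} contains non-finite values")
        object.__setattr__(self, "values", values)

    def check_aligned(self, other: "BrainMap") -> None:
        if not self.geometry.same_parcellation(other.geometry):
            raise AlignmentError(
                f"maps {self.name!r} and {other.name!r} are on different parcellations"
            )


def _labelled_voxels(atlas: LabelVolume):
    ijk = np.argwhere(atlas.labels > 0)
    if ijk.size == 0:
        raise ValueError("atlas has no nonzero labels")
    labs = atlas.labels[tuple(ijk.T)]
    return ijk, labs


def parcellate(points: StatPointSet, atlas: LabelVolume, name: str = "map") -> BrainMap:
    """Aggregate scattered statistical values onto atlas parcels.

    Every labelled voxel receives the value of its nearest stat point
    (Euclidean distance in mm; ties broken toward the lowest point index),
    and each parcel's value is the arithmetic mean over its voxels.
    Parcels are ordered by ascending label.
    """
    ijk, labs = _labelled_voxels(atlas)
    voxel_mm = atlas.voxel_mm(ijk)
    # cKDTree breaks exact ties toward the lowest index, matching our contract;
    # tiny fp asymmetries are avoided by exact coordinate arithmetic on ints.
    tree = cKDTree(points.coords)
    _, nearest = tree.query(voxel_mm, k=1)
    voxel_values = points.values[nearest]

    parcel_ids = np.unique(labs)
    values = np.array(
        [voxel_values[labs == k].mean() for k in parcel_ids], dtype=float
    )
    geom = build_geometry(atlas) if len(parcel_ids) >= 3 else None
    if geom is None:
        raise ValueError("need at least 3 parcels to build a map with geometry")
    return BrainMap(name=name, values=values, geometry=geom)


def parcel_means(points: StatPointSet, atlas: LabelVolume) -> dict[int, float]:
    """Per-label mean of nearest-point values (no geometry attached)."""
    ijk, labs = _labelled_voxels(atlas)
    voxel_mm = atlas.voxel_mm(ijk)
    tree = cKDTree(points.coords)
    _, nearest = tree.query(voxel_mm, k=1)
    voxel_values = points.values[nearest]
    return {
        int(k): float(voxel_values[labs == k].mean()) for k in np.unique(labs)
    }


def merge_hemispheres(
    values: Mapping[int, float],
    pairing: Sequence[tuple[int, int]],
    voxel_counts: Mapping[int, int],
    weighted: bool = True,
) -> dict[tuple[int, int], float]:
    """Merge left/right hemisphere parcel values into bilateral parcels.

    The merged value is the voxel-count-weighted mean of the two hemisphere
    means, i.e. the mean over the pooled bilateral voxel mask. With
    ``weighted=False`` a simple average is taken instead.
    """
    seen: set[int] = set()
    for left, right in pairing:
        for lab in (left, right):
            if lab in seen:
                raise ValueError(f"label {lab} appears in more than one pair")
            seen.add(lab)
    missing = set(values) - seen
    if missing:
        raise ValueError(f"labels not covered by any pair: {sorted(missing)}")
    out: dict[tuple[int, int], float] = {}
    for left, right in pairing:
        for lab in (left, right):
            if lab not in values:
                raise ValueError(f"pair label {lab} has no value")
            if voxel_counts.get(lab, 0) <= 0:
                raise ValueError(f"label {lab} has non-positive voxel count")
        if weighted:
            nl, nr = voxel_counts[left], voxel_counts[right]
            out[(left, right)] = (nl * values[left] + nr * values[right]) / (nl + nr)
        else:
            out[(left, right)] = 0.5 * (values[left] + values[right])
    return out


def build_geometry(atlas: LabelVolume) -> ParcelGeometry:
    """Volumetric parcel geometry: centroid = mean voxel-centre mm coordinate,
    distance = Euclidean centroid-to-centroid distance."""
    ijk, labs = _labelled_voxels(atlas)
    parcel_ids = np.unique(labs)
    if len(parcel_ids) < 3:
        raise ValueError("need at least 3 parcels")
    voxel_mm = atlas.voxel_mm(ijk)
    centroids = np.array(
        [voxel_mm[labs == k].mean(axis=0) for k in parcel_ids]
    )
    diff = centroids[:, None, :] - centroids[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    dist = 0.5 * (dist + dist.T)
    np.fill_diagonal(dist, 0.0)
    return ParcelGeometry(parcel_ids=parcel_ids, centroids=centroids, dist=dist)


def geometry_from_centroids(
    parcel_ids: Sequence, centroids: np.ndarray
) -> ParcelGeometry:
    """Geometry from explicit centroids (Euclidean distances)."""
    centroids = np.asarray(centroids, dtype=float)
    diff = centroids[:, None, :] - centroids[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    dist = 0.5 * (dist + dist.T)
    np.fill_diagonal(dist, 0.0)
    return ParcelGeometry(
        parcel_ids=np.asarray(parcel_ids), centroids=centroids, dist=dist
    )
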