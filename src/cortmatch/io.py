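"""Reading and writing parcel tables, feature panels and NIfTI volumes.

Parcel tables are UTF-8 TSV/CSV files with columns ``parcel_id`` and
``value`` ('.' decimal separator); values round-trip at full double
precision. A feature panel is either a directory of such tables or one
wide table ``parcel_id, map1, map2, ...``.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import BrainMap, LabelVolume, ParcelGeometry, StatPointSet

__all__ = [
    "read_parcel_table",
    "write_parcel_table",
    "read_feature_panel",
    "read_label_volume",
    "read_stat_volume",
    "write_geometry",
    "read_geometry",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _check_ids(ids: pd.Series, geometry: ParcelGeometry, path: Path) -> np.ndarray:
    """Return row order aligning table ids to the geometry's parcel order."""
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicated parcel_id rows: {sorted(set(dup))}")
    want = pd.Index(np.asarray(geometry.parcel_ids))
    have = pd.Index(ids.to_numpy())
    missing = want.difference(have)
    if len(missing):
        raise ValueError(f"{path}: missing parcel ids: {missing.tolist()}")
    extra = have.difference(want)
    if len(extra):
        raise ValueError(f"{path}: unknown parcel ids: {extra.tolist()}")
    return have.get_indexer(want)


def read_parcel_table(
    path: str | os.PathLike, geometry: ParcelGeometry, name: str | None = None
) -> BrainMap:
    """Read a ``parcel_id, value`` table as a map aligned to ``geometry``.

    Rows may come in any order; alignment is by explicit parcel_id match
    (positional alignment is never assumed). Missing, duplicate or
    non-numeric rows raise with the offending ids.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    if "parcel_id" not in df.columns or "value" not in df.columns:
        raise ValueError(f"{path}: expected columns parcel_id, value")
    vals = pd.to_numeric(df["value"], errors="coerce")
    bad = df.loc[vals.isna(), "parcel_id"]
    if len(bad):
        raise ValueError(f"{path}: non-numeric value for parcel_id {bad.tolist()}")
    order = _check_ids(df["parcel_id"], geometry, path)
    return BrainMap(
        name=name or path.stem,
        values=vals.to_numpy()[order],
        geometry=geometry,
    )


def write_parcel_table(brain_map: BrainMap, path: str | os.PathLike) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {"parcel_id": np.asarray(brain_map.geometry.parcel_ids),
         "value": brain_map.values}
    )
    # repr-roundtrip precision so write-then-read is bit exact
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


def read_feature_panel(
    path: str | os.PathLike, geometry: ParcelGeometry
) -> list[BrainMap]:
    """Read a panel of feature maps from a directory of parcel tables or a
    single wide table ``parcel_id, map1, map2, ...``."""
    path = Path(path)
    if path.is_dir():
        maps = []
        for f in sorted(path.iterdir()):
            if f.suffix.lower() in {".csv", ".tsv"}:
                maps.append(read_parcel_table(f, geometry))
        if not maps:
            raise ValueError(f"{path}: no .csv/.tsv tables found")
        return maps
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    if "parcel_id" not in df.columns:
        raise ValueError(f"{path}: wide panel needs a parcel_id column")
    order = _check_ids(df["parcel_id"], geometry, path)
    maps = []
    for col in df.columns:
        if col == "parcel_id":
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.loc[vals.isna(), "parcel_id"]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} for parcel_id {bad.tolist()}"
            )
        maps.append(BrainMap(name=col, values=vals.to_numpy()[order], geometry=geometry))
    return maps


def read_label_volume(path: str | os.PathLike) -> LabelVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    labels = np.rint(data).astype(np.int64)
    return LabelVolume(labels=labels, affine=np.asarray(img.affine))


def read_stat_volume(path: str | os.PathLike) -> StatPointSet:
    """Convert a statistical volume to a point set: all finite, nonzero voxels
    contribute their centre mm coordinate and value."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    mask = np.isfinite(data) & (data != 0)
    if not mask.any():
        raise ValueError(f"{path}: no finite nonzero voxels")
    ijk = np.argwhere(mask)
    affine = np.asarray(img.affine)
    coords = ijk @ affine[:3, :3].T + affine[:3, 3]
    return StatPointSet(coords=coords, values=data[mask])


def write_geometry(geometry: ParcelGeometry, path: str | os.PathLike) -> None:
    """Persist a geometry as a wide CSV: parcel_id, then one distance column
    per parcel (centroids are not required to reconstruct analyses)."""
    ids = np.asarray(geometry.parcel_ids)
    df = pd.DataFrame(geometry.dist, columns=[str(i) for i in ids])
    df.insert(0, "parcel_id", ids)
    df.to_csv(path, index=False, float_format="%.17g")


def read_geometry(path: str | os.PathLike) -> ParcelGeometry:
    df = pd.read_csv(path, float_precision="round_trip")
    ids = df["parcel_id"].to_numpy()
    dist = df.drop(columns=["parcel_id"]).to_numpy(dtype=float)
    return ParcelGeometry(parcel_ids=ids, centroids=None, dist=dist)
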