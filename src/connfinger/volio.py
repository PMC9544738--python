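"""Volume, atlas and motion-table I/O plus ROI utilities.

All carriers used by the pipeline live here: 4D runs (:class:`VolumeSeries`),
integer-labelled parcel atlases (:class:`ParcelAtlas`), six-parameter rigid
motion tables (:class:`MotionTable`) and 3D statistic maps (:class:`StatMap`).
Every other module depends only on these types.

Conventions: voxel indices are 0-based; the affine maps voxel index to world
mm (NIfTI convention); all volumes, atlases and maps in one analysis share a
single grid — mismatched grids are errors, never silently resampled.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Role",
    "VolumeSeries",
    "ParcelAtlas",
    "MotionTable",
    "StatMap",
    "read_volume",
    "write_volume",
    "read_motion_table",
    "write_motion_table",
    "read_atlas",
    "write_atlas",
    "roi_mean_timeseries",
]

MOTION_COLUMNS = ("roll", "pitch", "yaw", "dS", "dP", "dL")


class Role(str, enum.Enum):
    """Functional role of an atlas parcel."""

    ACC_DACC = "acc_dacc"
    ACC_OTHER = "acc_other"
    PHYSICS = "physics"
    SEARCHMASK = "searchmask"
    WM = "wm"
    VENTRICLE = "ventricle"


@dataclass
class VolumeSeries:
    """A 4D scalar field (X, Y, Z, T) with voxel geometry and repetition time.

    Parameters
    ----------
    data
        Real array of shape (X, Y, Z, T); a 3D array is promoted to T=1.
    voxel_size_mm
        Edge lengths of a voxel along x, y, z in mm (all > 0).
    tr_s
        Repetition time between volumes in seconds (> 0).
    affine
        4x4 matrix mapping 0-based voxel indices to world mm.
    """

    data: np.ndarray
    voxel_size_mm: np.ndarray
    tr_s: float
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise ValueError(f"data must be 3D or 4D, got ndim={self.data.ndim}")
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float).reshape(3)
        if np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel_size_mm must all be > 0")
        if not self.tr_s > 0:
            raise ValueError("tr_s must be > 0")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size_mm, 1.0])
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        bad = np.argwhere(~np.isfinite(self.data))
        if bad.size:
            raise ValueError(
                f"non-finite voxel value at index {tuple(int(i) for i in bad[0])}"
            )

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray) -> "VolumeSeries":
        """New series on the same grid/geometry with replaced data."""
        return VolumeSeries(data, self.voxel_size_mm, self.tr_s, self.affine)


@dataclass
class ParcelAtlas:
    """3D integer label field plus a label table.

    Label 0 is background. ``table`` maps label id -> (name, role). Physics
    parcels lie inside the fronto-parietal search mask, so a voxel carries
    the parcel label and :meth:`mask` for ``searchmask`` returns the union of
    voxels labelled searchmask and voxels in any physics parcel.
    """

    labels: np.ndarray
    table: pd.DataFrame  # columns: label_id, name, role

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = np.round(self.labels).astype(np.int32)
        self.table = pd.DataFrame(self.table)
        missing = {"label_id", "name", "role"} - set(self.table.columns)
        if missing:
            raise ValueError(f"label table missing columns: {sorted(missing)}")
        self.table["role"] = self.table["role"].map(Role)
        present = set(np.unique(self.labels)) - {0}
        known = set(self.table["label_id"].astype(int))
        orphan = present - known
        if orphan:
            raise ValueError(f"labels without table entries: {sorted(orphan)}")

    def ids_for_role(self, role: Role | str) -> list[int]:
        role = Role(role)
        sub = self.table[self.table["role"] == role]
        return [int(i) for i in sub["label_id"]]

    def mask(self, what: Role | str | int) -> np.ndarray:
        """Boolean mask for a label id or for all parcels of a role."""
        if isinstance(what, (int, np.integer)):
            return self.labels == int(what)
        role = Role(what)
        ids = self.ids_for_role(role)
        m = np.isin(self.labels, ids)
        if role is Role.SEARCHMASK:
            m = m | np.isin(self.labels, self.ids_for_role(Role.PHYSICS))
        return m

    def name_of(self, label_id: int) -> str:
        row = self.table[self.table["label_id"] == label_id]
        if row.empty:
            raise KeyError(f"label {label_id} not in table")
        return str(row["name"].iloc[0])


@dataclass
class MotionTable:
    """Per-volume rigid-body parameters: roll, pitch, yaw (deg); dS, dP, dL (mm)."""

    values: np.ndarray  # (T, 6)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValueError("motion table must be (T, 6)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("motion table contains non-finite values")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def rotations_deg(self) -> np.ndarray:
        return self.values[:, :3]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.values[:, 3:]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(MOTION_COLUMNS))


_STAT_KINDS = ("r", "z", "beta", "contrast", "t")


@dataclass
class StatMap:
    """A 3D map of one statistic with provenance metadata.

    ``kind`` is one of r, z, beta, contrast, t. ``source`` is a subject id
    or "group". A kind="r" map must be finite and within [-1, 1].
    """

    data: np.ndarray
    kind: str
    df: int | None = None
    source: str = "group"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("StatMap data must be 3D")
        if self.kind not in _STAT_KINDS:
            raise ValueError(f"kind must be one of {_STAT_KINDS}")
        if self.kind == "r":
            if not np.all(np.isfinite(self.data)):
                raise ValueError("r map must be finite")
            if np.any(np.abs(self.data) > 1 + 1e-12):
                raise ValueError("r map values must lie in [-1, 1]")

    def with_data(self, data: np.ndarray, kind: str | None = None) -> "StatMap":
        return StatMap(data, kind or self.kind, self.df, self.source)


# ---------------------------------------------------------------------------
# NIfTI round trip


def read_volume(path: str | Path, tr_s: float | None = None) -> VolumeSeries:
    """Read a 3D or 4D NIfTI-1 file.

    3D inputs are promoted to a single-volume series. TR is taken from the
    header (pixdim[4]) unless ``tr_s`` overrides it; a header TR of 0 (common
    for structural images) falls back to 1 s when no override is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim not in (3, 4):
        raise ValueError(f"expected 3 or 4 dimensions, got {data.ndim}")
    zooms = img.header.get_zooms()
    voxel = np.array(zooms[:3], dtype=float)
    if tr_s is None:
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    bad = np.argwhere(~np.isfinite(data))
    if bad.size:
        raise ValueError(f"{path}: non-finite voxel at index "
                         f"{tuple(int(i) for i in bad[0])}")
    return VolumeSeries(data, voxel, tr_s, np.asarray(img.affine))


def write_volume(vol: VolumeSeries, path: str | Path) -> None:
    """Write as NIfTI-1 (float32); a T=1 series writes a 3D file."""
    path = Path(path)
    data = vol.data.astype(np.float32)
    if data.shape[3] == 1:
        data = data[..., 0]
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms((*vol.voxel_size_mm, vol.tr_s)[: data.ndim])
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_motion_table(path: str | Path) -> MotionTable:
    """Read a whitespace/TSV motion table with header ``roll pitch yaw dS dP dL``."""
    df = pd.read_csv(path, sep=r"\s+")
    cols = [c for c in MOTION_COLUMNS if c in df.columns]
    if len(cols) != 6:
        raise ValueError(f"{path}: expected columns {MOTION_COLUMNS}, got {list(df.columns)}")
    return MotionTable(df[list(MOTION_COLUMNS)].to_numpy())


def write_motion_table(motion: MotionTable, path: str | Path) -> None:
    motion.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_atlas(nifti_path: str | Path, table_path: str | Path) -> ParcelAtlas:
    """Read an atlas from a label NIfTI and a TSV ``label_id name role`` table."""
    vol = read_volume(nifti_path)
    table = pd.read_csv(table_path, sep="\t")
    return ParcelAtlas(np.round(vol.data[..., 0]).astype(np.int32), table)


def write_atlas(atlas: ParcelAtlas, nifti_path: str | Path, table_path: str | Path,
                voxel_size_mm=(3.0, 3.0, 3.5)) -> None:
    vol = VolumeSeries(atlas.labels.astype(np.float64), voxel_size_mm, 1.0)
    write_volume(vol, nifti_path)
    out = atlas.table.copy()
    out["role"] = out["role"].map(lambda r: r.value)
    out.to_csv(table_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ROI utilities


def _check_grid(vol: VolumeSeries, atlas: ParcelAtlas) -> None:
    if vol.shape3d != atlas.labels.shape:
        raise ValueError(
            f"grid mismatch: volume {vol.shape3d} vs atlas {atlas.labels.shape}"
        )


def roi_mean_timeseries(vol: VolumeSeries, atlas: ParcelAtlas, label_id: int) -> np.ndarray:
    """Unweighted mean timeseries over all voxels carrying ``label_id``.

    Linear in the volume: extracting from a*U + b*V equals
    a*extract(U) + b*extract(V).
    """
    _check_grid(vol, atlas)
    m = atlas.labels == int(label_id)
    if not m.any():
        raise ValueError(f"ROI {label_id} is empty")
    return vol.data[m].mean(axis=0)


def mask_mean_timeseries(vol: VolumeSeries, mask: np.ndarray) -> np.ndarray:
    """Mean timeseries over an arbitrary boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.shape3d:
        raise ValueError("mask grid mismatch")
    if not mask.any():
        raise ValueError("empty mask")
    return vol.data[mask].mean(axis=0)
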