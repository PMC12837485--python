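"""Reading, writing and validating labeled 3D volumes and cohort tables.

The canonical in-memory representation is :class:`LabelVolume`: an integer
voxel grid with axis order ``(depth, height, width)`` where the depth axis
is the sweep direction of the ultrasound acquisition (slice ``k`` of the
volume is frame ``k`` of the sweep).  Canonical label codes are

====  ==========
code  structure
====  ==========
0     background
1     left atrium (LA)
2     pulmonary vein (PV)
3     confluent vein (TAPVC only)
====  ==========

The confluent vein is, by default, merged into the PV class when computing
indices (it is the PV-class structure behind the LA in TAPVC hearts); the
``merge_vein`` flag on :meth:`LabelVolume.structure_mask` disables this.

Two on-disk dialects are supported: NIfTI (``.nii``/``.nii.gz``) and a
directory of equally sized 8-bit PNG slices ordered by filename (one gray
level per label, slice index = depth index).  Voxel spacing metadata is
read but ignored; all distances downstream are in pixel units.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError

BACKGROUND = 0
LA = 1
PV = 2
VEIN = 3

CANONICAL_LABEL_MAP: dict[str, int] = {
    "BACKGROUND": BACKGROUND,
    "LA": LA,
    "PV": PV,
    "VEIN": VEIN,
}

GROUPS = ("normal", "TAPVC")
ROLES = ("ground_truth", "prediction")

_SLICE_EXTENSIONS = (".png", ".tif", ".tiff", ".bmp")


@dataclass
class LabelVolume:
    """A labeled 3D voxel grid with axis order (depth, height, width)."""

    voxels: np.ndarray
    label_map: dict[str, int] = field(default_factory=lambda: dict(CANONICAL_LABEL_MAP))
    case_id: str = ""
    source_path: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError(
                f"voxel grid must be 3D (depth, height, width); got ndim={self.voxels.ndim}"
            )
        if min(self.voxels.shape) < 1:
            raise ValidationError(f"every axis must have extent >= 1; got {self.voxels.shape}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            as_int = self.voxels.astype(np.int64)
            if not np.array_equal(as_int, self.voxels):
                raise ValidationError("voxel values must be integers")
            self.voxels = as_int
        if "BACKGROUND" not in self.label_map:
            self.label_map = {"BACKGROUND": BACKGROUND, **self.label_map}
        _check_alphabet(self.voxels, set(self.label_map.values()))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def structure_mask(self, structure: str, merge_vein: bool = True) -> np.ndarray:
        """Boolean mask of one structure.

        ``structure`` is ``"PV"``, ``"LA"``, ``"VEIN"`` or ``"PV_LA"`` (the
        PV∪LA aggregate).  With ``merge_vein`` the confluent-vein label
        counts as PV-class foreground.
        """
        if structure == "PV_LA":
            return self.structure_mask("PV", merge_vein) | self.structure_mask("LA", merge_vein)
        if structure not in self.label_map:
            if structure == "VEIN":
                return np.zeros(self.shape, dtype=bool)
            raise ValidationError(f"structure {structure!r} not in label map {self.label_map}")
        mask = self.voxels == self.label_map[structure]
        if structure == "PV" and merge_vein and "VEIN" in self.label_map:
            mask |= self.voxels == self.label_map["VEIN"]
        return mask


@dataclass(frozen=True)
class CohortRecord:
    """One row of a cohort table: which file is which case, group and role."""

    case_id: str
    volume_ref: str
    group: str
    role: str
    model_name: str | None = None

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValidationError("case_id must be non-empty")
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}; got {self.group!r}")
        if self.role not in ROLES:
            raise ValidationError(f"role must be one of {ROLES}; got {self.role!r}")


def _check_alphabet(voxels: np.ndarray, alphabet: set[int]) -> None:
    present = np.unique(voxels)
    bad = [int(v) for v in present if int(v) not in alphabet]
    if bad:
        coord = tuple(int(c) for c in np.argwhere(voxels == bad[0])[0])
        raise ValidationError(
            f"voxel value {bad[0]} at (depth,row,col)={coord} is not in the "
            f"declared label alphabet {sorted(alphabet)}"
        )


def _remap(voxels: np.ndarray, label_map: dict[str, int]) -> np.ndarray:
    """Remap file values to canonical codes; validate the alphabet."""
    file_map = {"BACKGROUND": BACKGROUND, **label_map}
    _check_alphabet(voxels, set(file_map.values()))
    out = np.zeros(voxels.shape, dtype=np.uint8)
    for name, file_value in file_map.items():
        if name not in CANONICAL_LABEL_MAP:
            raise ValidationError(f"unknown structure name {name!r} in label_map")
        out[voxels == file_value] = CANONICAL_LABEL_MAP[name]
    return out


def read_label_volume(
    path: str | os.PathLike,
    label_map: dict[str, int] | None = None,
    case_id: str = "",
    depth_axis: int | None = None,
) -> LabelVolume:
    """Read a labeled volume from NIfTI or a directory of 2D slice images.

    Parameters
    ----------
    path:
        A ``.nii``/``.nii.gz`` file or a directory of equally sized slice
        images ordered by filename.
    label_map:
        Mapping from structure name (``LA``, ``PV``, ``VEIN``) to the voxel
        value used in the file.  Defaults to the canonical encoding.
    depth_axis:
        For NIfTI input, which axis of the file array is the sweep (depth)
        axis.  By default the file's slowest-varying axis (the last index
        of the data array) is taken as depth.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if label_map is None:
        label_map = {k: v for k, v in CANONICAL_LABEL_MAP.items() if k != "BACKGROUND"}

    if path.is_dir():
        voxels = _read_slice_directory(path)
    else:
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
        if arr.ndim != 3:
            raise FormatError(f"{path}: expected a 3D NIfTI volume, got ndim={arr.ndim}")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError(f"{path}: non-integer voxel values in a label volume")
        arr = np.round(arr).astype(np.int64)
        axis = arr.ndim - 1 if depth_axis is None else depth_axis
        voxels = np.moveaxis(arr, axis, 0)

    canonical = _remap(voxels, label_map)
    return LabelVolume(
        voxels=canonical,
        label_map=dict(CANONICAL_LABEL_MAP),
        case_id=case_id or path.stem.replace(".nii", ""),
        source_path=str(path),
    )


def _read_slice_directory(path: Path) -> np.ndarray:
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _SLICE_EXTENSIONS
    )
    if not files:
        raise FormatError(f"{path}: no slice images found")
    slices = []
    shape = None
    for f in files:
        img = np.asarray(iio.imread(f))
        if img.ndim == 3:  # drop a redundant channel axis from paletted writers
            if not np.all(img == img[..., :1]):
                raise FormatError(f"{f}: label slices must be single-channel")
            img = img[..., 0]
        if img.ndim != 2:
            raise FormatError(f"{f}: expected a 2D slice image, got ndim={img.ndim}")
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise FormatError(
                f"{f}: slice shape {img.shape} differs from first slice {shape}"
            )
        slices.append(img.astype(np.int64))
    return np.stack(slices, axis=0)


def write_label_volume(volume: LabelVolume, path: str | os.PathLike) -> None:
    """Write a volume to NIfTI (``.nii``/``.nii.gz``) or a PNG slice directory.

    The inverse of :func:`read_label_volume`: a round trip is voxel-exact.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        # depth is the in-memory leading axis; store it as the file's last
        # (slowest-varying) axis so the default reader recovers it.
        arr = np.moveaxis(volume.voxels.astype(np.uint8), 0, -1)
        nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), str(path))
    else:
        path.mkdir(exist_ok=True)
        width = max(4, len(str(volume.n_slices)))
        for k in range(volume.n_slices):
            iio.imwrite(
                path / f"slice_{k:0{width}d}.png",
                volume.voxels[k].astype(np.uint8),
            )


def load_cohort(table_path: str | os.PathLike, check_files: bool = True) -> list[CohortRecord]:
    """Load a cohort CSV into validated records.

    Required columns: ``case_id, volume_ref, group, role, model_name``
    (``model_name`` may be empty).  Relative ``volume_ref`` paths are
    resolved against the CSV's directory.
    """
    table_path = Path(table_path)
    if not table_path.exists():
        raise FileNotFoundError(f"no such cohort table: {table_path}")
    df = pd.read_csv(table_path, dtype=str, keep_default_na=False)
    required = ["case_id", "volume_ref", "group", "role", "model_name"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{table_path}: missing columns {missing_cols}")

    records: list[CohortRecord] = []
    seen: set[tuple] = set()
    missing_files: list[str] = []
    for _, row in df.iterrows():
        ref = row["volume_ref"]
        resolved = Path(ref)
        if not resolved.is_absolute():
            resolved = table_path.parent / resolved
        rec = CohortRecord(
            case_id=row["case_id"],
            volume_ref=str(resolved),
            group=row["group"],
            role=row["role"],
            model_name=row["model_name"] or None,
        )
        key = (rec.case_id, rec.role, rec.model_name)
        if key in seen:
            raise ValidationError(
                f"{table_path}: duplicate (case_id, role, model_name) = {key}"
            )
        seen.add(key)
        if check_files and not resolved.exists():
            missing_files.append(str(resolved))
        records.append(rec)
    if missing_files:
        raise FileNotFoundError(
            f"{table_path}: {len(missing_files)} referenced volume(s) missing: "
            + ", ".join(missing_files)
        )
    return records


def write_cohort_csv(records: list[CohortRecord], path: str | os.PathLike) -> None:
    """Write cohort records in the format :func:`load_cohort` reads."""
    pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "volume_ref": r.volume_ref,
                "group": r.group,
                "role": r.role,
                "model_name": r.model_name or "",
            }
            for r in records
        ]
    ).to_csv(path, index=False)
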