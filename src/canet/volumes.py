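"""Nodule volume data model and deterministic CT preprocessing.

A :class:`NoduleVolume` is one nodule-centred CT crop at one screening
interval; a :class:`LongitudinalSeries` is the ordered 1-3 interval
sequence of one patient's nodule.  The preprocessing pipeline
(crop -> resample -> intensity window) turns raw Hounsfield-unit crops
into the fixed-shape, [0, 1]-normalised grids the networks consume.

Conventions: arrays are indexed (slice, row, col) = (z, y, x), axial
slices along axis 0; physical coordinates are in mm with voxel centre
``i`` at ``(i + 0.5) * spacing``; crops are half-open intervals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "NoduleVolume",
    "LongitudinalSeries",
    "AIR_HU",
    "DEFAULT_CROP_MM",
    "DEFAULT_TARGET_SPACING",
    "DEFAULT_HU_WINDOW",
    "crop_around_nodule",
    "resample",
    "normalize_intensity",
    "replicate_channels",
    "preprocess",
    "read_manifest",
    "write_manifest",
    "labels_from_malignancy_scores",
    "load_volume",
    "save_volume",
]

AIR_HU = -1000.0
#: Physical edge length of a nodule crop, mm (cubic crops).
DEFAULT_CROP_MM = 80.0
#: Resampled (z, y, x) voxel size in mm; an 80 mm cube becomes 20 x 64 x 64.
DEFAULT_TARGET_SPACING = (4.0, 1.25, 1.25)
#: Hounsfield window mapped onto [0, 1] (standard lung window).
DEFAULT_HU_WINDOW = (-1000.0, 400.0)

LABELS = ("benign", "malignant")


@dataclass
class NoduleVolume:
    """One nodule crop at one screening interval.

    ``voxels`` is (slices, rows, cols); ``spacing`` the matching per-axis
    voxel size in mm.  ``bbox_center`` is the annotated nodule centre in
    the crop's own physical (z, y, x) mm coordinates.  ``meta`` carries
    optional provenance (e.g. a phantom's true diameter).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    patient_id: str
    interval: int
    label: str
    bbox_center: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.interval not in (0, 1, 2):
            raise ValueError(f"interval must be in {{0,1,2}}, got {self.interval}")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.voxels.shape, self.spacing))

    def replace(self, **kw) -> "NoduleVolume":
        return dataclasses.replace(self, **kw)


@dataclass
class LongitudinalSeries:
    """Ordered volumes of one nodule across 1-3 screening intervals."""

    volumes: list[NoduleVolume]
    patient_id: str
    label: str

    def __post_init__(self):
        if len(self.volumes) < 1:
            raise ValueError("a series needs at least one volume")
        for v in self.volumes:
            if v.patient_id != self.patient_id:
                raise ValueError(
                    f"volume patient_id {v.patient_id!r} != series {self.patient_id!r}"
                )
            if v.label != self.label:
                raise ValueError(f"volume label {v.label!r} != series {self.label!r}")
        ivals = [v.interval for v in self.volumes]
        if not all(a < b for a, b in zip(ivals, ivals[1:])):
            raise ValueError(f"interval indices must be strictly increasing, got {ivals}")

    @property
    def intervals(self) -> list[int]:
        return [v.interval for v in self.volumes]

    def __len__(self) -> int:
        return len(self.volumes)


def crop_around_nodule(
    scan: np.ndarray,
    spacing: tuple[float, float, float],
    center_mm: tuple[float, float, float],
    size_mm: float = DEFAULT_CROP_MM,
    pad_value: float = AIR_HU,
    **volume_kw,
) -> NoduleVolume:
    """Cut a cubic crop of physical edge ``size_mm`` centred on ``center_mm``.

    ``scan`` is a (z, y, x) Hounsfield grid.  Voxels of the cube that fall
    outside the scan are filled with ``pad_value`` (air by default).  The
    returned volume's ``bbox_center`` is the nodule centre expressed in
    the crop's own coordinates.  Remaining :class:`NoduleVolume` fields
    are passed through ``volume_kw``.
    """
    scan = np.asarray(scan, dtype=np.float64)
    if size_mm <= 0:
        raise ValueError(f"size_mm must be > 0, got {size_mm}")
    spacing = tuple(float(s) for s in spacing)
    for ax, (c, n, s) in enumerate(zip(center_mm, scan.shape, spacing)):
        if not (0.0 <= c <= n * s):
            raise ValueError(
                f"center coordinate {c} mm on axis {ax} lies outside the scan "
                f"(extent {n * s} mm)"
            )
    n_vox = [int(round(size_mm / s)) for s in spacing]
    starts = [int(round(c / s - n / 2)) for c, s, n in zip(center_mm, spacing, n_vox)]
    out = np.full(n_vox, pad_value, dtype=np.float64)
    src, dst = [], []
    for ax in range(3):
        lo, hi = starts[ax], starts[ax] + n_vox[ax]
        src.append(slice(max(lo, 0), min(hi, scan.shape[ax])))
        dst.append(slice(max(-lo, 0), max(-lo, 0) + (min(hi, scan.shape[ax]) - max(lo, 0))))
    out[tuple(dst)] = scan[tuple(src)]
    center_in_crop = tuple(
        c - starts[ax] * spacing[ax] for ax, c in enumerate(center_mm)
    )
    return NoduleVolume(
        voxels=out, spacing=spacing, bbox_center=center_in_crop, **volume_kw
    )


def resample(
    volume: NoduleVolume, target_spacing: tuple[float, float, float] = DEFAULT_TARGET_SPACING
) -> NoduleVolume:
    """Trilinear resample onto a grid of ``round(extent / target_spacing)``
    voxels per axis; metadata is preserved, spacing updated."""
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target_spacing must be strictly positive, got {target_spacing}")
    extent = volume.extent_mm
    new_shape = tuple(max(1, int(round(e / t))) for e, t in zip(extent, target_spacing))
    # voxel-centre sampling: centre i sits at (i + 0.5) * spacing
    grids = [
        (np.arange(n) + 0.5) * t / s - 0.5
        for n, t, s in zip(new_shape, target_spacing, volume.spacing)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    vox = ndimage.map_coordinates(
        volume.voxels, np.stack(coords), order=1, mode="nearest"
    )
    return volume.replace(voxels=vox, spacing=target_spacing)


def normalize_intensity(
    volume: NoduleVolume, window: tuple[float, float] = DEFAULT_HU_WINDOW
) -> NoduleVolume:
    """Map the Hounsfield window [lo, hi] linearly onto [0, 1], clipping."""
    lo, hi = float(window[0]), float(window[1])
    if lo >= hi:
        raise ValueError(f"window must satisfy lo < hi, got ({lo}, {hi})")
    vox = np.clip((volume.voxels - lo) / (hi - lo), 0.0, 1.0)
    return volume.replace(voxels=vox)


def preprocess(
    volume: NoduleVolume,
    target_spacing: tuple[float, float, float] = DEFAULT_TARGET_SPACING,
    window: tuple[float, float] = DEFAULT_HU_WINDOW,
) -> NoduleVolume:
    """Resample then intensity-normalise; deterministic."""
    return normalize_intensity(resample(volume, target_spacing), window)


def replicate_channels(voxels: np.ndarray) -> np.ndarray:
    """Repeat each axial slice onto three identical channels.

    (N, H, W) -> (N, 3, H, W); lets grayscale CT feed RGB-trained 2-D
    backbones.
    """
    voxels = np.asarray(voxels)
    if voxels.ndim != 3:
        raise ValueError(f"expected a (N, H, W) volume, got shape {voxels.shape}")
    return np.repeat(voxels[:, None, :, :], 3, axis=1)


# ---------------------------------------------------------------------------
# NIfTI + CSV manifest I/O

MANIFEST_COLUMNS = [
    "patient_id",
    "interval",
    "label",
    "volume_path",
    "center_x_mm",
    "center_y_mm",
    "center_z_mm",
]


def labels_from_malignancy_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Manifest-preparation helper for radiologist-scored cohorts.

    ``scores`` has one row per (nodule_id, reader) with a 1-5 malignancy
    score.  Nodules with median score < 3 become "benign", > 3
    "malignant"; median-3 (indeterminate) nodules are dropped.  Returns
    a frame with columns nodule_id, median_score, label.
    """
    if not {"nodule_id", "score"} <= set(scores.columns):
        raise ValueError("scores needs columns nodule_id and score")
    med = scores.groupby("nodule_id")["score"].median().rename("median_score")
    out = med.reset_index()
    out = out[out.median_score != 3.0]
    out["label"] = np.where(out.median_score < 3.0, "benign", "malignant")
    return out.reset_index(drop=True)


def save_volume(volume: NoduleVolume, path: Path) -> None:
    """Write a NIfTI file; array stored (x, y, z) with spacing in the affine."""
    sz, sy, sx = volume.spacing
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(
        np.asarray(volume.voxels.transpose(2, 1, 0), dtype=np.float32), affine
    )
    nib.save(img, str(path))


def load_volume(path: Path, **volume_kw) -> NoduleVolume:
    img = nib.load(str(path))
    vox = np.asarray(img.get_fdata(), dtype=np.float64).transpose(2, 1, 0)
    zooms = img.header.get_zooms()[:3]  # (x, y, z)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return NoduleVolume(voxels=vox, spacing=spacing, **volume_kw)


def write_manifest(series_list: list[LongitudinalSeries], path: Path) -> pd.DataFrame:
    """Write volumes as NIfTI next to a CSV manifest at ``path``.

    Volumes go to ``<manifest dir>/volumes/<patient>_t<interval>.nii.gz``;
    ``volume_path`` entries are relative to the manifest directory.
    """
    path = Path(path)
    vol_dir = path.parent / "volumes"
    vol_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for series in series_list:
        for vol in series.volumes:
            rel = f"volumes/{vol.patient_id}_t{vol.interval}.nii.gz"
            save_volume(vol, path.parent / rel)
            cz, cy, cx = vol.bbox_center
            rows.append(
                {
                    "patient_id": vol.patient_id,
                    "interval": vol.interval,
                    "label": vol.label,
                    "volume_path": rel,
                    "center_x_mm": cx,
                    "center_y_mm": cy,
                    "center_z_mm": cz,
                }
            )
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_manifest(path: Path, load_volumes: bool = True) -> list[LongitudinalSeries]:
    """Read a CSV manifest back into grouped, interval-sorted series.

    Rejects duplicate (patient_id, interval) rows and unknown label
    tokens.  With ``load_volumes=False`` the voxel grids are left as
    1-voxel placeholders (manifest-structure work only).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    bad = set(df["label"].unique()) - set(LABELS)
    if bad:
        raise ValueError(f"unknown label tokens in manifest: {sorted(bad)}")
    dup = df.duplicated(subset=["patient_id", "interval"])
    if dup.any():
        pairs = df.loc[dup, ["patient_id", "interval"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate (patient_id, interval) rows: {pairs}")
    series_list = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("interval")
        labels = grp["label"].unique()
        if len(labels) > 1:
            raise ValueError(f"patient {pid!r} has conflicting labels {list(labels)}")
        vols = []
        for row in grp.itertuples(index=False):
            center = (float(row.center_z_mm), float(row.center_y_mm), float(row.center_x_mm))
            kw = dict(
                patient_id=str(row.patient_id),
                interval=int(row.interval),
                label=row.label,
                bbox_center=center,
            )
            if load_volumes:
                vols.append(load_volume(path.parent / row.volume_path, **kw))
            else:
                vols.append(NoduleVolume(voxels=np.zeros((1, 1, 1)), spacing=(1, 1, 1), **kw))
        series_list.append(LongitudinalSeries(volumes=vols, patient_id=str(pid), label=labels[0]))
    return series_list
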