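"""Synthetic longitudinal nodule phantoms.

Generates nodule-centred CT crops that mimic the statistical structure
of a longitudinal screening cohort: a soft-edged, mildly anisotropic
ellipsoidal blob of soft-tissue density on a noisy lung-parenchyma
background.  Benign nodules keep an essentially constant diameter
across screening intervals; malignant nodules grow steadily.  Benign
subjects have three annual scans; malignant subjects have two or three.

The generator is fully deterministic under its seed and emits the same
:class:`~canet.volumes.NoduleVolume` / CSV-manifest contract as the
real-data pipeline, so every downstream stage (preprocessing, models,
training, evaluation) can be exercised without restricted data.

The shipped diameter defaults (benign baseline ~N(6, 1.5^2) mm and
near-zero growth; malignant baseline ~N(8, 2^2) mm growing
~N(2.5, 0.75^2) mm per interval) are qualitative stand-ins chosen to
make growth, not baseline size alone, the discriminative signal at
realistic nodule scales; they are not measurements of any real cohort
and everything is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import (
    AIR_HU,
    DEFAULT_CROP_MM,
    LongitudinalSeries,
    NoduleVolume,
    write_manifest,
)

__all__ = [
    "ClassParams",
    "PhantomConfig",
    "generate_nodule_series",
    "generate_dataset",
    "matched_growth_task",
    "measure_diameter",
]


@dataclass(frozen=True)
class ClassParams:
    """Normal-distribution parameters for one class's nodule geometry (mm)."""

    baseline_mean: float
    baseline_sd: float
    growth_mean: float
    growth_sd: float


@dataclass(frozen=True)
class PhantomConfig:
    """Study-design knobs of the phantom cohort.

    ``spacing`` is the native acquisition grid the crops are synthesised
    on (slice thickness first); defaults echo a thin-slice screening
    protocol (2.5 mm slices, 0.7 mm in-plane).  Intensities are in
    Hounsfield units; ``noise_sigma_hu`` is the texture amplitude before
    smoothing.  ``seed`` fully determines the output.
    """

    n_benign: int = 650
    n_malignant: int = 207
    benign: ClassParams = field(default_factory=lambda: ClassParams(6.0, 1.5, 0.0, 0.3))
    malignant: ClassParams = field(default_factory=lambda: ClassParams(8.0, 2.0, 2.5, 0.75))
    crop_mm: float = DEFAULT_CROP_MM
    spacing: tuple[float, float, float] = (2.5, 0.7, 0.7)
    background_hu: float = -850.0
    nodule_hu: float = 20.0
    noise_sigma_hu: float = 60.0
    texture_smooth_vox: float = 1.5
    gradient_hu: float = 60.0
    edge_softness_vox: float = 1.0
    anisotropy_sd: float = 0.08
    center_jitter_mm: float = 1.5
    p_three_scans_malignant: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_benign < 0 or self.n_malignant < 0:
            raise ValueError("class counts must be >= 0")
        for cp in (self.benign, self.malignant):
            if cp.baseline_mean <= 0:
                raise ValueError("baseline diameters must be > 0")
        if self.noise_sigma_hu < 0:
            raise ValueError("noise_sigma_hu must be >= 0")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")


def _crop_shape(config: PhantomConfig) -> tuple[int, int, int]:
    return tuple(int(round(config.crop_mm / s)) for s in config.spacing)


def _background(config: PhantomConfig, shape, rng) -> np.ndarray:
    """Lung-like background: smoothed Gaussian noise + a low-frequency ramp."""
    bg = np.full(shape, config.background_hu)
    if config.noise_sigma_hu > 0:
        noise = rng.normal(0.0, config.noise_sigma_hu, size=shape)
        sm = config.texture_smooth_vox
        if sm > 0:
            noise = ndimage.gaussian_filter(noise, sigma=sm)
            # restore the requested amplitude after low-pass attenuation
            sd = noise.std()
            if sd > 0:
                noise *= config.noise_sigma_hu / sd
        bg += noise
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    grids = np.meshgrid(*[np.linspace(-0.5, 0.5, n) for n in shape], indexing="ij")
    ramp = sum(d * g for d, g in zip(direction, grids))
    bg += config.gradient_hu * ramp
    return bg


def _blob_profile(config: PhantomConfig, shape, center_mm, diameter_mm, axis_scale) -> np.ndarray:
    """Sigmoid-edged ellipsoid occupancy in [0, 1]."""
    spacing = np.asarray(config.spacing)
    semi = axis_scale * diameter_mm / 2.0
    coords = np.meshgrid(
        *[(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    rho = np.sqrt(
        sum(((g - c) / a) ** 2 for g, c, a in zip(coords, center_mm, semi))
    )
    softness_mm = config.edge_softness_vox * float(np.mean(spacing))
    signed_mm = (rho - 1.0) * float(np.mean(semi))
    return 1.0 / (1.0 + np.exp(np.clip(signed_mm / max(softness_mm, 1e-6), -60, 60)))


def generate_nodule_series(
    config: PhantomConfig, label: str, rng: np.random.Generator, patient_id: str = "P0000"
) -> LongitudinalSeries:
    """Synthesise one patient's longitudinal crop series in Hounsfield units.

    Diameter at the k-th scan of the series is ``baseline + k * growth``
    with a single growth draw per series (steady growth); the blob
    centre is jittered independently per interval to mimic imperfect
    scan-to-scan alignment.
    """
    cp = config.benign if label == "benign" else config.malignant
    shape = _crop_shape(config)
    baseline = -1.0
    while baseline <= 0:
        baseline = rng.normal(cp.baseline_mean, cp.baseline_sd)
    growth = rng.normal(cp.growth_mean, cp.growth_sd)
    if label == "benign":
        intervals = [0, 1, 2]
    else:
        three = rng.random() < config.p_three_scans_malignant
        intervals = [0, 1, 2] if three else [0, 1]
    axis_scale = np.exp(rng.normal(0.0, config.anisotropy_sd, size=3))
    axis_scale /= axis_scale.prod() ** (1.0 / 3.0)  # volume-preserving anisotropy
    crop_center = np.full(3, config.crop_mm / 2.0)
    volumes = []
    for k, t in enumerate(intervals):
        diameter = baseline + k * growth
        jitter = rng.normal(0.0, config.center_jitter_mm, size=3)
        center = crop_center + jitter
        if diameter >= config.crop_mm / 2.0:
            raise ValueError(
                f"nodule diameter {diameter:.1f} mm exceeds half the crop extent "
                f"({config.crop_mm} mm)"
            )
        vox = _background(config, shape, rng)
        profile = _blob_profile(config, shape, center, diameter, axis_scale)
        vox = vox + (config.nodule_hu - vox) * profile
        volumes.append(
            NoduleVolume(
                voxels=vox,
                spacing=config.spacing,
                patient_id=patient_id,
                interval=t,
                label=label,
                bbox_center=tuple(center),
                meta={"true_diameter_mm": float(diameter)},
            )
        )
    return LongitudinalSeries(volumes=volumes, patient_id=patient_id, label=label)


def generate_dataset(
    config: PhantomConfig, out_dir: Path | None = None
) -> tuple[list[LongitudinalSeries], pd.DataFrame | None]:
    """Generate the configured cohort; optionally write NIfTI + manifest.

    Returns the series list and, when ``out_dir`` is given, the manifest
    DataFrame (written to ``<out_dir>/manifest.csv``).
    """
    rng = np.random.default_rng(config.seed)
    series_list = []
    for i in range(config.n_benign):
        series_list.append(
            generate_nodule_series(config, "benign", rng, patient_id=f"B{i:04d}")
        )
    for i in range(config.n_malignant):
        series_list.append(
            generate_nodule_series(config, "malignant", rng, patient_id=f"M{i:04d}")
        )
    manifest = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = write_manifest(series_list, out_dir / "manifest.csv")
    return series_list, manifest


def matched_growth_task(config: PhantomConfig) -> list[LongitudinalSeries]:
    """Diagnostic cohort in which only growth separates the classes.

    Both classes draw baseline diameters from the same distribution (the
    average of the configured class baselines) and every subject gets
    three scans, so a classifier seeing only the first scan has no
    exploitable signal while a multi-time-point classifier does.
    """
    shared = ClassParams(
        baseline_mean=(config.benign.baseline_mean + config.malignant.baseline_mean) / 2.0,
        baseline_sd=(config.benign.baseline_sd + config.malignant.baseline_sd) / 2.0,
        growth_mean=0.0,
        growth_sd=0.0,
    )
    cfg = replace(
        config,
        benign=replace(shared, growth_mean=config.benign.growth_mean,
                       growth_sd=config.benign.growth_sd),
        malignant=replace(shared, growth_mean=config.malignant.growth_mean,
                          growth_sd=config.malignant.growth_sd),
        p_three_scans_malignant=1.0,
    )
    series_list, _ = generate_dataset(cfg)
    return series_list


def measure_diameter(volume: NoduleVolume, threshold_hu: float | None = None) -> float:
    """Sphere-equivalent diameter (mm) of the thresholded blob.

    Thresholds at the midpoint between parenchyma and nodule density by
    default, counts voxels above it and converts the volume to the
    diameter of the equal-volume sphere.
    """
    if threshold_hu is None:
        threshold_hu = (PhantomConfig.background_hu + PhantomConfig.nodule_hu) / 2.0
    voxel_volume = float(np.prod(volume.spacing))
    n = int((volume.voxels > threshold_hu).sum())
    return float((6.0 * n * voxel_volume / np.pi) ** (1.0 / 3.0))
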