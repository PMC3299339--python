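"""Digital phantoms and synthetic cohorts with known ground truth.

Two generators make every pipeline stage testable without clinical data:

``generate_phantom``
    A desk-scale digital CBCT scene: a porous high-density implant
    sphere, a water-density contralateral globe (corpus vitreum), a
    dense bone slab that supplies the dedicated volume's maximum, and
    optional radial surface spikes.  The "true" volume sits on the
    calibrated (MSCT-like) HU scale; the "observed" volume is the same
    scene after an unknown per-scan affine miscalibration
    (``observed = gain·true + offset``) plus additive Gaussian noise —
    the distortion model the two-point correction is designed to invert.
    Porosity is emulated as sub-resolution density reduction: a seeded
    fraction of implant voxels is set to soft-tissue density, mimicking
    ~80% porous ceramics at a 0.25 mm grid (true 150–400 µm pore
    microarchitecture is far below this resolution and is not modelled).

``generate_cohort``
    Table-style synthetic cohorts for the longitudinal analysis: per
    group, corrected density follows baseline + slope·(lifespan/yr) plus
    Gaussian residual; each record's raw (uncalibrated) implant mean is
    then *back-computed* by inverting the two-point correction through
    that record's own simulated anchors, so running the pipeline's
    correction recovers the generated truth exactly.

Both generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .hu_calibration import MsctReference
from .region_analysis import RegionMask, VoxelVolume
from .study_table import ImplantRecord

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, densities, noise and miscalibration of a digital scene.

    Defaults: a 128³ grid at 0.25 mm (32 mm cube) holding an 18 mm
    implant of 1800 HU bulk ceramic at 80% porosity over 40 HU soft
    tissue, an 8 mm water-density globe, and a 2024.67 HU bone slab.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: float = 0.25
    implant_center_mm: tuple[float, float, float] = (11.0, 16.0, 16.0)
    implant_diameter_mm: float = 18.0
    implant_true_hu: float = 1800.0
    pore_fraction: float = 0.8
    tissue_hu: float = 40.0
    cv_center_mm: tuple[float, float, float] = (26.0, 16.0, 16.0)
    cv_diameter_mm: float = 8.0
    cv_true_hu: float = 0.0
    bone_true_hu: float = 2024.67
    spike_count: int = 0
    spike_length_mm: float = 2.0
    noise_sd_hu: float = 50.0
    distortion_gain: float = 1.0
    distortion_offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pore_fraction < 1.0):
            raise ValueError("pore_fraction must be in [0, 1)")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be non-negative")
        if self.distortion_gain <= 0:
            raise ValueError("distortion_gain must be positive")
        ic = np.asarray(self.implant_center_mm, float)
        cc = np.asarray(self.cv_center_mm, float)
        gap = float(np.linalg.norm(ic - cc))
        if gap <= (self.implant_diameter_mm + self.cv_diameter_mm) / 2.0:
            raise ValueError("implant and corpus-vitreum spheres must be disjoint")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth bundle: calibrated scene, observed scene, masks."""

    true_volume: VoxelVolume
    observed_volume: VoxelVolume
    masks: Mapping[str, RegionMask]
    spike_voxels: frozenset[tuple[int, int, int]]
    spec: PhantomSpec


def _sphere_mask(vol_shape, spacing, center_mm, radius_mm) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n) for n in vol_shape], indexing="ij")
    idx = np.stack(grids, axis=-1).astype(float)
    centers = idx * spacing  # origin at 0
    d2 = np.sum((centers - np.asarray(center_mm, float)) ** 2, axis=-1)
    return d2 <= radius_mm**2


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Rasterise the scene, apply miscalibration and noise, return truth.

    Regions are rasterised by voxel-center membership.  Pores are a
    seeded uniform sample of implant voxels set to ``tissue_hu``; spikes
    are radial rays of implant material extending ``spike_length_mm``
    beyond the implant surface in seeded random directions.  The
    dedicated volume (DV) covers the whole grid except a 1 mm-dilated
    neighbourhood of the contralateral globe, so it contains the implant
    and the bone slab (whose density supplies the DV maximum) but never
    the corpus vitreum.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    spacing = np.full(3, float(spec.spacing_mm))
    origin = np.zeros(3)
    extent_mm = (np.asarray(shape) - 1) * spacing

    r_imp = spec.implant_diameter_mm / 2.0
    r_cv = spec.cv_diameter_mm / 2.0
    for c, r in ((spec.implant_center_mm, r_imp), (spec.cv_center_mm, r_cv)):
        c = np.asarray(c, float)
        if np.any(c - r < -spec.spacing_mm / 2) or np.any(
            c + r > extent_mm + spec.spacing_mm / 2
        ):
            raise ValueError("sphere exceeds the phantom grid")

    implant = _sphere_mask(shape, spacing, spec.implant_center_mm, r_imp)
    cv = _sphere_mask(shape, spacing, spec.cv_center_mm, r_cv)

    # Bone slab (~1 mm) along the top of the grid, clear of both spheres.
    bone = np.zeros(shape, dtype=bool)
    z_slab = max(1, int(round(1.0 / spec.spacing_mm)))
    bone[:, :, -z_slab:] = True
    bone &= ~implant & ~cv

    true_vals = np.full(shape, spec.tissue_hu, dtype=float)
    true_vals[implant] = spec.implant_true_hu
    true_vals[cv] = spec.cv_true_hu
    true_vals[bone] = spec.bone_true_hu

    # Sub-resolution porosity: seeded subset of implant voxels at tissue density.
    imp_idx = np.argwhere(implant)
    if spec.pore_fraction > 0 and imp_idx.shape[0] > 0:
        n_pores = int(round(spec.pore_fraction * imp_idx.shape[0]))
        chosen = rng.choice(imp_idx.shape[0], size=n_pores, replace=False)
        pores = imp_idx[chosen]
        true_vals[tuple(pores.T)] = spec.tissue_hu

    # Marginal spikes: radial rays of implant material beyond the surface.
    spike_voxels: set[tuple[int, int, int]] = set()
    center = np.asarray(spec.implant_center_mm, float)
    for _ in range(spec.spike_count):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        step = spec.spacing_mm / 2.0
        for t in np.arange(r_imp + step, r_imp + spec.spike_length_mm + step / 2, step):
            p = center + t * v
            ijk = np.round(p / spacing).astype(int)
            if np.all(ijk >= 0) and np.all(ijk < np.asarray(shape)):
                key = (int(ijk[0]), int(ijk[1]), int(ijk[2]))
                if not implant[key] and not cv[key]:
                    spike_voxels.add(key)
    for key in spike_voxels:
        true_vals[key] = spec.implant_true_hu

    oi_sel = implant.copy()
    for key in spike_voxels:
        oi_sel[key] = True

    dv_sel = ~_sphere_mask(shape, spacing, spec.cv_center_mm, r_cv + 1.0)

    noise = (
        rng.normal(0.0, spec.noise_sd_hu, size=shape) if spec.noise_sd_hu > 0 else 0.0
    )
    observed_vals = spec.distortion_gain * true_vals + spec.distortion_offset + noise

    true_volume = VoxelVolume(values=true_vals, spacing_mm=spacing, origin_mm=origin)
    observed_volume = VoxelVolume(
        values=observed_vals, spacing_mm=spacing, origin_mm=origin
    )
    masks = {
        "OI": RegionMask(selector=oi_sel, label="OI"),
        "CV": RegionMask(selector=cv, label="CV"),
        "DV": RegionMask(selector=dv_sel, label="DV"),
    }
    return PhantomTruth(
        true_volume=true_volume,
        observed_volume=observed_volume,
        masks=masks,
        spike_voxels=frozenset(spike_voxels),
        spec=spec,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Statistical structure of a synthetic longitudinal cohort.

    Defaults match the study conditions: two material groups of 17 and
    11 implants, yearly corrected-density slopes of −10 and −14 HU,
    lifespans uniform over 79–2636 days, 100 HU residual scatter, and
    per-record anchors drawn around the clinical anchor spread.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"HA": 17, "AO": 11}
    )
    baseline_hu: Mapping[str, float] = field(
        default_factory=lambda: {"HA": 800.0, "AO": 800.0}
    )
    slope_hu_per_year: Mapping[str, float] = field(
        default_factory=lambda: {"HA": -10.0, "AO": -14.0}
    )
    lifespan_range_days: tuple[int, int] = (79, 2636)
    residual_sd_hu: float = 100.0
    cv_anchor_mean_hu: float = -150.0
    cv_anchor_sd_hu: float = 150.0
    dv_anchor_mean_hu: float = 2100.0
    dv_anchor_sd_hu: float = 300.0
    days_per_year: float = 365.25
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lifespan_range_days
        if not (0 < lo <= hi):
            raise ValueError("lifespan range must be positive and ordered")
        if self.residual_sd_hu < 0:
            raise ValueError("residual_sd_hu must be non-negative")
        if any(n <= 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be positive")


def generate_cohort(
    spec: CohortSpec, reference: MsctReference | None = None
) -> tuple[list[ImplantRecord], pd.DataFrame]:
    """Draw a synthetic cohort and its generating-truth table.

    For each record: lifespan ~ U(range); true corrected density =
    baseline + slope·lifespan/days_per_year + N(0, residual_sd); anchors
    drawn from the anchor model (re-drawn until separated by > 50 HU);
    the raw implant mean is the exact affine inverse of the two-point
    correction through those anchors, so the pipeline's correction
    reproduces the true corrected density to machine precision.
    """
    reference = reference if reference is not None else MsctReference()
    rng = np.random.default_rng(spec.seed)
    ref_span = reference.dv_max_hu - reference.cv_mean_hu
    records: list[ImplantRecord] = []
    truth_rows = []
    diam_choices = np.array([16.0, 18.0, 20.0])
    diam_probs = np.array([1.0, 13.0, 16.0]) / 30.0
    for group in spec.n_per_group:
        slope_day = spec.slope_hu_per_year[group] / spec.days_per_year
        for i in range(spec.n_per_group[group]):
            lifespan = int(rng.integers(*spec.lifespan_range_days, endpoint=True))
            eps = rng.normal(0.0, spec.residual_sd_hu) if spec.residual_sd_hu else 0.0
            corrected_true = (
                spec.baseline_hu[group] + slope_day * lifespan + eps
            )
            while True:
                cv_scan = rng.normal(spec.cv_anchor_mean_hu, spec.cv_anchor_sd_hu)
                dv_scan = rng.normal(spec.dv_anchor_mean_hu, spec.dv_anchor_sd_hu)
                if dv_scan - cv_scan > 50.0:
                    break
            # invert HU_corr = (raw − cv)/(dv − cv)·ref_span + ref.cv
            raw = (
                (corrected_true - reference.cv_mean_hu)
                / ref_span
                * (dv_scan - cv_scan)
                + cv_scan
            )
            d = float(rng.choice(diam_choices, p=diam_probs))
            d_est = d + rng.normal(0.0, 0.28)
            rec = ImplantRecord(
                id_label=f"{group}.{i + 1}",
                diameter_measured_mm=d,
                diameter_estimated_mm=max(d_est, 0.1),
                lifespan_days=lifespan,
                oi_mean_hu=float(raw),
                oi_sd_hu=float(abs(rng.normal(250.0, 100.0))),
                corrected_mean_hu=float(corrected_true),
                cv_mean_hu=float(cv_scan),
                dv_max_hu=float(dv_scan),
            )
            records.append(rec)
            truth_rows.append(
                {
                    "id_label": rec.id_label,
                    "group": group,
                    "lifespan_days": lifespan,
                    "baseline_hu": spec.baseline_hu[group],
                    "slope_hu_per_year": spec.slope_hu_per_year[group],
                    "residual_hu": float(eps),
                    "corrected_true_hu": float(corrected_true),
                    "cv_scan_hu": float(cv_scan),
                    "dv_scan_hu": float(dv_scan),
                    "oi_raw_hu": float(raw),
                }
            )
    return records, pd.DataFrame(truth_rows)
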