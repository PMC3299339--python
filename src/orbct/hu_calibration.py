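"""Two-point Hounsfield calibration of uncalibrated CBCT densities.

The Hounsfield scale is an affine transform of the linear attenuation
coefficient fixed by two physical anchors: distilled water at STP is
0 HU and air at STP is −1000 HU,

    HU = 1000 · (μ_X − μ_water) / (μ_water − μ_air).

Medical multi-slice CT (MSCT) scanners are water-calibrated, so their
output sits on this scale.  CBCT units report HU-like numbers on a
scanner- and acquisition-dependent affine scale, so every CBCT
acquisition needs its own calibration.  The correction used here maps
two reference objects visible in each scan — the contralateral corpus
vitreum mean (water-like, low anchor) and the dedicated orbital volume's
maximum (dense bone, high anchor) — onto the values those objects take
in a water-calibrated MSCT control group:

    HU_corr = (HU − HU_cv_scan) / (HU_dv_scan − HU_cv_scan)
              · (HU_dv_ref − HU_cv_ref) + HU_cv_ref.

This is the unique affine map sending the scan-side anchors exactly onto
the reference-side anchors; the wider the anchor separation, the better
conditioned the map.  A variant without the trailing ``+ HU_cv_ref`` term
(which instead pins the low anchor to 0) is available behind
``literal_equation=False`` because the study's published corrected column
is numerically closer to that reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .region_analysis import VoxelVolume

__all__ = [
    "AttenuationContext",
    "MsctReference",
    "ScanCalibration",
    "DegenerateCalibrationError",
    "DEGENERACY_TOL_HU",
    "hounsfield_from_attenuation",
    "build_calibration",
    "correct_hu",
    "correct_volume",
]

#: Minimum allowed scan-side anchor separation (HU).  Anchors closer than
#: image noise make the affine map meaningless.
DEGENERACY_TOL_HU = 1.0


class DegenerateCalibrationError(ValueError):
    """Scan-side anchors coincide, are too close, or are swapped."""


@dataclass(frozen=True)
class AttenuationContext:
    """Linear attenuation coefficients (any consistent 1/length units)."""

    mu_x: float
    mu_water: float
    mu_air: float = 0.0

    def __post_init__(self) -> None:
        if not self.mu_water > self.mu_air:
            raise ValueError(
                "non-physical calibration pair: mu_water must exceed mu_air"
            )


@dataclass(frozen=True)
class MsctReference:
    """MSCT-side anchor values from the water-calibrated control group.

    Defaults are the control-cohort results: corpus-vitreum mean
    5.93 ± 3.97 HU and dedicated-volume maximum 2024.67 ± 103.49 HU.
    """

    cv_mean_hu: float = 5.93
    cv_sd_hu: float = 3.97
    dv_max_hu: float = 2024.67
    dv_max_sd_hu: float = 103.49

    def __post_init__(self) -> None:
        if not self.dv_max_hu > self.cv_mean_hu:
            raise ValueError("reference anchors must satisfy dv_max > cv_mean")


@dataclass(frozen=True)
class ScanCalibration:
    """Per-scan affine map from uncalibrated CBCT HU to the MSCT scale."""

    cv_scan_hu: float
    dvmax_scan_hu: float
    reference: MsctReference = field(default_factory=MsctReference)
    gain: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise DegenerateCalibrationError("calibration gain must be positive")


def hounsfield_from_attenuation(ctx: AttenuationContext) -> float:
    """Hounsfield value of attenuation ``mu_x``: water ↦ 0, air ↦ −1000."""
    return 1000.0 * (ctx.mu_x - ctx.mu_water) / (ctx.mu_water - ctx.mu_air)


def build_calibration(
    cv_scan_hu: float,
    dvmax_scan_hu: float,
    reference: MsctReference | None = None,
    *,
    tolerance_hu: float = DEGENERACY_TOL_HU,
    literal_equation: bool = True,
) -> ScanCalibration:
    """Solve the 2×2 affine system sending scan anchors to reference anchors.

    gain = (ref.dv_max − ref.cv_mean) / (dvmax_scan − cv_scan) and
    offset = ref.cv_mean − gain·cv_scan, so that ``cv_scan ↦ ref.cv_mean``
    and ``dvmax_scan ↦ ref.dv_max`` exactly.  With
    ``literal_equation=False`` the reference low-anchor term is dropped
    from the offset (``cv_scan ↦ 0``), matching the alternative reading
    of the published correction.

    Raises :class:`DegenerateCalibrationError` when the scan anchors are
    swapped or separated by less than ``tolerance_hu``.
    """
    reference = reference if reference is not None else MsctReference()
    delta = dvmax_scan_hu - cv_scan_hu
    if delta < 0:
        raise DegenerateCalibrationError(
            f"anchor orientation error: dvmax_scan ({dvmax_scan_hu}) < "
            f"cv_scan ({cv_scan_hu}); anchors appear swapped"
        )
    if abs(delta) <= tolerance_hu:
        raise DegenerateCalibrationError(
            f"degenerate calibration: anchor separation {delta} HU is within "
            f"tolerance {tolerance_hu} HU"
        )
    gain = (reference.dv_max_hu - reference.cv_mean_hu) / delta
    offset = -gain * cv_scan_hu
    if literal_equation:
        offset += reference.cv_mean_hu
    return ScanCalibration(
        cv_scan_hu=cv_scan_hu,
        dvmax_scan_hu=dvmax_scan_hu,
        reference=reference,
        gain=gain,
        offset=offset,
    )


def correct_hu(value, cal: ScanCalibration):
    """Apply the per-scan affine correction; scalars and arrays alike."""
    out = cal.gain * np.asarray(value, dtype=float) + cal.offset
    return float(out) if np.ndim(value) == 0 else out


def correct_volume(volume: VoxelVolume, cal: ScanCalibration) -> VoxelVolume:
    """Voxelwise correction; geometry (shape, spacing, origin) preserved.

    Shares the scalar affine map so scalar and volume paths cannot drift.
    """
    values = np.asarray(volume.values, dtype=float)
    bad = np.count_nonzero(~np.isfinite(values))
    if bad:
        raise ValueError(f"volume contains {bad} non-finite voxel(s)")
    return VoxelVolume(
        values=correct_hu(values, cal),
        spacing_mm=volume.spacing_mm,
        origin_mm=volume.origin_mm,
    )
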