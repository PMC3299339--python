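"""The published 30-patient CBCT cohort and its summary statistics.

Thirty enucleated patients received porous spherical orbital implants
(16/18/20 mm nominal diameter) and were scanned once each with a
large-volume CBCT unit at 0.25 mm isometric voxels.  For every scan the
study recorded the uncalibrated mean HU over the implant volume (OI), the
mean HU of the contralateral corpus vitreum (CV, the water-like low
anchor), the maximum HU of the dedicated orbital volume (DV, the dense
high anchor), the published two-point-corrected implant mean, the implant
lifespan in days, and the sphere-fit diameter estimate.

The table ships verbatim as a CSV fixture; decimal commas in the printed
diameters were normalised to periods at transcription.  Record 1.26 prints
a 10 mm measured diameter that conflicts with its 19.66 mm estimate and
with the stated 16/18/20 mm size list; it is kept as printed but flagged
``suspect_diameter`` and excluded from the diameter-deviation SD.

The implant material (hydroxyapatite vs aluminium oxide) and the two
excluded cases were encoded only as table colours in the source and are
not recoverable from text; all records therefore load with
``included=True`` and no material field, and callers supply exclusion
lists / material maps themselves.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from statistics import mean, stdev
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ImplantRecord",
    "CohortSummary",
    "DataIntegrityError",
    "load_study_table",
    "summarize_cohort",
    "records_to_dataframe",
    "records_to_csv",
    "records_to_json",
]

#: SHA-256 of the packaged fixture; guards against silent corruption.
_FIXTURE_SHA256 = "76df3b2c0da9d0b10268dcb179556625ea9c8fe0b9cfd6cae09d68b496901567"

#: Quality flag attached to record 1.26 (printed diameter inconsistent
#: with its estimate and the manufacturer size list).
SUSPECT_DIAMETER = "suspect_diameter"


class DataIntegrityError(RuntimeError):
    """Packaged fixture is missing or does not match its pinned checksum."""


@dataclass(frozen=True)
class ImplantRecord:
    """One cohort row: geometry, timing and density statistics of one scan.

    HU columns are on the scanner's uncalibrated CBCT scale except
    ``corrected_mean_hu``, which is the published value after the study's
    two-point correction onto the MSCT reference scale.
    """

    id_label: str
    diameter_measured_mm: float
    diameter_estimated_mm: float
    lifespan_days: int
    oi_mean_hu: float
    oi_sd_hu: float
    corrected_mean_hu: float
    cv_mean_hu: float
    dv_max_hu: float
    included: bool = True
    quality_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.lifespan_days <= 0:
            raise ValueError(f"{self.id_label}: lifespan_days must be positive")
        if self.diameter_measured_mm <= 0 or self.diameter_estimated_mm <= 0:
            raise ValueError(f"{self.id_label}: diameters must be positive")
        if not self.dv_max_hu > self.cv_mean_hu:
            raise ValueError(
                f"{self.id_label}: calibration anchors must be distinct "
                f"(dv_max_hu={self.dv_max_hu} <= cv_mean_hu={self.cv_mean_hu})"
            )

    def with_included(self, included: bool) -> "ImplantRecord":
        return replace(self, included=included)


@dataclass(frozen=True)
class CohortSummary:
    """Lifespan range/mean and the sphere-fit diameter deviation SD."""

    n_records: int
    lifespan_min_days: int
    lifespan_max_days: int
    lifespan_mean_days: float
    diameter_deviation_sd_mm: float | None

    def __post_init__(self) -> None:
        if not (
            self.lifespan_min_days
            <= self.lifespan_mean_days
            <= self.lifespan_max_days
        ):
            raise ValueError("lifespan summary ordering violated")


def _fixture_path() -> Path:
    return Path(resources.files("orbct").joinpath("data/table1.csv"))  # type: ignore[arg-type]


def load_study_table(path: str | Path | None = None, *, verify: bool = True) -> list[ImplantRecord]:
    """Load the packaged cohort table (or a user CSV in the same layout).

    Returns exactly the printed 30 records, all ``included=True``.
    With ``verify`` (default) the packaged fixture's SHA-256 is checked
    and a :class:`DataIntegrityError` raised on mismatch.
    """
    p = Path(path) if path is not None else _fixture_path()
    if not p.exists():
        raise DataIntegrityError(f"study table fixture not found: {p}")
    raw = p.read_bytes()
    if path is None and verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _FIXTURE_SHA256:
            raise DataIntegrityError(
                f"study table checksum mismatch: {digest} != {_FIXTURE_SHA256}"
            )
    df = pd.read_csv(p, dtype={"id_label": str, "quality_flags": str})
    records = []
    for row in df.itertuples(index=False):
        flags = frozenset(
            f for f in str(row.quality_flags).split(";") if f and f != "nan"
        )
        records.append(
            ImplantRecord(
                id_label=row.id_label,
                diameter_measured_mm=float(row.diameter_measured_mm),
                diameter_estimated_mm=float(row.diameter_estimated_mm),
                lifespan_days=int(row.lifespan_days),
                oi_mean_hu=float(row.oi_mean_hu),
                oi_sd_hu=float(row.oi_sd_hu),
                corrected_mean_hu=float(row.corrected_mean_hu),
                cv_mean_hu=float(row.cv_mean_hu),
                dv_max_hu=float(row.dv_max_hu),
                quality_flags=flags,
            )
        )
    return records


def summarize_cohort(records: Sequence[ImplantRecord]) -> CohortSummary:
    """Lifespan min/max/mean over ``records`` plus the diameter deviation SD.

    The deviation SD is the sample SD (n−1 denominator) of
    estimated − measured diameter over records *not* flagged
    ``suspect_diameter``; it is ``None`` when fewer than two such records
    exist.
    """
    if not records:
        raise ValueError("summarize_cohort requires at least one record")
    lifespans = [r.lifespan_days for r in records]
    deviations = [
        r.diameter_estimated_mm - r.diameter_measured_mm
        for r in records
        if SUSPECT_DIAMETER not in r.quality_flags
    ]
    sd = stdev(deviations) if len(deviations) >= 2 else None
    return CohortSummary(
        n_records=len(records),
        lifespan_min_days=min(lifespans),
        lifespan_max_days=max(lifespans),
        lifespan_mean_days=mean(lifespans),
        diameter_deviation_sd_mm=sd,
    )


def records_to_dataframe(records: Iterable[ImplantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {
            "id_label": r.id_label,
            "diameter_measured_mm": r.diameter_measured_mm,
            "diameter_estimated_mm": r.diameter_estimated_mm,
            "lifespan_days": r.lifespan_days,
            "oi_mean_hu": r.oi_mean_hu,
            "oi_sd_hu": r.oi_sd_hu,
            "corrected_mean_hu": r.corrected_mean_hu,
            "cv_mean_hu": r.cv_mean_hu,
            "dv_max_hu": r.dv_max_hu,
            "included": r.included,
            "quality_flags": ";".join(sorted(r.quality_flags)),
        }
        rows.append(d)
    return pd.DataFrame(rows)


def records_to_csv(records: Iterable[ImplantRecord], path: str | Path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)


def records_to_json(records: Iterable[ImplantRecord]) -> str:
    df = records_to_dataframe(records)
    return json.dumps(df.to_dict(orient="records"), indent=2)
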