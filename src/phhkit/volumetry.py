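"""Ventricular CSF volumetry from per-slice segmented areas.

Volume is estimated by the Cavalieri rule: the segmented cross-sectional
area of each MR slice times the slice thickness, summed over slices,

    V = sum_k A_k * t          [mm^3],  reported in mL (1 mL = 1000 mm^3).

Compartments are tracked separately; the default inclusion policy counts the
two lateral ventricles and the third ventricle, and excludes the aqueduct,
fourth ventricle and extra-axial subarachnoid spaces, so that posterior CSF
spaces that are hard to delineate consistently never contaminate the
ventriculomegaly readout.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    ConsistencyError,
    EmptyInputError,
    LabelingError,
    MappingError,
)


class Compartment(IntEnum):
    """CSF compartment labels; integer values are the mask label codes."""

    LATERAL_L = 1
    LATERAL_R = 2
    THIRD = 3
    AQUEDUCT = 4
    FOURTH = 5
    EXTRA_AXIAL = 6


#: Compartments entering the ventricular volume by default: lateral + third.
DEFAULT_INCLUSION = frozenset({Compartment.LATERAL_L, Compartment.LATERAL_R, Compartment.THIRD})


@dataclass(frozen=True)
class SliceAreaRecord:
    """One segmented compartment area on one MR slice."""

    subject_id: str
    day: int
    slice_index: int
    compartment: Compartment
    area: float  # mm^2
    thickness: float  # mm

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError(f"negative area {self.area} mm^2")
        if self.thickness <= 0:
            raise ValueError(f"non-positive slice thickness {self.thickness} mm")


@dataclass(frozen=True)
class VolumeMeasurement:
    """Ventricular CSF volume for one subject on one scan day."""

    subject_id: str
    day: int
    volume: float  # mL
    n_slices_included: int
    compartments_included: frozenset[Compartment]


def area_from_mask(
    label_mask: np.ndarray,
    pixel_spacing: tuple[float, float],
) -> dict[Compartment, float]:
    """Per-compartment area (mm^2) of one slice's segmentation mask.

    ``label_mask`` holds compartment codes (:class:`Compartment` values) with
    0 = background; ``pixel_spacing`` is (row, col) mm per pixel edge.  Area
    is pixel count times pixel area, so in-plane orientation is irrelevant.
    """
    row_sp, col_sp = pixel_spacing
    if row_sp <= 0 or col_sp <= 0:
        raise ConfigurationError(f"pixel spacing must be positive, got {pixel_spacing}")
    label_mask = np.asarray(label_mask)
    if label_mask.ndim != 2:
        raise LabelingError(f"label mask must be 2-D, got shape {label_mask.shape}")
    valid = {0} | {int(c) for c in Compartment}
    present = set(np.unique(label_mask).tolist())
    unknown = present - valid
    if unknown:
        raise LabelingError(f"unknown label values {sorted(unknown)} in mask; valid: {sorted(valid)}")
    pixel_area = row_sp * col_sp
    return {
        comp: float(np.count_nonzero(label_mask == int(comp))) * pixel_area
        for comp in Compartment
    }


def volume_from_areas(
    records: Iterable[SliceAreaRecord],
    inclusion: frozenset[Compartment] | set[Compartment] = DEFAULT_INCLUSION,
    allow_mixed_thickness: bool = False,
) -> VolumeMeasurement:
    """Cavalieri volume (mL) of one scan from its slice-area records.

    All records must share subject and day.  Slice thickness must be
    constant within the scan unless ``allow_mixed_thickness`` is set (the
    sum then uses each record's own thickness).
    """
    records = list(records)
    if not records:
        raise EmptyInputError("no slice-area records supplied")
    subjects = {r.subject_id for r in records}
    days = {r.day for r in records}
    if len(subjects) > 1 or len(days) > 1:
        raise ConsistencyError(
            f"records span multiple scans: subjects {sorted(subjects)}, days {sorted(days)}"
        )
    thicknesses = {r.thickness for r in records}
    if len(thicknesses) > 1 and not allow_mixed_thickness:
        raise ConsistencyError(
            f"mixed slice thicknesses {sorted(thicknesses)} mm within one scan; "
            "pass allow_mixed_thickness=True to override"
        )
    inclusion = frozenset(inclusion)
    included = [r for r in records if r.compartment in inclusion]
    volume_mm3 = sum(r.area * r.thickness for r in included)
    return VolumeMeasurement(
        subject_id=records[0].subject_id,
        day=records[0].day,
        volume=volume_mm3 / 1000.0,
        n_slices_included=len({r.slice_index for r in included}),
        compartments_included=inclusion,
    )


def build_trajectories(
    measurements: Iterable[VolumeMeasurement],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Long-format (group, subject, day, volume) table of a cohort.

    ``groups`` maps subject_id -> group label; a subject without a mapping is
    an error.  Missing visits stay absent — scans lost to early death are
    never imputed.
    """
    rows = []
    for m in measurements:
        if m.subject_id not in groups:
            raise MappingError(f"subject {m.subject_id!r} has no group assignment")
        rows.append((groups[m.subject_id], m.subject_id, m.day, m.volume))
    df = pd.DataFrame(rows, columns=["group", "subject", "day", "volume"])
    return df.sort_values(["group", "subject", "day"], kind="stable").reset_index(drop=True)


def group_day_means(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Mean volume per (group, day) — the trajectory entering trend analysis."""
    return (
        trajectories.groupby(["group", "day"], sort=True)["volume"]
        .mean()
        .reset_index()
        .rename(columns={"volume": "mean_volume"})
    )
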