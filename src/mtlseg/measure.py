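"""Border-to-landmark and anterior-extent distance measurement.

This stage reproduces the measurement campaign behind the protocol: on a
fixed set of reference levels (10, 9, 7, 5, 4 and 2.5 mm anterior to the
hippocampus tip) plus each region's anterior-most slice, the signed
arc-length distance from every cytoarchitectonic border of interest to its
candidate landmarks is recorded, along with each region's anterior-extent
distance to every candidate anchor structure.

Sign convention: distances are ``s_border - s_landmark`` along the ribbon,
so positive means the border lies lateral of the landmark and negative
medial of it.  Distances are arc-length differences, not Euclidean chords,
consistent with the geometry module.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MtlsegError, PairingError
from .geometry import LANDMARK_NAMES, LandmarkSet, derive_landmarks
from .rules import REGIONS

DEFAULT_REFERENCE_LEVELS: tuple[float, ...] = (10.0, 9.0, 7.0, 5.0, 4.0, 2.5)

ANCHOR_NAMES: tuple[str, ...] = (
    "hippocampus",
    "amygdala",
    "temporal_pole",
    "limen_insulae",
    "collateral_sulcus",
)

#: Which landmark(s) each border is measured against, and at which levels.
#: ``"first"`` denotes the region's anterior-most slice.  Mirrors the
#: published measurement tables.
MEASUREMENT_TEMPLATE: tuple[tuple[str, str, str, tuple[object, ...]], ...] = (
    ("ERC", "medial", "phg_superior_edge", (5.0, "first", 4.0, 2.5)),
    ("ERC", "medial", "phg_crown_midpoint", (5.0, "first")),
    ("ERC", "lateral", "cs_medial_edge", (5.0, "first", 4.0, 2.5)),
    ("BA35", "medial", "phg_superior_edge", (9.0, "first", 7.0, 5.0)),
    ("BA35", "lateral", "cs_fundus", (9.0, "first", 7.0, 5.0, 4.0, 2.5)),
    ("BA36", "medial", "medial_bank_half", (10.0, "first")),
    ("BA36", "lateral", "cs_fundus", (10.0, "first")),
    ("BA36", "lateral", "lateral_bank_quarter", (10.0, "first")),
)


@dataclass(frozen=True)
class DistanceRecord:
    """One signed border-to-landmark distance observation."""

    case_id: str
    slice_level: str
    slice_distance_mm: float
    region: str
    side: str
    segment: str
    landmark: str
    distance_mm: float

    def __post_init__(self) -> None:
        if self.landmark not in LANDMARK_NAMES:
            raise MtlsegError(f"unknown landmark: {self.landmark}")
        if not np.isfinite(self.distance_mm):
            raise MtlsegError("distance must be finite")


@dataclass(frozen=True)
class ExtentRecord:
    """One region-to-anchor anterior-extent distance."""

    case_id: str
    region: str
    anchor: str
    distance_mm: float

    def __post_init__(self) -> None:
        if self.anchor not in ANCHOR_NAMES:
            raise MtlsegError(f"unknown anchor: {self.anchor}")
        if not np.isfinite(self.distance_mm):
            raise MtlsegError("distance must be finite")


# ---------------------------------------------------------------------------
# elementary measurements
# ---------------------------------------------------------------------------

def signed_border_distance(
    border_s: float,
    landmark_s: float,
    border_slice_mm: float | None = None,
    landmark_slice_mm: float | None = None,
) -> float:
    """Signed arc-length distance border minus landmark (positive=lateral).

    When both slice distances are given they must match: a border can only
    be compared to a landmark of its own slice.
    """
    if (
        border_slice_mm is not None
        and landmark_slice_mm is not None
        and abs(border_slice_mm - landmark_slice_mm) > 1e-6
    ):
        raise PairingError(
            f"border (slice {border_slice_mm:g}) and landmark "
            f"(slice {landmark_slice_mm:g}) are on different slices"
        )
    return float(border_s - landmark_s)


def anterior_extent_distance(case, region: str, anchor: str) -> float:
    """Signed axial distance from a region's anterior extent to an anchor.

    The hippocampus tip is the axis origin, so the hippocampus-relative
    distance is the extent itself.  The reporting convention per anchor
    (region-minus-anchor vs anchor-minus-region) follows the case's anchor
    specification when available.
    """
    if region not in case.extents:
        raise MtlsegError(f"region {region} absent from case {case.case_id}")
    extent = case.extents[region]
    pos = case.anchors[anchor]
    return float(extent - pos)


# ---------------------------------------------------------------------------
# cohort-level measurement
# ---------------------------------------------------------------------------

def _nearest_slice(grid: Sequence[float], level: float) -> float:
    """Grid slice nearest a reference level; equidistant ties go posterior."""
    return min(grid, key=lambda d: (round(abs(d - level), 9), d))


def _pick_border(borders: pd.DataFrame, region: str, side: str) -> float | None:
    """Select the border observation for a (region, side) on one slice.

    For the BA35 medial border the flank segment takes precedence: where
    the ERC is wrapped by two BA35 segments, the medial-most BA35 border is
    the one measured.  Borders that coincide with the neighbouring region's
    border (BA35 medial where the ERC is present but unflanked, BA36 medial
    where BA35 is present) are not independently measurable and yield None,
    mirroring the N/A cells of the published measurement tables.
    """
    sel = borders[(borders["region"] == region) & (borders["side"] == side)]
    if sel.empty:
        return None
    if region == "BA35" and side == "medial":
        flank = sel[sel["segment"] == "medial_flank"]
        if not flank.empty:
            return float(flank["s"].iloc[0])
        if (borders["region"] == "ERC").any():
            return None
    if region == "BA36" and side == "medial":
        if (borders["region"] == "BA35").any():
            return None
    prim = sel[sel["segment"] == "primary"]
    return float(prim["s"].iloc[0]) if not prim.empty else float(sel["s"].iloc[0])


def distance_records(
    cohort,
    reference_levels: Sequence[float] = DEFAULT_REFERENCE_LEVELS,
) -> pd.DataFrame:
    """Measure all template distances across a cohort.

    Returns one row per (case, level, border, landmark) with ``present``
    False (and NaN distance) where a region has no border on the measured
    slice — the absence records that make per-level n vary across cells.
    """
    if not cohort.cases:
        raise MtlsegError("empty cohort")
    rows: list[dict] = []
    for case in cohort.cases:
        stack = cohort.slice_stack(case.case_id)
        grid = [c.slice_distance_mm for c in stack]
        by_d = {c.slice_distance_mm: c for c in stack}
        borders = cohort.truth_borders(case.case_id)
        landmark_cache: dict[float, LandmarkSet] = {}

        def landmarks_at(d: float) -> LandmarkSet:
            if d not in landmark_cache:
                landmark_cache[d] = derive_landmarks(by_d[d])
            return landmark_cache[d]

        levels: list[tuple[str, float | None]] = []
        for lv in reference_levels:
            levels.append((f"{lv:g}", _nearest_slice(grid, lv)))
        for region in REGIONS:
            present_d = borders.loc[
                borders["region"] == region, "slice_distance_mm"
            ]
            first_d = float(present_d.max()) if len(present_d) else None
            levels.append((f"first_slice_of_{region}", first_d))

        for level_name, d in levels:
            for region, side, landmark, cells in MEASUREMENT_TEMPLATE:
                cell_names = {
                    ("first" if c == "first" else f"{float(c):g}") for c in cells
                }
                wanted = level_name in cell_names or (
                    level_name == f"first_slice_of_{region}"
                    and "first" in cell_names
                )
                if not wanted:
                    continue
                if d is None:
                    rows.append(
                        dict(
                            case_id=case.case_id,
                            slice_level=level_name,
                            slice_distance_mm=np.nan,
                            region=region,
                            side=side,
                            segment="",
                            landmark=landmark,
                            distance_mm=np.nan,
                            present=False,
                        )
                    )
                    continue
                slice_borders = borders[
                    np.isclose(borders["slice_distance_mm"], d)
                ]
                s_border = _pick_border(slice_borders, region, side)
                if s_border is None:
                    rows.append(
                        dict(
                            case_id=case.case_id,
                            slice_level=level_name,
                            slice_distance_mm=d,
                            region=region,
                            side=side,
                            segment="",
                            landmark=landmark,
                            distance_mm=np.nan,
                            present=False,
                        )
                    )
                    continue
                seg = (
                    "medial_flank"
                    if (
                        region == "BA35"
                        and side == "medial"
                        and (
                            slice_borders.query(
                                "region=='BA35' and side=='medial' "
                                "and segment=='medial_flank'"
                            ).shape[0]
                            > 0
                        )
                    )
                    else "primary"
                )
                lms = landmarks_at(d)
                rows.append(
                    dict(
                        case_id=case.case_id,
                        slice_level=level_name,
                        slice_distance_mm=d,
                        region=region,
                        side=side,
                        segment=seg,
                        landmark=landmark,
                        distance_mm=signed_border_distance(
                            s_border, lms.position(landmark)
                        ),
                        present=True,
                    )
                )
    return pd.DataFrame(rows)


def extent_records(cohort) -> pd.DataFrame:
    """Anterior-extent distances of every region to every anchor.

    The distance is the exact axial extent difference, signed per the
    cohort's per-anchor reporting convention.
    """
    if not cohort.cases:
        raise MtlsegError("empty cohort")
    rows = []
    for case in cohort.cases:
        for region in REGIONS:
            for anchor in case.anchors:
                dist = anterior_extent_distance(case, region, anchor)
                spec = cohort.config.anchors.get(anchor)
                if spec is not None and spec.sign == "anchor_minus_region":
                    dist = -dist
                rows.append(
                    dict(
                        case_id=case.case_id,
                        region=region,
                        anchor=anchor,
                        distance_mm=dist,
                        present=True,
                    )
                )
    return pd.DataFrame(rows)


def measure_cohort(
    cohort,
    reference_levels: Sequence[float] = DEFAULT_REFERENCE_LEVELS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full measurement stage: (distance records, extent records)."""
    return distance_records(cohort, reference_levels), extent_records(cohort)
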