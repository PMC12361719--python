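"""Deterministic rule engine: apply a rule table to landmark-annotated slices.

Given the landmarks of a coronal slice and the machine-readable protocol,
the engine resolves every border to an arc-length position and assembles the
slice into an ordered, gap-free partition of labeled intervals:
``[BA35 flank?][ERC][BA35][BA36]`` where present.  Adjacent labels share
border positions exactly.

Rule dispatch generalizes the printed six-level grid to arbitrary slice
grids: cells that encode an *anterior-most-slice* behaviour (the ERC medial
border at the PHG crown midpoint, the BA36 bank-based borders, the BA35
medial flank) are applied on the first (or, for the BA36 lateral transition,
second) slice on which the region is labeled, and the remaining cells are
selected by nearest reference level.  Wherever a medial neighbour is present
the shared border is taken from that neighbour (BA35 medial = ERC lateral,
BA36 medial = BA35 lateral), which makes the partition invariant structural
rather than numerical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSliceError,
    SegmentationRangeError,
    StackGapError,
)
from .geometry import LandmarkSet, SliceContour, derive_landmarks
from .rules import REGIONS, BorderRule, RuleTable

logger = logging.getLogger(__name__)

#: Stable integer codes and ITK-SNAP colours for exported label rasters.
LABEL_CODES: dict[str, int] = {"ERC": 1, "BA35": 2, "BA36": 3}
LABEL_COLORS: dict[str, tuple[int, int, int]] = {
    "ERC": (0, 128, 0),       # green
    "BA35": (102, 178, 255),  # light blue
    "BA36": (0, 0, 153),      # dark blue
}


@dataclass(frozen=True)
class LabeledInterval:
    label: str
    segment: str
    s_start: float
    s_end: float

    def length(self) -> float:
        return self.s_end - self.s_start


@dataclass
class LabelMap:
    """Ordered labeled arc-length intervals per slice for one case."""

    case_id: str
    slices: dict[float, list[LabeledInterval]] = field(default_factory=dict)

    def labels(self) -> list[str]:
        return sorted(
            {iv.label for ivs in self.slices.values() for iv in ivs},
            key=lambda l: LABEL_CODES.get(l, 99),
        )

    def intervals(self, label: str) -> dict[float, list[tuple[float, float]]]:
        out: dict[float, list[tuple[float, float]]] = {}
        for d, ivs in self.slices.items():
            sel = [(iv.s_start, iv.s_end) for iv in ivs if iv.label == label]
            if sel:
                out[d] = sel
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "case_id": self.case_id,
                "slice_distance_mm": d,
                "label": iv.label,
                "segment": iv.segment,
                "s_start_mm": iv.s_start,
                "s_end_mm": iv.s_end,
            }
            for d in sorted(self.slices)
            for iv in self.slices[d]
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "case_id",
                "slice_distance_mm",
                "label",
                "segment",
                "s_start_mm",
                "s_end_mm",
            ],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> dict[str, "LabelMap"]:
        maps: dict[str, LabelMap] = {}
        for (cid, d), grp in frame.groupby(["case_id", "slice_distance_mm"]):
            lm = maps.setdefault(str(cid), cls(case_id=str(cid)))
            lm.slices[float(d)] = [
                LabeledInterval(
                    r["label"], r["segment"], float(r["s_start_mm"]), float(r["s_end_mm"])
                )
                for _, r in grp.sort_values("s_start_mm").iterrows()
            ]
        return maps


# ---------------------------------------------------------------------------
# rule dispatch
# ---------------------------------------------------------------------------

def slice_rule_level(slice_distance_mm: float, rule_table: RuleTable) -> float:
    """Nearest reference level for a slice; equidistant ties resolve to the
    posterior (smaller) level."""
    d = slice_distance_mm
    max_start = max(rule_table.region_starts.values())
    lo = rule_table.posterior_bound_mm - 0.5 * rule_table.slice_thickness_mm
    hi = max_start + 0.5 * rule_table.slice_thickness_mm
    if d < lo - 1e-9 or d > hi + 1e-9:
        raise SegmentationRangeError(
            f"slice {d:g} mm outside protocol range [{lo:g}, {hi:g}]"
        )
    best = None
    for lv in rule_table.levels:
        dist = abs(d - lv)
        if best is None or dist < best[0] - 1e-9 or (
            abs(dist - best[0]) <= 1e-9 and lv < best[1]
        ):
            best = (dist, lv)
    return best[1]  # type: ignore[index]


def _nearest_cell_level(
    rule_table: RuleTable,
    region: str,
    side: str,
    d: float,
    exclude: Iterable[float] = (),
    kinds: tuple[str, ...] = ("landmark", "offset", "region_ref"),
) -> float:
    usable = [
        lv
        for lv in rule_table.levels_for(region, side)
        if rule_table.cell(lv, region, side).kind in kinds
    ]
    levels = [lv for lv in usable if lv not in set(exclude)] or usable
    # nearest, ties posterior
    return min(levels, key=lambda lv: (round(abs(d - lv), 9), lv))


def _resolve(rule: BorderRule, landmarks: LandmarkSet) -> float:
    s = landmarks.position(rule.landmark)
    if rule.kind == "offset":
        step = rule.offset_mm if rule.direction == "lateral" else -rule.offset_mm
        s = s + step
    if s < 0.0 or s > landmarks.s_total:
        logger.warning(
            "border at s=%.2f clamped to contour domain [0, %.2f] "
            "(slice %.2f mm)", s, landmarks.s_total, landmarks.slice_distance_mm
        )
        s = min(max(s, 0.0), landmarks.s_total)
    return float(s)


def apply_rules_slice(
    landmarks: LandmarkSet,
    slice_distance_mm: float,
    rule_table: RuleTable,
    region_presence: Mapping[str, bool],
    slice_ordinals: Mapping[str, int] | None = None,
) -> list[LabeledInterval]:
    """Resolve one slice into its ordered labeled intervals.

    ``region_presence`` states which regions are labeled on this slice;
    ``slice_ordinals`` gives each present region's slice ordinal (1 = its
    anterior-most labeled slice, 2 = next, ...).  When omitted, ordinals are
    inferred from the rule-table starts and slice thickness.
    """
    d = slice_distance_mm
    th = rule_table.slice_thickness_mm
    present = {r: bool(region_presence.get(r, False)) for r in REGIONS}
    if not any(present.values()):
        return []

    if slice_ordinals is None:
        slice_ordinals = {
            r: 1 + int(np.floor((rule_table.start(r) - d) / th + 1e-6))
            for r in REGIONS
            if present[r]
        }

    def ordinal(region: str) -> int:
        return int(slice_ordinals.get(region, 99))

    def anterior_level(region: str, side: str) -> float:
        return rule_table.levels_for(region, side)[0]

    intervals: list[LabeledInterval] = []

    # --- ERC ---------------------------------------------------------------
    erc_medial = erc_lateral = None
    if present["ERC"]:
        lv_ant = anterior_level("ERC", "medial")
        if ordinal("ERC") == 1:
            med_rule = rule_table.cell(lv_ant, "ERC", "medial")
        else:
            lv = _nearest_cell_level(rule_table, "ERC", "medial", d, exclude=[lv_ant])
            med_rule = rule_table.cell(lv, "ERC", "medial")
        lat_lv = _nearest_cell_level(rule_table, "ERC", "lateral", d)
        lat_rule = rule_table.cell(lat_lv, "ERC", "lateral")
        erc_medial = _resolve(med_rule, landmarks)
        erc_lateral = _resolve(lat_rule, landmarks)

        # medial flank of BA35 wraps the ERC on its anterior-most slice
        if present["BA35"] and ordinal("ERC") == 1:
            flank_rule = rule_table.cell(lv_ant, "BA35", "medial", "medial_flank")
            if flank_rule is not None:
                flank_s = _resolve(flank_rule, landmarks)
                intervals.append(
                    LabeledInterval("BA35", "medial_flank", flank_s, erc_medial)
                )
        intervals.append(LabeledInterval("ERC", "primary", erc_medial, erc_lateral))

    # --- BA35 --------------------------------------------------------------
    ba35_lateral = None
    if present["BA35"]:
        if erc_lateral is not None:
            ba35_medial = erc_lateral
        else:
            # without an ERC the medial border follows the level-wise offset
            # track; where the primary cell defers to the (absent) ERC, the
            # flank cell of that level carries the offset
            cand: list[tuple[float, BorderRule]] = []
            for lv in rule_table.levels:
                cell = rule_table.cell(lv, "BA35", "medial")
                if cell is not None and cell.kind != "region_ref":
                    cand.append((lv, cell))
                else:
                    flank = rule_table.cell(lv, "BA35", "medial", "medial_flank")
                    if flank is not None:
                        cand.append((lv, flank))
            if ordinal("BA35") == 1 or len(cand) == 1:
                rule = cand[0][1]
            else:
                rule = min(
                    cand[1:], key=lambda c: (round(abs(d - c[0]), 9), c[0])
                )[1]
            ba35_medial = _resolve(rule, landmarks)
        lat_lv = _nearest_cell_level(rule_table, "BA35", "lateral", d)
        ba35_lateral = _resolve(rule_table.cell(lat_lv, "BA35", "lateral"), landmarks)
        intervals.append(
            LabeledInterval("BA35", "primary", ba35_medial, ba35_lateral)
        )

    # --- BA36 --------------------------------------------------------------
    if present["BA36"]:
        lv_first = anterior_level("BA36", "medial")
        if ba35_lateral is not None:
            ba36_medial = ba35_lateral
        else:
            ba36_medial = _resolve(
                rule_table.cell(lv_first, "BA36", "medial"), landmarks
            )
        lat_levels = rule_table.levels_for("BA36", "lateral")
        if ordinal("BA36") == 1:
            lv = lat_levels[0]
        elif ordinal("BA36") == 2 and len(lat_levels) > 1:
            lv = lat_levels[1]
        else:
            lv = _nearest_cell_level(
                rule_table, "BA36", "lateral", d, exclude=lat_levels[:2]
            )
        ba36_lateral = _resolve(rule_table.cell(lv, "BA36", "lateral"), landmarks)
        intervals.append(
            LabeledInterval("BA36", "primary", ba36_medial, ba36_lateral)
        )

    for iv in intervals:
        if iv.s_start >= iv.s_end - 1e-12:
            raise DegenerateSliceError(
                f"inverted interval for {iv.label}/{iv.segment} on slice "
                f"{d:g} mm: [{iv.s_start:.3f}, {iv.s_end:.3f}]"
            )
    return intervals


def segment_case(
    stack: Sequence[SliceContour],
    rule_table: RuleTable,
    landmarks: Mapping[float, LandmarkSet] | None = None,
    posterior_bound_mm: float | None = None,
) -> LabelMap:
    """Apply the protocol to a slice stack, producing a label map.

    Every slice from the posterior bound to each region's start is labeled;
    the stack must contain all grid slices in that range (missing slices
    raise :class:`StackGapError` listing the gaps).  ``landmarks`` may
    override the contour-derived landmark sets (used by the reliability
    perturbation experiment); the engine itself is deterministic.
    """
    if not stack:
        raise StackGapError("empty slice stack")
    th = rule_table.slice_thickness_mm
    bound = (
        rule_table.posterior_bound_mm
        if posterior_bound_mm is None
        else posterior_bound_mm
    )
    max_start = max(rule_table.region_starts.values())
    by_d = {round(c.slice_distance_mm, 6): c for c in stack}
    case_id = stack[0].case_id

    k_lo = int(np.ceil(bound / th - 1e-6))
    k_hi = int(np.floor(max_start / th + 1e-6))
    grid = [round(k * th, 6) for k in range(k_lo, k_hi + 1)]
    missing = [d for d in grid if d not in by_d]
    if missing:
        raise StackGapError(
            "stack missing protocol slices at distances: "
            + ", ".join(f"{d:g}" for d in missing)
        )

    first_slice = {
        r: max((d for d in grid if d <= rule_table.start(r) + 1e-9), default=None)
        for r in REGIONS
    }
    labelmap = LabelMap(case_id=case_id)
    for d in grid:
        present = {r: d <= rule_table.start(r) + 1e-9 for r in REGIONS}
        ordinals = {
            r: 1 + int(round((first_slice[r] - d) / th))
            for r in REGIONS
            if present[r] and first_slice[r] is not None
        }
        lms = (
            landmarks[d]
            if landmarks is not None and d in landmarks
            else derive_landmarks(by_d[d])
        )
        ivs = apply_rules_slice(lms, d, rule_table, present, ordinals)
        if ivs:
            labelmap.slices[d] = ivs
    return labelmap


# ---------------------------------------------------------------------------
# rasterization and export
# ---------------------------------------------------------------------------

def rasterize_labels(
    labelmap: LabelMap,
    stack: Sequence[SliceContour],
    resolution_mm: float = 0.5,
    ribbon_thickness_mm: float = 1.0,
    margin_mm: float = 2.0,
) -> tuple[np.ndarray, dict]:
    """Paint labeled arc-length intervals as ribbon bands on a voxel grid.

    Each interval becomes a band of the stated thickness centered on its
    piece of contour (flat end caps, so a straight L mm interval covers an
    area of L x thickness).  Voxels are assigned first-come in medial-to-
    lateral interval order, so adjacent intervals never double-label.
    Returns ``(volume, meta)`` with ``volume[k, iy, ix]`` indexed by slice,
    y, x and ``meta`` carrying origin, resolution and label codes.
    """
    import shapely
    from shapely.geometry import LineString
    from shapely.ops import substring

    if resolution_mm <= 0:
        raise ValueError("resolution must be positive")
    if resolution_mm > ribbon_thickness_mm:
        logger.warning(
            "raster resolution %.2f mm coarser than ribbon thickness %.2f mm",
            resolution_mm,
            ribbon_thickness_mm,
        )
    by_d = {round(c.slice_distance_mm, 6): c for c in stack}
    ds = sorted(labelmap.slices)
    pts = np.concatenate(
        [by_d[d].points for d in ds if d in by_d]
        or [np.zeros((1, 2))]
    )
    lo = pts.min(axis=0) - margin_mm
    hi = pts.max(axis=0) + margin_mm
    nx = int(np.ceil((hi[0] - lo[0]) / resolution_mm))
    ny = int(np.ceil((hi[1] - lo[1]) / resolution_mm))
    xs = lo[0] + (np.arange(nx) + 0.5) * resolution_mm
    ys = lo[1] + (np.arange(ny) + 0.5) * resolution_mm
    gx, gy = np.meshgrid(xs, ys)  # gy rows, gx cols

    volume = np.zeros((len(ds), ny, nx), dtype=np.int16)
    for k, d in enumerate(ds):
        if d not in by_d:
            raise StackGapError(f"label map slice {d:g} missing from stack")
        line = LineString(by_d[d].points)
        for iv in labelmap.slices[d]:
            piece = substring(line, iv.s_start, iv.s_end)
            band = piece.buffer(
                0.5 * ribbon_thickness_mm, cap_style="flat", join_style="round"
            )
            inside = shapely.contains_xy(band, gx.ravel(), gy.ravel()).reshape(
                ny, nx
            )
            mask = inside & (volume[k] == 0)
            volume[k][mask] = LABEL_CODES[iv.label]
    meta = {
        "origin_mm": (float(lo[0]), float(lo[1])),
        "resolution_mm": resolution_mm,
        "ribbon_thickness_mm": ribbon_thickness_mm,
        "slice_distances_mm": ds,
        "label_codes": dict(LABEL_CODES),
    }
    return volume, meta


def save_labelmap_nifti(
    path: str | Path, volume: np.ndarray, meta: Mapping[str, object],
    slice_thickness_mm: float = 1.3,
) -> None:
    """Export a rasterized label volume as NIfTI (x, y, slice axis order)."""
    import nibabel as nib

    res = float(meta["resolution_mm"])  # type: ignore[arg-type]
    data = np.transpose(volume, (2, 1, 0)).astype(np.int16)
    affine = np.diag([res, res, slice_thickness_mm, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def write_itk_snap_labels(path: str | Path) -> None:
    """Write an ITK-SNAP label description file for the exported codes."""
    lines = [
        "################################################",
        "# ITK-SnAP Label Description File",
        "# Fields: IDX -R- -G- -B- -A-- VIS MSH LABEL",
        "################################################",
        '    0     0    0    0        0  0  0    "Clear Label"',
    ]
    for label, code in sorted(LABEL_CODES.items(), key=lambda kv: kv[1]):
        r, g, b = LABEL_COLORS[label]
        lines.append(
            f'    {code}   {r:3d}  {g:3d}  {b:3d}        1  1  1    "{label}"'
        )
    Path(path).write_text("\n".join(lines) + "\n")
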