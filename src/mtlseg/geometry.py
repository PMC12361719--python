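"""Coronal slice contours, arc-length parameterization, and protocol landmarks.

A coronal section through the anterior medial temporal lobe is represented as
an open polyline running along the pial surface in a canonical medial-to-right
order: from the medial terminus of the parahippocampal gyrus (PHG), over the
PHG crown, down the medial bank of the collateral sulcus (CS) to its fundus,
up the lateral bank, and across the fusiform gyrus (FG) crown to the lateral
terminus.  All border rules of the segmentation protocol are expressed as
positions along this ribbon, so the fundamental coordinate is cumulative arc
length from the medial terminus (mm, increasing laterally).

Coordinate frame: right-handed coronal plane with the first coordinate
increasing laterally and the second increasing superiorly.  Left-hemisphere
contours are mirrored upstream (see :func:`canonicalize`) so that every
contour is processed in the same medial-to-lateral order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    MalformedContourError,
    MalformedSulcusError,
    MissingLandmarkError,
    OutOfDomainError,
)

#: Key vertices every tagged contour must carry, in medial-to-lateral order.
KEY_VERTEX_ORDER: tuple[str, ...] = (
    "medial_terminus",
    "phg_superior_edge",
    "cs_medial_mouth",
    "cs_fundus",
    "cs_lateral_mouth",
    "fg_crown_apex",
    "lateral_terminus",
)

#: Landmark vocabulary used by border rules, in medial-to-lateral order.
LANDMARK_NAMES: tuple[str, ...] = (
    "phg_superior_edge",
    "phg_crown_midpoint",
    "cs_medial_edge",
    "medial_bank_half",
    "cs_fundus",
    "lateral_bank_quarter",
    "fundus_fg_midpoint",
    "fg_crown_midpoint",
)

#: CS depth (mm) at and above which a sulcus counts as deep.  The dichotomy
#: is "shallow below 7 mm", so exactly 7.0 classifies as deep.
CS_DEPTH_THRESHOLD_MM: float = 7.0


@dataclass
class SliceContour:
    """A tagged pial-surface polyline on one coronal slice.

    Parameters
    ----------
    case_id : str
        Identifier of the case the slice belongs to.
    slice_distance_mm : float
        Distance anterior to the anterior tip of the hippocampus
        (positive = anterior).
    points : (n, 2) array_like
        Ordered vertices (mm); first coordinate lateral, second superior.
    key_vertices : mapping
        Key-vertex name -> vertex index, covering :data:`KEY_VERTEX_ORDER`.
    """

    case_id: str
    slice_distance_mm: float
    points: np.ndarray
    key_vertices: dict[str, int]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        pts = self.points
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise MalformedContourError("points must be an (n, 2) array")
        if len(pts) < 8:
            raise MalformedContourError(
                f"contour needs >= 8 vertices, got {len(pts)}"
            )
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg <= 0.0):
            idx = int(np.flatnonzero(seg <= 0.0)[0])
            raise MalformedContourError(
                f"duplicate consecutive vertices at index {idx}"
            )
        missing = [k for k in KEY_VERTEX_ORDER if k not in self.key_vertices]
        if missing:
            raise MissingLandmarkError(f"missing key vertex: {missing[0]}")
        idxs = [int(self.key_vertices[k]) for k in KEY_VERTEX_ORDER]
        if any(i < 0 or i >= len(pts) for i in idxs):
            raise MalformedContourError("key-vertex index out of range")
        if any(b <= a for a, b in zip(idxs, idxs[1:])):
            raise MalformedContourError(
                "key-vertex indices must strictly increase medial to lateral"
            )
        fundus = pts[self.key_vertices["cs_fundus"]]
        m_mouth = pts[self.key_vertices["cs_medial_mouth"]]
        l_mouth = pts[self.key_vertices["cs_lateral_mouth"]]
        if fundus[1] >= m_mouth[1] or fundus[1] >= l_mouth[1]:
            raise MalformedSulcusError(
                "cs_fundus must lie inferior to both CS mouth vertices"
            )

    # -- convenience --------------------------------------------------------
    def key_point(self, name: str) -> np.ndarray:
        try:
            return self.points[self.key_vertices[name]]
        except KeyError as exc:
            raise MissingLandmarkError(f"missing key vertex: {name}") from exc

    def key_arclength(self, name: str) -> float:
        return float(arc_length_positions(self)[self.key_vertices[name]])


@dataclass
class LandmarkSet:
    """Arc-length positions of all protocol landmarks on one slice.

    Positions are mm of arc from the medial terminus, increasing laterally,
    and are weakly increasing in the order of :data:`LANDMARK_NAMES`.
    ``s_total`` is the total contour arc length and bounds every position.
    """

    s_phg_superior_edge: float
    s_phg_crown_midpoint: float
    s_cs_medial_edge: float
    s_medial_bank_half: float
    s_cs_fundus: float
    s_lateral_bank_quarter: float
    s_fundus_fg_midpoint: float
    s_fg_crown_midpoint: float
    cs_depth_mm: float
    slice_distance_mm: float
    s_total: float

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        vals = [self.position(name) for name in LANDMARK_NAMES]
        if any(b < a - 1e-9 for a, b in zip(vals, vals[1:])):
            raise MalformedContourError(
                "landmark positions must be weakly increasing medial->lateral"
            )
        if vals[0] < -1e-9 or vals[-1] > self.s_total + 1e-9:
            raise OutOfDomainError("landmark position outside contour domain")
        if self.cs_depth_mm < 0:
            raise OutOfDomainError("cs_depth_mm must be non-negative")

    def position(self, landmark: str) -> float:
        """Arc-length position of a landmark by vocabulary name."""
        try:
            return float(getattr(self, f"s_{landmark}"))
        except AttributeError as exc:
            raise MissingLandmarkError(f"unknown landmark: {landmark}") from exc

    def as_dict(self) -> dict[str, float]:
        return {name: self.position(name) for name in LANDMARK_NAMES}


# ---------------------------------------------------------------------------
# arc-length operations
# ---------------------------------------------------------------------------

def arc_length_positions(contour: SliceContour) -> np.ndarray:
    """Cumulative arc length (mm) at each vertex, starting at 0."""
    seg = np.linalg.norm(np.diff(contour.points, axis=0), axis=1)
    if np.any(seg <= 0.0):
        raise MalformedContourError("duplicate consecutive vertices")
    return np.concatenate(([0.0], np.cumsum(seg)))


def total_arc_length(contour: SliceContour) -> float:
    return float(arc_length_positions(contour)[-1])


def point_at_arclength(contour: SliceContour, s: float) -> np.ndarray:
    """Coordinate of the point a given arc length along the contour.

    Linear interpolation along the polyline; ``s`` at a vertex returns that
    vertex exactly.  Raises :class:`OutOfDomainError` outside [0, total].
    """
    cum = arc_length_positions(contour)
    total = cum[-1]
    if s < -1e-9 or s > total + 1e-9:
        raise OutOfDomainError(
            f"arc length {s} outside [0, {total:.6f}]"
        )
    s = min(max(s, 0.0), total)
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(cum) - 2)
    t = (s - cum[i]) / (cum[i + 1] - cum[i])
    return (1.0 - t) * contour.points[i] + t * contour.points[i + 1]


def cs_depth(contour: SliceContour) -> float:
    """Depth of the collateral sulcus (mm).

    Euclidean distance from the fundus vertex to the midpoint of the chord
    joining the two sulcal mouth vertices.
    """
    fundus = contour.key_point("cs_fundus")
    m = contour.key_point("cs_medial_mouth")
    l = contour.key_point("cs_lateral_mouth")
    if fundus[1] >= m[1] and fundus[1] >= l[1]:
        raise MalformedSulcusError("fundus lies superior to both CS mouths")
    chord_mid = 0.5 * (m + l)
    return float(np.linalg.norm(fundus - chord_mid))


def classify_cs_depth(depth_mm: float) -> str:
    """Dichotomize a CS depth: ``"shallow"`` below 7 mm, else ``"deep"``."""
    if depth_mm < 0:
        raise OutOfDomainError("CS depth must be non-negative")
    return "shallow" if depth_mm < CS_DEPTH_THRESHOLD_MM else "deep"


def derive_landmarks(contour: SliceContour) -> LandmarkSet:
    """Compute all protocol landmarks of one slice from its tagged contour.

    Bank and crown fractions are measured by arc length along the pial
    ribbon (not by Euclidean chord): the PHG crown midpoint is the arc
    midpoint between the superior PHG edge and the medial CS mouth; the
    halfway point of the medial bank is the arc midpoint between the medial
    mouth and the fundus; the quarter point of the lateral bank sits a
    quarter of the bank's arc above the fundus; the FG crown midpoint is the
    arc midpoint between the lateral mouth and the lateral terminus; and the
    fundus-FG midpoint is the arc midpoint between the fundus and the FG
    crown midpoint.
    """
    cum = arc_length_positions(contour)

    def s_of(key: str) -> float:
        if key not in contour.key_vertices:
            raise MissingLandmarkError(f"missing key vertex: {key}")
        return float(cum[contour.key_vertices[key]])

    s_sup = s_of("phg_superior_edge")
    s_m_mouth = s_of("cs_medial_mouth")
    s_fundus = s_of("cs_fundus")
    s_l_mouth = s_of("cs_lateral_mouth")
    s_lat_term = s_of("lateral_terminus")

    s_fg_crown = 0.5 * (s_l_mouth + s_lat_term)
    return LandmarkSet(
        s_phg_superior_edge=s_sup,
        s_phg_crown_midpoint=0.5 * (s_sup + s_m_mouth),
        s_cs_medial_edge=s_m_mouth,
        s_medial_bank_half=0.5 * (s_m_mouth + s_fundus),
        s_cs_fundus=s_fundus,
        s_lateral_bank_quarter=s_fundus + 0.25 * (s_l_mouth - s_fundus),
        s_fundus_fg_midpoint=0.5 * (s_fundus + s_fg_crown),
        s_fg_crown_midpoint=s_fg_crown,
        cs_depth_mm=cs_depth(contour),
        slice_distance_mm=contour.slice_distance_mm,
        s_total=float(cum[-1]),
    )


# ---------------------------------------------------------------------------
# canonical orientation
# ---------------------------------------------------------------------------

def mirror(contour: SliceContour) -> SliceContour:
    """Mirror a contour across the sagittal plane (x -> -x), emulating the
    opposite hemisphere; the trace still runs medial first, but with x now
    decreasing laterally."""
    pts = contour.points.copy()
    pts[:, 0] *= -1.0
    return SliceContour(
        contour.case_id, contour.slice_distance_mm, pts,
        dict(contour.key_vertices),
    )


def canonicalize(contour: SliceContour) -> SliceContour:
    """Return a contour in the canonical frame (x increasing laterally).

    Opposite-hemisphere contours (lateral terminus at smaller x than the
    medial terminus) are mirrored back; canonical contours are returned
    unchanged.  Arc lengths, and hence all landmarks, are unaffected.
    """
    x_med = contour.key_point("medial_terminus")[0]
    x_lat = contour.key_point("lateral_terminus")[0]
    if x_lat >= x_med:
        return contour
    return mirror(contour)


# ---------------------------------------------------------------------------
# slice-stack file format (structured text, one JSON document per case)
# ---------------------------------------------------------------------------

_STACK_SCHEMA = "mtlseg-contours/1"


def write_contour_stack(
    path: str | Path,
    case_meta: Mapping[str, object],
    slices: Sequence[SliceContour],
) -> None:
    """Write one case's slice stack as a structured-text (JSON) document."""
    doc = {
        "schema": _STACK_SCHEMA,
        "case": dict(case_meta),
        "slices": [
            {
                "slice_distance_mm": c.slice_distance_mm,
                "points": np.asarray(c.points).tolist(),
                "key_vertices": {k: int(v) for k, v in c.key_vertices.items()},
            }
            for c in sorted(slices, key=lambda c: c.slice_distance_mm)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_contour_stack(
    path: str | Path,
) -> tuple[dict[str, object], list[SliceContour]]:
    """Read a slice-stack document, validating every contour invariant.

    The first violation is reported with the slice index within the file.
    """
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != _STACK_SCHEMA:
        raise MalformedContourError(
            f"unrecognized slice-stack schema in {path}"
        )
    meta = dict(doc["case"])
    case_id = str(meta.get("case_id", Path(path).stem))
    slices = []
    for i, sl in enumerate(doc["slices"]):
        try:
            slices.append(
                SliceContour(
                    case_id=case_id,
                    slice_distance_mm=float(sl["slice_distance_mm"]),
                    points=np.asarray(sl["points"], dtype=float),
                    key_vertices={
                        k: int(v) for k, v in sl["key_vertices"].items()
                    },
                )
            )
        except (MalformedContourError, MissingLandmarkError, KeyError) as exc:
            raise MalformedContourError(f"slice {i} of {path}: {exc}") from exc
    return meta, slices
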