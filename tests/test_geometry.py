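"""Contour arc-length parameterization, landmark derivation, CS depth."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mtlseg as m
from mtlseg.errors import (
    MalformedContourError,
    MalformedSulcusError,
    MissingLandmarkError,
    OutOfDomainError,
)

from conftest import make_simple_contour

SQRT37 = math.sqrt(37.0)
SQRT17 = math.sqrt(17.0)


# ---------------------------------------------------------------------------
# arc length
# ---------------------------------------------------------------------------

def test_arc_length_straight_and_right_angle(simple_contour):
    cum = m.arc_length_positions(simple_contour)
    assert cum[0] == 0.0
    assert cum[1] == pytest.approx(6.5)
    assert cum[2] == pytest.approx(13.0)
    assert cum[3] == pytest.approx(21.0)
    # brute-force per-segment oracle
    pts = simple_contour.points
    brute = [0.0]
    for a, b in zip(pts, pts[1:]):
        brute.append(brute[-1] + math.dist(a, b))
    assert np.allclose(cum, brute)
    assert np.all(np.diff(cum) > 0)


def test_arc_length_phantom_matches_brute_force(phantom_contour):
    cum = m.arc_length_positions(phantom_contour)
    pts = phantom_contour.points
    total = sum(math.dist(a, b) for a, b in zip(pts, pts[1:]))
    assert cum[-1] == pytest.approx(total, abs=1e-12)


def test_duplicate_vertices_rejected(simple_contour):
    pts = simple_contour.points.copy()
    pts[1] = pts[2]
    with pytest.raises(MalformedContourError):
        m.SliceContour("x", 5.2, pts, simple_contour.key_vertices)


def test_point_at_arclength_boundaries_and_interior(simple_contour):
    total = m.arc_length_positions(simple_contour)[-1]
    assert np.allclose(
        m.point_at_arclength(simple_contour, 0.0), simple_contour.points[0]
    )
    assert np.allclose(
        m.point_at_arclength(simple_contour, total), simple_contour.points[-1]
    )
    # midpoint of the straight 8 mm crown segment (s in [13, 21])
    assert np.allclose(m.point_at_arclength(simple_contour, 17.0), [4.0, 0.0])
    with pytest.raises(OutOfDomainError):
        m.point_at_arclength(simple_contour, total + 0.5)
    with pytest.raises(OutOfDomainError):
        m.point_at_arclength(simple_contour, -0.5)


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def test_landmarks_exact_on_straight_fixture(simple_contour):
    lm = m.derive_landmarks(simple_contour)
    assert lm.s_phg_superior_edge == pytest.approx(13.0)
    # straight 8 mm crown -> midpoint 4 mm lateral of the superior edge
    assert lm.s_phg_crown_midpoint == pytest.approx(17.0)
    assert lm.s_cs_medial_edge == pytest.approx(21.0)
    assert lm.s_medial_bank_half == pytest.approx(21.0 + SQRT37 / 2)
    assert lm.s_cs_fundus == pytest.approx(21.0 + SQRT37)
    assert lm.s_lateral_bank_quarter == pytest.approx(21.0 + 1.25 * SQRT37)
    fg_crown = 21.0 + 2 * SQRT37 + SQRT17
    assert lm.s_fg_crown_midpoint == pytest.approx(fg_crown)
    assert lm.s_fundus_fg_midpoint == pytest.approx(
        0.5 * (21.0 + SQRT37 + fg_crown)
    )
    assert lm.cs_depth_mm == pytest.approx(6.0)
    assert lm.s_total == pytest.approx(21.0 + 2 * SQRT37 + 2 * SQRT17)


def test_lateral_bank_quarter_on_straight_8mm_bank():
    # vertical 8 mm lateral bank: quarter point sits 2 mm of arc above fundus
    points = np.array(
        [
            [-13.0, 0.0],
            [-6.5, 0.0],
            [0.0, 0.0],
            [8.0, 0.0],
            [10.0, -6.0],
            [10.0, 2.0],
            [14.0, 3.0],
            [18.0, 2.0],
        ]
    )
    keys = dict(make_simple_contour().key_vertices)
    c = m.SliceContour("straightbank", 5.2, points, keys)
    lm = m.derive_landmarks(c)
    assert lm.s_lateral_bank_quarter - lm.s_cs_fundus == pytest.approx(2.0)


def test_landmarks_match_dense_resampling_oracle(phantom_contour):
    """Independent oracle: landmarks recomputed on a densely resampled
    polyline agree to 1e-6 mm."""
    lm = m.derive_landmarks(phantom_contour)
    pts = phantom_contour.points
    # resample each segment into ~1e-3 mm pieces (collinear insertions)
    dense = [pts[0]]
    for a, b in zip(pts, pts[1:]):
        n = max(2, int(math.dist(a, b) / 1e-3))
        for t in np.linspace(0, 1, n + 1)[1:]:
            dense.append((1 - t) * a + t * b)
    dense = np.array(dense)
    keyed = {}
    for name, idx in phantom_contour.key_vertices.items():
        target = pts[idx]
        keyed[name] = int(np.argmin(np.linalg.norm(dense - target, axis=1)))
    dc = m.SliceContour("dense", 5.2, dense, keyed)
    lm2 = m.derive_landmarks(dc)
    for name in m.geometry.LANDMARK_NAMES:
        assert lm2.position(name) == pytest.approx(lm.position(name), abs=1e-6)


def test_missing_key_vertex_named(simple_contour):
    keys = dict(simple_contour.key_vertices)
    del keys["cs_fundus"]
    with pytest.raises(MissingLandmarkError, match="cs_fundus"):
        m.SliceContour("x", 5.2, simple_contour.points, keys)


def test_landmarks_invariant_under_rigid_motion(phantom_contour):
    theta = 0.7
    R = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    moved = m.SliceContour(
        phantom_contour.case_id,
        phantom_contour.slice_distance_mm,
        phantom_contour.points @ R.T + np.array([12.3, -4.5]),
        phantom_contour.key_vertices,
    )
    a = m.derive_landmarks(phantom_contour)
    b = m.derive_landmarks(moved)
    for name in m.geometry.LANDMARK_NAMES:
        assert b.position(name) == pytest.approx(a.position(name), abs=1e-9)
    assert b.cs_depth_mm == pytest.approx(a.cs_depth_mm, abs=1e-9)


# ---------------------------------------------------------------------------
# CS depth
# ---------------------------------------------------------------------------

def test_cs_depth_vertical_drop():
    points = np.array(
        [
            [-13.0, 1.0],
            [-6.0, 1.0],
            [0.0, 1.0],
            [-2.0, 0.0],   # medial mouth
            [0.0, -5.0],   # fundus
            [2.0, 0.0],    # lateral mouth
            [6.0, 1.0],
            [10.0, 0.5],
        ]
    )
    keys = dict(make_simple_contour().key_vertices)
    c = m.SliceContour("depth", 0.0, points, keys)
    assert m.cs_depth(c) == pytest.approx(5.0)


def test_cs_depth_asymmetric_oracle(phantom_contour):
    fundus = phantom_contour.key_point("cs_fundus")
    mm = phantom_contour.key_point("cs_medial_mouth")
    lm_ = phantom_contour.key_point("cs_lateral_mouth")
    expected = math.dist(fundus, 0.5 * (mm + lm_))
    assert m.cs_depth(phantom_contour) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "depth,expected",
    [(6.9, "shallow"), (7.0, "deep"), (12.0, "deep"), (0.0, "shallow")],
)
def test_classify_cs_depth(depth, expected):
    assert m.classify_cs_depth(depth) == expected


def test_classify_negative_depth_rejected():
    with pytest.raises(OutOfDomainError):
        m.classify_cs_depth(-0.1)


# ---------------------------------------------------------------------------
# densification and mirroring
# ---------------------------------------------------------------------------

def test_collinear_densification_preserves_landmarks(simple_contour):
    lm = m.derive_landmarks(simple_contour)
    pts = simple_contour.points
    dense, keys = [pts[0]], {"medial_terminus": 0}
    inv = {v: k for k, v in simple_contour.key_vertices.items()}
    for i, (a, b) in enumerate(zip(pts, pts[1:])):
        for t in (0.25, 0.5, 0.75, 1.0):
            dense.append((1 - t) * a + t * b)
        if i + 1 in inv:
            keys[inv[i + 1]] = len(dense) - 1
    c2 = m.SliceContour("dense", 5.2, np.array(dense), keys)
    lm2 = m.derive_landmarks(c2)
    for name in m.geometry.LANDMARK_NAMES:
        assert lm2.position(name) == pytest.approx(lm.position(name), abs=1e-6)


def test_mirror_canonicalize_roundtrip(phantom_contour):
    mirrored = m.geometry.mirror(phantom_contour)
    back = m.geometry.canonicalize(mirrored)
    a = m.derive_landmarks(phantom_contour)
    b = m.derive_landmarks(back)
    for name in m.geometry.LANDMARK_NAMES:
        assert b.position(name) == pytest.approx(a.position(name), abs=1e-9)


@given(seed=st.integers(0, 10_000))
def test_generated_contours_satisfy_all_invariants(seed):
    """Every emitted phantom contour validates, and its landmark set is
    weakly ordered (property over generator seeds)."""
    cfg = m.CohortConfig(n_cases=1, seed=seed)
    coh = m.generate_cohort(cfg)
    case = coh.cases[0]
    grid = case.slice_grid(cfg.slice_thickness_mm)
    for d in (grid[0], grid[len(grid) // 2], grid[-1]):
        c = m.build_slice_contour(case, d)
        c.validate()  # raises on violation
        lm = m.derive_landmarks(c)
        vals = [lm.position(n) for n in m.geometry.LANDMARK_NAMES]
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))
        assert 0 <= vals[0] and vals[-1] <= lm.s_total + 1e-9


# ---------------------------------------------------------------------------
# stack file round trip
# ---------------------------------------------------------------------------

def test_contour_stack_roundtrip(tmp_path, zero_noise_cohort):
    case = zero_noise_cohort.cases[0]
    stack = zero_noise_cohort.slice_stack(case.case_id)
    path = tmp_path / "case.json"
    m.write_contour_stack(path, {"case_id": case.case_id}, stack)
    meta, loaded = m.read_contour_stack(path)
    assert meta["case_id"] == case.case_id
    assert len(loaded) == len(stack)
    for a, b in zip(stack, loaded):
        assert np.allclose(a.points, b.points)
        assert a.key_vertices == b.key_vertices


def test_stack_reader_reports_first_bad_slice(tmp_path, simple_contour):
    import json

    doc = {
        "schema": "mtlseg-contours/1",
        "case": {"case_id": "bad"},
        "slices": [
            {
                "slice_distance_mm": 2.6,
                "points": simple_contour.points.tolist()[:5],  # too few
                "key_vertices": simple_contour.key_vertices,
            }
        ],
    }
    p = tmp_path / "bad.json"
    p.write_text(json.dumps(doc))
    with pytest.raises(MalformedContourError, match="slice 0"):
        m.read_contour_stack(p)
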