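"""Rule engine: level dispatch, golden protocol columns, partition
invariants, rasterization and exports."""

import numpy as np
import pytest

import mtlseg as m
from mtlseg.engine import LABEL_CODES
from mtlseg.errors import (
    DegenerateSliceError,
    SegmentationRangeError,
    StackGapError,
)


# ---------------------------------------------------------------------------
# level dispatch
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "d,expected", [(9.1, 9.0), (7.8, 7.0), (10.4, 10.0), (2.6, 2.5), (5.2, 5.0)]
)
def test_nearest_level(d, expected, reference_rules):
    assert m.slice_rule_level(d, reference_rules) == expected


def test_equidistant_tie_resolves_posterior(reference_rules):
    # 3.25 mm is equidistant from the 4 and 2.5 mm levels
    assert m.slice_rule_level(3.25, reference_rules) == 2.5


def test_out_of_range_slice_rejected(reference_rules):
    with pytest.raises(SegmentationRangeError):
        m.slice_rule_level(14.0, reference_rules)
    with pytest.raises(SegmentationRangeError):
        m.slice_rule_level(0.5, reference_rules)


# ---------------------------------------------------------------------------
# golden protocol columns
# ---------------------------------------------------------------------------

def _golden_expected(lm, column):
    """Hand-derived intervals for each protocol column, straight from the
    landmark definitions (independent of the engine's dispatch logic)."""
    sup = lm.s_phg_superior_edge
    crown = lm.s_phg_crown_midpoint
    medge = lm.s_cs_medial_edge
    mbh = lm.s_medial_bank_half
    fundus = lm.s_cs_fundus
    lbq = lm.s_lateral_bank_quarter
    ffm = lm.s_fundus_fg_midpoint
    fgc = lm.s_fg_crown_midpoint
    if column == 10:
        return [("BA36", mbh, lbq)]
    if column == 9:
        return [("BA35", sup - 7, fundus), ("BA36", fundus, ffm)]
    if column == 7:
        return [("BA35", sup - 10, fundus), ("BA36", fundus, fgc)]
    if column == 5:
        return [
            ("BA35", sup - 5, crown),
            ("ERC", crown, medge),
            ("BA35", medge, fundus),
            ("BA36", fundus, fgc),
        ]
    # 4 and 2.5 mm columns
    return [
        ("ERC", sup, medge),
        ("BA35", medge, fundus),
        ("BA36", fundus, fgc),
    ]


@pytest.mark.parametrize(
    "d,column",
    [(10.4, 10), (9.1, 9), (7.8, 7), (6.5, 7), (5.2, 5), (3.9, 4), (2.6, 2.5)],
)
def test_engine_matches_hand_derived_columns(
    d, column, zero_noise_cohort, reference_rules
):
    case = zero_noise_cohort.cases[0]
    contour = {
        c.slice_distance_mm: c
        for c in zero_noise_cohort.slice_stack(case.case_id)
    }[d]
    lm = m.derive_landmarks(contour)
    labelmap = m.segment_case(
        zero_noise_cohort.slice_stack(case.case_id), reference_rules
    )
    got = [
        (iv.label, iv.s_start, iv.s_end) for iv in labelmap.slices[d]
    ]
    expected = _golden_expected(lm, column)
    assert len(got) == len(expected)
    for (gl, gs, ge), (el, es, ee) in zip(got, expected):
        assert gl == el
        assert gs == pytest.approx(es, abs=1e-9)
        assert ge == pytest.approx(ee, abs=1e-9)


# ---------------------------------------------------------------------------
# partition and extent invariants
# ---------------------------------------------------------------------------

def test_partition_no_gaps_no_overlaps(noisy_cohort, reference_rules):
    for case in noisy_cohort.cases:
        labelmap = m.segment_case(
            noisy_cohort.slice_stack(case.case_id), reference_rules
        )
        for d, ivs in labelmap.slices.items():
            for a, b in zip(ivs, ivs[1:]):
                assert a.s_end == pytest.approx(b.s_start, abs=0.0), (
                    f"gap/overlap on slice {d}"
                )
            assert all(iv.s_start < iv.s_end for iv in ivs)


def test_region_slice_runs_are_posterior_anchored(noisy_cohort, reference_rules):
    th = reference_rules.slice_thickness_mm
    for case in noisy_cohort.cases:
        labelmap = m.segment_case(
            noisy_cohort.slice_stack(case.case_id), reference_rules
        )
        for label in labelmap.labels():
            ds = sorted(labelmap.intervals(label))
            assert np.allclose(np.diff(ds), th)  # contiguous run
            assert ds[0] == pytest.approx(reference_rules.posterior_bound_mm)


def test_grid_enumeration_from_rule_starts(zero_noise_cohort, reference_rules):
    case = zero_noise_cohort.cases[0]
    labelmap = m.segment_case(
        zero_noise_cohort.slice_stack(case.case_id), reference_rules
    )
    assert sorted(labelmap.intervals("ERC")) == pytest.approx([2.6, 3.9, 5.2])
    assert len(labelmap.intervals("BA36")) == 7  # 10.4 down to 2.6
    assert sorted(labelmap.intervals("BA36"))[0] == pytest.approx(2.6)
    assert sorted(labelmap.intervals("BA36"))[-1] == pytest.approx(10.4)


def test_missing_slices_raise_gap_error(zero_noise_cohort, reference_rules):
    case = zero_noise_cohort.cases[0]
    stack = [
        c
        for c in zero_noise_cohort.slice_stack(case.case_id)
        if abs(c.slice_distance_mm - 3.9) > 1e-6
    ]
    with pytest.raises(StackGapError, match="3.9"):
        m.segment_case(stack, reference_rules)


def test_determinism(zero_noise_cohort, reference_rules):
    case = zero_noise_cohort.cases[0]
    a = m.segment_case(zero_noise_cohort.slice_stack(case.case_id), reference_rules)
    b = m.segment_case(zero_noise_cohort.slice_stack(case.case_id), reference_rules)
    assert a.to_frame().equals(b.to_frame())


def test_engine_equals_truth_on_zero_noise(zero_noise_cohort, reference_rules):
    for case in zero_noise_cohort.cases:
        engine_map = m.segment_case(
            zero_noise_cohort.slice_stack(case.case_id), reference_rules
        )
        truth_map = zero_noise_cohort.truth_labelmap(case.case_id)
        for label in ("ERC", "BA35", "BA36"):
            assert m.dsi(engine_map, truth_map, label).dsi == pytest.approx(1.0)


def test_degenerate_interval_raises(simple_contour, reference_rules):
    lm = m.derive_landmarks(simple_contour)
    # collapse the CS so the BA35 interval inverts
    bad = m.LandmarkSet(
        s_phg_superior_edge=lm.s_phg_superior_edge,
        s_phg_crown_midpoint=lm.s_phg_crown_midpoint,
        s_cs_medial_edge=lm.s_cs_fundus,  # medial edge pushed onto fundus
        s_medial_bank_half=lm.s_cs_fundus,
        s_cs_fundus=lm.s_cs_fundus,
        s_lateral_bank_quarter=lm.s_lateral_bank_quarter,
        s_fundus_fg_midpoint=lm.s_fundus_fg_midpoint,
        s_fg_crown_midpoint=lm.s_fg_crown_midpoint,
        cs_depth_mm=lm.cs_depth_mm,
        slice_distance_mm=2.6,
        s_total=lm.s_total,
    )
    with pytest.raises(DegenerateSliceError):
        m.apply_rules_slice(
            bad, 2.6, reference_rules,
            {"ERC": True, "BA35": True, "BA36": False},
        )


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _straight_band_fixture():
    """A single straight 10 mm ERC interval on one slice."""
    pts = np.array([[float(x), 0.0] for x in range(-14, 2)] +
                   [[2.0, -0.5], [3.0, -6.0], [4.0, -0.5], [8.0, 1.0],
                    [12.0, 0.0]])
    keys = {
        "medial_terminus": 0,
        "phg_superior_edge": 14,
        "cs_medial_mouth": 16,
        "cs_fundus": 17,
        "cs_lateral_mouth": 18,
        "fg_crown_apex": 19,
        "lateral_terminus": 20,
    }
    contour = m.SliceContour("band", 2.6, pts, keys)
    labelmap = m.LabelMap(case_id="band")
    labelmap.slices[2.6] = [m.LabeledInterval("ERC", "primary", 2.0, 12.0)]
    return contour, labelmap


def test_straight_band_voxel_count():
    contour, labelmap = _straight_band_fixture()
    vol, meta = m.rasterize_labels(labelmap, [contour], resolution_mm=0.5,
                                   ribbon_thickness_mm=1.0)
    count = int((vol == LABEL_CODES["ERC"]).sum())
    # area-count oracle: 10 mm x 1 mm band / (0.5 mm)^2 = 40 voxels, up to
    # one voxel row of discretization error along each edge
    assert abs(count - 40) <= 22


def test_empty_labelmap_rasterizes_to_zeros():
    contour, _ = _straight_band_fixture()
    empty = m.LabelMap(case_id="band")
    vol, _ = m.rasterize_labels(empty, [contour])
    assert vol.size == 0 or not vol.any()


def test_adjacent_intervals_never_double_label(zero_noise_cohort,
                                               reference_rules):
    case = zero_noise_cohort.cases[0]
    stack = zero_noise_cohort.slice_stack(case.case_id)
    labelmap = m.segment_case(stack, reference_rules)
    vol, meta = m.rasterize_labels(labelmap, stack, resolution_mm=0.4)
    # each voxel carries exactly one code by construction; all three labels
    # must be present
    present = set(np.unique(vol)) - {0}
    assert present == set(LABEL_CODES.values())


def test_labelmap_frame_roundtrip(zero_noise_cohort, reference_rules):
    case = zero_noise_cohort.cases[0]
    labelmap = m.segment_case(
        zero_noise_cohort.slice_stack(case.case_id), reference_rules
    )
    frame = labelmap.to_frame()
    back = m.LabelMap.from_frame(frame)[case.case_id]
    assert back.to_frame().equals(frame)


def test_nifti_export_roundtrip(tmp_path, zero_noise_cohort, reference_rules):
    import nibabel as nib

    case = zero_noise_cohort.cases[0]
    stack = zero_noise_cohort.slice_stack(case.case_id)
    labelmap = m.segment_case(stack, reference_rules)
    vol, meta = m.rasterize_labels(labelmap, stack, resolution_mm=0.8)
    path = tmp_path / "labels.nii.gz"
    m.engine.save_labelmap_nifti(path, vol, meta)
    img = nib.load(path)
    assert img.shape == (vol.shape[2], vol.shape[1], vol.shape[0])
    assert int(np.asarray(img.dataobj).sum()) == int(vol.sum())


def test_itk_snap_label_file(tmp_path):
    path = tmp_path / "labels.txt"
    m.engine.write_itk_snap_labels(path)
    text = path.read_text()
    for label, code in LABEL_CODES.items():
        assert f'"{label}"' in text
        assert text.count("\n") >= 4
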