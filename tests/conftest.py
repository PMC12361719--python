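"""Shared fixtures: hand-built contours and small phantom cohorts."""

import numpy as np
import pytest
from hypothesis import settings

import mtlseg as m

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_simple_contour(case_id="fix", slice_distance_mm=5.2):
    """Hand-built contour with straight segments and exact arc lengths.

    Medial run 13 mm, PHG crown 8 mm, symmetric CS banks of sqrt(37) mm
    around a fundus 6 mm below the mouth chord, FG crown 2*sqrt(17) mm.
    """
    points = np.array(
        [
            [-13.0, 0.0],
            [-6.5, 0.0],
            [0.0, 0.0],    # phg_superior_edge
            [8.0, 0.0],    # cs_medial_mouth
            [9.0, -6.0],   # cs_fundus
            [10.0, 0.0],   # cs_lateral_mouth
            [14.0, 1.0],   # fg_crown_apex
            [18.0, 0.0],   # lateral_terminus
        ]
    )
    keys = {
        "medial_terminus": 0,
        "phg_superior_edge": 2,
        "cs_medial_mouth": 3,
        "cs_fundus": 4,
        "cs_lateral_mouth": 5,
        "fg_crown_apex": 6,
        "lateral_terminus": 7,
    }
    return m.SliceContour(case_id, slice_distance_mm, points, keys)


@pytest.fixture
def simple_contour():
    return make_simple_contour()


@pytest.fixture(scope="session")
def reference_rules():
    return m.reference_rule_table()


@pytest.fixture(scope="session")
def zero_noise_cohort(reference_rules):
    """20-case noise-free cohort whose anatomy realizes the reference rules."""
    cfg = m.CohortConfig.from_rule_table(reference_rules, n_cases=20, seed=3)
    return m.generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Small cohort under the default study conditions (2 mm border noise)."""
    return m.generate_cohort(m.CohortConfig(n_cases=8, seed=17))


@pytest.fixture(scope="session")
def phantom_contour(noisy_cohort):
    case = noisy_cohort.cases[0]
    return m.build_slice_contour(case, 5.2)
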