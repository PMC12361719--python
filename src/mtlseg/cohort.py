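"""Seeded phantom cohort generator for the anterior medial temporal lobe.

The generator emulates the statistical structure of the histology cohort the
protocol was derived from: per-case anterior extents of ERC, BA35 and BA36
and of the anchor structures (hippocampus tip at the origin, amygdala tip,
temporal pole, limen insulae, collateral-sulcus tip), per-slice coronal pial
contours spanning the medial temporal surface through the parahippocampal
gyrus, a single collateral sulcus (shallow or deep) and the fusiform gyrus,
and ground-truth cytoarchitectonic borders placed at configurable landmark
offsets with Gaussian between-case noise.

Extents are sampled from location-scale distributions matched to the
published medians and between-subject SDs (a shifted normal by default, with
an optional skew-normal residual since the published means and medians
differ).  A shared per-case anterior shift is added to all region extents
and to all non-hippocampal anchor positions, so anchor-relative distances
partially cancel it — reproducing the published ordering in which the
amygdala-relative SDs sit slightly below the hippocampus-relative ones while
both stay far below the temporal-pole/limen/sulcus candidates.

Randomness uses numpy's PCG64 with per-case ``SeedSequence`` substreams, so
output is reproducible across platforms and earlier cases are unchanged when
``n_cases`` grows.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
import pandas as pd

from .errors import CohortConfigError, SegmentationRangeError
from .engine import LabeledInterval, LabelMap, apply_rules_slice
from .geometry import SliceContour, derive_landmarks
from .rules import REGIONS, RuleTable, reference_rule_table

_RETRY_BUDGET = 100


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtentSpec:
    """Location-scale (optionally skewed) spec for an anterior extent (mm).

    ``median`` is the distribution median, ``sd`` the total between-case SD
    (including any shared-shift component), ``skew`` the skew-normal shape
    of the residual (0 = shifted normal).
    """

    median: float
    sd: float
    skew: float = 0.0


@dataclass(frozen=True)
class AnchorSpec:
    """An anchor structure's axial position and reporting convention.

    ``position_mm`` is the structure's anterior-tip position on the
    hippocampus-anchored axis (positive = anterior of the hippocampus tip);
    ``sd`` its own between-case positional SD; ``sign`` states how the
    region-to-anchor distance is reported, since the published conventions
    differ by anchor (``"region_minus_anchor"`` or ``"anchor_minus_region"``).
    """

    position_mm: float
    sd: float
    sign: str = "region_minus_anchor"


DEFAULT_EXTENTS: dict[str, ExtentSpec] = {
    "ERC": ExtentSpec(4.75, 1.58),
    "BA35": ExtentSpec(9.25, 2.60),
    "BA36": ExtentSpec(10.25, 3.84),
}

DEFAULT_ANCHORS: dict[str, AnchorSpec] = {
    "hippocampus": AnchorSpec(0.0, 0.0, "region_minus_anchor"),
    "amygdala": AnchorSpec(4.0, 0.3, "region_minus_anchor"),
    "temporal_pole": AnchorSpec(26.5, 2.2, "anchor_minus_region"),
    "limen_insulae": AnchorSpec(5.5, 1.9, "anchor_minus_region"),
    "collateral_sulcus": AnchorSpec(19.5, 4.3, "anchor_minus_region"),
}


@dataclass
class CohortConfig:
    """Study conditions for a phantom cohort.

    Defaults mirror the source cohort: 20 cases, half with a deep collateral
    sulcus, 11/20 with a neurodegenerative disease, a 1.3 mm slice grid
    (0.5 mm is the histology-like alternative), published extent medians and
    SDs, and true borders following the reference rule table with 2 mm
    between-case Gaussian noise.
    """

    n_cases: int = 20
    seed: int = 0
    slice_thickness_mm: float = 1.3
    fraction_deep_cs: float = 0.5
    fraction_disease: float = 11 / 20
    stratify_cs: bool = False
    extents: dict[str, ExtentSpec] = field(
        default_factory=lambda: dict(DEFAULT_EXTENTS)
    )
    anchors: dict[str, AnchorSpec] = field(
        default_factory=lambda: dict(DEFAULT_ANCHORS)
    )
    shared_extent_sd: float = 0.5
    truth_rules: RuleTable | None = None
    border_sd_mm: float = 2.0
    flank_window_mm: float = 1.0
    rater_sigma_mm: float = 0.5
    posterior_bound_mm: float = 2.6

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise CohortConfigError("n_cases must be >= 1")
        if self.slice_thickness_mm <= 0:
            raise CohortConfigError("slice_thickness_mm must be positive")
        for frac in (self.fraction_deep_cs, self.fraction_disease):
            if not 0.0 <= frac <= 1.0:
                raise CohortConfigError("fractions must lie in [0, 1]")
        sds = [s.sd for s in self.extents.values()] + [
            a.sd for a in self.anchors.values()
        ] + [self.border_sd_mm, self.shared_extent_sd, self.rater_sigma_mm]
        if any(sd < 0 for sd in sds):
            raise CohortConfigError("all SDs must be non-negative")
        if self.truth_rules is None:
            self.truth_rules = reference_rule_table(
                self.slice_thickness_mm, self.posterior_bound_mm
            )

    @classmethod
    def from_rule_table(cls, rule_table: RuleTable, **kwargs) -> "CohortConfig":
        """Noise-free cohort whose anatomy realizes a rule table exactly.

        Extent medians are set to the table's region starts with zero SD
        (shared shift included) and true borders follow the table with zero
        noise — the configuration used for round-trip identity checks.
        """
        extents = {
            r: ExtentSpec(rule_table.start(r), 0.0) for r in REGIONS
        }
        anchors = {
            name: AnchorSpec(spec.position_mm, 0.0, spec.sign)
            for name, spec in DEFAULT_ANCHORS.items()
        }
        kwargs.setdefault("slice_thickness_mm", rule_table.slice_thickness_mm)
        kwargs.setdefault("posterior_bound_mm", rule_table.posterior_bound_mm)
        return cls(
            extents=extents,
            anchors=anchors,
            shared_extent_sd=0.0,
            truth_rules=rule_table,
            border_sd_mm=0.0,
            **kwargs,
        )


# ---------------------------------------------------------------------------
# per-case phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeParams:
    """Per-case contour shape parameters (mm)."""

    medial_span: float   # arc from medial terminus to superior PHG edge
    crown_width: float   # PHG crown, superior edge to medial CS mouth
    cs_halfwidth: float  # half the CS mouth opening
    fg_width: float      # lateral CS mouth to lateral terminus


@dataclass(frozen=True)
class BorderAnnotation:
    """One ground-truth border position on one slice."""

    region: str
    side: str
    segment: str
    s: float
    slice_distance_mm: float


@dataclass
class CasePhantom:
    """Sampled anatomy of one phantom case."""

    case_id: str
    hemisphere: str
    disease_group: bool
    cs_depth_class: str
    cs_depth_mm: float
    extents: dict[str, float]
    anchors: dict[str, float]
    shape: ShapeParams
    border_seed: int

    def cs_depth_at(self, slice_distance_mm: float) -> float:
        """CS depth profile; constant along the anterior extent by design."""
        return self.cs_depth_mm

    def slice_grid(
        self, slice_thickness_mm: float, min_top_mm: float = 0.0
    ) -> list[float]:
        """Grid slice distances covering [thickness, max extent + 2 mm].

        ``min_top_mm`` extends the stack anteriorly when the protocol range
        (the rule-table region starts) exceeds this case's own extents.
        """
        top = max(max(self.extents.values()) + 2.0, min_top_mm)
        n = int(math.ceil(top / slice_thickness_mm - 1e-9))
        return [round(k * slice_thickness_mm, 6) for k in range(1, n + 1)]


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def _case_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, index])))


def _sample_positive(
    rng: np.random.Generator,
    median: float,
    resid_sd: float,
    shift: float,
    skew: float,
    what: str,
) -> float:
    """Sample median + shift + residual, rejecting non-positive draws."""
    from scipy import stats

    if skew != 0.0 and resid_sd > 0.0:
        m0 = float(stats.skewnorm.median(skew))
        s0 = float(stats.skewnorm.std(skew))
    for _ in range(_RETRY_BUDGET):
        if resid_sd == 0.0:
            resid = 0.0
        elif skew == 0.0:
            resid = rng.normal(0.0, resid_sd)
        else:
            z = stats.skewnorm.rvs(skew, random_state=rng)
            resid = (z - m0) * (resid_sd / s0)
        val = median + shift + resid
        if val > 0.0:
            return float(val)
    raise CohortConfigError(
        f"could not sample a positive {what} in {_RETRY_BUDGET} attempts"
    )


def _sample_cs_depth(rng: np.random.Generator, deep: bool) -> float:
    for _ in range(_RETRY_BUDGET):
        if deep:
            d = rng.normal(9.5, 1.5)
            if 7.0 <= d <= 15.0:
                return float(d)
        else:
            d = rng.normal(4.5, 1.2)
            if 0.8 <= d < 7.0:
                return float(d)
    raise CohortConfigError("could not sample an admissible CS depth")


def _sample_case(config: CohortConfig, index: int) -> CasePhantom:
    rng = _case_rng(config.seed, index)
    g = rng.normal(0.0, config.shared_extent_sd) if config.shared_extent_sd else 0.0

    extents: dict[str, float] = {}
    for region in REGIONS:
        spec = config.extents[region]
        resid_sd = math.sqrt(max(spec.sd**2 - config.shared_extent_sd**2, 0.0))
        extents[region] = _sample_positive(
            rng, spec.median, resid_sd, g, spec.skew, f"{region} extent"
        )

    anchors: dict[str, float] = {}
    for name, spec in config.anchors.items():
        if name == "hippocampus":
            anchors[name] = 0.0  # the axis origin by construction
            continue
        own = rng.normal(0.0, spec.sd) if spec.sd else 0.0
        anchors[name] = float(spec.position_mm + g + own)

    if config.stratify_cs:
        deep = index < round(config.fraction_deep_cs * config.n_cases)
    else:
        deep = bool(rng.random() < config.fraction_deep_cs)
    depth = _sample_cs_depth(rng, deep)
    disease = bool(rng.random() < config.fraction_disease)
    hemisphere = "R" if rng.random() < 0.65 else "L"

    shape = ShapeParams(
        medial_span=float(np.clip(rng.normal(14.0, 1.0), 12.5, 18.0)),
        crown_width=float(np.clip(rng.normal(8.0, 0.7), 6.0, 11.0)),
        cs_halfwidth=float(np.clip(rng.normal(1.6, 0.2), 1.0, 2.5)),
        fg_width=float(np.clip(rng.normal(10.0, 1.0), 7.0, 14.0)),
    )
    border_seed = int(rng.integers(0, 2**31 - 1))
    return CasePhantom(
        case_id=f"case{index:04d}",
        hemisphere=hemisphere,
        disease_group=disease,
        cs_depth_class="deep" if depth >= 7.0 else "shallow",
        cs_depth_mm=depth,
        extents=extents,
        anchors=anchors,
        shape=shape,
        border_seed=border_seed,
    )


# ---------------------------------------------------------------------------
# contour synthesis
# ---------------------------------------------------------------------------

def _quad_bezier(
    p0: np.ndarray, c: np.ndarray, p1: np.ndarray, n: int
) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * c + t**2 * p1


def build_slice_contour(
    case: CasePhantom,
    slice_distance_mm: float,
    slice_thickness_mm: float = 1.3,
    max_slice_mm: float | None = None,
) -> SliceContour:
    """Synthesize the tagged pial contour of one coronal slice.

    The contour is a gently curved schematic of the medial temporal surface:
    medial PHG wall, PHG crown, the two collateral-sulcus banks meeting at a
    fundus whose chord depth equals the case's sampled CS depth, and the
    fusiform crown out to the lateral terminus (the medial mouth of the next
    sulcus).  The medial wall spans at least 12.5 mm of arc so that medial
    border offsets up to 10 mm stay on-contour.
    """
    grid = case.slice_grid(slice_thickness_mm, min_top_mm=max_slice_mm or 0.0)
    if not (grid[0] - 1e-6 <= slice_distance_mm <= grid[-1] + 1e-6):
        raise SegmentationRangeError(
            f"slice {slice_distance_mm:g} mm outside stack range "
            f"[{grid[0]:g}, {grid[-1]:g}]"
        )
    sh = case.shape
    depth = case.cs_depth_at(slice_distance_mm)

    span = sh.medial_span
    # medial wall: straight-line chord equal to the sampled span, bowed
    mt = np.array([-0.8 * span, -0.6 * span])
    sup = np.array([0.0, 0.0])
    m1 = np.array([sh.crown_width, -0.8])
    fundus = np.array([sh.crown_width + sh.cs_halfwidth, -0.8 - depth])
    m2 = np.array([sh.crown_width + 2 * sh.cs_halfwidth, -0.8])
    apex = np.array([m2[0] + 0.5 * sh.fg_width, 0.4])
    lt = np.array([m2[0] + sh.fg_width, -1.2])

    def bow(p0, p1, off):
        mid = 0.5 * (p0 + p1)
        d = p1 - p0
        perp = np.array([-d[1], d[0]]) / np.linalg.norm(d)
        return mid + off * perp

    sections = [
        (mt, bow(mt, sup, 0.6), sup, 8),
        (sup, bow(sup, m1, 0.5), m1, 6),
        (m1, bow(m1, fundus, 0.35), fundus, 6),
        (fundus, bow(fundus, m2, 0.35), m2, 6),
        (m2, bow(m2, apex, 0.3), apex, 5),
        (apex, bow(apex, lt, 0.3), lt, 5),
    ]
    pts_list: list[np.ndarray] = []
    key_idx: dict[str, int] = {}
    keys_at_section_end = [
        "phg_superior_edge",
        "cs_medial_mouth",
        "cs_fundus",
        "cs_lateral_mouth",
        "fg_crown_apex",
        "lateral_terminus",
    ]
    key_idx["medial_terminus"] = 0
    count = 0
    for (p0, c, p1, n), key in zip(sections, keys_at_section_end):
        seg = _quad_bezier(p0, c, p1, n)
        if pts_list:
            seg = seg[1:]
        pts_list.append(seg)
        count += len(seg)
        key_idx[key] = count - 1
    points = np.concatenate(pts_list)
    return SliceContour(
        case_id=case.case_id,
        slice_distance_mm=slice_distance_mm,
        points=points,
        key_vertices=key_idx,
    )


# ---------------------------------------------------------------------------
# ground-truth borders
# ---------------------------------------------------------------------------

def _truth_presence(
    case: CasePhantom, d: float, posterior_bound: float
) -> dict[str, bool]:
    return {
        r: (posterior_bound - 1e-9 <= d <= case.extents[r] + 1e-9)
        for r in REGIONS
    }


def _truth_ordinals(
    case: CasePhantom, d: float, thickness: float, table: RuleTable
) -> dict[str, int]:
    """Slice ordinals steering rule dispatch for ground-truth placement.

    Landmark-identity anterior cells (ERC crown midpoint, BA36 bank rules,
    the flank window) follow the case's own anatomy: ordinal 1 on the
    region's anterior-most slice.  The offset-bearing BA35 medial cells are
    keyed by nearest reference level instead, matching how the protocol
    words them ("at 9 mm ...") and how the measurement stage reads them.
    """
    ordinals = {
        r: 1 + int(math.floor((case.extents[r] - d) / thickness + 1e-6))
        for r in REGIONS
    }
    ba35_levels = table.levels_for("BA35", "medial")
    if ba35_levels:
        nearest = min(table.levels, key=lambda lv: (round(abs(d - lv), 9), lv))
        ordinals["BA35"] = 1 if nearest == ba35_levels[0] else 2
    return ordinals


def place_true_borders(
    case: CasePhantom,
    landmarks,
    slice_distance_mm: float,
    rng: np.random.Generator,
    config: CohortConfig,
) -> tuple[list[BorderAnnotation], list[LabeledInterval]]:
    """Ground-truth borders of one slice: protocol positions plus noise.

    The noise-free positions come from the same per-slice rule resolution
    the segmentation engine uses, with region presence taken from the case's
    sampled anterior extents (not the rule-table starts) and the BA35 medial
    flank emitted only where the configured flank window behind the ERC
    anterior extent contains the slice.  Each distinct border position is
    then jittered independently by Gaussian(0, ``border_sd_mm``), re-sorted
    to keep the partition ordered, and clamped to the contour domain.
    """
    d = slice_distance_mm
    table = config.truth_rules
    presence = _truth_presence(case, d, config.posterior_bound_mm)
    if not any(presence.values()):
        return [], []
    ordinals = _truth_ordinals(case, d, config.slice_thickness_mm, table)
    in_flank_window = (
        presence["ERC"]
        and case.extents["ERC"] - config.flank_window_mm - 1e-9 <= d
    )
    intervals = apply_rules_slice(landmarks, d, table, presence, ordinals)
    if not in_flank_window:
        intervals = [iv for iv in intervals if iv.segment != "medial_flank"]
    if not intervals:
        return [], []

    # jitter distinct breakpoints, preserving shared borders
    bps: list[float] = []
    for iv in intervals:
        for s in (iv.s_start, iv.s_end):
            if not bps or abs(s - bps[-1]) > 1e-9:
                if all(abs(s - b) > 1e-9 for b in bps):
                    bps.append(s)
    bps_arr = np.array(sorted(bps))
    if config.border_sd_mm > 0:
        jit = bps_arr + rng.normal(0.0, config.border_sd_mm, size=len(bps_arr))
        jit = np.clip(np.sort(jit), 0.0, landmarks.s_total)
    else:
        jit = bps_arr
    remap = {round(b, 9): j for b, j in zip(bps_arr, jit)}

    def moved(s: float) -> float:
        key = min(remap, key=lambda b: abs(b - s))
        return float(remap[key])

    out_intervals = [
        LabeledInterval(iv.label, iv.segment, moved(iv.s_start), moved(iv.s_end))
        for iv in intervals
    ]
    out_intervals = [iv for iv in out_intervals if iv.s_end - iv.s_start > 1e-9]
    annotations = []
    for iv in out_intervals:
        annotations.append(
            BorderAnnotation(iv.label, "medial", iv.segment, iv.s_start, d)
        )
        annotations.append(
            BorderAnnotation(iv.label, "lateral", iv.segment, iv.s_end, d)
        )
    return annotations, out_intervals


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------

class Cohort:
    """A generated phantom cohort with lazy, cached per-case geometry."""

    def __init__(self, config: CohortConfig, cases: list[CasePhantom]):
        self.config = config
        self.cases = cases
        self._stacks: dict[str, list[SliceContour]] = {}
        self._truth: dict[str, tuple[pd.DataFrame, LabelMap]] = {}

    def case(self, case_id: str) -> CasePhantom:
        for c in self.cases:
            if c.case_id == case_id:
                return c
        raise KeyError(case_id)

    def slice_stack(self, case_id: str) -> list[SliceContour]:
        if case_id not in self._stacks:
            case = self.case(case_id)
            # stacks always cover the protocol range, so cases whose own
            # extents fall short can still be segmented by the rule engine
            top = max(self.config.truth_rules.region_starts.values())
            self._stacks[case_id] = [
                build_slice_contour(
                    case, d, self.config.slice_thickness_mm, max_slice_mm=top
                )
                for d in case.slice_grid(
                    self.config.slice_thickness_mm, min_top_mm=top
                )
            ]
        return self._stacks[case_id]

    def _build_truth(self, case_id: str) -> tuple[pd.DataFrame, LabelMap]:
        if case_id not in self._truth:
            case = self.case(case_id)
            rows = []
            labelmap = LabelMap(case_id=case_id)
            for k, contour in enumerate(self.slice_stack(case_id)):
                d = contour.slice_distance_mm
                rng = np.random.Generator(
                    np.random.PCG64(
                        np.random.SeedSequence([case.border_seed, k])
                    )
                )
                lms = derive_landmarks(contour)
                annotations, intervals = place_true_borders(
                    case, lms, d, rng, self.config
                )
                if intervals:
                    labelmap.slices[d] = intervals
                for a in annotations:
                    rows.append(dataclasses.asdict(a))
            frame = pd.DataFrame(
                rows,
                columns=["region", "side", "segment", "s", "slice_distance_mm"],
            )
            frame.insert(0, "case_id", case_id)
            self._truth[case_id] = (frame, labelmap)
        return self._truth[case_id]

    def truth_borders(self, case_id: str) -> pd.DataFrame:
        return self._build_truth(case_id)[0]

    def truth_labelmap(self, case_id: str) -> LabelMap:
        return self._build_truth(case_id)[1]

    def case_table(self) -> pd.DataFrame:
        rows = []
        for c in self.cases:
            row = {
                "case_id": c.case_id,
                "hemisphere": c.hemisphere,
                "disease_group": c.disease_group,
                "cs_depth_class": c.cs_depth_class,
                "cs_depth_mm": c.cs_depth_mm,
                "border_seed": c.border_seed,
            }
            row.update({f"extent_{r}": c.extents[r] for r in REGIONS})
            row.update({f"anchor_{a}": p for a, p in sorted(c.anchors.items())})
            row.update(
                {f"shape_{k}": v for k, v in dataclasses.asdict(c.shape).items()}
            )
            rows.append(row)
        return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate ``config.n_cases`` phantom cases, deterministically."""
    cases = [_sample_case(config, i) for i in range(config.n_cases)]
    return Cohort(config, cases)


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write contours (structured text), truth borders and case metadata."""
    from .geometry import write_contour_stack

    out = Path(outdir)
    (out / "contours").mkdir(parents=True, exist_ok=True)
    cohort.case_table().to_csv(out / "cases.tsv", sep="\t", index=False)
    borders = []
    truth_frames = []
    for case in cohort.cases:
        write_contour_stack(
            out / "contours" / f"{case.case_id}.json",
            {
                "case_id": case.case_id,
                "hemisphere": case.hemisphere,
                "disease_group": case.disease_group,
                "cs_depth_class": case.cs_depth_class,
            },
            cohort.slice_stack(case.case_id),
        )
        borders.append(cohort.truth_borders(case.case_id))
        truth_frames.append(cohort.truth_labelmap(case.case_id).to_frame())
    pd.concat(borders, ignore_index=True).to_csv(
        out / "truth_borders.tsv", sep="\t", index=False
    )
    pd.concat(truth_frames, ignore_index=True).to_csv(
        out / "truth_labels.tsv", sep="\t", index=False
    )
    cohort.config.truth_rules.to_json(out / "truth_rules.json")
    cfg = dataclasses.replace(cohort.config)
    cfg.truth_rules = None  # serialized separately as truth_rules.json
    doc = dataclasses.asdict(cfg)
    doc.pop("truth_rules")
    (out / "config.json").write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


class LoadedCohort:
    """A cohort read back from disk; same access protocol as :class:`Cohort`."""

    def __init__(
        self,
        config: CohortConfig,
        cases: list[CasePhantom],
        stacks: dict[str, list[SliceContour]],
        truth: pd.DataFrame,
        truth_labels: pd.DataFrame,
    ):
        self.config = config
        self.cases = cases
        self._stacks = stacks
        self._truth = truth
        self._truth_maps = LabelMap.from_frame(truth_labels)

    def case(self, case_id: str) -> CasePhantom:
        for c in self.cases:
            if c.case_id == case_id:
                return c
        raise KeyError(case_id)

    def slice_stack(self, case_id: str) -> list[SliceContour]:
        return self._stacks[case_id]

    def truth_borders(self, case_id: str) -> pd.DataFrame:
        return self._truth[self._truth["case_id"] == case_id].reset_index(
            drop=True
        )

    def truth_labelmap(self, case_id: str) -> LabelMap:
        return self._truth_maps[case_id]

    def case_table(self) -> pd.DataFrame:
        return Cohort.case_table(self)  # type: ignore[arg-type]


def read_cohort(indir: str | Path) -> LoadedCohort:
    from .geometry import read_contour_stack

    ind = Path(indir)
    cfg_doc = json.loads((ind / "config.json").read_text())
    cfg_doc.pop("truth_rules", None)
    cfg_doc["extents"] = {
        k: ExtentSpec(**v) for k, v in cfg_doc.get("extents", {}).items()
    }
    cfg_doc["anchors"] = {
        k: AnchorSpec(**v) for k, v in cfg_doc.get("anchors", {}).items()
    }
    config = CohortConfig(**cfg_doc)
    rules_path = ind / "truth_rules.json"
    if rules_path.exists():
        config.truth_rules = RuleTable.from_json(rules_path)
    case_df = pd.read_csv(ind / "cases.tsv", sep="\t")
    cases = []
    stacks: dict[str, list[SliceContour]] = {}
    for _, row in case_df.iterrows():
        case = CasePhantom(
            case_id=str(row["case_id"]),
            hemisphere=str(row["hemisphere"]),
            disease_group=bool(row["disease_group"]),
            cs_depth_class=str(row["cs_depth_class"]),
            cs_depth_mm=float(row["cs_depth_mm"]),
            extents={r: float(row[f"extent_{r}"]) for r in REGIONS},
            anchors={
                a.removeprefix("anchor_"): float(row[a])
                for a in case_df.columns
                if a.startswith("anchor_")
            },
            shape=ShapeParams(
                **{
                    k.removeprefix("shape_"): float(row[k])
                    for k in case_df.columns
                    if k.startswith("shape_")
                }
            ),
            border_seed=int(row["border_seed"]),
        )
        cases.append(case)
        _, stack = read_contour_stack(ind / "contours" / f"{case.case_id}.json")
        stacks[case.case_id] = stack
    truth = pd.read_csv(ind / "truth_borders.tsv", sep="\t")
    truth_labels = pd.read_csv(ind / "truth_labels.tsv", sep="\t")
    return LoadedCohort(config, cases, stacks, truth, truth_labels)
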