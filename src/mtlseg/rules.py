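"""Rule-table derivation: summary statistics, anchor selection, quantization.

This stage turns measured border-to-landmark distances and anterior-extent
distances into the machine-readable protocol: region start distances on the
slice grid and per-level border rules of the form (landmark, integer offset,
direction).  The protocol has a fixed structural template — which landmark
anchors which border at which reference level — mirroring the published
border-placement grid; only the region starts and the three offset-bearing
BA35 medial cells are estimated from data.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import OutOfDomainError, RuleDerivationError
from .geometry import LANDMARK_NAMES

REGIONS: tuple[str, ...] = ("ERC", "BA35", "BA36")
REFERENCE_LEVELS: tuple[float, ...] = (10.0, 9.0, 7.0, 5.0, 4.0, 2.5)

#: Anchor candidates for region start distances, and whether each is easy to
#: identify on MRI (the amygdala's anterior tip is notoriously hard).
ANCHOR_IDENTIFIABILITY: dict[str, str] = {
    "hippocampus": "easy",
    "amygdala": "hard",
    "temporal_pole": "easy",
    "limen_insulae": "easy",
    "collateral_sulcus": "easy",
}


# ---------------------------------------------------------------------------
# elementary derivation arithmetic
# ---------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def quantize_to_grid(median_mm: float, slice_thickness_mm: float) -> float:
    """Snap a measured median distance to the slice grid.

    Returns ``thickness * round(median / thickness)`` with ties rounded half
    away from zero, e.g. a 4.75 mm median on a 1.3 mm grid gives 5.2 mm.
    """
    if median_mm <= 0 or slice_thickness_mm <= 0:
        raise OutOfDomainError("median and slice thickness must be positive")
    return round(slice_thickness_mm * _round_half_away(median_mm / slice_thickness_mm), 6)


def round_offset(median_mm: float) -> int:
    """Round an offset median to whole millimetres of magnitude.

    The direction (medial/lateral) is carried separately by the rule, so the
    result is the rounded magnitude: 9.96 -> 10, -5.40 -> 5.  Ties round away
    from zero.
    """
    if not np.isfinite(median_mm):
        raise OutOfDomainError("offset median must be finite")
    return _round_half_away(abs(median_mm))


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def summarize_distances(
    records: pd.DataFrame,
    by: Sequence[str] = ("region", "side", "landmark", "slice_level"),
) -> pd.DataFrame:
    """Per-cell n / mean / median / SD of signed border-landmark distances.

    Absence records (``present == False`` or NaN distances) are excluded
    from the statistics; ``n`` counts contributing observations only.  The
    SD is the sample (n-1) standard deviation, 0.0 for singleton cells; the
    median for even n is the midpoint of the central pair.
    """
    df = records
    if "present" in df.columns:
        df = df[df["present"].astype(bool)]
    df = df[np.isfinite(df["distance_mm"])]
    if df.empty:
        return pd.DataFrame(
            columns=[*by, "n", "mean", "median", "sd"]
        )
    g = df.groupby(list(by), dropna=False)["distance_mm"]
    out = g.agg(n="count", mean="mean", median="median", sd="std").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    return out


def summarize_extents(records: pd.DataFrame) -> pd.DataFrame:
    """Per (region, anchor) n / mean / median / SD of extent distances."""
    return summarize_distances(records, by=("region", "anchor"))


@dataclass(frozen=True)
class AnchorSelection:
    anchor: str
    ranking: pd.DataFrame
    note: str = ""


def select_anchor(
    extent_stats: pd.DataFrame,
    identifiability: Mapping[str, str] | None = None,
) -> AnchorSelection:
    """Choose the anchor structure for region start distances.

    Candidates are ranked by the sum of the between-case SDs of their
    region-to-anchor distances across all three regions (lower is better).
    Between the top two, the one flagged easy to identify on MRI wins —
    the amygdala edges out the hippocampus on raw SD but is much harder to
    localize, so the hippocampus tip is the expected pick under realistic
    inputs.  If every candidate is hard, the best-SD one is returned with a
    warning note.
    """
    ident = dict(ANCHOR_IDENTIFIABILITY)
    if identifiability:
        ident.update(identifiability)
    pivot = extent_stats.pivot_table(
        index="anchor", columns="region", values="sd"
    )
    pivot = pivot.dropna(axis=0, how="any")
    missing = [r for r in REGIONS if r not in pivot.columns]
    if missing or len(pivot) < 2:
        raise RuleDerivationError(
            "anchor selection needs >=2 anchors with SDs for all regions"
        )
    # ties (e.g. fully degenerate zero-noise inputs) resolve by a canonical
    # anchor preference, making the result input-order invariant
    preference = {a: i for i, a in enumerate(ANCHOR_IDENTIFIABILITY)}
    ranking = (
        pivot[list(REGIONS)]
        .assign(sd_sum=lambda d: d.sum(axis=1))
        .reset_index()
        .assign(_pref=lambda d: d["anchor"].map(lambda a: preference.get(a, 99)))
        .sort_values(["sd_sum", "_pref", "anchor"], kind="stable")
        .drop(columns="_pref")
        .reset_index(drop=True)
    )
    ranking["identifiability"] = ranking["anchor"].map(
        lambda a: ident.get(a, "easy")
    )
    top = ranking.head(2)
    easy_top = top[top["identifiability"] == "easy"]
    if len(easy_top):
        chosen = str(easy_top.iloc[0]["anchor"])
        note = ""
    else:
        easy_any = ranking[ranking["identifiability"] == "easy"]
        if len(easy_any):
            chosen = str(easy_any.iloc[0]["anchor"])
            note = "top-two anchors hard to identify; took best easy anchor"
        else:
            chosen = str(ranking.iloc[0]["anchor"])
            note = "warning: all anchors hard to identify on MRI"
    return AnchorSelection(anchor=chosen, ranking=ranking, note=note)


# ---------------------------------------------------------------------------
# rule table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BorderRule:
    """One border-placement rule.

    ``kind`` is ``"landmark"`` (border sits on the landmark), ``"offset"``
    (landmark plus a signed walk of ``offset_mm`` along the ribbon in
    ``direction``), or ``"region_ref"`` (border shared with the adjacent
    region named in ``ref_region``).
    """

    kind: str
    landmark: str | None = None
    offset_mm: float = 0.0
    direction: str | None = None
    ref_region: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("landmark", "offset", "region_ref"):
            raise ValueError(f"unknown rule kind: {self.kind}")
        if self.kind in ("landmark", "offset"):
            if self.landmark not in LANDMARK_NAMES:
                raise ValueError(f"unknown landmark: {self.landmark}")
        if self.kind == "offset" and self.direction not in ("medial", "lateral"):
            raise ValueError("offset rules need a medial/lateral direction")
        if self.kind == "region_ref" and self.ref_region not in REGIONS:
            raise ValueError(f"unknown referenced region: {self.ref_region}")

    def describe(self) -> str:
        if self.kind == "region_ref":
            return self.ref_region  # type: ignore[return-value]
        if self.kind == "landmark" or self.offset_mm == 0:
            return self.landmark  # type: ignore[return-value]
        return f"{self.offset_mm:g} mm {self.direction} to {self.landmark}"


#: (level, region, side, segment) keys; segment is "primary" except for the
#: medial flank of BA35 that wraps around the ERC on its first slice.
RuleKey = tuple[float, str, str, str]


@dataclass
class RuleTable:
    """Machine-readable border-placement protocol.

    ``region_starts`` are anterior start distances (mm anterior to the
    anchor), exact multiples of ``slice_thickness_mm``.  ``rules`` maps
    (level, region, side, segment) to a :class:`BorderRule`.  Labels run
    from ``posterior_bound_mm`` (where the pre-existing posterior atlas
    takes over) to each region's start.
    """

    slice_thickness_mm: float
    anchor: str
    region_starts: dict[str, float]
    levels: tuple[float, ...]
    rules: dict[RuleKey, BorderRule]
    posterior_bound_mm: float = 2.6
    provenance: dict = field(default_factory=dict)

    SCHEMA = "mtlseg-rules/1"

    def __post_init__(self) -> None:
        for region, start in self.region_starts.items():
            ratio = start / self.slice_thickness_mm
            if abs(ratio - round(ratio)) > 1e-6:
                raise ValueError(
                    f"{region} start {start} not a multiple of slice thickness"
                )
        lv = list(self.levels)
        if lv != sorted(lv, reverse=True):
            raise ValueError("levels must strictly decrease anterior->posterior")

    # -- lookups ------------------------------------------------------------
    def start(self, region: str) -> float:
        return self.region_starts[region]

    def cell(
        self, level: float, region: str, side: str, segment: str = "primary"
    ) -> BorderRule | None:
        return self.rules.get((level, region, side, segment))

    def levels_for(self, region: str, side: str | None = None) -> list[float]:
        """Reference levels that carry a primary cell for a region."""
        out = sorted(
            {
                lv
                for (lv, r, sd, seg) in self.rules
                if r == region and seg == "primary" and (side is None or sd == side)
            },
            reverse=True,
        )
        return out

    def flank_levels(self) -> list[float]:
        return sorted(
            {lv for (lv, r, sd, seg) in self.rules if seg == "medial_flank"},
            reverse=True,
        )

    def equals(self, other: "RuleTable", include_provenance: bool = False) -> bool:
        same = (
            abs(self.slice_thickness_mm - other.slice_thickness_mm) < 1e-9
            and self.anchor == other.anchor
            and self.levels == other.levels
            and abs(self.posterior_bound_mm - other.posterior_bound_mm) < 1e-9
            and set(self.region_starts) == set(other.region_starts)
            and all(
                abs(self.region_starts[r] - other.region_starts[r]) < 1e-9
                for r in self.region_starts
            )
            and self.rules == other.rules
        )
        if include_provenance:
            same = same and self.provenance == other.provenance
        return same

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "schema": self.SCHEMA,
            "slice_thickness_mm": self.slice_thickness_mm,
            "anchor": self.anchor,
            "posterior_bound_mm": self.posterior_bound_mm,
            "region_starts": self.region_starts,
            "levels": list(self.levels),
            "rules": [
                {
                    "level": lv,
                    "region": r,
                    "side": sd,
                    "segment": seg,
                    "kind": rule.kind,
                    "landmark": rule.landmark,
                    "offset_mm": rule.offset_mm,
                    "direction": rule.direction,
                    "ref_region": rule.ref_region,
                }
                for (lv, r, sd, seg), rule in sorted(self.rules.items())
            ],
            "provenance": self.provenance,
        }
        text = json.dumps(doc, indent=1, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RuleTable":
        text = str(source)
        if "{" not in text:  # a path, not JSON text
            text = Path(source).read_text()
        doc = json.loads(text)
        if doc.get("schema") != cls.SCHEMA:
            raise ValueError("unrecognized rule-table schema")
        rules = {
            (float(r["level"]), r["region"], r["side"], r["segment"]): BorderRule(
                kind=r["kind"],
                landmark=r["landmark"],
                offset_mm=float(r["offset_mm"]),
                direction=r["direction"],
                ref_region=r["ref_region"],
            )
            for r in doc["rules"]
        }
        return cls(
            slice_thickness_mm=float(doc["slice_thickness_mm"]),
            anchor=str(doc["anchor"]),
            region_starts={k: float(v) for k, v in doc["region_starts"].items()},
            levels=tuple(float(v) for v in doc["levels"]),
            rules=rules,
            posterior_bound_mm=float(doc["posterior_bound_mm"]),
            provenance=dict(doc.get("provenance", {})),
        )

    def render(self) -> str:
        """Human-readable grid mirroring the published protocol layout."""
        lines = [
            f"Border-placement rules (anchor: {self.anchor}, "
            f"slice thickness {self.slice_thickness_mm:g} mm)",
            "Region starts (mm anterior to anchor): "
            + ", ".join(f"{r} {self.region_starts[r]:g}" for r in REGIONS),
            "",
        ]
        header = ["region/border"] + [f"{lv:g} mm" for lv in self.levels]
        rows: list[list[str]] = []
        for region in REGIONS:
            for side in ("medial", "lateral"):
                row = [f"{region} {side}"]
                for lv in self.levels:
                    rule = self.cell(lv, region, side)
                    row.append(rule.describe() if rule else "-")
                rows.append(row)
        if self.flank_levels():
            row = ["BA35 flank medial"]
            for lv in self.levels:
                rule = self.cell(lv, "BA35", "medial", "medial_flank")
                row.append(rule.describe() if rule else "-")
            rows.append(row)
        widths = [
            max(len(r[i]) for r in [header] + rows) for i in range(len(header))
        ]
        for r in [header] + rows:
            lines.append("  ".join(c.ljust(w) for c, w in zip(r, widths)))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# the structural template and published reference table
# ---------------------------------------------------------------------------

def _fixed_cells() -> dict[RuleKey, BorderRule]:
    """Landmark-identity and adjacency cells of the protocol template."""
    L = lambda name: BorderRule("landmark", landmark=name)
    R = lambda region: BorderRule("region_ref", ref_region=region)
    cells: dict[RuleKey, BorderRule] = {}
    # 10 mm level: BA36 alone, bounded by the CS banks.  The medial border
    # follows the medial-bank halfway point (the textual protocol; the
    # published grid's "lateral bank" entry in this cell contradicts both
    # the text and the measurements feeding it).
    cells[(10.0, "BA36", "medial", "primary")] = L("medial_bank_half")
    cells[(10.0, "BA36", "lateral", "primary")] = L("lateral_bank_quarter")
    # 9 mm level: BA35 appears; BA36 lateral transitions smoothly.
    cells[(9.0, "BA35", "lateral", "primary")] = L("cs_fundus")
    cells[(9.0, "BA36", "medial", "primary")] = R("BA35")
    cells[(9.0, "BA36", "lateral", "primary")] = L("fundus_fg_midpoint")
    # 7 mm level.
    cells[(7.0, "BA35", "lateral", "primary")] = L("cs_fundus")
    cells[(7.0, "BA36", "medial", "primary")] = R("BA35")
    cells[(7.0, "BA36", "lateral", "primary")] = L("fg_crown_midpoint")
    # 5 mm level: ERC appears between two segments of BA35.
    cells[(5.0, "ERC", "medial", "primary")] = L("phg_crown_midpoint")
    cells[(5.0, "ERC", "lateral", "primary")] = L("cs_medial_edge")
    cells[(5.0, "BA35", "medial", "primary")] = R("ERC")
    cells[(5.0, "BA35", "lateral", "primary")] = L("cs_fundus")
    cells[(5.0, "BA36", "medial", "primary")] = R("BA35")
    cells[(5.0, "BA36", "lateral", "primary")] = L("fg_crown_midpoint")
    # 4 and 2.5 mm levels.
    for lv in (4.0, 2.5):
        cells[(lv, "ERC", "medial", "primary")] = L("phg_superior_edge")
        cells[(lv, "ERC", "lateral", "primary")] = L("cs_medial_edge")
        cells[(lv, "BA35", "medial", "primary")] = R("ERC")
        cells[(lv, "BA35", "lateral", "primary")] = L("cs_fundus")
        cells[(lv, "BA36", "medial", "primary")] = R("BA35")
        cells[(lv, "BA36", "lateral", "primary")] = L("fg_crown_midpoint")
    return cells


#: Offset-bearing template cells: (level, region, side, segment) -> landmark
#: the offset is measured against.
OFFSET_CELLS: dict[RuleKey, str] = {
    (9.0, "BA35", "medial", "primary"): "phg_superior_edge",
    (7.0, "BA35", "medial", "primary"): "phg_superior_edge",
    (5.0, "BA35", "medial", "medial_flank"): "phg_superior_edge",
}


def reference_rule_table(
    slice_thickness_mm: float = 1.3, posterior_bound_mm: float = 2.6
) -> RuleTable:
    """The published protocol, built from the printed medians.

    Starts quantize the printed extent medians (4.75, 9.25, 10.25 mm) to the
    slice grid; the BA35 medial offsets are the printed 7/10/5 mm values,
    all directed medially from the superior PHG edge.
    """
    printed_extent_medians = {"ERC": 4.75, "BA35": 9.25, "BA36": 10.25}
    rules = _fixed_cells()
    for (lv, region, side, seg), landmark in OFFSET_CELLS.items():
        offset = {9.0: 7, 7.0: 10, 5.0: 5}[lv]
        rules[(lv, region, side, seg)] = BorderRule(
            "offset", landmark=landmark, offset_mm=float(offset), direction="medial"
        )
    return RuleTable(
        slice_thickness_mm=slice_thickness_mm,
        anchor="hippocampus",
        region_starts={
            r: quantize_to_grid(m, slice_thickness_mm)
            for r, m in printed_extent_medians.items()
        },
        levels=REFERENCE_LEVELS,
        rules=rules,
        posterior_bound_mm=posterior_bound_mm,
        provenance={"source": "published medians"},
    )


# ---------------------------------------------------------------------------
# derivation
# ---------------------------------------------------------------------------

@dataclass
class DerivationConfig:
    """Options for :func:`derive_rule_table`.

    ``offset_direction_mode`` controls how the direction of the BA35 medial
    offsets is recorded: ``"table_wording"`` (default) pins all three to
    "medial of the superior PHG edge" as the protocol grid words them;
    ``"measured_sign"`` takes the direction from the sign of the measured
    median (negative = medial).  The measured medians and their signs are
    preserved in the table's provenance either way.
    """

    slice_thickness_mm: float = 1.3
    levels: tuple[float, ...] = REFERENCE_LEVELS
    anchor: str | None = None
    offset_direction_mode: str = "table_wording"
    posterior_bound_mm: float = 2.6
    identifiability: Mapping[str, str] | None = None


def derive_rule_table(
    distance_stats: pd.DataFrame,
    extent_stats: pd.DataFrame,
    config: DerivationConfig | None = None,
) -> tuple[RuleTable, dict]:
    """Derive the full rule table from summary statistics.

    Region starts quantize the median anterior-extent distance to the chosen
    anchor onto the slice grid; the three offset-bearing BA35 medial cells
    round the median signed distance to the superior PHG edge to whole
    millimetres; every other cell is a fixed landmark or adjacency rule of
    the protocol template.  Returns the table and a derivation report.
    """
    cfg = config or DerivationConfig()
    report: dict = {"notes": []}

    if cfg.anchor is None:
        sel = select_anchor(extent_stats, cfg.identifiability)
        anchor = sel.anchor
        report["anchor_ranking"] = sel.ranking
        if sel.note:
            report["notes"].append(sel.note)
    else:
        anchor = cfg.anchor
    report["anchor"] = anchor

    ext = extent_stats[extent_stats["anchor"] == anchor].set_index("region")
    starts: dict[str, float] = {}
    for region in REGIONS:
        if region not in ext.index:
            raise RuleDerivationError(
                f"missing extent statistics cell: region={region}, anchor={anchor}"
            )
        starts[region] = quantize_to_grid(
            float(ext.loc[region, "median"]), cfg.slice_thickness_mm
        )
    report["extent_medians"] = {
        r: float(ext.loc[r, "median"]) for r in REGIONS
    }

    rules = _fixed_cells()
    ds = distance_stats.set_index(["region", "side", "landmark", "slice_level"])
    offset_medians: dict[str, float] = {}
    for (lv, region, side, seg), landmark in OFFSET_CELLS.items():
        key = (region, side, landmark, f"{lv:g}")
        if key not in ds.index:
            raise RuleDerivationError(
                f"missing distance statistics cell: region={region}, side={side}, "
                f"landmark={landmark}, level={lv:g}"
            )
        median = float(ds.loc[key, "median"])
        offset_medians[f"{region}/{side}/{seg}@{lv:g}"] = median
        if cfg.offset_direction_mode == "measured_sign":
            direction = "medial" if median < 0 else "lateral"
        elif cfg.offset_direction_mode == "table_wording":
            direction = "medial"
        else:
            raise ValueError(
                f"unknown offset_direction_mode: {cfg.offset_direction_mode}"
            )
        rules[(lv, region, side, seg)] = BorderRule(
            "offset",
            landmark=landmark,
            offset_mm=float(round_offset(median)),
            direction=direction,
        )
        if cfg.offset_direction_mode == "table_wording" and median > 0:
            report["notes"].append(
                f"measured median at level {lv:g} is positive ({median:+.2f} mm, "
                "lateral by the measurement sign convention) but recorded as "
                "medial per the protocol grid wording"
            )
    report["offset_medians"] = offset_medians

    provenance = {
        "anchor": anchor,
        "extent_medians": report["extent_medians"],
        "offset_medians": offset_medians,
        "offset_direction_mode": cfg.offset_direction_mode,
    }
    provenance["config_hash"] = hashlib.sha256(
        json.dumps(provenance, sort_keys=True).encode()
    ).hexdigest()[:16]

    table = RuleTable(
        slice_thickness_mm=cfg.slice_thickness_mm,
        anchor=anchor,
        region_starts=starts,
        levels=tuple(cfg.levels),
        rules=rules,
        posterior_bound_mm=cfg.posterior_bound_mm,
        provenance=provenance,
    )
    return table, report
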