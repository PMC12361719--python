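"""Model-style interface to protocol derivation.

``ProtocolModel`` is built from the two measurement tables (border-landmark
distances and anterior-extent distances); ``fit()`` estimates the protocol —
anchor choice, grid-quantized region starts, rounded border offsets — and
returns a ``ProtocolResults`` carrying the rule table, the underlying
summary statistics, the anchor ranking and a ``summary()`` report.
Segmentation and reliability evaluation hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import pandas as pd

from .engine import LabelMap, segment_case
from .measure import measure_cohort
from .rules import (
    DerivationConfig,
    RuleTable,
    derive_rule_table,
    summarize_distances,
    summarize_extents,
)


class ProtocolModel:
    """Border-placement protocol estimated from distance measurements.

    Parameters
    ----------
    distances : DataFrame
        Border-to-landmark distance records (one observation per row, with
        ``region``, ``side``, ``landmark``, ``slice_level``, ``distance_mm``
        and optionally ``present`` columns).
    extents : DataFrame
        Region-to-anchor anterior-extent records (``region``, ``anchor``,
        ``distance_mm``).
    config : DerivationConfig, optional
        Slice grid, levels, anchor override and sign-convention options.
    """

    def __init__(
        self,
        distances: pd.DataFrame,
        extents: pd.DataFrame,
        config: DerivationConfig | None = None,
    ):
        self.distances = distances
        self.extents = extents
        self.config = config or DerivationConfig()

    @classmethod
    def from_cohort(cls, cohort, config: DerivationConfig | None = None):
        """Run the measurement stage on a cohort and build the model."""
        distances, extents = measure_cohort(cohort)
        if config is None:
            config = DerivationConfig(
                slice_thickness_mm=cohort.config.slice_thickness_mm,
                posterior_bound_mm=cohort.config.posterior_bound_mm,
            )
        return cls(distances, extents, config)

    def fit(self) -> "ProtocolResults":
        """Summarize the records and derive the rule table."""
        distance_stats = summarize_distances(self.distances)
        extent_stats = summarize_extents(self.extents)
        table, report = derive_rule_table(
            distance_stats, extent_stats, self.config
        )
        return ProtocolResults(
            model=self,
            rule_table=table,
            distance_stats=distance_stats,
            extent_stats=extent_stats,
            report=report,
        )


@dataclass
class ProtocolResults:
    """Fitted protocol: rule table, statistics and diagnostics."""

    model: ProtocolModel
    rule_table: RuleTable
    distance_stats: pd.DataFrame
    extent_stats: pd.DataFrame
    report: dict

    # -- downstream operations ---------------------------------------------
    def segment(self, stack) -> LabelMap:
        """Apply the fitted protocol to a landmark-tagged slice stack."""
        return segment_case(stack, self.rule_table)

    def reliability(self, cohort, **kwargs):
        from .reliability import reliability_experiment

        return reliability_experiment(cohort, self.rule_table, **kwargs)

    def save_rules(self, path: str | Path) -> None:
        self.rule_table.to_json(Path(path))

    # -- reporting ----------------------------------------------------------
    def anchor_ranking(self) -> pd.DataFrame | None:
        return self.report.get("anchor_ranking")

    def summary(self) -> str:
        """Plain-text report: anchor ranking, starts, and the rule grid."""
        lines = ["Protocol derivation summary", "=" * 27, ""]
        lines.append(f"Anchor structure: {self.report.get('anchor')}")
        ranking = self.anchor_ranking()
        if ranking is not None:
            lines.append("")
            lines.append("Anchor ranking (between-case SD of extent distances, mm):")
            lines.append(ranking.round(3).to_string(index=False))
        lines.append("")
        lines.append("Region starts (mm anterior to anchor, on the slice grid):")
        for region, start in self.rule_table.region_starts.items():
            median = self.report.get("extent_medians", {}).get(region)
            extra = f"  (median {median:.2f} mm)" if median is not None else ""
            lines.append(f"  {region}: {start:g} mm{extra}")
        lines.append("")
        lines.append(self.rule_table.render())
        if self.report.get("notes"):
            lines.append("Notes:")
            for note in self.report["notes"]:
                lines.append(f"  - {note}")
        return "\n".join(lines) + "\n"
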