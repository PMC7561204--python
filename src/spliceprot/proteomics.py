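"""Peptide-experiment detection (PED) counting and event-level profiles.

A peptide's PED count is the number of distinct experiments in which it
was identified — presence/absence evidence, not intensity.  A peptide
seen in every experiment of the 79-experiment reference cohort has 79
PEDs; a peptide seen once has one.  Event-side PED counts are the sums
of the PED contributions of the side's discriminating peptides, broken
down by tissue and by tissue group.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import Side, TissueSchema, assign_sides
from .errors import SchemaError, ValidationError

#: Accepted raw side labels in detection tables; anything not intersect is a
#: physical side identifier (typically "a"/"b") relabelled to main/alternative
#: from total PED support.
INTERSECT = Side.INTERSECT.value

DETECTION_COLUMNS = ("peptide", "gene_id", "event_id", "side", "experiment_id", "tissue")

#: Default event-inclusion threshold: each side needs >= 3 PEDs, because
#: tissue specificity cannot be assessed below that.
DEFAULT_MIN_PEDS = 3


def count_peds(detections: pd.DataFrame, peptide: str) -> int:
    """Number of distinct experiments in which ``peptide`` was detected."""
    if detections.empty:
        return 0
    sub = detections.loc[detections["peptide"] == peptide, "experiment_id"]
    return int(sub.nunique())


@dataclass(frozen=True)
class PedProfile:
    """Per-tissue, per-side PED counts for one splice event.

    ``tissue_counts`` is indexed by tissue with columns
    ``main``/``alternative``/``intersect``; ``side_map`` records which raw
    side label became main and which alternative.
    """

    event_id: str
    tissue_counts: pd.DataFrame
    side_map: dict[str, str]
    schema: TissueSchema

    def total(self, side: str) -> int:
        return int(self.tissue_counts[side].sum())

    def group_counts(self) -> pd.DataFrame:
        """Fold tissue-level counts into tissue-group counts."""
        groups = self.tissue_counts.index.to_series().map(self.schema.groups)
        out = self.tissue_counts.groupby(groups).sum()
        out.index.name = "group"
        return out.sort_index()

    def unit_counts(self, unit_kind: str) -> pd.DataFrame:
        if unit_kind == "tissue":
            return self.tissue_counts
        if unit_kind == "group":
            return self.group_counts()
        raise ValidationError(f"unit_kind must be tissue|group, got {unit_kind!r}")


def _dedupe(detections: pd.DataFrame) -> pd.DataFrame:
    return detections.drop_duplicates(subset=["peptide", "experiment_id"])


def build_ped_profile(
    event_id: str,
    detections: pd.DataFrame,
    schema: TissueSchema,
) -> PedProfile:
    """Aggregate one event's detections into a tissue x side PED profile.

    Rows are deduplicated on (peptide, experiment) before counting, so a
    peptide identified several times in one experiment contributes a
    single PED.  Raw side labels other than ``intersect`` are relabelled
    so that *main* is the side with most total PEDs (ties broken
    lexicographically on the raw label).
    """
    det = detections.loc[detections["event_id"] == event_id]
    unknown = set(det["tissue"]) - set(schema.groups)
    if unknown:
        raise SchemaError(
            f"{event_id}: tissues outside schema: {sorted(unknown)}"
        )
    det = _dedupe(det)

    raw_sides = sorted(set(det["side"]) - {INTERSECT})
    if len(raw_sides) > 2:
        raise ValidationError(f"{event_id}: more than two side labels {raw_sides}")

    counts = (
        det.groupby(["tissue", "side"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(index=schema.tissues, fill_value=0)
    )
    counts.index.name = "tissue"

    # totals per raw side drive the main/alternative relabelling
    if len(raw_sides) == 2:
        ra, rb = raw_sides
        main_raw, alt_raw = assign_sides(
            counts.get(ra, pd.Series(0, index=counts.index)).sum(),
            counts.get(rb, pd.Series(0, index=counts.index)).sum(),
            ids=(ra, rb),
        )
    elif len(raw_sides) == 1:
        main_raw, alt_raw = raw_sides[0], None
    else:
        main_raw = alt_raw = None

    tissue_counts = pd.DataFrame(0, index=counts.index, columns=["main", "alternative", "intersect"])
    if main_raw is not None and main_raw in counts:
        tissue_counts["main"] = counts[main_raw]
    if alt_raw is not None and alt_raw in counts:
        tissue_counts["alternative"] = counts[alt_raw]
    if INTERSECT in counts:
        tissue_counts["intersect"] = counts[INTERSECT]

    side_map = {"main": main_raw or "", "alternative": alt_raw or ""}
    return PedProfile(event_id=event_id, tissue_counts=tissue_counts,
                      side_map=side_map, schema=schema)


def build_profiles(detections: pd.DataFrame, schema: TissueSchema) -> list[PedProfile]:
    """Profiles for every event id present in the detection table."""
    events = sorted(detections["event_id"].dropna().unique())
    return [build_ped_profile(e, detections, schema) for e in events]


def filter_events(
    profiles: list[PedProfile],
    min_peds: int = DEFAULT_MIN_PEDS,
) -> list[PedProfile]:
    """Keep events with at least ``min_peds`` PEDs on *each* side."""
    if min_peds < 1:
        raise ValidationError("min_peds must be >= 1")
    return [
        p
        for p in profiles
        if p.total("main") >= min_peds and p.total("alternative") >= min_peds
    ]


def profiles_to_frame(profiles: list[PedProfile]) -> pd.DataFrame:
    """Long-format table: event_id, unit, unit_kind, side, ped."""
    rows = []
    for p in profiles:
        for kind in ("tissue", "group"):
            counts = p.unit_counts(kind)
            for unit, row in counts.iterrows():
                for side in ("main", "alternative", "intersect"):
                    rows.append((p.event_id, unit, kind, side, int(row[side])))
    return pd.DataFrame(rows, columns=["event_id", "unit", "unit_kind", "side", "ped"])
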