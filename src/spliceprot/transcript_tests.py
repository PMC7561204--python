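"""Transcript-level tissue-group specificity: the one-standard-deviation rule.

Junction reads supporting each side of a splice event are summed per
transcriptomics tissue group.  Each side's read vector is standardised
across groups (its own mean and population standard deviation); a group
is called enriched for a side when that side's standardised support
exceeds the other side's by at least one standard deviation.  An event
with at least one enriched group is transcript tissue-group specific.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .core import assign_sides
from .errors import InsufficientGroupsError, ValidationError
from .proteomics import INTERSECT

READ_COLUMNS = ("event_id", "group", "side", "reads")


@dataclass(frozen=True)
class ReadProfile:
    """Per-group, per-side junction read support for one event.

    ``reads`` is indexed by group with columns main/alternative/intersect;
    ``side_map`` records the raw-label -> main/alternative assignment
    (main = side with most total reads).
    """

    event_id: str
    reads: pd.DataFrame
    side_map: dict[str, str]
    ddof: int = 0

    def z(self, side: str) -> pd.Series:
        """Standardised read support of one side across groups (z = 0 if sd = 0)."""
        if len(self.reads.index) < 2:
            raise InsufficientGroupsError(
                f"{self.event_id}: need >= 2 groups to standardise"
            )
        x = self.reads[side].astype(float)
        sd = float(x.std(ddof=self.ddof))
        if sd == 0:
            return pd.Series(0.0, index=x.index)
        return (x - x.mean()) / sd


def build_read_profile(
    event_id: str,
    reads: pd.DataFrame,
    groups: Iterable[str],
    ddof: int = 0,
) -> ReadProfile:
    """Build a profile from the long read table, relabelling sides.

    Raw side labels other than ``intersect`` are relabelled so that main
    is the side with most total reads (ties broken lexicographically) —
    the transcript-level labels are assigned independently of the
    proteomics labels.
    """
    sub = reads.loc[reads["event_id"] == event_id]
    if (sub["reads"] < 0).any():
        raise ValidationError(f"{event_id}: negative read counts")
    groups = sorted(groups)
    unknown = set(sub["group"]) - set(groups)
    if unknown:
        raise ValidationError(f"{event_id}: groups outside schema {sorted(unknown)}")

    wide = (
        sub.groupby(["group", "side"])["reads"]
        .sum()
        .unstack(fill_value=0.0)
        .reindex(index=groups, fill_value=0.0)
    )
    wide.index.name = "group"

    raw_sides = sorted(set(sub["side"]) - {INTERSECT})
    if len(raw_sides) > 2:
        raise ValidationError(f"{event_id}: more than two side labels {raw_sides}")
    if len(raw_sides) == 2:
        ra, rb = raw_sides
        main_raw, alt_raw = assign_sides(
            float(wide.get(ra, pd.Series(dtype=float)).sum()),
            float(wide.get(rb, pd.Series(dtype=float)).sum()),
            ids=(ra, rb),
        )
    elif len(raw_sides) == 1:
        main_raw, alt_raw = raw_sides[0], None
    else:
        main_raw = alt_raw = None

    out = pd.DataFrame(0.0, index=wide.index, columns=["main", "alternative", "intersect"])
    if main_raw is not None and main_raw in wide:
        out["main"] = wide[main_raw]
    if alt_raw is not None and alt_raw in wide:
        out["alternative"] = wide[alt_raw]
    if INTERSECT in wide:
        out["intersect"] = wide[INTERSECT]
    return ReadProfile(
        event_id=event_id,
        reads=out,
        side_map={"main": main_raw or "", "alternative": alt_raw or ""},
        ddof=ddof,
    )


def side_z(profile: ReadProfile, side: str, group: str) -> float:
    """Standardised read support of ``side`` in ``group``."""
    return float(profile.z(side).loc[group])


def call_transcript_enrichment(
    profile: ReadProfile,
    sd_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-group enrichment calls under the standard-deviation rule.

    A group is enriched for the side whose z-value exceeds the other
    side's by at least ``sd_threshold``; at most one side per group.
    Returns columns event_id, group, enriched_side, z_main, z_alt.
    """
    z_main = profile.z("main")
    z_alt = profile.z("alternative")
    dz = z_main - z_alt
    side = np.where(dz >= sd_threshold, "main",
                    np.where(-dz >= sd_threshold, "alternative", "none"))
    return pd.DataFrame(
        {
            "event_id": profile.event_id,
            "group": z_main.index,
            "enriched_side": side,
            "z_main": z_main.values,
            "z_alt": z_alt.values,
        }
    ).reset_index(drop=True)


def call_all_transcript(
    reads: pd.DataFrame,
    groups: Iterable[str],
    sd_threshold: float = 1.0,
    ddof: int = 0,
) -> tuple[pd.DataFrame, dict[str, ReadProfile]]:
    """Enrichment calls plus profiles for every event in the read table."""
    groups = sorted(groups)
    profiles: dict[str, ReadProfile] = {}
    frames = []
    for e in sorted(reads["event_id"].dropna().unique()):
        p = build_read_profile(e, reads, groups, ddof=ddof)
        profiles[e] = p
        frames.append(call_transcript_enrichment(p, sd_threshold=sd_threshold))
    calls = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["event_id", "group", "enriched_side", "z_main", "z_alt"])
    )
    return calls, profiles


def z_difference_matrix(profiles: dict[str, ReadProfile]) -> pd.DataFrame:
    """Heatmap-ready event x group matrix of main-minus-alternative z values."""
    rows = {
        e: (p.z("main") - p.z("alternative")) for e, p in sorted(profiles.items())
    }
    return pd.DataFrame(rows).T.rename_axis(index="event_id")
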