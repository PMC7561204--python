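"""End-to-end pipeline driver: filter -> protein tests -> transcript calls
-> concordance -> age/disorder annotation.

The in-memory entry point is :func:`run_analysis`, which takes the input
tables as DataFrames and returns every intermediate and final table plus
a machine-readable summary of the stage funnel.  :func:`run_pipeline`
wraps it with file I/O for the command-line interface.  Stages whose
inputs are absent are skipped and marked as such; every filter logs its
in/out counts so the event funnel is auditable on any dataset.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import concordance as cc
from . import disorder as dis
from . import evolution as evo
from . import io as sio
from . import protein_tests as pt
from . import proteomics as pe
from . import transcript_tests as tt
from .core import AgeBin, Effect, Mechanism, SplicingEvent, TissueSchema
from .errors import (
    IncompleteInputError,
    UndefinedCorrelationError,
    ValidationError,
)
from .reference import (
    EXCLUDED_GROUPS,
    SHARED_GROUPS,
    TRANSCRIPTOMICS_GROUPS,
    reference_proteomics_schema,
)

log = logging.getLogger("spliceprot")


@dataclass
class RunConfig:
    """File-based pipeline configuration (YAML-mappable)."""

    events: Optional[str] = None
    detections: Optional[str] = None
    reads: Optional[str] = None
    scores: Optional[str] = None
    homology: Optional[str] = None
    schema: Optional[str] = None
    outdir: str = "results"
    alpha: float = 0.05
    correction: Optional[str] = None
    min_peds: int = pe.DEFAULT_MIN_PEDS
    sd_threshold: float = 1.0
    shared_groups: tuple[str, ...] = SHARED_GROUPS
    excluded_groups: tuple[str, ...] = EXCLUDED_GROUPS
    transcript_groups: tuple[str, ...] = TRANSCRIPTOMICS_GROUPS

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.min_peds < 1:
            raise ValidationError("min_peds must be >= 1")
        if self.sd_threshold <= 0:
            raise ValidationError("sd_threshold must be positive")


def events_from_frame(events: pd.DataFrame) -> dict[str, SplicingEvent]:
    out = {}
    for row in events.itertuples(index=False):
        out[row.event_id] = SplicingEvent(
            event_id=row.event_id,
            gene_id=row.gene_id,
            mechanism=Mechanism(row.mechanism),
            effect=Effect(row.effect),
            side_a_len=int(row.side_a_len),
            side_b_len=int(row.side_b_len),
            homologous_flag=bool(row.homologous_flag),
            age_label=AgeBin(row.age_label) if row.age_label else AgeBin.UNKNOWN,
        )
    return out


def run_analysis(
    events: Optional[pd.DataFrame] = None,
    detections: Optional[pd.DataFrame] = None,
    reads: Optional[pd.DataFrame] = None,
    scores: Optional[pd.DataFrame] = None,
    homology: Optional[pd.DataFrame] = None,
    schema: Optional[TissueSchema] = None,
    config: Optional[RunConfig] = None,
) -> dict:
    """Run every stage whose inputs are present; return tables + summary.

    Returns a dict with keys ``profiles`` (event -> PedProfile),
    ``protein_calls``, ``transcript_calls``, ``read_profiles``,
    ``pge_cases``, ``concordance_by_group``, ``pairwise``,
    ``support_points``, ``correlations``, ``ages``, ``disorder``,
    ``event_summary`` and ``summary`` (the JSON-able funnel).
    """
    config = config or RunConfig()
    schema = schema or reference_proteomics_schema()
    out: dict = {"summary": {"stages_skipped": []}}
    summary = out["summary"]

    typed_events = events_from_frame(events) if events is not None else {}
    summary["n_events_input"] = len(typed_events)

    # ------------------------------------------------------ protein evidence
    kept: list[pe.PedProfile] = []
    if detections is not None:
        profiles = pe.build_profiles(detections, schema)
        kept = pe.filter_events(profiles, min_peds=config.min_peds)
        out["profiles"] = {p.event_id: p for p in kept}
        summary["n_events_with_detections"] = len(profiles)
        summary["n_pass_filter"] = len(kept)
        log.info("PED filter: %d events in, %d with >=%d PEDs per side",
                 len(profiles), len(kept), config.min_peds)
        calls = pt.call_all(kept, alpha=config.alpha, correction=config.correction)
        out["protein_calls"] = calls
        flags = pt.event_specificity_flags(calls)
        out["specificity_flags"] = flags
        summary["n_tissue_specific"] = int(flags["tissue_specific"].sum())
        summary["n_group_specific"] = int(flags["group_specific"].sum())
        summary["n_specific_either"] = int(flags["specific"].sum())
        log.info("protein specificity: %d tissue-level, %d group-level, %d either",
                 summary["n_tissue_specific"], summary["n_group_specific"],
                 summary["n_specific_either"])
    else:
        summary["stages_skipped"].append("protein")

    # --------------------------------------------------- transcript evidence
    if reads is not None:
        tcalls, rprofiles = tt.call_all_transcript(
            reads, config.transcript_groups, sd_threshold=config.sd_threshold
        )
        out["transcript_calls"] = tcalls
        out["read_profiles"] = rprofiles
        enriched = tcalls[tcalls["enriched_side"] != "none"]
        summary["n_transcript_events"] = int(tcalls["event_id"].nunique())
        summary["n_transcript_specific"] = int(enriched["event_id"].nunique())
        log.info("transcript SD rule: %d events, %d group-specific",
                 summary["n_transcript_events"], summary["n_transcript_specific"])
    else:
        summary["stages_skipped"].append("transcript")

    # ------------------------------------------------------------ concordance
    if detections is not None and reads is not None:
        pge = cc.build_pge_cases(
            out["protein_calls"], config.shared_groups, config.excluded_groups
        )
        cases, by_group, pairwise = cc.concordance_summary(pge, out["transcript_calls"])
        out["pge_cases"] = cases
        out["concordance_by_group"] = by_group
        out["pairwise"] = pairwise
        summary["n_pge_cases"] = len(cases)
        summary["n_pge_events"] = int(cases["event_id"].nunique()) if len(cases) else 0
        summary["n_concordant"] = int(cases["transcript_concordant"].sum()) if len(cases) else 0
        summary["concordance_fraction"] = (
            cc.concordance_fraction(cases) if len(cases) else float("nan")
        )
        points = cc.support_points(cases, out["profiles"], out["read_profiles"])
        out["support_points"] = points
        try:
            out["correlations"] = cc.support_correlation(points)
        except UndefinedCorrelationError:
            out["correlations"] = pd.DataFrame(columns=["stratum", "n", "r"])
        log.info("concordance: %d PGE cases, %d transcript-concordant",
                 summary["n_pge_cases"], summary["n_concordant"])
    else:
        summary["stages_skipped"].append("concordance")

    # --------------------------------------------------------------- age bins
    if homology is not None and events is not None:
        lengths = pd.Series(
            {
                e.event_id: 3 * e.region_length_aa
                for e in typed_events.values()
            }
        )
        curated = pd.Series(
            {
                e.event_id: e.age_label.value
                for e in typed_events.values()
                if e.age_label is not AgeBin.UNKNOWN
            },
            dtype=str,
        )
        ages = evo.annotate_ages(homology, exon_lengths_bases=lengths, curated=curated)
        out["ages"] = ages
        summary["n_aged"] = int((ages["bin"] != AgeBin.UNKNOWN.value).sum())
    else:
        summary["stages_skipped"].append("age")

    # --------------------------------------------------------------- disorder
    if scores is not None and events is not None:
        calls = []
        by_region = {
            rid: grp.sort_values("position")["score"].to_list()
            for rid, grp in scores.groupby("region_id")
        }
        for e in typed_events.values():
            regions = {
                s: by_region[f"{e.event_id}|{s}"]
                for s in ("a", "b")
                if f"{e.event_id}|{s}" in by_region
            }
            if not regions and e.region_length_aa >= dis.MIN_EVENT_LENGTH_AA:
                continue
            try:
                calls.append(dis.call_event_disorder(e, regions))
            except IncompleteInputError:
                log.warning("%s: incomplete disorder regions, skipped", e.event_id)
        out["disorder"] = calls
        summary["n_disorder_called"] = sum(not c.excluded for c in calls)
        summary["n_disorder_excluded"] = sum(c.excluded for c in calls)
    else:
        summary["stages_skipped"].append("disorder")

    out["event_summary"] = _event_summary(out, typed_events)
    return out


def _event_summary(out: dict, typed_events: dict) -> pd.DataFrame:
    rows = []
    flags = out.get("specificity_flags")
    flags = flags.set_index("event_id") if flags is not None else None
    ages = out.get("ages")
    ages = ages.set_index("exon_id") if ages is not None else None
    disorder = {c.event_id: c for c in out.get("disorder", [])}
    tcalls = out.get("transcript_calls")
    profiles = out.get("profiles", {})
    for eid, e in sorted(typed_events.items()):
        t = g = False
        if flags is not None and eid in flags.index:
            t = bool(flags.loc[eid, "tissue_specific"])
            g = bool(flags.loc[eid, "group_specific"])
        tr_groups = ""
        if tcalls is not None:
            sel = tcalls[(tcalls["event_id"] == eid) & (tcalls["enriched_side"] != "none")]
            tr_groups = ";".join(sorted(sel["group"]))
        d = disorder.get(eid)
        rows.append(
            (
                eid,
                e.gene_id,
                e.mechanism.value,
                e.effect.value,
                eid in profiles,
                t,
                g,
                t or g,
                tr_groups,
                ages.loc[eid, "bin"] if ages is not None and eid in ages.index else "",
                ages.loc[eid, "source"] if ages is not None and eid in ages.index else "",
                d.fraction_disordered if d and not d.excluded else float("nan"),
                bool(d.disordered) if d else False,
                bool(d.excluded) if d else False,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id", "gene_id", "mechanism", "effect", "passed_filter",
            "tissue_specific", "group_specific", "specific",
            "transcript_groups", "age_bin", "age_source",
            "disorder_fraction", "disordered", "disorder_excluded",
        ],
    )


def run_pipeline(config: RunConfig) -> dict:
    """File-based pipeline: read inputs, run all stages, write the bundle."""
    schema = sio.read_schema(config.schema) if config.schema else None
    result = run_analysis(
        events=sio.read_events(config.events) if config.events else None,
        detections=sio.read_detections(config.detections) if config.detections else None,
        reads=sio.read_reads(config.reads) if config.reads else None,
        scores=sio.read_scores(config.scores) if config.scores else None,
        homology=sio.read_homology(config.homology) if config.homology else None,
        schema=schema,
        config=config,
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if "profiles" in result:
        sio.write_tsv(pe.profiles_to_frame(list(result["profiles"].values())),
                      outdir / "ped_profiles.tsv", ["event_id", "unit_kind", "unit", "side"])
        sio.write_tsv(result["protein_calls"], outdir / "protein_calls.tsv",
                      ["event_id", "unit_kind", "unit", "comparison"])
        sio.write_tsv(result["specificity_flags"], outdir / "specificity_flags.tsv",
                      ["event_id"])
    if "transcript_calls" in result:
        sio.write_tsv(result["transcript_calls"], outdir / "transcript_calls.tsv",
                      ["event_id", "group"])
    if "pge_cases" in result:
        sio.write_tsv(result["pge_cases"], outdir / "pge_cases.tsv", ["event_id", "group"])
        sio.write_tsv(result["concordance_by_group"], outdir / "concordance_by_group.tsv",
                      ["group"])
        sio.write_tsv(result["pairwise"], outdir / "concordance_pairwise.tsv",
                      ["group1", "group2"])
        sio.write_tsv(result["support_points"], outdir / "support_points.tsv",
                      ["event_id", "group"])
        sio.write_tsv(result["correlations"], outdir / "correlations.tsv", ["stratum"])
    if "ages" in result:
        sio.write_tsv(result["ages"], outdir / "event_ages.tsv", ["exon_id"])
    if "disorder" in result:
        ddf = pd.DataFrame(
            [
                (c.event_id, c.fraction_disordered, c.disordered, c.excluded)
                for c in result["disorder"]
            ],
            columns=["event_id", "fraction", "disordered", "excluded"],
        )
        sio.write_tsv(ddf, outdir / "disorder_calls.tsv", ["event_id"])
    sio.write_tsv(result["event_summary"], outdir / "event_summary.tsv", ["event_id"])

    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(result["summary"], fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result
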