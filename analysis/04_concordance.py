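#!/usr/bin/env python
"""Protein/transcript concordance of group-specific splicing.

Builds the protein group-enrichment case set (significant, enriched
direction, shared groups, blood excluded), intersects it with the
transcript-level calls, compares per-group concordance proportions by
pairwise Fisher tests and correlates percent PED support with percent
read support.  Scatter figures go under scratch/figures/.
"""

from pathlib import Path

import pandas as pd

from spliceprot import concordance as cc
from spliceprot import io as sio
from spliceprot.plots import support_scatter
from spliceprot.proteomics import build_profiles, filter_events
from spliceprot.reference import SHARED_GROUPS, TRANSCRIPTOMICS_GROUPS
from spliceprot.transcript_tests import call_all_transcript

BASE = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "figures"


def main() -> None:
    schema = sio.read_schema(BASE / "cohort" / "schema.tsv")
    detections = sio.read_detections(BASE / "cohort" / "detections.tsv")
    profiles = {p.event_id: p for p in
                filter_events(build_profiles(detections, schema))}
    protein_calls = pd.read_csv(BASE / "protein" / "protein_calls.tsv", sep="\t")
    reads = sio.read_reads(BASE / "cohort" / "reads.tsv")
    tcalls, rprofiles = call_all_transcript(reads, TRANSCRIPTOMICS_GROUPS)

    pge = cc.build_pge_cases(protein_calls, SHARED_GROUPS)
    cases, by_group, pairwise = cc.concordance_summary(pge, tcalls)
    points = cc.support_points(cases, profiles, rprofiles)
    corr = cc.support_correlation(points)

    out = BASE / "concordance"
    sio.write_tsv(cases, out / "pge_cases.tsv", ["event_id", "group"])
    sio.write_tsv(by_group, out / "concordance_by_group.tsv", ["group"])
    sio.write_tsv(pairwise, out / "concordance_pairwise.tsv", ["group1", "group2"])
    sio.write_tsv(points, out / "support_points.tsv", ["event_id", "group"])
    sio.write_tsv(corr, out / "correlations.tsv", ["stratum"])
    figures = support_scatter(points, SCRATCH)

    frac = cc.concordance_fraction(cases) if len(cases) else float("nan")
    print(f"{len(cases)} protein group-enrichment cases from "
          f"{cases['event_id'].nunique()} events")
    print(f"{int(cases['transcript_concordant'].sum())} concordant at the "
          f"transcript level ({100 * frac:.1f}%)")
    print("per-stratum PED/read support correlations:")
    for row in corr.itertuples(index=False):
        print(f"  {row.stratum}: r = {row.r:.3f} (n = {row.n})")
    print(f"{len(figures)} scatter figures -> {SCRATCH}")


if __name__ == "__main__":
    main()
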