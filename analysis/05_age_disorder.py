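#!/usr/bin/env python
"""Evolutionary age bins and intrinsic disorder of the simulated events.

Ages events from the two-mode homology hit table (curated labels take
precedence), calls disorder on the event regions, and summarises both
against the protein-level specificity flags — the age-by-specificity
and disorder-by-specificity breakdowns of the analysis.
"""

from pathlib import Path

import pandas as pd

from spliceprot import io as sio
from spliceprot.disorder import MIN_EVENT_LENGTH_AA, call_event_disorder
from spliceprot.evolution import annotate_ages
from spliceprot.pipeline import events_from_frame

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    events = sio.read_events(BASE / "cohort" / "events.tsv")
    typed = events_from_frame(events)
    hits = sio.read_homology(BASE / "cohort" / "homology.tsv")
    scores = sio.read_scores(BASE / "cohort" / "scores.tsv")
    flags = pd.read_csv(BASE / "protein" / "specificity_flags.tsv", sep="\t")

    lengths = pd.Series({e.event_id: 3 * e.region_length_aa for e in typed.values()})
    curated = pd.Series({e.event_id: e.age_label.value for e in typed.values()
                         if e.age_label.value != "unknown"}, dtype=str)
    ages = annotate_ages(hits, exon_lengths_bases=lengths, curated=curated)

    by_region = {rid: g.sort_values("position")["score"].to_list()
                 for rid, g in scores.groupby("region_id")}
    rows = []
    for e in typed.values():
        regions = {s: by_region[f"{e.event_id}|{s}"]
                   for s in ("a", "b") if f"{e.event_id}|{s}" in by_region}
        if not regions and e.region_length_aa >= MIN_EVENT_LENGTH_AA:
            continue
        c = call_event_disorder(e, regions)
        rows.append((c.event_id, c.fraction_disordered, c.disordered, c.excluded))
    disorder = pd.DataFrame(rows, columns=["event_id", "fraction", "disordered",
                                           "excluded"])

    out = BASE / "annotation"
    sio.write_tsv(ages, out / "event_ages.tsv", ["exon_id"])
    sio.write_tsv(disorder, out / "disorder_calls.tsv", ["event_id"])

    merged = ages.merge(flags, left_on="exon_id", right_on="event_id")
    print("age bins among specific vs non-specific events:")
    print(merged.groupby(["specific", "bin"]).size().unstack(fill_value=0))
    called = disorder[~disorder["excluded"]].merge(flags, on="event_id")
    for spec, sub in called.groupby("specific"):
        label = "specific" if spec else "non-specific"
        print(f"{100 * sub['disordered'].mean():.1f}% of {label} events disordered "
              f"(n = {len(sub)})")
    print(f"{int(disorder['excluded'].sum())} events of <= 4 aa excluded from disorder")


if __name__ == "__main__":
    main()
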