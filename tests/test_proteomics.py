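"""PED counting, event profiles and the minimum-support filter."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import detections_frame
from spliceprot.errors import SchemaError, ValidationError
from spliceprot.proteomics import (
    build_ped_profile,
    count_peds,
    filter_events,
    profiles_to_frame,
)


def test_count_peds_distinct_experiments():
    det = detections_frame(
        [
            ("PEP1", "G", "EV", "a", "e1", "cortex"),
            ("PEP1", "G", "EV", "a", "e2", "cortex"),
            ("PEP1", "G", "EV", "a", "e2", "cortex"),  # duplicate detection
        ]
    )
    assert count_peds(det, "PEP1") == 2
    assert count_peds(det, "ABSENT") == 0


def test_profile_counts_per_side_and_tissue(small_schema):
    rows = []
    for i in range(3):
        rows.append((f"PA", "G", "EV", "a", f"cortex_r{i+1}", "cortex"))
    for i in range(3):
        rows.append((f"PB", "G", "EV", "b", f"heart_r{i+1}", "heart"))
    prof = build_ped_profile("EV", detections_frame(rows), small_schema)
    # equal totals: tie broken lexicographically, side "a" becomes main
    assert prof.side_map == {"main": "a", "alternative": "b"}
    assert prof.tissue_counts.loc["cortex", "main"] == 3
    assert prof.tissue_counts.loc["heart", "alternative"] == 3
    assert prof.tissue_counts.drop(index=["cortex", "heart"]).to_numpy().sum() == 0


def test_main_side_is_side_with_most_peds(small_schema):
    rows = [("PA", "G", "EV", "a", "cortex_r1", "cortex")]
    rows += [("PB", "G", "EV", "b", f"heart_r{i+1}", "heart") for i in range(3)]
    prof = build_ped_profile("EV", detections_frame(rows), small_schema)
    assert prof.side_map["main"] == "b"
    assert prof.total("main") == 3
    assert prof.total("alternative") == 1


def test_group_counts_sum_member_tissues(small_schema):
    rows = [
        ("PA", "G", "EV", "a", "cortex_r1", "cortex"),
        ("PA", "G", "EV", "a", "retina_r1", "retina"),
        ("PX", "G", "EV", "intersect", "colon_r1", "colon"),
    ]
    prof = build_ped_profile("EV", detections_frame(rows), small_schema)
    groups = prof.group_counts()
    assert groups.loc["nervous", "main"] == 2  # cortex + retina
    assert groups.loc["digestive", "intersect"] == 1
    for side in ("main", "alternative", "intersect"):
        assert groups[side].sum() == prof.tissue_counts[side].sum()


def test_unknown_tissue_raises(small_schema):
    det = detections_frame([("P", "G", "EV", "a", "x_r1", "spleen")])
    with pytest.raises(SchemaError):
        build_ped_profile("EV", det, small_schema)


@given(st.permutations(range(6)))
@settings(max_examples=40, derandomize=True)
def test_profile_invariant_to_row_order(small_schema, order):
    rows = [
        ("PA", "G", "EV", "a", "cortex_r1", "cortex"),
        ("PA", "G", "EV", "a", "cortex_r2", "cortex"),
        ("PB", "G", "EV", "b", "heart_r1", "heart"),
        ("PB", "G", "EV", "b", "heart_r2", "heart"),
        ("PX", "G", "EV", "intersect", "colon_r1", "colon"),
        ("PX", "G", "EV", "intersect", "colon_r2", "colon"),
    ]
    base = build_ped_profile("EV", detections_frame(rows), small_schema)
    shuffled = build_ped_profile(
        "EV", detections_frame([rows[i] for i in order]), small_schema
    )
    pd.testing.assert_frame_equal(base.tissue_counts, shuffled.tissue_counts)


def test_adding_a_detection_never_decreases_counts(small_schema):
    rows = [
        ("PA", "G", "EV", "a", "cortex_r1", "cortex"),
        ("PB", "G", "EV", "b", "heart_r1", "heart"),
    ]
    before = build_ped_profile("EV", detections_frame(rows), small_schema)
    rows.append(("PA", "G", "EV", "a", "retina_r1", "retina"))
    after = build_ped_profile("EV", detections_frame(rows), small_schema)
    # "a" stays main (2 vs 1), so counts are comparable side by side
    assert (after.tissue_counts >= before.tissue_counts).all().all()


@pytest.mark.parametrize(
    "n_main,n_alt,kept",
    [(3, 3, True), (12, 2, False), (0, 50, False), (3, 2, False), (50, 3, True)],
)
def test_minimum_three_peds_per_side(small_schema, n_main, n_alt, kept):
    """Each side needs at least three PEDs; one weak side excludes the event."""
    exps = [
        (t, f"{t}_r{i+1}")
        for t in small_schema.tissues
        for i in range(small_schema.n_experiments[t])
    ]
    rows = []
    for j in range(n_main):
        t, e = exps[j % len(exps)]
        rows.append((f"PM{j // len(exps)}", "G", "EV", "a", e, t))
    for j in range(n_alt):
        t, e = exps[j % len(exps)]
        rows.append((f"PL{j // len(exps)}", "G", "EV", "b", e, t))
    if n_main + n_alt == 0:
        return
    prof = build_ped_profile("EV", detections_frame(rows), small_schema)
    assert (prof in filter_events([prof])) is kept


def test_filter_requires_positive_threshold(small_schema):
    with pytest.raises(ValidationError):
        filter_events([], min_peds=0)


def test_profiles_long_format_conserves_totals(small_schema):
    rows = [
        ("PA", "G", "EV", "a", "cortex_r1", "cortex"),
        ("PB", "G", "EV", "b", "heart_r1", "heart"),
    ]
    prof = build_ped_profile("EV", detections_frame(rows), small_schema)
    long = profiles_to_frame([prof])
    for side in ("main", "alternative"):
        tissue_sum = long[(long.unit_kind == "tissue") & (long.side == side)]["ped"].sum()
        group_sum = long[(long.unit_kind == "group") & (long.side == side)]["ped"].sum()
        assert tissue_sum == group_sum == prof.total(side)
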