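"""One-vs-rest Fisher tests: table construction, exactness, call logic."""

import numpy as np
import pandas as pd
import pytest

from conftest import detections_frame, fisher_enumeration
from spliceprot.errors import SchemaError, ValidationError
from spliceprot.proteomics import build_ped_profile
from spliceprot.protein_tests import (
    call_specificity,
    event_specificity_flags,
    fisher_two_sided,
    make_table,
)


def _profile(small_schema, main_by_tissue, alt_by_tissue, intersect_by_tissue=None):
    rows = []
    for side, counts in (("a", main_by_tissue), ("b", alt_by_tissue),
                         ("intersect", intersect_by_tissue or {})):
        for tissue, n in counts.items():
            for i in range(n):
                exp = f"{tissue}_r{i % small_schema.n_experiments[tissue] + 1}"
                rows.append((f"P{side}{i}", "G", "EV", side, exp, tissue))
    return build_ped_profile("EV", detections_frame(rows), small_schema)


def test_make_table_direct_construction(small_schema):
    prof = _profile(small_schema, {"cortex": 5, "heart": 5}, {"heart": 10})
    # main=a (10 vs 10, lexicographic tie), nervous unit holds 5 main, 0 alt
    table = make_table(prof, "nervous", "main_vs_alt", "group")
    assert table.tolist() == [[5, 5], [0, 10]]
    # margins equal side totals
    assert table.sum(axis=1).tolist() == [prof.total("main"), prof.total("alternative")]


def test_make_table_empty_unit_is_valid(small_schema):
    prof = _profile(small_schema, {"cortex": 3}, {"heart": 3})
    table = make_table(prof, "digestive", "main_vs_alt", "group")
    assert table[:, 0].tolist() == [0, 0]


def test_make_table_unknown_unit(small_schema):
    prof = _profile(small_schema, {"cortex": 3}, {"heart": 3})
    with pytest.raises(SchemaError):
        make_table(prof, "spleen", "main_vs_alt", "group")


def test_fisher_known_values():
    assert fisher_two_sided(np.array([[2, 2], [2, 2]])) == pytest.approx(1.0)
    # perfect segregation of 5 vs 5: 2/C(10,5)
    assert fisher_two_sided(np.array([[5, 0], [0, 5]])) == pytest.approx(2 / 252, abs=1e-12)


def test_fisher_reported_group_comparison():
    """Nervous vs digestive concordance counts give p far below 1e-5."""
    assert fisher_two_sided(np.array([[32, 46], [7, 78]])) < 1e-5


def test_fisher_matches_enumeration_oracle():
    rng = np.random.default_rng(1234)
    worst = 0.0
    for _ in range(400):
        n = int(rng.integers(1, 61))
        cells = rng.multinomial(n, rng.dirichlet(np.ones(4)))
        table = cells.reshape(2, 2)
        worst = max(worst, abs(fisher_two_sided(table) - fisher_enumeration(table)))
    assert worst < 1e-12


def test_fisher_row_swap_symmetry():
    rng = np.random.default_rng(7)
    for _ in range(50):
        t = rng.integers(0, 20, size=(2, 2))
        assert fisher_two_sided(t) == pytest.approx(fisher_two_sided(t[::-1]), abs=1e-12)


def test_fisher_proportional_tables_stay_null():
    """Scaling both rows proportionally never manufactures association."""
    for k in (1, 2, 5):
        assert fisher_two_sided(np.array([[3 * k, 6 * k], [1 * k, 2 * k]])) == pytest.approx(1.0)


def test_identical_distributions_never_significant(small_schema):
    prof = _profile(small_schema, {"cortex": 4, "heart": 4}, {"cortex": 4, "heart": 4})
    calls = call_specificity(prof, alpha=0.05)
    assert not calls["significant"].any()


def test_constructed_enrichment_detected(small_schema):
    """Alt side restricted to nervous tissue yields a significant nervous call."""
    prof = _profile(
        small_schema,
        {"cortex": 3, "heart": 3, "colon": 3},  # main spread out
        {"cortex": 5, "retina": 4},             # alt only nervous
        {"cortex": 2, "heart": 2, "colon": 2},
    )
    table = make_table(prof, "nervous", "main_vs_alt", "group")
    expected_p = fisher_enumeration(table)
    calls = call_specificity(prof, alpha=0.05, unit_level="group")
    row = calls[(calls.unit == "nervous") & (calls.comparison == "main_vs_alt")].iloc[0]
    assert row["p_value"] == pytest.approx(expected_p, abs=1e-12)
    assert row["significant"] and row["enriched_side"] == "alternative"
    assert row["direction"] == "enriched"


def test_two_distinct_enrichments_for_one_event(small_schema):
    """One event can be alt-enriched in one group and main-enriched in another."""
    prof = _profile(
        small_schema,
        {"heart": 9, "colon": 3},   # main concentrated in muscle (larger total)
        {"cortex": 7, "retina": 4}, # alt concentrated in nervous
        {"cortex": 3, "heart": 3, "colon": 3},
    )
    calls = call_specificity(prof, alpha=0.05, unit_level="group")
    sig = calls[(calls.comparison == "main_vs_alt") & calls.significant]
    by_unit = dict(zip(sig["unit"], sig["enriched_side"]))
    assert by_unit.get("nervous") == "alternative"
    assert by_unit.get("muscle") == "main"


def test_alpha_validation(small_schema):
    prof = _profile(small_schema, {"cortex": 3}, {"heart": 3})
    with pytest.raises(ValidationError):
        call_specificity(prof, alpha=1.5)


def test_event_flags_follow_main_vs_alt_calls(small_schema):
    prof = _profile(
        small_schema,
        {"cortex": 3, "heart": 3, "colon": 3},
        {"cortex": 5, "retina": 4},
    )
    calls = call_specificity(prof, alpha=0.05)
    flags = event_specificity_flags(calls)
    assert flags.loc[0, "specific"] == bool(
        calls[(calls.comparison == "main_vs_alt") & calls.significant].shape[0]
    )


def test_null_simulation_is_conservative(small_schema):
    """Per-test false-positive rate stays at or below alpha under the null."""
    rng = np.random.default_rng(99)
    tissues = list(small_schema.tissues)
    n_sig = n_tests = 0
    for _ in range(150):
        weights = rng.dirichlet(np.ones(len(tissues)))
        main = dict(zip(tissues, rng.multinomial(25, weights)))
        alt = dict(zip(tissues, rng.multinomial(25, weights)))
        prof = _profile(small_schema, main, alt)
        calls = call_specificity(prof, alpha=0.05, unit_level="group",
                                 comparisons=["main_vs_alt"])
        n_sig += int(calls["significant"].sum())
        n_tests += len(calls)
    assert n_sig / n_tests <= 0.08
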