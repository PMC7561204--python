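"""PGE case construction, concordance counting and support correlations."""

import numpy as np
import pandas as pd
import pytest

from conftest import fisher_enumeration
from spliceprot.concordance import (
    build_pge_cases,
    concordance_fraction,
    concordance_summary,
    pct_support,
    support_correlation,
)
from spliceprot.errors import UndefinedCorrelationError, UndefinedSupportError

SHARED = ("digestive", "liver", "muscle", "nervous", "reproductive", "urinary")


def _call(event, unit, unit_kind="group", comparison="main_vs_alt", sig=True,
          side="alternative", direction="enriched", p=0.001):
    return {
        "event_id": event, "unit_kind": unit_kind, "unit": unit,
        "comparison": comparison, "p_value": p, "significant": sig,
        "enriched_side": side, "direction": direction,
    }


def test_multi_group_enrichment_yields_one_case_per_group():
    calls = pd.DataFrame([
        _call("EV1", "nervous"),
        _call("EV1", "muscle", side="main"),
        _call("EV2", "digestive"),
    ])
    cases = build_pge_cases(calls, SHARED)
    assert len(cases) == 3
    assert len(cases[cases.event_id == "EV1"]) == 2


def test_blood_and_depleted_and_tissue_only_are_excluded():
    calls = pd.DataFrame([
        _call("EV1", "nervous"),                               # admitted
        _call("EV1", "blood", side="main"),                    # excluded group
        _call("EV2", "muscle", direction="depleted"),          # depleted signal
        _call("EV3", "frontal_cortex", unit_kind="tissue"),    # tissue level only
        _call("EV4", "nervous", sig=False),                    # not significant
    ])
    cases = build_pge_cases(calls, SHARED + ("blood",), excluded_groups=("blood",))
    assert cases["event_id"].tolist() == ["EV1"]
    assert cases["group"].tolist() == ["nervous"]


def test_pct_support_values_and_bounds():
    assert pct_support({"nervous": 5, "other": 0}, "nervous") == 100.0
    assert pct_support({"nervous": 3, "other": 9}, "nervous") == 25.0
    assert pct_support({"nervous": 0, "other": 9}, "nervous") == 0.0
    with pytest.raises(UndefinedSupportError):
        pct_support({"nervous": 0, "other": 0}, "nervous")


def _transcript_calls(pairs):
    return pd.DataFrame(
        [
            {"event_id": e, "group": g, "enriched_side": "alternative",
             "z_main": -1.0, "z_alt": 1.0}
            for e, g in pairs
        ]
    )


def test_concordance_counts_and_pairwise_fisher():
    # nervous: 32 of 78 transcript-enriched events also protein-enriched;
    # digestive: 7 of 85
    tr_pairs = [(f"N{i}", "nervous") for i in range(78)]
    tr_pairs += [(f"D{i}", "digestive") for i in range(85)]
    pge = pd.DataFrame(
        [{"event_id": f"N{i}", "group": "nervous", "enriched_side": "alternative"}
         for i in range(32)]
        + [{"event_id": f"D{i}", "group": "digestive", "enriched_side": "alternative"}
           for i in range(7)]
    )
    cases, by_group, pairwise = concordance_summary(pge, _transcript_calls(tr_pairs))
    assert cases["transcript_concordant"].all()
    g = by_group.set_index("group")
    assert (g.loc["nervous", "n_transcript_enriched"], g.loc["nervous", "n_also_protein"]) == (78, 32)
    p = pairwise.iloc[0]["p_value"]
    assert p == pytest.approx(fisher_enumeration([[32, 46], [7, 78]]), abs=1e-12)
    assert p < 1e-5


def test_identical_proportions_give_p_one():
    tr_pairs = [(f"A{i}", "muscle") for i in range(10)]
    tr_pairs += [(f"B{i}", "liver") for i in range(20)]
    pge = pd.DataFrame(
        [{"event_id": f"A{i}", "group": "muscle", "enriched_side": "main"} for i in range(5)]
        + [{"event_id": f"B{i}", "group": "liver", "enriched_side": "main"} for i in range(10)]
    )
    _, _, pairwise = concordance_summary(pge, _transcript_calls(tr_pairs))
    assert pairwise.iloc[0]["p_value"] == pytest.approx(1.0)


def test_concordance_fraction_and_order_invariance():
    pge = pd.DataFrame(
        [
            {"event_id": "E1", "group": "nervous", "enriched_side": "main"},
            {"event_id": "E2", "group": "muscle", "enriched_side": "main"},
        ]
    )
    tr = _transcript_calls([("E1", "nervous"), ("E2", "muscle")])
    cases, _, _ = concordance_summary(pge, tr)
    assert concordance_fraction(cases) == 1.0
    cases_rev, _, _ = concordance_summary(pge.iloc[::-1].reset_index(drop=True), tr)
    assert concordance_fraction(cases_rev) == 1.0


def _points(x, y, group="nervous"):
    return pd.DataFrame(
        {
            "event_id": [f"E{i}" for i in range(len(x))],
            "group": group,
            "pct_ped_enriched_side": x,
            "pct_ped_depleted_side": 0.0,
            "pct_reads_enriched_side": y,
        }
    )


def test_correlation_limits():
    x = [10.0, 40.0, 70.0, 95.0]
    r = support_correlation(_points(x, x))
    assert r.iloc[0]["r"] == pytest.approx(1.0)
    r = support_correlation(_points(x, [100 - v for v in x]))
    assert r.iloc[0]["r"] == pytest.approx(-1.0)


def test_constant_vector_is_undefined():
    with pytest.raises(UndefinedCorrelationError):
        support_correlation(_points([50.0] * 4, [1.0, 2.0, 3.0, 4.0]))


def test_detection_noise_degrades_correlation():
    """Heavy noise on one axis lowers |r| versus the noiseless stratum."""
    rng = np.random.default_rng(11)
    x = rng.uniform(0, 100, 60)
    clean = support_correlation(_points(x, x))
    noisy_y = np.clip(x + rng.normal(0, 40, x.size), 0, 100)
    noisy = support_correlation(_points(x, noisy_y))
    assert abs(noisy.iloc[0]["r"]) < abs(clean.iloc[0]["r"])


def test_spearman_flag_and_small_strata_skipped():
    pts = _points([1.0, 2.0], [2.0, 4.0])  # below min_points
    assert support_correlation(pts).empty
    pts = _points([1.0, 5.0, 30.0, 80.0], [2.0, 9.0, 60.0, 90.0])
    r = support_correlation(pts, method="spearman")
    assert r.iloc[0]["r"] == pytest.approx(1.0)
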