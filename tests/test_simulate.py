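"""Simulator: determinism, validity of generated tables, recovery scoring."""

import numpy as np
import pandas as pd
import pytest

from spliceprot.errors import ConfigError
from spliceprot.pipeline import run_analysis
from spliceprot.proteomics import build_profiles
from spliceprot.reference import reference_proteomics_schema
from spliceprot.simulate import SimulationConfig, recovery_report, simulate_cohort


def test_same_seed_identical_outputs():
    a = simulate_cohort(SimulationConfig(n_events=15, seed=5))
    b = simulate_cohort(SimulationConfig(n_events=15, seed=5))
    for name in ("events", "truth", "detections", "reads", "scores", "homology"):
        pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))
    c = simulate_cohort(SimulationConfig(n_events=15, seed=6))
    assert not a.detections.equals(c.detections)


def test_config_validation():
    with pytest.raises(ConfigError):
        SimulationConfig(seed=None)
    with pytest.raises(ConfigError):
        SimulationConfig(seed=1, p_detect=1.5)
    with pytest.raises(ConfigError):
        SimulationConfig(seed=1, psi_target=0.5, psi_background=0.5,
                         fraction_specific=0.3)


def test_reference_schema_matches_cohort_description():
    schema = reference_proteomics_schema()
    assert len(schema.tissues) == 30
    assert schema.total_experiments == 79
    assert len(schema.group_names) == 10
    assert schema.tissues_in_group("nervous") == [
        "fetal_brain", "frontal_cortex", "retina", "spinal_cord",
    ]


def test_simulated_tables_pass_ingest(default_cohort, tmp_path):
    """Every generated table round-trips through its reader unchanged-enough
    to drive the full pipeline without validation errors."""
    cfg, cohort = default_cohort
    result = run_analysis(
        events=cohort.events,
        detections=cohort.detections,
        reads=cohort.reads,
        scores=cohort.scores,
        homology=cohort.homology,
        schema=cfg.schema,
    )
    assert result["summary"]["stages_skipped"] == []
    assert result["summary"]["n_events_input"] == cfg.n_events


def test_expected_ped_count_matches_detection_model():
    """E[PED] of an intersect peptide = p_detect x 79 experiments."""
    cfg = SimulationConfig(n_events=40, fraction_specific=0.0, p_detect=0.4, seed=77)
    cohort = simulate_cohort(cfg)
    inter = cohort.detections[cohort.detections["side"] == "intersect"]
    peds = inter.groupby("peptide").size()
    expected = cfg.p_detect * cfg.schema.total_experiments  # 31.6
    n = cfg.n_events * cfg.n_intersect_peptides
    se = np.sqrt(expected * (1 - cfg.p_detect) / n)
    assert abs(peds.reindex([f"EV{i:04d}_intersect_p{j}" for i in range(cfg.n_events)
                             for j in range(cfg.n_intersect_peptides)], fill_value=0).mean()
               - expected) < 4 * se


def test_read_group_sums_scale_with_expression():
    lo = simulate_cohort(SimulationConfig(n_events=30, read_mean=20, seed=9,
                                          read_dispersion=0.0))
    hi = simulate_cohort(SimulationConfig(n_events=30, read_mean=80, seed=9,
                                          read_dispersion=0.0))
    ratio = hi.reads["reads"].sum() / lo.reads["reads"].sum()
    assert ratio == pytest.approx(4.0, rel=0.05)


def test_recovery_near_perfect_information():
    """With near-deterministic detection and strong usage shifts every stage
    recovers the truth almost perfectly."""
    cfg = SimulationConfig(
        n_events=40, fraction_specific=0.5, psi_target=0.95, psi_background=0.05,
        p_detect=0.95, read_dispersion=0.01, seed=314,
    )
    cohort = simulate_cohort(cfg)
    res = run_analysis(
        events=cohort.events, detections=cohort.detections, reads=cohort.reads,
        scores=cohort.scores, homology=cohort.homology, schema=cfg.schema,
    )
    report = recovery_report(
        cohort,
        protein_calls=res["protein_calls"],
        ped_profiles=res["profiles"],
        transcript_calls=res["transcript_calls"],
        read_profiles=res["read_profiles"],
        age_table=res["ages"],
        disorder_calls=res["disorder"],
    )
    assert report["protein_sensitivity"] >= 0.9
    assert report["transcript_sensitivity"] >= 0.9
    assert report["age_bin_accuracy"] >= 0.95
    assert report["disorder_accuracy"] >= 0.9


def test_shuffled_truth_recovers_at_chance(strong_cohort):
    """Randomly re-assigned target groups destroy apparent sensitivity."""
    cfg, cohort = strong_cohort
    res = run_analysis(events=cohort.events, detections=cohort.detections,
                       schema=cfg.schema)
    true_rep = recovery_report(cohort, protein_calls=res["protein_calls"],
                               ped_profiles=res["profiles"])
    shuffled = cohort.truth.copy()
    rng = np.random.default_rng(0)
    spec = shuffled["specific"]
    groups = [g for g in cfg.target_groups]
    shuffled.loc[spec, "target_group"] = rng.choice(groups, size=int(spec.sum()))
    shuffled.loc[spec, "enriched_side"] = rng.choice(["a", "b"], size=int(spec.sum()))
    import dataclasses
    fake = dataclasses.replace(cohort, truth=shuffled)
    fake_rep = recovery_report(fake, protein_calls=res["protein_calls"],
                               ped_profiles=res["profiles"])
    assert fake_rep["protein_sensitivity"] < true_rep["protein_sensitivity"]
    assert fake_rep["protein_sensitivity"] < 0.5
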