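"""Shared fixtures: a tiny tissue schema and simulated cohorts."""

from __future__ import annotations

from math import comb

import pandas as pd
import pytest

from spliceprot.core import TissueSchema
from spliceprot.simulate import SimulationConfig, simulate_cohort


def fisher_enumeration(table) -> float:
    """Independent two-sided Fisher oracle by hypergeometric enumeration.

    With the margins fixed, sums the probabilities of every table as or
    less probable than the observed one (ties within a 1e-7 relative
    tolerance count as observed, the standard two-sided convention).
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(r2, c1 - a) / denom
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = comb(r1, x) * comb(r2, c1 - x) / denom
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


@pytest.fixture(scope="session")
def small_schema() -> TissueSchema:
    """Two groups, four tissues, ten experiments."""
    return TissueSchema(
        groups={
            "cortex": "nervous",
            "retina": "nervous",
            "heart": "muscle",
            "colon": "digestive",
        },
        n_experiments={"cortex": 3, "retina": 2, "heart": 3, "colon": 2},
    )


def detections_frame(rows) -> pd.DataFrame:
    """Rows of (peptide, gene, event, side, experiment, tissue)."""
    return pd.DataFrame(
        rows,
        columns=["peptide", "gene_id", "event_id", "side", "experiment_id", "tissue"],
    )


@pytest.fixture(scope="session")
def default_cohort():
    """A small cohort at the default study conditions."""
    cfg = SimulationConfig(n_events=60, seed=20210)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def strong_cohort():
    """Strong-effect cohort: psi 0.9 vs 0.1, detection probability 0.8."""
    cfg = SimulationConfig(
        n_events=80,
        fraction_specific=0.5,
        psi_target=0.9,
        psi_background=0.1,
        p_detect=0.8,
        seed=4242,
    )
    return cfg, simulate_cohort(cfg)
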