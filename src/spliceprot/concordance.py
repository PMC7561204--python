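"""Protein/transcript concordance of tissue-group-specific splicing.

From the protein-level enrichment calls a case set is built (one case
per event x shared tissue group with a significant, enrichment-direction
group-level call; blood is excluded because the haematopoietic cells
have no transcriptomics counterpart).  Cases are then intersected with
the transcript-level standard-deviation calls, per-group concordance
counts are compared pairwise by Fisher tests, and percent-support
statistics relate PED support to read support per event side.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedCorrelationError, UndefinedSupportError, ValidationError
from .protein_tests import fisher_two_sided
from .proteomics import PedProfile
from .transcript_tests import ReadProfile

PGE_COLUMNS = ("event_id", "group", "enriched_side", "transcript_concordant")


def build_pge_cases(
    calls: pd.DataFrame,
    shared_groups: Iterable[str],
    excluded_groups: Iterable[str] = ("blood",),
) -> pd.DataFrame:
    """Protein group-enrichment cases from the enrichment-call table.

    Admits only group-level, significant, enrichment-direction
    main-vs-alt calls in shared groups; events significant only at the
    tissue level or with depleted-direction signals contribute nothing.
    An event enriched in k admissible groups yields k cases.
    """
    shared = set(shared_groups) - set(excluded_groups)
    sel = calls[
        (calls["unit_kind"] == "group")
        & (calls["comparison"] == "main_vs_alt")
        & calls["significant"]
        & (calls["direction"] == "enriched")
        & calls["unit"].isin(shared)
    ]
    out = (
        sel[["event_id", "unit", "enriched_side"]]
        .rename(columns={"unit": "group"})
        .drop_duplicates(subset=["event_id", "group"])
        .sort_values(["event_id", "group"])
        .reset_index(drop=True)
    )
    return out


def pct_support(counts_by_unit: Mapping[str, float] | pd.Series, group: str) -> float:
    """Percent of a side's total evidence that falls in one group."""
    s = pd.Series(counts_by_unit, dtype=float)
    total = float(s.sum())
    if total <= 0:
        raise UndefinedSupportError("side total is zero; percent support undefined")
    return 100.0 * float(s.get(group, 0.0)) / total


def concordance_summary(
    pge_cases: pd.DataFrame,
    transcript_calls: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Match protein cases against transcript calls on the same group.

    Returns ``(cases, by_group, pairwise)``:

    * ``cases`` — the PGE table with a ``transcript_concordant`` flag
      (the event is transcript-enriched in the same group);
    * ``by_group`` — per group, the number of transcript-enriched events
      and how many of those are also protein-enriched there;
    * ``pairwise`` — two-sided Fisher tests comparing the per-group
      concordance proportions between all group pairs.
    """
    tr = transcript_calls[transcript_calls["enriched_side"] != "none"]
    tr_pairs = set(zip(tr["event_id"], tr["group"]))
    cases = pge_cases.copy()
    cases["transcript_concordant"] = [
        (e, g) in tr_pairs for e, g in zip(cases["event_id"], cases["group"])
    ]

    pge_pairs = set(zip(pge_cases["event_id"], pge_cases["group"]))
    rows = []
    for g, sub in tr.groupby("group"):
        events = set(sub["event_id"])
        also = sum((e, g) in pge_pairs for e in events)
        rows.append((g, len(events), also))
    by_group = pd.DataFrame(
        rows, columns=["group", "n_transcript_enriched", "n_also_protein"]
    ).sort_values("group").reset_index(drop=True)

    pair_rows = []
    for (_, r1), (_, r2) in combinations(by_group.iterrows(), 2):
        table = [
            [r1["n_also_protein"], r1["n_transcript_enriched"] - r1["n_also_protein"]],
            [r2["n_also_protein"], r2["n_transcript_enriched"] - r2["n_also_protein"]],
        ]
        pair_rows.append((r1["group"], r2["group"], fisher_two_sided(np.array(table))))
    pairwise = pd.DataFrame(pair_rows, columns=["group1", "group2", "p_value"])
    return cases, by_group, pairwise


def concordance_fraction(cases: pd.DataFrame) -> float:
    """Fraction of protein-enrichment cases concordant at the transcript level."""
    if cases.empty:
        raise ValidationError("no protein group-enrichment cases")
    return float(cases["transcript_concordant"].mean())


def support_points(
    cases: pd.DataFrame,
    ped_profiles: Mapping[str, PedProfile],
    read_profiles: Mapping[str, ReadProfile],
) -> pd.DataFrame:
    """Percent-support coordinates per (event, group) case.

    For each case: the percentage of the enriched side's PEDs that fall
    in the case group, the same for the depleted (other) side, and the
    percentage of the enriched side's reads in that group.  Sides with a
    zero total are undefined and the corresponding case is dropped
    rather than recorded as zero.
    """
    rows = []
    for e, g, side in zip(cases["event_id"], cases["group"], cases["enriched_side"]):
        if e not in ped_profiles or e not in read_profiles:
            continue
        other = "alternative" if side == "main" else "main"
        ped = ped_profiles[e].group_counts()
        reads = read_profiles[e].reads
        try:
            pct_ped_enr = pct_support(ped[side], g)
            pct_ped_dep = pct_support(ped[other], g)
            pct_reads_enr = pct_support(reads[side], g)
        except UndefinedSupportError:
            continue
        rows.append((e, g, pct_ped_enr, pct_ped_dep, pct_reads_enr))
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "group",
            "pct_ped_enriched_side",
            "pct_ped_depleted_side",
            "pct_reads_enriched_side",
        ],
    )


def support_correlation(
    points: pd.DataFrame,
    x: str = "pct_ped_enriched_side",
    y: str = "pct_reads_enriched_side",
    stratify_by: Optional[str] = "group",
    method: str = "pearson",
    min_points: int = 3,
) -> pd.DataFrame:
    """Correlation of PED vs read percent support per stratum.

    Strata with fewer than ``min_points`` points are skipped; a constant
    vector within a stratum makes the coefficient undefined and raises.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"method must be pearson|spearman, got {method!r}")
    groups = (
        points.groupby(stratify_by) if stratify_by else [("all", points)]
    )
    rows = []
    for name, sub in groups:
        if len(sub) < min_points:
            continue
        xv, yv = sub[x].to_numpy(float), sub[y].to_numpy(float)
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            raise UndefinedCorrelationError(
                f"stratum {name!r}: constant percent-support vector"
            )
        if method == "pearson":
            r = stats.pearsonr(xv, yv)[0]
        else:
            r = stats.spearmanr(xv, yv)[0]
        rows.append((name, len(sub), float(r)))
    return pd.DataFrame(rows, columns=["stratum", "n", "r"])
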