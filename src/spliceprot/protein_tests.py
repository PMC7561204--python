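"""Protein-level tissue/group specificity via one-vs-rest Fisher exact tests.

For every tissue (or tissue group) and every splice event, three 2x2
contingency tables are built, always comparing the selected unit against
all remaining units: main vs alternative, main vs intersect and
alternative vs intersect.  The main-vs-alternative comparison drives the
event-level specificity call; the two intersect comparisons serve as a
gene-expression background and decide whether a significant signal
reflects genuine enrichment of the winning side or depletion of the
losing side.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import TissueSchema
from .errors import SchemaError, ValidationError
from .proteomics import PedProfile

COMPARISONS = ("main_vs_alt", "main_vs_intersect", "alt_vs_intersect")

_SIDES = {
    "main_vs_alt": ("main", "alternative"),
    "main_vs_intersect": ("main", "intersect"),
    "alt_vs_intersect": ("alternative", "intersect"),
}

CALL_COLUMNS = (
    "event_id",
    "unit_kind",
    "unit",
    "comparison",
    "p_value",
    "significant",
    "enriched_side",
    "direction",
)


def make_table(
    profile: PedProfile,
    unit: str,
    comparison: str,
    unit_kind: str = "group",
) -> np.ndarray:
    """2x2 table: rows = the two compared sides, columns = (unit, rest)."""
    if comparison not in _SIDES:
        raise ValidationError(f"unknown comparison {comparison!r}")
    counts = profile.unit_counts(unit_kind)
    if unit not in counts.index:
        raise SchemaError(f"unknown {unit_kind} {unit!r}")
    sx, sy = _SIDES[comparison]
    x_in = int(counts.loc[unit, sx])
    y_in = int(counts.loc[unit, sy])
    x_tot = int(counts[sx].sum())
    y_tot = int(counts[sy].sum())
    return np.array([[x_in, x_tot - x_in], [y_in, y_tot - y_in]], dtype=int)


def fisher_two_sided(table: np.ndarray) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table of counts."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValidationError("table must be 2x2 with non-negative counts")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _fractions(counts: pd.DataFrame, unit: str) -> dict[str, float]:
    """Within-unit share of each side's total evidence."""
    out = {}
    for side in ("main", "alternative", "intersect"):
        tot = counts[side].sum()
        out[side] = float(counts.loc[unit, side] / tot) if tot > 0 else np.nan
    return out


def _direction(
    winner: str,
    loser: str,
    frac: dict[str, float],
    p_support: dict[str, float],
    alpha: float,
) -> str:
    """Enriched vs depleted annotation for a significant main-vs-alt call.

    The winner is genuinely *enriched* only when its within-unit share
    exceeds the intersect (gene-background) share and the corresponding
    side-vs-intersect test is itself significant; otherwise the signal is
    attributed to *depletion* of the losing side — a main-vs-alt
    difference can arise just as well from the loser being absent from
    the unit as from the winner being concentrated there.  Without an
    informative intersect the winner is taken as enriched.
    """
    f_int = frac["intersect"]
    f_w = frac[winner]
    if np.isnan(f_int):
        return "enriched"
    p_w = p_support.get(winner, 1.0)
    if p_w < alpha and f_w > f_int:
        return "enriched"
    return "depleted"


def call_specificity(
    profile: PedProfile,
    alpha: float = 0.05,
    correction: Optional[str] = None,
    unit_level: str = "both",
    comparisons: Iterable[str] = COMPARISONS,
) -> pd.DataFrame:
    """All one-vs-rest enrichment calls for one event.

    Returns one row per unit x comparison with the exact two-sided
    p-value, the significance flag at ``alpha`` (optionally
    Benjamini-Hochberg corrected across the units of each comparison),
    and — for significant main-vs-alt calls — the enriched side and the
    enriched/depleted direction.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0,1), got {alpha}")
    if correction not in (None, "none", "bh"):
        raise ValidationError(f"correction must be none|bh, got {correction!r}")
    kinds = {"tissue": ("tissue",), "group": ("group",), "both": ("tissue", "group")}
    if unit_level not in kinds:
        raise ValidationError(f"unit_level must be tissue|group|both")
    comparisons = list(comparisons)
    unknown = set(comparisons) - set(COMPARISONS)
    if unknown:
        raise ValidationError(f"unknown comparisons {sorted(unknown)}")

    rows = []
    for kind in kinds[unit_level]:
        counts = profile.unit_counts(kind)
        units = list(counts.index)
        # p-values for the side-vs-intersect support tests, reused for direction
        support: dict[str, dict[str, float]] = {u: {} for u in units}
        for comp in ("main_vs_intersect", "alt_vs_intersect"):
            side = _SIDES[comp][0]
            for u in units:
                support[u][side] = fisher_two_sided(make_table(profile, u, comp, kind))
        for comp in comparisons:
            pvals = {
                u: (
                    support[u][_SIDES[comp][0]]
                    if comp != "main_vs_alt"
                    else fisher_two_sided(make_table(profile, u, comp, kind))
                )
                for u in units
            }
            adjusted = dict(pvals)
            if correction == "bh":
                from statsmodels.stats.multitest import multipletests

                rej, adj, _, _ = multipletests(
                    list(pvals.values()), alpha=alpha, method="fdr_bh"
                )
                adjusted = dict(zip(pvals, adj))
            for u in units:
                sig = bool(adjusted[u] < alpha)
                enriched_side = "none"
                direction = ""
                if comp == "main_vs_alt" and sig:
                    frac = _fractions(counts, u)
                    if frac["main"] >= frac["alternative"]:
                        winner, loser = "main", "alternative"
                    else:
                        winner, loser = "alternative", "main"
                    enriched_side = winner
                    direction = _direction(winner, loser, frac, support[u], alpha)
                elif sig:
                    side = _SIDES[comp][0]
                    frac = _fractions(counts, u)
                    direction = (
                        "enriched" if frac[side] >= frac["intersect"] else "depleted"
                    )
                rows.append(
                    (profile.event_id, kind, u, comp, pvals[u], sig, enriched_side, direction)
                )
    return pd.DataFrame(rows, columns=list(CALL_COLUMNS))


def call_all(
    profiles: Iterable[PedProfile],
    alpha: float = 0.05,
    correction: Optional[str] = None,
    unit_level: str = "both",
    comparisons: Iterable[str] = COMPARISONS,
) -> pd.DataFrame:
    """Concatenated enrichment calls for a set of event profiles."""
    frames = [
        call_specificity(p, alpha=alpha, correction=correction,
                         unit_level=unit_level, comparisons=comparisons)
        for p in profiles
    ]
    if not frames:
        return pd.DataFrame(columns=list(CALL_COLUMNS))
    return pd.concat(frames, ignore_index=True)


def event_specificity_flags(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-event flags: significant main-vs-alt call at tissue/group level."""
    ma = calls[(calls["comparison"] == "main_vs_alt") & calls["significant"]]
    events = sorted(calls["event_id"].unique())
    rows = []
    for e in events:
        sub = ma[ma["event_id"] == e]
        t = bool((sub["unit_kind"] == "tissue").any())
        g = bool((sub["unit_kind"] == "group").any())
        rows.append((e, t, g, t or g))
    return pd.DataFrame(
        rows, columns=["event_id", "tissue_specific", "group_specific", "specific"]
    )
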