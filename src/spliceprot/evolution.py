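"""Evolutionary age of alternative exons from homology-search hit tables.

Homology searches are run in two modes — the translated exon alone and
the exon joined to its flanking exon(s) — against increasingly distant
clades.  Hits with four or more residue insertions are discarded; the
most distant accepted clade in each mode is that mode's predicted age,
and the final age is the *minimum* (most recent) of the two modes.  Ages
are binned into primate (< ~75 My), theria (75-160 My), tetrapoda
(160-400 My) and ancient (> 400 My, predating lobe-finned fish).  Only
exons of at least 42 bases are aged automatically, to limit the error
rate; curated ages, where available, take precedence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .core import AgeBin
from .errors import ValidationError

#: Ordered clade ladder, most recent first.
CLADE_LADDER: tuple[str, ...] = (
    "primates",
    "euarchontoglires",
    "theria",
    "mammalia",
    "tetrapoda",
    "sarcopterygii",
    "vertebrata",
)

_CLADE_RANK = {c: i for i, c in enumerate(CLADE_LADDER)}

#: Clade -> age bin.  A homologue in lobe-finned fish (sarcopterygii) or
#: beyond means the exon predates the split > 400 My ago.
CLADE_BIN: dict[str, AgeBin] = {
    "primates": AgeBin.PRIMATE,
    "euarchontoglires": AgeBin.THERIA,
    "theria": AgeBin.THERIA,
    "mammalia": AgeBin.TETRAPODA,
    "tetrapoda": AgeBin.TETRAPODA,
    "sarcopterygii": AgeBin.ANCIENT,
    "vertebrata": AgeBin.ANCIENT,
}

SEARCH_MODES = ("exon_only", "exon_plus_flanks")

#: Minimum exon length (bases) for automatic age estimation.
MIN_EXON_BASES = 42
#: Maximum residue insertions in an accepted homologous hit ("fewer than four").
MAX_HIT_INSERTIONS = 3


@dataclass(frozen=True)
class HomologyHit:
    exon_id: str
    search_mode: str
    hit_clade: str
    insertion_residues: int

    def __post_init__(self) -> None:
        if self.search_mode not in SEARCH_MODES:
            raise ValidationError(f"unknown search mode {self.search_mode!r}")
        if self.hit_clade not in _CLADE_RANK:
            raise ValidationError(f"unknown clade {self.hit_clade!r}")
        if self.insertion_residues < 0:
            raise ValidationError("insertion count must be non-negative")


@dataclass(frozen=True)
class AgeEstimate:
    exon_id: str
    age_per_mode: dict[str, Optional[int]]  # mode -> clade rank (None if no hits)
    final_rank: Optional[int]

    @property
    def final_clade(self) -> Optional[str]:
        return CLADE_LADDER[self.final_rank] if self.final_rank is not None else None

    @property
    def bin(self) -> AgeBin:
        if self.final_rank is None:
            return AgeBin.UNKNOWN
        return CLADE_BIN[CLADE_LADDER[self.final_rank]]


def eligible_exon(exon_length_bases: int) -> bool:
    """Is the exon long enough (>= 42 bases) for automatic age estimation?"""
    if exon_length_bases < 0:
        raise ValidationError("exon length must be non-negative")
    return exon_length_bases >= MIN_EXON_BASES


def accept_hit(hit: HomologyHit) -> bool:
    """Accept homologous hits with fewer than four residue insertions."""
    return hit.insertion_residues <= MAX_HIT_INSERTIONS


def estimate_age(hits: Iterable[HomologyHit]) -> AgeEstimate:
    """Age estimate for one exon from its (possibly unfiltered) hit list.

    Per mode, the age is the most distant accepted clade; the final age
    is the minimum of the per-mode ages.  A mode with no hits is absent
    and the other mode's age stands alone; with no accepted hit in any
    mode the age is undetermined (reported as such, never defaulted).
    """
    hits = list(hits)
    if not hits:
        return AgeEstimate(exon_id="", age_per_mode={}, final_rank=None)
    exon_ids = {h.exon_id for h in hits}
    if len(exon_ids) != 1:
        raise ValidationError(f"hits span multiple exons: {sorted(exon_ids)}")
    (exon_id,) = exon_ids

    age_per_mode: dict[str, Optional[int]] = {}
    for mode in SEARCH_MODES:
        accepted = [
            _CLADE_RANK[h.hit_clade]
            for h in hits
            if h.search_mode == mode and accept_hit(h)
        ]
        if any(h.search_mode == mode for h in hits):
            age_per_mode[mode] = max(accepted) if accepted else None

    ranks = [r for r in age_per_mode.values() if r is not None]
    final = min(ranks) if ranks else None
    return AgeEstimate(exon_id=exon_id, age_per_mode=age_per_mode, final_rank=final)


def annotate_ages(
    hit_table: pd.DataFrame,
    exon_lengths_bases: Optional[pd.Series] = None,
    curated: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Age table for all exons in a homology hit table.

    ``hit_table`` columns: exon_id, mode, hit_clade, insertions (an
    optional hit_species column is carried but unused).  Exons shorter
    than 42 bases (when lengths are given) are not aged automatically.
    Curated age labels, where present and known, override automatic
    estimates; the ``source`` column records which applied.
    """
    rows = []
    exon_ids = sorted(set(hit_table["exon_id"]))
    if curated is not None:
        exon_ids = sorted(set(exon_ids) | set(curated.index))
    for exon in exon_ids:
        sub = hit_table[hit_table["exon_id"] == exon]
        ineligible = (
            exon_lengths_bases is not None
            and exon in exon_lengths_bases.index
            and not eligible_exon(int(exon_lengths_bases.loc[exon]))
        )
        if sub.empty or ineligible:
            est = AgeEstimate(exon_id=exon, age_per_mode={}, final_rank=None)
        else:
            est = estimate_age(
                HomologyHit(exon, m, c, int(i))
                for m, c, i in zip(sub["mode"], sub["hit_clade"], sub["insertions"])
            )
        bin_, source = est.bin.value, "automatic"
        if curated is not None and exon in curated.index:
            label = str(curated.loc[exon])
            if label and label != AgeBin.UNKNOWN.value:
                bin_, source = label, "curated"
        mode_a = est.age_per_mode.get("exon_only")
        mode_b = est.age_per_mode.get("exon_plus_flanks")
        rows.append(
            (
                exon,
                CLADE_LADDER[mode_a] if mode_a is not None else "",
                CLADE_LADDER[mode_b] if mode_b is not None else "",
                est.final_clade or "",
                bin_,
                source,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["exon_id", "age_mode_a", "age_mode_b", "final_age", "bin", "source"],
    )
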