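"""Domain model for two-sided alternative splicing events.

A splice event is a gene-local choice between two mutually exclusive
sequence outcomes ("sides").  Discriminating peptides or junction reads
support one side or the other; evidence mapping to sequence shared by
both isoforms is the "intersect" and serves as a gene-expression
background.  The side with most supporting evidence is labelled *main*,
the other *alternative*; the labels are assigned independently per
evidence source (proteomics vs transcriptomics).

Events are classified twice: by splicing mechanism (how the transcript
differs) and by the effect on the protein (what the isoforms look like).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .errors import UndeterminedSidesError, ValidationError


class Mechanism(str, enum.Enum):
    """Splicing mechanism generating the event."""

    SKIPPED_EXON = "skipped_exon"
    MUTUALLY_EXCLUSIVE = "mutually_exclusive"
    ALT_5_SPLICE_SITE = "alt_5_splice_site"
    ALT_3_SPLICE_SITE = "alt_3_splice_site"
    ALT_PROMOTER = "alt_promoter"
    ALT_POLYA = "alt_polyA"


class Effect(str, enum.Enum):
    """Effect of the event on the protein product."""

    INDEL = "indel"
    MICRO_INDEL = "micro_indel"
    HOMOLOGOUS_SUBSTITUTION = "homologous_substitution"
    C_TERMINAL_SUBSTITUTION = "c_terminal_substitution"
    N_TERMINAL_SUBSTITUTION = "n_terminal_substitution"
    INTERNAL_SUBSTITUTION = "internal_substitution"
    TWO_PROTEINS = "two_proteins"


class Side(str, enum.Enum):
    MAIN = "main"
    ALTERNATIVE = "alternative"
    INTERSECT = "intersect"


class AgeBin(str, enum.Enum):
    """Evolutionary age bins for splice events/exons."""

    PRIMATE = "primate"        # up to ~75 My
    THERIA = "theria"          # 75-160 My
    TETRAPODA = "tetrapoda"    # 160-400 My
    ANCIENT = "ancient"        # > 400 My, predates lobe-finned fish
    UNKNOWN = "unknown"


#: An indel shorter than four residues is a micro-indel ("smaller than four").
MICRO_INDEL_MAX_AA = 3

_POSITIONS = ("internal", "n_term", "c_term")
_POSITION_EFFECT = {
    "internal": Effect.INTERNAL_SUBSTITUTION,
    "n_term": Effect.N_TERMINAL_SUBSTITUTION,
    "c_term": Effect.C_TERMINAL_SUBSTITUTION,
}


def classify_effect(
    side_a_len: int,
    side_b_len: int,
    position: Optional[str] = None,
    *,
    shares_sequence: bool = True,
    homologous: bool = False,
) -> Effect:
    """Classify the protein-level effect of a splice event.

    Parameters
    ----------
    side_a_len, side_b_len
        Length in amino acids of the region unique to each side.  An
        indel has one side of length zero (the "deletion" side).
    position
        For substitutions: where in the protein the swap occurs
        (``internal``, ``n_term`` or ``c_term``).
    shares_sequence
        Whether the two isoforms share any amino acid sequence at all.
        Isoform pairs with no common sequence are a class of their own.
    homologous
        Curated flag: the substituted regions are homologous (typically
        mutually exclusive homologous exons).

    Precedence: two-proteins > homologous substitution > micro-indel >
    indel > positional substitution.  Indels shorter than four residues
    (e.g. the single-codon gain/loss of tandem NAGNAG acceptor choice)
    are micro-indels.
    """
    if side_a_len < 0 or side_b_len < 0:
        raise ValidationError("side lengths must be non-negative")
    if side_a_len == 0 and side_b_len == 0:
        raise ValidationError("event with no differing sequence on either side")
    if not shares_sequence:
        return Effect.TWO_PROTEINS
    if homologous:
        return Effect.HOMOLOGOUS_SUBSTITUTION
    if min(side_a_len, side_b_len) == 0:
        # one side is an insertion, the other its absence
        if abs(side_a_len - side_b_len) <= MICRO_INDEL_MAX_AA:
            return Effect.MICRO_INDEL
        return Effect.INDEL
    if position not in _POSITIONS:
        raise ValidationError(
            f"substitution requires position in {_POSITIONS}, got {position!r}"
        )
    return _POSITION_EFFECT[position]


def assign_sides(
    evidence_a: float,
    evidence_b: float,
    ids: Sequence[str] = ("a", "b"),
) -> tuple[str, str]:
    """Assign main/alternative labels from total evidence counts.

    The side with strictly more evidence (PEDs or junction reads) is
    *main*.  Ties are broken deterministically: the side whose
    identifier sorts first becomes main.

    Returns ``(main_id, alternative_id)``.
    """
    if evidence_a < 0 or evidence_b < 0:
        raise ValidationError("evidence counts must be non-negative")
    if evidence_a == 0 and evidence_b == 0:
        raise UndeterminedSidesError(
            f"no evidence on either side of {ids[0]!r}/{ids[1]!r}"
        )
    id_a, id_b = ids
    if evidence_a > evidence_b:
        return id_a, id_b
    if evidence_b > evidence_a:
        return id_b, id_a
    ordered = sorted([str(id_a), str(id_b)])
    if ordered[0] == str(id_a):
        return id_a, id_b
    return id_b, id_a


@dataclass(frozen=True)
class SplicingEvent:
    """One alternative splicing event with its two protein sides."""

    event_id: str
    gene_id: str
    mechanism: Mechanism
    effect: Effect
    side_a_len: int
    side_b_len: int
    homologous_flag: bool = False
    age_label: AgeBin = AgeBin.UNKNOWN

    def __post_init__(self) -> None:
        if self.side_a_len < 0 or self.side_b_len < 0:
            raise ValidationError(f"{self.event_id}: negative side length")
        if self.effect is Effect.MICRO_INDEL:
            if abs(self.side_a_len - self.side_b_len) > MICRO_INDEL_MAX_AA:
                raise ValidationError(
                    f"{self.event_id}: micro-indel longer than "
                    f"{MICRO_INDEL_MAX_AA} aa"
                )

    @property
    def region_length_aa(self) -> int:
        """Length of the (longest) differing region, in amino acids."""
        return max(self.side_a_len, self.side_b_len)


@dataclass(frozen=True)
class TissueSchema:
    """Tissue -> group mapping with per-tissue replicate experiment counts.

    The reference proteomics cohort has 30 tissues pooled into 10 groups
    with 79 usable replicate experiments in total.
    """

    groups: Mapping[str, str]
    n_experiments: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("tissue schema has no tissues")
        missing = set(self.groups) ^ set(self.n_experiments)
        if missing:
            raise ValidationError(
                f"tissues without group or experiment count: {sorted(missing)}"
            )
        for tissue, n in self.n_experiments.items():
            if n < 1:
                raise ValidationError(f"{tissue}: experiment count must be >= 1")

    @property
    def tissues(self) -> list[str]:
        return sorted(self.groups)

    @property
    def group_names(self) -> list[str]:
        return sorted(set(self.groups.values()))

    @property
    def total_experiments(self) -> int:
        return sum(self.n_experiments.values())

    def tissues_in_group(self, group: str) -> list[str]:
        return sorted(t for t, g in self.groups.items() if g == group)

    def experiments_in_group(self, group: str) -> int:
        return sum(self.n_experiments[t] for t in self.tissues_in_group(group))

    def group_of(self, tissue: str) -> str:
        try:
            return self.groups[tissue]
        except KeyError:
            raise ValidationError(f"unknown tissue {tissue!r}") from None

    def experiment_ids(self, tissue: str) -> list[str]:
        """Deterministic replicate experiment identifiers for a tissue."""
        return [f"{tissue}_r{i + 1}" for i in range(self.n_experiments[tissue])]
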