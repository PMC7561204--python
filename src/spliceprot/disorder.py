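"""Intrinsic disorder calls for splice-event regions.

Per-residue disorder propensities (IUPred-style long-disorder scores in
[0,1]) are inputs.  A residue is disordered when its score exceeds 0.5
(strict); a region is disordered when more than half of its residues
are.  Indels contribute the inserted region only; substitutions
contribute both swapped regions and the one with the highest disordered
fraction represents the event.  Events of four or fewer residues are
excluded from the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import Effect, SplicingEvent
from .errors import IncompleteInputError, ValidationError

#: A residue is disordered when score > 0.5 (strict).
RESIDUE_THRESHOLD = 0.5
#: A region is disordered when its disordered fraction > 0.5 (strict).
REGION_THRESHOLD = 0.5
#: Events of four or fewer residues are excluded.
MIN_EVENT_LENGTH_AA = 5

_SUBSTITUTIONS = {
    Effect.HOMOLOGOUS_SUBSTITUTION,
    Effect.C_TERMINAL_SUBSTITUTION,
    Effect.N_TERMINAL_SUBSTITUTION,
    Effect.INTERNAL_SUBSTITUTION,
    Effect.TWO_PROTEINS,
}


@dataclass(frozen=True)
class DisorderCall:
    event_id: str
    fraction_disordered: float
    disordered: bool
    excluded: bool


def region_fraction(scores: Sequence[float]) -> float:
    """Fraction of residues with disorder score strictly above 0.5."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValidationError("empty score region")
    if (arr < 0).any() or (arr > 1).any():
        raise ValidationError("disorder scores must lie in [0,1]")
    return float((arr > RESIDUE_THRESHOLD).mean())


def call_event_disorder(
    event: SplicingEvent,
    regions: Mapping[str, Sequence[float]],
) -> DisorderCall:
    """Disorder call for one event from its per-region residue scores.

    ``regions`` maps region labels (e.g. side identifiers) to score
    vectors: one region for indels (the insertion), two for
    substitutions.  The representative fraction is the maximum over the
    supplied regions.
    """
    if event.region_length_aa < MIN_EVENT_LENGTH_AA:
        return DisorderCall(event.event_id, float("nan"), False, excluded=True)
    if not regions:
        raise IncompleteInputError(f"{event.event_id}: no score regions supplied")
    if event.effect in _SUBSTITUTIONS and len(regions) < 2:
        raise IncompleteInputError(
            f"{event.event_id}: substitution needs both swapped regions"
        )
    fraction = max(region_fraction(v) for v in regions.values())
    return DisorderCall(
        event_id=event.event_id,
        fraction_disordered=fraction,
        disordered=fraction > REGION_THRESHOLD,
        excluded=False,
    )
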