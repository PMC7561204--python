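"""Reference cohort schema and the published headline tallies.

The proteomics cohort is the 30-tissue human body map (17 adult tissues,
7 foetal tissues, 6 purified haematopoietic cell types; 79 usable
replicate experiments) pooled into 10 tissue groups.  The exact
tissue-to-group table and per-tissue replicate counts are not part of
this repository's inputs, so the mapping below is a synthetic
reconstruction constrained by everything the study reports: 30 tissues,
79 experiments of which 18 are foetal, adult heart with five replicates,
every tissue with at least two, nervous = frontal cortex + fetal brain +
spinal cord + retina, and the ten group names.  It is adequate for
simulation and testing; it is not the original supplementary table.

The transcriptomics cohort groups RNA-seq tissues into 12 groups, nine
of which are shared with proteomics; skin, fat and immune system have no
proteomics counterpart and blood (haematopoietic cells) has no
transcriptomics counterpart.
"""

from __future__ import annotations

from .core import TissueSchema

# ---------------------------------------------------------------------------
# Proteomics schema (synthetic reconstruction, see module docstring)

_PROTEOMICS_TISSUES: dict[str, tuple[str, int]] = {
    # tissue: (group, n replicate experiments)
    "frontal_cortex": ("nervous", 3),
    "spinal_cord": ("nervous", 2),
    "retina": ("nervous", 3),
    "fetal_brain": ("nervous", 3),
    "heart": ("muscle", 5),
    "fetal_heart": ("muscle", 3),
    "esophagus": ("digestive", 3),
    "colon": ("digestive", 3),
    "rectum": ("digestive", 2),
    "gallbladder": ("digestive", 2),
    "pancreas": ("digestive", 3),
    "fetal_gut": ("digestive", 3),
    "liver": ("liver", 3),
    "fetal_liver": ("liver", 3),
    "ovary": ("reproductive", 3),
    "testis": ("reproductive", 3),
    "prostate": ("reproductive", 3),
    "fetal_ovary": ("reproductive", 2),
    "fetal_testis": ("reproductive", 2),
    "lung": ("respiratory", 3),
    "kidney": ("urinary", 3),
    "urinary_bladder": ("urinary", 2),
    "adrenal_gland": ("endocrine", 2),
    "placenta": ("placenta", 2),
    "monocytes": ("blood", 3),
    "nk_cells": ("blood", 2),
    "b_cells": ("blood", 2),
    "cd4_t_cells": ("blood", 2),
    "cd8_t_cells": ("blood", 2),
    "platelets": ("blood", 2),
}


def reference_proteomics_schema() -> TissueSchema:
    """The 30-tissue / 79-experiment / 10-group proteomics schema."""
    return TissueSchema(
        groups={t: g for t, (g, _) in _PROTEOMICS_TISSUES.items()},
        n_experiments={t: n for t, (_, n) in _PROTEOMICS_TISSUES.items()},
    )


#: The 12 transcriptomics tissue groups.
TRANSCRIPTOMICS_GROUPS: tuple[str, ...] = (
    "digestive",
    "endocrine",
    "fat",
    "immune",
    "liver",
    "muscle",
    "nervous",
    "placenta",
    "reproductive",
    "respiratory",
    "skin",
    "urinary",
)

#: Groups present in both the proteomics and transcriptomics cohorts.
SHARED_GROUPS: tuple[str, ...] = (
    "digestive",
    "endocrine",
    "liver",
    "muscle",
    "nervous",
    "placenta",
    "reproductive",
    "respiratory",
    "urinary",
)

#: Proteomics group with no transcriptomics counterpart.
EXCLUDED_GROUPS: tuple[str, ...] = ("blood",)


# ---------------------------------------------------------------------------
# Headline tallies reported by the reference study.  These are inputs for
# arithmetic cross-checks (fractions, contingency tables), not outputs of
# this package.

#: Splice events with >= 3 PEDs on each side.
ASE_EVENTS = 255
#: Events significant in at least one of the 30 tissues.
TISSUE_LEVEL_SPECIFIC = 51
#: Events significant in at least one of the 10 groups.
GROUP_LEVEL_SPECIFIC = 87
#: Events significant at tissue or group level (union).
EITHER_LEVEL_SPECIFIC = 95
#: Events significant at both levels.
BOTH_LEVEL_SPECIFIC = 43
#: Cases of group-level protein enrichment (shared groups, blood excluded).
PGE_CASES = 99
#: PGE cases also enriched in the same group at the transcript level.
CONCORDANT_CASES = 66
#: Concordant cases traceable to a common ancestor with fish ("all but three").
CONCORDANT_CONSERVED = CONCORDANT_CASES - 3

#: Per-group transcript-level enriched event counts and how many of those
#: were also protein-enriched in the same group.
GROUP_CONCORDANCE_COUNTS: dict[str, tuple[int, int]] = {
    # group: (also protein-enriched, transcript-enriched total)
    "nervous": (32, 78),
    "muscle": (21, 48),
    "digestive": (7, 85),
    "reproductive": (3, 71),
}


def tissue_specific_fraction() -> float:
    """Fraction of validated events that are tissue or group specific."""
    return EITHER_LEVEL_SPECIFIC / ASE_EVENTS


def concordant_conservation_fraction() -> float:
    """Fraction of protein/transcript-concordant cases conserved back to fish."""
    return CONCORDANT_CONSERVED / CONCORDANT_CASES


def group_concordance_table(group1: str, group2: str) -> list[list[int]]:
    """2x2 table [also-protein-enriched, not] x [group1, group2]."""
    a1, n1 = GROUP_CONCORDANCE_COUNTS[group1]
    a2, n2 = GROUP_CONCORDANCE_COUNTS[group2]
    return [[a1, n1 - a1], [a2, n2 - a2]]
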