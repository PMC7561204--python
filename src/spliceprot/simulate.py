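"""Ground-truth cohort simulator for the whole analysis pipeline.

Emulates the statistical structure the analysis assumes: a proteomics
cohort of 30 tissues / 79 replicate experiments pooled into 10 groups
and a transcriptomics cohort of 12 tissue groups.  Per event the two
sides are mutually exclusive splicing outcomes with a per-group usage
fraction; a tissue-specific event shifts the usage of its enriched side
up to ``psi_target`` in one target group while the background stays at
``psi_background``.  Peptide detection is presence/absence Bernoulli per
experiment (PEDs count presence, not intensity) and junction reads are
negative-binomial per group.  Disorder scores and homology hits are
drawn consistently with a per-event ground truth, so every downstream
module can be scored against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import AgeBin, TissueSchema
from .errors import ConfigError
from .evolution import CLADE_LADDER, CLADE_BIN
from .reference import (
    SHARED_GROUPS,
    TRANSCRIPTOMICS_GROUPS,
    reference_proteomics_schema,
)

_MECHANISM_PROBS = {
    # Mechanism mix resembling the reference event set (skipped exons
    # dominate, alternative 3' sites a distant second).
    "skipped_exon": 0.365,
    "alt_3_splice_site": 0.145,
    "mutually_exclusive": 0.13,
    "alt_5_splice_site": 0.12,
    "alt_promoter": 0.12,
    "alt_polyA": 0.12,
}

_EFFECT_PROBS = {
    "indel": 0.41,
    "micro_indel": 0.12,
    "homologous_substitution": 0.12,
    "c_terminal_substitution": 0.13,
    "n_terminal_substitution": 0.13,
    "internal_substitution": 0.05,
    "two_proteins": 0.04,
}

_AGE_PROBS = {
    # Age mix of the reference event set: mostly ancient, few primate.
    AgeBin.PRIMATE: 0.078,
    AgeBin.THERIA: 0.15,
    AgeBin.TETRAPODA: 0.25,
    AgeBin.ANCIENT: 0.522,
}

#: Representative clade per age bin and a species name for hit tables.
_BIN_CLADE = {
    AgeBin.PRIMATE: "primates",
    AgeBin.THERIA: "theria",
    AgeBin.TETRAPODA: "tetrapoda",
    AgeBin.ANCIENT: "sarcopterygii",
}
_CLADE_SPECIES = {
    "primates": "pan_troglodytes",
    "euarchontoglires": "mus_musculus",
    "theria": "monodelphis_domestica",
    "mammalia": "ornithorhynchus_anatinus",
    "tetrapoda": "xenopus_tropicalis",
    "sarcopterygii": "latimeria_chalumnae",
    "vertebrata": "danio_rerio",
}

_SUBSTITUTION_EFFECTS = {
    "homologous_substitution",
    "c_terminal_substitution",
    "n_terminal_substitution",
    "internal_substitution",
    "two_proteins",
}


def _default_target_groups() -> tuple[str, ...]:
    """Shared proteomics/transcriptomics groups with >= 5 experiments."""
    schema = reference_proteomics_schema()
    return tuple(
        g for g in SHARED_GROUPS if schema.experiments_in_group(g) >= 5
    )


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; the defaults mirror the reference study.

    ``psi_target``/``psi_background`` are the usage fractions of the
    enriched side of a specific event inside/outside its target group;
    the other side always uses the complement.  ``read_dispersion`` is
    the negative-binomial overdispersion alpha (variance = mu + alpha
    mu^2); zero gives Poisson reads.
    """

    n_events: int = 255
    fraction_specific: float = 0.373
    psi_target: float = 0.8
    psi_background: float = 0.3
    p_detect: float = 0.3
    n_peptides_per_side: int = 2
    n_intersect_peptides: int = 3
    read_mean: float = 50.0
    read_dispersion: float = 0.3
    intersect_read_factor: float = 2.0
    disorder_fraction: float = 0.436
    curated_age_fraction: float = 0.5
    target_groups: tuple[str, ...] = field(default_factory=_default_target_groups)
    schema: TissueSchema = field(default_factory=reference_proteomics_schema)
    transcript_groups: tuple[str, ...] = TRANSCRIPTOMICS_GROUPS
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("fraction_specific", "psi_target", "psi_background",
                     "p_detect", "disorder_fraction", "curated_age_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0,1], got {v}")
        if self.seed is None:
            raise ConfigError("a seed is mandatory")
        if self.n_events < 1:
            raise ConfigError("n_events must be >= 1")
        if self.read_dispersion < 0 or self.read_mean < 0:
            raise ConfigError("read parameters must be non-negative")
        if self.fraction_specific > 0 and self.psi_target == self.psi_background:
            raise ConfigError(
                "psi_target must differ from psi_background when specific "
                "events are requested"
            )
        bad = set(self.target_groups) - set(self.schema.group_names)
        if bad:
            raise ConfigError(f"target groups outside schema: {sorted(bad)}")


@dataclass
class SimulatedCohort:
    """All tables of one simulated cohort plus its ground truth."""

    config: SimulationConfig
    events: pd.DataFrame
    truth: pd.DataFrame
    detections: pd.DataFrame
    reads: pd.DataFrame
    scores: pd.DataFrame
    homology: pd.DataFrame


def _nb_draws(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        return rng.poisson(mu).astype(float)
    n = 1.0 / alpha
    p = n / (n + np.maximum(mu, 1e-12))
    out = rng.negative_binomial(n, p).astype(float)
    out[mu == 0] = 0.0
    return out


def _usage(config: SimulationConfig, specific: bool, is_enriched_side: bool,
           group: str, target_group: str) -> float:
    """Usage fraction of one side in one group (sides are complementary)."""
    if specific and group == target_group:
        psi = config.psi_target
    else:
        psi = config.psi_background
    return psi if is_enriched_side else 1.0 - psi


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw a full synthetic cohort with known per-event ground truth."""
    root = np.random.default_rng(config.seed)
    rng_events, rng_det, rng_reads, rng_scores, rng_hom = root.spawn(5)

    schema = config.schema
    # flat experiment list: (tissue, experiment_id, group)
    experiments = [
        (t, e, schema.groups[t])
        for t in schema.tissues
        for e in schema.experiment_ids(t)
    ]
    exp_groups = np.array([g for _, _, g in experiments])
    tr_groups = sorted(config.transcript_groups)

    # ------------------------------------------------------------------ events
    mech_names = list(_MECHANISM_PROBS)
    mech_p = np.array(list(_MECHANISM_PROBS.values()))
    eff_names = list(_EFFECT_PROBS)
    eff_p = np.array(list(_EFFECT_PROBS.values()))
    age_names = list(_AGE_PROBS)
    age_p = np.array(list(_AGE_PROBS.values()))

    ev_rows, truth_rows = [], []
    for i in range(config.n_events):
        event_id = f"EV{i:04d}"
        gene_id = f"GENE{i:04d}"
        mech = mech_names[rng_events.choice(len(mech_names), p=mech_p / mech_p.sum())]
        eff = eff_names[rng_events.choice(len(eff_names), p=eff_p / eff_p.sum())]
        if eff == "micro_indel":
            lens = (0, int(rng_events.integers(1, 4)))
        elif eff == "indel":
            lens = (0, int(rng_events.integers(4, 61)))
        else:
            lens = (int(rng_events.integers(5, 61)), int(rng_events.integers(5, 61)))
        if rng_events.random() < 0.5:
            lens = (lens[1], lens[0])
        specific = bool(rng_events.random() < config.fraction_specific)
        target = (
            str(rng_events.choice(sorted(config.target_groups)))
            if specific
            else ""
        )
        enriched = "a" if rng_events.random() < 0.5 else "b"
        age = age_names[rng_events.choice(len(age_names), p=age_p / age_p.sum())]
        curated = rng_events.random() < config.curated_age_fraction
        dis_a = bool(rng_events.random() < config.disorder_fraction)
        dis_b = bool(rng_events.random() < config.disorder_fraction)
        ev_rows.append(
            (
                event_id,
                gene_id,
                mech,
                eff,
                lens[0],
                lens[1],
                eff == "homologous_substitution",
                age.value if curated else AgeBin.UNKNOWN.value,
            )
        )
        truth_rows.append((event_id, specific, target, enriched, age.value, dis_a, dis_b))

    events = pd.DataFrame(
        ev_rows,
        columns=[
            "event_id",
            "gene_id",
            "mechanism",
            "effect",
            "side_a_len",
            "side_b_len",
            "homologous_flag",
            "age_label",
        ],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "event_id",
            "specific",
            "target_group",
            "enriched_side",
            "age_bin",
            "disordered_a",
            "disordered_b",
        ],
    )

    # -------------------------------------------------------------- detections
    det_rows = []
    for ev, tr in zip(ev_rows, truth_rows):
        event_id, gene_id = ev[0], ev[1]
        specific, target, enriched = tr[1], tr[2], tr[3]
        for side in ("a", "b", "intersect"):
            n_pep = (
                config.n_intersect_peptides
                if side == "intersect"
                else config.n_peptides_per_side
            )
            if side == "intersect":
                u = np.ones(len(experiments))
            else:
                u = np.array(
                    [
                        _usage(config, specific, side == enriched, g, target)
                        for g in exp_groups
                    ]
                )
            prob = config.p_detect * u
            hits = rng_det.random((n_pep, len(experiments))) < prob[None, :]
            for j, row in enumerate(hits):
                for k in np.nonzero(row)[0]:
                    tissue, exp_id, _ = experiments[k]
                    det_rows.append(
                        (
                            f"{event_id}_{side}_p{j}",
                            gene_id,
                            event_id,
                            side,
                            exp_id,
                            tissue,
                        )
                    )
    detections = pd.DataFrame(
        det_rows,
        columns=["peptide", "gene_id", "event_id", "side", "experiment_id", "tissue"],
    )

    # ------------------------------------------------------------------- reads
    read_rows = []
    for ev, tr in zip(ev_rows, truth_rows):
        event_id = ev[0]
        specific, target, enriched = tr[1], tr[2], tr[3]
        for side in ("a", "b", "intersect"):
            if side == "intersect":
                mu = np.full(len(tr_groups), config.read_mean * config.intersect_read_factor)
            else:
                mu = config.read_mean * np.array(
                    [
                        _usage(config, specific, side == enriched, g, target)
                        for g in tr_groups
                    ]
                )
            draws = _nb_draws(rng_reads, mu, config.read_dispersion)
            for g, r in zip(tr_groups, draws):
                read_rows.append((event_id, g, side, float(r)))
    reads = pd.DataFrame(read_rows, columns=["event_id", "group", "side", "reads"])

    # ------------------------------------------------------------------ scores
    score_rows = []
    for ev, tr in zip(ev_rows, truth_rows):
        event_id, eff = ev[0], ev[3]
        lens = {"a": ev[4], "b": ev[5]}
        dis = {"a": tr[5], "b": tr[6]}
        if eff in _SUBSTITUTION_EFFECTS:
            sides = [s for s in ("a", "b") if lens[s] > 0]
        else:  # indel / micro-indel: only the inserted region exists
            sides = [max(("a", "b"), key=lambda s: lens[s])]
        for s in sides:
            n = max(lens[s], 1)
            # disordered regions draw high propensities, ordered ones low
            scores = (
                rng_scores.beta(3.0, 1.0, n) if dis[s] else rng_scores.beta(1.0, 3.0, n)
            )
            for pos, sc in enumerate(scores, start=1):
                score_rows.append((f"{event_id}|{s}", pos, float(sc)))
    scores = pd.DataFrame(score_rows, columns=["region_id", "position", "score"])

    # ---------------------------------------------------------------- homology
    hom_rows = []
    for ev, tr in zip(ev_rows, truth_rows):
        event_id, age = ev[0], AgeBin(tr[4])
        true_clade = _BIN_CLADE[age]
        true_rank = CLADE_LADDER.index(true_clade)
        for mode in ("exon_only", "exon_plus_flanks"):
            # guaranteed accepted hit at the true clade in both modes
            hom_rows.append(
                (
                    event_id,
                    mode,
                    _CLADE_SPECIES[true_clade],
                    true_clade,
                    int(rng_hom.integers(0, 4)),
                )
            )
            for rank, clade in enumerate(CLADE_LADDER):
                if rank < true_rank and rng_hom.random() < 0.7:
                    hom_rows.append(
                        (event_id, mode, _CLADE_SPECIES[clade], clade,
                         int(rng_hom.integers(0, 4)))
                    )
                elif rank > true_rank and rng_hom.random() < 0.4:
                    # spurious distant alignments carry >= 4 insertions
                    hom_rows.append(
                        (event_id, mode, _CLADE_SPECIES[clade], clade,
                         int(rng_hom.integers(4, 12)))
                    )
    homology = pd.DataFrame(
        hom_rows, columns=["exon_id", "mode", "hit_species", "hit_clade", "insertions"]
    )

    return SimulatedCohort(
        config=config,
        events=events,
        truth=truth,
        detections=detections,
        reads=reads,
        scores=scores,
        homology=homology,
    )


# ---------------------------------------------------------------------------
# Recovery scoring against ground truth


def recovery_report(
    cohort: SimulatedCohort,
    protein_calls: Optional[pd.DataFrame] = None,
    ped_profiles: Optional[dict] = None,
    transcript_calls: Optional[pd.DataFrame] = None,
    read_profiles: Optional[dict] = None,
    age_table: Optional[pd.DataFrame] = None,
    disorder_calls: Optional[Sequence] = None,
) -> dict[str, float]:
    """Confusion-matrix summaries of each stage against the ground truth.

    Sensitivity counts a truly specific event as recovered when the
    stage calls its enriched side (mapped back through the profile's
    side relabelling) enriched in its target group; specificity is the
    fraction of truly non-specific events with no enriched group-level
    call anywhere.
    """
    truth = cohort.truth.set_index("event_id")
    out: dict[str, float] = {}

    if protein_calls is not None and ped_profiles is not None:
        sel = protein_calls[
            (protein_calls["unit_kind"] == "group")
            & (protein_calls["comparison"] == "main_vs_alt")
            & protein_calls["significant"]
            & (protein_calls["direction"] == "enriched")
        ]
        out.update(
            _score_calls(
                truth,
                {(e, u): s for e, u, s in zip(sel["event_id"], sel["unit"], sel["enriched_side"])},
                {e: p.side_map for e, p in ped_profiles.items()},
                tested_events=set(ped_profiles),
                prefix="protein",
            )
        )

    if transcript_calls is not None and read_profiles is not None:
        sel = transcript_calls[transcript_calls["enriched_side"] != "none"]
        out.update(
            _score_calls(
                truth,
                {(e, g): s for e, g, s in zip(sel["event_id"], sel["group"], sel["enriched_side"])},
                {e: p.side_map for e, p in read_profiles.items()},
                tested_events=set(read_profiles),
                prefix="transcript",
            )
        )

    if age_table is not None:
        merged = age_table.merge(
            cohort.truth[["event_id", "age_bin"]],
            left_on="exon_id",
            right_on="event_id",
        )
        known = merged[merged["bin"] != AgeBin.UNKNOWN.value]
        if len(known):
            out["age_bin_accuracy"] = float((known["bin"] == known["age_bin"]).mean())

    if disorder_calls is not None:
        correct = total = 0
        for call in disorder_calls:
            if call.excluded:
                continue
            row = truth.loc[call.event_id]
            ev = cohort.events.set_index("event_id").loc[call.event_id]
            flags = []
            if ev["effect"] in _SUBSTITUTION_EFFECTS:
                if ev["side_a_len"] > 0:
                    flags.append(bool(row["disordered_a"]))
                if ev["side_b_len"] > 0:
                    flags.append(bool(row["disordered_b"]))
            else:
                s = "a" if ev["side_a_len"] >= ev["side_b_len"] else "b"
                flags.append(bool(row[f"disordered_{s}"]))
            total += 1
            correct += int(call.disordered == any(flags))
        if total:
            out["disorder_accuracy"] = correct / total

    return out


def _score_calls(truth, calls, side_maps, tested_events, prefix):
    tp = pos = 0
    fp_events = neg = 0
    for e in sorted(tested_events):
        row = truth.loc[e]
        event_calls = {(ee, g): s for (ee, g), s in calls.items() if ee == e}
        if row["specific"]:
            pos += 1
            called = event_calls.get((e, row["target_group"]))
            if called is not None:
                raw = side_maps.get(e, {}).get(called, "")
                if raw == row["enriched_side"]:
                    tp += 1
        else:
            neg += 1
            if event_calls:
                fp_events += 1
    out = {}
    if pos:
        out[f"{prefix}_sensitivity"] = tp / pos
    if neg:
        out[f"{prefix}_specificity"] = 1.0 - fp_events / neg
    return out
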