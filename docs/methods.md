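# Methods

## Events, sides and evidence

A splice event is a binary choice between two sequence outcomes of one
gene.  Evidence (discriminating peptides at the protein level, junction
reads at the transcript level) maps to one side or to the shared
"intersect" sequence.  *Main* is the side with most total evidence,
assigned independently per evidence source; ties — which the data
sources themselves do not resolve — are broken lexicographically on the
raw side identifier so that runs are reproducible.

Events are classified by splicing mechanism (six classes: skipped exon,
mutually exclusive exons, alternative 5′/3′ splice sites, alternative
promoter, alternative poly-A) and by protein-level effect (seven
classes).  Effect classification precedence: isoform pairs sharing no
sequence are *two proteins*; curated homologous swaps are *homologous
substitutions*; indels (one side empty) shorter than four residues are
*micro-indels* (this covers NAGNAG tandem-acceptor single-residue
gains/losses), longer ones *indels*; remaining substitutions are binned
by position (N-terminal / C-terminal / internal).  The micro-indel
threshold is applied to |len_a − len_b|, i.e. "smaller than four"
means ≤ 3 aa.

## PED counting and the inclusion filter

A peptide-experiment detection (PED) is presence of a peptide in one
experiment; counts are deduplicated on (peptide, experiment) so repeated
identifications within an experiment count once.  Peptides mapping to
more than one gene are expected to be removed upstream.  Counts are
*not* normalised for unequal replicate numbers per tissue (an optional
weighting hook exists but is off: the reference analysis uses raw PEDs).
An event is analysed only when each side has ≥ `min_peds` (default 3)
PEDs; no minimum is imposed on the intersect, which only serves as a
background.

## Protein-level specificity

For each unit (tissue or group) and each of the three side pairs a 2×2
one-vs-rest contingency table is tested with a two-sided Fisher exact
test (scipy's implementation; the test suite checks it against an
independent hypergeometric enumeration to 1e-12).  Defaults: α = 0.05,
uncorrected — Benjamini–Hochberg across units is available by flag but
off by default, mirroring the reference procedure.  An event is
tissue-specific (group-specific) when any tissue-level (group-level)
main-vs-alt test is significant.

**Direction.**  A significant main-vs-alt difference in unit *u* is
ambiguous: the winning side may be concentrated in *u*, or the losing
side may merely be absent from it.  The winner is annotated *enriched*
only when its within-unit share of its own total exceeds the intersect's
share **and** the winner-vs-intersect test is itself significant;
otherwise the call is *depleted*.  Depleted calls are reported but
excluded from the protein group-enrichment (PGE) case set.  This
positive-evidence rule was the main genuinely open design choice; the
weaker alternative (comparing within-unit shares only) mislabels
losing-side depletions as enrichments whenever the winner tracks the
gene background, which breaks the expected protein/transcript agreement
in the noise-free limit.

## Transcript-level specificity (SD rule)

Each side's per-group read vector is standardised by its own mean and
*population* (ddof = 0, configurable) standard deviation; z is defined
as 0 when the sd is 0.  Group *g* is enriched for side *s* when
z_s(g) − z_other(g) ≥ 1 (threshold configurable).  The intersect's z
values are computed and reported but do not enter the call.  Read counts
are used as provided; library-size normalisation is the caller's
responsibility.  Note the rule is liberal under independent overdispersed
group noise — with 12 groups the maximal z-difference frequently exceeds
1 by chance — which is visible in the synthetic cohorts as a high
transcript-specific fraction.

## Concordance

PGE cases are the significant, enriched-direction, group-level calls in
the shared proteomics∩transcriptomics groups (blood excluded: the
haematopoietic cells have no transcriptomics counterpart); an event
enriched in k admissible groups contributes k cases.  A case is
concordant when the event is transcript-enriched in the same group (the
side label is not required to match, since main/alt labels are assigned
per source).  Per-group concordance proportions are compared pairwise
with two-sided Fisher tests.  Percent support of a side in a group is
100 × count(side, group)/total(side) — the side's own total is the
denominator, so a fully tissue-restricted side scores 100% — and sides
with zero totals are dropped as undefined rather than scored 0.
Correlations between percent PED and percent read support are Pearson by
default (Spearman by flag), per group or per age stratum, requiring ≥ 3
points.

## Exon age

Homology hits from two search modes (exon alone; exon plus flanking
exon(s)) are filtered to those with ≤ 3 residue insertions.  Per mode
the age is the most distant accepted clade on the ladder
primates < euarchontoglires < theria < mammalia < tetrapoda <
sarcopterygii < vertebrata; the final age is the minimum (most recent)
of the per-mode ages, and a mode without hits simply does not
constrain.  Clades map onto four categorical bins — primate (< ~75 My),
theria (75–160), tetrapoda (160–400), ancient (> 400, predating
lobe-finned fish); the ladder and mapping are explicit configuration
because only the bins, not a full ladder, are fixed by the underlying
procedure.  Exons shorter than 42 bases are not aged automatically, and
exons with no accepted hit are reported as undetermined, never
defaulted.  Curated age labels override automatic estimates and are
flagged by a `source` column.

## Disorder

Per-residue disorder propensities in [0,1] (IUPred-style long-mode
scores) are inputs.  Thresholds are strict: a residue is disordered at
score > 0.5 and a region when its disordered fraction > 0.5.  Indels
supply the inserted region; substitutions supply both swapped regions
and the maximum fraction represents the event (equal fractions give
equal flags, so ties are harmless).  Events of ≤ 4 aa are excluded.

## The simulator

`simulate_cohort` draws, per event: mechanism/effect/length from
frequencies resembling the reference event set; a ground-truth
specificity flag (default fraction 0.373), target group and enriched
side; an age bin (primate 7.8%, theria 15%, tetrapoda 25%, ancient
52.2%) and per-region disorder truth (43.6%).  The two sides of an
event are complementary: the enriched side's usage is ψ_target
(default 0.8) in the target group and ψ_background (default 0.3)
elsewhere, the other side uses the complement; non-specific events use
ψ_background uniformly.  Peptide detection is Bernoulli per experiment
with probability p_detect × usage (default p_detect 0.3 — discriminating
peptides are seen in a minority of experiments, as in real label-free
data); the intersect has usage 1.  Reads are negative-binomial with
mean = read_mean × usage (default mean 50, overdispersion α = 0.3,
variance μ + αμ²; α = 0 gives Poisson) per transcriptomics group.
Disorder scores come from Beta(3,1) (disordered truth) vs Beta(1,3)
(ordered).  Homology tables contain a guaranteed accepted hit at the
true clade in both modes, accepted nearer hits, and spurious more
distant hits carrying ≥ 4 insertions.  Default target groups are the
shared groups with ≥ 5 proteomics experiments (nervous, muscle,
digestive, liver, reproductive, urinary), so power calculations are not
dominated by one-tissue groups.  One seeded root generator spawns
independent sub-streams per table; the seed is mandatory.

The reference tissue schema (30 tissues, 79 experiments, 10 groups) is a
synthetic reconstruction: the real supplementary grouping table is not
shipped, so tissues and replicate counts were laid out to satisfy every
published constraint (totals, fetal/adult split, five adult-heart
replicates, the named nervous-group members, the ten group names).
Curated age labels are generated for half the events (the rest exercise
the automatic estimator).

**What the simulator does not emulate:** peptide detectability from
sequence, correlated detection across experiments of one replicate
series, shared library-size noise between the two sides of an event (it
draws sides independently, which makes the SD rule fire more often than
on real data), linkage between mechanism and age/disorder, and genes
with multiple events.  Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery on data with
the assumed structure, not the biological conclusions of any particular
cohort.

## Calibration and problem sizes

The per-test group-level false-positive rate on a 500-event null cohort
(identical usage everywhere) is ≈ 0.01 at α = 0.05 — far below α,
because Fisher tests on sparse discrete tables are conservative.  Under
a strong effect (ψ 0.9 vs 0.1, p_detect 0.8) protein and transcript
sensitivities are ≈ 1, and on an all-specific, near-noiseless cohort the
protein/transcript concordance fraction reaches 1.  Simulation sizes
used throughout (500 null events, 200 strong-effect events, 120
low-noise events, 2,000 random tables for the Fisher sweep) were chosen
to keep Monte-Carlo error well below the decision margins while keeping
any single run in the order of a minute.

## Known limitations

* The combination rule turning three comparisons into one event-level
  verdict, the multiple-testing stance, and the percent-support
  denominator are all under-determined by the reference procedure; the
  choices above are documented defaults with flags where an alternative
  is defensible.
* Ages are categorical; no million-year dating is attempted.
* The pipeline consumes tabular upstream outputs (PSM tables, junction
  counts, disorder scores, homology hits); it does not run spectral
  search, alignment, BLAST or IUPred.
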