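# Methods

## Problem and scope

Label-free LC-MS/MS profiling of extracellular-vesicle (EV) protein cargo is
noisy in two distinct ways: *qualitatively* — a protein identified in one
replicate may be missing from the next — and *quantitatively* — an
identified protein's abundance fluctuates between replicates.  The two
sources behave differently for technical replicates (TRs; re-injections of
one lysate) and biological replicates (BRs; independent culture passages).
`evrepro` quantifies both kinds of variability for a crossed
`n_bio x n_tech` replicate design, tests whether mean abundance differs
across replicate groups, and estimates how many replicates a design needs.
It consumes the *outputs* of identification/quantification software (an
LFQ-style intensity table used purely as a presence/absence signal, and an
APEX-style absolute-abundance table normalized so each sample's abundances
sum to a constant C, 1.0E8 by default); it does not reprocess spectra.

## Replicate design and groupings

The canonical design is 3 passages x 3 injections with positional labels
R1..R9.  Two triad groupings are analysed:

* TR groups: `{R1,R2,R3}, {R4,R5,R6}, {R7,R8,R9}`
* BR groups: `{R1,R4,R7}, {R2,R5,R8}, {R3,R6,R9}`

Which of the two label patterns actually shares a lysate depends on how the
runs were numbered, and published descriptions of such designs are not
always unambiguous.  Both conventions are first-class
(`numbering = tr_triads_same_lysate | br_triads_same_lysate`); the default
is `tr_triads_same_lysate` (consecutive labels are splits of one lysate).
Groupings generalize to any crossing as `n_bio` consecutive blocks of
`n_tech` labels (TR) and `n_tech` strided groups (BR); each TR group meets
each BR group in exactly one replicate (Latin-square property), which the
test suite asserts for several design sizes.

## Presence, occupancy and Venn partitions

A protein is *identified* in a replicate when its intensity exceeds a
threshold (default 0, i.e. any nonzero value).  Missing and blank cells are
canonicalized to 0 on load, so "absent" and "not reported" coincide — the
convention of intensity tables in which non-detection is an empty cell.
Occupancy (the number of replicates a protein appears in) partitions the
detected proteins into all-replicates / intermediate / singleton classes;
the conservation identity `all + intermediate + singleton = total` holds on
every input.  Per-triad 3-set Venn diagrams are collapsed to
unique / shared-by-2 / common-to-3 counts, averaged over triads, and
expressed as percentages of the cell-line total.

## Relative standard deviation (RSD)

All dispersion summaries are RSD = sample SD / mean x 100, with the n-1
denominator.  The member value per replicate is the identified-protein
count (qualitative) or the column total abundance (quantitative).  Two
scheme-level assemblies are supported because the field uses both:

* `within_group_mean` (default): RSD within each triad over its member
  values, then the unweighted mean across triads (groups are equal-sized, so
  weighting is moot);
* `between_group_sums`: a single RSD over the per-group totals.

For data whose columns are each normalized to C, the all-protein column
totals are constant by construction, so the quantitative RSD defaults to
the replicate-common (complete-case) protein set — the same protein set an
absolute-abundance supplementary table typically lists.  A `calibrate`
helper (also `evrepro report --calibrate`) evaluates all four
(numbering x interpretation) combinations against user-supplied reference
RSDs and reports which combination reproduces them, for users holding the
original tables of a published study.

## Repeated-measures ANOVA

Subjects are complete-case proteins (nonzero in every involved replicate);
each subject contributes one value per condition, the mean of its abundances
over that group's members (for the all-replicates analysis each replicate is
its own condition).  The classical within-subject decomposition is used:
`SS_total = SS_conditions + SS_subjects + SS_error`,
`F = MS_conditions / MS_error` with df `(k-1, (k-1)(s-1))` and p from the
central F distribution.  No sphericity correction is applied.  Responses
are raw abundances by default with a natural-log switch
(`log_transform=True`); raw values are the default because per-sample
normalized abundance tables are already on a common scale.  Thresholds are
Bonferroni-corrected: alpha/3 for three groups (0.0167 at alpha 0.05) and
alpha/9 across nine replicates (0.0056).  Degenerate inputs: when the
between-condition sum of squares is below 1e-12 of the total (identical
conditions up to rounding) the test reports F = 0, p = 1.

## Power analysis and replicate sufficiency

Power uses the noncentral F distribution: for k groups, n per group,
effect size Cohen's f (population SD of condition means over pooled
within-condition SD), the noncentrality is `f^2 k n` with df
`(k-1, k(n-1))`; at f = 0 the power equals alpha exactly.
`required_replicates` estimates f from the observed complete-case
condition matrix and inverts the power function by doubling-plus-bisection
(power is monotone in n).  Defaults: power target 0.8 at the
Bonferroni-corrected alpha 0.016.  A zero effect size yields
`n_required = None` (no finite n reaches the target) rather than an error,
so degenerate no-noise runs still produce a complete report.

## Accumulation curve and fold increase

The expected distinct-protein count S(n) for n of the observed replicates
is computed by subset averaging (exhaustive when C(R, n) <= 200, otherwise
seeded Monte-Carlo).  A saturating model — Michaelis-Menten
`S(n) = Vmax n / (K + n)` by default, or `a + b ln n` — is fit to the curve
and evaluated at the target replicate number; the fold increase is
`(S_target - S_observed) / S_observed`.  This extrapolation is a heuristic
for "how much more would further replicates reveal", not an unbiased
richness estimator; the extrapolated value is floored at the observed
richness so the fold increase is never negative, and a flat curve
short-circuits to fold 0 (saturating fits on constant data can undershoot
by rounding).

## Synthetic data generator

The generator emulates the statistical structure of a deep EV proteome
profile so every stage is testable without instrument data:

* **Base abundances**: i.i.d. log-normal, ln-scale mean 10 and SD 2
  (~4-5 decades of dynamic range, typical of deep label-free profiles).
* **Passage (biological) effects**: multiplicative, mean-1 log-normal with
  total CV `bio_cv` (default 0.5), shared by all injections of one passage.
* **Injection (technical) effects**: same construction with CV `tech_cv`
  (default 0.1), independent per run.
* **Hierarchical structure**: each effect splits its log-variance into a
  sample-level component common to every protein in that passage/injection
  (prep yield, loading amount, ion-source efficiency) and a protein-specific
  component (cargo loading shifting between passages; peptide-level
  interference between runs).  Default split: 50/50
  (`bio_shared_fraction = tech_shared_fraction = 0.5`).  The shared
  component matters: identification counts sum ~1000 near-independent
  detection events, so purely protein-specific effects would average away
  and biological replicates would look no more variable than technical
  ones, contrary to what replicate series of label-free data show.
* **Detection**: Bernoulli per (protein, replicate) with logistic
  probability in log abundance, midpoint at the median log abundance and
  slope 0.8 — near-certain detection in the top decade, ~50% dropout at the
  median, and frequent dropout below it.  This produces the characteristic
  occupancy shape: a reproducible all-replicates core and a large class of
  proteins seen in only one replicate.  One detection mask is shared by the
  LFQ- and APEX-flavor tables, since both derive from the same runs.
* **Tables**: the LFQ-flavor table holds observed abundances as-is; the
  APEX-flavor table rescales each column to sum to C.

Everything is reproducible from the config seed, and the ground truth
(base abundances, factors, detection mask) is returned and serialized with
fixtures.

What the generator does *not* emulate: peptide-level identification and FDR
filtering, shared-peptide ambiguity between protein groups, chromatographic
drift and batch order effects, and correlated detection between related
proteins.  Passing the recovery tests therefore shows that the pipeline
measures what this model encodes — multiplicative hierarchical noise with
abundance-dependent dropout — not that real instruments behave exactly
this way.

## Numerical and testing notes

* Sample SDs use ddof=1 throughout; RSD with a zero mean is an error, not 0.
* Ranking ties are broken by lexicographic protein id so heatmap layouts are
  deterministic.
* The most-abundant filter means across *all* replicate columns, zeros
  included, with an inclusive cutoff (default 2.0E6 under C = 1.0E8).
* Independent oracles in the test suite: an explicit-loop sums-of-squares
  decomposition and pingouin's repeated-measures ANOVA for F/p/df;
  statsmodels' noncentral-F routine for power; exhaustive subset
  enumeration for Venn regions and accumulation curves.
* Monte-Carlo suite sizes (200 seeds at 1000 proteins for recovery checks,
  100 seeds at 150 proteins for noise-ordering checks) were chosen to keep
  the default test run fast while leaving the orderings far from their
  decision boundaries.
* Measured recovery at the default conditions, for calibration of
  expectations: the BR > TR ordering holds in ~95% of seeds for the count
  RSD and ~92-94% for the abundance RSD (the per-group RSD carries only two
  degrees of freedom and complete-case totals are dominated by a few top
  proteins, so single-seed orderings reverse occasionally even though the
  underlying effect ratio is 5:1); the singleton class is non-empty in
  every seed observed.
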