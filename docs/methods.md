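# Methods

This note documents the models, conventions, parameter choices and known
limitations of `lignoreg`.  All empirical statements here are computed by
the test suite or by `scripts/acceptance.py`; nothing is asserted that the
code does not reproduce.

## qPCR quantification

The quantification model assumes exponential amplification at a constant
per-assay efficiency E (fold amplification per cycle, 1 < E ≤ 2.2):
a sample with relative input q crosses threshold at
Cq = baseline − log_E(q).  Efficiencies are estimated from a dilution
series by ordinary least squares of Cq on log₁₀(input); E = 10^(−1/slope).
Fewer than three points or a non-negative slope is an error; values outside
(1.6, 2.2) only warn, since no QC gate is part of the model.

Normalization follows the multi-reference qBase scheme.  The calibrator is
the across-sample arithmetic mean Cq per assay (the qBase default; the
variant actually used upstream of the analysis this package models is not
recorded, and the choice cancels in all between-condition ratios).  The
normalization factor per sample is the geometric mean of the reference-gene
relative quantities, which forces the geometric mean of reference NRQs to 1
in every sample.  Undetected reactions ("ND") are missing data, never zero:
they are excluded from means and tests, and an assay with no detected
observations in a condition is reported not-testable rather than imputed.

Replicate handling: the default treats each of the 3 biological × 3
technical = 9 wells per condition as a test unit (the "n = 9" design);
`average_technical=True` collapses technical replicates first and tests
n = 3 biological units.  The rank test is invariant to monotone transforms,
so testing NRQ or log₂ NRQ gives identical calls.

A note on a tempting invariance: "adding a constant to every Cq of a
sample leaves NRQ unchanged" holds exactly only when all assays share one
efficiency.  The physically meaningful transform — scaling a sample's
input by f, which shifts each assay's Cq by log_E(f) — leaves NRQ invariant
under any efficiency mix, and that is what the tests assert (plus the
constant-shift case at equal efficiencies).

### Exact Mann–Whitney

The two-sided p-value counts label assignments whose U statistic is at
least as far from the null mean n₁n₂/2 as observed, over all C(n₁+n₂, n₁)
assignments, with mid-ranks for ties.  The null distribution is computed by
a subset-sum dynamic program over doubled mid-ranks (integers), which is
algebraically identical to full enumeration; tests verify agreement with a
literal enumeration oracle to 10⁻¹² on tied and untied inputs.  Groups
larger than 12 fall back to the tie-corrected normal approximation and are
flagged.

## Co-expression clustering

Profiles are clustered by a k-medians variant under Pearson distance
d = 1 − r (the metric/center combination of the TM4 MeV k-means/medians
tool).  Zero-variance profiles are excluded with a warning, as Pearson
correlation is undefined for them.

Design choice: the element-wise median is not the exact minimizer of
summed Pearson distance, so the textbook update/reassign loop has no
monotonicity guarantee under this metric.  We therefore define the
objective as a pure function of the partition — the summed distance of
members to their cluster's element-wise median — and accept a
nearest-center reassignment sweep only when it strictly lowers that
objective.  Consequences: the objective trace is provably non-increasing,
the loop terminates, and on tiny instances the best run over all initial
partitions provably attains the exhaustive-search optimum (verified for
n ≤ 7, k ≤ 3).  Ties in nearest-center go to the lowest cluster index;
empty clusters receive the profile farthest from its assigned center.
k defaults to 10 (the MeV default) but is data-dependent and exposed;
`consensus_over_restarts` reports the best of n seeded restarts and a
stability score (mean pairwise adjusted Rand index across restarts).

## miRNA target prediction

Duplexes are ungapped and antiparallel: miRNA position i (1 = 5′ end)
pairs with window position L − i + 1.  Pair classes are M (Watson–Crick),
W (G:U wobble) and X (mismatch); penalty = 1.0·#X + 0.5·#W.  A wobble
counts as a *pair* for all positional rules but still costs 0.5 — the
convention under which a 0–2.5 penalty range is meaningful.  Acceptance
requires: at most one X at positions 1–9 (SEED), no X at 10–11 (SITE), no
run of more than two consecutive X after position 11 (RUN), and penalty ≤
2.5 inclusive (PENALTY).  Non-consecutive mismatch totals after position 11
are deliberately unconstrained beyond the penalty cap, matching the rule as
stated ("consecutive").  Two stricter variants are exposed as flags:
Watson–Crick-only at positions 10–11, and seed-region penalty doubling —
both off by default since the plain-sum 0–2.5 threshold is the documented
behaviour.  The predicted cleavage coordinate is the transcript base paired
with miRNA position 10, i.e. the 5′ nucleotide of the 3′ cleavage fragment
that RLM-RACE captures.

## RACE cleavage mapping

Fragments are adaptor-trimmed Sanger reads from the transcripts they came
from, so mapping is exact full-length substring search; a fragment counts
only if it occurs exactly once across the whole transcript set
(multi-locus → ambiguous, absent → unmapped; mapped + ambiguous + unmapped
= input count).  Position matching is strict to the nucleotide: a clone one
base off the predicted site does not support it.  The primary statistic is
the fraction "clones at predicted site / total mapped clones"; the boolean
VALIDATED call (≥ 2 clones at the site by default) is advisory, since the
underlying assay reports raw fractions without a stated cutoff.

## Promoter motif scanning

Promoters are the 500 bp immediately upstream of the annotated translation
start — the only anchor that is reproducibly annotated in draft plant
genomes lacking UTR models — reported 5′→3′ on the coding strand and
truncated (with a warning) at scaffold edges.  Both strands are scanned for
MBS (YAACWAMC) and MBSIIG (YACCWAMC); each consensus expands to exactly 8
concrete 8-mers, so on i.i.d. uniform background the per-position,
per-strand hit probability is 8/4⁸ = 2⁻¹³ (verified empirically over 10⁷
positions).  All overlapping and self-overlapping occurrences are reported.
Positions are emitted both promoter-local (1-based) and anchor-relative
(anchor = 0; a full-length promoter yields [−500, −8]), since either
convention may be wanted downstream.

## Candidate prioritization

The bona fide gate is explicit and configurable: log₂ fold change ≥ 1
(2-fold) with exact Mann–Whitney P < 0.01 in all of stem vs leaf, root vs
leaf, and inner vs outer stem tissue.  The gate is monotone — raising
`min_lfc` or lowering `alpha` can only remove candidates.  Co-membership in
the modal cluster of the candidates and MBSIIG promoter presence are
corroborating evidence only; genes induced solely in the hypolignified
outer tissues fail the IT/OT gate and are excluded.  Phylogenetic placement
can be supplied as an optional boolean column but is never computed here.

## Synthetic data

The generators emit every input the pipeline consumes, with a JSON truth
manifest, and are deterministic to the byte under a fixed seed.  Defaults
encode the study conditions the pipeline models: 3 biological × 3 technical
replicates (n = 9); organ fold-changes of 5–25× and inner/outer ratios of
4–9× for the six planted candidates plus one outer-tissue-induced decoy; a
45-transcript screen with 11 rule-satisfying planted duplexes spanning
penalties 0–2.5 and 4 planted rule violations (one per reason code); RACE
clone sets of 10 with 7 at the planted cleavage site; MBS/MBSIIG plantings
across both promoter strands.  Where no value was dictated by the modeled
design, one realistic value was fixed: Gaussian Cq noise of 0.1 cycles
(typical Fluidigm technical scatter; 0.15 in the stress tests), assay
efficiencies drawn from 1.85–2.0, noise-free dilution series, 40 nt RACE
reads, 12-condition expression profiles.  The mature miRNA shipped as the
default is the conserved plant miR397 family sequence, a synthetic stand-in
for the flax copy (published only as a figure).

Generator guarantees worth knowing: planted promoter motifs are
scan-verified and redrawn if a planting is clobbered or an accidental match
overlaps one (non-overlapping accidental matches are kept and recorded);
planted duplex windows are verified to be the only accepted window of their
transcript; decoy transcripts are verified to contain no window of penalty
≤ 2.5; profile archetypes are mutually orthogonal after centering, so
cluster separation is controlled exactly.  Background sequence is i.i.d.
uniform ACGT.

What the generators do *not* emulate — hence what green tests do not show
about field data: sequencing error and adaptor remnants in RACE clones,
inter-run calibration drift and plate effects in Cq data, non-uniform
genomic base composition and repeat structure, cross-hybridizing primer
groups, partial transcript models, or stress-response time courses.

## Problem sizes and numerics

The shipped analyses use a 20-gene cohort, 45-transcript screen and
63-profile clustering instance; oracle-equivalence tests use 50–150
transcripts, 10⁴–10⁵ scored windows and 10⁷ scanned motif positions —
sizes chosen so the full suite and the acceptance script each complete in
well under a minute while exercising every code path.  Numerical details:
ties in nearest-center assignment break to the lowest index; the clustering
descent requires strict improvement (>10⁻¹² absolute); permutation-tail
comparisons use a 10⁻⁹ slack on rank sums; efficiencies are floats and the
noise-free recovery contract is met to <10⁻⁹ in log₂.

## Known limitations

Gapped/bulged miRNA duplexes, target-site accessibility energies and
translational inhibition are out of scope, as are PWM-based motif scoring,
single-reference ΔΔCq modes, degradome-scale (PARE) mapping, and any
phylogenetic computation.  `k` for clustering is not selected
automatically.  The exact Mann–Whitney switches to an approximation above
group size 12 by design.
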