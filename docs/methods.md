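# Methods

## Read preprocessing

Reads are 50-bp single-end molecules consisting of a small-RNA insert
followed by the 3' sequencing adapter.  Trimming is adapter-required:
a read whose adapter cannot be located (full match or a 3'-partial prefix
of at least 6 nt, allowing 10% mismatches over the compared length) is
discarded, because an adapterless read is longer than any miRNA and its
3' boundary is unknown.  Surviving inserts are kept when 16–28 nt long
(inclusive) and their mean Phred is at least 20, then collapsed to unique
sequences with multiplicities.  The quality threshold and adapter
parameters are configurable; the published pipelines this emulates state
the tools but not their settings, so common trimmer defaults are used.
U/T are interchangeable on input; internally all sequence is DNA.

## Alignment model

Each collapsed read is placed on each mature reference at 5' offsets −2
to +2 (covering common isomiRs), with the last two read bases excluded
from scoring (non-templated 3' additions), scored 3' overhangs beyond
the reference tolerated up to 2 nt, at least 12 scored positions
required, and at most one substitution mismatch (no indels — reads map
to ~22-nt references where the editing signal is a substitution).
Exactly one reference must attain the best mismatch count ("unique best
hit"); ties across references, or between two placements within one
reference, flag the read as multimapping and exclude it from per-position
tallies.  Mismatches are reported in 1-based mature coordinates, the
convention in which edited sites are named (miR-200b-3p position 5).
The 2-nt 3' trim is applied to the read (not the reference), since
non-templated additions are a read-side artefact; this is configurable.

## Editing detection

For every reference adenosine outside the 3'-terminal 5 nt the detector
forms (x, n): n weighted covering reads, x of them reporting G.  The
terminal exclusion is 3'-only: seed-region edits at position 5 are real
calls, whereas the 3' end is dominated by degradation and tailing
artefacts, so a both-ends exclusion would contradict the biology the
pipeline exists to measure.

The test is the exact one-sided upper-tail binomial probability
P[X ≥ x | n, p₀]: editing can only raise the A→G rate above the error
floor.  p₀ defaults to mean(10^(−Q/10))/3 over the covering reads'
qualities — the /3 converts a per-base error rate into the specific A→G
substitution rate under a substitution-symmetric error model — with a
fixed fallback of 0.001 when qualities are unavailable.  BH adjustment
runs across all tallied sites of a sample; calls require FDR ≤ α = 0.05
(configurable).  Three specificity filters then apply, in order:
repeat-element (blacklisted) host miRNA; canonical miRNA expression
below 1 RPM; and in-silico multimapping — the edited mature sequence is
realigned against the whole reference panel and the site is discarded if
it matches another reference at least as well as its own.

Editing levels are x/n as percentages (2 decimals in tables).  The
cohort table keeps sites called in at least one sample and reports the
per-sample level wherever the site is covered, call or not, so group
means estimate the underlying fractions without a selection bias.

## Expression statistics

Low-count filtering works on the CPM scale equivalent to 10 raw counts
in the smallest library (gene mode; 1 count for miRNA mode).  Whether a
feature must clear the threshold in all samples or any sample is
configurable; the pipeline uses "any" for genes so that strongly
regulated genes are not removed for being low in one arm.

TMM factors follow the weighted-trimmed-mean-of-M-values definition:
M and A values against a reference library (the one whose upper-quartile
CPM is closest to the mean upper quartile), inverse-asymptotic-variance
weights, double trimming of 30% (M) and 5% (A) by ranks, factors
rescaled to geometric mean 1.  log-CPM is
log₂((count + 0.5)/(TMM-effective library size + 1) × 10⁶).

The two-group moderated test shrinks per-feature pooled variances toward
a prior fitted by method of moments on log variances (scaled-F model;
prior df from the inverse trigamma of the excess log-variance spread),
forms t statistics with residual-plus-prior degrees of freedom, and
applies BH.  Precision weights (voom) are intentionally omitted: the
package's claims are parameter-recovery properties, not bit-parity with
any particular implementation, and the moderated t on log-CPM delivers
the operating characteristics the tests assert (≥ 80% recovery of
|log₂FC| = 2 effects at n = 10/group with realised FDP ≤ 0.10).

The sample-size closed form for a fold change Δ at depth μ and
coefficient of variation cv is n = ⌈2 (z₁₋α/₂ + z_power)² (1/μ + cv²) /
ln²Δ⌉.  Depth and cv are inputs: published sample sizes computed from
unreported pilot depths cannot be reproduced without them.

## Clinical association

Editing levels are compared between unpaired tumour and control groups
by two-sided Mann–Whitney U (exact when min(n) ≤ 8 without ties, normal
approximation with tie correction otherwise).  Correlations with overall
survival, FIGO stage and the TNM M flag are Pearson on the ordinal codes
as numeric scores.  Survival uses the Kaplan–Meier product-limit
estimator with a median split of the editing level: strictly above the
median is "high", ties at the median go to "low" (a documented
convention — the split description "high > 50% of the median" is read as
an above/below-median split, the only reading that partitions a cohort);
groups are compared with the standard 1-df log-rank test.

## Seed retargeting

The seed is miRNA positions 2–8 (an alternative positions-1–5 usage
exists in descriptive contexts, but 2–8 is the canonical pairing region
and is what target scanning uses).  An A-to-I edit is applied in silico
as A→G.  Site patterns on the mRNA sense strand derive from the 7-nt m8
core (reverse complement of seed 2–8): 7mer-m8 = core, 7mer-A1 =
reverse complement of 2–7 followed by A, 8mer = core + A.  The scan
reports every occurrence (0-based half-open coordinates); the binary
"binding site" count collapses matches sharing an m8 core, and by
default counts only core occurrences (8mer included, 6mer excluded) —
7mer-m8 is the weakest broadly accepted canonical site, and criterion
(c) below needs a clean present/absent call.  No thermodynamic or
context scoring is attempted.

Candidate targets of the edited miRNA must (a) be significantly
downregulated under the edited mimic (FDR ≤ 0.05 and log₂FC ≤ −1) — and,
when a wild-type contrast is supplied, not significantly downregulated
under the wild-type mimic; (b) appear in the supplied prediction list;
(c) carry ≥ 1 edited-seed site and 0 wild-type sites in their 3'UTR.
Failures carry reason codes.  The targetome shift is the set
decomposition gained/lost/shared between wild-type and edited target
sets.

## qPCR quantification

E = 10^(−1/slope) from the standard curve; assays with E < 1.6 are
removed (the boundary E = 1.6 is kept, matching "below 1.6 removed").
Relative expression uses group-mean Ct values,
ratio = E_t^ΔCt_t / E_ref^ΔCt_ref with ΔCt = mean Ct(control) − mean
Ct(test); multiple reference assays combine by the geometric mean of
their factors (standard multi-reference practice).  At E = 2 this is the
textbook 2^(−ΔΔCt).  The edited/wild-type readout is the quotient of the
two species' relative ratios against a shared reference.

## Synthetic cohort

The generator emulates the study design: 60 tumour and 48 control
samples, 50-bp reads with the TruSeq small-RNA 3' adapter, a 25-member
mature miRNA panel, and one differential seed site —
hsa-miR-200b-3p position 5 edited at fraction 0.01 in control tissue and
0.01 + 0.09 in tumours, spanning the reported per-cohort range of mean
hotspot levels (~0.01–11.5%).  Per-sample biological spread around the
group mean is 3 percentage points (the cohort shows wide inter-patient
variation).  Sequencing errors are uniform and substitution-symmetric at
e = 0.001 per base (e/3 per specific change), matching the detector's
null; e is a visible configuration knob since no instrument error rate
is published, and Phred symbols encode the quality corresponding to e.
IsomiR structure: 5' offsets {0: 0.80, ±1: 0.08, ±2: 0.02} and templated
3' trimming {0: 0.80, 1: 0.15, 2: 0.05} — enough to exercise the offset
logic without dominating the signal.  The edited miRNA is given a large
library share (the miR-200 family dominates ovarian epithelial small-RNA
libraries), so its hotspot is covered by several hundred reads per
sample at the simulated depth.

Survival is exponential with log mean survival time linear in the
standardised editing level (baseline 36 months, administrative censoring
at 84 months, matching the cohort's observed 8–82-month range).  The
coupling coefficient β = −0.8 was calibrated so the simulated Pearson
correlation between editing level and overall survival reproduces the
reported effect size (r ≈ −0.56) at n = 60; FIGO stage and the TNM M
flag increase with the editing level plus unit-variance noise.  Control
samples carry no outcome data.  The per-sample editing level drawn for
the clinical table also drives that sample's read simulation, so the
read-level estimate, the clinical outcome and the group difference are
mutually consistent, as they are in a real cohort.

Gene counts are negative-binomial (dispersion 0.1, lognormal baseline
means around 200, library-size factors 0.7–1.3×) for a two-arm mimic
contrast with 8% DE genes at |log₂FC| = 2; the planted target genes are
forced downregulated and kept off the low-count-filter floor (real
candidates emerge from the DEG analysis and are by construction
expressed).  Their UTRs carry planted edited-seed 8mer sites (3/1/2 for
the three planted genes) in random backgrounds free of both seed cores;
the prediction list contains the planted genes (scores 70–100) plus
predicted decoys that fail exactly one cascade criterion.  qPCR runs are
Gaussian around per-group mean Ct with the edited species halved under
ADAR1 knockdown.

All generators are pure functions of (parameters, seed); seeded reruns
are byte-identical, and pipeline manifests record sha256 checksums.

### What the synthetic data does not capture

Cross-mapping to non-miRNA loci, genomic SNPs masquerading as edits,
position-dependent error profiles, adapter dimers and UMI structure,
non-exponential survival, covariate structure (age, BMI), and the real
MXI1 3'UTR sequence — the bundled MXI1-pattern UTR is a synthetic
stand-in constructed to the published property (three edited-seed sites,
no wild-type site).  Passing tests therefore demonstrate that the
implementation recovers known truth under its stated error model at
scaled-down depth, not that it would be artefact-free on raw instrument
data.

## Problem sizes

Defaults were chosen so a full cohort analysis is seconds, not hours:
4000 reads/sample (hotspot coverage of several hundred reads — deep
enough that measurement error is well below the biological spread, the
regime real million-read libraries are in), 400 genes, 10/group in the
mimic contrast.  Detector calibration uses 200 sites × 50 replicates;
the end-to-end recovery analysis uses 20 seeded cohort replicates.

## Numerical notes

Exact binomial tails come from the regularised incomplete beta (scipy);
BH is the statsmodels step-up; Kaplan–Meier and log-rank are lifelines,
cross-checked in tests against hand product-limit computations; TMM,
the moderated test, the aligner, the trimmer, the site scanner and the
qPCR arithmetic are implemented here and tested against literal
re-implementations of their definitions, enumeration oracles, or closed
forms.  Degenerate inputs fail loudly: zero mapped reads, all-zero
libraries, constant vectors in correlations, non-A positions in edit
operations and positive qPCR slopes all raise errors rather than
returning silent defaults.  Ties in the aligner are conservative
(ambiguous, excluded); ties at the survival median go to "low"; the
E = 1.6 efficiency boundary is kept.
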