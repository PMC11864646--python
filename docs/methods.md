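# Methods

`cmakit` implements the computational core of a chaperone-mediated
autophagy (CMA) study pipeline: motif scanning of proteomes, a
transcriptional CMA activation score, qPCR relative expression,
label-free protein quantification, and motif-class enrichment, with
seeded generators producing every input the pipeline consumes.

## KFERQ-like motif rules

CMA substrates carry a pentapeptide targeting signal recognised by
HSC70. The scanner evaluates every window of width 5 with the anchor
at either end (window position 1 or 5, 1-based) and the remaining four
residues forming the body. Residue chemistry classes:

| class | residues |
|---|---|
| hydrophobic | F, I, L, V |
| positive | K, R |
| negative | D, E |
| phospho-acceptor | S, T, Y |
| anchor | Q (or K for the acetyl-generated class) |

- **Canonical**: anchor Q; body = 1–2 hydrophobic + 1–2 positive +
  exactly 1 negative, and nothing outside those classes.
- **Phosphorylation-generated**: anchor Q; body has no D/E but exactly
  one S/T/Y (which acquires the negative charge upon phosphorylation),
  plus 1–2 hydrophobic and 1–2 positive.
- **Acetylation-generated**: K in the anchor position (acetyl-lysine
  mimics glutamine); body satisfies the canonical composition. The
  anchor K does not count toward the body's positive quota.

Conventions: coordinates are 0-based half-open; overlapping hits are
all reported; a Q in a body position belongs to no class and
invalidates that anchor reading; windows containing X are skipped
(FASTA input rejects ambiguity codes unless explicitly allowed, since
the rules are undefined for them). C and W are not counted as
hydrophobic and N does not substitute for Q; both sets are arguments
of `classify_pentapeptide` for sensitivity analysis. All classes
satisfied over both anchor readings are reported as a set; under this
particular rule table the set is in fact always a singleton or empty —
any Q in the window invalidates a K-anchor reading and the
canonical/phospho body requirements are mutually exclusive — but the
reporting contract does not rely on that.

The classifier is verified exhaustively against an independent
brute-force evaluator of the rule table over all 20^5 pentapeptides
(zero disagreements).

## CMA activation score

The score aggregates the expression of the CMA network — effectors
plus positive and negative modulators — into one signed number per
sample:

    S_j = Σ_g  w_g · d_g · T(x_gj)

with direction d_g = +1 (promotes CMA) or −1 (inhibits), and weights
derived from paralog-family structure: each gene in a family of n
paralogs gets w = 1/n (the family contributes 1 in total), except the
LAMP2A family — the rate-limiting receptor — whose family total is 2,
split between paralogs in proportion to their measured relative
contribution to CMA activity (equal split by default; measured
fractions and explicit per-gene weights are accepted and logged).

**Transform T.** Default is log2 fold change versus the per-gene
geometric mean of a reference group, which centres the reference at
score 0 and makes the score additive in log2 effect sizes (a doubling
of one positive singleton gene adds exactly +1·w). `fold_change` and
`zscore` are provided for sensitivity analysis. The literature
describes the score both as a weighted average and as a sum; the
implementation computes the weighted **sum** and exposes
`average=True` to divide by total weight — the two differ by a
constant factor and never change direction or test results.

**Undetected transcripts.** A measured zero (e.g. a knocked-out
transcript) has no log2 value. The default assigns it a detection
floor of −10 log2 units relative to the reference (≈0.1% of reference
level, below qPCR dynamic range): biologically, losing the
rate-limiting receptor should drag the score down decisively, not
drop out of it. The floor is a parameter (`undetected_floor_log2`);
passing `-inf` excludes such cells instead, which treats knockout and
non-measurement identically and is appropriate when zeros mean
"not assayed".

**Missing genes.** Unmeasured genes are excluded per sample; with the
default `exclude_renormalize` policy the used weights are rescaled so
their sum equals the full network total, keeping scores comparable
across tissues that detect different gene subsets (a tissue lacking
one transcript is not biased toward 0). `exclude` keeps raw weights.

Group comparison delegates to standard routines: a two-tailed
equal-variance t-test for two-group designs, and a two-way additive
ANOVA (tissue + condition, type II) for multi-tissue designs.

## qPCR relative expression

ΔCT method: ratio = 2^−(Ct_target − Ct_reference), assuming perfect
doubling per cycle. E-method: ratio =
E_t^−Ct_t / E_r^−Ct_r with measured per-primer amplification
efficiencies in (1, 2], computed in log space; with E = 2 it reduces
exactly to ΔCT. Fold induction divides per-sample ratios by the
**geometric** mean of the reference group (Ct-derived ratios are
log-scale quantities), so the reference group's geometric mean maps
to 1. Undetectable (zero) expression yields fold 0 with a flag, never
silent omission. The lysosomal binding/uptake assay arithmetic —
uptake = association − binding in densitometric units — returns
negative values flagged rather than clamped, since small negative
differences are noise around zero uptake.

## Label-free quantification (median-ratio fitting)

Input is a long table of ion intensities (protein, ion, run); zeros
are treated as missing (non-observation, not true absence). Per
protein:

1. **Pairwise ratios** — for each run pair, the protein ratio is the
   median over ions observed in both runs (pairwise-complete; even
   counts use the mean of the two middle ratios, in ratio space). The
   lower triangle is filled with reciprocals, so M[s,r] = 1/M[r,s]
   holds by construction; pairs sharing no ion are left undefined.
2. **Least squares** — in log2 space, one equation x_r − x_s =
   log2 M[r,s] per defined pair, solved by ordinary least squares.
   Log2 space makes up/down ratios symmetric and the gauge structure
   linear. The run graph must be connected; disconnected proteins are
   reported (and skipped with a warning in the bulk driver).
3. **Rescaling** — the additive gauge freedom is fixed by scaling so
   the per-run abundances sum to the protein's total observed ion
   abundance across runs.

On noise-free data with multiplicative ion and run factors this
reconstruction is exact (relative error at machine precision), and
under lognormal ion noise its error shrinks as the ion count grows.

**Differential abundance** uses a two-tailed pooled-variance Student
t-test on log2 abundances; log2 fold change is the difference of
group means of log2 values. No multiple-testing correction is applied
by default (mirroring the raw p < 0.05 convention of the analysis
this emulates); proteins with fewer than two usable runs in either
group are skipped and logged, and zero-variance cases are flagged
degenerate rather than given a fabricated p. Hits are called **up**
when p < 0.05 and fold change > 1.41, **down** when p < 0.05 and
fold change < 1/1.41; summary percentages are reported to one
decimal. The source analysis states both ±2 and 1.41 as relevance
thresholds; 1.41 (the value behind its headline counts) is the
default and 2 is available by flag.

## Enrichment

Per protein set and motif class, prevalence is the fraction of
proteins with ≥1 hit of the class (a protein with many hits counts
once). Association between two sets is Fisher's exact test: odds
ratio by cross-product (a·d)/(b·c), flagged infinite on a zero
denominator, and the two-sided exact p as the sum of hypergeometric
probabilities of tables (same margins) no more probable than the
observed one — the common two-sided convention, stated explicitly
because conventions differ. No continuity correction; sets here are
small, so only the exact test is offered.

## Synthetic data

All generators are pure functions of (parameters, seed), using NumPy's
`default_rng` (PCG64); identical seeds give bit-identical outputs
within this implementation.

- **Proteomes**: backgrounds are motif-free by construction (anchor
  residues of any accidental motif are neutralised to glycine, which
  belongs to no chemistry class and can never create a new motif);
  planted pentapeptides of exactly one class are padded with 4-glycine
  flanks, so a scan recovers exactly the planted truth. Residue
  composition is otherwise uniform — real proteomes are not, so
  absolute hit rates here say nothing about real motif frequencies;
  only the scanner's correctness is exercised.
- **Network expression**: controls at baseline 1 with log2-normal
  noise (σ = 0.25, a typical qPCR biological CV); knockout sets one
  transcript to exactly 0 (undetected); the stressor multiplies
  positive-direction elements by 2, emulating coordinated induction
  under hypoxia. Group sizes default to 7 (the knockout design) and
  6 is used for the stressor analyses. Real designs have gene-specific
  effect sizes and correlated regulation; the generator's uniform
  induction is deliberately simple so the expected score shift has a
  closed form (Σ of positive weights).
- **Ion abundances**: ion base intensities 2^N(20, 2) (≈10^6 scale),
  per-run protein factors 2^N(0, 1) unless supplied, lognormal ion
  noise, missingness applied cell-wise but repaired to keep every ion
  observed and each protein's run graph connected. No retention-time
  structure, detector saturation, or intensity-dependent missingness
  is simulated — passing tests show the fitting arithmetic is right,
  not that real LC-MS artefacts are handled.
- **qPCR**: Ct = baseline − log2(fold) + N(0, σ cycles), σ = 0.15 by
  default (typical technical replicate scatter); the reference gene is
  held at baseline.

## Problem sizes and numerics

The shipped analyses use 150 proteins × 30 planted motifs per class,
7+7 and 6+6 expression samples, 400 proteins × 8 runs × 5 ions for
the differential experiment, and 100 replicates per direction-recovery
simulation; these sizes give stable statistics while keeping every
analysis in seconds. Tolerances: weight-sum checks at 1e-12,
noise-free quantification at 1e-9 relative, contribution fractions
must sum to 1 within 1e-9. Ties in the pairwise median use NumPy's
mean-of-middle-two convention. `lstsq` is used with `rcond=None`; the
solution is shifted to its maximum before exponentiation to avoid
overflow prior to rescaling.

## Limitations

- The CMA score is a transcriptional proxy; nothing here claims it
  equals lysosomal CMA activity, and the network gene list/weights
  are inputs, not claims (the bundled example network is illustrative).
- Quantification starts from an ion-abundance table; database search,
  spectral processing and cross-assignment are out of scope.
- The motif rule table is configurable because published finders
  differ in edge conventions (hydrophobic membership, N-for-Q
  substitution); results on shared sequences should be compared, not
  assumed identical, against any external tool.
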