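# Methods

`asra` re-implements, as a tested pipeline, a strategy for discovering gene
signatures of asymmetric self-renewal — the defining division pattern of
non-embryonic ("distributed") stem cells — from a three-state engineered
cell-line microarray design, and for evaluating such signatures as
self-renewal-pattern classifiers.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic test
bed does and does not establish.

## The three-state design and the intersection classifier

The experimental design contrasts three congenic fibroblast states grown
under identical (Zn-supplemented) conditions:

* **ASYM** — p53-inducible cells undergoing asymmetric self-renewal
  (3 replicate arrays);
* **SYM** — p53-null vector controls, symmetric self-renewal (3 arrays);
* **p53SYM** — p53-induced cells forced back to symmetric self-renewal by
  constitutive IMPDH II expression (2 arrays).

Two rank-products comparisons are run: **A** = ASYM vs SYM and
**B** = ASYM vs p53SYM.  A gene significant in the same direction in both
comparisons is *asymmetric-self-renewal associated* (ASRA_up / ASRA_down):
its change requires the asymmetric state itself, not merely p53 induction or
IMPDH II loss.  Genes significant in exactly one comparison, or in opposite
directions, fall into the six remaining self-renewal-pattern-associated
(SRPA) categories (A_up, A_down, B_up, B_down, A_up/B_down, A_down/B_up).
Up-regulated ASRA genes whose detection call is "A" (absent) on **every**
SYM array are flagged *exclusive*; absence on every array of at least one of
the two symmetric states sets the broader absent-in-any flag.  Marginal
("M") calls never count as absent, and absence requires unanimity across a
state's replicate arrays.

## Rank products and the pfp estimate

For an n1-vs-n2 comparison all K = n1·n2 one-vs-one log2-difference lists
are formed.  Gene g's statistic is the geometric mean of its K ranks
(rank 1 = most up-regulated; the down-regulated direction is ranked
separately).  Tied differences share their average rank: a positional
tie-break would hand one gene the best rank of its tie block in every list
and manufacture spurious cross-list consistency — in the noiseless limit,
where all undifferentiated genes tie at a difference of zero, that artifact
alone produces hundreds of false intersection calls, while average ranks
leave the noiseless limit exact.

Significance is controlled by the percent-false-positive (pfp) estimate, a
false-discovery-rate-style quantity: with E_g the expected number of null
rank products at or below the observed one per permutation round and rho_g
the (ascending, average-for-ties) rank of the observed statistic,
pfp_g = E_g / rho_g.  Values are not clipped at 1, and a gene is called at
pfp ≤ cutoff (default 0.05).  A cutoff of exactly 0 disables calling, since
a sampled pfp of 0 only means "below the permutation resolution".

Two permutation nulls are available:

* **within-array** (default): every permutation round shuffles the gene
  assignment independently within each array and recomputes all K lists.
  Lists that share an array are correlated — a gene whose replicate noise
  happens to align is favored in several lists at once — and this null
  carries exactly that dependence, because the shuffled arrays feed the same
  list construction.
* **independent-lists**: each list's rank vector is replaced by an
  independent uniform permutation of 1..G (the original rank-products null).
  For pairwise lists built from shared arrays this null is strongly
  anti-conservative: measured on the default synthetic design it
  underestimates the tail mass of the null statistic by a factor of ~25 and
  admits on the order of two hundred false calls per direction at
  pfp ≤ 0.05.  It is retained because it is the published formulation, it is
  exactly testable by exhaustive enumeration on toy instances, and it is the
  correct null whenever the lists really are independent experiments.

B = 100 permutation rounds is the default; the estimate pools B·G null
values, so even the extreme tail is resolved at the default problem size.
Seeds are mandatory for every stochastic call; per-stage seeds are spawned
from one master seed.

## Between-group analysis (BGA)

Supervised ordination by correspondence analysis (COA) of the genes ×
group-mean table.  With two groups — the training contrast is ASYM vs the
merged SYM/p53SYM pool — there is exactly one non-trivial axis.  COA follows
the standard construction (P = N/total, residual
S = D_r^(-1/2)(P − r cᵀ)D_c^(-1/2), SVD of S); axes with singular value
below 1e-12 of the largest are dropped, so a table with proportional columns
yields a zero-inertia, degenerate model that refuses projection.

New samples are placed on the axis by the supplementary-column transition
formula: the sample's column profile (values normalized to sum 1 over the
model genes) averaged over the standard row coordinates, equivalently the
principal-coordinate projection scaled by 1/√eigenvalue.  A sample whose
profile equals a training group's mean profile lands exactly on that group's
centroid.  Expression must be nonnegative (log2 intensities are); negative
input is refused with an explicit opt-in global shift.

Conventions, configurable but fixed by default:

* orientation — the symmetric-reference group centroid is positive, so
  "symmetric character" is the upper field and "asymmetric character" the
  lower, matching the training classification field;
* decision boundary — midpoint of the two group centroids (the published
  figure shows a boundary line without defining it; the midpoint is the
  symmetric choice);
* boundary ties are labeled symmetric-character and logged;
* when a test set lacks part of the signature, the model is refitted on the
  shared gene subset before projection (logged); no additional normalization
  is applied to external sets;
* group separation is tested with the pooled-variance (not Welch) two-sided
  Student's t on the axis coordinates; zero pooled variance degenerates to
  p = 1 (equal means) or p = 0 (unequal, logged).

## Random-subset uniqueness evaluation

A discovered signature's specialness is quantified against size-matched
random gene subsets: each subset is evaluated by the same
fit-project-t-test procedure, giving a null distribution of discrimination
p-values.  Reported quantities: the signature's percentile (strict
inequality p < signature_p; 10,000 draws by default, 200 in the test
profile); the frequency with which better-than-signature subsets contain
k = 0, 1, 2, … signature genes against the exact hypergeometric expectation;
and, given two external test sets in asymmetric/symmetric roles, each
subset's test-set separation relative to its training separation, with
ratios ≤ 0 pooled as "<0" and the fraction > 1 summarized.  Subsets are
drawn without replacement from the full analyzed universe, independently
across draws; whole runs are bit-reproducible for a fixed seed.

One property of the published procedure deserves emphasis: the
discriminator axis is fitted on the *same* eight training samples whose
projections are then t-tested.  The axis is therefore selected toward
separation, and on data with no group structure at all the subset p-values
concentrate near zero (measured median ~1e-4) instead of being uniform.
The percentile and enrichment statistics are unaffected — they compare the
signature against subsets evaluated by the identical procedure — but the
absolute p-values should not be read as calibrated significance levels.
The corresponding uniformity check in the acceptance suite documents this
gap and fails by design.

## Assay metrics

The sister-pair (SPr) and cytochalasin-D (CD) assays score asymmetric
biomarker expression between sister cells (or sister nuclei) under
ASYM- and SYM-promoting conditions.  Under the simplifying model that the
engineered lines are 0% asymmetric under SYM conditions and 100% under ASYM
conditions, the condition × call table is a confusion matrix:
TP = asymmetric-pattern calls under ASYM conditions, FP = such calls under
SYM conditions, and sensitivity/specificity/PPV follow in the usual way,
rounded half-away-from-zero to integer percent.  Published tables print
rounded percentages; the integer counts are recovered as the k with
round(100k/n) equal to the printed percent and minimal rounding error
(ties → smaller k; an optional lenient mode accepts the globally nearest k
when no count rounds to the printed value).  All six published PPVs
reproduce exactly from the printed (%, n) pairs.  The published Sen/Spe
columns do **not** follow from this model with the standard confusion-matrix
formulas (under it, sensitivity is identical to the printed ASYM-condition
pattern rate); the package reports the model-derived values and does not
force agreement.  Fisher's exact test is two-tailed with the
probability-mass criterion (scipy's implementation; the test suite checks it
against full margin-fixed enumeration).

Population-division-cycle bookkeeping labels a culture's growth kinetics:
symmetric self-renewal doubles the cycling population per cycle
(PDC_sym = log2(nt/n0)); pure asymmetric self-renewal keeps one cycling cell
per lineage and adds one arrested cell per cycle (PDC_asym = nt/n0 − 1).
Whichever is nearer the known culture duration (2 cycles in the original
design) labels the culture.

## The synthetic test bed

The generator plants the published signature composition into a
22,587-gene, 8-array design: 78 ASRA_up (11 of them exclusive, 20 absent in
at least one symmetric state), 7 ASRA_down, and 320/265/194/56/5/5 genes in
the six SRPA categories (845 total).  Per-state true means are baseline +
nonnegative shifts realizing each category's semantics; the "similar" state
pairs (e.g. p53SYM ≈ ASYM for A-only genes) are equal true means, so their
non-significance is left entirely to noise and the pfp cutoff.  Planted
log2 shifts are 2.0 (4-fold) except the ASRA_up genes, which span 2.0–4.52
(4- to 23-fold, the published induction range of the most-induced genes).
Observed values add i.i.d. Gaussian noise (sd 0.15 log2 units, a tight
technical-replicate scale); detection calls threshold the observed value
(A below τ = 5.0, M within the 0.5-wide marginal band, P above).  Baselines
are Normal(8, 1.5) truncated ≥ τ + band + 0.6 so that detectable states
essentially never produce spurious absent calls; states planted as
undetectable sit at 4.0, far below τ relative to the noise.  External-style
test sets reuse the planted means: NSC-like samples carry the ASYM-state
profile, ESC-like the SYM-state profile, with optional random gene dropout
simulating platform mismatch.

What the generator does *not* emulate: gene–gene correlation, per-gene
variance heterogeneity, heavy-tailed or intensity-dependent noise, batch and
spatial artifacts, and probe-level effects.  Passing recovery tests
therefore show that the pipeline's inference machinery is correct under its
own assumptions — planted structure is recovered essentially exactly at the
default conditions — not that real arrays would yield an equally clean
boundary.  On real data the pfp threshold lands wherever the continuous
effect/noise landscape puts it.

A note on what "exact recovery" can mean: pfp is an FDR-type quantity, so at
cutoff 0.05 a perfectly calibrated estimator would tolerate roughly
0.05/0.95 × (number of true calls) false calls per direction — about 20 here.
The within-array null is conservative in the extreme tail (its shuffled
rounds recycle the planted effects into occasional aligned configurations,
inflating E_g exactly where the first false positives would appear), which
is why recovery of the planted composition is typically exact, with at most
one or two single-comparison false calls at some seeds.

## Problem sizes and defaults used by the shipped checks

The acceptance script and the recovery tests run the full default design
(22,587 genes × 8 arrays, B = 100, pfp ≤ 0.05); a discovery run takes a few
seconds.  The uniqueness machinery is exercised at 200 subset draws
(10,000 remains the library default); unit tests use a 400-gene scaled-down
composition.  All stochastic stages take explicit integer seeds, and
identical seeds reproduce results bit-for-bit.

## Known limitations

* Two-group BGA only; multi-group designs and randomization tests of the
  axis are out of scope.
* Cross-platform gene matching is exact-string (plus an optional two-column
  id-mapping file); no probe-set remapping is provided.
* Expression input is assumed already log2-normalized and complete; there is
  no background correction, normalization or imputation.
* The independent-lists pfp null should not be combined with pairwise lists
  from shared arrays except for comparison purposes (see above).
* Percentile/enrichment statistics of the uniqueness evaluation are
  internally consistent but, because of the fit-then-test selection effect,
  the underlying p-values are not calibrated tail probabilities.
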