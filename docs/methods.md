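# Methods

## Model of the data

The pipeline operates on gene × sample matrices of log2 expression with a
three-arm design per lot (vehicle control, low dose, high dose; five
replicates per arm by default) across several lots of pooled primary
hepatocytes. The lot is the unit of biological replication; replicates
within an arm are treated as exchangeable. All analyses default to the
high-dose-vs-control contrast, since the low dose produces only minimal
injury; the contrast is configurable.

## Differential expression

Fold change is the difference of arm means on the log2 scale. The log2
base is a package convention — report tables in this field are labelled
log2(FC), and all thresholds here are interpreted on that scale.

Significance uses a per-gene Welch unequal-variance t-test on the log2
values with Welch–Satterthwaite degrees of freedom, then
Benjamini–Hochberg step-up adjustment; a gene is called differentially
expressed when q ≤ 0.1 (boundary inclusive). The Welch test is a
deliberately simple, fully documented gene-level test for matrix-shaped
inputs: this package starts from gene-level log2 expression, so
transcript-abundance variance modelling (bootstrap/shrinkage estimators)
is out of scope by design, and the test is isolated behind a single
operation (`welch_test`) so an alternative can be substituted. Genes with
zero variance in both arms get p = 1 when the arm means agree (no
evidence), p = 0 when they differ exactly.

## Gene-set scoring

For a set S with members measured in the fold-change map:

* AAFC(S) = mean |FC| over measured members — direction-blind; used for
  injury modules and toxicity feature sets;
* AFC(S) = mean signed FC — carries direction; used for pathway display.
  |AFC| ≤ AAFC always (triangle inequality).

The permutation null draws `n_perm` (default 10,000) random subsets of the
same size, uniformly **without replacement**, from the measured-gene
universe of the same lot's fold-change table (not the union across lots).
Then

* z = (raw − null_mean)/null_sd, with sample SD over the null draws;
* p = (1 + #{null ≥ raw}) / (n_perm + 1) — the add-one rule avoids zero
  p-values, and "≥" is used for conservatism;
* a module is *activated* when z ≥ 2 (configurable `z_activation`).

Degenerate nulls (all draws identical, e.g. a constant |FC| universe or a
set equal to the whole universe) are flagged and reported with z = 0.
Ties and degeneracy are detected at a relative tolerance of 1e-12 because
float summation order varies across draws. For AFC a signed display value
z_signed = sign(raw)·|z| is also reported. Sets with fewer than
`min_genes` (default 3) measured members are reported NA rather than
scored. Nulls are cached per (lot, method, set size), so collections of
equally sized sets share one null; each null's seed derives
deterministically from the global seed via a seed sequence keyed by lot
and set size.

Feature-set toxicity scores are plain per-lot AAFC values summarised by
the cross-lot mean and sample SD. A generic one-sided hypergeometric
over-representation test (BH-adjusted across sets) is included as
plumbing for enrichment tables; it makes no claim to reproduce any
specific annotation backend.

## Consistency analytics

* Overlap matrix: |DE_i ∩ DE_j| with per-lot DE counts on the diagonal.
* Common genes: the intersection of DE calls across *all* lots.
* Merged profile: unweighted per-gene mean FC across lots (and, for set
  scores, the unweighted mean of per-lot z). The merged column
  participates in correlation matrices even though it is a function of
  the lots — the inclusive convention; correlations of a lot with the
  merge therefore include that lot's own contribution.
* SD profiles: per-gene (or per-set) sample SD across lots, with the
  fraction **strictly below** each threshold (defaults 0.5 and 1.0).
* Cross-lot summary statistics use the arithmetic mean and the sample SD
  (n−1). The n−1 choice was validated by recomputing published panel
  rows from their printed per-lot values (e.g. the CYP26B1 row's SD of
  1.66 matches n−1, not n).
* Top-k tables rank the merged FC (restricted to the common genes when
  they exist); ties break by gene symbol ascending.
* Sign consistency: `consistent_up` iff every lot's FC > 0,
  `consistent_down` iff every FC < 0, otherwise `mixed`; an exact zero
  breaks consistency. Genes with a consistent direction but no
  significant call in any lot carry a star annotation.
* Report tables round half-away-from-zero at 2 decimals; full-precision
  values are always emitted alongside.

Printed per-lot panel values (transporters, CYPs, PTGS/TMG scores) are
shipped in `pooltox.panels` as reference inputs for these summaries. Two
published rows whose printed Avg./SD are not self-consistent with their
own printed per-lot values at 2 dp (a rounding artefact of the source
tables) are not used as checks.

## Synthetic data generator

The generator emulates the study design on the log2 scale: per-gene
baselines ~ N(6, 2²), Gaussian replicate noise with SD 0.25, 5 lots × 3
arms × 5 replicates, 15,000 genes by default. The treatment response is

* a shared core of `n_core_de` (default 800) genes with signed effects:
  |effect| ~ N(1.0, 0.5²) clipped below at 0.2, random sign, multiplied
  per lot by (1 + N(0, 0.3²)) jitter — producing correlated but
  heterogeneous lot responses;
* `n_lot_specific_de` (default 1,500) additional DE genes **private to
  each lot** and disjoint across lots — chosen to reproduce the
  qualitative pattern of weak all-gene lot-to-lot correlations alongside
  strong common-gene correlations;
* optional injected gene sets: member effects |effect| ~ N(m, 0.2²)
  clipped at 0.05 with random signs, where m is the requested mean
  magnitude; auto-generated random null sets accompany them as negative
  controls;
* low-dose effects are the high-dose effects scaled by 0.15 (a minimal
  injury at the low dose).

Gaussian log-scale simulation is deliberate: the pipeline's inputs are
log2 matrices, and read-level quantification is outside its scope. The
generator therefore does **not** emulate count-level mean–variance
structure, library-size effects, donor demographics, or dose–response
viability; passing tests demonstrate the correctness and calibration of
the analytics on log-normal data, not distributional robustness to raw
RNA-seq artefacts. Within-lot replicate variance of the real assay is not
published, so residual_sd = 0.25 is a design choice giving a per-gene FC
standard error of 0.25·√(2/5) ≈ 0.16 — small enough for well-powered
calls at |FC| ≈ 1, large enough that weak effects are missed, as
observed in practice. One global seed drives a per-purpose seed sequence
(baseline, effects, set membership, noise), so identical configs are
byte-identical.

## Numerical and design choices

* BH adjustment and the Welch p-value are delegated to statsmodels/scipy;
  both are cross-checked in the test suite against independent
  brute-force/closed-form oracles.
* The permutation z uses the same null as the empirical p — one
  resampling scheme, self-consistent and directly testable against
  exhaustive enumeration on small universes.
* Permutation draws are vectorised via random-key partial sorting
  (equivalent to a partial Fisher–Yates shuffle) in bounded-memory
  chunks.
* The "random fold-change selection" null is read as random *gene
  subsets* of the observed fold-change universe, the natural reading for
  set-size-matched nulls.
* Zero-variance correlation cells are NA, not errors.
* Validation sizes: null calibration runs at 2,000 genes; power/recovery
  at 3,000 genes with core/lot-specific DE counts scaled to the same
  proportions as the 15,000-gene defaults (160/300) over 20 seeds with
  2,000 permutations — large enough for stable rates, chosen as the
  package's standard benchmark sizes. Injected-set activation is judged
  on the merged (lot-averaged) z, the consensus metric.

## Known limitations

* The Welch test assumes approximate normality of log2 expression within
  arms; with n = 5 per arm this is a pragmatic, not optimal, choice.
* AFC nulls for very asymmetric fold-change distributions are skewed;
  the z-score is a summary, not an exact standard-normal deviate, which
  is why the empirical p is always reported alongside.
* Single-lot studies degrade gracefully (merged = the lot; no
  correlations or SD profiles), but consistency analytics are only
  meaningful with ≥ 2 lots.
* The ORA component depends entirely on user-supplied annotation sets;
  no annotation database is bundled.
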