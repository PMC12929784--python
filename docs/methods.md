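# Methods

## The analysis

`dnarna` analyzes cohorts in which tumor DNA and tumor RNA were profiled on
the same gene panel, producing call-level tables: per patient, a set of
genes with genomic alterations (each call classed as frameshift/stop-gain,
copy-number gain or loss, missense SNV, fusion/rearrangement, or splice
site) and a set of genes with altered expression (over- or
under-expressed). Four questions are addressed:

1. **Same-gene concordance.** A *concordant event* is a (patient, gene)
   pair altered by both assays. Directional consistency is deliberately not
   required — a deletion paired with overexpression still counts — because
   the event definition is "alterations in the same gene", with alteration
   classes tabulated separately. When a (patient, gene) carries several DNA
   classes, a single *primary class* is assigned by the priority
   copy-number gain > copy-number loss > fusion > splice site >
   frameshift/stop-gain > missense (configurable); copy-number dominance at
   the event level motivates putting it first. Among events carrying both a
   copy number and an expression score, their association is summarized by
   the Spearman midrank correlation. Detectability of concordance depends
   on tumor purity; the package tests this with a two-sided Mann-Whitney U
   comparison of purity between patients with and without events.

2. **The exhaustive pair screen.** Every gene reported by DNA profiling is
   crossed with every gene reported by RNA profiling. For each pair
   (g, h) a patient-level 2×2 table is built — with/without a DNA
   alteration in g crossed with with/without an expression alteration in h,
   membership counted as distinct-gene presence — and tested with the
   two-sided Fisher exact test (minimum-likelihood rule: the p-value sums
   hypergeometric probabilities of all tables at the observed margins no
   more probable than the observed one). A pair with a zero row or column
   margin has p = 1 and an undefined odds ratio. Benjamini-Hochberg
   correction runs across the full family of pairs, including zero-margin
   pairs — the family is "all pairs", not "testable pairs". Pairs whose two
   genes are the same symbol are *concordant pairs*; significance is
   adjusted p < α (default 0.05). Output ordering is deterministic:
   adjusted p, then raw p, then lexicographic.

3. **Annotation.** Genes appearing in significant pairs (union of both
   sides) are tested for over-representation against a GMT gene-set
   collection filtered to sets with ≥10 and <250 members. The test is the
   one-sided hypergeometric upper tail P(X ≥ overlap) with
   X ~ Hypergeom(N = |universe|, K = |set ∩ universe|, n = |query|); BH runs
   across all filtered sets, and sets are reported when overlap ≥ 10 and
   adjusted p < 0.05. The default background universe is the union of the
   filtered sets' members — self-contained, no external gene catalog — and
   can be overridden. Significant pairs are also joined against a directed
   TF→target edge list (TRRUST-v2 dialect); the match is directed (the
   DNA-altered gene must be the regulator). Two edge-disjoint networks are
   built — TF-target pairs and the remainder — with DNA genes as sources,
   RNA genes as targets, and edge weight −log10(adjusted p); an adjusted p
   that underflows to zero is clamped to the smallest positive float so
   weights stay finite.

4. **Tumor transcriptional burden (TTB) and survival.** TTB is the
   per-patient count of distinct genes with altered expression. Patients
   are stratified at configurable TTB breakpoints (default upper bounds
   [2, 5], i.e. 0–2 / 3–5 / ≥6 genes — the optimal cut-off is an open
   question, hence the config knob), and overall survival in the treated
   subset is summarized per stratum by the Kaplan-Meier product-limit
   estimator with Greenwood standard errors and compared by the k-sample
   log-rank test (χ² on k−1 df). Ties follow the standard convention that
   deaths precede censorings at equal times; survival time is in months
   with right censoring. TTB is also compared between PD-L1-negative and
   PD-L1-positive patients (unknown status excluded from this test only)
   with a two-sided Mann-Whitney U test using tie and continuity
   corrections; exact enumeration is used when both groups have ≤8
   untied observations.

Baseline-characteristics 2×2 comparisons use the Pearson chi-squared test
with the Yates continuity correction ON by default (|O−E| shrunk by 0.5,
floored at 0). The correction matters: on a published-style cohort
comparison the age row gives p = 0.207 with Yates vs 0.174 without, and a
near-balanced sex split reaches p = 1 only with the floored correction.

## Missing data

LDH, tumor purity, and PD-L1 status may be missing and are excluded
pairwise from exactly the tests that use them; patients are retained
everywhere else. Duplicate RNA rows for one (patient, gene) are collapsed
with a warning; DNA calls are deduplicated on (patient, gene, class). Gene
identity is exact match on the normalized (uppercased, stripped) symbol; an
optional alias map hook exists but no alias table is bundled.

## The synthetic cohort generator

Real patient-level data of this kind are not publicly deposited, so the
package ships a seeded generator whose defaults emulate the statistical
structure the analysis assumes. All randomness flows from one integer seed
through `numpy.random.default_rng`; identical config + seed gives
byte-identical TSVs.

Defaults and calibration (all overridable in `SimulationConfig`):

- 253 patients; 242-gene DNA universe, 52-gene RNA universe (a subset of
  the DNA universe so same-gene concordance is observable). Gene
  frequencies are Zipf-like (DNA exponent 1.0, RNA 0.8): a minority of
  recurrently altered genes (TP53, KRAS, CDKN2A, …) dominate, as in real
  panels. The RNA frequency ranking leads with filler genes of moderate DNA
  frequency, keeping accidental same-gene overlap modest; VEGFA sits at
  RNA rank 5, so cross-gene structure between a DNA hotspot and a
  recurrently dysregulated transcript is representable and plantable.
- Per-patient distinct DNA-altered genes: negative binomial (r = 6,
  mean 4.45) truncated to [0, 21]; from the exact CDF the cohort median is
  4 with ≈97% probability at n = 253. Per-patient baseline
  expression-altered genes: an explicit probability vector on 0..9 chosen
  so that, after coupling-induced calls, the cohort median is 2 and the
  upper TTB strata are populated enough for per-stratum survival medians
  to be estimable (the vector was selected on seeds disjoint from those
  used in the test suite).
- Alteration classes drawn per call from the mixture 42.9% frameshift/
  stop-gain, 30.4% copy number (75% gains), 23.8% missense, 2.9% fusion;
  RNA directions 87.7% over / 12.3% under for baseline calls.
- Copy-number→expression coupling: a copy-number call in an RNA-panel gene
  induces the matching expression call (gain→over, loss→under) with
  probability 0.26 × tumor purity (purity ~ Beta(4.0, 2.2), mean ≈ 0.65).
  Copy number and induced expression score share a latent Gaussian with
  correlation 0.88; after pooling gains with losses and diluting with
  accidental overlaps, the realized Spearman correlation among concordant
  events averages ≈ 0.72. Coupling for non-copy-number classes exists but
  is off by default.
- Planted cross-gene pairs: for (g, h, ω), patients carrying a DNA
  alteration in g receive an expression call in h with probability raised
  so that the odds of h among carriers are ω times the cohort baseline
  odds. This is the hook used for screen-recovery experiments.
- Survival: OS is drawn per realized TTB stratum as exponential with
  stratum medians 9.8 / 11.9 / 6.7 months (low/mid/high) — drawn per
  stratum rather than via a monotone hazard in TTB because the target
  medians are deliberately non-monotone — with independent exponential
  censoring calibrated to a 20% censoring fraction. PD-L1 negativity is
  logistic in TTB (intercept −0.3, slope 0.15 per gene, 6% unknown), a
  weak anti-correlation. The treated flag is Bernoulli(217/253).

### What the generator does not emulate

Tumor-type-specific alteration spectra (tumor type is an independent
categorical), variant-level detail (positions, VAFs, reads), gene-gene
co-mutation structure beyond the planted pairs and frequency skew,
informative censoring, and covariate effects on survival other than the
TTB stratum. Passing recovery tests therefore demonstrates that the
pipeline detects the structure it claims to detect when present at the
configured strength — not that real cohorts contain that structure.

## Numerical choices

- Fisher p-values are memoized over distinct (n11, margin, margin, N)
  tuples; a full 242×52 screen at n = 253 runs in well under a second.
- BH is the step-up procedure (monotone, capped at 1), applied in input
  order via ranked cumulative minima.
- Mann-Whitney: normal approximation with tie and continuity corrections by
  default; exact enumeration when both groups ≤ 8 and untied.
- KM median is the first time the survival estimate drops to ≤ 0.5; it is
  NaN when the curve never reaches 0.5.
- Degenerate inputs yield explicit "insufficient data" results rather than
  exceptions for the rank tests and the Spearman summary (<3 usable
  events); structural errors (empty survival input, <2 log-rank groups,
  zero chi-squared margins) raise.
- Problem sizes in the statistical test suite — 100-seed null and planted
  screens, 50-seed survival recovery, 20-seed calibration — keep the whole
  suite in the low minutes on one CPU while leaving binomial noise well
  inside the asserted margins.

## Known limitations

- The enrichment universe default (union of filtered set members) makes
  enrichment p-values depend on the collection supplied; with a small
  custom GMT they are not comparable to catalog-wide results.
- The screen models presence/absence only; alteration class and direction
  do not enter the 2×2 tables (mirrored from the contingency definition).
- Concordance between genes assayed by DNA but absent from the RNA panel is
  unobservable in the call-level data model.
- No Cox regression or covariate adjustment; the survival module is
  deliberately limited to stratified KM + log-rank.
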