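# Methods

This note records the statistical models, conventions and design choices
behind `epiprog`, in the spirit of the methods documentation of packages
like statsmodels or msprime: what is computed, under which assumptions,
with which defaults, and what the synthetic validation does and does not
establish.

## Data model and coordinate conventions

Input files use 1-based, fully inclusive coordinates (methylKit-style CpG
tables: `chrBase chr base strand coverage freqC freqT`, with `F`/`R`
strand symbols; refGene-style annotation with `txStart`/`txEnd`).
Internally all positions are 0-based and intervals half-open; writers
convert back. Methylated counts are recovered from the percentage columns
as `round(coverage × freqC / 100)`; rows where `freqC + freqT` deviates
from 100 by more than 0.5 are rejected with the file and line named.
CpG calls from opposite strands are never merged: enhanced RRBS calls are
strand-resolved, and pooling them would entangle strand-specific coverage
noise. Sites missing from a sample are kept with coverage 0 (union
semantics), which downstream coverage filters then handle explicitly.

## Differential expression

Counts are transformed to `log2((count + 0.5) / library_size × 1e6)` with
library size the raw column sum. The 0.5 pseudocount avoids −∞ at zero
counts; no between-sample scaling beyond library size (e.g. TMM) is
applied, which is adequate as long as differential genes are roughly
balanced between directions — a strongly one-sided perturbation shifts
all log-ratios by the library-size ratio (see *Known limitations*).

The default test is a moderated t: per-gene pooled two-group variances
are shrunk toward a scaled inverse-chi-square prior whose parameters
(d₀, s₀²) are fitted across genes by matching the moments of log s²
(Smyth 2004), and the t statistic uses d₀ + d residual degrees of
freedom. At triplicate depth this moderation is not a refinement but a
requirement: a plain Welch t with ~4 degrees of freedom cannot push
p-values past a Benjamini–Hochberg threshold of 0.01 over thousands of
genes, and its end-to-end sensitivity for 8-fold planted changes is near
zero. The Welch variant remains available (`engine="welch"`) behind the
same interface for designs with more replicates. Calling thresholds are
inclusive: |log2FC| ≥ 2 and BH-adjusted P ≤ 0.01.

## Differential methylation

Per site, the methylation difference is the difference of
coverage-pooled proportions, `100 × (Σm_B/Σc_B − Σm_A/Σc_A)` — stable
under uneven coverage, unlike the mean of per-sample fractions. With at
least two samples per group the p-value is the likelihood-ratio test of
the binomial logistic model `methylated/coverage ~ group` against the
intercept-only model. Because group is the only covariate, both MLEs are
pooled proportions and the LRT has a closed form, which the
implementation vectorizes across sites; the statistic is referred to
χ²(1). The 1-vs-1 design falls back to a two-sided Fisher exact test,
which the validation suite checks against exhaustive hypergeometric
enumeration on every table with margins ≤ 40.

Replicates are pooled as binomial trials without an overdispersion
correction, mirroring the default behavior of the standard per-CpG
callers; the q-value is Benjamini–Hochberg over tested sites (methylKit
defaults to the SLIM correction, an external package's estimator with no
simple closed form; BH is conservative and testable, and the q-value
step sits behind a single function boundary if an alternative is
wanted). Sites with coverage below 10 in *any* sample of either group
are excluded before testing. A cytosine is a DMC at q ≤ 0.01 and
|Δmeth| ≥ 25 points, both inclusive.

Under the generator's beta-binomial replicate noise (precision 300) the
pooled false-DMC rate at these thresholds is ~10⁻⁵ per site: most null
datasets yield zero DMCs, an occasional one yields one or two, and since
a region call needs three DMCs in one gene region, stray singletons never
reach the integrated output.

## Regions and integration

Promoter: TSS ± 500 bp inclusive; gene body: TSS + 501 to the
transcription end, inclusive, in gene-strand orientation (the boundary
base TSS + 500 belongs to the promoter only, keeping the regions
disjoint; the two definitions would otherwise overlap at one base). The
gene's strand, never the CpG's, orients the arithmetic. A site may map
to regions of several overlapping genes. Interval lookup uses an
interval tree; tests compare it against a brute-force linear scan.

A gene region is called when it contains at least three DMCs (`min_cpgs`
counts DMCs, not tested CpGs — the reading that makes the rule about
*differentially methylated* regions; `count="tested"` switches to the
other reading). The region Δmeth is the arithmetic mean of member DMC
differences; mixed-sign members set a `discordant` flag, and discordant
regions are excluded from integration by default as ambiguous evidence.

Integration emits a (gene, region) pair when the expression direction
and region methylation direction satisfy promoter hypo→up, promoter
hyper→down, body hyper→up or body hypo→down. Genes carrying both a
promoter and a body call are excluded when either region's |Δmeth|
exceeds 20 points (strict inequality); the excluded genes are reported
to a side table. The sentence defining this rule is ambiguous — it could
also mean the promoter-vs-body discrepancy exceeding 20 points — so both
readings are implemented (`dual_rule="either"` default, `"between"`
alternative). Genes with both calls at ≤ 20 points remain eligible for
both a promoter and a body mode.

## Signatures

Signatures are pure set algebra over the per-comparison integrated
lists, with membership requiring the same expression direction in every
supporting comparison (a gene up in one comparison and down in another
is not a coherent member). With parental P, premalignant 4C,
nonmetastatic 4C11− and metastatic 4C11+:

* malignancy: same direction in (P→4C) ∩ (P→4C11−) ∩ (P→4C11+);
* EMT: up members satisfy up in P→4C and P→4C11− and down in 4C→4C11+
  and 4C11−→4C11+ (down members mirror-imaged) — the two-vs-two
  mesenchymal/differentiated contrast; the P→4C11+ comparison is
  uninformative for that split and is ignored;
* metastasis: same direction in (P→4C11+) ∩ (4C→4C11+) ∩ (4C11−→4C11+),
  minus genes appearing in P→4C or P→4C11− (the "only in the metastatic
  line" clause; toggleable).

Each member records its mode and supporting comparisons. All three
operations are tested against independently coded brute-force
enumerations on randomized inputs, and planted archetypes (effects in
{4C, 4C11−, 4C11+}, {4C, 4C11−} or {4C11+} only) must land exclusively
in their intended signature. Joint recovery of an archetype is the
product of three-to-four per-comparison sensitivities, so ~0.95 per
comparison yields ~0.81–0.86 end to end at default effect sizes.

## Scoring and survival

Features are z-transformed per feature across patients with the sample
(n−1) variance; zero-variance features are dropped with a warning. The
combined score is `(Σ z_up − Σ z_down) / (|up| + |down|)`; with one set
empty it equals the other set's mean. Median dichotomization sends ties
to the low group (score ≤ median → low), deterministic and configurable.
Quantile stratification uses linear-interpolation percentiles with
strict inequalities (< 25th → low, > 75th → high), mirroring
"below"/"above" wording; the convention is pinned here for
reproducibility, not claimed to match any particular cohort's original
analysis.

Kaplan–Meier is the plain product-limit estimator. The two-group
log-rank statistic is `(Σ(O−E))² / ΣV` over distinct event times with
the hypergeometric variance at each risk set, referred to χ²(1). Cox
regression maximizes the Efron-corrected partial likelihood by
Newton–Raphson with step-halving, on internally standardized covariates
(back-transformed afterwards); it reports HR, the 95% Wald CI and p for
the covariate of interest, plus coefficients of any adjustment
covariates. Non-convergence, constant covariates, singular information
and diverging coefficients (complete separation) raise errors. The
implementation is the deliverable — lifelines is used in the tests as an
independent cross-check (agreement to 1e-6 with ties) but never called
by the pipeline. Spearman correlation handles covariate association.

## Synthetic data generators

The generators encode the study conditions every validation runs under:

* **Annotation**: non-overlapping genes laid along chromosomes
  (alternating), random strand, lengths uniform in a configurable range;
  CpG sites on a jittered grid guaranteeing ≥ 6 promoter and ≥ 6 body
  sites per gene (infeasible spacing raises). Validation runs use 2,000
  genes of 1.4–1.7 kb, giving ≈ 25k CpG sites — the stated scale of the
  calibration experiments.
* **Counts**: negative binomial with variance μ + 0.1·μ² (fixed
  dispersion 0.1, typical of well-behaved RNA-seq triplicates); per-gene
  baselines uniform on (0.25, 2.5) × 200; planted genes' means multiply
  by 2^log2FC in affected groups. Default planted effect |log2FC| = 3
  with the four coupling modes in equal proportion, so up/down effects
  balance and library-size normalization stays honest.
* **Methylomes**: coverage ~ 1 + Poisson(29); per-sample methylation
  level Beta(mean, precision = 300), methylated count binomial given
  coverage. The beta layer is replicate overdispersion — precisely what
  the binomial LRT must survive — at a magnitude typical of cell-line
  technical triplicates (between-replicate SD ≈ 3 points at 50%
  methylation). Planted regions shift all their CpGs by ± 40 points,
  clipped to [0.02, 0.98] with a logged warning. The baseline is a flat
  50% at every site; real methylomes are bimodal with CpG-island
  structure, which the generator deliberately does not model.
* **Cohorts**: gene expression i.i.d. standard normal; the combined
  score is computed through the actual scoring code, standardized to
  unit SD, and drives an exponential hazard
  `h₀ · exp(β · score)` (h₀ = 0.1/year). Censoring is independent
  exponential with its rate solved numerically so the expected censored
  fraction hits the target (default 20%). This is exactly the
  proportional-hazards generative model the Cox stage assumes, making
  parameter recovery a sharp test of the estimator rather than of model
  misspecification.

One global seed fans out to per-stage child seeds through
`numpy.random.SeedSequence.spawn`, so stages are independently
reproducible.

What passing these validations shows: the machinery is internally
correct (oracle equivalence, set algebra, numerical exactness), honest
under the null, and able to recover effects of the planted size under
the planted noise model. What it does not show: performance on real
bisulfite data with bimodal baselines, CpG-island correlation structure,
coverage biases, batch effects, or cohorts whose hazards violate
proportionality.

## Problem sizes of the standard validation runs

Fisher sweep: all 739,600 tables with margins ≤ 40. Null calibration: 50
datasets × (2,000 genes, ≈ 25k CpGs, 4 groups × 3 replicates), five
pairwise comparisons each. Planted recovery: 3 datasets with 200 coupled
genes + 20 decoys among 2,000. Set algebra: 1,000 random instances.
Scoring: 200 random small cohorts (n ≤ 12) for the log-rank oracle. Cox:
200 cohorts of 700 patients at β = ln 1.49; 500 null cohorts for
log-rank uniformity. The complete sweep runs in about ten minutes on one
CPU.

## Known limitations

* Column-sum library normalization biases log-ratios when differential
  expression is strongly one-sided; a robust scaling (TMM/median-of-
  ratios) would be the first upgrade for real data.
* The binomial LRT is mildly anticonservative under strong replicate
  overdispersion; a quasi-binomial scale correction would trade power
  for calibration if real replicates are noisier than the generator's.
* Single-isoform gene models only; no multi-TSS handling, CpG-island or
  enhancer annotation, and no sliding-window DMR discovery.
* The Cox implementation covers right censoring with Efron ties; no
  time-varying covariates, stratification or competing risks.
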