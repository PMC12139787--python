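# Methods

This note documents the models implemented in `sowselect`, the
assumptions behind them, the synthetic-data generator that exercises
them, and the numerical and design choices that were genuinely open.

## The experimental design being modelled

A panel of *N* inbred (effectively homozygous) accessions is sown in
equal numbers at each of several field sites — the default
configuration mirrors a design of 200 accessions at 40 seeds each, i.e.
8,000 seeds per subplot, at four sites. After one or two generations in
the field, individual plants are sampled (*n* per site, defaults 171,
199, 208 and 137) and genotyped at low coverage. Because everything
starts at frequency 1/N, an accession's frequency among the sampled
experimental individuals is directly an estimate of its relative
fitness over the full life cycle.

## Drift-null allele-frequency model

The surviving experimental population at a site is treated as a
Wright–Fisher multinomial sample of effective size Ne from the
equal-frequency starting panel; the genotyped sample is a second
multinomial draw of known size n from that population. For a SNP with
starting frequency p₀ (the unweighted mean of panel genotypes), the
change Δp between p₀ and the sample frequency then satisfies

    E[Δp] = 0,
    Var[Δp] = (1/n + 1/Ne + 1/(n·Ne)) · p₀(1 − p₀).

**Ne estimation.** The variance law is linear in p₀(1 − p₀), so the
slope *s* of the least-squares regression of (Δp)² on p₀(1 − p₀)
through the origin identifies Ne at known n via the exact inversion
Ne = (1 + 1/n)/(s − 1/n). SNPs below a minor-allele-frequency floor
(default 0.03) are excluded from the fit, which requires at least 100
usable SNPs; a slope at or below 1/n (no variance beyond sampling)
cannot be inverted and is reported invalid rather than replaced by a
fabricated number. The cross term 1/(n·Ne) is retained because it is
free, though it moves Ne by less than 1 for every n ≥ 100 in the
regime of interest; for the two-stage multinomial sampling scheme the
generator uses, the mathematically exact cross term actually enters
with a negative sign, a ~1% difference that is far below the
estimator's sampling noise.

**The scan.** Per SNP, z = (Δp − c)/√Var[Δp], with c the genome-wide
mean Δp by default. Centering is on by default because real panels show
a non-zero mean Δp from reference-allele bias in genotyping; under a
clean simulation c ≈ 0 and centering is harmless. Significance is the
two-sided standard-normal probability (the direction of selection is
not assumed). SNPs fixed in the panel have zero null variance and are
excluded with a reported count. Sites are combined by multiplying
per-SNP p-values; the product is a *ranking score*, not a calibrated
p-value (−ln of a product of k independent uniform p-values is
Gamma(k, 1), which the tests verify), so an optional Fisher chi-square
transform is provided for users who need calibrated tails.

Calibration caveat: structured panels induce correlation among SNPs, so
scan p-values are exchangeable-marginal quantities, not independent
tests; the pipeline applies no multiple-testing control.

## Genotype assignment

A field sample is compared to every panel accession by its mismatch
rate: discordant homozygous calls divided by informative sites (sites
where the sample call is homozygous and the accession call is
non-missing; heterozygous and missing calls count in neither numerator
nor denominator). Classification precedence:

1. heterozygous-call fraction above threshold (default 0.05 of
   non-missing calls) → **heterozygous** (outcrossed or contaminated);
   an extensively heterozygous sample is never assigned;
2. fewer informative sites than the floor (default 10,000) →
   **low_data**;
3. minimum-mismatch accession at mismatch ≤ 0.015 → **experimental**;
   an *exact tie* between two matching accessions is genuine ambiguity
   and is refused (low_data with both candidates reported) rather than
   broken arbitrarily, protecting downstream fitness estimates;
4. otherwise → **native_volunteer**.

The 0.015 threshold is an empirically established default for this kind
of low-coverage identification and is exposed in configuration.
`min_snps_by_simulation` estimates the smallest SNP count at which every
accession is uniquely identified across random SNP subsets; exact
duplicate accessions are reported as permanently indistinguishable and
excluded from the criterion. Samples and panel are joined on
(chromosome, 1-based position); a sample SNP absent from the panel, or
an allele-encoding disagreement between files, is an error, never a
silent flip.

## Native filtering

Wild ("volunteer") individuals of the local population appear inside
experimental plots. Unmatched volunteers are harmless, but an
experimental accession collected near a site may have *indistinguishable*
wild relatives there, inflating its apparent fitness. Strong isolation
by distance — the probability that two individuals are genotype-identical
decays rapidly over a few km — justifies a distance rule:
an (accession, site) pair is a *potential native* when the great-circle
distance (haversine, Earth radius 6371 km) from the accession's
collection point to the site is at most the cutoff, default 5.6 km.
The boundary is inclusive: at exactly the cutoff the accession is
flagged, the conservative choice. Accessions without coordinates are
reported unflaggable, not silently passed.

`identity_vs_distance` estimates the decay curve from the panel itself:
pairs are "identical" at mismatch ≤ 0.015 (reusing the assignment
ceiling, which tolerates genotyping error), binned by distance, and
fitted with a monotone-decreasing isotonic curve — no parametric family
is imposed because none is implied by the mechanism. The cutoff is the
smallest distance at which the fitted identity probability falls below
a configurable floor.

Exclusion of flagged accessions uses one of two modes, both logged:

* **threshold** (default): exclude a potential native whose home-site
  frequency is ≥ 0.10 *and* ≥ 3× its maximum away-site frequency;
* **top1**: exclude a potential native that is the single largest
  frequency at its home site — mirroring exclusion of obvious outliers
  by judgment, which catches confounded accessions whose away-site
  frequencies are also high.

Exclusion removes the accession from the affected site's denominator
only; no other accession's raw count changes.

## Fitness

Frequencies are computed over experimental-class samples (natives,
heterozygous and low-data samples are excluded from the denominator;
an `all-samples` denominator is available for sensitivity analysis).
After exclusions the remaining frequencies are renormalised and sum to
one. Zero counts stay zero — fitness here is a frequency estimate, not
a likelihood, so no pseudocounts. Relative fitness is N·f, so the mean
over all accessions is exactly 1 when none are excluded, and the
fold-change from the 1/N start equals the relative fitness.

Two exact pattern statistics summarise group-level consistency:

* `prob_any_group_extreme(k, m)` = k·(1/k)^m — the chance under
  exchangeability that *some* one of k groups ranks last in all m
  experiments (the k events are disjoint); verified against exhaustive
  enumeration of all k^m last-place assignments.
* `binomial_tail(s, t, p)` — exact upper-tail binomial probability by
  direct summation, no normal approximation, so e.g. P(X ≥ 7) at
  (8, 1/6) is exact at 2.44×10⁻⁵.

## Liability-threshold survival model

Accession *i* has Gaussian liability N(μᵢ, σ_E) in environment E and
survives iff liability falls below the environment's threshold τ_E; the
harsher environment has the lower threshold. Between a milder site A
and a harsher site B this gives

    p_B = ½·erfc( α/√2 + β·erfc⁻¹(2·p_A) ),
    α = (τ_A − τ_B)/σ_B,   β = σ_A/σ_B,

the only identifiable parameter combinations (the μᵢ cancel). α = 0,
β = 1 is the identity map; α > 0 means uniformly harsher. The map is
strictly increasing and carries (0,1) into (0,1); boundary survival
probabilities are handled by their limits (0 → 0, 1 → 1) with a
warning, and observed survival of exactly 0 or 1 in the mild site is
shrunk by a half-count correction p → (k + ½)/(n + 1) before the
inverse-erfc transform.

Fitting is nonlinear least squares of predicted against observed
harsh-site survival, weighted by binomial trial counts by default
(unweighted is available since the weighting convention is a
judgment call), multi-started from a coarse grid α ∈ [−3, 3],
β ∈ (0, 4] plus a few seeded random starts to avoid local minima.
Standard errors come from the Gauss–Newton covariance s²(JᵀJ)⁻¹. An
accession subset can be supplied so the curve can be fitted on a
genetically homogeneous subgroup.

## The synthetic-data generator

The generator exists so that every stage is testable against known
truth. It emulates:

* **Panel structure** — Balding–Nichols draws: ancestral frequency
  Uniform(0.05, 0.95) per SNP, group frequency Beta(p(1−F)/F,
  (1−p)(1−F)/F) at differentiation F (default 0.2), accessions as
  homozygous Bernoulli draws from their group; geographic origins
  jittered around per-group centres so groups are spatially clustered.
* **Selection + drift** — sampling at *accession* level (stage 1:
  multinomial of size Ne with probabilities ∝ fitness/N; stage 2:
  multinomial of size n from the stage-1 composition), so the
  genome-wide SNP correlations that population structure induces arise
  naturally instead of being simulated per SNP.
* **Field genotyping** — per-call drop-out (default 0.5) and allele
  error (default 0.01), emulating low-coverage sequencing of tiny field
  samples; heterozygous contaminants built as mixtures of two
  accessions (half of the calls drawn from the mixture by default,
  heterozygous wherever the parents disagree), with partners redrawn
  until the sample is unambiguously heterozygous, since its truth class
  is assigned, not sampled; native volunteers drawn from a group's
  allele frequencies and redrawn until they mismatch every panel
  accession by more than 0.015 — natives share the local structure but
  are distinguishable by construction.
* **Class counts** — native (default 15.8%) and heterozygous (default
  8.8%) sample counts are exact rounded counts, not binomial draws, so
  generator truth is a sharp oracle for the composition summaries.
* **Liability survival** — accession liability means μᵢ ~ N(0, 2),
  dispersed enough that survival probabilities span nearly the whole
  unit interval, as per-accession overwinter survival does in harsh
  seasons; defaults (τ, σ) = (0.5, 1.2) mild vs (0.0, 1.0) harsh, i.e.
  (α, β) = (0.5, 1.2), at 24 binomial trials per accession.

All randomness derives from one root seed through named
`SeedSequence` substreams (`panel`, `experiment:<site>`,
`natives:<site>`, `degrade:<site>`, `liability`), so identical
configurations give bit-identical outputs, including on-disk files.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: linkage disequilibrium within groups
(SNPs are conditionally independent given group frequencies), seed
dormancy and seed banks, dispersal between plots, real recombination or
outcrossing genetics (heterozygous samples are genotype mixtures, not
meioses), sequencing-read-level artefacts, and temporal environmental
variation. Results on real data depend on those processes; the tests
validate the estimators under the stated model, not the model itself.

## Numerical choices and scales

* Mismatch computation is vectorised as float32 matrix products;
  integer counts remain exact up to 2²⁴ sites, far beyond any panel
  used here.
* Scan tables are written as TSV sorted by (chromosome, position) and
  read back with round-trip float parsing, so write → read → write is
  byte-identical. Site identifiers such as "NA" are never interpreted
  as missing values.
* The test suite and the statistical acceptance properties run at
  reduced but adequate scale — 20,000-SNP panels, 10–20 replicates per
  property — chosen so medians and means of the estimators are tight
  relative to the stated tolerances: Ne recovery within ±25% (median of
  20 replicates) across (Ne, n) ∈ {(16,137), (34,208), (70,199)}; scan
  false-positive rate 0.05 ± 0.01 (mean of 10 replicates); assignment
  accuracy 100% noiseless and ≥99% at 1% error with 50% missingness;
  liability (α, β) within ±10% (median of 20 replicates).
* In pipeline runs, the informative-site floor is capped at half the
  panel's SNP count so that small synthetic panels remain classifiable;
  the cap is logged and recorded in the manifest.
* When Ne estimation fails on a degenerate input (slope ≤ 1/n), the
  pipeline falls back to the configured Ne if one exists and logs the
  fallback; the model surface itself reports invalid rather than
  guessing.

## Known limitations

* The p-value product across sites is uncalibrated by design; use the
  Fisher transform when tail calibration matters, and neither when SNPs
  are strongly correlated.
* The liability fit treats mild-site survival as a fixed predictor;
  binomial noise in the predictor attenuates (α, β) slightly when
  accession survival probabilities are narrowly spread.
* Identity-by-distance cutoff estimation requires dense geographic
  sampling; with few pairs near the decay front the isotonic fit is
  coarse and the cutoff accordingly uncertain.
* `min_snps_by_simulation` is a randomized certificate, not a proof:
  a k that passes every replicate can still fail for an unseen subset.
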