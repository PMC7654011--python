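# Methods

This note records the statistical model behind `mrflow`, the defaults
and numerical choices that matter, what the synthetic generator does and
does not emulate, and the design decisions taken where the conventions
of the field leave room.

## Setting and assumptions

Two-sample MR treats germline variants as instrumental variables: the
exposure associations (γ̂ⱼ, σ_xj) and outcome associations (Γ̂ⱼ, σ_yj)
come from non-overlapping GWAS cohorts and are combined only through
summary statistics. Validity rests on the three IV conditions —
relevance (the variant is associated with the exposure), independence
from confounders, and exclusion (no path to the outcome except through
the exposure). The estimators differ in how much violation of exclusion
(horizontal pleiotropy) they tolerate; the pipeline's job is to make the
residual pleiotropy visible and to quantify how much it moves the
estimate.

## Instrument selection

1. Genome-wide significance, p < 5×10⁻⁸ (strict inequality).
2. Greedy LD clumping against a reference panel: r² threshold 0.001,
   window 10,000 kb. SNPs absent from the panel are removed; the
   remaining SNPs are sorted by ascending p (ties broken
   lexicographically by rsid, which makes the output invariant to input
   row order), and each index SNP claims every unclaimed SNP on its
   chromosome within the window whose r² with it exceeds the threshold.
3. MAF filter: min(EAF, 1−EAF) < 0.01 removed (strict). SNPs with
   missing EAF are retained and flagged by default; a strict mode
   removes them.

The filters run in the order significance → clumping → MAF, following
the usual QC narrative for this design; each stage's removals are
counted in the instrument set's provenance so input size is conserved.

Proxy search (when an instrument is absent from the outcome GWAS) uses
panel r² ≥ 0.8 within 250 kb, taking the maximal-r² candidate with
lexicographic tie-break. These two values are conventions of ours —
reported alongside results via provenance — since common practice varies
and nothing in the design pins them down.

## Harmonization

Allele pairs are classified as same / swapped / strand-complement /
complement-swapped / palindromic / incompatible. Swapped configurations
negate the outcome beta and flip its EAF; strand complements realign
silently; incompatible pairs (e.g. A/G vs A/C) are always dropped — a
"correction" for non-concordant allele sets is not actionable, so none
is attempted. Palindromic SNPs (A/T, G/C) carry no strand information
in their labels; in the default `infer` mode they are kept only when
both EAFs are present and outside 0.5 ± 0.08, aligning by frequency
concordance (discordant sides ⇒ the outcome effect belongs to the other
allele ⇒ sign flip); a `drop` mode removes them outright. The 0.08
ambiguity half-width is the package default, wide enough that sampling
noise in the EAFs of the cohort sizes involved here (≳8k) rarely crosses
0.5. Missing EAF on either side drops the palindrome. Harmonization
never changes |Γ̂ⱼ|, only signs and labels, and is idempotent.

## Estimators — numerical choices

* Wald ratio SEs are first-order delta (σ_yj/|γ̂ⱼ|) by default; the
  second-order form adding Γ̂ⱼ²σ_xj²/γ̂ⱼ⁴ is available by flag. With
  genome-wide-significant instruments the difference is ≲3%.
* IVW model `auto` chooses multiplicative random effects iff the Q test
  has p < 0.05 (the chosen model is recorded); the Q statistic inside
  IVW and the one reported by the heterogeneity diagnostic are the same
  computation.
* MR-Egger orients each SNP to γ̂ⱼ > 0 before fitting (the fit is not
  orientation-invariant otherwise), weights by 1/σ_yj², floors the
  residual overdispersion factor at 1 so SEs never fall below the
  fixed-effect ones, and uses t(J−2) inference. The regression itself
  is delegated to statsmodels WLS.
* Weighted median: cumulative-weight percentiles pⱼ = Sⱼ − w′ⱼ/2 with
  linear interpolation at 0.5; with equal weights this is exactly the
  simple median.
* MBE: weighted Gaussian KDE evaluated on a fixed 512-point grid over
  [min ratio, max ratio]; bandwidth φ·0.9·min(sd, IQR/1.349)·J^(−1/5)
  with φ = 1 by default (φ is always recorded — results should be read
  as conditional on it). When the IQR is zero the sd alone sets the
  scale; when all ratios coincide the common value is returned.
* WM/MBE standard errors use a parametric bootstrap (redraw both betas
  from N(observed, SE²), default 1000 replicates, explicit seed);
  deterministic given the seed.
* RAPS solves a 1-D profile over β (41-point bracket around the IVW
  slope, then bounded refinement to 1e-10): at each β the
  overdispersion τ² ≥ 0 solves Σσⱼ⁻²(ψ(tⱼ)tⱼ − δ) = 0 by Brent's
  method, where tⱼ are standardized residuals, ψ is the score of the
  chosen loss and δ = E[ψ(Z)Z] under N(0,1) keeps τ̂² consistent under
  the Huber loss (tuning constant 1.345, the 95%-efficiency choice;
  default loss is Huber with overdispersion on). The SE is an
  M-estimator sandwich with the bread obtained by central differencing
  of the profile score.
* All p-values are two-sided and clamped into (0, 1] so log transforms
  stay defined.

## MR-PRESSO

Observed residuals are RSSⱼ = wⱼ(Γ̂ⱼ − β̂₋ⱼγ̂ⱼ)² with wⱼ = 1/σ_yj² and
β̂₋ⱼ the leave-one-out fixed-effect IVW slope. The null redraws
γ̂ⱼ* ~ N(γ̂ⱼ, σ_xj²) and Γ̂ⱼ* ~ N(β̂₋ⱼγ̂ⱼ, σ_yj²) and recomputes the
leave-one-out residuals on each replicate. Monte-Carlo p-values use the
add-one convention (1 + #exceedances)/(1 + n_sim), so they are never
zero; per-SNP p-values are Bonferroni-multiplied by J and flagged at
0.05 on the adjusted scale by default (a raw-scale criterion is a
switch). The distortion test compares D = (β_before − β_after)/|β_after|
with the same quantity under removal of equally many random non-outlier
SNPs (two-sided empirical p; D = 0 and p = 1 by convention when nothing
is flagged). All computations sort SNPs by rsid first, making results
invariant to input order, and are bit-reproducible given the seed.

**The p-value floor.** With add-one p-values the smallest attainable
Bonferroni-adjusted per-SNP p is J/(n_sim + 1). At J = 100 the
conventional n_sim = 1000 leaves that floor at ≈0.1 — above the 0.05
flagging threshold, so no outlier can ever be flagged. The default
n_sim stays at 1000 for the global test's sake, but any analysis that
relies on the outlier test at J ≈ 100 should set n_sim ≳ 2500; the
validation suites here use n_sim = 2500–3900. Choosing n_sim so that
the Bonferroni cut sits inside the floor's resolution (only
zero-exceedance counts flag) additionally caps the null family-wise
flag rate at J/(n_sim + 1) rather than the nominal 5%.

## Staged workflow

Escalation is: step 2 iff the step-1 global p < 0.05 **and** at least
one outlier was flagged (pleiotropy with no flaggable outlier is
reported at step 1 with a warning); step 3 iff step-2 IVW heterogeneity
has p < 0.05 **and** the "outlier p < 1" pruning (read against the
adjusted p-values, switchable to raw; adjusted p < 1 ⇔ raw p < 1/J)
removes strictly more SNPs than step 2 did. Step-3 removals are defined
from the step-1 (full-set) outlier test, which guarantees the SNP sets
shrink strictly down the ladder. Any stage with fewer than 4 harmonized
SNPs aborts with an error naming the stage.

The overall verdict — "causal" when the lead method (IVW) passes the
Bonferroni threshold 0.05/5 with no influential-SNP flag, "suggestive"
when any method passes, "null" otherwise — is this package's
operationalization of the usual narrative reading of such tables, not a
community standard; the per-method booleans are always reported
alongside it. "Potentially influential" in the leave-one-out analysis
means a significance flip at 0.05 (the full set significant, the
leave-one-out estimate not); an alternative outside-the-95%-CI rule is
available by flag.

## Synthetic generator

The generator emulates the summary-statistic structure of a case-control
exposure (defaults: 12,882 cases / 21,770 controls, logOR) against a
continuous outcome (default n = 20,000, g/cm²) with ~100 independent
instruments and causal effects around −0.02 outcome units per logOR —
the scale of an IBD→BMD analysis, with the outcome cohort kept modest so
repeated-simulation studies stay fast. Per SNP: EAF ~ U(0.1, 0.9); true
instrument effects γⱼ ~ N(0, 0.15²); SEs from the standard
frequency-based approximations (case-control:
σ_x² = (1/(2·N_ca·pq) + 1/(2·N_co·pq)); continuous: σ_y² = 1/(2·n·pq));
observed betas are truth plus normal noise. Pleiotropy: with probability
π a SNP gets a direct effect αⱼ with mean μ_α (directional iff ≠ 0), SD
σ_α, and optional correlation with γⱼ (InSIDE violation). Planted
outliers get αⱼ = scale·σ_yj·sign(γⱼ) — aligned with the instrument's
sign so the set displaces the pooled Wald ratio in one direction, which
is what makes an "outlier scenario" distort the estimate rather than
merely inflate heterogeneity. By default instruments are re-drawn until
their observed exposure p clears 5×10⁻⁸, mimicking the post-selection
lists a real analysis consumes (a switch disables this for selection-bias
studies). Randomness flows from one seed through per-component
sub-streams, so outputs are byte-reproducible.

What the generator does **not** emulate: real LD structure (the panel is
block-diagonal with geometric within-block decay), sample overlap
between cohorts, population stratification, allele-frequency differences
between cohorts, or winner's-curse beyond the significance truncation.
Passing recovery and calibration tests therefore show the estimators are
correct under their own model at the study's scale — not that any real
IBD→BMD conclusion is right.

## Validation sizes

The simulation studies behind the acceptance checks use 2,000 replicates
for test size, 500 for bias/coverage at the study scale, 50–200 runs for
MR-PRESSO operating characteristics, and 10 replicates per staged-ladder
scenario — sizes at which the Monte-Carlo error of each reported rate is
well below the acceptance bands while the whole suite runs in about a
minute.

## Known limitations

* MBE results depend on φ; no data-driven φ selection is provided.
* The RAPS implementation profiles a single overdispersion parameter;
  it does not implement the shrinkage variants.
* Per-SNP r² in the Steiger test uses the t²/(t²+n−2) approximation for
  binary as well as continuous traits; for case-control exposures this
  is an observed-scale approximation, and the F statistic uses the total
  (cases + controls) sample size.
* No multivariable MR, no CAUSE/contamination-mixture estimators, no
  real-panel LD computation, no genotype-level simulation.
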