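# Methods

## Study design being modelled

The pipeline analyses a factorial coral cross between two source
populations.  Dams and sires (default four per population, with colonies
serving in both roles and self-crosses excluded) are crossed into 25
families, each reared in three culture replicates.  Outcomes per replicate
are culture survival, larval dry weight, settlement count, and the number of
juveniles surviving a field deployment; per-family juvenile mortality then
defines a high class (> 90%) and a low class (< 10%), and juveniles from the
extreme families are amplicon-sequenced for their symbiont (OTU) profiles.

## Mixed models and variance partitioning

Settlement counts are modelled as log-link Poisson with independent Normal
random intercepts for dam, sire, their interaction, and one observation-level
effect (OLRE) per replicate row; the OLRE is the standard device for
overdispersion in Poisson GLMMs.  Juvenile survivors (summed per family) are
negative binomial (NB2, dispersion θ) with settlement count as a fixed
covariate and dam/sire/interaction random; when sire and interaction
variances collapse to zero the model is refitted without them, the refits
compared by AICc (kept when not worse by more than 2).

Estimation maximizes the marginal likelihood with the random effects
integrated out by a Laplace approximation at the joint mode.  Because the
penalized log-likelihood is concave in (β, u) for both families, the fixed
effects are profiled inside the inner Newton solve and the outer
optimization runs only over standard deviations (bounded at [0, 20], so
singular fits are admissible) and log θ (bounded at [−4, 8]); L-BFGS-B with
a numerical gradient is polished by a Nelder–Mead simplex because the
objective is flat in a standard deviation at the zero boundary.  For models
whose random dimension is small the Laplace value can be refined by
tensor-product adaptive Gauss–Hermite quadrature centred and scaled at the
mode; this is the accuracy reference used by the likelihood oracle test
(agreement with dense-grid numerical integration to ~10 significant
figures on a two-dam × two-sire toy).  Wald covariances for the fixed
effects come from the inverse joint Hessian at the mode, conditional on the
variance parameters.

Variance shares use a latent-scale (ICC-style) decomposition.  The total is
the variance of the fitted fixed-effect predictor (when a covariate is
present) plus the random-intercept variances plus a distribution-level
residual: ln(1 + 1/exp(η̄)) for Poisson and ln(1 + 1/μ̄ + 1/θ) for NB —
the usual log-normal approximations of count noise on the log scale.  Shares
are reported as percent of total (summing to 100 ± 0.1) and each random
component also as percent of the combined random share.  The total maternal
contribution to juvenile survival is the direct dam share of survival plus
the carry-on component: the dam share of settlement times the settlement
share of survival, each rounded to one decimal (half-up) before summing.
`propagate_maternal` also accepts a pre-computed carry-on value for use when
the upstream product was formed from unrounded internals.

Per-parent contrasts refit the settlement model with the focal parent fixed
and deviation-coded (each level against the grand mean; estimates sum to
zero by construction), the other parent, interaction and OLRE remaining
random, with Wald p values per level.

## Synthetic-data generator

The generator is the test bed for every stage; its defaults mirror the study
design (4 + 4 dams and sires per population, 25 families, 3 replicates,
library sizes 20 000–180 000 reads).

* Settlement is generated exactly as the fitted model assumes (Poisson with
  log-normal OLRE), so that model is well specified.  Default latent
  variances (dam 0.4, sire 0.6, interaction 0.1, OLRE 0.5) give the
  overdispersed, parent-structured counts the design implies, with a larger
  sire than dam component.
* Larval weights are Normal per dam (truncated at zero), with default dam
  means spanning roughly 9.7–17.6 µg — Orpheus-type dams heavier — and a
  2 µg within-dam standard deviation.
* Juvenile survivors are NB with mean exp(β₀ + 0.02·settled + u_dam +
  w_family), right-truncated at the settlement count: the biology forces
  survivors ≤ settlers even though the fitted models do not encode it.  A
  family-level effect (default variance 2.25, like the dam effect) is
  included because observed family mortalities are near-bimodal (0–100%)
  and sibling crosses of one dam can fail while others thrive; a dam-only
  effect with eight dams cannot reproduce that spread reliably.  The NB mean
  is capped at 10× the settlement count (the truncation dominates anyway).
* `simulate_study` re-draws the outcome stage (deterministically, bounded)
  until at least two families fall in each mortality class, because the
  sequencing design it emulates selects the extreme-mortality families — the
  community stage is defined conditionally on their existence.
* Symbiont counts per sample are NB around library-size × softmax(baseline
  + class shift·ln2 + logit noise).  Defaults plant: five beneficial-type
  OTUs depleted in the high-mortality class, one opportunistic type enriched
  by +2.8 log2 (~sevenfold), eight rare OTUs present only in high-mortality
  samples (so that class is the richer one), and two variant pairs in which
  the second OTU tracks the first at a fixed abundance ratio with ~5% noise.
  Pair sequences derive from a shared 300 bp ancestor mutated to a target
  aligned identity (98% and 96% by default); below 97% a 1–3 bp deletion
  block is added, which drags the alignment-free k-mer similarity below the
  aligned identity, as real variants with deletion blocks behave.  The
  96%-identity pair deliberately sits below the 97% screen threshold: it is
  the proportional-but-divergent (shared-niche) pattern, not a multicopy
  truth.

What the generator does **not** emulate: taxonomic mis-annotation, chimeras,
raw-read error, phylogenetic correlation between OTUs, or environmental
covariates of mortality.  Passing tests therefore demonstrate that the
implementation recovers the structure it models, not that the models capture
every feature of real reef data.

## Community statistics

Size factors are median-of-ratios against a geometric-mean pseudo-reference
over OTUs detected in every sample (modified geometric mean over positive
entries as fallback), rescaled to geometric mean one.  The
variance-stabilizing transform is log2(count/size factor + shift) with the
shift defaulting to one count.  Differential abundance fits one NB
regression per OTU (statsmodels, ML dispersion; method-of-moments fallback
flagged per OTU) with log size factors as offsets and BH adjustment across
tested OTUs; no empirical-Bayes dispersion shrinkage is applied — per-OTU
estimation is a deliberate, documented divergence from shrinkage-based
tools.  Because the plain normal-reference Wald test with ML dispersion is
tail-liberal at tens of samples, the test applies a small-sample
correction: the dispersion is degrees-of-freedom adjusted (× n/(n−2)), the
standard error comes from the fixed-dispersion GLM, and the p value is
referred to a t distribution on n−2 degrees of freedom.  OTUs detected in
fewer than two samples are excluded.  Chao1 uses the classic singleton/doubleton form with the
bias-corrected branch when no doubletons exist.  NMDS minimizes Kruskal
stress-1 by SMACOF, alternating a Guttman update with isotonic regression of
configuration distances on the rank order of the dissimilarities;
disparities are rescaled to the configuration's sum of squares each
iteration (preventing scale collapse), the best of 20 random starts is kept,
and the solution is centred and rotated to principal axes.  When classes are
perfectly separable the non-metric problem is degenerate and stress
approaches zero; a warning is emitted, as ordination packages do.  PERMANOVA
partitions squared distances one-way, with p from random relabelings,
(1 + #{F* ≥ F}) / (n_perm + 1), default 999 permutations, seeded.

## Variant screen

Defaults are interpretive because no numeric thresholds accompany the
three-criteria rule: presence ≥ 1 read; co-occurrence in ≥ 90% of
either-present samples; signed R² ≥ 0.9 on the variance-normalized table
(separating "strong" from "moderate" proportionality); aligned identity
≥ 97% (the conventional OTU clustering radius).  Alignment scoring is match
+1 / mismatch −1 / gap open −2 / gap extend −1, global end-to-end, identity
= matched columns / alignment length.  The alignment-free companion measure
is cosine similarity of 5-mer count profiles — a geometric sequence-space
measure substituted for an unspecified phylogenetic distance and labelled as
such; only its qualitative relation to aligned identity (lower for variants
with deletion blocks) is asserted.  Proportionality uses all samples, and
the screened pairs default to within-clade combinations; callers normally
restrict them to the differentially abundant OTUs.

## Numerical and test-design choices

* Inner Newton: gradient tolerance 1e-8, ≤ 40 iterations, step halving;
  warm-started across outer evaluations; η clipped at 300 before
  exponentiation.  Failed outer evaluations receive a penalty sloped back
  toward the start so searches cannot wander on a flat failure plateau.
* Parameter-recovery tests run at reduced designs (e.g. 20 dams × 20 sires,
  100–150 families) with medians over 3–5 seeds; the dam×sire interaction
  variance is weakly informed at that scale (three observations per level)
  and is checked for magnitude rather than the 50% band the better-informed
  components meet.  Survival-slope recovery uses conditions under which the
  survival ceiling rarely binds (narrow settlement spread, moderate baseline
  survival): under a wide settlement spread the log-linear-in-settlement NB
  model is misspecified in the tail and the fitted slope attenuates — a
  property of the model, not of the fitter.
* Differential-abundance calibration is demonstrated on the within-model
  null (NB counts without extra logit noise, 20 vs 20 samples), where the
  corrected test attains its nominal level; under additional log-normal
  logit noise the NB model is misspecified and some residual liberality
  remains — a robustness caveat, not an implementation defect.  The planted
  fold-change recovery plants only the one shifted OTU so the compositional
  denominator stays comparable between classes.
* Fisher's exact test is discrete and conservative at study-scale margins
  (rejection rate ≈ 0.01 at 13 vs 12 families); its type-I calibration is
  therefore demonstrated at margins of 100 per group, where the achievable
  level approaches the nominal 0.05.
* Chao1 is computed per sample and then averaged per class/family (matching
  the "average ± s.e." style of reporting richness), not on pooled counts.

## Known limitations

Laplace marginal likelihoods are biased for very small counts per random
level; the AGHQ refinement covers low-dimensional checks only.  The NB
survival model cannot separate a family-level random effect from its own
dispersion with one observation per family (a likelihood ridge; θ is
bounded to keep it finite).  The screen's thresholds are heuristics: a pair
failing co-occurrence is called distinct even if it is a true variant with
presence–absence noise.  None of the community methods model phylogenetic
relatedness or compositionality beyond size-factor normalization.
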