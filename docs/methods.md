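# Methods

This note documents the models, numerical choices and limitations behind
`lotictraits`, in the order the pipeline runs them.

## Study design and the synthetic survey generator

The generator emulates a space-for-time restoration appraisal: `n_site_pairs`
pairs of reaches, each pair one control and one restored reach; organic
biotopes (macroalgae, *Ranunculus*-type and *Sparganium*-type macrophyte
stands) occur in every reach, while bare mineralogical biotopes (gravel,
sand, gravel+sand) occur only in restored reaches, where channel works
exposed them. Each (reach, biotope) cell receives `replicates` kick samples
(default 3 — the smallest count the dominant-biotope rule accepts). The
default design is therefore 3 × (3 + 6) × 3 = 81 samples, 27 control and 54
restored; real surveys of this kind are a little more ragged (not every
restored reach exposes every mineral biotope), and `StudyDesign` accepts
arbitrary per-reach biotope lists for that case.

Counts are negative binomial on a log link:

    log mu(s, t) = base_t + affinity(t, biotope_s) + delta * restored_s + eps_{s,t}
    eps_{s,t} ~ N(0, sigma * (phi if restored_s else 1)),   X ~ NB(mean = mu, size = k)

* `base_t ~ N(1.5, 1)` unless supplied: median family around 4–5 individuals
  per 15-s kick sample with a realistic spread from dominant (hundreds) to
  rare (absent) families.
* `delta` (location shift, default 0) moves restored communities on the log
  scale — the "multivariate location" effect.
* `phi >= 1` (dispersion multiplier, default 1) scales the standard deviation
  of the sample-level random effect in restored reaches. The effect is drawn
  per (sample, taxon): a single scalar per sample would only perturb total
  abundance, which the ln(x + 1) transform and Bray–Curtis largely absorb,
  whereas independent per-taxon draws move each restored sample in a
  different compositional direction — exactly the heterogeneity PERMDISP
  measures. Sample-level exchangeability within a reach is preserved.
* `sigma` (`random_effect_sd`, default 0.4) sets baseline among-sample
  heterogeneity; `k` (`negbin_size`, default 5) sets count overdispersion.
  Both defaults give Bray–Curtis dissimilarities in the 0.2–0.5 range typical
  of replicate kick samples.
* `biotope_affinity_effects` defaults to zero so that the control/restored
  contrast is exactly null when `delta = 0`, `phi = 1` (control reaches carry
  no mineral biotopes, so any biotope effect is a real reach difference).
  `biotope_affinity_matrix` assigns each taxon one preferred biotope when
  biotope-structured signal is wanted.

One seed (`rng_seed`) drives everything; sub-generators (base abundances,
counts, trait database) use deterministically spawned child seeds, so
datasets are bitwise reproducible.

What the generator does **not** emulate: spatial autocorrelation along the
channel, taxon drift between paired reaches, seasonal turnover, and
trait-mediated habitat filtering (trait syndromes are independent of biotope
preferences). Passing calibration tests therefore demonstrates the
correctness of the statistical machinery under a known exchangeable null,
not the field realism of any particular effect size.

## Trait processing

Fuzzy-coded affinities (integers 0–5; some grouping features use a 0–3
scale) are processed in five steps. The per-feature unit-sum standardization
(step ii) makes the scoring scale irrelevant, so mixed 0–3/0–5 features need
no special handling and raw integers are stored unscaled. Aggregation to a
coarser rank (step iii) uses the unweighted arithmetic mean of member
profiles followed by re-standardization — members with all-zero blocks pull
the mean below 1 and the re-standardization restores it. All-zero (taxon,
feature) blocks are kept at zero and *flagged*, never imputed uniform: they
contribute nothing at step (v) and the final per-sample re-standardization
absorbs the missing mass. Step (v) renormalizes per sample (not per reach
total), so each profile row carries one unit of mass per non-flagged
grouping feature; the composite of steps (iv)–(v) equals the
ln(x + 1)-weighted mean of member profiles, which the tests verify against a
loop oracle. Taxa present in samples but absent from the trait table are
dropped from trait analyses with a logged report. Natural logarithms
throughout.

## Dissimilarity, ordination, dispersion

Bray–Curtis d(x, y) = Σ|x_i − y_i| / Σ(x_i + y_i) is applied to ln(x + 1)
abundances and, unchanged, to trait profile rows (each row sums to the
number of non-flagged features; the same dissimilarity serves both
compositions). PCoA eigendecomposes the Gower-centered −½D²; eigenvalues
within 1e−10·max|λ| of zero are treated as null (floating-point rank
deficiency), and negative eigenvalues are *retained* as imaginary axes
rather than removed by Lingoes/Cailliez shifts, because the dispersion
analysis consumes them: squared distance to a group centroid is the real
part minus the imaginary part, clamped at zero with a logged warning when
cancellation overshoots. PERMDISP uses group centroids (not spatial
medians), no small-sample bias adjustment, and ANOVA-based significance with
r² = SS_group/SS_total on the distances; a permutation test is available but
off by default. A relative tolerance of 1e−12 on the distance sums of
squares classifies the all-equal-distances case as F = 0 rather than 0/0.

## Permutational inference

"Nested/blocked" PERMANOVA is implemented as one-factor PERMANOVA with
permutations restricted within blocks (strata) — the blocking semantics of
the standard R implementation — not a nested sums-of-squares decomposition.
The sums of squares use the inter-point formulation (no explicit centroids),
which makes the univariate-Euclidean case collapse exactly onto classical
one-way ANOVA (tested to 1e−10). When the number of distinct within-block
relabelings is ≤ 10,000 the test enumerates them all and reports the exact
p = count/total (observed arrangement included); otherwise p = (1 + count) /
(1 + n_perm), the standard bias-avoiding estimator. Permuted statistics are
compared to the observed one with a 1e−12 relative tie tolerance. Blocks
containing a single group are legal but warned about (their labels cannot
shuffle). Default `n_perm = 999` for every permutation procedure; seeds are
mandatory in the CLI and explicit everywhere else.

SIMPER averages per-pair, per-variable contributions |x_iv − x_jv| /
Σ_m(x_im + x_jm) over all between-group pairs, so contributions sum exactly
to the mean between-group dissimilarity (tested to 1e−10). Per-variable
significance permutes group labels and counts permuted average contributions
≥ observed; with more than two groups all pairwise contrasts are run.

## Diversity and indicators

Alpha diversity is inverse Simpson D = 1/Σp² — chosen over richness because
the trait profile has a fixed number of non-independent modalities.
Taxonomic D is computed on ln(x + 1) abundances (consistent with the global
transform; a raw-count call is a one-liner), trait D on the per-sample
concatenated profile renormalized across all traits (overall rather than
per-feature; per-feature diversity can be had by slicing the profile).
Contrasts use classical one-way ANOVA plus Tukey HSD via the studentized
range distribution; residual diagnostics (Shapiro–Wilk, Levene, sd ratio)
are reported but never enforced.

IndVal is group-equalized: specificity A of combination C is
Σ_{g∈C} ā_g / Σ_g ā_g with ā_g the within-group *mean* (so unequal biotope
sample counts do not bias A; abundance-based A is used for trait matrices
too), fidelity B is the fraction of samples in C with a positive value, and
the statistic is √(A·B). The combination space is every non-empty proper
subset of the groups — the full set is excluded because an item present
everywhere indicates nothing. Significance permutes sample memberships and
recomputes the best-combination statistic (max over combinations per
permutation). IndVal and SIMPER p-values are reported unadjusted; a Holm
correction is a deliberate non-default (the analyses are exploratory
screens, and adjusted significance can be applied downstream).

Rarity uses the strict < 1% share rule on raw counts; exclusivity flags taxa
found in only one reach type. The dominant-biotope filter drops (reach,
biotope) cells with fewer than `min_patches` (default 3) replicate samples.

## Problem sizes

The calibration experiments use the generator's default conditions: the
81-sample, 40-taxon design, 200 replicate surveys at 199 permutations for
the null type-I error (binomial 99% band [0.02, 0.09] around 0.05), and 100
surveys for the phi = 3 dispersion-recovery check. The acceptance script
runs the full pipeline at 999 permutations on one effectful survey
(delta = 0.5, phi = 2, unit-strength biotope affinities) and repeats both
calibration experiments with seeds derived from its `--seed`.

## Known limitations

* Exact enumeration counts distinct *label arrangements*; heavy ties in the
  distance matrix can make the permutation distribution coarse.
* PERMANOVA location inference is sensitive to dispersion differences under
  group imbalance (visible in `examples/reach_contrast.py`); this is a
  property of the statistic, not of the implementation.
* The IndVal permutation test permutes raw group memberships, ignoring the
  block structure; with strong site-pair effects its p-values are
  anticonservative for reach-level questions (it is aimed at biotopes).
* Trait profiles treat grouping features as equally weighted; no
  down-weighting of correlated features is attempted.
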