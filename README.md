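# lotictraits

Trait-based community analysis for paired-reach river-restoration appraisals.

`lotictraits` is a Python library for ecologists assessing whether physical
river restoration changed the benthic macroinvertebrate communities of
distinct in-channel habitats (*biotopes*: macrophyte stands, macroalgae,
gravel and sand patches). It covers the whole analysis chain:

* **Fuzzy-coded functional traits** — processing of graded taxon × trait
  affinity scores (0 = no affinity, up to 3 or 5 = strong affinity, in the
  style of the European freshwater invertebrate trait database of Tachet et
  al.) into per-sample community-weighted trait profiles.
* **Dissimilarity and ordination** — ln(x + 1) transform, Bray–Curtis
  dissimilarity, principal coordinates analysis retaining
  negative-eigenvalue axes.
* **Permutational inference** — PERMANOVA with permutations restricted
  within blocks (paired control/restored sites), PERMDISP multivariate
  dispersion with the imaginary-axis correction, SIMPER decomposition.
* **Diversity and indicators** — inverse Simpson alpha diversity, dispersion
  as beta diversity, one-way ANOVA + Tukey HSD contrasts, group-equalized
  IndVal over biotope combinations, a rarity/exclusivity audit, and the
  dominant-biotope (≥ 3 patches) filter.
* **A synthetic survey generator** with known location and dispersion
  effects, so every stage is testable without field data.

## The statistics in brief

With N samples, a groups and Bray–Curtis dissimilarities d_ij, PERMANOVA
partitions inter-point sums of squares

SS_total = (1/N) Σ_{i<j} d²_ij,  SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij,

and tests pseudo-F = (SS_between/(a−1)) / (SS_within/(N−a)) by shuffling
group labels *within* each site pair (block), switching automatically to
exact enumeration when the relabeling space is small. PERMDISP measures each
sample's distance to its group centroid in PCoA space, z_i = √(Δ²_real −
Δ²_imaginary), and compares groups by ANOVA — the dispersion contrast that
reveals heterogeneity gains even when average composition barely moves.
SIMPER attributes the mean between-group dissimilarity additively to
variables; IndVal scores each taxon/trait against every biotope combination
as √(A·B), A the group-equalized specificity and B the occurrence fidelity.

Trait profiles follow five steps: (i) restrict the fuzzy table to the taxa
observed, (ii) standardize affinities to unit sum per grouping feature,
(iii) average to the working rank and re-standardize, (iv) weight by
ln(abundance + 1), (v) sum over taxa and re-standardize per feature.

## Worked example

```python
from lotictraits import (GeneratorConfig, bray_curtis, generate_abundances,
                         generate_design, log_transform, permanova, permdisp)

dataset = generate_abundances(
    generate_design(),   # 3 site pairs, 6 biotopes, 3 replicates -> 81 samples
    GeneratorConfig(location_shift_delta=0.0, dispersion_multiplier_phi=3.0,
                    rng_seed=42),
)
dm = bray_curtis(log_transform(dataset.abundances))
groups, blocks = dataset.metadata["reach_type"], dataset.metadata["site_pair"]
print(permanova(dm, groups, blocks, n_perm=999, seed=1))
disp = permdisp(dm, groups)
print(disp.anova_f, disp.group_means)
```

prints

```
PERMANOVA: F = 1.795, r2 = 0.02221, p = 0.003 (sampled, 999 perms)
213.34 {'control': 0.1430..., 'restored': 0.2300...}
```

The survey was generated with *no* shift in average composition but three
times the community heterogeneity in restored reaches. PERMDISP recovers
exactly that: restored samples sit much farther from their centroid (0.2300
vs 0.1431; F = 213.34). The PERMANOVA p-value is small with a tiny r² — with
unbalanced groups a pure dispersion difference leaks into the location test,
which is why the two analyses must be read together.

The `examples/` directory holds one narrative script per capability
(`generate_survey.py`, `trait_profiles_demo.py`, `reach_contrast.py`,
`biotope_indicators.py`); each prints its numbers with a line on what they
mean. A thin CLI mirrors the pipeline: `lotictraits synth|run|permanova|
permdisp|simper|indval|diversity --help`.

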