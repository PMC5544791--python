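"""Synthetic paired-reach biotope surveys with known effects.

Emulates the sampling design of a paired control/restored river-restoration
appraisal: each site pair contributes one control and one restored reach;
organic biotopes (macrophyte stands, macroalgae) occur in both reach types
while bare mineralogical biotopes (gravel, sand, and their mix) are confined
to restored reaches; each (reach, biotope) cell is sampled with a fixed
number of replicate kick samples. Family-level taxon counts are drawn from a
negative binomial on a log link:

    log mean(s, t) = base_t + biotope_affinity(t, biotope_s)
                     + delta * [reach_s is restored] + eps_{s,t},
    eps_{s,t} ~ N(0, sigma * (phi if restored else 1)),

so ``delta`` shifts the multivariate location of restored communities and
``phi`` >= 1 inflates their among-sample heterogeneity (the quantity
multivariate dispersion measures). The exact configuration is recorded in
the dataset's ``truth`` for effect-recovery tests. A fuzzy-coded trait
database with syndrome structure is generated alongside the counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .traits import TraitSchema, load_trait_schema

__all__ = [
    "ORGANIC_BIOTOPES",
    "MINERAL_BIOTOPES",
    "DOMINANT_BIOTOPES",
    "StudyDesign",
    "GeneratorConfig",
    "SyntheticDataset",
    "generate_design",
    "generate_abundances",
    "generate_trait_database",
    "biotope_affinity_matrix",
]

# the six dominant biotope categories of a lowland restoration survey:
# three organic (present in every reach) and three mineralogical
# (bare-substrate patches created by channel works, restored reaches only)
ORGANIC_BIOTOPES = ("macroalgae", "ranunculus", "sparganium")
MINERAL_BIOTOPES = ("gravel", "sand", "gravel_sand")
DOMINANT_BIOTOPES = ORGANIC_BIOTOPES + MINERAL_BIOTOPES

CONTROL = "control"
RESTORED = "restored"


@dataclass(frozen=True)
class StudyDesign:
    """Paired-reach sampling layout.

    ``biotopes_per_reach`` maps (site_pair, reach_type) to the biotopes
    sampled there; every site pair must have exactly one control and one
    restored reach, and every (reach, biotope) cell receives ``replicates``
    samples.
    """

    site_pairs: tuple
    biotopes_per_reach: dict
    replicates: int = 3

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for pair in self.site_pairs:
            for reach in (CONTROL, RESTORED):
                if (pair, reach) not in self.biotopes_per_reach:
                    raise ValueError(f"site pair {pair!r} lacks a {reach} reach")
                if not self.biotopes_per_reach[(pair, reach)]:
                    raise ValueError(f"reach ({pair!r}, {reach}) has no biotopes")

    @property
    def n_samples(self) -> int:
        return self.replicates * sum(
            len(b) for b in self.biotopes_per_reach.values()
        )

    def metadata(self) -> pd.DataFrame:
        """Sample table: sample_id (index), site_pair, reach_type, biotope, replicate."""
        rows = []
        for pair in self.site_pairs:
            for reach in (CONTROL, RESTORED):
                for biotope in self.biotopes_per_reach[(pair, reach)]:
                    for rep in range(1, self.replicates + 1):
                        rows.append(
                            {
                                "sample_id": f"{pair}:{reach}:{biotope}:{rep}",
                                "site_pair": pair,
                                "reach_type": reach,
                                "biotope": biotope,
                                "replicate": rep,
                            }
                        )
        return pd.DataFrame(rows).set_index("sample_id")


def generate_design(
    n_site_pairs: int = 3,
    organic_biotopes=ORGANIC_BIOTOPES,
    mineral_biotopes=MINERAL_BIOTOPES,
    replicates: int = 3,
    seed: int | None = None,
) -> StudyDesign:
    """Build the default paired layout: organic biotopes everywhere,
    mineralogical biotopes only in restored reaches.

    ``seed`` is accepted for interface symmetry with the stochastic
    generators; the layout itself is deterministic.
    """
    del seed
    if n_site_pairs < 1:
        raise ValueError("n_site_pairs must be >= 1")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    organic = tuple(organic_biotopes)
    mineral = tuple(mineral_biotopes)
    if not organic:
        raise ValueError("organic biotope list must be non-empty")
    overlap = set(organic) & set(mineral)
    if overlap:
        raise ValueError(f"organic and mineral biotope labels overlap: {sorted(overlap)}")
    pairs = tuple(f"P{i + 1}" for i in range(n_site_pairs))
    layout = {}
    for pair in pairs:
        layout[(pair, CONTROL)] = organic
        layout[(pair, RESTORED)] = organic + mineral
    return StudyDesign(pairs, layout, replicates)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic count model (see module docstring).

    ``location_shift_delta`` (delta) and ``dispersion_multiplier_phi`` (phi)
    are the recoverable effects; both default to the null (0 and 1).
    ``biotope_affinity_effects`` is an optional taxa x biotope matrix of
    additive log-scale effects (zero when absent — see
    :func:`biotope_affinity_matrix` for structured affinities).
    """

    n_taxa: int = 40
    taxon_base_log_abundance: np.ndarray | float | None = None
    biotope_affinity_effects: pd.DataFrame | None = None
    location_shift_delta: float = 0.0
    dispersion_multiplier_phi: float = 1.0
    random_effect_sd: float = 0.4
    negbin_size: float = 5.0
    affinity_scale_max: int = 5
    n_syndromes: int = 4
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        if self.dispersion_multiplier_phi < 1:
            raise ValueError("dispersion_multiplier_phi must be >= 1")
        if self.negbin_size <= 0:
            raise ValueError("negbin_size must be > 0")
        if self.random_effect_sd < 0:
            raise ValueError("random_effect_sd must be >= 0")
        if self.affinity_scale_max not in (3, 5):
            raise ValueError("affinity_scale_max must be 3 or 5")
        for name in ("location_shift_delta", "dispersion_multiplier_phi",
                     "random_effect_sd", "negbin_size"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["taxon_base_log_abundance"], np.ndarray):
            d["taxon_base_log_abundance"] = d["taxon_base_log_abundance"].tolist()
        if isinstance(self.biotope_affinity_effects, pd.DataFrame):
            d["biotope_affinity_effects"] = {
                "taxa": list(self.biotope_affinity_effects.index),
                "biotopes": list(self.biotope_affinity_effects.columns),
                "values": self.biotope_affinity_effects.to_numpy().tolist(),
            }
        return d


@dataclass
class SyntheticDataset:
    """Counts, metadata, trait database and the generating configuration."""

    abundances: pd.DataFrame
    metadata: pd.DataFrame
    traits: pd.DataFrame
    truth: GeneratorConfig
    design: StudyDesign = field(default=None, repr=False)

    def write(self, out_dir) -> dict:
        """Write abundances.csv, metadata.csv, traits.csv and truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "abundances": out / "abundances.csv",
            "metadata": out / "metadata.csv",
            "traits": out / "traits.csv",
            "truth": out / "truth.json",
        }
        self.abundances.to_csv(paths["abundances"], index_label="sample_id")
        self.metadata.to_csv(paths["metadata"], index_label="sample_id")
        self.traits.to_csv(paths["traits"], index=False)
        paths["truth"].write_text(json.dumps(self.truth.to_dict(), indent=2))
        return paths


def _taxon_names(n_taxa: int) -> list[str]:
    width = len(str(n_taxa))
    return [f"Taxon{str(i + 1).zfill(width)}" for i in range(n_taxa)]


def biotope_affinity_matrix(
    taxa,
    biotopes=DOMINANT_BIOTOPES,
    strength: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Structured taxa x biotope log-scale affinity effects.

    Each taxon is assigned one preferred biotope receiving ``+strength``;
    all other biotopes get zero. Useful when biotope contrasts (biotope
    PERMANOVA, IndVal) should carry real signal.
    """
    if isinstance(taxa, int):
        taxa = _taxon_names(taxa)
    rng = np.random.default_rng(seed)
    biotopes = list(biotopes)
    values = np.zeros((len(taxa), len(biotopes)))
    preferred = rng.integers(0, len(biotopes), size=len(taxa))
    values[np.arange(len(taxa)), preferred] = strength
    return pd.DataFrame(values, index=list(taxa), columns=biotopes)


def generate_trait_database(
    taxa,
    schema: TraitSchema | None = None,
    n_syndromes: int = 4,
    seed: int | None = None,
    affinity_scale_max: int = 5,
) -> pd.DataFrame:
    """Fuzzy-coded trait table with trait-syndrome structure.

    Taxa are partitioned into ``n_syndromes`` syndromes; each syndrome has a
    template scoring one preferred modality per grouping feature at the top
    of the scale with low background scores, and each taxon perturbs its
    template by +-1 (clipped to [0, scale max], preferred modality kept
    positive). Returns a long table (taxon, rank, grouping_feature,
    trait_code, affinity) with integer affinities.
    """
    if n_syndromes < 1:
        raise ValueError("n_syndromes must be >= 1")
    if schema is None:
        schema = load_trait_schema()
    if isinstance(taxa, int):
        taxa = _taxon_names(taxa)
    taxa = list(taxa)
    rng = np.random.default_rng(seed)
    codes = schema.trait_codes
    n_traits = len(codes)

    templates = np.zeros((n_syndromes, n_traits), dtype=int)
    for s in range(n_syndromes):
        pos = 0
        for feature in schema.grouping_features:
            k = len(schema.traits_per_feature[feature])
            block = rng.integers(0, 2, size=k)  # sparse background 0/1
            block[rng.integers(0, k)] = affinity_scale_max
            templates[s, pos : pos + k] = block
            pos += k

    syndrome_of = rng.integers(0, n_syndromes, size=len(taxa))
    rows = []
    for i, taxon in enumerate(taxa):
        template = templates[syndrome_of[i]]
        noise = rng.integers(-1, 2, size=n_traits)
        affinity = np.clip(template + noise, 0, affinity_scale_max)
        # keep each taxon's strongest modality per feature positive
        affinity[template == affinity_scale_max] = np.maximum(
            affinity[template == affinity_scale_max], 1
        )
        for code, value in zip(codes, affinity):
            rows.append(
                {
                    "taxon": taxon,
                    "rank": "family",
                    "grouping_feature": schema.feature_of[code],
                    "trait_code": code,
                    "affinity": int(value),
                }
            )
    return pd.DataFrame(rows)


def generate_abundances(design: StudyDesign, config: GeneratorConfig) -> SyntheticDataset:
    """Draw a full synthetic dataset from the negative-binomial count model.

    Deterministic given ``config.rng_seed``: the same seed and configuration
    reproduce the dataset bitwise. The configuration used is stored in the
    result's ``truth``.
    """
    seeds = np.random.SeedSequence(config.rng_seed).spawn(3)
    rng_base = np.random.default_rng(seeds[0])
    rng_counts = np.random.default_rng(seeds[1])

    metadata = design.metadata()
    taxa = _taxon_names(config.n_taxa)
    n_samples = len(metadata)

    base = config.taxon_base_log_abundance
    if base is None:
        base = rng_base.normal(1.5, 1.0, size=config.n_taxa)
    else:
        base = np.broadcast_to(np.asarray(base, dtype=float), (config.n_taxa,)).copy()

    affinity = np.zeros((n_samples, config.n_taxa))
    if config.biotope_affinity_effects is not None:
        eff = config.biotope_affinity_effects
        if not isinstance(eff, pd.DataFrame):
            raise TypeError("biotope_affinity_effects must be a DataFrame (taxa x biotopes)")
        for s, biotope in enumerate(metadata["biotope"]):
            if biotope in eff.columns:
                affinity[s] = eff.reindex(index=taxa)[biotope].fillna(0.0).to_numpy()

    restored = (metadata["reach_type"] == RESTORED).to_numpy()
    sd = config.random_effect_sd * np.where(
        restored, config.dispersion_multiplier_phi, 1.0
    )
    eps = rng_counts.normal(0.0, 1.0, size=(n_samples, config.n_taxa)) * sd[:, None]

    log_mean = (
        base[None, :]
        + affinity
        + config.location_shift_delta * restored[:, None]
        + eps
    )
    mean = np.exp(log_mean)
    k = config.negbin_size
    counts = rng_counts.negative_binomial(k, k / (k + mean))

    abundances = pd.DataFrame(counts, index=metadata.index, columns=taxa)
    traits = generate_trait_database(
        taxa,
        n_syndromes=config.n_syndromes,
        seed=seeds[2],
        affinity_scale_max=config.affinity_scale_max,
    )
    return SyntheticDataset(abundances, metadata, traits, config, design)
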