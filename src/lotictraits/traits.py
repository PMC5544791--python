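"""Fuzzy-coded functional-trait processing.

Freshwater invertebrate trait databases (Tachet et al. / Usseglio-Polatera
et al. for European taxa) score each taxon's affinity for the modalities
("traits") of each trait category ("grouping feature") on a graded integer
scale: 0 = no affinity up to 3 or 5 = strong affinity, depending on the
literature available for that feature. This module turns such a table plus a
sample x taxon abundance matrix into per-sample community-weighted trait
profiles, in five steps:

(i)   restrict the database to the taxa of interest (:func:`filter_taxa`);
(ii)  standardize each taxon's affinities to sum to 1 within every grouping
      feature (:func:`standardize_affinities`), so scoring scale and taxon
      identity carry equal weight;
(iii) average to the working taxonomic resolution, e.g. species to family,
      and re-standardize (:func:`aggregate_to_rank`);
(iv)  weight by ln(abundance + 1) to build a sample x taxon x trait array
      (:func:`build_trait_abundance_array`);
(v)   sum over taxa and re-standardize per grouping feature to obtain the
      community trait profile (:func:`community_trait_profile`).

Feature blocks in which a taxon (or a whole sample) has no affinity at all
are left at zero and flagged rather than imputed; the step-(v)
re-standardization absorbs the missing mass.

The packaged schema (:func:`load_trait_schema` with no argument) is the
13-grouping-feature, 76-modality layout of the European database.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .ordination import log_transform

__all__ = [
    "TraitSchema",
    "StandardizedTraits",
    "TraitAbundanceArray",
    "TraitProfiles",
    "load_trait_schema",
    "filter_taxa",
    "standardize_affinities",
    "aggregate_to_rank",
    "build_trait_abundance_array",
    "community_trait_profile",
    "trait_profiles",
]

logger = logging.getLogger(__name__)

# unit-sum tolerance for standardized feature blocks
UNIT_SUM_TOL = 1e-12


@dataclass(frozen=True)
class TraitSchema:
    """Ordered grouping features and the trait codes within each."""

    grouping_features: tuple
    traits_per_feature: dict

    def __post_init__(self):
        seen = set()
        for feature in self.grouping_features:
            codes = self.traits_per_feature.get(feature, ())
            if not codes:
                raise ValueError(f"grouping feature {feature!r} has no traits")
            for c in codes:
                if c in seen:
                    raise ValueError(f"duplicate trait code {c!r}")
                seen.add(c)

    @property
    def trait_codes(self) -> list:
        return [c for f in self.grouping_features for c in self.traits_per_feature[f]]

    @property
    def feature_of(self) -> dict:
        return {
            c: f for f in self.grouping_features for c in self.traits_per_feature[f]
        }

    @property
    def n_features(self) -> int:
        return len(self.grouping_features)

    def blocks(self):
        """Yield (feature, list of column positions in trait_codes order)."""
        pos = 0
        for f in self.grouping_features:
            codes = self.traits_per_feature[f]
            yield f, list(range(pos, pos + len(codes)))
            pos += len(codes)


def load_trait_schema(source=None) -> TraitSchema:
    """Load a trait schema from a CSV with columns grouping_feature,trait_code.

    With no argument the packaged European-database schema is returned
    (13 grouping features, 76 trait modalities). Extra columns (e.g. a
    description) are ignored. Duplicate trait codes raise ``ValueError``.
    """
    if source is None:
        source = resources.files("lotictraits.data") / "trait_schema.csv"
        with resources.as_file(source) as path:
            frame = pd.read_csv(path)
    else:
        frame = pd.read_csv(source)
    if frame.empty:
        raise ValueError("schema file contains no rows")
    for col in ("grouping_feature", "trait_code"):
        if col not in frame.columns:
            raise ValueError(f"schema file missing column {col!r}")
    features = list(dict.fromkeys(frame["grouping_feature"]))
    per_feature = {
        f: tuple(frame.loc[frame["grouping_feature"] == f, "trait_code"])
        for f in features
    }
    return TraitSchema(tuple(features), per_feature)


@dataclass
class StandardizedTraits:
    """Taxon x trait matrix of per-feature unit-sum affinity proportions.

    ``zero_features`` flags (taxon, grouping feature) blocks where every raw
    affinity was zero; those rows of ``values`` stay exactly zero.
    """

    values: pd.DataFrame
    zero_features: pd.DataFrame
    schema: TraitSchema


@dataclass
class TraitAbundanceArray:
    """Sample x taxon x trait array of profile x ln(abundance + 1) products."""

    values: np.ndarray
    samples: list
    taxa: list
    trait_codes: list
    weights: pd.DataFrame = field(repr=False, default=None)
    schema: TraitSchema = None


@dataclass
class TraitProfiles:
    """Per-sample community trait profile, unit-sum within grouping features.

    ``zero_features`` flags (sample, feature) blocks with zero total weight.
    """

    values: pd.DataFrame
    zero_features: pd.DataFrame
    schema: TraitSchema


def _as_wide(table: pd.DataFrame, schema: TraitSchema) -> pd.DataFrame:
    """Pivot a long fuzzy table to taxon x trait_code, validating contents."""
    required = {"taxon", "trait_code", "affinity"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    unknown = set(table["trait_code"]) - set(schema.trait_codes)
    if unknown:
        raise ValueError(f"trait codes not in schema: {sorted(unknown)}")
    if table.duplicated(["taxon", "trait_code"]).any():
        dupes = table[table.duplicated(["taxon", "trait_code"])]
        raise ValueError(
            f"duplicate (taxon, trait_code) rows: {dupes[['taxon', 'trait_code']].values[:5]}"
        )
    aff = table["affinity"].to_numpy()
    if np.any(aff < 0) or np.any(aff > 5):
        raise ValueError("affinities must lie in [0, 5]")
    wide = table.pivot(index="taxon", columns="trait_code", values="affinity")
    wide = wide.reindex(columns=schema.trait_codes).fillna(0.0)
    return wide


def filter_taxa(table: pd.DataFrame, keep: set) -> pd.DataFrame:
    """Step (i): keep only the listed taxa in a long fuzzy-coded table.

    Taxa requested but absent from the table are reported with a warning,
    not an error (the caller may simply lack trait data for them).
    """
    keep = set(keep)
    if not keep:
        raise ValueError("keep set must be non-empty")
    present = set(table["taxon"])
    absent = sorted(keep - present)
    if absent:
        warnings.warn(f"taxa not found in trait table: {absent}", stacklevel=2)
    return table[table["taxon"].isin(keep)].reset_index(drop=True)


def standardize_affinities(table: pd.DataFrame, schema: TraitSchema) -> StandardizedTraits:
    """Step (ii): scale each (taxon, grouping feature) block to sum to 1.

    All-zero blocks are left at zero and flagged in ``zero_features``; this
    keeps the scoring scale (0-3 vs 0-5) irrelevant and gives every taxon
    equal weight per feature.
    """
    wide = _as_wide(table, schema).astype(float)
    flags = pd.DataFrame(
        False, index=wide.index, columns=list(schema.grouping_features)
    )
    values = wide.to_numpy()
    for feature, cols in schema.blocks():
        block = values[:, cols]
        sums = block.sum(axis=1)
        zero = sums == 0
        flags[feature] = zero
        safe = np.where(zero, 1.0, sums)
        values[:, cols] = block / safe[:, None]
    out = pd.DataFrame(values, index=wide.index, columns=wide.columns)
    return StandardizedTraits(out, flags, schema)


def aggregate_to_rank(
    standardized: StandardizedTraits, rank_map: dict
) -> StandardizedTraits:
    """Step (iii): average member profiles up to a coarser rank, re-standardize.

    ``rank_map`` sends each fine taxon to its coarse taxon (e.g. species to
    family). The coarse profile is the unweighted arithmetic mean of member
    profiles; because members flagged all-zero in a feature contribute zeros,
    the mean can fall short of unit sum and is re-standardized. A coarse
    taxon ends up flagged only where *every* member was flagged.
    """
    values = standardized.values
    missing = set(values.index) - set(rank_map)
    if missing:
        raise ValueError(f"rank_map missing fine taxa: {sorted(missing)[:5]}")
    coarse_of = pd.Series({t: rank_map[t] for t in values.index})
    requested = set(rank_map.values())
    covered = set(coarse_of)
    empty = requested - covered
    if empty:
        raise ValueError(f"coarse taxa with no members present: {sorted(empty)}")

    mean = values.groupby(coarse_of).mean()
    schema = standardized.schema
    flags = pd.DataFrame(False, index=mean.index, columns=list(schema.grouping_features))
    agg_values = mean.to_numpy()
    member_flags = standardized.zero_features.groupby(coarse_of).all()
    for feature, cols in schema.blocks():
        block = agg_values[:, cols]
        sums = block.sum(axis=1)
        zero = sums == 0
        flags[feature] = zero
        safe = np.where(zero, 1.0, sums)
        agg_values[:, cols] = block / safe[:, None]
    flags |= member_flags.reindex(index=mean.index, columns=flags.columns)
    out = pd.DataFrame(agg_values, index=mean.index, columns=values.columns)
    return StandardizedTraits(out, flags, schema)


def build_trait_abundance_array(
    standardized: StandardizedTraits, abundances: pd.DataFrame
) -> TraitAbundanceArray:
    """Step (iv): weight standardized profiles by ln(abundance + 1).

    Entry (s, t, j) = profile(t, j) * ln(abundance(s, t) + 1). Abundance-table
    taxa without trait data are dropped with a logged report; negative
    abundances raise.
    """
    traits = standardized.values
    taxa = [t for t in abundances.columns if t in traits.index]
    dropped = [t for t in abundances.columns if t not in traits.index]
    if dropped:
        logger.warning(
            "dropping %d taxa without trait data: %s", len(dropped), dropped
        )
    if not taxa:
        raise ValueError("no abundance-table taxon has trait data")
    weights = log_transform(abundances[taxa])
    profile = traits.loc[taxa].to_numpy()  # taxa x traits
    array = weights.to_numpy()[:, :, None] * profile[None, :, :]
    return TraitAbundanceArray(
        values=array,
        samples=list(abundances.index),
        taxa=taxa,
        trait_codes=list(traits.columns),
        weights=weights,
        schema=standardized.schema,
    )


def community_trait_profile(array: TraitAbundanceArray) -> TraitProfiles:
    """Step (v): sum the trait-abundance array over taxa and re-standardize.

    Per sample, each grouping-feature block of the taxon-summed trait values
    is rescaled to unit sum; this makes profiles comparable across samples
    (and reaches) with very different total abundances. Samples with zero
    total abundance raise; (sample, feature) blocks with zero total weight
    are flagged and left at zero.
    """
    totals = array.weights.sum(axis=1)
    empty = list(totals.index[totals == 0])
    if empty:
        raise ValueError(f"sample(s) with zero total abundance: {empty}")
    summed = array.values.sum(axis=1)  # samples x traits
    schema = array.schema
    flags = pd.DataFrame(
        False, index=array.samples, columns=list(schema.grouping_features)
    )
    for feature, cols in schema.blocks():
        block = summed[:, cols]
        sums = block.sum(axis=1)
        zero = sums == 0
        flags[feature] = zero
        safe = np.where(zero, 1.0, sums)
        summed[:, cols] = block / safe[:, None]
    values = pd.DataFrame(summed, index=array.samples, columns=array.trait_codes)
    return TraitProfiles(values, flags, schema)


def trait_profiles(
    trait_table: pd.DataFrame,
    abundances: pd.DataFrame,
    schema: TraitSchema,
    rank_map: dict | None = None,
) -> TraitProfiles:
    """Run steps (ii)-(v) in one call.

    Convenience wrapper: standardize the fuzzy table, optionally aggregate to
    a coarser rank, weight by ln(x + 1) abundances, and form the per-sample
    community trait profile.
    """
    standardized = standardize_affinities(trait_table, schema)
    if rank_map is not None:
        standardized = aggregate_to_rank(standardized, rank_map)
    array = build_trait_abundance_array(standardized, abundances)
    return community_trait_profile(array)
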