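"""End-to-end analysis driver.

Reproduces the full appraisal sequence on file inputs or a synthetic survey:
dominant-biotope filter, ln(x + 1) transform, trait steps (ii)-(v),
Bray-Curtis + PCoA for taxonomic and trait compositions, blocked PERMANOVA
and PERMDISP for the reach contrast (full and organic-only subset), SIMPER,
biotope PERMANOVA, alpha/beta diversity with ANOVA + Tukey contrasts,
group-equalized IndVal over biotopes, and the rarity/exclusivity audit.
Everything is seeded; identical configurations produce identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as lio
from .diversity import (
    classify_rare,
    contrast_anova_tukey,
    filter_dominant_biotopes,
    indval,
    inverse_simpson,
)
from .ordination import bray_curtis, log_transform, pcoa
from .permutation import permanova, permdisp, simper
from .synthetic import GeneratorConfig, StudyDesign, generate_abundances, generate_design
from .traits import load_trait_schema, trait_profiles

__all__ = ["AnalysisConfig", "ReportBundle", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Inputs and knobs for :func:`run_pipeline`.

    Either the four input paths are set, or ``generator`` (with an optional
    ``design``) selects synthetic mode.
    """

    abundance_path: str | None = None
    trait_path: str | None = None
    schema_path: str | None = None
    metadata_path: str | None = None
    generator: GeneratorConfig | None = None
    design: StudyDesign | None = None
    n_perm: int = 999
    rng_seed: int = 0
    alpha: float = 0.05
    min_patches: int = 3
    run_taxonomic: bool = True
    run_traits: bool = True
    run_organic_subset: bool = True

    def __post_init__(self):
        if self.generator is None and self.abundance_path is None:
            raise ValueError("either input paths or a generator config is required")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        raw = json.loads(Path(path).read_text())
        if "generator" in raw and raw["generator"] is not None:
            raw["generator"] = GeneratorConfig(**raw["generator"])
        return cls(**raw)


@dataclass
class ReportBundle:
    """All stage outputs keyed by analysis name, plus provenance."""

    results: dict
    provenance: dict
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"provenance": self.provenance, "results": _jsonable(self.results)},
            indent=2,
            sort_keys=True,
        )

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())


def _jsonable(obj):
    """Recursively convert results (dataclasses, frames, arrays) to JSON types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
            if f.name not in ("schema", "design")
        }
    if isinstance(obj, pd.DataFrame):
        frame = obj.reset_index()
        frame.columns = [str(c) for c in frame.columns]
        return frame.to_dict(orient="records")
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __init__(self, label):
            self.label = label

        def __enter__(self):
            logger.info("stage %s: start", self.label)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"stage {self.label!r} failed: {exc}") from exc
            logger.info("stage %s: done", self.label)
            return False

    return _Ctx(name)


def run_pipeline(config: AnalysisConfig, out_dir=None) -> ReportBundle:
    """Run the complete analysis sequence and return a :class:`ReportBundle`.

    When ``out_dir`` is given, the bundle JSON is written there (plus a
    ``FAILED`` marker naming the stage if a stage aborts).
    """
    seeds = [int(s) for s in
             np.random.SeedSequence(config.rng_seed).generate_state(16) % (2**31)]
    results: dict = {}
    try:
        bundle = _run(config, seeds, results)
    except Exception as exc:
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / "FAILED").write_text(str(exc))
            (out / "partial_report.json").write_text(
                json.dumps(_jsonable(results), indent=2, sort_keys=True)
            )
        raise
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle.write(out / "report.json")
    return bundle


def _run(config: AnalysisConfig, seeds: list, results: dict) -> ReportBundle:
    with _stage("load"):
        if config.generator is not None:
            design = config.design or generate_design()
            dataset = generate_abundances(design, config.generator)
            abundances, metadata, traits = (
                dataset.abundances,
                dataset.metadata,
                dataset.traits,
            )
        else:
            abundances = lio.read_abundance_table(config.abundance_path)
            metadata = lio.read_metadata(config.metadata_path)
            traits = lio.read_trait_table(config.trait_path)
        schema = load_trait_schema(config.schema_path)
        if set(abundances.index) != set(metadata.index):
            raise ValueError("abundance and metadata sample IDs differ")
        metadata = metadata.loc[abundances.index]

    with _stage("dominant_biotope_filter"):
        metadata, excluded = filter_dominant_biotopes(metadata, config.min_patches)
        abundances = abundances.loc[metadata.index]
        results["biotope_filter"] = {
            "n_samples_retained": int(len(metadata)),
            "excluded_cells": excluded,
        }

    groups = metadata["reach_type"]
    blocks = metadata["site_pair"]
    biotopes = metadata["biotope"]
    # organic biotopes occur in control reaches too; mineral ones do not
    organic = sorted(set(metadata.loc[groups == "control", "biotope"]))
    organic_mask = biotopes.isin(organic)

    compositions = {}
    with _stage("transform"):
        if config.run_taxonomic:
            compositions["taxonomic"] = log_transform(abundances)
        if config.run_traits:
            profiles = trait_profiles(traits, abundances, schema)
            compositions["trait"] = profiles.values
            results["trait_zero_feature_flags"] = int(
                profiles.zero_features.to_numpy().sum()
            )

    with _stage("ordination"):
        dms = {name: bray_curtis(data) for name, data in compositions.items()}
        results["ordination"] = {
            name: {
                "n_negative_eigenvalues": pcoa(dm).n_negative,
                "first_eigenvalues": pcoa(dm).eigenvalues[:3],
            }
            for name, dm in dms.items()
        }

    with _stage("reach_contrast"):
        contrast = {}
        for i, (name, dm) in enumerate(dms.items()):
            contrast[name] = {
                "permanova": permanova(
                    dm, groups, blocks, config.n_perm, seed=seeds[0] + i
                ),
                "permdisp": permdisp(dm, groups),
            }
        results["reach_contrast"] = contrast

    if config.run_organic_subset:
        with _stage("reach_contrast_organic_only"):
            subset = {}
            ids = list(metadata.index[organic_mask])
            for i, (name, dm) in enumerate(dms.items()):
                sub_dm = dm.filter(ids)
                # same stage seed as the full contrast, so that a design
                # without mineral biotopes gives bit-identical results
                subset[name] = {
                    "permanova": permanova(
                        sub_dm, groups[ids], blocks[ids], config.n_perm,
                        seed=seeds[0] + i,
                    ),
                    "permdisp": permdisp(sub_dm, groups[ids]),
                }
            results["reach_contrast_organic_only"] = subset

    with _stage("simper"):
        results["simper"] = {
            name: simper(data, groups, config.n_perm, seed=seeds[2] + i)
            for i, (name, data) in enumerate(compositions.items())
        }

    with _stage("biotope_contrast"):
        results["biotope_contrast"] = {
            name: permanova(dm, biotopes, blocks, config.n_perm, seed=seeds[3] + i)
            for i, (name, dm) in enumerate(dms.items())
        }

    with _stage("diversity"):
        diversity = {}
        for name, data in compositions.items():
            alpha = inverse_simpson(data)
            beta = permdisp(dms[name], biotopes)
            diversity[name] = {
                "alpha": alpha,
                "alpha_contrast": contrast_anova_tukey(alpha, biotopes, config.alpha),
                "beta": beta,
                "beta_contrast": contrast_anova_tukey(
                    beta.distances, biotopes, config.alpha
                ),
            }
        results["diversity"] = diversity

    with _stage("indval"):
        results["indval"] = {
            name: indval(data, biotopes, config.n_perm, seed=seeds[4] + i)
            for i, (name, data) in enumerate(compositions.items())
        }

    with _stage("rarity_audit"):
        results["rarity"] = classify_rare(abundances, metadata)

    provenance = {
        "package_version": __version__,
        "rng_seed": config.rng_seed,
        "n_perm": config.n_perm,
        "alpha": config.alpha,
        "min_patches": config.min_patches,
        "n_samples": int(len(metadata)),
        "n_taxa": int(abundances.shape[1]),
        "organic_biotopes": organic,
        "synthetic": config.generator is not None,
    }
    return ReportBundle(results=results, provenance=provenance)
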