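"""Diversity measures, group contrasts and indicator analysis.

Alpha diversity is the inverse Simpson index D = 1 / sum(p_i^2), the
effective number of equally common taxa (or trait modalities) in a sample.
Beta diversity is measured as multivariate dispersion: the spread of samples
around their biotope centroid in dissimilarity space. Group contrasts of
either quantity use a one-way ANOVA with Tukey HSD post-hoc comparisons.
Indicator analysis follows the group-equalized IndVal of De Caceres &
Legendre: for every combination of biotopes the statistic sqrt(A * B)
combines specificity A (concentration of within-group mean abundance in the
combination) and fidelity B (occurrence frequency inside it).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .permutation import DispersionResult, align_labels, permdisp

__all__ = [
    "inverse_simpson",
    "beta_dispersion_by_group",
    "ContrastResult",
    "contrast_anova_tukey",
    "IndicatorResult",
    "indval",
    "classify_rare",
    "filter_dominant_biotopes",
]

logger = logging.getLogger(__name__)


def inverse_simpson(composition: pd.DataFrame | np.ndarray) -> pd.Series:
    """Inverse Simpson diversity of each row of a composition matrix.

    Rows are normalized to proportions p, and D = 1 / sum(p^2). D ranges
    from 1 (a single category) to the number of nonzero categories (uniform).
    Zero-sum rows raise.
    """
    if isinstance(composition, pd.DataFrame):
        index = composition.index
        values = composition.to_numpy(dtype=float)
    else:
        values = np.atleast_2d(np.asarray(composition, dtype=float))
        index = pd.RangeIndex(values.shape[0])
    if np.any(values < 0):
        raise ValueError("compositions must be nonnegative")
    totals = values.sum(axis=1)
    if np.any(totals == 0):
        empty = list(index[totals == 0])
        raise ValueError(f"zero-sum composition(s): {empty}")
    p = values / totals[:, None]
    d = 1.0 / (p**2).sum(axis=1)
    return pd.Series(d, index=index, name="inverse_simpson")


def beta_dispersion_by_group(dm, groups) -> DispersionResult:
    """Multivariate dispersion with (typically) biotope as the grouping factor.

    Thin alias of :func:`lotictraits.permutation.permdisp`; the per-sample
    distances to biotope centroids are the beta-diversity values.
    """
    return permdisp(dm, groups)


@dataclass
class ContrastResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons and diagnostics."""

    anova_f: float
    p_value: float
    r_squared: float
    tukey: pd.DataFrame
    diagnostics: dict
    alpha: float


def contrast_anova_tukey(values, groups, alpha: float = 0.05) -> ContrastResult:
    """Compare a per-sample response (e.g. diversity) between groups.

    Classical one-way ANOVA plus all-pairs Tukey HSD via the studentized
    range distribution at family-wise level ``alpha``. Residual diagnostics
    (Shapiro-Wilk normality p, Levene homogeneity p, spread ratio of group
    standard deviations) are reported, not enforced.
    """
    if isinstance(values, pd.Series):
        values = values.astype(float)
    else:
        values = pd.Series(np.asarray(values, dtype=float))
    group_series = align_labels(list(values.index), groups, "groups")
    names = sorted(set(group_series))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    per_group = [values[(group_series == g).to_numpy()].to_numpy() for g in names]
    if any(len(v) < 2 for v in per_group):
        raise ValueError("every group needs at least two samples")

    grand = values.mean()
    ss_total = ((values - grand) ** 2).sum()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in per_group)
    ss_within = ss_total - ss_between
    df_b = len(names) - 1
    df_w = len(values) - len(names)
    if df_w <= 0:
        raise ValueError("no residual degrees of freedom")
    if ss_within <= 1e-300:
        raise ValueError("degenerate model: zero residual variance")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    r2 = float(ss_between / ss_total) if ss_total > 0 else 0.0

    hsd = stats.tukey_hsd(*per_group)
    ci = hsd.confidence_interval(confidence_level=1 - alpha)
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        rows.append(
            {
                "group_1": names[i],
                "group_2": names[j],
                "mean_difference": float(np.mean(per_group[i]) - np.mean(per_group[j])),
                "ci_low": float(ci.low[i, j]),
                "ci_high": float(ci.high[i, j]),
                "p_adjusted": float(hsd.pvalue[i, j]),
                "significant": bool(hsd.pvalue[i, j] <= alpha),
            }
        )
    tukey = pd.DataFrame(rows)

    residuals = np.concatenate([v - v.mean() for v in per_group])
    shapiro_p = float(stats.shapiro(residuals).pvalue) if len(residuals) >= 3 else np.nan
    levene_p = float(stats.levene(*per_group).pvalue)
    sds = [v.std(ddof=1) for v in per_group]
    spread_ratio = float(max(sds) / min(sds)) if min(sds) > 0 else np.inf
    diagnostics = {
        "shapiro_p": shapiro_p,
        "levene_p": levene_p,
        "sd_ratio": spread_ratio,
        "normality_flag": bool(shapiro_p < 0.05) if np.isfinite(shapiro_p) else None,
        "heteroscedasticity_flag": bool(levene_p < 0.05),
    }
    return ContrastResult(float(f), p, r2, tukey, diagnostics, alpha)


@dataclass
class IndicatorResult:
    """Best biotope combination per item with IndVal components A, B."""

    table: pd.DataFrame
    excluded: list
    group_names: list
    n_permutations: int


def _indval_best(
    values: np.ndarray,
    codes: np.ndarray,
    n_groups: int,
    combos: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Best-combination IndVal statistic per item (column of ``values``).

    ``combos`` is a (n_combinations x n_groups) 0/1 matrix. Returns
    (stat, A, B, best index) arrays over items.
    """
    n_items = values.shape[1]
    group_means = np.empty((n_groups, n_items))
    presence = values > 0
    group_presence = np.empty((n_groups, n_items))
    group_sizes = np.bincount(codes, minlength=n_groups).astype(float)
    for g in range(n_groups):
        mask = codes == g
        group_means[g] = values[mask].mean(axis=0)
        group_presence[g] = presence[mask].sum(axis=0)

    total_mean = group_means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (combos @ group_means) / total_mean[None, :]
    a = np.nan_to_num(a, nan=0.0)
    combo_sizes = combos @ group_sizes
    b = (combos @ group_presence) / combo_sizes[:, None]
    stat = np.sqrt(a * b)
    best = stat.argmax(axis=0)
    cols = np.arange(n_items)
    return stat[best, cols], a[best, cols], b[best, cols], best


def indval(
    data: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> IndicatorResult:
    """Group-equalized indicator-value analysis over group combinations.

    For every non-empty *proper* subset C of the groups (a combination equal
    to the full group set indicates nothing and is excluded):

    * A (specificity) = sum of within-group mean values over C divided by the
      sum over all groups — group means, not sums, so unequal group sizes do
      not bias A ("group-equalized");
    * B (fidelity) = fraction of samples in C where the item is present (> 0);
    * statistic = sqrt(A * B), and each item is assigned the combination
      maximizing it.

    Significance is by permuting sample group memberships and recomputing the
    best-combination statistic: p = (1 + #{perm >= observed}) / (1 + n_perm).
    Items with zero total value are excluded and reported.
    """
    if not isinstance(data, pd.DataFrame):
        data = pd.DataFrame(np.asarray(data, dtype=float))
    group_series = align_labels(list(data.index), groups, "groups")
    group_names, codes = np.unique(group_series.to_numpy(), return_inverse=True)
    n_groups = len(group_names)
    if n_groups < 2:
        raise ValueError("IndVal needs at least two groups")

    totals = data.sum(axis=0)
    excluded = list(totals.index[totals.to_numpy() == 0])
    if excluded:
        logger.warning("excluding %d item(s) with zero total value: %s",
                       len(excluded), excluded)
    kept = data.loc[:, totals.to_numpy() > 0]
    values = kept.to_numpy(dtype=float)

    combos = []
    for r in range(1, n_groups):  # proper subsets only
        for subset in itertools.combinations(range(n_groups), r):
            row = np.zeros(n_groups)
            row[list(subset)] = 1.0
            combos.append((subset, row))
    combo_matrix = np.array([row for _, row in combos])

    stat, a, b, best = _indval_best(values, codes, n_groups, combo_matrix)

    rng = np.random.default_rng(seed)
    count = np.zeros(values.shape[1])
    tol = 1e-12 * np.maximum(1.0, stat)
    for _ in range(n_perm):
        perm_codes = rng.permutation(codes)
        perm_stat, _, _, _ = _indval_best(values, perm_codes, n_groups, combo_matrix)
        count += perm_stat >= stat - tol
    p_values = (1 + count) / (1 + n_perm)

    table = pd.DataFrame(
        {
            "combination": [
                " + ".join(str(group_names[g]) for g in combos[k][0]) for k in best
            ],
            "n_groups_in_combination": [len(combos[k][0]) for k in best],
            "A": a,
            "B": b,
            "stat": stat,
            "p_value": p_values,
        },
        index=kept.columns,
    ).sort_values("stat", ascending=False)
    return IndicatorResult(table, excluded, [str(g) for g in group_names], n_perm)


def classify_rare(
    abundances: pd.DataFrame,
    metadata: pd.DataFrame,
    threshold: float = 0.01,
) -> pd.DataFrame:
    """Rarity and reach-type exclusivity audit of raw counts.

    A taxon is "rare" when its share of the total community count is
    strictly below ``threshold`` (default 1%). Exclusivity records whether a
    taxon occurs only in control or only in restored reaches; occurrence is
    the number of samples with a positive count.
    """
    totals = abundances.sum(axis=0)
    grand = totals.sum()
    if grand == 0:
        raise ValueError("empty community: grand total is zero")
    shares = totals / grand
    present = abundances > 0
    occurrence = present.sum(axis=0)

    reach = align_labels(list(abundances.index), metadata["reach_type"], "reach_type")
    reach_types = sorted(set(reach))
    occ_by_reach = {
        rt: present[(reach == rt).to_numpy()].any(axis=0) for rt in reach_types
    }
    exclusive_to = []
    for taxon in abundances.columns:
        where = [rt for rt in reach_types if occ_by_reach[rt][taxon]]
        exclusive_to.append(where[0] if len(where) == 1 else None)

    return pd.DataFrame(
        {
            "total_abundance": totals,
            "share": shares,
            "rare": shares < threshold,
            "n_samples": occurrence,
            "exclusive_to": exclusive_to,
        },
        index=abundances.columns,
    )


def filter_dominant_biotopes(
    metadata: pd.DataFrame, min_patches: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop biotopes sampled from fewer than ``min_patches`` patches per reach.

    A biotope counts as "dominant" within a reach (one site_pair x reach_type
    cell) only when at least ``min_patches`` replicate samples exist there;
    other (reach, biotope) cells are excluded. Returns the filtered metadata
    and an exclusion report; raises if nothing survives.
    """
    if min_patches < 1:
        raise ValueError("min_patches must be >= 1")
    counts = (
        metadata.groupby(["site_pair", "reach_type", "biotope"], sort=True)
        .size()
        .rename("n_samples")
        .reset_index()
    )
    excluded = counts[counts["n_samples"] < min_patches].reset_index(drop=True)
    keep_cells = set(
        map(
            tuple,
            counts.loc[
                counts["n_samples"] >= min_patches,
                ["site_pair", "reach_type", "biotope"],
            ].to_numpy(),
        )
    )
    mask = [
        (row.site_pair, row.reach_type, row.biotope) in keep_cells
        for row in metadata.itertuples()
    ]
    filtered = metadata[mask]
    if filtered.empty:
        raise ValueError("all biotopes excluded by the dominant-biotope filter")
    if len(excluded):
        logger.info(
            "dominant-biotope filter dropped %d (reach, biotope) cells", len(excluded)
        )
    return filtered, excluded
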