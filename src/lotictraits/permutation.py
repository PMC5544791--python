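"""Permutational inference on community dissimilarities.

Implements the distance-based statistics used to contrast community
compositions between reach types and biotopes:

* :func:`permanova` — one-factor permutational multivariate analysis of
  variance with permutations optionally restricted within blocks (strata),
  the standard way to respect a paired control/restored site design.
* :func:`permdisp` — permutational analysis of multivariate dispersion:
  per-sample distances to group centroids in principal-coordinate space
  (imaginary axes subtract), compared by one-way ANOVA.
* :func:`simper` — similarity-percentage decomposition of the average
  between-group Bray-Curtis dissimilarity into per-variable contributions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .ordination import pcoa

__all__ = [
    "PermanovaResult",
    "DispersionResult",
    "SimperResult",
    "permanova",
    "permdisp",
    "simper",
    "align_labels",
]

# relative slack when counting permuted statistics >= observed (float ties)
_TIE_RTOL = 1e-12


def align_labels(ids, labels, name: str = "labels") -> pd.Series:
    """Align a grouping to a sequence of sample ids.

    ``labels`` may be a dict, a pandas Series indexed by sample id, or a
    plain sequence in the same order as ``ids``.
    """
    ids = list(ids)
    if isinstance(labels, pd.Series):
        missing = [i for i in ids if i not in labels.index]
        if missing:
            raise KeyError(f"{name} missing for samples: {missing}")
        return labels.reindex(ids)
    if isinstance(labels, dict):
        missing = [i for i in ids if i not in labels]
        if missing:
            raise KeyError(f"{name} missing for samples: {missing}")
        return pd.Series([labels[i] for i in ids], index=ids)
    labels = list(labels)
    if len(labels) != len(ids):
        raise ValueError(f"{name} length {len(labels)} != number of samples {len(ids)}")
    return pd.Series(labels, index=ids)


@dataclass
class PermanovaResult:
    """Pseudo-F test of group location differences in distance space."""

    f: float
    r_squared: float
    p_value: float
    n_permutations_used: int
    exact_enumeration: bool
    n_samples: int
    n_groups: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        mode = "exact" if self.exact_enumeration else "sampled"
        return (
            f"PERMANOVA: F = {self.f:.4g}, r2 = {self.r_squared:.4g}, "
            f"p = {self.p_value:.4g} ({mode}, {self.n_permutations_used} perms)"
        )


@dataclass
class DispersionResult:
    """Per-sample distances to group centroids with an ANOVA comparison."""

    distances: pd.Series
    groups: pd.Series
    group_means: dict
    anova_f: float
    p_value: float
    r_squared: float
    n_clamped: int


@dataclass
class SimperResult:
    """Per-variable decomposition of average between-group dissimilarity.

    ``table`` is sorted by decreasing average contribution and carries
    columns: average, sd, share, cumulative_share, mean_<group>, sd_<group>
    (per-group summaries of the input values) and p_value (permutation).
    """

    table: pd.DataFrame
    overall_dissimilarity: float
    group_labels: tuple
    n_permutations: int


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Pseudo-F and r2 from a squared distance matrix and group codes."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub.sum() / (2.0 * idx.size)
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    if ss_within <= 0:
        # perfectly separated groups: F diverges
        f = math.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / df_between) / (ss_within / df_within)
    r2 = ss_between / ss_total
    return f, r2


def _distinct_arrangements(items: tuple) -> list[tuple]:
    """All distinct orderings of a multiset of hashable labels."""
    counter = Counter(items)
    keys = sorted(counter)
    n = len(items)
    slot = [None] * n
    out: list[tuple] = []

    def rec(pos: int) -> None:
        if pos == n:
            out.append(tuple(slot))
            return
        for k in keys:
            if counter[k]:
                counter[k] -= 1
                slot[pos] = k
                rec(pos + 1)
                counter[k] += 1

    rec(0)
    return out


def _n_arrangements(items: tuple) -> int:
    counter = Counter(items)
    total = math.factorial(len(items))
    for c in counter.values():
        total //= math.factorial(c)
    return total


def permanova(
    dm: DistanceMatrix,
    groups,
    blocks=None,
    n_perm: int = 999,
    seed: int | None = None,
    exact_threshold: int = 10_000,
) -> PermanovaResult:
    """One-factor PERMANOVA with permutations restricted within blocks.

    Sums of squares follow the inter-point formulation: with N samples and
    a groups, SS_total = (1/N) sum_{i<j} d_ij^2, SS_within = sum_g (1/n_g)
    sum_{i<j in g} d_ij^2, and F = (SS_between/(a-1)) / (SS_within/(N-a)).
    Group labels are permuted independently *within* each block, which keeps
    block (site-pair) effects out of the null distribution. When the number
    of distinct within-block relabelings is at most ``exact_threshold`` the
    full enumeration is used and the p-value is exact (count/total over all
    relabelings, observed included); otherwise ``n_perm`` random relabelings
    give p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).

    Parameters
    ----------
    dm
        Distance matrix among samples.
    groups
        Group label per sample (dict, Series, or aligned sequence).
    blocks
        Optional block label per sample; ``None`` treats all samples as one
        exchangeable block (free permutation).
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(np.asarray(dm, dtype=float))
    ids = list(dm.ids)
    n = len(ids)
    group_series = align_labels(ids, groups, "groups")
    group_names, codes = np.unique(group_series.to_numpy(), return_inverse=True)
    a = len(group_names)
    if a < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    d2 = dm.data**2
    if d2.sum() == 0:
        raise ValueError("degenerate input: all samples identical (SS_total = 0)")

    if blocks is None:
        block_series = pd.Series(["_all"] * n, index=ids)
    else:
        block_series = align_labels(ids, blocks, "blocks")
    block_index: list[np.ndarray] = []
    for b, sub in group_series.groupby(block_series, sort=True):
        idx = np.array([ids.index(i) for i in sub.index])
        if idx.size < 2:
            raise ValueError(f"block {b!r} has fewer than 2 samples")
        if len(set(sub)) < 2:
            warnings.warn(
                f"block {b!r} contains a single group; its labels cannot be shuffled",
                stacklevel=2,
            )
        block_index.append(idx)

    f_obs, r2 = _pseudo_f(d2, codes, a)
    tie_tol = _TIE_RTOL * max(1.0, abs(f_obs))

    total_exact = 1
    for idx in block_index:
        total_exact *= _n_arrangements(tuple(codes[idx]))
        if total_exact > exact_threshold:
            break

    if total_exact <= exact_threshold:
        per_block = [_distinct_arrangements(tuple(codes[idx])) for idx in block_index]
        count = 0
        perm_codes = codes.copy()
        for combo in itertools.product(*per_block):
            for idx, arrangement in zip(block_index, combo):
                perm_codes[idx] = arrangement
            f_perm, _ = _pseudo_f(d2, perm_codes, a)
            if f_perm >= f_obs - tie_tol:
                count += 1
        p = count / total_exact
        return PermanovaResult(f_obs, r2, p, total_exact, True, n, a)

    rng = np.random.default_rng(seed)
    count = 0
    perm_codes = codes.copy()
    for _ in range(n_perm):
        for idx in block_index:
            perm_codes[idx] = perm_codes[idx][rng.permutation(idx.size)]
        f_perm, _ = _pseudo_f(d2, perm_codes, a)
        if f_perm >= f_obs - tie_tol:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(f_obs, r2, p, n_perm, False, n, a)


def permdisp(
    dm: DistanceMatrix,
    groups,
    permutations: int | None = None,
    seed: int | None = None,
) -> DispersionResult:
    """Multivariate dispersion: distances to group centroids, ANOVA-tested.

    The distance matrix is embedded by PCoA keeping imaginary axes; the
    squared distance of sample i to its group centroid is the squared real
    Euclidean distance minus the squared imaginary one (Anderson's
    correction for semi-metric dissimilarities), clamped at zero with a
    warning if negative. Group differences in these distances are assessed
    with a classical one-way ANOVA (the default), or by permuting distances
    across groups when ``permutations`` is given.
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(np.asarray(dm, dtype=float))
    ids = list(dm.ids)
    group_series = align_labels(ids, groups, "groups")
    group_names, codes = np.unique(group_series.to_numpy(), return_inverse=True)
    if len(group_names) < 2:
        raise ValueError("PERMDISP needs at least two groups")
    sizes = np.bincount(codes)
    if np.any(sizes < 2):
        small = [str(group_names[g]) for g in np.flatnonzero(sizes < 2)]
        raise ValueError(f"groups with fewer than 2 samples: {small}")

    ordination = pcoa(dm)
    real = ordination.coordinates.to_numpy()
    imag = ordination.imaginary_coordinates.to_numpy()

    z2 = np.empty(len(ids))
    for g in range(len(group_names)):
        idx = np.flatnonzero(codes == g)
        c_real = real[idx].mean(axis=0)
        c_imag = imag[idx].mean(axis=0) if imag.shape[1] else np.zeros(0)
        d_real = ((real[idx] - c_real) ** 2).sum(axis=1)
        d_imag = ((imag[idx] - c_imag) ** 2).sum(axis=1) if imag.shape[1] else 0.0
        z2[idx] = d_real - d_imag

    n_clamped = int((z2 < -1e-12).sum())
    if n_clamped:
        warnings.warn(
            f"{n_clamped} squared centroid distance(s) negative after the "
            "imaginary-axis correction; clamped to 0",
            stacklevel=2,
        )
    distances = np.sqrt(np.clip(z2, 0.0, None))

    if np.allclose(distances, 0.0):
        raise ValueError("degenerate input: zero dispersion in every group")

    per_group = [distances[codes == g] for g in range(len(group_names))]
    grand = distances.mean()
    ss_total = ((distances - grand) ** 2).sum()
    ss_between = sum(len(d) * (d.mean() - grand) ** 2 for d in per_group)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0

    df_b = len(group_names) - 1
    df_w = len(ids) - len(group_names)
    ss_within = ss_total - ss_between
    # guard against catastrophic cancellation when all distances coincide
    var_tol = 1e-12 * max(float((distances**2).sum()), 1e-300)
    if ss_within <= var_tol:
        f = 0.0 if ss_between <= var_tol else math.inf
    else:
        f = (ss_between / df_b) / (ss_within / df_w)

    if permutations is None:
        p = float(stats.f.sf(f, df_b, df_w)) if math.isfinite(f) else 0.0
    else:
        rng = np.random.default_rng(seed)
        tie_tol = _TIE_RTOL * max(1.0, abs(f))
        count = 0
        for _ in range(permutations):
            perm = rng.permutation(codes)
            pg = [distances[perm == g] for g in range(len(group_names))]
            ssb = sum(len(d) * (d.mean() - grand) ** 2 for d in pg)
            ssw = ss_total - ssb
            f_perm = math.inf if ssw <= 0 else (ssb / df_b) / (ssw / df_w)
            if f_perm >= f - tie_tol:
                count += 1
        p = (1 + count) / (1 + permutations)

    dist_series = pd.Series(distances, index=ids, name="distance_to_centroid")
    means = {
        str(group_names[g]): float(per_group[g].mean()) for g in range(len(group_names))
    }
    return DispersionResult(
        distances=dist_series,
        groups=group_series,
        group_means=means,
        anova_f=float(f),
        p_value=float(p),
        r_squared=float(r2),
        n_clamped=n_clamped,
    )


def _simper_contributions(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Average per-variable Bray-Curtis contribution over between-group pairs."""
    diff = np.abs(x1[:, None, :] - x2[None, :, :])
    denom = x1.sum(axis=1)[:, None] + x2.sum(axis=1)[None, :]
    contrib = diff / denom[:, :, None]
    return contrib.mean(axis=(0, 1))


def simper(
    data: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
):
    """SIMPER decomposition of between-group Bray-Curtis dissimilarity.

    For samples i in group 1 and j in group 2, variable v contributes
    |x_iv - x_jv| / sum_m (x_im + x_jm) to their dissimilarity; contributions
    are averaged over all between-group pairs and therefore sum exactly to
    the mean between-group dissimilarity. Per-variable significance is by
    permuting group labels: p = (1 + #{perm average >= observed}) / (1 + n_perm).

    With more than two groups every pairwise contrast is run and a dict keyed
    by group-label pairs is returned.
    """
    if not isinstance(data, pd.DataFrame):
        data = pd.DataFrame(np.asarray(data, dtype=float))
    group_series = align_labels(list(data.index), groups, "groups")
    names = sorted(set(group_series))
    if len(names) < 2:
        raise ValueError("SIMPER needs at least two groups")
    if len(names) > 2:
        out = {}
        for g1, g2 in itertools.combinations(names, 2):
            mask = group_series.isin([g1, g2])
            out[(g1, g2)] = simper(data.loc[mask.to_numpy()], group_series[mask.to_numpy()], n_perm, seed)
        return out

    g1, g2 = names
    values = data.to_numpy(dtype=float)
    m1 = (group_series == g1).to_numpy()
    m2 = (group_series == g2).to_numpy()
    if m1.sum() == 0 or m2.sum() == 0:
        raise ValueError("each group needs at least one sample")
    x1, x2 = values[m1], values[m2]

    observed = _simper_contributions(x1, x2)
    overall = float(observed.sum())

    rng = np.random.default_rng(seed)
    n1 = int(m1.sum())
    count = np.zeros(values.shape[1])
    tie_tol = _TIE_RTOL * np.maximum(1.0, np.abs(observed))
    for _ in range(n_perm):
        perm = rng.permutation(values.shape[0])
        contrib = _simper_contributions(values[perm[:n1]], values[perm[n1:]])
        count += contrib >= observed - tie_tol
    p_values = (1 + count) / (1 + n_perm)

    # per-pair contributions for the sd column
    diff = np.abs(x1[:, None, :] - x2[None, :, :])
    denom = x1.sum(axis=1)[:, None] + x2.sum(axis=1)[None, :]
    per_pair = (diff / denom[:, :, None]).reshape(-1, values.shape[1])

    table = pd.DataFrame(
        {
            "average": observed,
            "sd": per_pair.std(axis=0, ddof=1) if per_pair.shape[0] > 1 else 0.0,
            f"mean_{g1}": x1.mean(axis=0),
            f"sd_{g1}": x1.std(axis=0, ddof=1) if x1.shape[0] > 1 else 0.0,
            f"mean_{g2}": x2.mean(axis=0),
            f"sd_{g2}": x2.std(axis=0, ddof=1) if x2.shape[0] > 1 else 0.0,
            "p_value": p_values,
        },
        index=data.columns,
    )
    table = table.sort_values("average", ascending=False)
    share = table["average"] / overall if overall > 0 else table["average"] * 0.0
    table.insert(1, "share", share)
    table.insert(2, "cumulative_share", share.cumsum())
    return SimperResult(
        table=table,
        overall_dissimilarity=overall,
        group_labels=(g1, g2),
        n_permutations=n_perm,
    )
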