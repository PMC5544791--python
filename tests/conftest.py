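"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from lotictraits import load_trait_schema


def brute_force_blocked_permanova(d: np.ndarray, labels, blocks):
    """Exact blocked-PERMANOVA p by explicit enumeration and double loops.

    Written independently of the package implementation: sums of squares via
    nested index loops, and the within-block relabeling space enumerated with
    ``set(itertools.permutations(...))`` per block.
    Returns (F_observed, exact p).
    """
    d = np.asarray(d, dtype=float)
    n = len(labels)

    def f_stat(lbls):
        names = sorted(set(lbls))
        a = len(names)
        sst = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                sst += d[i, j] ** 2
        sst /= n
        ssw = 0.0
        for g in names:
            idx = [i for i in range(n) if lbls[i] == g]
            s = 0.0
            for ii in range(len(idx)):
                for jj in range(ii + 1, len(idx)):
                    s += d[idx[ii], idx[jj]] ** 2
            ssw += s / len(idx)
        ssb = sst - ssw
        if ssw == 0:
            return float("inf") if ssb > 0 else 0.0
        return (ssb / (a - 1)) / (ssw / (n - a))

    block_names = sorted(set(blocks))
    block_idx, block_arrangements = [], []
    for b in block_names:
        idx = [i for i in range(n) if blocks[i] == b]
        block_idx.append(idx)
        block_arrangements.append(
            sorted(set(itertools.permutations([labels[i] for i in idx])))
        )

    f_obs = f_stat(list(labels))
    count = total = 0
    for combo in itertools.product(*block_arrangements):
        lbls = list(labels)
        for idx, arrangement in zip(block_idx, combo):
            for k, i in enumerate(idx):
                lbls[i] = arrangement[k]
        total += 1
        if f_stat(lbls) >= f_obs - 1e-12 * max(1.0, abs(f_obs)):
            count += 1
    return f_obs, count / total


def random_distance_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    """Bray-Curtis distances among random positive compositions."""
    from scipy.spatial.distance import pdist, squareform

    data = rng.gamma(2.0, 2.0, size=(n, 6)) + 0.05
    return squareform(pdist(data, metric="braycurtis"))


@pytest.fixture(scope="session")
def schema():
    return load_trait_schema()


@pytest.fixture
def rng():
    return np.random.default_rng(20140701)


@pytest.fixture
def tiny_trait_table():
    """Two-feature schema-compatible fuzzy table for hand-checkable cases."""
    rows = [
        ("mayfly", "Feat1", "F1.a", 3),
        ("mayfly", "Feat1", "F1.b", 1),
        ("mayfly", "Feat1", "F1.c", 0),
        ("mayfly", "Feat2", "F2.a", 0),
        ("mayfly", "Feat2", "F2.b", 0),
        ("caddis", "Feat1", "F1.a", 0),
        ("caddis", "Feat1", "F1.b", 0),
        ("caddis", "Feat1", "F1.c", 5),
        ("caddis", "Feat2", "F2.a", 2),
        ("caddis", "Feat2", "F2.b", 2),
    ]
    return pd.DataFrame(
        rows, columns=["taxon", "grouping_feature", "trait_code", "affinity"]
    ).assign(rank="family")


@pytest.fixture
def tiny_schema():
    from lotictraits.traits import TraitSchema

    return TraitSchema(
        ("Feat1", "Feat2"),
        {"Feat1": ("F1.a", "F1.b", "F1.c"), "Feat2": ("F2.a", "F2.b")},
    )
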