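"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from metastate import FeatureTable
from metastate.selection import criterion_loocv_error


def brute_force_kendall(series: np.ndarray) -> float:
    """Independent variance-of-rank-sums computation of Kendall's W.

    Ranks each row with an explicit loop and returns 12*S / (K^2 (n^3 - n))
    with S the sum of squared deviations of the rank sums from their mean.
    Deliberately written differently from the library implementation.
    """
    series = np.asarray(series, dtype=float)
    K, n = series.shape
    ranks = np.empty_like(series)
    for j in range(K):
        ranks[j] = rankdata(series[j])
    rank_sums = np.array([ranks[:, i].sum() for i in range(n)])
    S = float(np.sum((rank_sums - rank_sums.mean()) ** 2))
    return 12.0 * S / (K ** 2 * (n ** 3 - n))


def exhaustive_search(table: FeatureTable, max_size: int) -> dict[int, tuple[tuple[int, ...], float]]:
    """Global optimum of the LOOCV criterion per subset size, by enumeration."""
    best: dict[int, tuple[tuple[int, ...], float]] = {}
    for k in range(1, max_size + 1):
        scored = [
            (criterion_loocv_error(table, subset), subset)
            for subset in itertools.combinations(table.region_labels, k)
        ]
        val, subset = min(scored, key=lambda t: (t[0], t[1]))
        best[k] = (subset, val)
    return best


def paired_table(X: np.ndarray, y_signs: np.ndarray,
                 feature_kind: str = "synthetic") -> FeatureTable:
    """Wrap a raw matrix and +/-1 labels into a paired-design FeatureTable."""
    n = X.shape[0]
    assert n % 2 == 0
    y = np.where(y_signs > 0, "hunger", "satiety").astype(object)
    subjects = np.repeat([f"S{i + 1:02d}" for i in range(n // 2)], 2)
    return FeatureTable(X=X, y=y, subject_id=subjects,
                        region_labels=list(range(1, X.shape[1] + 1)),
                        feature_kind=feature_kind)


def xor_style_table() -> FeatureTable:
    """A table where SFS is trapped by the nesting effect and SFFS is not.

    Regions 1 and 2 carry the class signal plus and minus a large shared
    nuisance component, so they separate perfectly only jointly (their sum
    cancels the nuisance); region 5 is a decent but imperfect singleton.
    Greedy forward selection picks 5 first and never reaches {1, 2}; the
    floating variant drops 5 via conditional exclusion.  Verified against
    exhaustive search in the acceptance suite.
    """
    rng = np.random.default_rng(3)
    n_sub = 10
    u = rng.normal(0.0, 3.0, 2 * n_sub)
    y_signs = np.tile([1.0, -1.0], n_sub)
    X = rng.normal(0.0, 1.0, size=(2 * n_sub, 8))
    X[:, 0] = y_signs + u
    X[:, 1] = y_signs - u
    X[:, 4] = 1.2 * y_signs + rng.normal(0.0, 1.0, 2 * n_sub)
    return paired_table(X, y_signs)


@pytest.fixture(scope="session")
def octant_parcellation():
    from metastate import make_toy_parcellation

    return make_toy_parcellation((6, 6, 6), 8)
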