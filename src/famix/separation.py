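"""Source-separation testing: one-way PERMANOVA and pairwise comparisons.

Mixing models can only apportion diet among sources whose tracer signatures
actually differ, so before fitting we test whether the candidate prey have
distinguishable FA compositions. The test is a one-way permutational
multivariate ANOVA (PERMANOVA) on a dissimilarity matrix: the pseudo-F
statistic partitions among- and within-group sums of squared dissimilarities
and is compared against a null distribution obtained by permuting group
labels. With more than two sources, all unordered pairs are compared and the
per-pair p-values are Bonferroni adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .fa_data import ConsumerDataset, FAProfile

__all__ = [
    "PermanovaResult",
    "PairwiseComparison",
    "distance_matrix",
    "permanova",
    "pairwise_permanova",
    "pairwise_to_frame",
]

_METRICS = ("bray_curtis", "euclidean")


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    df_between: int
    df_within: int

    def __str__(self):
        return (
            f"PERMANOVA pseudo-F({self.df_between},{self.df_within}) = "
            f"{self.pseudo_F:.2f}, p = {self.p_value:.4g} "
            f"({self.n_permutations} permutations)"
        )


@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    result: PermanovaResult
    p_adjusted: float


def _as_matrix(profiles) -> np.ndarray:
    if isinstance(profiles, ConsumerDataset):
        return profiles.to_matrix()
    if isinstance(profiles, np.ndarray):
        return np.asarray(profiles, dtype=float)
    if profiles and isinstance(profiles[0], FAProfile):
        return np.vstack([p.values for p in profiles])
    return np.asarray(profiles, dtype=float)


def distance_matrix(profiles, metric: str = "bray_curtis") -> np.ndarray:
    """Symmetric pairwise dissimilarity matrix between profiles.

    ``bray_curtis`` (the default for compositional FA data) lies in [0, 1];
    ``euclidean`` is available for sensitivity analyses.
    """
    X = _as_matrix(profiles)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two profiles")
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    if metric == "bray_curtis":
        if np.any(X.sum(axis=1) == 0):
            raise ValueError("Bray-Curtis is undefined for an all-zero profile")
        D = squareform(pdist(X, metric="braycurtis"))
    else:
        D = squareform(pdist(X, metric="euclidean"))
    return D


def _permanova_from_distances(
    D: np.ndarray, groups: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> PermanovaResult:
    n = D.shape[0]
    labels, inv = np.unique(groups, return_inverse=True)
    a = labels.size
    if a < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    counts = np.bincount(inv)
    if np.any(counts < 2):
        warnings.warn(
            "group(s) with a single member: within-group variance is undefined "
            "for them and the test has little power",
            stacklevel=3,
        )
    D2 = D**2
    ss_total = D2[np.triu_indices(n, 1)].sum() / n

    def ss_within(label_rows: np.ndarray) -> np.ndarray:
        # label_rows: (P, n) integer labels; returns (P,) within-group SS
        ssw = np.zeros(label_rows.shape[0])
        for g in range(a):
            B = (label_rows == g).astype(float)
            ssw += np.einsum("pi,ij,pj->p", B, D2, B) / (2.0 * counts[g])
        return ssw

    ssw_obs = ss_within(inv[None, :])[0]
    df_b, df_w = a - 1, n - a
    if ssw_obs <= 0:
        f_obs = np.inf
    else:
        f_obs = ((ss_total - ssw_obs) / df_b) / (ssw_obs / df_w)

    perms = np.empty((n_permutations, n), dtype=inv.dtype)
    for p in range(n_permutations):
        perms[p] = rng.permutation(inv)
    ssw_perm = ss_within(perms)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = ((ss_total - ssw_perm) / df_b) / (ssw_perm / df_w)
    f_perm = np.where(ssw_perm <= 0, np.inf, f_perm)
    p_value = (np.count_nonzero(f_perm >= f_obs) + 1) / (n_permutations + 1)
    return PermanovaResult(float(f_obs), float(p_value), n_permutations, df_b, df_w)


def permanova(
    profiles,
    groups,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = None,
    metric: str = "bray_curtis",
) -> PermanovaResult:
    """One-way PERMANOVA of ``profiles`` against group labels.

    The p-value is ``(#{permuted F >= observed F} + 1) / (n_permutations + 1)``,
    so its smallest attainable value is ``1/(n_permutations + 1)`` (0.001 at
    the default 999 permutations). Raw labels are permuted; the design is
    one-way only.
    """
    D = distance_matrix(profiles, metric=metric)
    groups = np.asarray([str(g) for g in groups])
    if groups.shape[0] != D.shape[0]:
        raise ValueError("one group label per profile is required")
    if np.unique(groups).size < 2:
        raise ValueError("all group labels identical; nothing to test")
    rng = np.random.default_rng(seed)
    return _permanova_from_distances(D, groups, n_permutations, rng)


def pairwise_permanova(
    profiles,
    groups,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = None,
    metric: str = "bray_curtis",
) -> list[PairwiseComparison]:
    """PERMANOVA on every unordered pair of groups, Bonferroni adjusted.

    Each pair gets an independent seeded permutation stream derived from
    ``seed``; adjusted p-values are ``min(1, p * n_pairs)``.
    """
    X = _as_matrix(profiles)
    groups = np.asarray([str(g) for g in groups])
    labels = sorted(np.unique(groups).tolist())
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=len(pairs))
    out = []
    for (a, b), s in zip(pairs, child_seeds):
        mask = (groups == a) | (groups == b)
        res = permanova(
            X[mask], groups[mask], n_permutations=n_permutations,
            seed=int(s), metric=metric,
        )
        out.append(
            PairwiseComparison((a, b), res, min(1.0, res.p_value * len(pairs)))
        )
    return out


def pairwise_to_frame(comparisons: list[PairwiseComparison]) -> pd.DataFrame:
    """Tabular export (pair, F, df, p_raw, p_adj) for reporting."""
    return pd.DataFrame(
        {
            "group_1": [c.pair[0] for c in comparisons],
            "group_2": [c.pair[1] for c in comparisons],
            "pseudo_F": [c.result.pseudo_F for c in comparisons],
            "df_between": [c.result.df_between for c in comparisons],
            "df_within": [c.result.df_within for c in comparisons],
            "p_raw": [c.result.p_value for c in comparisons],
            "p_adj": [c.p_adjusted for c in comparisons],
        }
    )
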