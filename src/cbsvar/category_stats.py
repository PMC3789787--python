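"""Randomization test for phenotype-category / structural-feature association.

Alleles are partitioned into groups (phenotype category, optionally
crossed with construction method — six groups in all) and per-group means
of each structural feature are compared with an empirical null obtained
by randomly reassigning the same number of alleles to each group many
times (10,000 by default).  Two one-sided empirical p-values with add-one
correction report whether the observed group mean is higher or lower than
expected under random assignment.

``exhaustive_test`` enumerates every assignment exactly and serves as the
small-n oracle for the Monte-Carlo version.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sympy.utilities.iterables import multiset_permutations

__all__ = [
    "GroupSpec",
    "PermutationResult",
    "group_means",
    "permutation_test",
    "exhaustive_test",
    "DEFAULT_N_PERM",
]

DEFAULT_N_PERM = 10_000
EXHAUSTIVE_LIMIT = 10 ** 6


@dataclass(frozen=True)
class GroupSpec:
    """One analysis group: a phenotype (x construction) cell and its members."""

    name: str
    members: tuple[str, ...]   # allele identifiers (substitution tokens)

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError(f"group {self.name!r} is empty")


@dataclass(frozen=True)
class PermutationResult:
    group: str
    feature: str
    observed_mean: float
    null_mean: float
    null_sd: float
    p_high: float    # P(null mean >= observed)
    p_low: float     # P(null mean <= observed)
    n_perm: int
    seed: int | None

    def __post_init__(self) -> None:
        for p in (self.p_high, self.p_low):
            if not 0.0 < p <= 1.0:
                raise ValueError("empirical p-values lie in (0, 1]")


def _check_partition(groups: Sequence[GroupSpec]) -> list[str]:
    alleles: list[str] = []
    for g in groups:
        alleles.extend(g.members)
    if len(set(alleles)) != len(alleles):
        raise ValueError("groups must partition the alleles (duplicate member)")
    return alleles


def group_means(features: Mapping[str, Mapping[str, float]],
                groups: Sequence[GroupSpec]) -> dict[tuple[str, str], float]:
    """Arithmetic mean of each feature within each group.

    ``features`` maps allele -> feature name -> value; boolean features
    should be passed as 0/1 so their mean is an occupancy fraction.
    Alleles missing a feature are excluded from that feature's mean; a
    group losing all members for a feature is an error.
    """
    feature_names = sorted({f for per in features.values() for f in per})
    out: dict[tuple[str, str], float] = {}
    for g in groups:
        for fname in feature_names:
            values = [
                float(features[a][fname]) for a in g.members
                if a in features and fname in features[a]
                and features[a][fname] is not None
            ]
            if not values:
                raise ValueError(
                    f"group {g.name!r} has no values for feature {fname!r}")
            out[(g.name, fname)] = float(np.mean(values))
    return out


def _feature_matrix(features: Mapping[str, Mapping[str, float]],
                    alleles: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    feature_names = sorted({f for per in features.values() for f in per})
    mat = np.full((len(alleles), len(feature_names)), np.nan)
    for i, a in enumerate(alleles):
        for j, fname in enumerate(feature_names):
            v = features.get(a, {}).get(fname)
            if v is not None:
                mat[i, j] = float(v)
    return mat, feature_names


def _results_from_null(observed: np.ndarray, null: np.ndarray,
                       groups: Sequence[GroupSpec], feature_names: list[str],
                       n_perm: int, seed: int | None) -> list[PermutationResult]:
    results = []
    for gi, g in enumerate(groups):
        for fj, fname in enumerate(feature_names):
            obs = observed[gi, fj]
            draws = null[:, gi, fj]
            p_high = (1 + int((draws >= obs - 1e-12).sum())) / (n_perm + 1)
            p_low = (1 + int((draws <= obs + 1e-12).sum())) / (n_perm + 1)
            results.append(PermutationResult(
                group=g.name, feature=fname, observed_mean=float(obs),
                null_mean=float(draws.mean()), null_sd=float(draws.std()),
                p_high=p_high, p_low=p_low, n_perm=n_perm, seed=seed))
    return results


def _null_means(mat: np.ndarray, sizes: Sequence[int],
                assignment: np.ndarray) -> np.ndarray:
    """Group-mean matrix (n_groups, n_features) for one allele ordering,
    slicing the permuted rows into consecutive blocks of the group sizes."""
    out = np.empty((len(sizes), mat.shape[1]))
    start = 0
    for gi, size in enumerate(sizes):
        block = mat[assignment[start:start + size]]
        out[gi] = np.nanmean(block, axis=0)
        start += size
    return out


def permutation_test(features: Mapping[str, Mapping[str, float]],
                     groups: Sequence[GroupSpec],
                     n_perm: int = DEFAULT_N_PERM,
                     seed: int | None = None) -> list[PermutationResult]:
    """Monte-Carlo permutation test of per-group feature means.

    Each shuffle permutes the allele -> group assignment while preserving
    group sizes (and the per-allele covariance across features, since the
    feature rows travel together).  Empirical p-values use the add-one
    correction, so the smallest attainable p is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    alleles = _check_partition(groups)
    mat, feature_names = _feature_matrix(features, alleles)
    sizes = [len(g.members) for g in groups]

    observed = _null_means(mat, sizes, np.arange(len(alleles)))
    rng = np.random.default_rng(seed)
    # uniform random permutations, all drawn at once
    perms = np.argsort(rng.random((n_perm, len(alleles))), axis=1)
    null = np.empty((n_perm, len(groups), len(feature_names)))
    start = 0
    for gi, size in enumerate(sizes):
        block = mat[perms[:, start:start + size]]     # (n_perm, size, n_feat)
        null[:, gi, :] = np.nanmean(block, axis=1)
        start += size
    return _results_from_null(observed, null, groups, feature_names, n_perm, seed)


def _n_assignments(sizes: Sequence[int]) -> int:
    n = sum(sizes)
    total = math.factorial(n)
    for s in sizes:
        total //= math.factorial(s)
    return total


def exhaustive_test(features: Mapping[str, Mapping[str, float]],
                    groups: Sequence[GroupSpec]) -> list[PermutationResult]:
    """Exact version of :func:`permutation_test` by full enumeration.

    Enumerates every distinct assignment of alleles to the group sizes
    (a multiset permutation of group labels), so the p-values are exact
    proportions with no Monte-Carlo error; the add-one convention is not
    needed because the observed assignment is itself enumerated.
    """
    alleles = _check_partition(groups)
    sizes = [len(g.members) for g in groups]
    total = _n_assignments(sizes)
    if total > EXHAUSTIVE_LIMIT:
        raise ValueError(
            f"{total} assignments exceed the enumeration bound "
            f"({EXHAUSTIVE_LIMIT}); use permutation_test")
    mat, feature_names = _feature_matrix(features, alleles)

    observed = _null_means(mat, sizes, np.arange(len(alleles)))
    labels = np.repeat(np.arange(len(groups)), sizes)
    null = np.empty((total, len(groups), len(feature_names)))
    for t, lab in enumerate(multiset_permutations(list(labels))):
        lab = np.asarray(lab)
        order = np.argsort(lab, kind="stable")
        null[t] = _null_means(mat, sizes, order)

    results = []
    for gi, g in enumerate(groups):
        for fj, fname in enumerate(feature_names):
            obs = observed[gi, fj]
            draws = null[:, gi, fj]
            p_high = int((draws >= obs - 1e-12).sum()) / total
            p_low = int((draws <= obs + 1e-12).sum()) / total
            results.append(PermutationResult(
                group=g.name, feature=fname, observed_mean=float(obs),
                null_mean=float(draws.mean()), null_sd=float(draws.std()),
                p_high=p_high, p_low=p_low, n_perm=total, seed=None))
    return results
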