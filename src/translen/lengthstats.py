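"""Finite-population transcript-length statistics with Cantelli P-value bounds.

Three test designs, all with a sampling-without-replacement null:

* one_subset    — a subset of M transcripts drawn from a set of N; the
                  statistic is the difference between the subset's average
                  length and the set's.  Null variance
                  sigma^2 (N-M) / (M (N-1)) with sigma^2 the population
                  variance of the set.
* two_subset    — two subsets drawn independently from the union of the two;
                  the statistic is the difference of their averages and the
                  null variance is the sum of the two one-subset variances
                  computed on the union's moments.
* split         — a subset of M transcripts divided into a part of L and its
                  complement; the statistic is the difference of the parts'
                  averages.  Null variance sigma_M^2 M^2 / (L (M-L) (M-1)).

Each design's P-value is the one-sided Cantelli (one-sided Chebyshev) upper
bound Var / (Var + delta^2) on the probability of a displacement at least as
extreme as observed, in the observed direction.  An enumeration / Monte-Carlo
null oracle validates the closed forms and provides exact tail probabilities
on small instances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Set

import numpy as np

__all__ = [
    "LengthTable",
    "SubsetTestResult",
    "set_moments",
    "one_subset_test",
    "two_subset_test",
    "split_test",
    "null_oracle",
    "NullDistribution",
]

_EXHAUSTIVE_LIMIT = 10**6


@dataclass
class LengthTable:
    """Per-entity transcript lengths (nt) plus named annotation subsets."""

    entity_ids: Sequence[str]
    lengths: np.ndarray
    annotation_sets: Dict[str, Set[str]] = field(default_factory=dict)
    extra: Optional[Dict[str, np.ndarray]] = None  # e.g. max/min gene lengths

    def __post_init__(self) -> None:
        ids = list(self.entity_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate entity ids")
        lengths = np.asarray(self.lengths, dtype=float)
        if lengths.shape != (len(ids),):
            raise ValueError("lengths must align with entity_ids")
        if np.any(lengths <= 0):
            raise ValueError("lengths must be positive")
        universe = set(ids)
        for term, members in self.annotation_sets.items():
            extraneous = set(members) - universe
            if extraneous:
                raise ValueError(f"annotation {term!r} contains unknown ids")
        self.entity_ids = ids
        self.lengths = lengths
        self._index = {g: i for i, g in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.entity_ids)

    def lengths_of(self, ids: Iterable[str]) -> np.ndarray:
        return self.lengths[[self._index[g] for g in ids]]

    def subset(self, name_or_ids) -> Set[str]:
        if isinstance(name_or_ids, str):
            return set(self.annotation_sets[name_or_ids])
        return set(name_or_ids)


@dataclass
class SubsetTestResult:
    design: str
    delta_observed: float
    null_mean: float
    null_variance: float
    cantelli_p: float
    direction: str
    sizes: Dict[str, int]
    oracle_p: Optional[float] = None


def set_moments(lengths: Sequence[float]) -> tuple:
    """Average and population variance (divide by N) of a length set."""
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise ValueError("empty length set")
    mean = float(arr.mean())
    var = float(((arr - mean) ** 2).mean())
    return mean, var


def _cantelli(var: float, delta: float) -> float:
    # zero-variance null: no displacement is evidence of anything
    if var <= 0:
        return 1.0
    return var / (var + delta**2)


def _one_subset_variance(var: float, N: int, M: int) -> float:
    return var * (N - M) / (M * (N - 1))


def one_subset_test(table: LengthTable, subset) -> SubsetTestResult:
    """Subset-vs-set test: is the subset's average length atypical?"""
    sub = table.subset(subset)
    N, M = len(table), len(sub)
    if M == 0 or M >= N:
        raise ValueError("subset must be a nonempty proper subset of the table")
    mean_all, var_all = set_moments(table.lengths)
    mean_sub, _ = set_moments(table.lengths_of(sub))
    delta = mean_sub - mean_all
    var = _one_subset_variance(var_all, N, M)
    return SubsetTestResult(
        design="one_subset",
        delta_observed=delta,
        null_mean=0.0,
        null_variance=var,
        cantelli_p=_cantelli(var, delta),
        direction="shorter" if delta < 0 else "longer",
        sizes={"N": N, "M": M},
    )


def two_subset_test(table: LengthTable, subset_a, subset_b) -> SubsetTestResult:
    """Two possibly overlapping subsets, each treated as independently drawn
    from the union of the two."""
    a, b = table.subset(subset_a), table.subset(subset_b)
    if not a or not b:
        raise ValueError("both subsets must be nonempty")
    union = sorted(a | b)
    N = len(union)
    mean_u, var_u = set_moments(table.lengths_of(union))
    mean_a, _ = set_moments(table.lengths_of(a))
    mean_b, _ = set_moments(table.lengths_of(b))
    delta = mean_a - mean_b
    var = 0.0
    if N > 1:
        var = (_one_subset_variance(var_u, N, len(a))
               + _one_subset_variance(var_u, N, len(b)))
    return SubsetTestResult(
        design="two_subset",
        delta_observed=delta,
        null_mean=0.0,
        null_variance=var,
        cantelli_p=_cantelli(var, delta),
        direction="shorter" if delta < 0 else "longer",
        sizes={"N": N, "L": len(a), "M": len(b)},
    )


def split_test(table: LengthTable, part_a, universe) -> SubsetTestResult:
    """Mutually exclusive split of a universe of M into a part of L and its
    complement; statistic = mean(part) - mean(complement)."""
    part = table.subset(part_a)
    uni = table.subset(universe)
    if not part or not part < uni:
        raise ValueError("part must be a nonempty proper subset of the universe")
    M, L = len(uni), len(part)
    comp = uni - part
    mean_part, _ = set_moments(table.lengths_of(part))
    mean_comp, _ = set_moments(table.lengths_of(comp))
    _, var_m = set_moments(table.lengths_of(uni))
    delta = mean_part - mean_comp
    var = var_m * M**2 / (L * (M - L) * (M - 1)) if M > 1 else 0.0
    return SubsetTestResult(
        design="split",
        delta_observed=delta,
        null_mean=0.0,
        null_variance=var,
        cantelli_p=_cantelli(var, delta),
        direction="shorter" if delta < 0 else "longer",
        sizes={"M": M, "L": L},
    )


@dataclass
class NullDistribution:
    """Empirical null of a design's statistic (exhaustive or Monte-Carlo)."""

    design: str
    statistics: np.ndarray
    mode: str

    @property
    def mean(self) -> float:
        return float(self.statistics.mean())

    @property
    def variance(self) -> float:
        return float(((self.statistics - self.statistics.mean()) ** 2).mean())

    def tail_probability(self, delta: float) -> float:
        """P(statistic at least as extreme as delta, in delta's direction)."""
        s = self.statistics
        tol = 1e-12 * (1.0 + abs(delta))
        if delta >= 0:
            return float(np.mean(s >= delta - tol))
        return float(np.mean(s <= delta + tol))


def _check_exhaustive(count: int) -> None:
    if count > _EXHAUSTIVE_LIMIT:
        raise ValueError(
            f"{count} subsets exceed the exhaustive limit; use mode='monte_carlo'")


def null_oracle(lengths: Sequence[float], design: str, sizes: Dict[str, int],
                mode: str = "exhaustive", seed: int = 0,
                n_reps: int = 10000) -> NullDistribution:
    """Empirical null distribution of a design's statistic.

    For ``one_subset`` pass sizes {"M": M}; for ``two_subset`` {"L": L, "M": M}
    (both drawn from all of ``lengths``, i.e. the union); for ``split``
    {"L": L}.  Exhaustive mode enumerates every subset (or pair of subsets)
    and is exact; Monte-Carlo mode is seed-deterministic.
    """
    arr = np.asarray(lengths, dtype=float)
    N = arr.size
    rng = np.random.default_rng(seed)
    stats: list = []
    if design == "one_subset":
        M = sizes["M"]
        mean_all = arr.mean()
        if mode == "exhaustive":
            _check_exhaustive(math.comb(N, M))
            for idx in itertools.combinations(range(N), M):
                stats.append(arr[list(idx)].mean() - mean_all)
        else:
            for _ in range(n_reps):
                idx = rng.choice(N, size=M, replace=False)
                stats.append(arr[idx].mean() - mean_all)
    elif design == "two_subset":
        L, M = sizes["L"], sizes["M"]
        if mode == "exhaustive":
            _check_exhaustive(math.comb(N, L) * math.comb(N, M))
            subs_l = [arr[list(i)].mean() for i in itertools.combinations(range(N), L)]
            subs_m = [arr[list(i)].mean() for i in itertools.combinations(range(N), M)]
            for ml in subs_l:
                for mm in subs_m:
                    stats.append(ml - mm)
        else:
            for _ in range(n_reps):
                il = rng.choice(N, size=L, replace=False)
                im = rng.choice(N, size=M, replace=False)
                stats.append(arr[il].mean() - arr[im].mean())
    elif design == "split":
        L = sizes["L"]
        total = arr.sum()
        if mode == "exhaustive":
            _check_exhaustive(math.comb(N, L))
            for idx in itertools.combinations(range(N), L):
                part = arr[list(idx)].sum()
                stats.append(part / L - (total - part) / (N - L))
        else:
            for _ in range(n_reps):
                idx = rng.choice(N, size=L, replace=False)
                part = arr[idx].sum()
                stats.append(part / L - (total - part) / (N - L))
    else:
        raise ValueError(f"unknown design {design!r}")
    return NullDistribution(design=design, statistics=np.asarray(stats), mode=mode)


def subset_report(table: LengthTable, subsets: Sequence, reference=None):
    """One-subset (or two-subset against ``reference``) tests for a list of
    annotation subsets; returns a pandas DataFrame with report-style
    columns (subset, M, mean length, delta, P-value)."""
    import pandas as pd

    rows = []
    for name in subsets:
        ids = table.subset(name)
        mean_sub, _ = set_moments(table.lengths_of(ids))
        if reference is None:
            res = one_subset_test(table, ids)
        else:
            res = two_subset_test(table, ids, reference)
        rows.append({
            "subset": name if isinstance(name, str) else "<ids>",
            "M": len(ids),
            "mean_length_nt": mean_sub,
            "delta_nt": res.delta_observed,
            "cantelli_p": res.cantelli_p,
        })
    return pd.DataFrame(rows)
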