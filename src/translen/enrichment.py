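"""Overexpression annotation, subset partitioning and hypergeometric enrichment.

An entity is annotated as overexpressed in a condition (e.g. normal brain or
tumor) if it ranks among the top X most expressed entities in at least a
fraction f (default 20%) of that condition's samples.  Two conditions' calls
partition the entities into three mutually exclusive subsets (a-only, b-only,
both) plus the two overall subsets; each subset is then scanned for
enrichment in flat annotation terms with the hypergeometric upper tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, Mapping, Set

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "OverexpressionCall",
    "SubsetPartition",
    "annotate_overexpressed",
    "partition_subsets",
    "hypergeom_enrichment",
    "enrichment_scan",
    "consistent_terms",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Entities x samples abundance table with per-sample condition labels."""

    values: np.ndarray
    entity_ids: tuple
    sample_ids: tuple
    conditions: tuple

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        ids = tuple(self.entity_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate entity ids")
        if vals.shape != (len(ids), len(self.sample_ids)):
            raise ValueError("values shape must be entities x samples")
        if len(self.conditions) != len(self.sample_ids):
            raise ValueError("one condition label per sample required")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "entity_ids", ids)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "conditions", tuple(self.conditions))

    def samples_of(self, condition: str) -> np.ndarray:
        idx = np.array([i for i, c in enumerate(self.conditions) if c == condition])
        if idx.size == 0:
            raise ValueError(f"no samples with condition {condition!r}")
        return idx


@dataclass
class OverexpressionCall:
    condition: str
    cutoff: int
    fraction: Fraction
    entity_ids: tuple
    counts: np.ndarray     # samples in which each entity ranked top-X
    n_samples: int

    @property
    def flags(self) -> np.ndarray:
        return np.array([Fraction(int(c), self.n_samples) >= self.fraction
                         for c in self.counts])

    @property
    def flagged_ids(self) -> Set[str]:
        return {g for g, f in zip(self.entity_ids, self.flags) if f}


def _as_fraction(f) -> Fraction:
    if isinstance(f, Fraction):
        return f
    return Fraction(str(f))


def annotate_overexpressed(E: ExpressionMatrix, condition: str, X: int,
                           f=Fraction(1, 5)) -> OverexpressionCall:
    """Flag entities ranked top-X by abundance in >= f of a condition's samples.

    Per-sample ranking is by descending value with ties broken by stable
    input order; the >= f comparison is exact rational (for ten normal
    samples, f = 1/5 means at least 2 samples).
    """
    n = len(E.entity_ids)
    if not (1 <= X <= n):
        raise ValueError(f"cutoff X={X} out of range 1..{n}")
    frac = _as_fraction(f)
    cols = E.samples_of(condition)
    counts = np.zeros(n, dtype=int)
    for j in cols:
        order = np.argsort(-E.values[:, j], kind="stable")
        counts[order[:X]] += 1
    return OverexpressionCall(
        condition=condition,
        cutoff=X,
        fraction=frac,
        entity_ids=E.entity_ids,
        counts=counts,
        n_samples=int(cols.size),
    )


@dataclass
class SubsetPartition:
    a_only: Set[str]
    b_only: Set[str]
    both: Set[str]

    @property
    def a_overall(self) -> Set[str]:
        return self.a_only | self.both

    @property
    def b_overall(self) -> Set[str]:
        return self.b_only | self.both

    def named(self, a: str = "a", b: str = "b") -> Dict[str, Set[str]]:
        return {
            f"{a}_only": self.a_only,
            f"{b}_only": self.b_only,
            "both": self.both,
            f"{a}_overall": self.a_overall,
            f"{b}_overall": self.b_overall,
        }


def partition_subsets(call_a: OverexpressionCall,
                      call_b: OverexpressionCall) -> SubsetPartition:
    """Mutually exclusive a-only / b-only / both partition of two calls."""
    if call_a.entity_ids != call_b.entity_ids:
        raise ValueError("calls must share the same entity universe")
    a, b = call_a.flagged_ids, call_b.flagged_ids
    return SubsetPartition(a_only=a - b, b_only=b - a, both=a & b)


def hypergeom_enrichment(N: int, Y: int, M: int, y: int) -> float:
    """Upper-tail hypergeometric probability of >= y annotated entities in a
    subset of M, given Y annotated among N total."""
    if not (0 <= Y <= N and 0 <= M <= N):
        raise ValueError("require 0 <= Y, M <= N")
    if not (0 <= y <= min(Y, M)):
        raise ValueError("require 0 <= y <= min(Y, M)")
    if y < max(0, M + Y - N):
        raise ValueError("inconsistent counts: y below the support minimum")
    p = float(hypergeom.sf(y - 1, N, Y, M))
    return min(max(p, 0.0), 1.0)


def enrichment_scan(subsets: Mapping[str, Set[str]],
                    annotations: Mapping[str, Set[str]],
                    universe: Iterable[str]) -> pd.DataFrame:
    """Hypergeometric enrichment of every (subset, term) pair.

    ``universe`` is the global entity set (size N); terms with no member in
    the universe are skipped with a warning.  Rows are sorted by p ascending.
    """
    uni = set(universe)
    N = len(uni)
    rows = []
    for term, members in annotations.items():
        members_in = set(members) & uni
        if not members_in:
            logger.warning("annotation %r absent from the universe; skipped", term)
            continue
        Y = len(members_in)
        for name, sub in subsets.items():
            sub_in = set(sub) & uni
            M = len(sub_in)
            if M == 0:
                continue
            y = len(sub_in & members_in)
            rows.append({
                "subset": name, "term": term,
                "N": N, "Y": Y, "M": M, "y": y,
                "p": hypergeom_enrichment(N, Y, M, y),
            })
    df = pd.DataFrame(rows, columns=["subset", "term", "N", "Y", "M", "y", "p"])
    return df.sort_values(["p", "subset", "term"], kind="stable").reset_index(drop=True)


def consistent_terms(scans: Mapping[int, pd.DataFrame], subset: str,
                     alpha: float = 0.05) -> Set[str]:
    """Terms significantly enriching ``subset`` at every supplied cutoff.

    Mirrors the robustness device of requiring an enrichment to persist
    across all overexpression cutoffs before reporting it.
    """
    per_cutoff = []
    for X, df in scans.items():
        hits = set(df.loc[(df["subset"] == subset) & (df["p"] < alpha), "term"])
        per_cutoff.append(hits)
    return set.intersection(*per_cutoff) if per_cutoff else set()
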