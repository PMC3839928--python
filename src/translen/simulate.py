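"""Seeded generators with the exact statistical structure the analysis assumes.

Three families of fixtures:

* coherent-state profile matrices — each row is an asymmetric Gaussian
  profile whose peak is itself drawn from an asymmetric Gaussian around the
  equilibrium, with log-normal amplitudes and multiplicative log-normal
  measurement noise (default sigma 0.05, matching an approximately 5 %
  measurement precision);
* annotated length tables — log-normal transcript lengths with planted
  annotation subsets of controlled mean-length shifts;
* expression matrices — planted top-X overexpression structure that the
  annotation step recovers exactly by construction.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from fractions import Fraction
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .enrichment import ExpressionMatrix
from .lengthstats import LengthTable
from .model import ACSParams, GelGrid
from .svd import ProfileMatrix

__all__ = [
    "SimulationConfig",
    "sample_peaks",
    "simulate_profile_matrix",
    "simulate_annotated_lengths",
    "simulate_expression",
    "human_like_config",
    "yeast_like_config",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a coherent-state profile matrix.

    ``k_alpha`` sets the width of the peak (equilibrium) distribution,
    ``k_beta`` the width of each transcript's own profile; the asymmetry
    ``s`` is shared by both levels, as the coherent-state model requires.
    """

    n_transcripts: int
    grid: GelGrid
    x0: float
    k_alpha: float
    k_beta: float
    s: float = 1.1
    amplitude_mu_log: float = 0.0
    amplitude_sigma_log: float = 0.5
    noise_sigma: float = 0.05
    noise_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_alpha", "k_beta", "s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sigma < 0 or self.noise_floor < 0:
            raise ValueError("noise parameters must be nonnegative")
        if self.n_transcripts < 1:
            raise ValueError("need at least one transcript")

    @property
    def peak_params(self) -> ACSParams:
        return ACSParams(x0=self.x0, k=self.k_alpha, s=self.s)

    @property
    def profile_params(self) -> ACSParams:
        return ACSParams(x0=self.x0, k=self.k_beta, s=self.s)


def human_like_config(n_transcripts: int = 4109, seed: int = 0) -> SimulationConfig:
    """Human-scale study conditions: 50 slices of 2 mm spanning 26-124 mm,
    equilibrium at 84 mm."""
    return SimulationConfig(
        n_transcripts=n_transcripts,
        grid=GelGrid.uniform(26.0, 50, 2.0),
        x0=84.0, k_alpha=1.0 / 256.0, k_beta=1.0 / 16.0, seed=seed)


def yeast_like_config(n_transcripts: int = 3620, seed: int = 0) -> SimulationConfig:
    """Yeast-scale study conditions: 30 slices of 2 mm spanning 42-100 mm,
    equilibrium at 78 mm."""
    return SimulationConfig(
        n_transcripts=n_transcripts,
        grid=GelGrid.uniform(42.0, 30, 2.0),
        x0=78.0, k_alpha=1.0 / 100.0, k_beta=1.0 / 16.0, seed=seed)


def sample_peaks(config: SimulationConfig,
                 rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """I.i.d. draws from the normalized asymmetric Gaussian peak distribution.

    A side is chosen with probability proportional to its mass (left:right =
    s:1 under the package's curvature convention), then a half-normal draw
    with that side's standard deviation (left 1/sqrt(k_alpha), right
    1/(s*sqrt(k_alpha))) is reflected onto the side.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    P = config.n_transcripts
    s = config.s
    left = rng.random(P) < s / (1.0 + s)
    sigma_left = 1.0 / math.sqrt(config.k_alpha)
    sigma_right = sigma_left / s
    mags = np.abs(rng.standard_normal(P))
    return np.where(left, config.x0 - mags * sigma_left,
                    config.x0 + mags * sigma_right)


def simulate_profile_matrix(config: SimulationConfig) -> Tuple[ProfileMatrix, dict]:
    """Simulate a coherent-state profile matrix and its ground truth.

    Row p is ``amplitude_p * exp(-K(x)(x - b_p)^2 / 2)`` evaluated on the
    grid with per-transcript curvature k_beta and shared asymmetry s, times
    elementwise multiplicative log-normal noise, plus an additive floor.
    """
    rng = np.random.default_rng(config.seed)
    peaks = sample_peaks(config, rng)
    amps = rng.lognormal(config.amplitude_mu_log, config.amplitude_sigma_log,
                         config.n_transcripts)
    x = config.grid.positions
    u = x[None, :] - peaks[:, None]
    kk = np.where(u <= 0, config.k_beta, config.k_beta * config.s**2)
    clean = amps[:, None] * np.exp(-kk * u**2 / 2.0)
    if config.noise_sigma > 0:
        noise = rng.lognormal(0.0, config.noise_sigma, clean.shape)
    else:
        noise = 1.0
    values = clean * noise + config.noise_floor
    ids = tuple(f"G{p:05d}" for p in range(config.n_transcripts))
    matrix = ProfileMatrix(values=values, row_ids=ids, grid=config.grid)
    truth = {"peaks": peaks, "amplitudes": amps,
             "x0": config.x0, "k_alpha": config.k_alpha,
             "k_beta": config.k_beta, "s": config.s}
    return matrix, truth


def _lognormal_params(mean: float, var: float) -> Tuple[float, float]:
    """(mu, sigma) of a log-normal with the requested mean and variance."""
    if mean <= 0 or var < 0:
        raise ValueError("need positive mean and nonnegative variance")
    sigma2 = math.log(1.0 + var / mean**2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def simulate_annotated_lengths(N: int,
                               term_specs: Sequence[Tuple[str, int, float]],
                               base_mean: float = 2480.0,
                               base_var: float = 1.0e6,
                               seed: int = 0) -> Tuple[LengthTable, dict]:
    """Length table with planted annotation subsets of shifted mean length.

    ``term_specs`` is a list of (term, M, shift_nt); each term's M members
    (disjoint across terms) are drawn log-normal with mean base_mean + shift
    and the background variance.  The defaults echo a human-scale global set
    (mean 2,480 nt).  Returns the table and the realized per-term deltas.
    """
    total_planted = sum(m for _, m, _ in term_specs)
    if total_planted >= N:
        raise ValueError("planted subsets exceed the table size")
    for term, M, shift in term_specs:
        if base_mean + shift <= 0:
            raise ValueError(f"term {term!r} implies non-positive lengths")
    rng = np.random.default_rng(seed)
    ids = [f"G{i:05d}" for i in range(N)]
    lengths = np.empty(N)
    mu0, s0 = _lognormal_params(base_mean, base_var)
    lengths[:] = rng.lognormal(mu0, s0, N)
    annotation_sets: Dict[str, Set[str]] = {}
    cursor = 0
    truth = {}
    for term, M, shift in term_specs:
        mu, sg = _lognormal_params(base_mean + shift, base_var)
        members = ids[cursor:cursor + M]
        lengths[cursor:cursor + M] = rng.lognormal(mu, sg, M)
        annotation_sets[term] = set(members)
        truth[term] = {"planted_shift": shift, "M": M}
        cursor += M
    table = LengthTable(entity_ids=ids, lengths=lengths,
                        annotation_sets=annotation_sets)
    for term in annotation_sets:
        realized = (table.lengths_of(annotation_sets[term]).mean()
                    - lengths.mean())
        truth[term]["realized_delta"] = float(realized)
    return table, truth


def simulate_expression(n_entities: int,
                        samples: Mapping[str, int],
                        planted: Mapping[str, Set[str]],
                        X: int,
                        seed: int = 0,
                        planted_fraction: float = 0.5) -> ExpressionMatrix:
    """Expression matrix whose top-X overexpression calls are known exactly.

    Each condition's planted entities are staggered round-robin across that
    condition's samples so that every planted entity occupies top-X ranks in
    exactly ``max(2, ceil(planted_fraction * n_samples))`` distinct samples
    (and ranks below X elsewhere); planted sets larger than X are feasible
    as long as the per-sample load fits.  The remaining top-X slots rotate
    round-robin through the non-planted pool so that no decoy can reach the
    20% flagging threshold; ``annotate_overexpressed`` then recovers exactly
    the planted flags.
    """
    ids = [f"G{i:05d}" for i in range(n_entities)]
    id_set = set(ids)
    for cond, ents in planted.items():
        if not set(ents) <= id_set:
            raise ValueError(f"planted set for {cond!r} has unknown entities")
    f = Fraction(1, 5)  # the annotation threshold the guarantee targets
    n_pool = n_entities - len(set().union(*planted.values()) if planted else set())
    if n_pool < X:
        raise ValueError("need at least X non-planted entities for decoy ranks")
    for cond, n_samp in (samples.items() if planted else ()):
        # decoys rotate round-robin, so within a condition's n_samp * X slots
        # each decoy appears at most ceil(slots / pool) times; that count must
        # stay below the flagging threshold ceil(f * n_samp)
        max_appearances = -(-n_samp * X // n_pool)
        threshold = -(-f.numerator * n_samp // f.denominator)
        if max_appearances >= threshold:
            raise ValueError(
                f"condition {cond!r}: decoy pool too small for cutoff X={X}; "
                "a decoy could cross the 20% flagging threshold and exact "
                "recovery could not be guaranteed")
    rng = np.random.default_rng(seed)
    pos = {g: i for i, g in enumerate(ids)}
    sample_ids, conditions, columns = [], [], []
    planted_all = set().union(*planted.values()) if planted else set()
    pool = [g for g in ids if g not in planted_all]
    pool = list(rng.permutation(pool))
    pool_cursor = 0
    for cond, n_samp in samples.items():
        members = sorted(planted.get(cond, set()))
        n_hot = max(2, math.ceil(planted_fraction * n_samp)) if members else 0
        n_hot = min(n_hot, n_samp)
        # stagger planted members round-robin across samples: each member is
        # top-X in exactly n_hot (consecutive, distinct) samples, so planted
        # sets larger than X are feasible as long as the per-sample load fits
        hot_by_sample = [[] for _ in range(n_samp)]
        t = 0
        for g in members:
            for _ in range(n_hot):
                hot_by_sample[t % n_samp].append(g)
                t += 1
        max_load = max((len(h) for h in hot_by_sample), default=0)
        if max_load > X:
            raise ValueError(
                f"condition {cond!r}: planted load {max_load} exceeds the "
                f"top-{X} capacity of a sample")
        for j in range(n_samp):
            hot = hot_by_sample[j]
            n_decoy = X - len(hot)
            decoys = []
            for _ in range(n_decoy):
                decoys.append(pool[pool_cursor % len(pool)])
                pool_cursor += 1
            top = list(hot) + decoys
            top_set = set(top)
            rest = [g for g in ids if g not in top_set]
            rest = list(rng.permutation(rest))
            ranking = top + rest  # rank 0 = most expressed
            values = np.empty(n_entities)
            idx = np.fromiter((pos[g] for g in ranking), dtype=int,
                              count=n_entities)
            values[idx] = n_entities - np.arange(n_entities, dtype=float)
            columns.append(values)
            sample_ids.append(f"{cond}_{j:03d}")
            conditions.append(cond)
    return ExpressionMatrix(values=np.column_stack(columns),
                            entity_ids=tuple(ids),
                            sample_ids=tuple(sample_ids),
                            conditions=tuple(conditions))
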