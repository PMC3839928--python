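"""SVD identification of the asymmetric generalized coherent state.

The transcript-profile matrix D (P transcripts x X gel slices) is decomposed
by SVD; the leading right singular vectors are fitted against the series of
asymmetric Hermite functions, the leading eigenvalues (squared singular
values) against a geometric series eta**q, and the overall profile (column
sums) against an asymmetric Gaussian.  Together these identify the data's
length distribution function as an asymmetric generalized coherent state and
read off its equilibrium x0, Hooke magnitude k and asymmetry s.

Determinism: the (k, s) search runs on a fixed logarithmic grid followed by a
Nelder-Mead refinement started from the best grid point, so identical inputs
give identical outputs.  The candidate equilibria are the slice positions
(2 mm resolution, matching the even-mm equilibria that gel data resolve); a
continuous refinement of x0 is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .model import ACSParams, Calibration, GelGrid

__all__ = [
    "ProfileMatrix",
    "EigenSystem",
    "CoherentStateFit",
    "decompose",
    "fit_hermite_series",
    "fit_geometric_series",
    "overall_profile",
    "fit_profile_gaussian",
]

# Fixed (k, s) search grid: 32 log-spaced k in [1e-3, 10] mm^-2,
# 32 log-spaced s in [1/8, 8].
_K_GRID = np.logspace(-3, 1, 32)
_S_GRID = np.logspace(np.log10(1 / 8), np.log10(8), 32)


@dataclass(frozen=True)
class ProfileMatrix:
    """Nonnegative P x X table of transcript abundance across gel slices."""

    values: np.ndarray
    row_ids: tuple
    grid: GelGrid

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.size == 0:
            raise ValueError("profile matrix must be a nonempty 2-D array")
        if np.any(~np.isfinite(vals)):
            raise ValueError("profile matrix contains missing/non-finite values")
        if np.any(vals < 0):
            raise ValueError("profile matrix must be nonnegative")
        if vals.shape[1] != self.grid.n_slices:
            raise ValueError("column count must match the gel grid")
        if len(self.row_ids) != vals.shape[0]:
            raise ValueError("row_ids length must match row count")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "row_ids", tuple(self.row_ids))

    @property
    def n_transcripts(self) -> int:
        return self.values.shape[0]

    @property
    def n_slices(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EigenSystem:
    """SVD of a profile matrix: singular vectors/values, eigenvalue
    fractions and the normalized Shannon entropy."""

    right_vectors: np.ndarray      # X x X, rows of V^T
    left_vectors: np.ndarray       # P x X, columns of U
    singular_values: np.ndarray    # nonincreasing, length X
    eigenvalue_fractions: np.ndarray
    entropy: float
    grid: GelGrid

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.singular_values**2


def decompose(D: ProfileMatrix) -> EigenSystem:
    """SVD of the profile matrix D = U Sigma V^T.

    The right singular vectors (rows of V^T) are the eigenvectors of D^T D
    with eigenvalues lambda_q = eps_q**2; the eigenvalue fractions
    p_q = lambda_q / sum(lambda) measure the information captured by each
    eigenvector, and the normalized Shannon entropy
    d = -(1/ln X) * sum p_q ln p_q measures the data's complexity
    (0 = rank one, 1 = all fractions equal).
    """
    U, sv, Vt = np.linalg.svd(D.values, full_matrices=False)
    lam = sv**2
    total = lam.sum()
    if total == 0:
        raise ValueError("all-zero profile matrix")
    frac = lam / total
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(frac > 0, frac * np.log(frac), 0.0)
    entropy = float(-plogp.sum() / np.log(D.n_slices))
    return EigenSystem(
        right_vectors=Vt,
        left_vectors=U,
        singular_values=sv,
        eigenvalue_fractions=frac,
        entropy=entropy,
        grid=D.grid,
    )


@dataclass
class CoherentStateFit:
    """Result of fitting leading eigenvectors to the asymmetric Hermite series."""

    params: ACSParams
    per_order_correlations: np.ndarray
    mean_correlation: float
    n_orders: int
    signs: np.ndarray
    eigenvalue_series_correlation: Optional[float] = None
    equilibrium_length_nt: Optional[float] = None
    equilibrium_length_uncertainty_nt: Optional[float] = None


def _hermite_design(x: np.ndarray, x0: float, k: np.ndarray, s: np.ndarray,
                    Q: int) -> np.ndarray:
    """Evaluate psi_q for q=0..Q-1 on x for every (k, s) pair.

    k, s are broadcastable arrays; returns shape (*k_s_shape, Q, len(x)).
    """
    from scipy.special import eval_hermite

    u = x - x0  # (X,)
    kk = np.where(u <= 0, k[..., None], (k * s**2)[..., None])  # (..., X)
    arg = np.sqrt(kk) * u
    env = np.exp(-(arg**2) / 2.0)
    out = np.empty(kk.shape[:-1] + (Q, x.size))
    for q in range(Q):
        out[..., q, :] = eval_hermite(q, arg) * env
    return out


def _pearson_last_axis(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation along the last axis, broadcasting leading axes."""
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    num = (a * b).sum(axis=-1)
    den = np.sqrt((a**2).sum(axis=-1) * (b**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    return r


def _mean_abs_corr(vectors: np.ndarray, x: np.ndarray, x0: float,
                   k: np.ndarray, s: np.ndarray, Q: int) -> np.ndarray:
    """Mean over q of |corr(eigenvector q+1, psi_q)| for each (k, s)."""
    psi = _hermite_design(x, x0, k, s, Q)        # (..., Q, X)
    v = vectors[:Q]                               # (Q, X)
    r = _pearson_last_axis(psi, v)                # (..., Q)
    return np.abs(r).mean(axis=-1)


def fit_hermite_series(eig: EigenSystem, grid: Optional[GelGrid] = None,
                       Q: int = 5, continuous_x0: bool = False,
                       calibration: Optional[Calibration] = None) -> CoherentStateFit:
    """Fit the Q leading eigenvectors with the asymmetric Hermite series.

    A single shared (x0, k, s) is sought that maximizes the mean absolute
    Pearson correlation between the (q+1)-th right singular vector and the
    q-th asymmetric Hermite function, q = 0..Q-1.  Eigenvector signs are
    aligned to the basis afterwards (SVD fixes singular vectors only up to
    sign).  x0 is restricted to the slice positions unless
    ``continuous_x0=True``, in which case a golden-section refinement within
    one slice of the best grid point is applied.
    """
    grid = grid or eig.grid
    x = grid.positions
    if Q < 2:
        raise ValueError("need at least Q = 2 orders")
    if Q > eig.right_vectors.shape[0]:
        raise ValueError("Q exceeds the number of eigenvectors")
    V = eig.right_vectors
    if np.any(np.ptp(V[:Q], axis=1) == 0):
        raise ValueError("degenerate (constant) eigenvector; correlation undefined")

    kk, ss = np.meshgrid(_K_GRID, _S_GRID, indexing="ij")
    # s candidates ordered by closeness to 1 for the tie-break
    best = (-np.inf, None)  # (score, (x0, k, s))
    s_order = np.argsort(np.abs(np.log(_S_GRID)), kind="stable")
    for x0 in x:  # ascending: earlier x0 wins ties
        scores = _mean_abs_corr(V, x, float(x0), kk, ss, Q)  # (nk, ns)
        for ik in range(_K_GRID.size):          # ascending k wins ties
            row = scores[ik]
            for is_ in s_order:                  # s closest to 1 wins ties
                sc = row[is_]
                if np.isfinite(sc) and sc > best[0]:
                    best = (sc, (float(x0), float(_K_GRID[ik]), float(_S_GRID[is_])))
    if best[1] is None:
        raise ValueError("fit failed: no finite correlation")
    x0_best, k_best, s_best = best[1]

    def neg_score_ks(log_ks, x0_val):
        k_, s_ = np.exp(log_ks)
        return -_mean_abs_corr(V, x, x0_val, np.array(k_), np.array(s_), Q)

    res = minimize(neg_score_ks, np.log([k_best, s_best]), args=(x0_best,),
                   method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 400})
    k_ref, s_ref = np.exp(res.x)
    if -res.fun >= best[0]:
        k_best, s_best = float(k_ref), float(s_ref)

    if continuous_x0:
        from scipy.optimize import minimize_scalar
        w = grid.slice_width

        def neg_score_x0(x0_val):
            return -float(_mean_abs_corr(V, x, float(x0_val),
                                         np.array(k_best), np.array(s_best), Q))

        r = minimize_scalar(neg_score_x0, bounds=(x0_best - w, x0_best + w),
                            method="bounded", options={"xatol": 1e-4})
        if -r.fun > best[0]:
            x0_best = float(r.x)

    params = ACSParams(x0=x0_best, k=k_best, s=s_best)
    psi = _hermite_design(x, x0_best, np.array(k_best), np.array(s_best), Q)
    r = _pearson_last_axis(psi, V[:Q])
    signs = np.sign(r)
    signs[signs == 0] = 1.0
    fit = CoherentStateFit(
        params=params,
        per_order_correlations=np.abs(r),
        mean_correlation=float(np.abs(r).mean()),
        n_orders=Q,
        signs=signs,
    )
    if calibration is not None:
        fit.equilibrium_length_nt = float(calibration.migration_to_length(x0_best))
        fit.equilibrium_length_uncertainty_nt = calibration.length_uncertainty(
            x0_best, grid.slice_width / 2.0)
    return fit


def fit_geometric_series(eig: EigenSystem, Q: int = 5) -> tuple:
    """Fit the Q leading eigenvalues with a geometric series c * eta**q.

    eta is exp(slope) of the least-squares regression of ln(lambda_q) on q;
    the returned correlation is the Pearson correlation between lambda_q and
    the fitted series.
    """
    lam = eig.eigenvalues[:Q]
    if Q < 2:
        raise ValueError("need at least Q = 2 eigenvalues")
    if np.any(lam <= 0):
        raise ValueError("zero eigenvalue within the fitted range")
    q = np.arange(Q, dtype=float)
    slope, intercept = np.polyfit(q, np.log(lam), 1)
    eta = float(np.exp(slope))
    fitted = np.exp(intercept) * eta**q
    r = float(np.corrcoef(lam, fitted)[0, 1])
    return eta, r


def overall_profile(D: ProfileMatrix) -> np.ndarray:
    """The overall transcript profile: the sum of the individual profiles
    (column sums of D)."""
    return D.values.sum(axis=0)


def fit_profile_gaussian(profile: np.ndarray, grid: GelGrid,
                         shared_s: Optional[float] = None,
                         center: Optional[float] = None) -> tuple:
    """Least-squares fit of ``amplitude * asymmetric_gaussian`` to a profile.

    The centre is scanned over the slice positions unless fixed; (k, s) use
    the fixed logarithmic grid plus Nelder-Mead refinement (s fixed if
    ``shared_s`` is given).  Returns ``(params, correlation)`` where
    ``params.amplitude`` carries the least-squares amplitude and the
    correlation is Pearson's r between profile and fit.
    """
    y = np.asarray(profile, dtype=float)
    x = grid.positions
    if y.shape != x.shape:
        raise ValueError("profile length must match the grid")
    if np.any(y < 0):
        raise ValueError("profile must be nonnegative")
    if not np.any(y > 0):
        raise ValueError("all-zero profile")

    centers = [float(center)] if center is not None else [float(c) for c in x]
    s_cands = np.array([shared_s]) if shared_s is not None else _S_GRID
    s_order = np.argsort(np.abs(np.log(s_cands)), kind="stable")

    def sse_for(c, k_, s_):
        u = x - c
        kk = np.where(u <= 0, k_, k_ * s_**2)
        g = np.exp(-kk * u**2 / 2.0)
        gg = float(g @ g)
        amp = float(g @ y) / gg if gg > 0 else 0.0
        amp = max(amp, 0.0)
        resid = y - amp * g
        return float(resid @ resid), amp, g

    best = (np.inf, None)
    for c in centers:
        for k_ in _K_GRID:
            for is_ in s_order:
                s_ = float(s_cands[is_])
                sse, amp, _ = sse_for(c, k_, s_)
                if sse < best[0]:
                    best = (sse, (c, float(k_), s_, amp))
    c_best, k_best, s_best, amp_best = best[1]

    if shared_s is None:
        def neg(log_ks):
            k_, s_ = np.exp(log_ks)
            return sse_for(c_best, k_, s_)[0]
        x0_init = np.log([k_best, s_best])
    else:
        def neg(log_k):
            return sse_for(c_best, float(np.exp(log_k[0])), s_best)[0]
        x0_init = np.log([k_best])
    res = minimize(neg, x0_init, method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-12, "maxiter": 400})
    if res.fun <= best[0]:
        if shared_s is None:
            k_best, s_best = (float(v) for v in np.exp(res.x))
        else:
            k_best = float(np.exp(res.x[0]))
    sse, amp_best, g = sse_for(c_best, k_best, s_best)
    corr = float(np.corrcoef(y, amp_best * g)[0, 1]) if np.ptp(g) > 0 else np.nan
    params = ACSParams(x0=c_best, k=k_best, s=s_best, amplitude=amp_best)
    return params, corr
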