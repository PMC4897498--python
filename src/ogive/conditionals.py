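"""Exact samplers for the three full conditional distributions.

With the augmented variables Z in place, one Gibbs sweep of the 2PNO model
draws, in order,

1. ``Z_ij | .  ~  N(alpha_j theta_i - beta_j, 1)`` truncated to (0, inf)
   where y_ij = 1 and to (-inf, 0) where y_ij = 0;
2. ``theta_i | .  ~  N(mean_i, v)`` with, in "as-printed" mode,
   ``mean_i = sum_j (z_ij + beta_j) alpha_j / sum_j alpha_j^2`` and
   ``v = 1 / sum_j alpha_j^2``, or, in "conjugate" mode, the same sums with
   the prior precision of theta ~ N(0, 1) added to the denominator
   (``1 + sum_j alpha_j^2``);
3. ``xi_j = (alpha_j, beta_j)' | .  ~  N((x'x)^{-1} x' Z_j, (x'x)^{-1})``
   restricted to ``alpha_j > 0``, with design ``x = [theta, -1]``.

The two theta modes exist because the unit-information update (mode
"as-printed") omits the prior-precision term that the standard-normal trait
prior implies; "conjugate" includes it.  Both are exposed so users can
choose fidelity to the classical update or full conjugacy; see
docs/methods.md.

Truncated-normal draws use a one-uniform-per-variate inverse-CDF transform.
Moderate truncations go through ndtr/ndtri in linear probability space; far
tails (standardized bound beyond 5) switch to a log-space route via
``log_ndtr``/``ndtri_exp`` which keeps full relative accuracy where the
interval mass underflows linearly.  One uniform per draw keeps the draw
count predictable, which the block-decomposed runner relies on for its
serial-equivalence guarantee.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtr, ndtri, ndtri_exp

from .exceptions import DegenerateDesignError, TailMassError, TruncationStallError
from .model import AugmentedMatrix, ItemParameters, ResponseMatrix, TraitVector

__all__ = [
    "ThetaPosteriorParams",
    "ItemPosteriorParams",
    "sample_truncated_normal",
    "update_Z",
    "theta_posterior_params",
    "sample_theta",
    "compute_xtx",
    "update_items",
]

_TAIL_SWITCH = 5.0
_TINY = np.finfo(np.float64).tiny

PRIOR_MODES = ("as-printed", "conjugate")


@dataclass
class ThetaPosteriorParams:
    """Full-conditional mean vector and (shared) variance for the traits."""

    mean: np.ndarray
    variance: float

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=np.float64))
        self.variance = float(self.variance)
        if not self.variance > 0:
            raise ValueError(f"theta conditional variance must be positive, got {self.variance}")


@dataclass
class ItemPosteriorParams:
    """Bivariate normal parameters of one item's (slope, intercept) conditional."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64).reshape(2)
        self.covariance = np.asarray(self.covariance, dtype=np.float64).reshape(2, 2)
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.covariance).min() <= 0:
            raise ValueError("covariance must be positive definite")


def _trunc_std_lower(u: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Quantile transform of u in [0,1) to N(0,1) truncated to (a, inf).

    Uses the survival identity  sf(t) = (1 - u) * sf(a):  monotone in u and
    exact at the endpoints.  Vectorized; ``a`` may be -inf.
    """
    u, a = np.broadcast_arrays(np.asarray(u, float), np.asarray(a, float))
    out = np.empty(u.shape, dtype=np.float64)

    far = a > _TAIL_SWITCH
    if far.any():
        # log sf(t) = log(1-u) + log sf(a); ndtri_exp inverts Phi on the log scale
        out[far] = -ndtri_exp(np.log1p(-u[far]) + log_ndtr(-a[far]))
    near = ~far
    if near.any():
        an = a[near]
        un = u[near]
        qa = ndtr(-an)  # sf(a), not tiny here
        p = ndtr(an) + un * qa  # cdf of the draw
        q = (1.0 - un) * qa     # sf of the draw
        # evaluate on whichever side of the median keeps ndtri accurate
        out[near] = np.where(
            p <= 0.5, ndtri(np.maximum(p, _TINY)), -ndtri(np.maximum(q, _TINY))
        )
    return out


def _trunc_std_two_sided(u: np.ndarray, a: float, b: float) -> np.ndarray:
    """Quantile transform to N(0,1) truncated to a finite interval (a, b)."""
    if a >= 0:  # interval in the upper tail: work on the survival scale
        qa, qb = ndtr(-a), ndtr(-b)
        mass = qa - qb
        if not mass > 0:
            raise TailMassError(
                f"truncation interval ({a}, {b}) carries no representable mass"
            )
        return -ndtri(qa - u * mass)
    if b <= 0:  # mirror of the above
        return -_trunc_std_two_sided(u, -b, -a)
    pa, pb = ndtr(a), ndtr(b)
    mass = pb - pa
    if not mass > 0:
        raise TailMassError(
            f"truncation interval ({a}, {b}) carries no representable mass"
        )
    return ndtri(pa + u * mass)


def sample_truncated_normal(mu, lower, upper, rng: np.random.Generator, size=None):
    """Draw from N(mu, 1) restricted to the open interval (lower, upper).

    ``lower`` may be -inf and ``upper`` +inf.  Draws lie strictly inside the
    interval; a draw that rounds onto a finite bound is nudged one ulp
    inward, which is the measure-zero analogue of rejecting it.
    """
    mu = float(mu)
    lower = float(lower)
    upper = float(upper)
    if not math.isfinite(mu):
        raise ValueError("mu must be finite")
    if not lower < upper:
        raise ValueError(f"need lower < upper, got ({lower}, {upper})")

    u = rng.random(size if size is not None else ())
    a = lower - mu
    b = upper - mu
    if b == math.inf:
        t = _trunc_std_lower(u, a)
    elif a == -math.inf:
        # z < upper  <=>  -z > -upper, drawn from the mirrored lower-truncation
        t = -_trunc_std_lower(u, -b)
    else:
        t = _trunc_std_two_sided(np.asarray(u, float), a, b)
    draw = mu + t
    lo = np.nextafter(lower, np.inf) if math.isfinite(lower) else lower
    hi = np.nextafter(upper, -np.inf) if math.isfinite(upper) else upper
    draw = np.clip(draw, lo, hi)
    if size is None:
        return float(draw)
    return draw


def z_cells_from_uniforms(yv: np.ndarray, mu: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Elementwise augmented-data transform shared by the serial and blocked runners.

    For y = 1 the draw is N(mu,1) on (0, inf); for y = 0 it is the mirrored
    draw on (-inf, 0).  Purely elementwise, so any partition of the matrix
    yields bitwise-identical cells given identical uniforms.
    """
    a = np.where(yv == 1, -mu, mu)
    t = _trunc_std_lower(u, a)
    z = np.where(yv == 1, mu + t, mu - t)
    # keep draws strictly off the truncation boundary at 0
    return np.where(yv == 1, np.maximum(z, _TINY), np.minimum(z, -_TINY))


def update_Z(
    y: ResponseMatrix,
    theta: TraitVector,
    params: ItemParameters,
    rng: np.random.Generator,
) -> AugmentedMatrix:
    """Gibbs step 1: redraw the augmented matrix Z given traits and items.

    Cells are drawn row-major from a single uniform matrix, the package's
    canonical draw order.
    """
    if theta.n != y.n or params.k != y.k:
        raise ValueError(
            f"dimension mismatch: y is {y.n}x{y.k}, theta has {theta.n}, "
            f"items have {params.k}"
        )
    mu = np.outer(theta.theta, params.alpha) - params.beta
    u = rng.random(mu.shape)
    return AugmentedMatrix(z_cells_from_uniforms(y.values, mu, u))


def theta_posterior_params(
    z: AugmentedMatrix, params: ItemParameters, prior_mode: str = "as-printed"
) -> ThetaPosteriorParams:
    """Full-conditional mean and variance of the traits given Z and items."""
    if prior_mode not in PRIOR_MODES:
        raise ValueError(f"prior_mode must be one of {PRIOR_MODES}, got {prior_mode!r}")
    if z.z.shape[1] != params.k:
        raise ValueError("z and item parameters disagree on the item count")
    numerator = ((z.z + params.beta) * params.alpha).sum(axis=1)
    ssa = float(np.sum(params.alpha**2))
    if ssa <= 0:
        raise ValueError("sum of squared slopes must be positive")
    denom = ssa if prior_mode == "as-printed" else 1.0 + ssa
    return ThetaPosteriorParams(mean=numerator / denom, variance=1.0 / denom)


def sample_theta(post: ThetaPosteriorParams, rng: np.random.Generator) -> TraitVector:
    """Gibbs step 2: independent normal trait draws, ascending person index."""
    eps = rng.standard_normal(post.mean.size)
    return TraitVector(post.mean + math.sqrt(post.variance) * eps)


def compute_xtx(theta: TraitVector):
    """The 2x2 cross-product x'x for the design x = [theta, -1], and its inverse.

    Returns ``(xtx, xtx_inv)``.  Raises :class:`DegenerateDesignError` when
    all traits coincide (rank-1 design).
    """
    t = theta.theta
    n = t.size
    if n < 2:
        raise DegenerateDesignError("need at least 2 persons to form x'x")
    if np.ptp(t) == 0.0:
        raise DegenerateDesignError(
            "all person traits are identical: x = [theta, -1] is rank deficient"
        )
    s1 = float(np.sum(t))
    s2 = float(np.sum(t * t))
    xtx = np.array([[s2, -s1], [-s1, float(n)]])
    det = s2 * n - s1 * s1
    if det <= 0:
        raise DegenerateDesignError(
            f"x'x is numerically singular (determinant {det:.3e})"
        )
    inv = np.array([[float(n), s1], [s1, s2]]) / det
    return xtx, inv


def sample_item_pair(
    rng: np.random.Generator,
    mean: np.ndarray,
    chol: np.ndarray,
    max_rejects: int,
    item: int = 0,
):
    """One (slope, intercept) draw from N(mean, chol chol') restricted to slope > 0.

    The bivariate proposal is redrawn jointly until the slope coordinate is
    positive, matching the indicator form of the truncation.
    """
    for _ in range(max_rejects):
        xi = mean + chol @ rng.standard_normal(2)
        if xi[0] > 0:
            return xi
    sd = math.sqrt(chol[0, 0] ** 2 + chol[0, 1] ** 2)
    raise TruncationStallError(
        item=item, max_rejects=max_rejects, acceptance_estimate=float(ndtr(mean[0] / sd))
    )


def update_items(
    z: AugmentedMatrix,
    theta: TraitVector,
    rng: np.random.Generator,
    max_rejects: int = 10_000,
) -> ItemParameters:
    """Gibbs step 3: redraw all item pairs, ascending item index.

    Each item j is drawn independently from
    N((x'x)^{-1} x' Z_j, (x'x)^{-1}) I(alpha_j > 0).
    """
    if z.z.shape[0] != theta.n:
        raise ValueError("z and theta disagree on the person count")
    _, inv = compute_xtx(theta)
    chol = np.linalg.cholesky(inv)
    t = theta.theta
    k = z.z.shape[1]
    alpha = np.empty(k)
    beta = np.empty(k)
    for j in range(k):
        zj = z.z[:, j]
        xtz = np.array([float(np.sum(t * zj)), -float(np.sum(zj))])
        mean = inv @ xtz
        xi = sample_item_pair(rng, mean, chol, max_rejects, item=j)
        alpha[j] = xi[0]
        beta[j] = xi[1]
    return ItemParameters(alpha=alpha, beta=beta)


def item_posterior_params(z_col: np.ndarray, theta: TraitVector) -> ItemPosteriorParams:
    """Untruncated bivariate-normal parameters of one item's conditional."""
    _, inv = compute_xtx(theta)
    t = theta.theta
    xtz = np.array([float(np.sum(t * z_col)), -float(np.sum(z_col))])
    return ItemPosteriorParams(mean=inv @ xtz, covariance=inv)
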