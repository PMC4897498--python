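"""Core types and the two-parameter normal ogive (2PNO) response function.

The 2PNO model describes a binary response of person ``i`` to item ``j``
through a probit link:

    P(y_ij = 1) = Phi(alpha_j * theta_i - beta_j),

where ``Phi`` is the standard normal CDF, ``alpha_j > 0`` is the item slope
(discrimination), ``beta_j`` the item intercept, and ``theta_i`` the
person's latent trait on a standard-normal scale.  The trait value
``theta = beta_j / alpha_j`` is the item's difficulty point, where the
response probability crosses one half.

Orientation is fixed package-wide: persons index rows, items index columns.

``Phi`` is evaluated through :func:`scipy.special.ndtr`, a complementary-
error-function route that stays inside (0, 1) for linear predictors out to
roughly +/-37, beyond which double precision itself gives exact 0/1.  The
augmentation step downstream relies on those finite tail masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import ndtr

__all__ = [
    "ResponseMatrix",
    "ItemParameters",
    "TraitVector",
    "AugmentedMatrix",
    "response_probability",
    "item_response_curve",
]


def _finite_or_raise(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")


@dataclass
class ResponseMatrix:
    """An ``n x k`` binary observation matrix: 1 = correct, 0 = incorrect."""

    values: np.ndarray
    person_ids: Sequence[str] | None = None
    item_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError(f"response matrix must be 2-D, got shape {v.shape}")
        if v.size == 0:
            raise ValueError("response matrix is empty")
        if not np.isin(v, (0, 1)).all():
            bad = np.argwhere(~np.isin(v, (0, 1)))[0]
            raise ValueError(
                f"response matrix entries must be 0 or 1; "
                f"offending entry at row {bad[0] + 1}, column {bad[1] + 1}"
            )
        self.values = v.astype(np.int8)
        n, k = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 persons, got {n}")
        if k < 1:
            raise ValueError(f"need at least 1 item, got {k}")
        if self.person_ids is not None and len(self.person_ids) != n:
            raise ValueError(
                f"person_ids has length {len(self.person_ids)}, expected {n}"
            )
        if self.item_ids is not None and len(self.item_ids) != k:
            raise ValueError(
                f"item_ids has length {len(self.item_ids)}, expected {k}"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class ItemParameters:
    """Per-item slopes ``alpha > 0`` and intercepts ``beta`` (the xi pairs)."""

    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=np.float64))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=np.float64))
        if self.alpha.shape != self.beta.shape or self.alpha.ndim != 1:
            raise ValueError(
                f"alpha and beta must be equal-length vectors, got shapes "
                f"{self.alpha.shape} and {self.beta.shape}"
            )
        _finite_or_raise("alpha", self.alpha)
        _finite_or_raise("beta", self.beta)
        if np.any(self.alpha <= 0):
            j = int(np.argmax(self.alpha <= 0))
            raise ValueError(f"item slopes must be positive; alpha[{j}] = {self.alpha[j]}")

    @property
    def k(self) -> int:
        return self.alpha.size


@dataclass
class TraitVector:
    """Per-person latent traits on a standard-normal scale."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=np.float64))
        if self.theta.ndim != 1:
            raise ValueError("theta must be a vector")
        _finite_or_raise("theta", self.theta)

    @property
    def n(self) -> int:
        return self.theta.size


@dataclass
class AugmentedMatrix:
    """The ``n x k`` continuous augmented variables Z.

    Z_ij is positive where y_ij = 1 and negative where y_ij = 0; an exact
    zero has probability zero under the model and is rejected.
    """

    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.float64)
        if self.z.ndim != 2:
            raise ValueError("z must be 2-D")
        _finite_or_raise("z", self.z)
        if np.any(self.z == 0.0):
            raise ValueError("augmented variables must be nonzero")

    def check_signs(self, y: ResponseMatrix) -> None:
        """Raise unless sign(z) agrees with y everywhere."""
        if self.z.shape != y.values.shape:
            raise ValueError(
                f"z has shape {self.z.shape}, response matrix {y.values.shape}"
            )
        ok = np.where(y.values == 1, self.z > 0, self.z < 0)
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"z sign disagrees with y at row {bad[0] + 1}, column {bad[1] + 1}"
            )


def response_probability(alpha, beta, theta):
    """2PNO response probability ``Phi(alpha * theta - beta)``.

    Accepts scalars or broadcastable arrays; returns a float for scalar
    input.  Strictly increasing in ``theta`` for any fixed positive slope.
    """
    alpha = np.asarray(alpha, dtype=np.float64)
    beta = np.asarray(beta, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    for name, arr in (("alpha", alpha), ("beta", beta), ("theta", theta)):
        _finite_or_raise(name, arr)
    if np.any(alpha <= 0):
        raise ValueError("item slope alpha must be positive")
    p = ndtr(alpha * theta - beta)
    if p.ndim == 0:
        return float(p)
    return p


def item_response_curve(params: ItemParameters, item_index: int, theta_grid) -> np.ndarray:
    """Response probabilities of one item over a grid of trait values.

    Monotone nondecreasing along an increasing grid, since the slope is
    positive by the :class:`ItemParameters` invariant.
    """
    if not 0 <= item_index < params.k:
        raise IndexError(
            f"item_index {item_index} out of range for {params.k} items"
        )
    grid = np.asarray(theta_grid, dtype=np.float64)
    _finite_or_raise("theta_grid", grid)
    return np.asarray(
        response_probability(params.alpha[item_index], params.beta[item_index], grid)
    )
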