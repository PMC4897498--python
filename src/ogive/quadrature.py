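"""Brute-force posterior moments for tiny 2PNO instances by dense-grid quadrature.

For a handful of persons the joint posterior

    p(alpha, beta, theta | y)  ∝  prod_i phi(theta_i)
        * prod_j I(alpha_j > 0) prod_i Bern(y_ij; Phi(alpha_j theta_i - beta_j))

can be integrated numerically on a dense (alpha, beta, theta) product grid,
giving marginal means and variances against which the Gibbs sampler can be
validated.  This module shares no code path with the sampler: it evaluates
the unnormalized density directly and reduces it with tensor contractions.

Only the "conjugate" trait prior (theta ~ N(0,1)) is supported, because the
"as-printed" trait update does not correspond to a single joint density.
The slope/intercept priors are the model's diffuse ones, truncated to the
quadrature box; with so few observations the exact posterior is heavy-
tailed (and, strictly, improper under fully flat item priors), so the box
must be chosen generously and reported with the results.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .model import ResponseMatrix

__all__ = ["QuadratureGrid", "tiny_posterior_moments"]


@dataclass(frozen=True)
class QuadratureGrid:
    """Midpoint product grid for (alpha, beta, theta).

    Defaults cover slopes on (0, 10], intercepts on [-10, 10] and traits on
    [-5, 5]; step sizes cancel in normalized moments so only the node
    placement matters.
    """

    alpha: np.ndarray
    beta: np.ndarray
    theta: np.ndarray

    @classmethod
    def default(
        cls,
        alpha_max: float = 10.0,
        beta_max: float = 10.0,
        theta_max: float = 5.0,
        n_alpha: int = 100,
        n_beta: int = 100,
        n_theta: int = 41,
    ) -> "QuadratureGrid":
        da = alpha_max / n_alpha
        alpha = np.linspace(da / 2, alpha_max - da / 2, n_alpha)
        db = 2 * beta_max / n_beta
        beta = np.linspace(-beta_max + db / 2, beta_max - db / 2, n_beta)
        theta = np.linspace(-theta_max, theta_max, n_theta)
        return cls(alpha=alpha, beta=beta, theta=theta)


def tiny_posterior_moments(y: ResponseMatrix, grid: QuadratureGrid | None = None) -> dict:
    """Marginal posterior means and variances for every parameter.

    Returns a dict keyed by ``("alpha", j)``, ``("beta", j)`` and
    ``("theta", i)`` (0-based indices), each mapping to ``(mean, variance)``.
    Practical only for very small n (the theta grid is raised to the n-th
    tensor power); refuses n > 4.
    """
    n, k = y.n, y.k
    if n > 4:
        raise ValueError(f"dense-grid quadrature supports at most 4 persons, got {n}")
    if grid is None:
        grid = QuadratureGrid.default()
    a, b, t = grid.alpha, grid.beta, grid.theta
    na, nb, nt = a.size, b.size, t.size

    # P[ia, ib, it] = Phi(alpha_ia * theta_it - beta_ib), shared by all cells
    P = ndtr(a[:, None, None] * t[None, None, :] - b[None, :, None])
    Q = 1.0 - P

    letters = string.ascii_lowercase[8 : 8 + n]  # person axes i, j, k, l
    spec = ",".join(f"AB{c}" for c in letters) + "->" + "".join(letters)
    wspec = "AB," + ",".join(f"AB{c}" for c in letters) + "->" + "".join(letters)

    def person_factors(j: int) -> list[np.ndarray]:
        return [P if y.values[i, j] == 1 else Q for i in range(n)]

    # per-item contractions over the (alpha, beta) axes
    ones = np.ones((na, nb))
    m = []  # marginal item evidence over the theta grid
    item_w = {}  # alpha/beta-weighted versions for item moments
    wa = a[:, None] * ones
    wa2 = (a**2)[:, None] * ones
    wb = b[None, :] * ones
    wb2 = (b**2)[None, :] * ones
    for j in range(k):
        fac = person_factors(j)
        m.append(np.einsum(spec, *fac, optimize=True))
        item_w[j] = {
            "alpha": np.einsum(wspec, wa, *fac, optimize=True),
            "alpha2": np.einsum(wspec, wa2, *fac, optimize=True),
            "beta": np.einsum(wspec, wb, *fac, optimize=True),
            "beta2": np.einsum(wspec, wb2, *fac, optimize=True),
        }

    # standard-normal trait prior over the theta grid
    phi = np.exp(-0.5 * t**2)
    prior = phi
    for _ in range(n - 1):
        prior = np.multiply.outer(prior, phi)

    base = prior
    for j in range(k):
        base = base * m[j]
    norm = base.sum()
    if not norm > 0:
        raise ValueError("posterior mass underflowed on the quadrature grid")

    moments: dict = {}
    axes = tuple(range(n))
    for i in range(n):
        other = tuple(ax for ax in axes if ax != i)
        marg = base.sum(axis=other)
        w = marg / marg.sum()
        mean = float(np.sum(w * t))
        var = float(np.sum(w * (t - mean) ** 2))
        moments[("theta", i)] = (mean, var)
    for j in range(k):
        # swap item j's evidence for its weighted counterpart
        rest = base / m[j]
        for name in ("alpha", "beta"):
            e1 = float((rest * item_w[j][name]).sum() / norm)
            e2 = float((rest * item_w[j][name + "2"]).sum() / norm)
            moments[(name, j)] = (e1, e2 - e1**2)
    return moments
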