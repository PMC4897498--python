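"""Synthetic 2PNO response generator with known ground truth.

Responses are drawn from the generative model itself: traits
``theta_i ~ N(0, 1)``, slopes and intercepts from user-specified laws, and
``y_ij ~ Bernoulli(Phi(alpha_j theta_i - beta_j))`` independently.  The
default slope law U(0.3, 1.3) brackets the range seen in published CBASE
item calibrations (roughly 0.29-0.72) while allowing steeper items; the
default intercept law is standard normal.  The truth is always returned
(and written) alongside the data so recovery studies never re-derive it.

A useful closed-form check: under theta ~ N(0,1) the marginal proportion
correct of item j is ``Phi(-beta_j / sqrt(1 + alpha_j^2))`` (probit-normal
identity), which the tests use as the generator's oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .model import ItemParameters, ResponseMatrix, TraitVector

__all__ = [
    "GeneratorSpec",
    "simulate_responses",
    "condition_grid",
    "write_dataset",
    "marginal_proportion_correct",
]

# distribution specs are ("uniform", lo, hi), ("normal", mean, sd) or
# ("fixed", values); slope laws must have strictly positive support
DEFAULT_ALPHA_LAW = ("uniform", 0.3, 1.3)
DEFAULT_BETA_LAW = ("normal", 0.0, 1.0)


def _validate_law(law, positive: bool, name: str) -> None:
    kind = law[0]
    if kind == "uniform":
        lo, hi = float(law[1]), float(law[2])
        if not lo < hi:
            raise ValueError(f"{name}: uniform bounds must satisfy lo < hi")
        if positive and lo <= 0:
            raise ValueError(f"{name}: support must be strictly positive, got lo={lo}")
    elif kind == "normal":
        if positive:
            raise ValueError(f"{name}: a normal law has support on all reals; "
                             "slopes need a strictly positive law")
        if float(law[2]) < 0:
            raise ValueError(f"{name}: sd must be non-negative")
    elif kind == "fixed":
        vals = np.asarray(law[1], dtype=np.float64)
        if positive and np.any(vals <= 0):
            raise ValueError(f"{name}: fixed values must be strictly positive")
    else:
        raise ValueError(f"{name}: unknown law kind {kind!r}")


def _draw_law(law, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = law[0]
    if kind == "uniform":
        return rng.uniform(float(law[1]), float(law[2]), size)
    if kind == "normal":
        return float(law[1]) + float(law[2]) * rng.standard_normal(size)
    vals = np.asarray(law[1], dtype=np.float64)
    if vals.size == 1:
        return np.full(size, vals.item())
    if vals.size != size:
        raise ValueError(f"fixed law supplies {vals.size} values for size {size}")
    return vals.copy()


@dataclass
class GeneratorSpec:
    """Sizes, parameter laws and seed for one synthetic data set."""

    n: int
    k: int
    alpha_law: tuple = DEFAULT_ALPHA_LAW
    beta_law: tuple = DEFAULT_BETA_LAW
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2 or self.k < 1:
            raise ValueError(f"need n >= 2 and k >= 1, got n={self.n}, k={self.k}")
        _validate_law(self.alpha_law, positive=True, name="alpha_law")
        _validate_law(self.beta_law, positive=False, name="beta_law")


def simulate_responses(spec: GeneratorSpec):
    """Draw (ResponseMatrix, ItemParameters, TraitVector) from the 2PNO model.

    Draw order is fixed (slopes, intercepts, traits, responses) so a seed
    pins the entire data set.
    """
    rng = np.random.default_rng(spec.seed)
    alpha = _draw_law(spec.alpha_law, spec.k, rng)
    beta = _draw_law(spec.beta_law, spec.k, rng)
    theta = rng.standard_normal(spec.n)
    p = ndtr(np.outer(theta, alpha) - beta)
    yv = (rng.random((spec.n, spec.k)) < p).astype(np.int8)
    return (
        ResponseMatrix(yv),
        ItemParameters(alpha=alpha, beta=beta),
        TraitVector(theta),
    )


def marginal_proportion_correct(alpha, beta) -> np.ndarray:
    """Closed-form item proportion correct under theta ~ N(0,1)."""
    alpha = np.asarray(alpha, dtype=np.float64)
    beta = np.asarray(beta, dtype=np.float64)
    return ndtr(-beta / np.sqrt(1.0 + alpha**2))


def condition_grid(n_list, k_list, base_seed: int | None = None) -> list[GeneratorSpec]:
    """Fully crossed person-by-item condition grid, row-major by n then k.

    Duplicates are preserved.  With ``base_seed`` given, each cell receives
    a distinct derived seed.
    """
    n_list = list(n_list)
    k_list = list(k_list)
    if not n_list or not k_list:
        raise ValueError("condition lists must be non-empty")
    specs = []
    for idx_n, n in enumerate(n_list):
        for idx_k, k in enumerate(k_list):
            seed = None
            if base_seed is not None:
                seed = base_seed + idx_n * len(k_list) + idx_k
            specs.append(GeneratorSpec(n=n, k=k, seed=seed))
    return specs


def write_dataset(directory, y: ResponseMatrix, items: ItemParameters, theta: TraitVector):
    """Write the response matrix plus truth sidecars as CSV.

    Files: ``responses.csv`` (n x k, no header), ``items_truth.csv``
    (alpha, beta) and ``persons_truth.csv`` (theta).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(y.values).to_csv(directory / "responses.csv", header=False, index=False)
    pd.DataFrame({"alpha": items.alpha, "beta": items.beta}).to_csv(
        directory / "items_truth.csv", index=False
    )
    pd.DataFrame({"theta": theta.theta}).to_csv(
        directory / "persons_truth.csv", index=False
    )
    return directory
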