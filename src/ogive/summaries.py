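"""Posterior summarization: means, Monte Carlo standard errors, difficulty
ratios, item-response-curve tables and a trait-density table.

The Monte Carlo standard error (MCSE) of a posterior mean is estimated by
non-overlapping batch means with ``floor(sqrt(M))`` batches, which is robust
to the autocorrelation of Gibbs draws without extra dependencies.  The
per-item difficulty ratio ``beta_hat / alpha_hat`` is the trait value at
which the estimated response curve crosses one half; it is carried at full
precision and rounded (4 decimals, half-even) only at report time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .model import ItemParameters, item_response_curve
from .sampler import ChainSamples

__all__ = [
    "PosteriorSummary",
    "posterior_means",
    "posterior_summary",
    "mcse",
    "difficulty_ratio",
    "trait_density_table",
    "item_table",
    "person_table",
    "curve_table",
    "REPORT_DECIMALS",
]

REPORT_DECIMALS = 4


@dataclass
class PosteriorSummary:
    """Per-item and per-person posterior means with their MCSEs."""

    alpha_hat: np.ndarray
    alpha_mcse: np.ndarray
    beta_hat: np.ndarray
    beta_mcse: np.ndarray
    difficulty_ratio: np.ndarray
    theta_hat: np.ndarray
    theta_mcse: np.ndarray
    kept: int

    def __post_init__(self) -> None:
        if np.any(self.alpha_hat <= 0):
            raise ValueError("posterior mean slopes must be positive")
        for name in ("alpha_mcse", "beta_mcse", "theta_mcse"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")


def mcse(draws) -> float:
    """Batch-means Monte Carlo standard error of the mean of ``draws``.

    Uses ``b = floor(sqrt(M))`` equal batches (trailing remainder dropped):
    ``SE = SD(batch means) / sqrt(b)``.
    """
    x = np.asarray(draws, dtype=np.float64).ravel()
    m = x.size
    if m < 4:
        raise ValueError(f"need at least 4 draws for a batch-means MCSE, got {m}")
    b = int(math.isqrt(m))
    size = m // b
    means = x[: b * size].reshape(b, size).mean(axis=1)
    return float(means.std(ddof=1) / math.sqrt(b))


def difficulty_ratio(alpha_hat, beta_hat):
    """The difficulty point ``beta_hat / alpha_hat`` at full precision."""
    alpha_hat = np.asarray(alpha_hat, dtype=np.float64)
    beta_hat = np.asarray(beta_hat, dtype=np.float64)
    if np.any(alpha_hat <= 0):
        raise ValueError("difficulty ratio requires a positive slope estimate")
    r = beta_hat / alpha_hat
    return float(r) if r.ndim == 0 else r


def posterior_summary(samples: ChainSamples) -> PosteriorSummary:
    """Posterior means, batch-means MCSEs, and difficulty ratios from kept draws."""
    if not samples.usable:
        raise ValueError("samples are flagged unusable (aborted chain)")
    if samples.kept < 2:
        raise ValueError(f"need at least 2 kept draws, got {samples.kept}")
    alpha_hat = samples.alpha_draws.mean(axis=0)
    beta_hat = samples.beta_draws.mean(axis=0)
    theta_hat = samples.theta_draws.mean(axis=0)
    if samples.kept >= 4:
        alpha_mcse = np.array([mcse(samples.alpha_draws[:, j]) for j in range(samples.k)])
        beta_mcse = np.array([mcse(samples.beta_draws[:, j]) for j in range(samples.k)])
        theta_mcse = np.array([mcse(samples.theta_draws[:, i]) for i in range(samples.n)])
    else:
        alpha_mcse = np.full(samples.k, np.nan)
        beta_mcse = np.full(samples.k, np.nan)
        theta_mcse = np.full(samples.n, np.nan)
    return PosteriorSummary(
        alpha_hat=alpha_hat,
        alpha_mcse=alpha_mcse,
        beta_hat=beta_hat,
        beta_mcse=beta_mcse,
        difficulty_ratio=difficulty_ratio(alpha_hat, beta_hat),
        theta_hat=theta_hat,
        theta_mcse=theta_mcse,
        kept=samples.kept,
    )


# alias matching the operation name: fills the means (and, when possible, MCSEs)
posterior_means = posterior_summary


def item_table(summary: PosteriorSummary, rounded: bool = False) -> pd.DataFrame:
    """Tidy one-row-per-item summary (slope, intercept, MCSEs, ratio)."""
    df = pd.DataFrame(
        {
            "item": np.arange(1, summary.alpha_hat.size + 1),
            "alpha_hat": summary.alpha_hat,
            "alpha_mcse": summary.alpha_mcse,
            "beta_hat": summary.beta_hat,
            "beta_mcse": summary.beta_mcse,
            "ratio": summary.difficulty_ratio,
        }
    )
    if rounded:
        num = df.columns.drop("item")
        df[num] = df[num].round(REPORT_DECIMALS)  # numpy round: half-even
    return df


def person_table(summary: PosteriorSummary) -> pd.DataFrame:
    """Tidy one-row-per-person trait summary."""
    return pd.DataFrame(
        {
            "person": np.arange(1, summary.theta_hat.size + 1),
            "theta_hat": summary.theta_hat,
            "theta_mcse": summary.theta_mcse,
        }
    )


def curve_table(params: ItemParameters, theta_grid=None) -> pd.DataFrame:
    """Item response curves P(correct | theta) for every item over a grid."""
    if theta_grid is None:
        theta_grid = np.linspace(-4.0, 4.0, 161)
    grid = np.asarray(theta_grid, dtype=np.float64)
    data = {"theta": grid}
    for j in range(params.k):
        data[f"item{j + 1}"] = item_response_curve(params, j, grid)
    return pd.DataFrame(data)


def trait_density_table(theta_hat, grid=None) -> pd.DataFrame:
    """Gaussian-kernel density estimate of the posterior trait means.

    Silverman bandwidth; the default grid spans the mean +/- 4 SD, wide
    enough that the trapezoid integral of the table is 1 to within 1e-3.
    """
    x = np.asarray(theta_hat, dtype=np.float64).ravel()
    if x.size < 10:
        raise ValueError(f"need at least 10 persons for a density estimate, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("trait estimates are all identical: density is degenerate")
    if grid is None:
        grid = np.linspace(x.mean() - 4 * sd, x.mean() + 4 * sd, 513)
    grid = np.asarray(grid, dtype=np.float64)
    kde = gaussian_kde(x, bw_method="silverman")
    return pd.DataFrame({"theta": grid, "density": kde(grid)})
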