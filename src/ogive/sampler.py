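"""The Gibbs chain runner and its block-decomposed execution scheme.

One iteration applies the three conditional updates in fixed order —
augmented data Z, then traits theta, then item pairs (alpha, beta) — each
conditioning on the freshest values.  Early iterations are discarded as
burn-in and the remainder (optionally thinned) is returned as
:class:`ChainSamples`.

Block decomposition
-------------------
The response matrix can be partitioned over an ``r x c`` grid of blocks:
the Z update runs independently per block, the trait update per row block,
and the item update per column block.  Two stream modes are offered:

* ``"serial-equivalent"``: all blocks consume a single random stream in the
  canonical draw order (Z cells row-major, traits ascending person index,
  items ascending item index), and reductions use the canonical single-pass
  routine.  Output is bitwise identical to the serial runner for every grid
  shape — the mode exists to prove the decomposition touches every cell in
  exactly the serial order.
* ``"per-block"``: each (kernel, block) pair owns an independent stream
  seeded from the chain seed and the block coordinates, and cross-block
  sums are accumulated as per-block partials reduced in ascending block
  index (deterministic despite floating-point non-associativity).  Output
  is a different but equally valid chain; blocks may execute concurrently
  under this contract.

The backend is an execution contract, not a technology: the sequential
loop over blocks implemented here conforms, and so would a thread pool or
an accelerator, provided streams and reduction order are respected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import conditionals as cond
from .exceptions import ChainAborted
from .model import AugmentedMatrix, ItemParameters, ResponseMatrix, TraitVector

__all__ = [
    "BlockGrid",
    "ChainConfig",
    "ChainState",
    "ChainSamples",
    "initialize_state",
    "gibbs_step",
    "run_chain",
    "run_chain_blocked",
    "reduce_block_sums",
]

logger = logging.getLogger(__name__)

STREAM_MODES = ("serial-equivalent", "per-block")
INIT_POLICIES = ("sum-scores", "zeros")

# kernel tags used when deriving per-block stream seeds
_KERNEL_Z, _KERNEL_THETA, _KERNEL_ITEMS = 0, 1, 2


@dataclass(frozen=True)
class BlockGrid:
    """Contiguous r x c partition of an n x k matrix.

    ``row_bounds``/``col_bounds`` are cumulative split indices including the
    endpoints, e.g. ``(0, 3, 6, 10)`` partitions 10 rows into blocks of
    sizes 3, 3, 4.  When the dimension is divisible by the block count all
    blocks are equal; otherwise the trailing block absorbs the remainder
    (no padding, which would bias sums).
    """

    row_bounds: tuple[int, ...]
    col_bounds: tuple[int, ...]

    def __post_init__(self) -> None:
        for name, bounds in (("row_bounds", self.row_bounds), ("col_bounds", self.col_bounds)):
            if len(bounds) < 2 or bounds[0] != 0:
                raise ValueError(f"{name} must start at 0 and contain at least one block")
            if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
                raise ValueError(f"{name} must be strictly increasing: {bounds}")

    @classmethod
    def from_shape(cls, r: int, c: int, n: int, k: int) -> "BlockGrid":
        if not (1 <= r <= n and 1 <= c <= k):
            raise ValueError(f"grid {r}x{c} does not fit a {n}x{k} matrix")

        def bounds(count: int, size: int) -> tuple[int, ...]:
            base = size // count
            cuts = [i * base for i in range(count)] + [size]
            return tuple(cuts)

        return cls(row_bounds=bounds(r, n), col_bounds=bounds(c, k))

    @property
    def r(self) -> int:
        return len(self.row_bounds) - 1

    @property
    def c(self) -> int:
        return len(self.col_bounds) - 1

    def row_slices(self) -> list[slice]:
        return [slice(a, b) for a, b in zip(self.row_bounds, self.row_bounds[1:])]

    def col_slices(self) -> list[slice]:
        return [slice(a, b) for a, b in zip(self.col_bounds, self.col_bounds[1:])]

    def validate_for(self, n: int, k: int) -> None:
        if self.row_bounds[-1] != n or self.col_bounds[-1] != k:
            raise ValueError(
                f"grid covers {self.row_bounds[-1]}x{self.col_bounds[-1]}, "
                f"matrix is {n}x{k}"
            )


@dataclass
class ChainConfig:
    """Configuration of one Gibbs chain."""

    iterations: int
    burn_in: int = 0
    seed: int = 0
    prior_mode: str = "as-printed"
    grid: BlockGrid | None = None
    stream_mode: str = "serial-equivalent"
    init: str = "sum-scores"
    thin: int = 1
    max_rejects: int = 10_000
    progress_every: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be positive")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError(
                f"need 0 <= burn_in < iterations, got {self.burn_in} / {self.iterations}"
            )
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_mode not in cond.PRIOR_MODES:
            raise ValueError(f"prior_mode must be one of {cond.PRIOR_MODES}")
        if self.stream_mode not in STREAM_MODES:
            raise ValueError(f"stream_mode must be one of {STREAM_MODES}")
        if self.init not in INIT_POLICIES:
            raise ValueError(f"init must be one of {INIT_POLICIES}")

    @property
    def kept(self) -> int:
        return (self.iterations - self.burn_in) // self.thin

    def to_dict(self) -> dict:
        d = {
            "iterations": self.iterations,
            "burn_in": self.burn_in,
            "seed": self.seed,
            "prior_mode": self.prior_mode,
            "stream_mode": self.stream_mode,
            "init": self.init,
            "thin": self.thin,
            "max_rejects": self.max_rejects,
        }
        if self.grid is not None:
            d["grid"] = {
                "row_bounds": list(self.grid.row_bounds),
                "col_bounds": list(self.grid.col_bounds),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ChainConfig":
        d = dict(d)
        grid = d.pop("grid", None)
        if grid is not None:
            grid = BlockGrid(tuple(grid["row_bounds"]), tuple(grid["col_bounds"]))
        return cls(grid=grid, **d)


@dataclass
class ChainState:
    """One Gibbs state (Z, theta, xi) at iteration ``iteration``.

    ``z`` is None before the first sweep: the initial augmented matrix is
    implied by the first Z update.
    """

    z: AugmentedMatrix | None
    theta: TraitVector
    items: ItemParameters
    iteration: int = 0


@dataclass
class ChainSamples:
    """Post-burn-in (thinned) draws of all model parameters."""

    theta_draws: np.ndarray  # (kept, n)
    alpha_draws: np.ndarray  # (kept, k)
    beta_draws: np.ndarray  # (kept, k)
    config: dict = field(default_factory=dict)
    usable: bool = True

    @property
    def kept(self) -> int:
        return self.theta_draws.shape[0]

    @property
    def n(self) -> int:
        return self.theta_draws.shape[1]

    @property
    def k(self) -> int:
        return self.alpha_draws.shape[1]

    def equals(self, other: "ChainSamples") -> bool:
        """Bitwise equality of all stored draws."""
        return (
            self.theta_draws.shape == other.theta_draws.shape
            and self.alpha_draws.shape == other.alpha_draws.shape
            and np.array_equal(self.theta_draws, other.theta_draws)
            and np.array_equal(self.alpha_draws, other.alpha_draws)
            and np.array_equal(self.beta_draws, other.beta_draws)
        )


def reduce_block_sums(partials) -> float:
    """Combine per-block partial sums in ascending block index.

    A fixed left-to-right reduction order makes blocked results
    run-to-run deterministic despite floating-point non-associativity.
    """
    acc = 0.0
    for p in partials:
        acc += float(p)
    return acc


def initialize_state(y: ResponseMatrix, config: ChainConfig) -> ChainState:
    """Starting values: standardized sum scores for theta, unit slopes, zero intercepts.

    Sum scores are the classical-test-theory trait estimate, so they start
    the chain in the right ordering; all-equal scores fall back to zeros.
    The "zeros" policy starts every trait at zero instead.
    """
    if config.init == "sum-scores":
        scores = y.values.sum(axis=1).astype(np.float64)
        sd = scores.std(ddof=1)
        theta0 = np.zeros(y.n) if sd == 0 else (scores - scores.mean()) / sd
    else:
        theta0 = np.zeros(y.n)
    items0 = ItemParameters(alpha=np.ones(y.k), beta=np.zeros(y.k))
    return ChainState(z=None, theta=TraitVector(theta0), items=items0, iteration=0)


def gibbs_step(
    state: ChainState,
    y: ResponseMatrix,
    config: ChainConfig,
    rng: np.random.Generator,
) -> ChainState:
    """One serial three-step transition: Z, then theta, then items."""
    z = cond.update_Z(y, state.theta, state.items, rng)
    post = cond.theta_posterior_params(z, state.items, config.prior_mode)
    theta = cond.sample_theta(post, rng)
    items = cond.update_items(z, theta, rng, config.max_rejects)
    return ChainState(z=z, theta=theta, items=items, iteration=state.iteration + 1)


def _record_loop(y, config, step):
    """Shared bookkeeping: run ``step`` L times, discard burn-in, thin."""
    state = initialize_state(y, config)
    kept = config.kept
    theta_draws = np.empty((kept, y.n))
    alpha_draws = np.empty((kept, y.k))
    beta_draws = np.empty((kept, y.k))
    stored = 0
    try:
        for _ in range(config.iterations):
            state = step(state)
            past = state.iteration - config.burn_in
            if past > 0 and past % config.thin == 0:
                theta_draws[stored] = state.theta.theta
                alpha_draws[stored] = state.items.alpha
                beta_draws[stored] = state.items.beta
                stored += 1
            if config.progress_every and state.iteration % config.progress_every == 0:
                logger.info(
                    "iteration %d/%d (%d draws kept)",
                    state.iteration,
                    config.iterations,
                    stored,
                )
    except Exception as exc:
        partial = ChainSamples(
            theta_draws[:stored],
            alpha_draws[:stored],
            beta_draws[:stored],
            config=config.to_dict(),
            usable=False,
        )
        raise ChainAborted(
            f"chain aborted at iteration {state.iteration + 1}: {exc}", partial=partial
        ) from exc
    assert stored == kept
    return ChainSamples(
        theta_draws, alpha_draws, beta_draws, config=config.to_dict(), usable=True
    )


def run_chain(y: ResponseMatrix, config: ChainConfig) -> ChainSamples:
    """Run the Gibbs sampler serially (or blocked, if the config carries a grid)."""
    if config.grid is not None:
        return run_chain_blocked(y, config)
    rng = np.random.default_rng(config.seed)
    return _record_loop(y, config, lambda s: gibbs_step(s, y, config, rng))


# ---------------------------------------------------------------------------
# blocked execution


def _block_stream(seed: int, kernel: int, block_row: int, block_col: int) -> np.random.Generator:
    """Independent stream for one (kernel, block) pair, derived from the chain seed."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(kernel, block_row, block_col))
    return np.random.Generator(np.random.PCG64(ss))


class _BlockedKernel:
    """Per-iteration blocked sweep over an r x c grid.

    Holds the per-block streams (created once, advanced across iterations,
    mirroring persistent per-kernel random states) and dispatches between
    the two stream modes.
    """

    def __init__(self, y: ResponseMatrix, config: ChainConfig):
        grid = config.grid
        grid.validate_for(y.n, y.k)
        self.y = y
        self.config = config
        self.grid = grid
        self.rows = grid.row_slices()
        self.cols = grid.col_slices()
        self.serial_equivalent = config.stream_mode == "serial-equivalent"
        if self.serial_equivalent:
            self.rng = np.random.default_rng(config.seed)
        else:
            s = config.seed
            self.z_streams = {
                (bi, bj): _block_stream(s, _KERNEL_Z, bi, bj)
                for bi in range(grid.r)
                for bj in range(grid.c)
            }
            self.theta_streams = [
                _block_stream(s, _KERNEL_THETA, bi, 0) for bi in range(grid.r)
            ]
            self.item_streams = [
                _block_stream(s, _KERNEL_ITEMS, 0, bj) for bj in range(grid.c)
            ]

    # -- step 1: Z ---------------------------------------------------------
    def _update_z(self, theta: TraitVector, items: ItemParameters) -> AugmentedMatrix:
        yv = self.y.values
        mu = np.outer(theta.theta, items.alpha) - items.beta
        z = np.empty(yv.shape)
        if self.serial_equivalent:
            # one row-major uniform matrix = the canonical serial draw order
            u = self.rng.random(yv.shape)
            for rs in self.rows:
                for cs in self.cols:
                    z[rs, cs] = cond.z_cells_from_uniforms(yv[rs, cs], mu[rs, cs], u[rs, cs])
        else:
            for bi, rs in enumerate(self.rows):
                for bj, cs in enumerate(self.cols):
                    u = self.z_streams[(bi, bj)].random(
                        (rs.stop - rs.start, cs.stop - cs.start)
                    )
                    z[rs, cs] = cond.z_cells_from_uniforms(yv[rs, cs], mu[rs, cs], u)
        return AugmentedMatrix(z)

    # -- step 2: theta ------------------------------------------------------
    def _update_theta(self, z: AugmentedMatrix, items: ItemParameters) -> TraitVector:
        n = self.y.n
        alpha, beta = items.alpha, items.beta
        if self.serial_equivalent:
            post = cond.theta_posterior_params(z, items, self.config.prior_mode)
            mean, var = post.mean, post.variance
            sd = math.sqrt(var)
            eps = self.rng.standard_normal(n)
            theta = np.empty(n)
            for rs in self.rows:  # per-row-block assembly, same values as serial
                theta[rs] = mean[rs] + sd * eps[rs]
            return TraitVector(theta)
        # per-block mode: column-block partials reduced in ascending order
        ssa = reduce_block_sums(np.sum(alpha[cs] ** 2) for cs in self.cols)
        denom = ssa if self.config.prior_mode == "as-printed" else 1.0 + ssa
        sd = math.sqrt(1.0 / denom)
        theta = np.empty(n)
        for bi, rs in enumerate(self.rows):
            num = np.zeros(rs.stop - rs.start)
            for cs in self.cols:
                num += ((z.z[rs, cs] + beta[cs]) * alpha[cs]).sum(axis=1)
            mean = num / denom
            theta[rs] = mean + sd * self.theta_streams[bi].standard_normal(mean.size)
        return TraitVector(theta)

    # -- step 3: items ------------------------------------------------------
    def _update_items(self, z: AugmentedMatrix, theta: TraitVector) -> ItemParameters:
        k = self.y.k
        alpha = np.empty(k)
        beta = np.empty(k)
        t = theta.theta
        if self.serial_equivalent:
            _, inv = cond.compute_xtx(theta)
            chol = np.linalg.cholesky(inv)
            for cs in self.cols:
                for j in range(cs.start, cs.stop):
                    zj = z.z[:, j]
                    xtz = np.array([float(np.sum(t * zj)), -float(np.sum(zj))])
                    xi = cond.sample_item_pair(
                        self.rng, inv @ xtz, chol, self.config.max_rejects, item=j
                    )
                    alpha[j], beta[j] = xi
            return ItemParameters(alpha, beta)
        # per-block mode: x'x and x'Z_j from row-block partials, ascending order
        s1 = reduce_block_sums(np.sum(t[rs]) for rs in self.rows)
        s2 = reduce_block_sums(np.sum(t[rs] * t[rs]) for rs in self.rows)
        n = float(self.y.n)
        det = s2 * n - s1 * s1
        if det <= 0:
            from .exceptions import DegenerateDesignError

            raise DegenerateDesignError("x'x is singular in blocked item update")
        inv = np.array([[n, s1], [s1, s2]]) / det
        chol = np.linalg.cholesky(inv)
        for bj, cs in enumerate(self.cols):
            stream = self.item_streams[bj]
            for j in range(cs.start, cs.stop):
                zj = z.z[:, j]
                tz = reduce_block_sums(np.sum(t[rs] * zj[rs]) for rs in self.rows)
                sz = reduce_block_sums(np.sum(zj[rs]) for rs in self.rows)
                xtz = np.array([tz, -sz])
                xi = cond.sample_item_pair(
                    stream, inv @ xtz, chol, self.config.max_rejects, item=j
                )
                alpha[j], beta[j] = xi
        return ItemParameters(alpha, beta)

    def step(self, state: ChainState) -> ChainState:
        z = self._update_z(state.theta, state.items)
        theta = self._update_theta(z, state.items)
        items = self._update_items(z, theta)
        return ChainState(z=z, theta=theta, items=items, iteration=state.iteration + 1)


def run_chain_blocked(y: ResponseMatrix, config: ChainConfig) -> ChainSamples:
    """Run the Gibbs sampler under the r x c block-decomposition contract."""
    if config.grid is None:
        raise ValueError("run_chain_blocked requires a BlockGrid in the config")
    kernel = _BlockedKernel(y, config)
    return _record_loop(y, config, kernel.step)
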