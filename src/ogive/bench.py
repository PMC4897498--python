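"""Speedup/efficiency arithmetic and a small wall-clock benchmark harness.

Relative speedup and efficiency of a parallel execution are

    S = T_S / T_P        E = S / P = T_S / (P * T_P),

with ``T_S`` the serial time, ``T_P`` the parallel time and ``P`` the
number of processing units.  ``E`` may exceed 1 when the parallel layout
relieves a memory bottleneck the serial run suffers from.

Wall-clock numbers from :func:`run_benchmark` are hardware-dependent and
reported as such; only the S/E arithmetic carries guarantees.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import pandas as pd

from .model import ResponseMatrix
from .sampler import BlockGrid, ChainConfig, run_chain, run_chain_blocked

__all__ = ["BenchmarkRecord", "speedup", "efficiency", "run_benchmark"]


def speedup(t_serial: float, t_parallel: float) -> float:
    """Relative speedup ``T_S / T_P``."""
    if not (t_serial > 0 and t_parallel > 0):
        raise ValueError("execution times must be positive")
    return t_serial / t_parallel


def efficiency(t_serial: float, t_parallel: float, p: int) -> float:
    """Per-processing-unit efficiency ``T_S / (P * T_P)``."""
    if p < 1:
        raise ValueError("processing-unit count must be >= 1")
    return speedup(t_serial, t_parallel) / p


@dataclass
class BenchmarkRecord:
    """One timed comparison of a serial and a parallel execution."""

    label: str
    t_serial: float
    t_parallel: float
    p: int

    def __post_init__(self) -> None:
        if not (self.t_serial > 0 and self.t_parallel > 0):
            raise ValueError("execution times must be positive")
        if self.p < 1:
            raise ValueError("processing-unit count must be >= 1")

    @property
    def speedup(self) -> float:
        return speedup(self.t_serial, self.t_parallel)

    @property
    def efficiency(self) -> float:
        return efficiency(self.t_serial, self.t_parallel, self.p)


def run_benchmark(
    y: ResponseMatrix,
    iterations: int,
    grid_shapes: list[tuple[int, int]],
    seed: int = 0,
    burn_in: int = 0,
) -> pd.DataFrame:
    """Time the serial runner against blocked runs for each grid shape.

    The blocked runner here executes blocks sequentially, so these numbers
    measure decomposition overhead on this machine, not true parallel
    gains; they are hardware-dependent and excluded from any correctness
    guarantee.  P is taken as r*c, the block count.
    """
    t0 = time.perf_counter()
    run_chain(y, ChainConfig(iterations=iterations, burn_in=burn_in, seed=seed))
    t_serial = time.perf_counter() - t0

    records = []
    for r, c in grid_shapes:
        grid = BlockGrid.from_shape(r, c, y.n, y.k)
        config = ChainConfig(
            iterations=iterations,
            burn_in=burn_in,
            seed=seed,
            grid=grid,
            stream_mode="per-block",
        )
        t0 = time.perf_counter()
        run_chain_blocked(y, config)
        t_parallel = time.perf_counter() - t0
        rec = BenchmarkRecord(
            label=f"{r}x{c}", t_serial=t_serial, t_parallel=t_parallel, p=r * c
        )
        records.append(
            {
                "label": rec.label,
                "t_serial": rec.t_serial,
                "t_parallel": rec.t_parallel,
                "P": rec.p,
                "S": rec.speedup,
                "E": rec.efficiency,
            }
        )
    return pd.DataFrame(records)
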