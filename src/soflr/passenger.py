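"""Passenger-only simulation: isolates needed for the overlap to vanish.

Under the passenger model each of T genes is active in a given isolate
independently with probability p, so the running intersection of active
sets across isolates thins geometrically (expected size T p^n after n
isolates).  The quantity simulated here is the first isolate count at
which that intersection is empty — the point past which any remaining
common genes must be drivers.  The closed-form CDF of that minimum is
P(min n <= k) = (1 - p^k)^T, used as the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PassengerSimConfig",
    "PassengerSimResult",
    "CapReachedError",
    "min_isolates_single_run",
    "min_isolates_single_run_naive",
    "mean_min_isolates",
    "sweep_grid",
    "min_isolates_cdf",
]

DEFAULT_MAX_ISOLATES = 10_000


class CapReachedError(RuntimeError):
    """The running intersection did not empty within max_isolates."""

    def __init__(self, max_isolates: int):
        super().__init__(
            f"passenger overlap still nonempty after {max_isolates} isolates; "
            "raise max_isolates (p may be too close to 1)"
        )
        self.max_isolates = max_isolates


@dataclass(frozen=True)
class PassengerSimConfig:
    """Passenger-set size T, per-isolate activation probability p,
    replicate count (10 in the reference design), isolate cap and seed."""

    T: int
    p: float
    replicates: int = 10
    max_isolates: int = DEFAULT_MAX_ISOLATES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 0:
            raise ValueError("T must be nonnegative")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.max_isolates < 1:
            raise ValueError("max_isolates must be >= 1")


@dataclass(frozen=True)
class PassengerSimResult:
    """Replicate minimum-isolate values with their mean and standard error."""

    mean_min_isolates: float
    se: float
    replicate_values: tuple[int, ...]


def min_isolates_single_run(
    T: int, p: float, max_isolates: int = DEFAULT_MAX_ISOLATES, rng: Optional[np.random.Generator] = None
) -> int:
    """First isolate count (>= 1) at which the running intersection is empty.

    Memory-light thinning: only the size of the running intersection is
    tracked; each surviving gene stays active in the next isolate with
    probability p, so the size after each isolate is Binomial(previous, p)
    — distributionally identical to materializing the full active sets.
    The intersection over a single isolate is that isolate's active set,
    so the base case n = 1 can already be empty.
    """
    if rng is None:
        rng = np.random.default_rng()
    if T == 0:
        return 1
    alive = T
    for n in range(1, max_isolates + 1):
        alive = int(rng.binomial(alive, p))
        if alive == 0:
            return n
    raise CapReachedError(max_isolates)


def min_isolates_single_run_naive(
    T: int, p: float, max_isolates: int = DEFAULT_MAX_ISOLATES, rng: Optional[np.random.Generator] = None
) -> int:
    """Reference implementation materializing full boolean active sets."""
    if rng is None:
        rng = np.random.default_rng()
    if T == 0:
        return 1
    common = np.ones(T, dtype=bool)
    for n in range(1, max_isolates + 1):
        common &= rng.random(T) < p
        if not common.any():
            return n
    raise CapReachedError(max_isolates)


def mean_min_isolates(cfg: PassengerSimConfig) -> PassengerSimResult:
    """Replicated minimum-isolate simulation: mean, SE and raw values."""
    rng = np.random.default_rng(cfg.seed)
    values = tuple(
        min_isolates_single_run(cfg.T, cfg.p, cfg.max_isolates, rng)
        for _ in range(cfg.replicates)
    )
    arr = np.asarray(values, dtype=float)
    se = float(arr.std(ddof=1) / np.sqrt(cfg.replicates)) if cfg.replicates > 1 else 0.0
    return PassengerSimResult(mean_min_isolates=float(arr.mean()), se=se, replicate_values=values)


def sweep_grid(
    T_values: Sequence[int],
    p_values: Sequence[float],
    replicates: int = 10,
    seed: int = 0,
    max_isolates: int = DEFAULT_MAX_ISOLATES,
) -> pd.DataFrame:
    """Full factorial sweep over (T, p); tidy table (T, p, mean, se).

    Every grid cell gets an independent RNG substream spawned from the
    master seed, so cells are individually reproducible regardless of
    grid shape or evaluation order.
    """
    if len(T_values) == 0 or len(p_values) == 0:
        raise ValueError("T_values and p_values must be nonempty")
    master = np.random.SeedSequence(seed)
    streams = master.spawn(len(T_values) * len(p_values))
    rows = []
    i = 0
    for T in T_values:
        for p in p_values:
            cell_seed = int(streams[i].generate_state(1)[0] % (2**31))
            i += 1
            res = mean_min_isolates(
                PassengerSimConfig(
                    T=int(T), p=float(p), replicates=replicates,
                    max_isolates=max_isolates, seed=cell_seed,
                )
            )
            rows.append({"T": int(T), "p": float(p), "mean": res.mean_min_isolates, "se": res.se})
    return pd.DataFrame(rows)


def min_isolates_cdf(T: int, p: float, k) -> np.ndarray:
    """Closed-form P(min isolates <= k) = (1 - p^k)^T.

    Each gene independently survives k consecutive isolates with
    probability p^k; the intersection is empty at k iff no gene survived.
    """
    k = np.asarray(k, dtype=float)
    return (1.0 - p**k) ** T
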