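"""Synthetic data under the driver / passenger / non-responsive model.

Generates activation matrices in which a fixed driver set is active in
every isolate, each passenger gene is active per isolate independently
with probability p, and the remaining probes never respond — the
generative model whose overlap curve has expectation E[y_k] = d + T p^k.
Optionally lifts the calls to a positive intensity matrix so that the
fold-change activation caller can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .activation import (
    ActivationMatrix,
    Direction,
    ExpressionMatrix,
    call_activation,
    mean_overlap_curve,
)
from .regression import SoflrFit, soflr_fit

__all__ = [
    "IntensityParams",
    "SyntheticConfig",
    "SyntheticTruth",
    "RecoveryReport",
    "generate_activation",
    "generate_expression",
    "end_to_end_recovery",
]


@dataclass(frozen=True)
class IntensityParams:
    """Log-normal baseline and fold-change margins for intensity lifting.

    control_mean_log / control_sd_log parameterize the per-probe baseline
    intensity (natural-log scale, arbitrary units); margin is the
    fold-change buffer that keeps every constructed value decisively on
    the intended side of the 2-fold call boundary.
    """

    control_mean_log: float = 6.0
    control_sd_log: float = 1.0
    margin: float = 0.2
    n_control: int = 3
    threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("fold-change margin must be positive")
        if self.n_control < 1:
            raise ValueError("need at least one control sample")
        if self.threshold <= 1:
            raise ValueError("threshold must be > 1")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters of the driver/passenger/non-responsive model."""

    d: int
    T: int
    p: float
    n_nonresponsive: int = 0
    n_isolates: int = 6
    seed: int = 0
    direction: Direction = "induced"
    intensity: Optional[IntensityParams] = None

    def __post_init__(self) -> None:
        if min(self.d, self.T, self.n_nonresponsive) < 0:
            raise ValueError("d, T and n_nonresponsive must be nonnegative")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if self.n_isolates < 1:
            raise ValueError("need at least one isolate")

    @property
    def n_probes(self) -> int:
        return self.d + self.T + self.n_nonresponsive


@dataclass(frozen=True)
class SyntheticTruth:
    """Exact disjoint partition of probe IDs used by the generator."""

    driver_ids: tuple[str, ...]
    passenger_ids: tuple[str, ...]
    nonresponsive_ids: tuple[str, ...]
    config: SyntheticConfig

    def __post_init__(self) -> None:
        all_ids = self.driver_ids + self.passenger_ids + self.nonresponsive_ids
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("truth partition must be disjoint")
        if len(all_ids) != self.config.n_probes:
            raise ValueError("truth partition must cover every probe exactly once")


@dataclass(frozen=True)
class RecoveryReport:
    """Parameter recovery of a fit against the generating truth."""

    config: SyntheticConfig
    fit: SoflrFit
    d_true: int
    d_hat: int
    T_hat: float
    p_hat: float

    @property
    def d_error(self) -> int:
        return self.d_hat - self.d_true

    @property
    def p_error(self) -> float:
        return self.p_hat - self.config.p

    @property
    def T_error(self) -> float:
        return self.T_hat - self.config.T


def generate_activation(cfg: SyntheticConfig) -> tuple[ActivationMatrix, SyntheticTruth]:
    """Draw one activation matrix under the model.

    Drivers are active everywhere, passengers are iid Bernoulli(p) across
    genes and isolates (p = 1 deterministically active), non-responsive
    probes are never active.  Reproducible per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_isolates
    calls = np.zeros((cfg.n_probes, n), dtype=bool)
    calls[: cfg.d, :] = True
    if cfg.T > 0:
        calls[cfg.d : cfg.d + cfg.T, :] = rng.random((cfg.T, n)) < cfg.p
    probe_ids = tuple(
        [f"drv{i:05d}" for i in range(cfg.d)]
        + [f"psg{i:05d}" for i in range(cfg.T)]
        + [f"nrp{i:05d}" for i in range(cfg.n_nonresponsive)]
    )
    isolate_ids = tuple(f"iso{j:02d}" for j in range(1, n + 1))
    act = ActivationMatrix(
        probe_ids=probe_ids, isolate_ids=isolate_ids, calls=calls, direction=cfg.direction
    )
    truth = SyntheticTruth(
        driver_ids=probe_ids[: cfg.d],
        passenger_ids=probe_ids[cfg.d : cfg.d + cfg.T],
        nonresponsive_ids=probe_ids[cfg.d + cfg.T :],
        config=cfg,
    )
    return act, truth


def generate_expression(
    act: ActivationMatrix, truth: SyntheticTruth, cfg: SyntheticConfig
) -> ExpressionMatrix:
    """Lift activation calls to a positive intensity matrix.

    Control samples scatter around a log-normal per-probe baseline; each
    transformed value is the realized control mean times a fold change
    drawn beyond (threshold + margin) where the call is true (below its
    reciprocal in repressed mode) and strictly inside the no-call band
    where false.  By construction ``call_activation`` recovers the input
    calls exactly for any positive margin.
    """
    if cfg.intensity is None:
        raise ValueError("cfg.intensity must be set to generate expression data")
    ip = cfg.intensity
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n_probes, n_iso = act.calls.shape
    baseline = np.exp(rng.normal(ip.control_mean_log, ip.control_sd_log, size=n_probes))
    controls = baseline[:, None] * np.exp(
        rng.normal(0.0, 0.1, size=(n_probes, ip.n_control))
    )
    control_mean = controls.mean(axis=1)

    thr = ip.threshold
    # no-call band, shrunk multiplicatively by the margin on both sides
    lo_false = (1.0 / thr) * (1.0 + ip.margin)
    hi_false = thr / (1.0 + ip.margin)
    u = rng.random(size=act.calls.shape)
    fold_false = lo_false + u * (hi_false - lo_false)
    if act.direction == "induced":
        fold_true = (thr + ip.margin) * (1.0 + rng.random(size=act.calls.shape))
    else:
        fold_true = 1.0 / ((thr + ip.margin) * (1.0 + rng.random(size=act.calls.shape)))
    values = control_mean[:, None] * np.where(act.calls, fold_true, fold_false)

    sample_ids = tuple(f"ctl{j:02d}" for j in range(1, ip.n_control + 1)) + act.isolate_ids
    labels = ("control",) * ip.n_control + ("transformed",) * n_iso
    return ExpressionMatrix(
        probe_ids=act.probe_ids,
        sample_ids=sample_ids,
        values=np.hstack([controls, values]),
        group_labels=labels,
    )


def end_to_end_recovery(cfg: SyntheticConfig) -> RecoveryReport:
    """Generate, summarize and fit: the package's headline self-check.

    Draws an activation matrix under cfg, computes its exact mean overlap
    curve, runs the d grid search and reports the recovered (d, T, p)
    against the generating truth.
    """
    if cfg.n_isolates < 4:
        raise ValueError("end-to-end recovery needs at least 4 isolates")
    act, truth = generate_activation(cfg)
    curve = mean_overlap_curve(act)
    fit = soflr_fit(curve)
    return RecoveryReport(
        config=cfg, fit=fit, d_true=cfg.d, d_hat=fit.d_hat, T_hat=fit.T_hat, p_hat=fit.p_hat
    )
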