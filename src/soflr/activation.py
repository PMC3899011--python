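"""Activation calling and overlap-decay curves.

Converts an expression matrix (probes x samples, positive intensities) into
binary activation calls against the control mean, and summarizes a call
matrix into the mean overlap-decay curve ``y_1..y_n`` that the driver-count
regression consumes: ``y_k`` is the mean size of the k-way intersection of
active probe sets over all size-k subsets of isolates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

logger = logging.getLogger(__name__)

Direction = Literal["induced", "repressed"]

_DIRECTIONS = ("induced", "repressed")


def _check_direction(direction: str) -> str:
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}, got {direction!r}")
    return direction


def _check_unique(ids: Sequence[str], what: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what} must be unique")
    return ids


@dataclass(frozen=True)
class ExpressionMatrix:
    """Positive expression intensities for probes x samples.

    ``group_labels`` marks each sample as ``"control"`` (untransformed
    parental line) or ``"transformed"`` (one independently transformed
    isolate per column in the intended design).
    """

    probe_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    group_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "probe_ids", _check_unique(self.probe_ids, "probe_ids"))
        object.__setattr__(self, "sample_ids", _check_unique(self.sample_ids, "sample_ids"))
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({len(self.probe_ids)} probes, {len(self.sample_ids)} samples)"
            )
        object.__setattr__(self, "values", values)
        labels = tuple(self.group_labels)
        if len(labels) != len(self.sample_ids):
            raise ValueError("one group label per sample is required")
        bad = set(labels) - {"control", "transformed"}
        if bad:
            raise ValueError(f"group labels must be 'control' or 'transformed', got {sorted(bad)}")
        if "control" not in labels or "transformed" not in labels:
            raise ValueError("need at least one control and one transformed sample")
        object.__setattr__(self, "group_labels", labels)

    @property
    def control_mask(self) -> np.ndarray:
        return np.asarray([g == "control" for g in self.group_labels])

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.probe_ids), columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, groups: dict[str, str]) -> "ExpressionMatrix":
        labels = tuple(groups[str(s)] for s in frame.columns)
        return cls(
            probe_ids=tuple(str(i) for i in frame.index),
            sample_ids=tuple(str(c) for c in frame.columns),
            values=frame.to_numpy(dtype=float),
            group_labels=labels,
        )

    @classmethod
    def from_tsv(cls, path, samples_path) -> "ExpressionMatrix":
        """Read a TSV (first column probe ID, header of sample IDs) plus a
        two-column samples file (sample_id, group)."""
        frame = pd.read_csv(path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep=None, engine="python")
        groups = dict(zip(samples.iloc[:, 0].astype(str), samples.iloc[:, 1].astype(str)))
        return cls.from_frame(frame, groups)

    def to_tsv(self, path) -> None:
        self.to_frame().rename_axis("probe_id").to_csv(path, sep="\t")


@dataclass(frozen=True)
class ActivationMatrix:
    """Boolean activation calls, probes x isolates, for one direction."""

    probe_ids: tuple[str, ...]
    isolate_ids: tuple[str, ...]
    calls: np.ndarray
    direction: Direction = "induced"

    def __post_init__(self) -> None:
        object.__setattr__(self, "probe_ids", _check_unique(self.probe_ids, "probe_ids"))
        object.__setattr__(self, "isolate_ids", _check_unique(self.isolate_ids, "isolate_ids"))
        calls = np.asarray(self.calls, dtype=bool)
        if calls.shape != (len(self.probe_ids), len(self.isolate_ids)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"({len(self.probe_ids)} probes, {len(self.isolate_ids)} isolates)"
            )
        object.__setattr__(self, "calls", calls)
        _check_direction(self.direction)

    @property
    def n_isolates(self) -> int:
        return len(self.isolate_ids)

    def active_set(self, isolate: str) -> frozenset[str]:
        j = self.isolate_ids.index(isolate)
        return frozenset(p for p, on in zip(self.probe_ids, self.calls[:, j]) if on)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls.astype(int), index=list(self.probe_ids), columns=list(self.isolate_ids)
        )

    def to_tsv(self, path) -> None:
        self.to_frame().rename_axis("probe_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, direction: Direction = "induced") -> "ActivationMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            probe_ids=tuple(str(i) for i in frame.index),
            isolate_ids=tuple(str(c) for c in frame.columns),
            calls=frame.to_numpy() != 0,
            direction=direction,
        )


@dataclass(frozen=True)
class OverlapCurve:
    """Mean k-way intersection sizes y_1..y_n for k = 1..n isolates.

    The index k is the regression covariate x; y_k is the mean, over all
    C(n, k) subsets of k isolates, of the number of probes active in every
    isolate of the subset.  y is nonincreasing and y_n is the exact
    full-intersection count when derived from an ActivationMatrix.
    """

    y: np.ndarray
    direction: Direction = "induced"

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        if y.ndim != 1 or y.size < 1:
            raise ValueError("y must be a nonempty 1-D vector")
        if not np.all(np.isfinite(y)) or np.any(y < 0):
            raise ValueError("y must be finite and nonnegative")
        if np.any(np.diff(y) > 1e-9):
            raise ValueError("overlap curve must be nonincreasing in k")
        object.__setattr__(self, "y", y)
        _check_direction(self.direction)

    @property
    def n(self) -> int:
        return int(self.y.size)

    @property
    def x(self) -> np.ndarray:
        return np.arange(1, self.n + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.x, "y": self.y})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, direction: Direction = "induced") -> "OverlapCurve":
        frame = pd.read_csv(path)
        frame = frame.sort_values(frame.columns[0])
        k = frame.iloc[:, 0].to_numpy()
        if not np.array_equal(k, np.arange(1, len(k) + 1)):
            raise ValueError("curve file must contain consecutive k = 1..n")
        return cls(y=frame.iloc[:, 1].to_numpy(dtype=float), direction=direction)


class ActivationCaller(TransformerMixin, BaseEstimator):
    """Fold-change activation caller in scikit-learn transformer form.

    ``fit`` learns the per-probe control mean from control arrays laid out
    as (n_control_samples, n_probes); ``transform`` maps transformed-isolate
    arrays of the same width to boolean calls.  A probe is called induced
    when value / control_mean >= threshold, repressed when <= 1/threshold
    (boundaries inclusive).  Probes whose control mean is nonpositive or
    non-finite are dropped (their count is logged and exposed as
    ``n_dropped_``); MAS5-style intensities are positive, so this is a
    guard rather than a filter.

    Parameters
    ----------
    direction : {"induced", "repressed"}
        Which direction of change to call.
    threshold : float, default 2.0
        Fold-change boundary; must be > 1.
    """

    def __init__(self, direction: Direction = "induced", threshold: float = 2.0):
        self.direction = direction
        self.threshold = threshold

    def fit(self, X, y=None):
        _check_direction(self.direction)
        if not self.threshold > 1.0:
            raise ValueError("threshold must be > 1")
        X = check_array(X, ensure_min_samples=1, ensure_all_finite=False)
        mean = np.nanmean(X, axis=0)
        keep = np.isfinite(mean) & (mean > 0)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropping %d probes with nonpositive or non-finite control mean", n_dropped)
        self.n_features_in_ = X.shape[1]
        self.control_mean_ = mean
        self.retained_mask_ = keep
        self.n_dropped_ = n_dropped
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "control_mean_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of probes than seen in fit")
        fold = X[:, self.retained_mask_] / self.control_mean_[self.retained_mask_]
        if self.direction == "induced":
            return fold >= self.threshold
        return fold <= 1.0 / self.threshold


def call_activation(
    expr: ExpressionMatrix, direction: Direction = "induced", threshold: float = 2.0
) -> ActivationMatrix:
    """Call activation of every probe in every transformed sample.

    The reference is the arithmetic mean of the control-sample intensities
    per probe.  Returns one call column per transformed sample.
    """
    ctrl = expr.control_mask
    caller = ActivationCaller(direction=direction, threshold=threshold)
    caller.fit(expr.values[:, ctrl].T)
    calls = caller.transform(expr.values[:, ~ctrl].T).T
    probe_ids = tuple(p for p, keep in zip(expr.probe_ids, caller.retained_mask_) if keep)
    isolate_ids = tuple(s for s, c in zip(expr.sample_ids, ctrl) if not c)
    return ActivationMatrix(
        probe_ids=probe_ids, isolate_ids=isolate_ids, calls=calls, direction=direction
    )


def per_isolate_counts(act: ActivationMatrix) -> np.ndarray:
    """Number of active probes in each isolate (column sums)."""
    return act.calls.sum(axis=0).astype(int)


def mean_overlap_curve(act: ActivationMatrix) -> OverlapCurve:
    """Exact mean overlap-decay curve of an activation matrix.

    Rather than enumerating the C(n, k) subsets, uses the identity
    ``y_k = sum_g C(m_g, k) / C(n, k)`` where ``m_g`` is the number of
    isolates in which probe g is active: a probe contributes to a size-k
    subset's intersection iff the subset is drawn from its m_g active
    isolates.  The result is exact, never subsampled.
    """
    n = act.n_isolates
    m = act.calls.sum(axis=1)
    counts = np.bincount(m, minlength=n + 1)
    y = np.empty(n, dtype=float)
    for k in range(1, n + 1):
        total = sum(counts[mm] * math.comb(mm, k) for mm in range(k, n + 1))
        y[k - 1] = total / math.comb(n, k)
    return OverlapCurve(y=y, direction=act.direction)


def full_intersection_count(act: ActivationMatrix) -> int:
    """Number of probes active in every isolate (the exact y_n)."""
    return int(act.calls.all(axis=1).sum())
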