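"""Windowed statistical-moment dimensionality reduction.

The filtered m/z rows are partitioned into consecutive windows of a fixed
number of *points* (not Daltons); within each window and for each sample
the mean, variance, skewness and kurtosis of the intensities summarise
that waveform segment.  With all four moments a matrix of m rows becomes
``4 * ceil(m / width)`` feature rows — e.g. 39,905 rows at width 40 give
3,992 features and 24,545 rows at width 50 give 1,964.

Moment conventions (pinned; the whole package and its tests use these):

* mean      = sum(Y) / N
* variance  = sum((Y - mean)^2) / N          (population, N denominator)
* S         = sqrt(variance)
* skewness  = sum((Y - mean)^3) / (N * S^3)
* kurtosis  = sum((Y - mean)^4) / (N * S^4)  (raw, not excess)

A zero-variance window gets skewness = kurtosis = 0 so that constant
segments produce finite features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import UsageError
from .io import RefinedMatrix

__all__ = [
    "MOMENT_NAMES",
    "WindowPlan",
    "MomentFeatures",
    "plan_windows",
    "window_moments",
    "transform",
    "select_width",
]

#: canonical moment order used everywhere
MOMENT_NAMES = ("mean", "variance", "skewness", "kurtosis")


@dataclass
class WindowPlan:
    """Partition of ``m`` row indices into consecutive fixed-width windows.

    ``boundaries`` are half-open ``[start, end)`` index intervals covering
    all rows; every interval has length ``width`` except possibly the last.
    """

    width: int
    boundaries: list[tuple[int, int]]

    @property
    def n_windows(self) -> int:
        return len(self.boundaries)


@dataclass
class MomentFeatures:
    """Stacked per-window moment features, window-major, moment-minor.

    Row ordering: window 0 moment 0, window 0 moment 1, ..., window 1
    moment 0, ...  ``features`` has shape ``(k * n_windows, n_samples)``.
    """

    features: np.ndarray
    moment_names: tuple[str, ...]
    plan: WindowPlan
    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.moment_names)
        expected = k * self.plan.n_windows
        if self.features.shape[0] != expected:
            raise UsageError(
                f"feature row count {self.features.shape[0]} != "
                f"k*W = {k}*{self.plan.n_windows}"
            )

    @property
    def n_features(self) -> int:
        return self.features.shape[0]

    @property
    def feature_names(self) -> list[str]:
        return [
            f"w{w:04d}_{name}"
            for w in range(self.plan.n_windows)
            for name in self.moment_names
        ]


def plan_windows(m: int, width: int) -> WindowPlan:
    """Divide ``m`` rows into ``ceil(m / width)`` consecutive windows.

    The final partial window (length 1..width) is retained.
    """
    if m < 1:
        raise UsageError(f"need at least one row, got m={m}")
    if width < 2:
        raise UsageError(
            f"window width must be >= 2 points (got {width}); moments "
            "beyond the mean are meaningless on single-point windows"
        )
    starts = range(0, m, width)
    boundaries = [(s, min(s + width, m)) for s in starts]
    assert len(boundaries) == math.ceil(m / width)
    return WindowPlan(width=width, boundaries=boundaries)


def window_moments(values: np.ndarray) -> tuple[float, float, float, float]:
    """Mean, variance, skewness and kurtosis of one window's intensities."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise UsageError("window_moments requires a non-empty vector")
    if not np.all(np.isfinite(values)):
        raise UsageError("window_moments requires finite values")
    mean = values.mean()
    dev = values - mean
    variance = np.mean(dev**2)
    if variance == 0.0:
        return float(mean), 0.0, 0.0, 0.0
    s = math.sqrt(variance)
    skewness = np.mean(dev**3) / s**3
    kurtosis = np.mean(dev**4) / s**4
    return float(mean), float(variance), float(skewness), float(kurtosis)


def _normalise_moments(moments: Sequence[str]) -> tuple[str, ...]:
    unknown = [m for m in moments if m not in MOMENT_NAMES]
    if unknown:
        raise UsageError(f"unknown moments {unknown}; choose from {MOMENT_NAMES}")
    ordered = tuple(m for m in MOMENT_NAMES if m in set(moments))
    if not ordered:
        raise UsageError("at least one moment must be selected")
    return ordered


def transform(
    matrix: RefinedMatrix,
    width: int,
    moments: Sequence[str] = MOMENT_NAMES,
) -> MomentFeatures:
    """Apply the windowed moment transform to every sample column.

    Output shape is ``(k * ceil(m / width), n_samples)`` with the
    window-major, moment-minor row ordering of :class:`MomentFeatures`.
    """
    moments = _normalise_moments(moments)
    plan = plan_windows(matrix.n_mz, width)
    X = matrix.intensities
    n = matrix.n_samples
    k = len(moments)
    out = np.empty((k * plan.n_windows, n))
    for w, (start, end) in enumerate(plan.boundaries):
        block = X[start:end]  # (window_len, n)
        mean = block.mean(axis=0)
        dev = block - mean
        variance = np.mean(dev**2, axis=0)
        row: dict[str, np.ndarray] = {"mean": mean, "variance": variance}
        if "skewness" in moments or "kurtosis" in moments:
            s = np.sqrt(variance)
            with np.errstate(divide="ignore", invalid="ignore"):
                skew = np.mean(dev**3, axis=0) / s**3
                kurt = np.mean(dev**4, axis=0) / s**4
            zero = variance == 0.0
            skew[zero] = 0.0
            kurt[zero] = 0.0
            row["skewness"] = skew
            row["kurtosis"] = kurt
        for i, name in enumerate(moments):
            out[w * k + i] = row[name]
    return MomentFeatures(
        features=out,
        moment_names=moments,
        plan=plan,
        sample_ids=list(matrix.sample_ids),
        labels=matrix.labels,
    )


def select_width(
    matrix: RefinedMatrix,
    candidate_widths: Sequence[int],
    evaluate_fn: Callable[[MomentFeatures], tuple[float, float]],
    moments: Sequence[str] = MOMENT_NAMES,
) -> tuple[int, dict[int, tuple[float | None, float | None]]]:
    """Pick the window width maximising mean cross-validated accuracy.

    ``evaluate_fn`` receives the transformed features (labels attached) and
    returns ``(mean_Ac, mean_CC)`` under the caller's validation protocol.
    Ties break toward the smaller width.  A candidate whose evaluation is
    degenerate (raises) is recorded as ``(None, None)`` and skipped.

    Returns the winning width and the full width -> (Ac, CC) table.
    """
    candidates = sorted(set(int(w) for w in candidate_widths))
    if len(candidates) < 1:
        raise UsageError("select_width needs at least one candidate width")
    table: dict[int, tuple[float | None, float | None]] = {}
    best_width, best_ac = None, -np.inf
    for width in candidates:
        try:
            feats = transform(matrix, width, moments)
            ac, cc = evaluate_fn(feats)
        except (UsageError, ValueError):
            table[width] = (None, None)
            continue
        table[width] = (ac, cc)
        if ac > best_ac:  # strict: first (smallest) width wins ties
            best_width, best_ac = width, ac
    if best_width is None:
        raise UsageError("every candidate width failed evaluation")
    return best_width, table
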