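"""Spectrum alignment, refinement and per-m/z t-test filtering.

The preprocessing chain mirrors standard practice for surface-based
TOF profiling matrices:

1. ``align_union`` — place every spectrum on the sorted union of all
   observed m/z values (exact equality defines a shared point; no
   tolerance merging), leaving explicit missing cells;
2. ``refine`` — drop every m/z row with at least one missing cell,
   yielding a complete matrix;
3. ``t_filter`` — keep only rows whose intensities differ between the
   cancer (+1) and non-cancer (-1) classes by a two-sided two-sample
   t-test at significance level ``alpha`` (default 1%), with no
   multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import EmptyOutputError, UsageError
from .io import RawSpectrum, RefinedMatrix, SpectrumSet

__all__ = ["FilterResult", "align_union", "refine", "t_filter"]


@dataclass
class FilterResult:
    """Outcome of the per-row t-test filter.

    ``kept_indices`` indexes rows of the *input* matrix with p < alpha;
    ``p_values`` stores the two-sided p-value of every input row.
    """

    kept_indices: np.ndarray
    p_values: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise UsageError(f"alpha must be in (0, 1), got {self.alpha}")
        self.kept_indices = np.asarray(self.kept_indices, dtype=int)
        self.p_values = np.asarray(self.p_values, dtype=float)


def align_union(spectra: list[RawSpectrum], labels) -> SpectrumSet:
    """Align spectra on the sorted union of their m/z values.

    Cell (i, j) holds sample j's intensity at the i-th union m/z when that
    sample observed it, NaN otherwise.  Two observations share a row only
    when their m/z values are exactly equal.
    """
    if len(spectra) < 2:
        raise UsageError("align_union needs at least 2 spectra")
    labels = np.asarray(labels, dtype=int)
    if labels.size != len(spectra):
        raise UsageError("one label per spectrum required")
    axis = np.unique(np.concatenate([s.mz for s in spectra]))
    mat = np.full((axis.size, len(spectra)), np.nan)
    for j, spec in enumerate(spectra):
        rows = np.searchsorted(axis, spec.mz)
        mat[rows, j] = spec.intensity
    return SpectrumSet(
        mz_axis=axis,
        intensities=mat,
        sample_ids=[s.sample_id for s in spectra],
        labels=labels,
    )


def refine(sset: SpectrumSet) -> RefinedMatrix:
    """Keep exactly the m/z rows observed in every sample.

    Row and sample order are preserved.  Raises ``EmptyOutputError`` with a
    per-row missing-count diagnostic when no row survives.
    """
    missing = sset.missing_mask()
    keep = ~missing.any(axis=1)
    if not keep.any():
        worst = int(missing.sum(axis=1).max())
        best = int(missing.sum(axis=1).min())
        raise EmptyOutputError(
            "no m/z row is complete across all samples "
            f"(missing cells per row range {best}..{worst} of "
            f"{sset.n_samples} samples)"
        )
    return RefinedMatrix(
        mz_axis=sset.mz_axis[keep],
        intensities=sset.intensities[keep],
        sample_ids=list(sset.sample_ids),
        labels=sset.labels,
    )


def t_filter(
    matrix: RefinedMatrix, alpha: float = 0.01, *, equal_var: bool = True
) -> tuple[RefinedMatrix, FilterResult]:
    """Filter m/z rows by a two-sided two-sample t-test between classes.

    The null hypothesis for each row is that cancer (+1) and non-cancer
    (-1) intensities share the same distribution; rows with p < ``alpha``
    are retained in their original order.  ``equal_var=True`` gives the
    classical pooled-variance (Student) test; ``False`` gives Welch.

    Rows with zero variance in both groups carry no class signal when the
    group means coincide; their p-value is defined as 1 and they are
    dropped (a zero-variance row with *different* group means yields
    p = 0 and is kept).
    """
    if not 0.0 < alpha < 1.0:
        raise UsageError(f"alpha must be in (0, 1), got {alpha}")
    y = matrix.labels
    pos = matrix.intensities[:, y == 1]
    neg = matrix.intensities[:, y == -1]
    if pos.shape[1] < 2 or neg.shape[1] < 2:
        raise UsageError(
            "t_filter needs at least 2 samples per class "
            f"(got {pos.shape[1]} cancer, {neg.shape[1]} control)"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(pos, neg, axis=1, equal_var=equal_var)
        pvals = np.asarray(res.pvalue, dtype=float)
    zero_var = (pos.std(axis=1) == 0) & (neg.std(axis=1) == 0)
    same_mean = pos.mean(axis=1) == neg.mean(axis=1)
    pvals[zero_var & same_mean] = 1.0
    pvals[zero_var & ~same_mean] = 0.0
    pvals[np.isnan(pvals)] = 1.0  # any residual degenerate case
    kept = np.flatnonzero(pvals < alpha)
    result = FilterResult(kept_indices=kept, p_values=pvals, alpha=alpha)
    filtered = RefinedMatrix(
        mz_axis=matrix.mz_axis[kept],
        intensities=matrix.intensities[kept],
        sample_ids=list(matrix.sample_ids),
        labels=matrix.labels,
    )
    return filtered, result
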