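"""Robust summaries: bootstrap medians and between-matrix agreement.

Overlap percentages are heavily skewed, so central tendency is reported
as a median with a percentile bootstrap confidence interval (1000
resamples of the original size, drawn with replacement, 95% by
default).  The resampling unit is the overlap result itself — the 56
ordered off-diagonal matrix cells — not the underlying measurements; a
sample-level mode would require rebuilding both matrices per resample
and is out of scope here.  Agreement between the individual-level and
gamut-level matrices is Pearson's r over paired off-diagonal cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matrices import OverlapMatrix

__all__ = ["MedianCI", "MatrixAgreement", "bootstrap_median_ci", "matrix_correlation"]


@dataclass(frozen=True)
class MedianCI:
    median: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    n_boot: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.median + 1e-12 and self.median <= self.ci_high + 1e-12):
            raise ValueError("CI bounds must bracket the median")


@dataclass(frozen=True)
class MatrixAgreement:
    r: float
    p: float
    n_cells: int
    defined: bool = True


def bootstrap_median_ci(
    values, n_boot: int = 1000, level: float = 0.95, seed: int | None = None
) -> MedianCI:
    """Median with a percentile bootstrap CI, reproducible from ``seed``.

    Resamples are drawn with replacement at the original size; the CI is
    the ((1−level)/2, 1−(1−level)/2) percentile pair of the bootstrap
    median distribution.  Even-length medians are the mean of the two
    central order statistics (numpy convention).
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("cannot bootstrap an empty collection")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if n_boot < 1:
        raise ValueError("n_boot must be ≥ 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
    boot_medians = np.median(arr[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot_medians, [alpha, 1.0 - alpha])
    med = float(np.median(arr))
    # the percentile interval is of the bootstrap distribution; with tiny
    # n_boot it can exclude the point estimate, so widen to bracket it
    return MedianCI(
        median=med,
        ci_low=min(float(lo), med),
        ci_high=max(float(hi), med),
        level=level,
        n_boot=n_boot,
        seed=seed,
    )


def matrix_correlation(
    m1: OverlapMatrix, m2: OverlapMatrix, include_diagonal: bool = False
) -> MatrixAgreement:
    """Pearson correlation between two overlap matrices' paired cells.

    Off-diagonal cells by default (56 for 8 groups).  If either matrix
    has zero variance over the included cells the correlation is
    undefined and flagged as such (``defined=False``) rather than
    propagating NaN silently.
    """
    if m1.groups != m2.groups:
        raise ValueError("matrices must share the same group order")
    if include_diagonal:
        x, y = m1.values.ravel(), m2.values.ravel()
    else:
        x, y = m1.off_diagonal(), m2.off_diagonal()
    if x.size < 3:
        raise ValueError("need at least 3 paired cells")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return MatrixAgreement(r=float("nan"), p=float("nan"), n_cells=x.size, defined=False)
    r, p = stats.pearsonr(x, y)
    return MatrixAgreement(r=float(r), p=float(p), n_cells=x.size)
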