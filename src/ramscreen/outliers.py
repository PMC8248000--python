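"""PCA-based replicate outlier screening.

Replicate scans of one sample are decomposed by PCA; the per-scan
statistic is the signed sum of the scores on the first three components,
and scans whose statistic falls outside the central ``coverage``
(default 99%) empirical quantile interval of the pooled statistics are
flagged. PCA can be fitted within each unique sample's replicates
(``per_sample``, the default) or on the whole set (``global``); the
quantile cutoffs are always computed on the pooled statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import RankError, UsageError, ValidationError
from .spectra_io import SpectrumSet


def pca(matrix, ncomp: int):
    """PCA via SVD of the column-mean-centered matrix.

    Returns ``(scores, loadings, explained_variance_fractions)`` with
    orthonormal loadings (p × ncomp), orthogonal score columns
    (n × ncomp) and non-increasing variance fractions. The sign of each
    component is fixed by making the largest-magnitude loading element
    positive, so results are reproducible.
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, p = X.shape
    if n < 2:
        raise UsageError("pca needs at least two rows")
    if not (1 <= ncomp <= min(n - 1, p)):
        raise RankError(f"ncomp={ncomp} exceeds min(n-1, p)={min(n - 1, p)}")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s**2).sum())
    scores = U[:, :ncomp] * s[:ncomp]
    loadings = Vt[:ncomp].T
    # fix component signs: largest-|.| loading element positive
    for j in range(ncomp):
        k = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    evf = (s[:ncomp] ** 2) / total if total > 0 else np.zeros(ncomp)
    return scores, loadings, evf


@dataclass
class OutlierReport:
    """Per-spectrum score statistic, quantile cutoffs, and flags."""

    statistic: np.ndarray
    lower: float
    upper: float
    flags: np.ndarray
    mode: str
    coverage: float

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def _score_sum(matrix, ncomp: int) -> np.ndarray:
    """Sum of scores on PCs 1..ncomp; missing components contribute 0."""
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, p = X.shape
    k = min(ncomp, n - 1, p)
    if k < 1:
        return np.zeros(n)
    Xc = X - X.mean(axis=0)
    # all replicates (numerically) identical: zero-variance PCA, no scores
    scale = np.max(np.abs(X)) if np.any(X) else 1.0
    if np.max(np.abs(Xc)) <= 1e-12 * scale:
        return np.zeros(n)
    scores, _, _ = pca(X, k)
    return scores.sum(axis=1)


def flag_outliers(sset: SpectrumSet, ncomp: int = 3, coverage: float = 0.99,
                  mode: str = "per_sample") -> OutlierReport:
    """Flag replicate scans outside the central ``coverage`` interval.

    The flag decision is invariant to the ordering of spectra within the
    set and is fully deterministic.
    """
    if mode not in ("per_sample", "global"):
        raise UsageError("mode must be 'per_sample' or 'global'")
    if not (0.0 < coverage <= 1.0):
        raise ValidationError("coverage must lie in (0, 1]")
    n = len(sset)
    statistic = np.zeros(n)
    eligible = np.ones(n, dtype=bool)

    if mode == "global":
        if n < 10:
            raise UsageError("global mode needs at least 10 spectra")
        statistic = _score_sum(sset.matrix, ncomp)
    else:
        groups: dict[str, list[int]] = {}
        for i, meta in enumerate(sset.metas):
            groups.setdefault(meta.sample_id, []).append(i)
        for sample_id, idx in groups.items():
            if len(idx) < 2:
                warnings.warn(
                    f"sample {sample_id!r} has a single replicate; "
                    "left unflagged", stacklevel=2)
                eligible[idx] = False
                continue
            statistic[idx] = _score_sum(sset.matrix[idx], ncomp)

    pooled = statistic[eligible]
    if pooled.size == 0:
        raise ValidationError("no samples with >= 2 replicates to screen")
    alpha = 1.0 - coverage
    lower = float(np.quantile(pooled, alpha / 2.0))
    upper = float(np.quantile(pooled, 1.0 - alpha / 2.0))
    flags = eligible & ((statistic < lower) | (statistic > upper))
    return OutlierReport(statistic=statistic, lower=lower, upper=upper,
                         flags=flags, mode=mode, coverage=coverage)
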