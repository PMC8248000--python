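"""Combined PLS-DA/PLS-R detection criterion.

Rules are evaluated in order, first match wins:

1. PLS-DA prediction ≥ ``da_positive`` (0.8) → positive;
2. ``da_ambiguous_low`` (0.65) < PLS-DA < 0.8 and PLS-R > ``r_cut_wt_pct``
   (30 wt%) → positive;
3. otherwise (PLS-DA ≤ 0.65 or PLS-R ≤ 30 wt%) → negative.

The printed rules 1 and 3 overlap when PLS-DA ≥ 0.8 but PLS-R ≤ 30 wt%;
ordered evaluation resolves this in favor of rule 1 (a high discriminant
score alone is treated as a sufficient indicator). The ambiguous
interval is open at both ends: 0.65 exactly is negative (rule 3's ≤),
0.8 exactly is positive (rule 1's ≥).

``batch_classify`` optionally gates weak scans as "inconclusive" before
classification, emulating the device's no-match outcome for low-signal
scans; the gate is off by default because the PLS pipeline itself never
produces inconclusives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import UsageError, ValidationError
from .pls import PLSModel, predict_pls
from .preprocess import PLSDA_CHAIN, PLSR_CHAIN, apply_chain_matrix, roi_mask
from .spectra_io import SpectrumSet

POSITIVE = "positive"
NEGATIVE = "negative"
INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class DecisionThresholds:
    da_positive: float = 0.8
    da_ambiguous_low: float = 0.65
    r_cut_wt_pct: float = 30.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.da_ambiguous_low < self.da_positive <= 1.0):
            raise ValidationError(
                "need 0 <= da_ambiguous_low < da_positive <= 1")
        if not (0.0 < self.r_cut_wt_pct < 100.0):
            raise ValidationError("r_cut_wt_pct must lie in (0, 100)")


DEFAULT_THRESHOLDS = DecisionThresholds()


@dataclass(frozen=True)
class DetectionResult:
    """Outcome plus both model scores and the rule that fired.

    ``rule_fired`` is 1–3 for classified scans and None for scans gated
    as inconclusive before classification.
    """

    outcome: str
    da_score: float
    r_pred: float
    rule_fired: int | None


def classify_detection(da_score: float, r_pred: float,
                       thresholds: DecisionThresholds = DEFAULT_THRESHOLDS
                       ) -> DetectionResult:
    """Apply the ordered three-rule criterion to one (DA, R) score pair."""
    if not (math.isfinite(da_score) and math.isfinite(r_pred)):
        raise ValidationError("scores must be finite")
    t = thresholds
    if da_score >= t.da_positive:
        return DetectionResult(POSITIVE, da_score, r_pred, 1)
    if t.da_ambiguous_low < da_score < t.da_positive and r_pred > t.r_cut_wt_pct:
        return DetectionResult(POSITIVE, da_score, r_pred, 2)
    return DetectionResult(NEGATIVE, da_score, r_pred, 3)


def roi_signal_strength(sset: SpectrumSet, lo: float | None = None,
                        hi: float | None = None):
    """(smoothed ROI max−min, per-scan noise estimate) on raw spectra.

    The signal statistic is the peak-to-trough range of the 9-point
    quadratic-smoothed raw ROI (smoothing keeps a real band's range but
    suppresses the range pure noise produces across 21 points). Noise is
    estimated robustly from first differences of the full raw spectrum:
    1.4826·median(|Δ|)/√2.
    """
    from .preprocess import savgol_smooth
    lo = PLSR_CHAIN.roi_lo if lo is None else lo
    hi = PLSR_CHAIN.roi_hi if hi is None else hi
    mask = roi_mask(sset.grid.values, lo, hi)
    roi = np.apply_along_axis(savgol_smooth, 1, sset.matrix[:, mask])
    signal = roi.max(axis=1) - roi.min(axis=1)
    diffs = np.abs(np.diff(sset.matrix, axis=1))
    noise = 1.4826 * np.median(diffs, axis=1) / np.sqrt(2.0)
    return signal, noise


def batch_classify(sset: SpectrumSet, plsr_model: PLSModel,
                   plsda_model: PLSModel,
                   thresholds: DecisionThresholds = DEFAULT_THRESHOLDS,
                   inconclusive_snr: float | None = None
                   ) -> list[DetectionResult]:
    """Classify every spectrum of a set with both models.

    Equals the pointwise map of :func:`classify_detection` over the two
    model predictions; when ``inconclusive_snr`` is set, scans whose raw
    ROI peak-to-trough falls below ``inconclusive_snr`` × noise estimate
    are returned as inconclusive without classification.
    """
    if plsr_model.chain_id != "plsr" or plsda_model.chain_id != "plsda":
        raise UsageError("models passed in the wrong order or wrong chains")
    r_pred = predict_pls(plsr_model, apply_chain_matrix(sset, PLSR_CHAIN))
    da = predict_pls(plsda_model, apply_chain_matrix(sset, PLSDA_CHAIN))
    weak = np.zeros(len(sset), dtype=bool)
    if inconclusive_snr is not None and inconclusive_snr > 0:
        signal, noise = roi_signal_strength(sset)
        weak = signal < inconclusive_snr * noise
    out = []
    for i in range(len(sset)):
        if weak[i]:
            out.append(DetectionResult(INCONCLUSIVE, float(da[i]),
                                       float(r_pred[i]), None))
        else:
            out.append(classify_detection(float(da[i]), float(r_pred[i]),
                                          thresholds))
    return out
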