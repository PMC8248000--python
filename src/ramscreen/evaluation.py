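"""Screening-performance evaluation: confusion tables with an
inconclusive category, false-negative-rate curves per adulterant and
concentration, and composition-dependent limit-of-detection estimates.

Two inconclusive policies mirror field practice: ``include`` counts an
inconclusive scan of a cocaine-containing sample as a false negative
with the full replicate denominator; ``exclude`` drops inconclusive
scans from numerator and denominator (an officer would simply rescan).

The LOD for an adulterant is the lowest tested cocaine level at which
the detection rate reaches the threshold (default 0.5, i.e. a majority
of replicates detected) and stays at or above it at every higher tested
level; if no such level exists the LOD is reported as not reached.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .decision import INCONCLUSIVE, NEGATIVE, POSITIVE
from .errors import UsageError, ValidationError
from .spectra_io import SpectrumSet

OUTCOMES = (POSITIVE, NEGATIVE, INCONCLUSIVE)

#: Sentinel for an adulterant whose LOD was not reached on the panel.
LOD_NOT_REACHED = None


@dataclass
class ConfusionTable:
    """2×3 counts: truth {cocaine, non-cocaine} × outcome
    {positive, negative, inconclusive}."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (2, 3) or (c < 0).any():
            raise ValidationError("counts must be a non-negative 2x3 table")
        self.counts = c

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=["cocaine", "non_cocaine"],
                            columns=list(OUTCOMES))


def confusion_table(truth, outcomes) -> ConfusionTable:
    """Cross-tabulate binary cocaine truth against screening outcomes."""
    truth = list(truth)
    outcomes = list(outcomes)
    if len(truth) != len(outcomes):
        raise UsageError("truth and outcomes must have equal length")
    counts = np.zeros((2, 3), dtype=int)
    col = {o: j for j, o in enumerate(OUTCOMES)}
    for t, o in zip(truth, outcomes):
        if o not in col:
            raise ValidationError(f"unknown outcome label {o!r}")
        counts[0 if t else 1, col[o]] += 1
    return ConfusionTable(counts)


def _round_half_up_1dp(numerator: int, denominator: int) -> float:
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def row_rates(table: ConfusionTable, denominator="row_total") -> np.ndarray:
    """Per-cell percentages, rounded half-up to one decimal.

    ``denominator`` is ``"row_total"`` or an explicit count — either one
    integer applied to both rows or a (cocaine_n, non_cocaine_n) pair.
    An explicit denominator supports reporting against a stated sample
    count that differs from the tabulated row total.
    """
    counts = table.counts
    if isinstance(denominator, str):
        if denominator != "row_total":
            raise UsageError("denominator must be 'row_total' or explicit n")
        denoms = counts.sum(axis=1)
        if (denoms == 0).all():
            raise ValidationError("empty table has no reportable rows")
    else:
        if np.isscalar(denominator):
            denoms = np.array([denominator, denominator])
        else:
            denoms = np.asarray(denominator)
        if (denoms <= 0).any():
            raise ValidationError("zero or negative denominator")
    return np.array([[_round_half_up_1dp(int(counts[i, j]), int(denoms[i]))
                      if denoms[i] > 0 else np.nan
                      for j in range(3)] for i in range(2)])


@dataclass
class PanelResult:
    """False-negative rates per (adulterant, cocaine wt% level)."""

    fn_rate: dict[tuple[str, float], float]
    n: dict[tuple[str, float], int]
    policy: str

    def adulterants(self) -> list[str]:
        return sorted({a for a, _ in self.fn_rate})

    def levels(self, adulterant: str) -> list[float]:
        return sorted(l for a, l in self.fn_rate if a == adulterant)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"adulterant": a, "cocaine_wt_pct": l,
                 "n": self.n[(a, l)], "fn_rate": self.fn_rate[(a, l)],
                 "policy": self.policy}
                for (a, l) in sorted(self.fn_rate)]
        return pd.DataFrame(rows)


def fn_rate_curve(panel: SpectrumSet, results,
                  policy: str = "include") -> PanelResult:
    """False-negative fraction per (adulterant, level) on panel scans.

    Only cocaine-containing scans (wt% > 0) enter the curve; the
    adulterant label is the panel agent recorded in ``source_tag``.
    """
    if policy not in ("include", "exclude"):
        raise UsageError("policy must be 'include' or 'exclude'")
    if len(panel) != len(results):
        raise UsageError("panel and results length mismatch")
    fn_cnt: dict[tuple[str, float], int] = {}
    denom: dict[tuple[str, float], int] = {}
    for meta, res in zip(panel.metas, results):
        if meta.cocaine_wt_pct <= 0:
            continue
        if not meta.source_tag:
            raise ValidationError(
                f"panel scan {meta.sample_id!r} lacks an adulterant tag")
        key = (meta.source_tag, float(meta.cocaine_wt_pct))
        outcome = res if isinstance(res, str) else res.outcome
        if outcome == INCONCLUSIVE and policy == "exclude":
            continue
        denom[key] = denom.get(key, 0) + 1
        if outcome != POSITIVE:
            fn_cnt[key] = fn_cnt.get(key, 0) + 1
    rate = {k: fn_cnt.get(k, 0) / n for k, n in denom.items() if n > 0}
    return PanelResult(fn_rate=rate, n=denom, policy=policy)


def lod_estimate(panel_result: PanelResult,
                 detection_rate_threshold: float = 0.5) -> dict:
    """Lowest sustained-detection cocaine level per adulterant.

    Returns adulterant → wt% level, or ``LOD_NOT_REACHED`` (None) when
    the detection rate never sustains the threshold.
    """
    if not panel_result.fn_rate:
        raise ValidationError("empty false-negative curve")
    if not (0.0 < detection_rate_threshold <= 1.0):
        raise ValidationError("threshold must lie in (0, 1]")
    out = {}
    for agent in panel_result.adulterants():
        levels = panel_result.levels(agent)
        lod = LOD_NOT_REACHED
        for lvl in reversed(levels):  # descend; track lowest sustained level
            rate = 1.0 - panel_result.fn_rate[(agent, lvl)]
            if rate >= detection_rate_threshold:
                lod = lvl
            else:
                break
        out[agent] = lod
    return out


def lod_frame(lods: dict) -> pd.DataFrame:
    return pd.DataFrame(
        [{"adulterant": a,
          "lod_wt_pct": "not reached" if l is LOD_NOT_REACHED else l}
         for a, l in sorted(lods.items())])
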