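"""The two spectral preprocessing chains feeding the PLS models.

Both chains combine four primitives — standard normal variate (SNV)
normalization, Savitzky–Golay (SG) smoothing, selection of the
1,700–1,728 cm⁻¹ region of interest (ROI) around the cocaine carbonyl
peaks, and minimum-subtraction baseline correction — but in a different
order:

* regression chain (``plsr``):  SNV on the full spectrum → SG → ROI →
  baseline.  Normalizing before cutting keeps the concentration
  dependence carried by out-of-ROI signal.
* discriminant chain (``plsda``): ROI → SNV → SG → baseline.
  Normalizing after cutting removes all concentration dependence and
  emphasizes peak shape only.

Consequently the discriminant features are invariant to any spectral
change outside the ROI, while the regression features are not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateInputError, RangeError, UsageError
from .spectra_io import Spectrum, SpectrumSet

ROI_LO_CM1 = 1700.0
ROI_HI_CM1 = 1728.0


def snv(intensities) -> np.ndarray:
    """Standard normal variate: center to mean 0, scale to sample sd 1.

    Uses the n−1 (sample) standard deviation. Removes multiplicative
    gain and additive offset exactly: ``snv(a*x + b) == snv(x)`` for any
    a > 0.
    """
    x = np.asarray(intensities, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise UsageError("snv needs a 1-D vector of length >= 2")
    sd = x.std(ddof=1)
    if sd <= 0 or not np.isfinite(sd):
        raise DegenerateInputError("zero-variance spectrum cannot be SNV-scaled")
    return (x - x.mean()) / sd


def savgol_smooth(intensities, window: int = 9, order: int = 2) -> np.ndarray:
    """Savitzky–Golay smoothing (default 9-point quadratic).

    Edges are handled by evaluating the least-squares polynomial fit of
    the first/last window at the edge offsets, so any polynomial of
    degree <= ``order`` is reproduced exactly at every point.
    """
    x = np.asarray(intensities, dtype=float)
    if window % 2 == 0:
        raise UsageError("window must be odd")
    if order < 0 or window < order + 2:
        raise UsageError("window must be >= order + 2")
    if x.ndim != 1 or x.size < window:
        raise UsageError(f"window {window} exceeds vector length {x.size}")
    return savgol_filter(x, window_length=window, polyorder=order,
                         mode="interp")


def select_roi(spectrum: Spectrum, lo: float = ROI_LO_CM1,
               hi: float = ROI_HI_CM1) -> Spectrum:
    """Keep grid points with lo <= wavenumber <= hi (closed interval)."""
    if lo >= hi:
        raise UsageError(f"roi bounds reversed: [{lo}, {hi}]")
    mask = (spectrum.grid.values >= lo) & (spectrum.grid.values <= hi)
    if not mask.any():
        raise RangeError(f"no grid points inside [{lo}, {hi}]")
    from .spectra_io import WavenumberGrid  # local to avoid cycle at import
    return Spectrum(WavenumberGrid(spectrum.grid.values[mask]),
                    spectrum.intensities[mask])


def roi_mask(grid_values: np.ndarray, lo: float = ROI_LO_CM1,
             hi: float = ROI_HI_CM1) -> np.ndarray:
    if lo >= hi:
        raise UsageError(f"roi bounds reversed: [{lo}, {hi}]")
    mask = (np.asarray(grid_values) >= lo) & (np.asarray(grid_values) <= hi)
    if mask.sum() < 2:
        raise RangeError(f"grid has <2 points inside [{lo}, {hi}]")
    return mask


def baseline_min_subtract(intensities) -> np.ndarray:
    """Subtract the lowest data point from all data points (min → 0)."""
    x = np.asarray(intensities, dtype=float)
    if x.size < 1:
        raise UsageError("empty vector")
    return x - x.min()


@dataclass(frozen=True)
class PreprocessChain:
    """Configuration of one preprocessing chain.

    ``chain_id`` selects the operation order (see module docstring).
    """

    chain_id: str
    roi_lo: float = ROI_LO_CM1
    roi_hi: float = ROI_HI_CM1
    sg_window: int = 9
    sg_order: int = 2

    def __post_init__(self) -> None:
        if self.chain_id not in ("plsr", "plsda"):
            raise UsageError("chain_id must be 'plsr' or 'plsda'")
        if self.roi_lo >= self.roi_hi:
            raise UsageError("roi_lo must be < roi_hi")
        if self.sg_window % 2 == 0 or self.sg_window < self.sg_order + 2:
            raise UsageError("sg_window must be odd and >= sg_order + 2")


PLSR_CHAIN = PreprocessChain("plsr")
PLSDA_CHAIN = PreprocessChain("plsda")


def apply_chain(spectrum: Spectrum, chain: PreprocessChain) -> np.ndarray:
    """Run one spectrum through a chain; returns the ROI feature vector."""
    mask = roi_mask(spectrum.grid.values, chain.roi_lo, chain.roi_hi)
    x = spectrum.intensities
    if chain.chain_id == "plsr":
        x = snv(x)
        x = savgol_smooth(x, chain.sg_window, chain.sg_order)
        x = x[mask]
    else:
        x = x[mask]
        x = snv(x)
        x = savgol_smooth(x, chain.sg_window, chain.sg_order)
    return baseline_min_subtract(x)


def apply_chain_matrix(sset: SpectrumSet, chain: PreprocessChain) -> np.ndarray:
    """Feature matrix (n_spectra × n_roi_points) for a whole set."""
    return np.vstack([apply_chain(sset.spectrum(i), chain)
                      for i in range(len(sset))])
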