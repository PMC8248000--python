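"""Synthetic handheld-Raman spectra of cocaine/cutting-agent powders.

The generator emulates the statistical structure the downstream
chemometrics assumes rather than calibrated physics:

* each compound is a list of Lorentzian bands (center, FWHM, relative
  intensity) plus an optional broad fluorescence background and a
  per-compound Raman cross-section multiplier;
* a mixture spectrum is the mass-fraction-weighted sum of scaled pure
  component spectra (Raman intensities are additive in this model);
* every scan draws a multiplicative log-normal gain, an additive linear
  baseline, and i.i.d. Gaussian noise, reproducing the large
  scan-to-scan intensity/offset variation of direct solid-sample
  measurements.

Band centers for cocaine HCl (1,599/1,716 cm⁻¹), cocaine base
(1,603/1,712 cm⁻¹), the shared ~1,000 cm⁻¹ aromatic ring-breathing mode,
and the near-1,700 cm⁻¹ procaine shoulder follow the published
assignments; relative intensities and cross-section scales are invented
fixtures chosen so that strong scatterers with bands near the diagnostic
peaks (procaine, paracetamol) mask cocaine at low mass fractions while
Raman-transparent diluents (inositol, lactose) do not. Absolute LODs
from these fixtures are design-dependent; only orderings are meaningful.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import UsageError, ValidationError
from .spectra_io import (SampleMeta, Spectrum, SpectrumSet, WavenumberGrid,
                         default_grid)

#: The eight cutting agents of the binary-mixture panel.
DEFAULT_AGENTS = ("levamisole", "procaine", "paracetamol", "phenacetin",
                  "caffeine", "lactose", "mannitol", "inositol")

#: Panel cocaine levels in wt% (pure agent 0 and pure cocaine 100 are
#: added automatically).
DEFAULT_LEVELS = tuple(range(10, 100, 10))

_FLUOR_CENTER_CM1 = 900.0
_FLUOR_FWHM_CM1 = 1500.0


@dataclass(frozen=True)
class PeakProfile:
    """One Lorentzian band: height ``rel_intensity`` at ``center``."""

    center: float
    fwhm: float
    rel_intensity: float

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValidationError("fwhm must be > 0")
        if self.rel_intensity < 0:
            raise ValidationError("rel_intensity must be >= 0")


@dataclass(frozen=True)
class CompoundProfile:
    """Ground-truth spectral fixture for one compound."""

    name: str
    peaks: tuple[PeakProfile, ...]
    fluorescence_amp: float = 0.0
    raman_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.fluorescence_amp < 0:
            raise ValidationError("fluorescence_amp must be >= 0")
        if self.raman_scale <= 0:
            raise ValidationError("raman_scale must be > 0")

    def band_profile(self, grid_values: np.ndarray) -> np.ndarray:
        """Unit-scale sum of Lorentzian bands on the grid."""
        x = np.asarray(grid_values, dtype=float)
        out = np.zeros_like(x)
        for p in self.peaks:
            gamma = p.fwhm / 2.0
            out += p.rel_intensity * gamma**2 / ((x - p.center) ** 2 + gamma**2)
        return out

    def fluorescence_profile(self, grid_values: np.ndarray) -> np.ndarray:
        """Broad Gaussian fluorescence background (unit amplitude × amp)."""
        x = np.asarray(grid_values, dtype=float)
        return self.fluorescence_amp * np.exp(
            -4.0 * np.log(2.0) * ((x - _FLUOR_CENTER_CM1) / _FLUOR_FWHM_CM1) ** 2)


@dataclass(frozen=True)
class InstrumentModel:
    """Scan-to-scan variation of the handheld instrument.

    ``gain_sigma`` is the log-scale sd of the multiplicative gain;
    ``weak_scan_prob`` scans are misaligned and get gain ×0.05 (used to
    emulate inconclusive, low-signal scans; off by default).
    """

    gain_sigma: float = 0.3
    baseline_offset_range: tuple[float, float] = (20.0, 150.0)
    baseline_slope_range: tuple[float, float] = (-0.01, 0.01)
    noise_sd: float = 25.0
    weak_scan_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain_sigma < 0 or self.noise_sd < 0:
            raise ValidationError("sds must be >= 0")
        if not (0.0 <= self.weak_scan_prob <= 1.0):
            raise ValidationError("weak_scan_prob must lie in [0, 1]")


#: Noise/gain switched off — for additivity and oracle tests.
NOISELESS_INSTRUMENT = InstrumentModel(gain_sigma=0.0,
                                       baseline_offset_range=(0.0, 0.0),
                                       baseline_slope_range=(0.0, 0.0),
                                       noise_sd=0.0, weak_scan_prob=0.0)


@dataclass(frozen=True)
class Composition:
    """Mass-fraction composition of one powder sample."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValidationError("composition is empty")
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError("mass fractions must be >= 0")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"mass fractions sum to {total}, expected 1")

    @property
    def cocaine_wt_pct(self) -> float:
        return 100.0 * sum(v for k, v in self.weights.items()
                           if k.startswith("cocaine"))


def _profiles(*triples) -> tuple[PeakProfile, ...]:
    return tuple(PeakProfile(c, f, r) for c, f, r in triples)


def builtin_compound_library() -> dict[str, CompoundProfile]:
    """Fixture library of pure-compound profiles.

    Diagnostic band positions (cocaine carbonyl/aromatic pairs, the
    shared ~1,000 cm⁻¹ ring mode, the procaine shoulder just below the
    ROI) follow published assignments; everything else is an invented,
    versioned fixture. No non-cocaine compound has a band centered above
    1,700 cm⁻¹.
    """
    lib = {
        "cocaine_hcl": CompoundProfile(
            "cocaine_hcl",
            _profiles((898, 10, 0.40), (1003, 9, 0.80), (1276, 11, 0.45),
                      (1599, 11, 0.85), (1716, 12, 1.00)),
            raman_scale=900.0),
        "cocaine_base": CompoundProfile(
            "cocaine_base",
            _profiles((898, 10, 0.40), (1003, 9, 0.80), (1276, 11, 0.45),
                      (1603, 11, 0.85), (1712, 12, 1.00)),
            raman_scale=900.0),
        "levamisole": CompoundProfile(
            "levamisole",
            _profiles((780, 10, 0.50), (1003, 9, 0.90), (1340, 12, 0.40),
                      (1570, 12, 0.55), (1590, 12, 0.45)),
            raman_scale=1200.0),
        "procaine": CompoundProfile(
            "procaine",
            _profiles((861, 10, 0.50), (1170, 11, 0.55), (1282, 11, 0.50),
                      (1605, 12, 1.00), (1695, 14, 0.75)),
            raman_scale=1500.0),
        "paracetamol": CompoundProfile(
            "paracetamol",
            _profiles((858, 10, 0.60), (1236, 11, 0.50), (1324, 11, 0.70),
                      (1610, 12, 0.80), (1648, 13, 0.60)),
            fluorescence_amp=800.0, raman_scale=800.0),
        "phenacetin": CompoundProfile(
            "phenacetin",
            _profiles((1182, 11, 0.50), (1515, 12, 0.60), (1600, 12, 0.70),
                      (1652, 12, 0.55)),
            raman_scale=1000.0),
        "caffeine": CompoundProfile(
            "caffeine",
            _profiles((555, 10, 0.60), (1329, 11, 0.70), (1600, 12, 0.35),
                      (1656, 12, 0.80)),
            raman_scale=1100.0),
        "lactose": CompoundProfile(
            "lactose",
            _profiles((355, 10, 0.50), (477, 10, 0.60), (850, 10, 0.50),
                      (1086, 11, 0.60)),
            raman_scale=350.0),
        "mannitol": CompoundProfile(
            "mannitol",
            _profiles((876, 10, 1.00), (1052, 10, 0.60), (1260, 11, 0.40),
                      (1460, 12, 0.50)),
            raman_scale=1600.0),
        "inositol": CompoundProfile(
            "inositol",
            _profiles((435, 10, 0.60), (875, 10, 0.50), (1062, 11, 0.40)),
            raman_scale=300.0),
        # non-cocaine drugs used for negative case-like samples
        "ketamine": CompoundProfile(
            "ketamine",
            _profiles((1003, 9, 0.70), (1590, 12, 0.50), (1690, 13, 0.40)),
            raman_scale=1000.0),
        "amphetamine": CompoundProfile(
            "amphetamine",
            _profiles((621, 10, 0.50), (1003, 9, 0.80), (1605, 12, 0.30)),
            fluorescence_amp=60.0, raman_scale=700.0),
        "mdma": CompoundProfile(
            "mdma",
            _profiles((716, 10, 0.60), (810, 10, 0.70), (1250, 11, 0.40)),
            fluorescence_amp=300.0, raman_scale=600.0),
    }
    return lib


def library_to_yaml(library: dict[str, CompoundProfile], path) -> None:
    """Serialize a compound library as YAML (the versioned fixture format)."""
    import yaml
    payload = {
        name: {
            "peaks": [{"center": p.center, "fwhm": p.fwhm,
                       "rel_intensity": p.rel_intensity} for p in prof.peaks],
            "fluorescence_amp": prof.fluorescence_amp,
            "raman_scale": prof.raman_scale,
        }
        for name, prof in library.items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def library_from_yaml(path) -> dict[str, CompoundProfile]:
    import yaml
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    return {
        name: CompoundProfile(
            name=name,
            peaks=_profiles(*[(p["center"], p["fwhm"], p["rel_intensity"])
                              for p in spec["peaks"]]),
            fluorescence_amp=float(spec.get("fluorescence_amp", 0.0)),
            raman_scale=float(spec.get("raman_scale", 1.0)))
        for name, spec in payload.items()
    }


def derive_seed(root_seed: int, *tokens) -> int:
    """Stable sub-seed from a root seed and string tokens (< 2**31)."""
    key = "|".join([str(int(root_seed)), *map(str, tokens)]).encode()
    digest = hashlib.blake2b(key, digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


def clean_mixture_signal(comp: Composition, library, grid: WavenumberGrid):
    """Noise-free (raman, fluorescence) component pair for a composition."""
    for name in comp.weights:
        if name not in library:
            raise KeyError(f"compound {name!r} not in library")
    x = grid.values
    raman = np.zeros_like(x)
    fluor = np.zeros_like(x)
    for name, w in comp.weights.items():
        prof = library[name]
        raman += w * prof.raman_scale * prof.band_profile(x)
        fluor += w * prof.fluorescence_profile(x)
    return raman, fluor


def simulate_spectrum(comp: Composition, library, instrument: InstrumentModel,
                      grid: WavenumberGrid | None = None,
                      seed: int | None = None) -> Spectrum:
    """One scan: gain·(mixture Raman) + baseline + fluorescence + noise.

    Deterministic for a fixed seed (defaults to ``instrument.seed``).
    The result is clipped at zero (detector counts are non-negative).
    """
    grid = grid if grid is not None else default_grid()
    raman, fluor = clean_mixture_signal(comp, library, grid)
    rng = np.random.default_rng(instrument.seed if seed is None else seed)

    gain = float(np.exp(rng.normal(0.0, instrument.gain_sigma))) \
        if instrument.gain_sigma > 0 else 1.0
    if instrument.weak_scan_prob > 0 and rng.random() < instrument.weak_scan_prob:
        gain *= 0.05
    lo, hi = instrument.baseline_offset_range
    offset = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    lo, hi = instrument.baseline_slope_range
    slope = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    noise = rng.normal(0.0, instrument.noise_sd, size=len(grid)) \
        if instrument.noise_sd > 0 else 0.0

    x = grid.values
    baseline = offset + slope * (x - x[0])
    out = gain * raman + baseline + fluor + noise
    return Spectrum(grid, np.maximum(out, 0.0))


def _panel_compositions(agent: str, levels, cocaine: str = "cocaine_hcl"):
    """(level, composition) pairs for one agent column of the panel."""
    out = [(0.0, Composition({agent: 1.0}))]
    for lvl in levels:
        w = lvl / 100.0
        out.append((float(lvl), Composition({cocaine: w, agent: 1.0 - w})))
    out.append((100.0, Composition({cocaine: 1.0})))
    return out


def generate_binary_panel(library=None, agents=DEFAULT_AGENTS,
                          levels=DEFAULT_LEVELS, replicates: int = 10,
                          instrument: InstrumentModel | None = None,
                          seed: int = 0,
                          grid: WavenumberGrid | None = None) -> SpectrumSet:
    """The binary cocaine-HCl/cutting-agent mixture panel.

    With the defaults this reproduces the published design: 8 pure
    cutting agents, 72 mixtures (8 agents × 9 levels, 10–90 wt% in
    10 wt% steps), and 8 pure-cocaine entries (one per agent slot) — 88
    unique samples, each scanned ``replicates`` times.
    """
    library = library if library is not None else builtin_compound_library()
    instrument = instrument if instrument is not None else InstrumentModel()
    grid = grid if grid is not None else default_grid()
    agents = list(agents)
    levels = sorted(float(l) for l in levels)
    if not agents or not levels:
        raise ValidationError("agents and levels must be non-empty")
    missing = [a for a in agents if a not in library]
    if missing:
        raise KeyError(f"agents not in library: {missing}")
    if any(not (0.0 < l < 100.0) for l in levels):
        raise ValidationError("mixture levels must lie strictly in (0, 100)")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")

    rows, metas = [], []
    for agent in agents:
        for lvl, comp in _panel_compositions(agent, levels):
            sample_id = f"panel:{agent}:{lvl:g}"
            form = "HCl" if lvl > 0 else "none"
            for rep in range(1, replicates + 1):
                sp = simulate_spectrum(
                    comp, library, instrument, grid,
                    seed=derive_seed(seed, sample_id, rep))
                rows.append(sp.intensities)
                metas.append(SampleMeta(
                    sample_id=sample_id, replicate_index=rep,
                    composition=dict(comp.weights), cocaine_wt_pct=lvl,
                    cocaine_form=form, source_tag=agent))
    return SpectrumSet(grid, np.vstack(rows), metas)


def _truncated_normal(mean, sd, lo, hi, rng) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd,
                                     random_state=rng))


def generate_case_like_set(n_hcl: int = 58, n_base: int = 32,
                           n_negative: int = 52,
                           hcl_purity=(64.4, 15.0, 19.1, 85.5),
                           base_purity=(75.4, 12.0, 31.5, 99.4),
                           adulterant_pool=DEFAULT_AGENTS,
                           negative_drugs=("ketamine", "amphetamine", "mdma"),
                           replicates: int = 3,
                           instrument: InstrumentModel | None = None,
                           seed: int = 0,
                           grid: WavenumberGrid | None = None,
                           library=None) -> SpectrumSet:
    """Case-like samples with street-sample purity distributions.

    Purities are truncated normals (mean, sd, lo, hi per salt form);
    the non-cocaine remainder is split over 1–3 adulterants from the
    pool; negatives are pure adulterants, adulterant mixtures, or
    non-cocaine drugs.
    """
    library = library if library is not None else builtin_compound_library()
    instrument = instrument if instrument is not None else InstrumentModel()
    grid = grid if grid is not None else default_grid()
    pool = list(adulterant_pool)
    if (n_hcl > 0 or n_base > 0 or n_negative > 0) and not pool:
        raise ValidationError("adulterant pool is empty")
    if min(n_hcl, n_base, n_negative) < 0:
        raise ValidationError("counts must be >= 0")

    rng = np.random.default_rng(derive_seed(seed, "case-design"))
    rows, metas = [], []

    def _emit(sample_id, comp, form):
        for rep in range(1, replicates + 1):
            sp = simulate_spectrum(comp, library, instrument, grid,
                                   seed=derive_seed(seed, sample_id, rep))
            rows.append(sp.intensities)
            metas.append(SampleMeta(
                sample_id=sample_id, replicate_index=rep,
                composition=dict(comp.weights),
                cocaine_wt_pct=comp.cocaine_wt_pct,
                cocaine_form=form, source_tag="case"))

    for form, n, purity, compound in (("HCl", n_hcl, hcl_purity, "cocaine_hcl"),
                                      ("base", n_base, base_purity,
                                       "cocaine_base")):
        mean, sd, lo, hi = purity
        for i in range(n):
            p = _truncated_normal(mean, sd, lo, hi, rng) / 100.0
            k = int(rng.integers(1, 4))
            adults = list(rng.choice(pool, size=min(k, len(pool)),
                                     replace=False))
            fracs = rng.dirichlet(np.ones(len(adults))) * (1.0 - p)
            comp = Composition({compound: p,
                                **{a: float(f) for a, f in zip(adults, fracs)}})
            _emit(f"case:{form.lower()}:{i:03d}", comp, form)

    neg_kinds = ("pure_agent", "agent_mix", "other_drug")
    for i in range(n_negative):
        kind = neg_kinds[int(rng.integers(0, len(neg_kinds)))]
        if kind == "pure_agent" or (kind == "other_drug" and not negative_drugs):
            comp = Composition({pool[int(rng.integers(0, len(pool)))]: 1.0})
        elif kind == "agent_mix":
            k = int(rng.integers(2, 4))
            adults = list(rng.choice(pool, size=min(k, len(pool)),
                                     replace=False))
            fracs = rng.dirichlet(np.ones(len(adults)))
            comp = Composition({a: float(f) for a, f in zip(adults, fracs)})
        else:
            drug = negative_drugs[int(rng.integers(0, len(negative_drugs)))]
            comp = Composition({drug: 1.0})
        _emit(f"case:neg:{i:03d}", comp, "none")

    if not rows:
        raise ValidationError("empty case-like set requested")
    return SpectrumSet(grid, np.vstack(rows), metas)
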