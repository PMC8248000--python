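"""Labeled Raman spectrum sets on a shared wavenumber grid.

The canonical acquisition grid is the handheld instrument's fixed
300–1,800 cm⁻¹ range sampled at 1,153 points (≈1.3 cm⁻¹ resolution).
Spectra are stored row-wise in a :class:`SpectrumSet` together with
per-sample metadata (composition, cocaine mass percentage, salt form).

Supported on-disk formats are plain text only:

``csv-wide``
    One row per spectrum; leading metadata columns, then one column per
    grid point named by its wavenumber (4 decimals). Canonical format.
``csv-long``
    Tidy triplets (sample_id, replicate, wavenumber, intensity) with the
    metadata repeated per row; accepted for import/export.
``jcamp-dx``
    Minimal JCAMP-DX with AFFN ``##XYDATA=(X++(Y..Y))`` tables, one
    block per spectrum; compressed (SQZ/DIF) encodings are not supported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, RangeError, UsageError, ValidationError

GRID_MIN_CM1 = 300.0
GRID_MAX_CM1 = 1800.0
GRID_POINTS = 1153

#: Grids closer than this (max abs difference, cm⁻¹) are treated as equal.
GRID_MATCH_TOL = 1e-6

_COCAINE_FORMS = ("HCl", "base", "none")
_META_COLUMNS = ["sample_id", "replicate", "cocaine_wt_pct", "cocaine_form",
                 "composition", "source_tag"]


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly increasing wavenumber axis in cm⁻¹."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 2:
            raise ValidationError("grid needs at least two points")
        if not np.all(np.isfinite(vals)):
            raise ValidationError("grid contains non-finite wavenumbers")
        if not np.all(np.diff(vals) > 0):
            raise ValidationError("grid must be strictly increasing")

    def __len__(self) -> int:
        return int(self.values.size)

    def matches(self, other: "WavenumberGrid", tol: float = GRID_MATCH_TOL) -> bool:
        return len(self) == len(other) and float(
            np.max(np.abs(self.values - other.values))) < tol

    @property
    def spacing(self) -> float:
        """Mean grid step in cm⁻¹."""
        return float((self.values[-1] - self.values[0]) / (len(self) - 1))


def default_grid() -> WavenumberGrid:
    """The instrument's fixed 300–1,800 cm⁻¹ grid with 1,153 points."""
    return WavenumberGrid(np.linspace(GRID_MIN_CM1, GRID_MAX_CM1, GRID_POINTS))


@dataclass(frozen=True)
class Spectrum:
    """One scan: intensities (arbitrary units) on a wavenumber grid."""

    grid: WavenumberGrid
    intensities: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", vals)
        if vals.ndim != 1 or vals.size != len(self.grid):
            raise ValidationError("intensities length must equal grid length")
        if not np.all(np.isfinite(vals)):
            raise ValidationError("intensities contain non-finite values")


@dataclass
class SampleMeta:
    """Ground-truth labels for one scan.

    ``composition`` maps compound name to mass fraction (sums to 1); an
    empty map means composition-unknown, in which case no consistency
    check against ``cocaine_wt_pct`` is possible.
    """

    sample_id: str
    replicate_index: int = 1
    composition: dict[str, float] = field(default_factory=dict)
    cocaine_wt_pct: float = 0.0
    cocaine_form: str = "none"
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.replicate_index < 1:
            raise ValidationError("replicate_index must be >= 1")
        if self.cocaine_form not in _COCAINE_FORMS:
            raise ValidationError(
                f"cocaine_form must be one of {_COCAINE_FORMS}")
        if not (0.0 <= self.cocaine_wt_pct <= 100.0):
            raise ValidationError("cocaine_wt_pct must lie in [0, 100]")
        if self.composition:
            total = sum(self.composition.values())
            if any(v < 0 for v in self.composition.values()):
                raise ValidationError("mass fractions must be >= 0")
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"mass fractions sum to {total}, expected 1")
            coc = 100.0 * sum(v for k, v in self.composition.items()
                              if k.startswith("cocaine"))
            if abs(coc - self.cocaine_wt_pct) > 1e-6:
                raise ValidationError(
                    "cocaine_wt_pct inconsistent with composition "
                    f"({self.cocaine_wt_pct} vs {coc})")


@dataclass
class SpectrumSet:
    """A matrix of spectra sharing one grid, with per-row metadata."""

    grid: WavenumberGrid
    matrix: np.ndarray
    metas: list[SampleMeta]

    def __post_init__(self) -> None:
        mat = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.matrix = mat
        if mat.shape[1] != len(self.grid):
            raise ValidationError("matrix column count must equal grid length")
        if mat.shape[0] != len(self.metas):
            raise ValidationError("matrix row count must equal metas count")
        if not np.all(np.isfinite(mat)):
            raise ValidationError("matrix contains non-finite values")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.grid, self.matrix[i])

    def subset(self, mask) -> "SpectrumSet":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return SpectrumSet(self.grid, self.matrix[idx],
                           [self.metas[int(i)] for i in idx])


def concat_sets(sets: list[SpectrumSet]) -> SpectrumSet:
    """Stack spectrum sets that share one grid."""
    if not sets:
        raise UsageError("need at least one set")
    grid = sets[0].grid
    for s in sets[1:]:
        if not grid.matches(s.grid):
            raise ValidationError("sets are on different grids")
    return SpectrumSet(grid, np.vstack([s.matrix for s in sets]),
                       [m for s in sets for m in s.metas])


def resample_linear(spectrum: Spectrum, target: WavenumberGrid) -> Spectrum:
    """Piecewise-linear resampling onto ``target`` (no extrapolation)."""
    src = spectrum.grid
    if src.matches(target):
        return Spectrum(target, spectrum.intensities.copy())
    if target.values[0] < src.values[0] - GRID_MATCH_TOL or \
            target.values[-1] > src.values[-1] + GRID_MATCH_TOL:
        raise RangeError("target grid extends beyond source grid span")
    out = np.interp(target.values, src.values, spectrum.intensities)
    return Spectrum(target, out)


# ---------------------------------------------------------------------------
# serialization helpers

def _composition_to_str(comp: dict[str, float]) -> str:
    return ";".join(f"{k}:{float(v)!r}" for k, v in comp.items())


def _composition_from_str(text: str) -> dict[str, float]:
    text = (text or "").strip()
    if not text:
        return {}
    out: dict[str, float] = {}
    for part in text.split(";"):
        if not part:
            continue
        try:
            name, frac = part.rsplit(":", 1)
            out[name] = float(frac)
        except ValueError as exc:
            raise FormatError(f"bad composition field {part!r}") from exc
    return out


def _meta_to_row(meta: SampleMeta) -> dict:
    return {
        "sample_id": meta.sample_id,
        "replicate": meta.replicate_index,
        "cocaine_wt_pct": meta.cocaine_wt_pct,
        "cocaine_form": meta.cocaine_form,
        "composition": _composition_to_str(meta.composition),
        "source_tag": meta.source_tag,
    }


def _meta_from_row(row: dict) -> SampleMeta:
    def _get(key, default):
        val = row.get(key, default)
        if val is None or (isinstance(val, float) and math.isnan(val)):
            return default
        return val

    return SampleMeta(
        sample_id=str(_get("sample_id", "unknown")),
        replicate_index=int(_get("replicate", 1)),
        composition=_composition_from_str(str(_get("composition", ""))),
        cocaine_wt_pct=float(_get("cocaine_wt_pct", 0.0)),
        cocaine_form=str(_get("cocaine_form", "none")),
        source_tag=str(_get("source_tag", "")),
    )


def _grid_from_columns(cols) -> WavenumberGrid:
    try:
        values = np.array([float(c) for c in cols])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavenumber column: {exc}") from exc
    if values.size < 2 or not np.all(np.diff(values) > 0):
        raise FormatError("wavenumber columns must be strictly increasing")
    return WavenumberGrid(values)


def _read_csv_wide(path) -> SpectrumSet:
    df = pd.read_csv(path, dtype={"composition": str, "source_tag": str,
                                  "sample_id": str, "cocaine_form": str})
    meta_cols = [c for c in _META_COLUMNS if c in df.columns]
    grid_cols = [c for c in df.columns if c not in _META_COLUMNS]
    if not grid_cols:
        raise FormatError("no wavenumber columns found")
    grid = _grid_from_columns(grid_cols)
    mat = df[grid_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(mat)):
        raise FormatError("ragged or non-numeric intensity rows")
    metas = [_meta_from_row(row) for row in df[meta_cols].to_dict("records")]
    return SpectrumSet(grid, mat, metas)


def _write_csv_wide(sset: SpectrumSet, path) -> None:
    rows = [_meta_to_row(m) for m in sset.metas]
    meta_df = pd.DataFrame(rows, columns=_META_COLUMNS)
    # 10 decimals: 4 would alias grids distinct at the 1e-6 match tolerance
    grid_cols = [f"{w:.10f}" for w in sset.grid.values]
    spec_df = pd.DataFrame(sset.matrix, columns=grid_cols)
    pd.concat([meta_df, spec_df.set_index(meta_df.index)], axis=1).to_csv(
        path, index=False, float_format="%.12g")


def _read_csv_long(path) -> SpectrumSet:
    df = pd.read_csv(path, dtype={"composition": str, "source_tag": str,
                                  "sample_id": str, "cocaine_form": str})
    needed = {"sample_id", "replicate", "wavenumber", "intensity"}
    if not needed.issubset(df.columns):
        raise FormatError(f"csv-long needs columns {sorted(needed)}")
    grids, rows, metas = [], [], []
    for (sid, rep), grp in df.groupby(["sample_id", "replicate"], sort=False):
        grp = grp.sort_values("wavenumber")
        grids.append(grp["wavenumber"].to_numpy(dtype=float))
        rows.append(grp["intensity"].to_numpy(dtype=float))
        metas.append(_meta_from_row(grp.iloc[0].to_dict()))
    if not rows:
        raise FormatError("empty csv-long table")
    lengths = {len(g) for g in grids}
    if len(lengths) != 1:
        raise FormatError("ragged spectra: unequal point counts per scan")
    ref = grids[0]
    for g in grids[1:]:
        if np.max(np.abs(g - ref)) >= GRID_MATCH_TOL:
            raise FormatError("spectra in one file must share a grid")
    if not np.all(np.diff(ref) > 0):
        raise FormatError("wavenumbers must be strictly increasing")
    return SpectrumSet(WavenumberGrid(ref), np.vstack(rows), metas)


def _write_csv_long(sset: SpectrumSet, path) -> None:
    frames = []
    for i, meta in enumerate(sset.metas):
        row = _meta_to_row(meta)
        frames.append(pd.DataFrame({
            "sample_id": row["sample_id"],
            "replicate": row["replicate"],
            "wavenumber": sset.grid.values,
            "intensity": sset.matrix[i],
            "cocaine_wt_pct": row["cocaine_wt_pct"],
            "cocaine_form": row["cocaine_form"],
            "composition": row["composition"],
            "source_tag": row["source_tag"],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.12g")


# -- JCAMP-DX (AFFN only) ----------------------------------------------------

def _read_jcamp(path) -> SpectrumSet:
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    blocks, current = [], None
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.upper().startswith("##TITLE="):
            current = {"labels": {}, "ydata": [], "in_table": False}
            blocks.append(current)
        if current is None:
            raise FormatError("data before ##TITLE block")
        if line.startswith("##"):
            label, _, value = line[2:].partition("=")
            label = label.strip().upper().replace(" ", "")
            value = value.strip()
            current["in_table"] = label == "XYDATA"
            current["labels"][label] = value
            continue
        if line.startswith("$$"):
            continue
        if current["in_table"]:
            tokens = line.replace(",", " ").split()
            try:
                vals = [float(t) for t in tokens]
            except ValueError as exc:
                raise FormatError(
                    f"non-AFFN token in XYDATA line {line!r}") from exc
            # first token is the line's X start; the rest are Y values
            current["ydata"].append(vals[1:])

    if not blocks:
        raise FormatError("no JCAMP-DX blocks found")
    grids, rows, metas = [], [], []
    for blk in blocks:
        lab = blk["labels"]
        xunits = lab.get("XUNITS", "1/CM").upper()
        if xunits not in ("1/CM", "CM-1", "CM^-1"):
            raise FormatError(f"unsupported XUNITS {xunits!r}")
        try:
            firstx = float(lab["FIRSTX"])
            lastx = float(lab["LASTX"])
            npoints = int(float(lab["NPOINTS"]))
        except KeyError as exc:
            raise FormatError(f"missing JCAMP label {exc}") from exc
        xfactor = float(lab.get("XFACTOR", 1.0))
        yfactor = float(lab.get("YFACTOR", 1.0))
        y = np.array([v for chunk in blk["ydata"] for v in chunk]) * yfactor
        if y.size != npoints:
            raise FormatError(
                f"NPOINTS={npoints} but table holds {y.size} values")
        x = np.linspace(firstx * xfactor, lastx * xfactor, npoints)
        if x[0] >= x[-1]:
            raise FormatError("descending JCAMP grids are not supported")
        grids.append(x)
        rows.append(y)
        metas.append(_meta_from_row({
            "sample_id": lab.get("TITLE", "unknown"),
            "replicate": lab.get("$REPLICATE", 1),
            "cocaine_wt_pct": lab.get("$COCAINEWTPCT", 0.0),
            "cocaine_form": lab.get("$COCAINEFORM", "none"),
            "composition": lab.get("$COMPOSITION", ""),
            "source_tag": lab.get("$SOURCETAG", ""),
        }))
    ref = grids[0]
    for g in grids[1:]:
        if g.size != ref.size or np.max(np.abs(g - ref)) >= GRID_MATCH_TOL:
            raise FormatError("JCAMP blocks in one file must share a grid")
    return SpectrumSet(WavenumberGrid(ref), np.vstack(rows), metas)


def _write_jcamp(sset: SpectrumSet, path) -> None:
    lines: list[str] = []
    grid = sset.grid.values
    for i, meta in enumerate(sset.metas):
        row = _meta_to_row(meta)
        lines += [
            f"##TITLE={row['sample_id']}",
            "##JCAMP-DX=4.24",
            "##DATA TYPE=RAMAN SPECTRUM",
            f"##$REPLICATE={row['replicate']}",
            f"##$COCAINEWTPCT={row['cocaine_wt_pct']!r}",
            f"##$COCAINEFORM={row['cocaine_form']}",
            f"##$COMPOSITION={row['composition']}",
            f"##$SOURCETAG={row['source_tag']}",
            "##XUNITS=1/CM",
            "##YUNITS=ARBITRARY UNITS",
            "##XFACTOR=1.0",
            "##YFACTOR=1.0",
            f"##FIRSTX={float(grid[0])!r}",
            f"##LASTX={float(grid[-1])!r}",
            f"##NPOINTS={grid.size}",
            "##XYDATA=(X++(Y..Y))",
        ]
        y = sset.matrix[i]
        for start in range(0, grid.size, 6):
            chunk = y[start:start + 6]
            lines.append(" ".join([repr(float(grid[start]))] +
                                  [repr(float(v)) for v in chunk]))
        lines.append("##END=")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


_READERS = {"csv-wide": _read_csv_wide, "csv-long": _read_csv_long,
            "jcamp-dx": _read_jcamp}
_WRITERS = {"csv-wide": _write_csv_wide, "csv-long": _write_csv_long,
            "jcamp-dx": _write_jcamp}


def read_spectrum_table(path, format: str = "csv-wide") -> SpectrumSet:
    """Read a labeled spectrum set; see module docstring for dialects."""
    try:
        reader = _READERS[format]
    except KeyError:
        raise UsageError(f"unknown format {format!r}; "
                         f"choose from {sorted(_READERS)}") from None
    return reader(path)


def write_spectrum_table(sset: SpectrumSet, path,
                         format: str = "csv-wide") -> None:
    """Write a labeled spectrum set; round-trips through read_spectrum_table."""
    try:
        writer = _WRITERS[format]
    except KeyError:
        raise UsageError(f"unknown format {format!r}; "
                         f"choose from {sorted(_WRITERS)}") from None
    writer(sset, path)
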