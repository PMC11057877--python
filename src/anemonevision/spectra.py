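"""Canonical spectrum container, file I/O, resampling and integration.

Every downstream stage (pigment fitting, quantum-catch integration, stimulus
design) works on wavelength-indexed curves sampled on a common grid.  The
container is deliberately thin: a pair of numpy arrays with validation, plus
the handful of numerical operations the colour model needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

SpectrumKind = Literal["radiance", "absorbance", "transmittance"]

_KINDS = ("radiance", "absorbance", "transmittance")


class SpectrumError(ValueError):
    """Raised for malformed or physically invalid spectral data."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nm.

    The default spans 300-700 nm at 1 nm, covering the visual range of a
    UV-sensitive reef fish; 1 nm resolves every LED and pigment-template
    feature used here.
    """

    start: float = 300.0
    stop: float = 700.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise SpectrumError(f"grid start {self.start} must be < stop {self.stop}")
        if self.step <= 0:
            raise SpectrumError(f"grid step must be positive, got {self.step}")

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)


DEFAULT_GRID = WavelengthGrid()


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed curve: radiance, absorbance or transmittance.

    Radiance is quantal (photons s^-1 cm^-2 nm^-1), absorbance is in
    normalised arbitrary units, transmittance is a fraction in [0, 1].
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: SpectrumKind = "radiance"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if self.kind not in _KINDS:
            raise SpectrumError(f"unknown spectrum kind {self.kind!r}")
        if wl.ndim != 1 or vals.ndim != 1 or wl.shape != vals.shape:
            raise SpectrumError("wavelengths and values must be 1-D arrays of equal length")
        if wl.size < 2:
            raise SpectrumError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(vals)):
            raise SpectrumError("spectrum contains non-finite entries")
        if np.any(np.diff(wl) <= 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        if np.any(vals < 0):
            raise SpectrumError("spectral values must be non-negative")
        if self.kind == "transmittance" and np.any(vals > 1.0 + 1e-9):
            raise SpectrumError("transmittance values must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def with_values(self, values: np.ndarray) -> "Spectrum":
        return Spectrum(self.wavelengths, values, self.kind)

    def value_at(self, wavelength: float) -> float:
        """Linearly interpolated value at one wavelength (must be in range)."""
        wl = self.wavelengths
        if not (wl[0] <= wavelength <= wl[-1]):
            raise SpectrumError(f"{wavelength} nm outside spectrum range [{wl[0]}, {wl[-1]}]")
        return float(np.interp(wavelength, wl, self.values))


def read_spectrum(path: str | Path, kind: SpectrumKind = "radiance") -> Spectrum:
    """Read a two-column delimited text file (wavelength nm, value).

    Accepts comma, tab or whitespace delimiters; '#' comment lines and a
    single non-numeric header row are permitted.  Parse failures report the
    offending line number.
    """
    path = Path(path)
    wavelengths: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").replace("\t", " ").split()
            if len(parts) < 2:
                raise SpectrumError(f"{path}:{lineno}: expected two columns, got {raw!r}")
            try:
                wl, val = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1 or (not wavelengths and lineno <= 2):
                    continue  # header row
                raise SpectrumError(f"{path}:{lineno}: non-numeric row {raw!r}") from None
            wavelengths.append(wl)
            values.append(val)
    if len(wavelengths) < 2:
        raise SpectrumError(f"{path}: fewer than 2 data rows")
    wl_arr = np.array(wavelengths)
    if np.any(np.diff(wl_arr) == 0):
        raise SpectrumError(f"{path}: duplicate wavelengths")
    if np.any(np.diff(wl_arr) < 0):
        raise SpectrumError(f"{path}: wavelengths not monotonically increasing")
    try:
        return Spectrum(wl_arr, np.array(values), kind)
    except SpectrumError as err:
        raise SpectrumError(f"{path}: {err}") from None


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    """Write a spectrum as 2-column CSV (wavelength_nm, value)."""
    arr = np.column_stack([s.wavelengths, s.values])
    np.savetxt(path, arr, delimiter=",", header="wavelength_nm,value", comments="# ")


def resample(
    s: Spectrum,
    grid: WavelengthGrid = DEFAULT_GRID,
    *,
    fill_zero: bool = False,
) -> Spectrum:
    """Linearly interpolate a spectrum onto a uniform grid.

    By default the grid must lie within the source range; extrapolation is an
    error because it silently hides calibration problems.  ``fill_zero=True``
    pads out-of-range wavelengths with zero (appropriate for emission spectra
    that genuinely end before the grid does).
    """
    wl = grid.wavelengths
    src = s.wavelengths
    if (wl[0] < src[0] - 1e-9 or wl[-1] > src[-1] + 1e-9) and not fill_zero:
        raise SpectrumError(
            f"grid [{wl[0]}, {wl[-1]}] exceeds source range [{src[0]}, {src[-1]}]; "
            "pass fill_zero=True to pad with zeros"
        )
    vals = np.interp(wl, src, s.values, left=0.0, right=0.0)
    return Spectrum(wl, vals, s.kind)


def normalise(
    s: Spectrum,
    mode: Literal["max", "at-wavelength"] = "max",
    wavelength: float | None = None,
) -> Spectrum:
    """Scale a spectrum by its maximum, or by its value at one wavelength.

    ``at-wavelength`` is used for lens transmission curves, which are
    conventionally scaled to their transmission at 700 nm.
    """
    if mode == "max":
        const = float(np.max(s.values))
    elif mode == "at-wavelength":
        if wavelength is None:
            raise SpectrumError("at-wavelength normalisation needs a wavelength")
        const = s.value_at(wavelength)
    else:
        raise SpectrumError(f"unknown normalisation mode {mode!r}")
    if const <= 0:
        raise SpectrumError(f"normalising constant must be positive, got {const}")
    vals = s.values / const
    if s.kind == "transmittance":
        vals = np.clip(vals, 0.0, 1.0)
    return s.with_values(vals)


def integrate_product(a: Spectrum, b: Spectrum, grid: WavelengthGrid = DEFAULT_GRID) -> float:
    """Trapezoidal integral of the pointwise product of two spectra on a grid.

    This is the quantum-catch integrand: stimulus radiance times receptor
    sensitivity, integrated over the visual range.
    """
    wl = grid.wavelengths
    for name, s in (("a", a), ("b", b)):
        if s.wavelengths.shape != wl.shape or not np.allclose(s.wavelengths, wl):
            raise SpectrumError(f"spectrum {name!r} is not sampled on the integration grid")
    return float(np.trapezoid(a.values * b.values, wl))
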