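"""Visual-pigment template fitting, scan binning, and lens transmission.

λmax of a photoreceptor's visual pigment is estimated from a normalised
absorbance scan the way microspectrophotometry (MSP) labs do it: a straight
line is regressed through the long-wavelength limb between 30% and 70% of
peak absorbance, the wavelength at 50% absorbance is read off that line, and
the Govardovskii et al. (2000) A1 or A2 rhodopsin template is inverted to
find the λmax whose template has its long-limb half-maximum at that
wavelength.  The half-maximum point is used because the limb is the steepest,
least noise-sensitive part of the curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from .spectra import DEFAULT_GRID, Spectrum, SpectrumError, WavelengthGrid

Chromophore = Literal["A1", "A2"]

#: Validity range of the rhodopsin templates (nm).
LAMBDA_MAX_RANGE = (330.0, 600.0)


class PigmentError(ValueError):
    """Raised when a scan cannot support a pigment fit."""


@dataclass(frozen=True)
class PigmentScan:
    """One absorbance scan of a photoreceptor outer segment."""

    absorbance: Spectrum
    cell_id: str = ""
    fish_id: str = ""


@dataclass(frozen=True)
class PigmentFit:
    """Template fit of one scan: λmax, chromophore, and fit diagnostics."""

    lambda_max: float
    chromophore: Chromophore
    lambda_50: float
    rss: float
    n_points_used: int

    def __post_init__(self) -> None:
        if not self.lambda_max < self.lambda_50:
            raise PigmentError(
                "the 50% point must lie on the long-wavelength limb "
                f"(λmax={self.lambda_max}, λ50={self.lambda_50})"
            )


@dataclass(frozen=True)
class LensProfile:
    """Ocular lens transmission normalised at 700 nm, summarised by T50."""

    transmittance: Spectrum
    t50: float


# Govardovskii et al. (2000) template coefficients.  The alpha band is
# S(x) = 1 / (exp[A(a-x)] + exp[B(b-x)] + exp[C(c-x)] + D) with x = λmax/λ;
# the beta band is a Gaussian in λ.  A2 pigments (3,4-didehydroretinal
# chromophore) have broader curves than A1 (retinal).

def _alpha_band(wl: np.ndarray, lmax: float, chromophore: Chromophore) -> np.ndarray:
    x = lmax / wl
    if chromophore == "A1":
        a = 0.8795 + 0.0459 * np.exp(-((lmax - 300.0) ** 2) / 11940.0)
        A, B, b, C, c, D = 69.7, 28.0, 0.922, -14.9, 1.104, 0.674
    else:
        a = 0.875 + 0.0268 * np.exp((lmax - 665.0) / 40.7)
        A = 62.7 + 1.834 * np.exp((lmax - 625.0) / 54.2)
        B, b, C, c, D = 20.85, 0.9101, -10.37, 1.1123, 0.5343
    return 1.0 / (np.exp(A * (a - x)) + np.exp(B * (b - x)) + np.exp(C * (c - x)) + D)


def _beta_band(wl: np.ndarray, lmax: float, chromophore: Chromophore) -> np.ndarray:
    if chromophore == "A1":
        A_beta = 0.26
        lm_beta = 189.0 + 0.315 * lmax
        bw = -40.5 + 0.195 * lmax
    else:
        A_beta = 0.37
        lm_beta = 216.7 + 0.287 * lmax
        bw = 317.0 - 1.149 * lmax + 0.00124 * lmax**2
    return A_beta * np.exp(-(((wl - lm_beta) / bw) ** 2))


def _template_values(wl: np.ndarray, lmax: float, chromophore: Chromophore) -> np.ndarray:
    return _alpha_band(wl, lmax, chromophore) + _beta_band(wl, lmax, chromophore)


def pigment_template(
    lambda_max: float,
    chromophore: Chromophore = "A1",
    grid: WavelengthGrid = DEFAULT_GRID,
) -> Spectrum:
    """Normalised absorbance template (alpha + beta band) peaking at λmax."""
    if chromophore not in ("A1", "A2"):
        raise PigmentError(f"unknown chromophore {chromophore!r}")
    lo, hi = LAMBDA_MAX_RANGE
    if not lo <= lambda_max <= hi:
        raise PigmentError(f"λmax {lambda_max} nm outside template validity [{lo}, {hi}]")
    wl = grid.wavelengths
    vals = _template_values(wl, lambda_max, chromophore)
    vals = vals / vals.max()
    return Spectrum(wl, vals, "absorbance")


def _template_lambda_50(lmax: float, chromophore: Chromophore) -> float:
    """Wavelength on the long-wavelength limb where the template crosses 0.5."""
    peak = _template_values(np.array([lmax]), lmax, chromophore)[0]

    def f(wl: float) -> float:
        return _template_values(np.array([wl]), lmax, chromophore)[0] / peak - 0.5

    return brentq(f, lmax, lmax + 250.0, xtol=1e-4)


def estimate_lambda_max(
    scan: PigmentScan | Spectrum,
    chromophore: Chromophore | Literal["auto"] = "auto",
    *,
    smooth: bool = False,
) -> PigmentFit:
    """Estimate λmax from an absorbance scan via long-limb regression.

    Steps: normalise the scan to peak 1; keep wavelengths beyond the peak;
    regress absorbance on wavelength over the points with normalised
    absorbance in [0.3, 0.7]; read λ50 from the regression line; invert the
    template's long-limb 50% crossing by bisection (0.01 nm tolerance).
    Under ``auto`` both chromophore templates are fitted and the one with
    lower full-curve residual sum of squares is kept.

    The peak height and location are estimated from an 11-point local
    average of the scan: the raw maximum of a noisy scan is biased high by
    extreme-value noise, which would deflate the normalised limb and bias
    λmax short.  The regression itself always uses the raw values;
    ``smooth=True`` additionally applies a 5 nm boxcar to them.
    """
    spec = scan.absorbance if isinstance(scan, PigmentScan) else scan
    vals = spec.values
    if smooth:
        kernel = np.ones(5) / 5.0
        vals = np.convolve(vals, kernel, mode="same")
    window = min(11, 2 * (vals.size // 2) - 1)
    smoothed = np.convolve(vals, np.ones(window) / window, mode="same")
    peak = smoothed.max()
    if peak <= 0:
        raise PigmentError("scan has no positive absorbance")
    norm = vals / peak
    wl = spec.wavelengths

    i_peak = int(np.argmax(smoothed))
    limb = norm[i_peak + 1 :]
    limb_wl = wl[i_peak + 1 :]
    band = (limb >= 0.3) & (limb <= 0.7)
    n_band = int(band.sum())
    if n_band < 3:
        raise PigmentError(f"only {n_band} points in the 30-70% long-limb band (need >= 3)")

    slope, intercept = np.polyfit(limb_wl[band], limb[band], 1)
    if slope >= 0:
        raise PigmentError("long-wavelength limb is not descending")
    lambda_50 = (0.5 - intercept) / slope

    candidates: Sequence[Chromophore]
    candidates = ("A1", "A2") if chromophore == "auto" else (chromophore,)
    best: PigmentFit | None = None
    for chrom in candidates:
        lmax = _invert_lambda_50(lambda_50, chrom)
        template = pigment_template(lmax, chrom, WavelengthGrid(wl[0], wl[-1], 1.0))
        tvals = np.interp(wl, template.wavelengths, template.values)
        rss = float(np.sum((norm - tvals) ** 2))
        fit = PigmentFit(lmax, chrom, lambda_50, rss, n_band)
        if best is None or rss < best.rss:
            best = fit
    assert best is not None
    return best


def _invert_lambda_50(lambda_50: float, chromophore: Chromophore) -> float:
    """Find the λmax whose template has its long-limb half maximum at λ50."""
    lo, hi = LAMBDA_MAX_RANGE

    def g(lmax: float) -> float:
        return _template_lambda_50(lmax, chromophore) - lambda_50

    g_lo, g_hi = g(lo), g(hi)
    if g_lo * g_hi > 0:
        raise PigmentError(
            f"λ50={lambda_50:.1f} nm cannot be bracketed by templates with "
            f"λmax in [{lo}, {hi}]"
        )
    return brentq(g, lo, hi, xtol=0.01)


def bin_scans(
    fits: Sequence[tuple[PigmentScan, PigmentFit]],
    max_gap: float = 10.0,
) -> list[PigmentFit]:
    """Group scans whose λmax differ by <= ``max_gap`` nm and refit bin means.

    Grouping is single linkage: scans chain into one bin whenever adjacent
    λmax estimates (in sorted order) are within the gap.  Within each bin the
    normalised absorbance spectra are averaged, renormalised and re-analysed.
    """
    if not fits:
        raise PigmentError("no scans to bin")
    order = np.argsort([f.lambda_max for _, f in fits])
    bins: list[list[tuple[PigmentScan, PigmentFit]]] = [[fits[order[0]]]]
    for idx in order[1:]:
        scan, fit = fits[idx]
        prev_fit = bins[-1][-1][1]
        if fit.lambda_max - prev_fit.lambda_max <= max_gap:
            bins[-1].append((scan, fit))
        else:
            bins.append([(scan, fit)])

    out: list[PigmentFit] = []
    for group in bins:
        if len(group) == 1:
            out.append(group[0][1])
            continue
        wl = group[0][0].absorbance.wavelengths
        stack = []
        for scan, _ in group:
            v = scan.absorbance.values
            vi = np.interp(wl, scan.absorbance.wavelengths, v)
            stack.append(vi / vi.max())
        mean_curve = np.mean(stack, axis=0)
        mean_spec = Spectrum(wl, mean_curve / mean_curve.max(), "absorbance")
        chrom = group[0][1].chromophore
        out.append(estimate_lambda_max(mean_spec, chrom))
    return out


def lens_t50(transmission: Spectrum) -> LensProfile:
    """Locate T50, the wavelength where lens transmission crosses 50%.

    The input must already be normalised to its transmission at 700 nm.  The
    longest-wavelength upward crossing of 0.5 is taken, interpolated linearly
    between the bracketing samples; multiple crossings indicate a noisy or
    non-monotone curve and only the longest-wavelength one is reported.
    """
    wl = transmission.wavelengths
    vals = transmission.values
    below = vals < 0.5
    upward = below[:-1] & ~below[1:]
    idx = np.nonzero(upward)[0]
    if idx.size == 0:
        if np.all(vals >= 0.5) or np.all(vals < 0.5):
            raise PigmentError("transmission curve never crosses 0.5")
        raise PigmentError("no upward crossing of 0.5 found")
    i = int(idx[-1])
    # linear interpolation between the bracketing grid points
    w0, w1 = wl[i], wl[i + 1]
    v0, v1 = vals[i], vals[i + 1]
    t50 = w0 + (0.5 - v0) / (v1 - v0) * (w1 - w0)
    return LensProfile(transmission, float(t50))


def apply_lens(receptor: Spectrum, lens: LensProfile | Spectrum) -> Spectrum:
    """Filter a receptor sensitivity by lens transmission; renormalise to 1."""
    lens_spec = lens.transmittance if isinstance(lens, LensProfile) else lens
    if receptor.wavelengths.shape != lens_spec.wavelengths.shape or not np.allclose(
        receptor.wavelengths, lens_spec.wavelengths
    ):
        raise SpectrumError("receptor and lens must share a wavelength grid")
    product = receptor.values * lens_spec.values
    if product.max() <= 0:
        raise PigmentError("lens-filtered sensitivity is identically zero")
    return Spectrum(receptor.wavelengths, product / product.max(), "absorbance")
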