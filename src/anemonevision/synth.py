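"""Synthetic study generator: display, visual system, MSP scans, choice data.

The generator reproduces the study conditions with known ground truth so the
whole pipeline can be exercised without the original stimulus tables: a
five-channel LED display peaking at 367/395/466/526/629 nm, a tetrachromatic
visual system (cone λmax 386/497/515/535 nm behind a lens with T50 334 nm,
σ 0.11 for the single cone and 0.14 for double cones, cone ratio 1:2:1:1),
nine colour lines radiating from grey, 13 grey distractors, and binomial
choice data drawn from planted sigmoid psychometric functions.

True LED line shapes and the screen radiance were never published, so the
channels are Gaussian stand-ins and the background is spectrally flat; both
are declared synthetic, not inferred.  Every generator is a pure function of
(config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .pigments import LensProfile, apply_lens, pigment_template, PigmentScan
from .rnl import RECEPTOR_LABELS, VisualSystem
from .spectra import DEFAULT_GRID, Spectrum, WavelengthGrid
from .stimuli import ColourLine, LedDisplay, build_colour_line, select_grey_set

#: Planted per-set discrimination thresholds (ΔS at P=0.5), the mean
#: thresholds reported for the nine behavioural colour sets.
PLANTED_THRESHOLDS = {
    "blue": 1.5,
    "purple": 1.6,
    "green": 1.2,
    "red": 1.0,
    "orange": 0.8,
    "UV-blue": 0.8,
    "UV": 0.8,
    "violet-green": 0.4,
    "UV-red": 0.9,
}

#: Planted psychometric spreads: the sets reported with steep curves get a
#: small spread, those with gradual curves a larger one.
PLANTED_SPREADS = {
    "blue": 0.3,
    "purple": 0.3,
    "green": 0.3,
    "red": 0.15,
    "orange": 0.15,
    "UV-blue": 0.3,
    "UV": 0.3,
    "violet-green": 0.15,
    "UV-red": 0.15,
}

#: Per-line saturation ceilings (ΔS) where the display gamut runs out
#: before the default depth; the M1-opponent bearing of UV-blue is the
#: shallowest direction of the five-primary gamut.
LINE_MAX_DS = {
    "UV-blue": 1.2,
}

#: Targets per colour line, as tested behaviourally.
LINE_COUNTS = {
    "UV": 10,
    "UV-blue": 6,
    "blue": 9,
    "green": 9,
    "red": 9,
    "violet-green": 9,
    "purple": 6,
    "UV-red": 11,
    "orange": 7,
}

#: Hue directions (elevation Θ, azimuth φ in degrees) of the nine colour
#: lines in noise-corrected space.  Published threshold elevations are used
#: directly; azimuths are printed only for the two complementary pairs, so
#: the remaining bearings are synthetic stand-ins consistent with each set's
#: LED composition (e.g. red along +x, UV-red between +x and the UV pole)
#: and spread across the double-cone plane so the nine lines jointly sample
#: all opponent directions — UV-blue sits near the M1-opponent bearing,
#: where the display gamut is shallow but tri- vs tetrachromat models
#: differ most.
LINE_ANGLES = {
    "UV": (81.0, 127.0),
    "violet-green": (65.0, 298.0),
    "UV-red": (71.0, 10.0),
    "UV-blue": (10.0, 105.0),
    "blue": (-45.0, 150.0),
    "green": (-78.0, 297.0),
    "red": (-4.0, 0.0),
    "orange": (6.0, 335.0),
    "purple": (-58.0, 128.0),
}


def direction_from_angles(theta: float, phi: float) -> np.ndarray:
    """Unit xyz vector at elevation Θ and azimuth φ (degrees)."""
    th, ph = np.radians(theta), np.radians(phi)
    return np.array(
        [np.cos(th) * np.cos(ph), np.cos(th) * np.sin(ph), np.sin(th)]
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of the synthetic study."""

    led_peaks: tuple[float, ...] = (367.0, 395.0, 466.0, 526.0, 629.0)
    led_fwhm: float = 20.0
    led_peak_radiance: float = 400.0
    background_radiance: float = 1.0
    cone_lambda_max: tuple[float, ...] = (386.0, 497.0, 515.0, 535.0)
    lens_t50: float = 334.0
    lens_slope: float = 0.1  # logistic steepness, nm^-1
    sigma_single: float = 0.11
    sigma_double: float = 0.14
    cone_ratio: tuple[float, ...] = (1.0, 2.0, 1.0, 1.0)
    n_greys: int = 13
    trials_per_level: int = 10
    fish_per_set: int = 5
    guess: float = 0.0
    lapse: float = 0.0
    seed: int = 0


def gen_led_display(
    cfg: SyntheticConfig = SyntheticConfig(), grid: WavelengthGrid = DEFAULT_GRID
) -> LedDisplay:
    """Gaussian LED channels at the configured peaks plus a flat background.

    The background stands in for the diffusing screen under ambient light; it
    is strictly positive across the grid so every quantum catch is defined.
    """
    wl = grid.wavelengths
    sd = cfg.led_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    channels = tuple(
        Spectrum(
            wl,
            cfg.led_peak_radiance * np.exp(-0.5 * ((wl - peak) / sd) ** 2),
            "radiance",
        )
        for peak in cfg.led_peaks
    )
    background = Spectrum(wl, np.full_like(wl, cfg.background_radiance), "radiance")
    return LedDisplay(channels, background)


def gen_lens(cfg: SyntheticConfig = SyntheticConfig(), grid: WavelengthGrid = DEFAULT_GRID) -> LensProfile:
    """Logistic lens transmission with midpoint at the configured T50."""
    wl = grid.wavelengths
    vals = 1.0 / (1.0 + np.exp(-cfg.lens_slope * (wl - cfg.lens_t50)))
    from .pigments import lens_t50 as _t50

    return _t50(Spectrum(wl, vals, "transmittance"))


def gen_visual_system(
    cfg: SyntheticConfig = SyntheticConfig(), grid: WavelengthGrid = DEFAULT_GRID
) -> VisualSystem:
    """Tetrachromatic visual system: lens-filtered A1 templates plus noise."""
    lens = gen_lens(cfg, grid)
    receptors = tuple(
        apply_lens(pigment_template(lm, "A1", grid), lens) for lm in cfg.cone_lambda_max
    )
    sigma = (cfg.sigma_single,) + (cfg.sigma_double,) * 3
    return VisualSystem(receptors, sigma, cfg.cone_ratio, RECEPTOR_LABELS)


def gen_msp_scans(
    lambda_max: float,
    n: int = 20,
    noise_sd: float = 0.05,
    seed: int = 0,
    *,
    chromophore: str = "A1",
    baseline_drift: float = 0.0,
    grid: WavelengthGrid = DEFAULT_GRID,
    fish_id: str = "synthetic",
) -> list[PigmentScan]:
    """Noisy absorbance scans around a pigment template (seeded).

    Each scan is the template plus independent Gaussian noise per wavelength
    and an optional linear baseline drift, clipped at zero (absorbance is
    non-negative), mimicking single-cell MSP records.
    """
    rng = np.random.default_rng(seed)
    template = pigment_template(lambda_max, chromophore, grid)
    scans = []
    for i in range(n):
        noise = rng.normal(0.0, noise_sd, size=template.values.size) if noise_sd > 0 else 0.0
        drift = 0.0
        if baseline_drift:
            wl = template.wavelengths
            drift = baseline_drift * (wl - wl[0]) / (wl[-1] - wl[0])
        vals = np.clip(template.values + noise + drift, 0.0, None)
        scans.append(
            PigmentScan(Spectrum(template.wavelengths, vals, "absorbance"), f"cell{i}", fish_id)
        )
    return scans


def gen_colour_lines(
    display: LedDisplay,
    vs: VisualSystem,
    *,
    angles: dict[str, tuple[float, float]] | None = None,
    counts: dict[str, int] | None = None,
    planted: dict[str, float] | None = None,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> dict[str, ColourLine]:
    """Build the nine default colour lines inside the display gamut.

    Each line's maximum ΔS is the planted threshold plus 1.5 ΔS (capped at
    3) so the psychometric curve's rise is bracketed by the tested levels.
    """
    angles = angles or LINE_ANGLES
    counts = counts or LINE_COUNTS
    planted = planted or PLANTED_THRESHOLDS
    lines = {}
    for label, (theta, phi) in angles.items():
        max_ds = min(planted.get(label, 1.0) + 1.5, 3.0, LINE_MAX_DS.get(label, np.inf))
        lines[label] = build_colour_line(
            display,
            vs,
            direction_from_angles(theta, phi),
            label=label,
            n=counts.get(label, 8),
            max_ds=max_ds,
            grid=grid,
        )
    return lines


def gen_choice_data(
    lines: dict[str, ColourLine],
    planted_m: dict[str, float] | None = None,
    planted_s: dict[str, float] | None = None,
    *,
    cfg: SyntheticConfig = SyntheticConfig(),
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-trial Bernoulli choice records from planted psychometric curves.

    For every fish assigned to a set, each target level receives
    ``trials_per_level`` trials with success probability
    γ + (1−γ−λ)·logistic((ΔS−m)/s).  ΔS=0 control rows succeed with
    probability γ (zero by default: the fish never pecks a grey control).
    Deterministic under the seed.
    """
    planted_m = planted_m or PLANTED_THRESHOLDS
    planted_s = planted_s or PLANTED_SPREADS
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    rows = []
    fish_counter = 0
    for label, line in lines.items():
        m = planted_m[label]
        s = planted_s.get(label, 0.2)
        if m > line.delta_s.max():
            import warnings

            warnings.warn(
                f"set {label!r}: planted threshold {m} exceeds the line's "
                f"max ΔS {line.delta_s.max():.2f}; threshold unrecoverable by design"
            )
        fish_ids = [f"fish{fish_counter + i:02d}" for i in range(cfg.fish_per_set)]
        fish_counter += cfg.fish_per_set
        for fish in fish_ids:
            for t_idx, ds in enumerate(line.delta_s):
                p = cfg.guess + (1.0 - cfg.guess - cfg.lapse) / (
                    1.0 + np.exp(-(ds - m) / s)
                )
                correct = rng.random(cfg.trials_per_level) < p
                for c in correct:
                    rows.append(
                        {
                            "fish_id": fish,
                            "colour_set": label,
                            "target_id": f"{label}:{t_idx}",
                            "delta_s": float(ds),
                            "correct": int(c),
                            "is_control": 0,
                        }
                    )
            # control trials at zero contrast
            for c in rng.random(2) < cfg.guess:
                rows.append(
                    {
                        "fish_id": fish,
                        "colour_set": label,
                        "target_id": f"{label}:control",
                        "delta_s": 0.0,
                        "correct": int(c),
                        "is_control": 1,
                    }
                )
    return pd.DataFrame(rows)


def build_experiment(
    cfg: SyntheticConfig = SyntheticConfig(), grid: WavelengthGrid = DEFAULT_GRID
) -> dict:
    """Build every in-memory piece of a synthetic experiment.

    Returns a dict with keys display, vs, lines, greys, trials — the inputs
    the analysis stages consume.
    """
    display = gen_led_display(cfg, grid)
    vs = gen_visual_system(cfg, grid)
    lines = gen_colour_lines(display, vs, grid=grid)
    greys = select_grey_set(display, vs, n=cfg.n_greys, seed=cfg.seed, grid=grid)
    trials = gen_choice_data(lines, cfg=cfg, seed=cfg.seed + 1)
    return {
        "display": display,
        "vs": vs,
        "lines": lines,
        "greys": greys,
        "trials": trials,
    }


def generate_experiment(
    out_dir: str | Path,
    cfg: SyntheticConfig = SyntheticConfig(),
    grid: WavelengthGrid = DEFAULT_GRID,
    experiment: dict | None = None,
) -> dict:
    """Write a complete synthetic experiment directory and return its manifest.

    Produces the display spectra, visual-system sensitivities, stimulus
    manifest (weights, ΔS, hue angles), grey set, per-trial choice CSV and a
    ground-truth JSON.  Pass a prebuilt ``experiment`` (from
    `build_experiment`) to avoid regenerating.
    """
    from .spectra import write_spectrum
    from .stimuli import catch_for_weights

    out = Path(out_dir)
    (out / "spectra").mkdir(parents=True, exist_ok=True)
    if experiment is None:
        experiment = build_experiment(cfg, grid)
    display = experiment["display"]
    vs = experiment["vs"]
    lines = experiment["lines"]
    greys = experiment["greys"]
    trials = experiment["trials"]
    for name, ch in zip(display.names, display.channels):
        write_spectrum(ch, out / "spectra" / f"led_{name}.csv")
    write_spectrum(display.background, out / "spectra" / "background.csv")
    for lab, rec in zip(vs.labels, vs.receptors):
        write_spectrum(rec, out / "spectra" / f"receptor_{lab}.csv")

    manifest_rows = []
    for label, line in lines.items():
        for t_idx, (w, ds) in enumerate(zip(line.weights, line.delta_s)):
            row = {"target_id": f"{label}:{t_idx}", "colour_set": label, "delta_s": float(ds)}
            row.update({f"w_{nm}": float(x) for nm, x in zip(display.names, w)})
            q = catch_for_weights(display, vs, w, grid)
            row.update({f"q_{lab}": float(v) for lab, v in zip(vs.labels, q.q)})
            manifest_rows.append(row)
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out / "stimuli.csv", index=False)

    grey_rows = []
    for i, (w, ds) in enumerate(zip(greys.weights, greys.delta_s)):
        row = {"grey_id": f"grey:{i}", "delta_s": float(ds)}
        row.update({f"w_{nm}": float(x) for nm, x in zip(display.names, w)})
        grey_rows.append(row)
    pd.DataFrame(grey_rows).to_csv(out / "greys.csv", index=False)

    trials.to_csv(out / "trials.csv", index=False)

    truth = {
        "config": asdict(cfg),
        "planted_thresholds": PLANTED_THRESHOLDS,
        "planted_spreads": PLANTED_SPREADS,
        "line_angles": {k: list(v) for k, v in LINE_ANGLES.items()},
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return truth
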