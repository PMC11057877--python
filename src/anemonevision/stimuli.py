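"""Five-channel LED display model and stimulus construction.

Stimuli are additive mixtures of five LED primaries (UV 367, violet 395,
blue 466, green 526, red 629 nm) shown on a diffusing screen whose own
radiance — the display with all LEDs off, under ambient light — is the
adapting background.  Colour lines radiate from the achromatic point in a
fixed chromatic direction, increasing in saturation (ΔS) but not hue; grey
distractors are near-achromatic mixtures used as the field the target must
be picked from.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .rnl import (
    QuantumCatchVector,
    VisualSystem,
    noise_corrected_xyz,
    quantum_catch,
    rnl_delta_s,
)
from .spectra import DEFAULT_GRID, Spectrum, WavelengthGrid

LED_CHANNEL_NAMES = ("U367", "V395", "B466", "G526", "R629")


class StimulusError(ValueError):
    """Raised when a stimulus cannot be constructed within the display gamut."""


@dataclass(frozen=True)
class LedDisplay:
    """Five LED radiance channels at full drive, plus the screen background."""

    channels: tuple[Spectrum, ...]
    background: Spectrum
    names: tuple[str, ...] = LED_CHANNEL_NAMES

    def __post_init__(self) -> None:
        if len(self.channels) != 5:
            raise StimulusError(f"expected 5 LED channels, got {len(self.channels)}")

    @property
    def peak_wavelengths(self) -> np.ndarray:
        return np.array(
            [c.wavelengths[int(np.argmax(c.values))] for c in self.channels]
        )


def mix_leds(display: LedDisplay, weights: Sequence[float]) -> Spectrum:
    """Radiance of the screen with the five channels driven at ``weights``.

    Weights in [0, 1] scale each channel linearly; the screen background is
    always present (weights of zero reproduce the background exactly).
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (5,):
        raise StimulusError(f"expected 5 weights, got shape {w.shape}")
    if np.any(w < 0) or np.any(w > 1):
        raise StimulusError(f"weights must lie in [0, 1], got {w}")
    vals = display.background.values + sum(
        wi * ch.values for wi, ch in zip(w, display.channels)
    )
    return Spectrum(display.background.wavelengths, vals, "radiance")


def catch_for_weights(
    display: LedDisplay,
    vs: VisualSystem,
    weights: Sequence[float],
    grid: WavelengthGrid = DEFAULT_GRID,
) -> QuantumCatchVector:
    """Quantum catches of an LED mixture against the screen background."""
    return quantum_catch(mix_leds(display, weights), display.background, vs, grid)


class _CatchModel:
    """Precomputed linear map from LED weights to quantum catches.

    Catches are linear in radiance, so q_i(w) = 1 + Σ_j w_j C_ij with
    C_ij the channel-j catch in receptor i relative to the background catch.
    Identical to integrating the mixed spectrum, but lets the weight solvers
    avoid re-integrating on every evaluation.
    """

    def __init__(self, display: LedDisplay, vs: VisualSystem, grid: WavelengthGrid):
        from .rnl import _chromatic_basis
        from .spectra import integrate_product

        bg = np.array([integrate_product(display.background, r, grid) for r in vs.receptors])
        if np.any(bg <= 0):
            raise StimulusError("background catch is zero in some receptor")
        chan = np.array(
            [
                [integrate_product(ch, r, grid) for ch in display.channels]
                for r in vs.receptors
            ]
        )
        self.C = chan / bg[:, None]
        self.e = vs.noise
        self.basis = _chromatic_basis(self.e)

    def q(self, w: np.ndarray) -> np.ndarray:
        return 1.0 + self.C @ w

    def xyz(self, w: np.ndarray) -> np.ndarray:
        return self.basis @ (np.log(self.q(w)) / self.e)

    def brightness(self, w: np.ndarray) -> float:
        """Achromatic level: mean log catch across receptors."""
        return float(np.mean(np.log(self.q(w))))


def _xyz_of_weights(display, vs, weights, grid) -> np.ndarray:
    return noise_corrected_xyz(catch_for_weights(display, vs, weights, grid), vs=vs).xyz


@dataclass(frozen=True)
class ColourLine:
    """A saturation series: targets at increasing ΔS along one hue direction."""

    label: str
    direction: np.ndarray  # unit vector in noise-corrected xyz space
    weights: np.ndarray  # (n, 5) LED weights
    delta_s: np.ndarray  # (n,) ΔS from the achromatic point

    def __post_init__(self) -> None:
        n = self.delta_s.size
        if not 1 <= n:
            raise StimulusError("a colour line needs at least one target")
        if np.any(np.diff(self.delta_s) <= 0):
            raise StimulusError("ΔS must be strictly increasing along a colour line")

    def __len__(self) -> int:
        return int(self.delta_s.size)


def build_colour_line(
    display: LedDisplay,
    vs: VisualSystem,
    direction: Sequence[float],
    label: str = "",
    n: int = 8,
    max_ds: float = 2.5,
    *,
    grid: WavelengthGrid = DEFAULT_GRID,
    tol: float = 0.02,
    brightness: float | None = 2.0,
) -> ColourLine:
    """Find LED weights placing ``n`` targets on a ray from grey.

    Target loci t·direction for t spanning (0, max_ds] are solved by bounded
    least squares on the 5 LED weights (residual = achieved xyz minus the
    requested locus), warm-starting each level from the previous solution.
    A level whose residual exceeds ``tol`` ΔS means the requested direction
    leaves the display gamut before max_ds.

    The chromatic locus under-determines the 5 weights, so ``brightness``
    (mean log catch) is applied as a soft preference to pin the leftover
    intensity freedom near the middle of the grey-distractor range; pass
    ``None`` to leave intensity wherever the solver lands.
    """
    if max_ds <= 0:
        raise StimulusError("max_ds must be positive")
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise StimulusError("direction must be a nonzero vector")
    d = d / norm

    model = _CatchModel(display, vs, grid)
    levels = np.linspace(max_ds / n, max_ds, n)
    weights = np.zeros((n, 5))
    achieved = np.zeros(n)
    rng = np.random.default_rng(12345)  # deterministic fallback starts
    w0 = np.full(5, 0.01)
    for i, t in enumerate(levels):
        target = t * d

        def residual(w: np.ndarray) -> np.ndarray:
            chroma = model.xyz(w) - target
            if brightness is None:
                return chroma
            return np.append(chroma, 0.2 * (model.brightness(w) - brightness))

        starts = [np.clip(w0, 1e-6, 1 - 1e-6), np.full(5, 0.01), np.full(5, 0.1)]
        starts += [rng.uniform(0.0, 0.3, 5) for _ in range(5)]
        best = None
        best_err = np.inf
        for start in starts:
            sol = least_squares(
                residual, start, bounds=(0.0, 1.0), xtol=1e-12, ftol=1e-12, gtol=1e-12
            )
            err_c = float(np.linalg.norm(sol.fun[:3]))
            if err_c < best_err:
                best, best_err = sol, err_c
            if best_err <= min(tol / 4, 1e-3):
                break
        if best_err > tol and brightness is not None:
            # near the gamut boundary the soft intensity preference can block
            # an otherwise reachable chromatic locus; retry unconstrained
            for start in starts:
                sol = least_squares(
                    lambda w: model.xyz(w) - target,
                    start,
                    bounds=(0.0, 1.0),
                    xtol=1e-12,
                    ftol=1e-12,
                    gtol=1e-12,
                )
                err_c = float(np.linalg.norm(sol.fun[:3]))
                if err_c < best_err:
                    best, best_err = sol, err_c
                if best_err <= min(tol / 4, 1e-3):
                    break
        err = best_err
        if err > tol:
            raise StimulusError(
                f"line {label!r}: level {t:.3f} ΔS unreachable within the gamut "
                f"(residual {err:.3f} ΔS)"
            )
        weights[i] = best.x
        achieved[i] = float(np.linalg.norm(model.xyz(best.x)))
        w0 = np.clip(best.x * (levels[min(i + 1, n - 1)] / t), 0.0, 1.0)
    return ColourLine(label, d, weights, achieved)


def _icosahedral_proposal(rng: np.random.Generator, n: int, shell: float) -> np.ndarray:
    """n jittered loci: a randomly rotated icosahedral shell plus its centre."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    base = []
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            base.append([0.0, s1, s2 * phi])
            base.append([s1, s2 * phi, 0.0])
            base.append([s2 * phi, 0.0, s1])
    verts = np.array(base) / np.sqrt(1.0 + phi**2)
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    pts = np.vstack([np.zeros(3), (verts @ Q.T)]) * shell
    # the centre point sits slightly off origin so its ΔS to grey is > 0
    pts[0] = rng.normal(scale=0.01, size=3)
    jitter = np.clip(rng.normal(scale=0.006, size=pts.shape), -0.012, 0.012)
    return (pts + jitter)[:n]


@dataclass(frozen=True)
class GreySet:
    """Near-achromatic distractor mixtures with controlled mutual spacing."""

    weights: np.ndarray  # (n, 5)
    delta_s: np.ndarray  # (n,) ΔS from the achromatic point

    def __len__(self) -> int:
        return int(self.delta_s.size)


def select_grey_set(
    display: LedDisplay,
    vs: VisualSystem,
    n: int = 13,
    seed: int = 0,
    *,
    max_radius: float = 1.0,
    pair_range: tuple[float, float] = (0.3, 0.8),
    brightness_range: tuple[float, float] = (0.9, 3.3),
    grid: WavelengthGrid = DEFAULT_GRID,
    max_attempts: int = 20000,
) -> GreySet:
    """Sample ``n`` grey distractors near the achromatic point.

    Every grey lies within ``max_radius`` ΔS of the achromatic point and all
    pairwise distances fall in ``pair_range``.  Both bounds together are a
    tight packing (13 points, minimum separation 0.3, diameter <= 0.8), so
    for n <= 13 candidate loci are proposed from a seeded random rotation of
    a jittered icosahedral shell plus a near-centre point — a configuration
    that satisfies the constraints by construction — then solved to LED
    weights and re-verified through the model.  Larger sets fall back to
    greedy rejection sampling.  Deterministic given the seed.

    The greys additionally span ``brightness_range`` (mean log catch) so
    that a target's intensity can later be bracketed by a distractor subset;
    brightness is orthogonal to the chromatic constraints, which concern
    only the xyz loci.
    """
    lo, hi = pair_range
    if lo >= hi:
        raise StimulusError(f"infeasible pairwise range [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    model = _CatchModel(display, vs, grid)
    if n <= 13:
        shell_lo = lo / 1.0515  # icosahedron edge = 1.0515 x circumradius
        shell_hi = min(hi / 2.0, max_radius)
        if shell_lo < shell_hi:
            shell = 0.5 * (shell_lo + shell_hi)
            for attempt in range(40):
                pts = _icosahedral_proposal(rng, n, shell)
                levels = rng.permutation(np.linspace(*brightness_range, n))
                sols = []
                ok = True
                for p, b in zip(pts, levels):

                    def resid(w: np.ndarray, p=p, b=b) -> np.ndarray:
                        return np.append(model.xyz(w) - p, 0.5 * (model.brightness(w) - b))

                    sol = least_squares(
                        resid,
                        np.full(5, 0.02),
                        bounds=(0.0, 1.0),
                        xtol=1e-10,
                        ftol=1e-12,
                    )
                    if float(np.linalg.norm(sol.fun[:3])) > 0.01:
                        ok = False
                        break
                    sols.append(sol.x)
                if not ok:
                    continue
                xyz = np.array([model.xyz(w) for w in sols])
                radii = np.linalg.norm(xyz, axis=1)
                dists = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
                iu = np.triu_indices(n, 1)
                if np.all(radii < max_radius) and np.all(
                    (dists[iu] >= lo) & (dists[iu] <= hi)
                ):
                    return GreySet(np.array(sols), radii)
            raise StimulusError(
                f"grey-set construction failed after 40 proposals "
                f"(radius {max_radius}, pair range {pair_range}); the shell at "
                f"{shell:.2f} ΔS may be unreachable in this gamut"
            )
    ball = min(max_radius, hi / 2.0)  # diameter of sampling ball <= pairwise cap
    margin = 0.02  # solver slack kept inside the hard pairwise bounds
    accepted_xyz: list[np.ndarray] = []
    accepted_w: list[np.ndarray] = []
    attempts = 0
    stall = 0
    w0 = np.full(5, 0.02)
    while attempts < max_attempts and len(accepted_xyz) < n:
        attempts += 1
        # greedy packing can wedge itself; on a long stall evict one point
        if stall > 300 and accepted_xyz:
            drop = int(rng.integers(len(accepted_xyz)))
            accepted_xyz.pop(drop)
            accepted_w.pop(drop)
            stall = 0
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = ball * rng.uniform(0.1, 1.0) ** (1.0 / 3.0)
        target = r * u
        # geometric pre-check before spending a weight solve
        if any(
            not (lo + margin <= np.linalg.norm(target - p) <= hi - margin)
            for p in accepted_xyz
        ):
            stall += 1
            continue

        def residual(w: np.ndarray) -> np.ndarray:
            return model.xyz(w) - target

        sol = least_squares(residual, w0, bounds=(0.0, 1.0), xtol=1e-10, ftol=1e-12)
        if float(np.linalg.norm(sol.fun)) > margin:
            stall += 1
            continue
        xyz = model.xyz(sol.x)
        if np.linalg.norm(xyz) >= max_radius or any(
            not (lo <= np.linalg.norm(xyz - p) <= hi) for p in accepted_xyz
        ):
            stall += 1
            continue
        accepted_xyz.append(xyz)
        accepted_w.append(sol.x)
        stall = 0
    if len(accepted_xyz) < n:
        raise StimulusError(
            f"grey-set sampling found only {len(accepted_xyz)}/{n} greys after "
            f"{max_attempts} attempts (radius {max_radius}, pair range {pair_range}); "
            "the constraints may be jointly infeasible in this gamut"
        )
    xyz_arr = np.array(accepted_xyz)
    return GreySet(np.array(accepted_w), np.linalg.norm(xyz_arr, axis=1))


def average_grey_spectrum(display: LedDisplay, greys: GreySet) -> Spectrum:
    """Mean radiance of the grey distractors — the reference for target ΔS."""
    specs = [mix_leds(display, w).values for w in greys.weights]
    return Spectrum(display.background.wavelengths, np.mean(specs, axis=0), "radiance")


def match_intensity_distractors(
    target_weights: Sequence[float],
    greys: GreySet,
    display: LedDisplay,
    vs: VisualSystem,
    k_range: tuple[int, int] = (6, 10),
    grid: WavelengthGrid = DEFAULT_GRID,
) -> GreySet:
    """Choose the smallest grey subset that brackets the target's intensity.

    For every receptor the target's quantum catch must lie strictly between
    the subset's minimum and maximum catches, so the target is never the
    brightest or dimmest pixel in any channel and cannot be found by an
    achromatic cue.  Subsets of each admissible size are searched
    exhaustively; ties prefer greys closer to the target in ΔS.
    """
    from itertools import combinations

    k_lo, k_hi = k_range
    target_q = catch_for_weights(display, vs, target_weights, grid).q
    grey_q = np.array([catch_for_weights(display, vs, w, grid).q for w in greys.weights])
    target_catch = catch_for_weights(display, vs, target_weights, grid)
    grey_ds = np.array(
        [
            rnl_delta_s(target_catch, catch_for_weights(display, vs, w, grid), vs)
            for w in greys.weights
        ]
    )
    m = len(greys)
    for k in range(k_lo, min(k_hi, m) + 1):
        best: tuple[float, tuple[int, ...]] | None = None
        for combo in combinations(range(m), k):
            sub = grey_q[list(combo)]
            if np.all(sub.min(axis=0) < target_q) and np.all(target_q < sub.max(axis=0)):
                cost = float(grey_ds[list(combo)].sum())
                if best is None or cost < best[0]:
                    best = (cost, combo)
        if best is not None:
            idx = list(best[1])
            return GreySet(greys.weights[idx], greys.delta_s[idx])
    raise StimulusError(
        f"no grey subset of size {k_lo}-{k_hi} brackets the target on all receptors"
    )
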