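"""Receptor-noise-limited (RNL) colour model for 2-4 receptor visual systems.

Colour distances ΔS follow the log-signal Vorobyev-Osorio model: receptor
quantum catches are von Kries adapted to the background, log-transformed, and
compared through opponent differences weighted by per-channel noise
e_i = σ_i / sqrt(η_i), where σ_i is the single-cell Weber-fraction numerator
and η_i the relative abundance of cone class i.  One ΔS nominally equals one
just-noticeable difference.

For a tetrachromat the chromatic signals live in a 3-D subspace; this module
also provides the distance-preserving Cartesian embedding of that subspace
(`noise_corrected_xyz`), spherical hue angles (elevation Θ, azimuth φ),
complementary-pair detection, and non-spectral colour classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .spectra import DEFAULT_GRID, Spectrum, WavelengthGrid, integrate_product

RECEPTOR_LABELS = ("U", "M1", "M2", "L")


class VisualModelError(ValueError):
    """Raised for invalid visual-system configurations or catch vectors."""


def receptor_noise(sigma: Sequence[float], ratio: Sequence[float]) -> np.ndarray:
    """Per-channel noise e_i = σ_i / sqrt(η_i)."""
    sigma = np.asarray(sigma, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    if sigma.shape != ratio.shape:
        raise VisualModelError("sigma and ratio must have the same length")
    if np.any(sigma <= 0) or np.any(ratio <= 0):
        raise VisualModelError("sigma and ratio entries must be positive")
    return sigma / np.sqrt(ratio)


@dataclass(frozen=True)
class VisualSystem:
    """Ordered receptor set with lens-filtered sensitivities and noise.

    Receptors are ordered by increasing λmax (U, M1, M2, L for the full
    tetrachromat).  Systems of 2-4 receptors are supported so dichromat and
    trichromat variants can be compared against the tetrachromat.
    """

    receptors: tuple[Spectrum, ...]
    sigma: tuple[float, ...]
    ratio: tuple[float, ...]
    labels: tuple[str, ...] = RECEPTOR_LABELS

    def __post_init__(self) -> None:
        n = len(self.receptors)
        if not 2 <= n <= 4:
            raise VisualModelError(f"2-4 receptors supported, got {n}")
        if len(self.sigma) != n or len(self.ratio) != n or len(self.labels) != n:
            raise VisualModelError("sigma, ratio and labels must match receptor count")
        peaks = [r.wavelengths[int(np.argmax(r.values))] for r in self.receptors]
        if np.any(np.diff(peaks) <= 0):
            raise VisualModelError("receptors must be ordered by strictly increasing λmax")
        self.noise  # validates positivity

    @property
    def n(self) -> int:
        return len(self.receptors)

    @property
    def noise(self) -> np.ndarray:
        """Derived per-channel noise e_i."""
        return receptor_noise(self.sigma, self.ratio)

    def to_yaml(self, path: str | Path, sensitivity_files: Sequence[str]) -> None:
        cfg = {
            "receptors": [
                {"label": lab, "sensitivity": f, "sigma": s, "ratio": r}
                for lab, f, s, r in zip(self.labels, sensitivity_files, self.sigma, self.ratio)
            ]
        }
        Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def load_visual_system(path: str | Path, grid: WavelengthGrid = DEFAULT_GRID) -> VisualSystem:
    """Load a visual system from a YAML config listing per-receptor files."""
    from .spectra import read_spectrum, resample

    cfg = yaml.safe_load(Path(path).read_text())
    base = Path(path).parent
    receptors, sigma, ratio, labels = [], [], [], []
    for rec in cfg["receptors"]:
        spec = resample(read_spectrum(base / rec["sensitivity"], "absorbance"), grid)
        receptors.append(spec)
        sigma.append(float(rec["sigma"]))
        ratio.append(float(rec["ratio"]))
        labels.append(str(rec["label"]))
    return VisualSystem(tuple(receptors), tuple(sigma), tuple(ratio), tuple(labels))


@dataclass(frozen=True)
class QuantumCatchVector:
    """Background-adapted receptor catches q_i and log-signals f_i = ln q_i."""

    q: np.ndarray
    labels: tuple[str, ...] = RECEPTOR_LABELS

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "q", q)
        if np.any(q <= 0) or not np.all(np.isfinite(q)):
            raise VisualModelError("quantum catches must be positive and finite")

    @property
    def f(self) -> np.ndarray:
        return np.log(self.q)


def quantum_catch(
    stimulus: Spectrum,
    background: Spectrum,
    vs: VisualSystem,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> QuantumCatchVector:
    """Von Kries adapted quantum catches of a stimulus seen against a background.

    q_i = ∫ S(λ) R_i(λ) dλ / ∫ S_b(λ) R_i(λ) dλ — the adapting scale factor
    k_i = 1/∫S_b R_i is applied internally, so the background itself always
    yields q = 1 in every channel.
    """
    q = np.empty(vs.n)
    for i, (rec, lab) in enumerate(zip(vs.receptors, vs.labels)):
        denom = integrate_product(background, rec, grid)
        if denom <= 0:
            raise VisualModelError(f"zero background catch in receptor {lab}")
        num = integrate_product(stimulus, rec, grid)
        if num <= 0:
            raise VisualModelError(f"zero stimulus catch in receptor {lab}")
        q[i] = num / denom
    return QuantumCatchVector(q, vs.labels)


def _delta_s_from_df(df: np.ndarray, e: np.ndarray) -> float:
    # Chromatic Mahalanobis distance: component of Δf orthogonal (in the
    # 1/e^2 metric) to the achromatic direction.  Algebraically identical to
    # the published closed forms for n = 2, 3, 4.  Centring on the weighted
    # mean first avoids the cancellation of the sum-of-squares form.
    w = 1.0 / e**2
    mu = np.sum(w * df) / np.sum(w)
    return float(np.sqrt(np.sum(w * (df - mu) ** 2)))


def rnl_delta_s(
    a: QuantumCatchVector, b: QuantumCatchVector, vs: VisualSystem
) -> float:
    """RNL chromatic distance ΔS between two catch vectors, in JND units.

    Uses the general-n opponent form: the noise-weighted norm of the
    component of Δf orthogonal to the achromatic (uniform) direction.  Pure
    intensity changes therefore give ΔS = 0.
    """
    if a.q.shape != b.q.shape or a.q.size != vs.n:
        raise VisualModelError("catch vectors and visual system disagree on receptor count")
    return _delta_s_from_df(a.f - b.f, vs.noise)


# Opponent contrasts defining the Cartesian axes of the tetrachromatic
# chromaticity space: x ~ L-(M1+M2), y ~ M1-(M2+L), z ~ U-(M1+M2+L).
_AXIS_CONTRASTS = {
    "x": np.array([0.0, -1.0, -1.0, 1.0]),
    "y": np.array([0.0, 1.0, -1.0, -1.0]),
    "z": np.array([1.0, -1.0, -1.0, -1.0]),
}


def _chromatic_basis(e: np.ndarray) -> np.ndarray:
    """Orthonormal basis (rows x, y, z) of the chromatic subspace.

    Works in whitened coordinates u_i = f_i / e_i, where ΔS is the Euclidean
    norm after projecting out the achromatic direction v_i = 1/e_i.  The
    frame is oriented so the three opponent contrasts above project
    positively on +x, +y, +z: z is aligned with the projected UV contrast,
    x with the projected L contrast orthogonalised against z, and y is the
    remaining basis vector with its sign fixed by the M1 contrast.
    """
    v = 1.0 / e
    v = v / np.linalg.norm(v)

    def project(d: np.ndarray) -> np.ndarray:
        u = d / e  # contrast direction mapped into whitened coordinates
        return u - np.dot(u, v) * v

    ez = project(_AXIS_CONTRASTS["z"])
    ez = ez / np.linalg.norm(ez)
    ex = project(_AXIS_CONTRASTS["x"])
    ex = ex - np.dot(ex, ez) * ez
    ex = ex / np.linalg.norm(ex)
    # complete the orthonormal frame in the 3-D chromatic subspace
    M = np.vstack([v, ez, ex])
    _, _, vt = np.linalg.svd(M)
    ey = vt[-1]
    if np.dot(project(_AXIS_CONTRASTS["y"]), ey) < 0:
        ey = -ey
    return np.vstack([ex, ey, ez])


@dataclass(frozen=True)
class ThresholdVector:
    """A colour locus as noise-corrected Cartesian coordinates plus hue angles."""

    xyz: np.ndarray
    theta: float
    phi: float  # NaN when undefined (pole)

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.xyz))


def noise_corrected_xyz(
    c: QuantumCatchVector,
    reference: QuantumCatchVector | None = None,
    vs: VisualSystem | None = None,
) -> ThresholdVector:
    """Map a catch vector to noise-corrected xyz coordinates.

    The embedding is an isometry of the chromatic subspace: the Euclidean
    distance between any two mapped points equals their RNL ΔS, and the
    reference (by default the adapting background, q = 1) maps to the origin.
    Requires a tetrachromatic system.
    """
    if vs is None:
        raise VisualModelError("a VisualSystem is required")
    if vs.n != 4:
        raise VisualModelError("noise-corrected xyz is defined for tetrachromats only")
    if reference is None:
        reference = QuantumCatchVector(np.ones(4), vs.labels)
    e = vs.noise
    basis = _chromatic_basis(e)
    du = (c.f - reference.f) / e
    xyz = basis @ du
    if np.linalg.norm(xyz) == 0:  # the reference itself: angles undefined
        return ThresholdVector(xyz, float("nan"), float("nan"))
    theta, phi = hue_angles_from_xyz(xyz)
    return ThresholdVector(xyz, theta, phi)


def hue_angles_from_xyz(xyz: np.ndarray) -> tuple[float, float]:
    """Elevation Θ and azimuth φ (degrees) of a chromatic vector.

    Θ is the signed angle between the vector and the xy plane (−90..90 deg,
    positive for net UV-cone excitation); φ is the bearing from +x through
    +y, mapped to [0, 360) by adding 360 to negatives.  At the poles
    (x = y = 0) the azimuth is undefined and returned as NaN.
    """
    xyz = np.asarray(xyz, dtype=float)
    r = np.linalg.norm(xyz)
    if r == 0:
        raise VisualModelError("hue angles are undefined for the zero vector")
    x, y, z = xyz
    planar = np.hypot(x, y)
    if planar == 0:
        theta = 90.0 if z > 0 else -90.0
        return theta, float("nan")
    # signed angle between the vector and its xy-plane projection; atan2 is
    # the numerically stable form of the dot-product/arccos construction
    theta = float(np.degrees(np.arctan2(z, planar)))
    phi = float(np.degrees(np.arctan2(y, x)))
    if phi < 0:
        phi += 360.0
    return theta, phi


def hue_angles(v: ThresholdVector | np.ndarray) -> tuple[float, float]:
    """Hue angles of a threshold vector (see `hue_angles_from_xyz`)."""
    xyz = v.xyz if isinstance(v, ThresholdVector) else np.asarray(v, dtype=float)
    return hue_angles_from_xyz(xyz)


def complementary_pairs(
    sets: Sequence[tuple],
    tolerance: float = 15.0,
) -> list[tuple[str, str, float]]:
    """All label pairs whose azimuths sit within ``tolerance`` of 180° apart.

    Complementary colours lie on opposite sides of the achromatic point, so
    their azimuths differ by ~180°.  Entries are (label, phi) or
    (label, phi, theta); when both elevations are supplied the pair must
    also straddle the double-cone plane (opposite Θ signs) — two colours on
    the same side of grey cannot mix to grey however polar their bearings.
    Returns (label_a, label_b, |Δφ−180|) sorted by closeness to exact
    polarity; a label may appear in several candidate pairs.
    """
    if not 0 < tolerance < 90:
        raise VisualModelError(f"tolerance must be in (0, 90) deg, got {tolerance}")
    pairs = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            la, pa, *ta = sets[i]
            lb, pb, *tb = sets[j]
            d = abs(pa - pb) % 360.0
            d = min(d, 360.0 - d)  # circular separation in [0, 180]
            dev = abs(d - 180.0)
            if dev > tolerance:
                continue
            if ta and tb and ta[0] * tb[0] > 0:
                continue  # same side of the xy plane
            pairs.append((la, lb, dev))
    return sorted(pairs, key=lambda p: p[2])


def classify_non_spectral(c: QuantumCatchVector) -> bool:
    """True if the stimulus excites non-adjacent receptors above an intermediate.

    With receptors ordered by λmax, a non-spectral colour (e.g. UV-red, the
    fish equivalent of human purple) stimulates classes on both sides of some
    intermediate class more strongly than that class, and so cannot be
    matched by any monochromatic light mixed with grey.
    """
    q = c.q
    n = q.size
    if n < 3:
        raise VisualModelError("non-spectral classification needs >= 3 receptors")
    for j in range(1, n - 1):
        if np.any(q[:j] > q[j]) and np.any(q[j + 1 :] > q[j]):
            return True
    return False
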