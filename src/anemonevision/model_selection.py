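"""Visual-model selection: σ grid scan and tri- vs tetrachromat comparison.

The behavioural thresholds are expressed in ΔS units, but ΔS itself depends
on the assumed visual model (which receptors contribute, and how noisy each
class is).  If the model is right, thresholds should sit near 1 ΔS — one
just-noticeable difference.  The scan therefore recomputes every target's ΔS
under each candidate model (the full tetrachromat and each drop-one
trichromat, over a grid of single-cone and double-cone σ values), refits the
psychometric curves on the rescaled axis, and ranks models by the mean
absolute deviation of per-set thresholds from 1 ΔS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .rnl import VisualSystem, _delta_s_from_df, receptor_noise
from .psychometric import PsychometricError, fit_counts

#: Default σ grid scanned jointly for single- and double-cone classes.
SIGMA_GRID = tuple(np.round(np.arange(0.05, 0.1501, 0.01), 2))


class ModelComparisonError(ValueError):
    """Raised for invalid model variants or unusable scan inputs."""


@dataclass(frozen=True)
class ModelVariant:
    """A candidate visual model: receptor subset plus class σ values."""

    drop: str | None  # receptor label removed, or None for the tetrachromat
    sigma_single: float
    sigma_double: float

    @property
    def name(self) -> str:
        return "tetrachromat" if self.drop is None else f"trichromat-no-{self.drop}"


def build_variant(
    vs: VisualSystem,
    drop: str | None,
    sigma_single: float,
    sigma_double: float,
) -> VisualSystem:
    """Visual system with one receptor removed and σ reassigned by class.

    The single-cone class (U) takes ``sigma_single``; all double-cone
    classes take ``sigma_double``.  Remaining cone-ratio entries are kept
    unchanged (not renormalised) so each surviving class keeps its noise
    e_i = σ_i/√η_i.
    """
    labels = list(vs.labels)
    if drop is not None:
        if drop not in labels:
            raise ModelComparisonError(f"unknown receptor label {drop!r}; have {labels}")
        keep = [i for i, lab in enumerate(labels) if lab != drop]
    else:
        keep = list(range(vs.n))
    if len(keep) < 3:
        raise ModelComparisonError("cannot drop below 3 receptors")
    sigma = tuple(
        sigma_single if vs.labels[i] == "U" else sigma_double for i in keep
    )
    return VisualSystem(
        receptors=tuple(vs.receptors[i] for i in keep),
        sigma=sigma,
        ratio=tuple(vs.ratio[i] for i in keep),
        labels=tuple(vs.labels[i] for i in keep),
    )


def deviation_metric(thresholds: Sequence[float]) -> float:
    """Mean absolute deviation of per-colour-set thresholds from 1 ΔS."""
    thr = np.asarray(list(thresholds), dtype=float)
    if thr.size == 0:
        raise ModelComparisonError("no thresholds to score")
    return float(np.mean(np.abs(thr - 1.0)))


def _delta_s_batch(delta_f: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Row-wise RNL ΔS for a (n_stimuli, n_receptors) Δf matrix."""
    w = 1.0 / e**2
    sq = delta_f**2 @ w - (delta_f @ w) ** 2 / w.sum()
    return np.sqrt(np.clip(sq, 0.0, None))


def _target_delta_f(
    target_catches: pd.DataFrame,
    reference_catches: np.ndarray,
    labels: Sequence[str],
) -> np.ndarray:
    """Δf (log catch difference to the distractor mean) per target, per receptor."""
    q = target_catches[list(labels)].to_numpy(dtype=float)
    return np.log(q) - np.log(np.asarray(reference_catches, dtype=float))


def scan_models(
    trials: pd.DataFrame,
    target_catches: pd.DataFrame,
    reference_catches: dict[str, float],
    vs: VisualSystem,
    sigma_grid: Sequence[float] = SIGMA_GRID,
    drops: Sequence[str | None] = (None, "U", "M1", "M2", "L"),
    *,
    guess: float = 0.0,
    n_starts: int = 3,
) -> pd.DataFrame:
    """Rank candidate visual models by threshold deviation from 1 ΔS.

    Parameters
    ----------
    trials
        Per-trial rows (fish_id, colour_set, target_id, correct).  Control
        rows (no target_id / ΔS 0) must already be excluded.
    target_catches
        One row per target_id with columns colour_set and one quantum-catch
        column per receptor label of ``vs`` (catches against the adapting
        background).  ΔS under each candidate model is recomputed from these
        catches, so the scan never trusts the ΔS the experiment was designed
        with.
    reference_catches
        Quantum catches of the average grey distractor, keyed by receptor
        label.
    vs
        The full tetrachromatic system supplying the receptor sensitivities.

    Returns a DataFrame with one row per (variant, σ_single, σ_double),
    sorted ascending by the deviation metric; ``flagged`` counts fish × set
    fits that failed or produced degenerate ΔS axes.
    """
    sigma_grid = [float(s) for s in sigma_grid]
    ref = np.array([reference_catches[lab] for lab in vs.labels], dtype=float)
    delta_f_full = _target_delta_f(target_catches, ref, vs.labels)  # (n_targets, 4)
    target_ids = target_catches.index.to_numpy()
    id_to_row = {tid: i for i, tid in enumerate(target_ids)}
    target_set = target_catches["colour_set"]

    # Pre-aggregate choice counts per (fish, colour_set, target): these never
    # change across the scan; only the ΔS assigned to each target does.
    counts = (
        trials.groupby(["fish_id", "colour_set", "target_id"])["correct"]
        .agg(["size", "sum"])
        .rename(columns={"size": "n", "sum": "k"})
        .reset_index()
    )
    groups = []
    for (fish, cset), grp in counts.groupby(["fish_id", "colour_set"], sort=False):
        rows = np.array([id_to_row[t] for t in grp.target_id])
        groups.append((fish, cset, rows, grp.n.to_numpy(float), grp.k.to_numpy(float)))

    label_idx = {lab: i for i, lab in enumerate(vs.labels)}
    results = []
    for drop in drops:
        keep = [i for i, lab in enumerate(vs.labels) if lab != drop]
        if len(keep) < 3:
            raise ModelComparisonError("cannot drop below 3 receptors")
        df_sub = delta_f_full[:, keep]
        ratio_sub = np.array([vs.ratio[i] for i in keep], dtype=float)
        is_single = np.array([vs.labels[i] == "U" for i in keep])
        warm: dict[int, tuple[float, float]] = {}  # group index -> (m, s)
        for ss in sigma_grid:
            for sd in sigma_grid:
                sigma = np.where(is_single, ss, sd)
                e = receptor_noise(sigma, ratio_sub)
                ds = _delta_s_batch(df_sub, e)
                per_set: dict[str, list[float]] = {}
                flagged = 0
                for gi, (fish, cset, rows, n, k) in enumerate(groups):
                    x = ds[rows]
                    if np.ptp(x) < 1e-9:
                        flagged += 1  # variant collapses the set's ΔS axis
                        continue
                    try:
                        fit = fit_counts(
                            x, n, k, guess=guess, n_starts=n_starts, warm_start=warm.get(gi)
                        )
                    except PsychometricError:
                        flagged += 1
                        continue
                    warm[gi] = (fit.m, fit.s)
                    if fit.threshold is not None:
                        per_set.setdefault(cset, []).append(fit.threshold)
                set_means = {c: float(np.mean(v)) for c, v in per_set.items()}
                if not set_means:
                    continue
                row = {
                    "variant": "tetrachromat" if drop is None else f"trichromat-no-{drop}",
                    "drop": drop or "",
                    "sigma_single": ss,
                    "sigma_double": sd,
                    "metric": deviation_metric(list(set_means.values())),
                    "n_sets": len(set_means),
                    "flagged": flagged,
                }
                for c, v in set_means.items():
                    row[f"thr_{c}"] = v
                results.append(row)
    table = pd.DataFrame(results).sort_values("metric", kind="mergesort").reset_index(drop=True)
    return table


def best_model(scan: pd.DataFrame) -> pd.Series:
    """Top-ranked row of a `scan_models` table."""
    if scan.empty:
        raise ModelComparisonError("empty scan table")
    return scan.iloc[0]
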