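"""Psychometric curve fitting and discrimination-threshold estimation.

The probability that a fish pecks the correct (target) pixel is modelled as

    P(correct | ΔS) = γ + (1 − γ − λ) · F((ΔS − m) / s)

with F a sigmoid (logistic by default, cumulative normal optionally),
γ the guess rate, λ the lapse rate, m the location and s the spread.
The discrimination threshold is the ΔS at which P = 0.5 — near the curve's
steepest point.  With 37 distractors and only one rewarded pixel, the chance
of a correct guess is essentially nil, so γ defaults to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.special import expit
from scipy.stats import norm

SigmoidFamily = Literal["logistic", "normal"]

_P_FLOOR = 1e-9


class PsychometricError(ValueError):
    """Raised for unusable choice data or degenerate fits."""


def _sigmoid(t: np.ndarray, family: SigmoidFamily) -> np.ndarray:
    if family == "logistic":
        return expit(t)
    return norm.cdf(t)


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted psychometric curve and the threshold derived from it."""

    m: float
    s: float
    guess: float
    lapse: float
    log_likelihood: float
    threshold: float | None
    ci: tuple[float, float] | None = None
    family: SigmoidFamily = "logistic"
    boundary: bool = False  # data pinned at 0 or 1; parameters unreliable

    def predict(self, delta_s: np.ndarray | float) -> np.ndarray:
        t = (np.asarray(delta_s, dtype=float) - self.m) / self.s
        return self.guess + (1.0 - self.guess - self.lapse) * _sigmoid(t, self.family)


def aggregate_trials(data: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-trial rows to (delta_s, n_trials, n_correct) counts.

    Accepts either raw rows with a 0/1 ``correct`` column or already
    aggregated rows with ``n_trials``/``n_correct``; the fit is identical
    either way because the binomial likelihood factorises over trials.
    """
    if {"n_trials", "n_correct"}.issubset(data.columns):
        agg = (
            data.groupby("delta_s", as_index=False)[["n_trials", "n_correct"]]
            .sum()
            .sort_values("delta_s")
        )
    elif "correct" in data.columns:
        g = data.groupby("delta_s")["correct"]
        agg = pd.DataFrame(
            {"delta_s": g.size().index, "n_trials": g.size().values, "n_correct": g.sum().values}
        ).sort_values("delta_s")
    else:
        raise PsychometricError("data needs either 'correct' or 'n_trials'/'n_correct' columns")
    bad = (agg.n_correct < 0) | (agg.n_correct > agg.n_trials)
    if bad.any():
        raise PsychometricError("n_correct outside [0, n_trials]")
    return agg.reset_index(drop=True)


def _nll(params, x, n, k, guess, lapse_free, family):
    m, s = params[0], params[1]
    lapse = params[2] if lapse_free else 0.0
    p = guess + (1.0 - guess - lapse) * _sigmoid((x - m) / s, family)
    p = np.clip(p, _P_FLOOR, 1.0 - _P_FLOOR)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def _nll_grad(params, x, n, k, guess, lapse_free, family):
    """Negative log-likelihood and its gradient (analytic, logistic/normal)."""
    m, s = params[0], params[1]
    lapse = params[2] if lapse_free else 0.0
    amp = 1.0 - guess - lapse
    t = (x - m) / s
    F = _sigmoid(t, family)
    p = np.clip(guess + amp * F, _P_FLOOR, 1.0 - _P_FLOOR)
    nll = -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))
    dl_dp = -(k / p - (n - k) / (1.0 - p))
    dF = F * (1.0 - F) if family == "logistic" else norm.pdf(t)
    common = dl_dp * amp * dF
    grad = [
        float(np.sum(common * (-1.0 / s))),
        float(np.sum(common * (-t / s))),
    ]
    if lapse_free:
        grad.append(float(np.sum(dl_dp * (-F))))
    return nll, np.array(grad)


def fit_counts(
    x: np.ndarray,
    n: np.ndarray,
    k: np.ndarray,
    guess: float = 0.0,
    lapse: float | Literal["free"] = 0.0,
    family: SigmoidFamily = "logistic",
    n_starts: int = 5,
    warm_start: tuple[float, ...] | None = None,
) -> PsychometricFit:
    """Maximum-likelihood fit on pre-aggregated per-level counts.

    This is the array fast path used by the σ-grid model scan, which refits
    thousands of curves against rescaled ΔS axes; `fit_psychometric` wraps
    it for DataFrame input and adds the bootstrap CI.  ``warm_start`` seeds
    the optimiser with (m, s[, lapse]) from a related fit (e.g. the previous
    σ-grid cell) ahead of the deterministic quantile starts.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.unique(x).size < 3:
        raise PsychometricError(f"need >= 3 distinct ΔS levels, got {np.unique(x).size}")
    if not 0 <= guess < 1:
        raise PsychometricError(f"guess rate must be in [0, 1), got {guess}")
    lapse_free = lapse == "free"
    lapse_fixed = 0.0 if lapse_free else float(lapse)
    if not lapse_free and not 0 <= lapse_fixed < 0.5:
        raise PsychometricError(f"lapse must be in [0, 0.5), got {lapse}")

    # Boundary data: pinned at 0/1 (likelihood unbounded in m), or performance
    # that never reaches the 0.5 criterion, making any threshold an
    # extrapolation.  Fit parameters are still reported, the threshold is not.
    boundary = bool(
        np.all(k == n) or np.all(k == 0) or float((k / n).max()) < 0.5
    )

    span = max(x.max() - x.min(), 1e-3)
    starts = np.quantile(x, np.linspace(0.1, 0.9, n_starts))
    bounds = [(x.min() - span, x.max() + 2 * span), (1e-3, 5 * span)]
    if lapse_free:
        bounds.append((0.0, 0.5))

    if warm_start is not None:
        starts = np.concatenate([[warm_start[0]], starts])
    best = None
    for i, m0 in enumerate(starts):
        p0 = [m0, span / 4]
        if warm_start is not None and i == 0:
            p0 = list(warm_start)[: 2 + lapse_free]
        if lapse_free and len(p0) == 2:
            p0.append(0.02)
        p0 = np.clip(p0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            _nll_grad,
            p0,
            args=(x, n, k, guess, lapse_free, family),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise PsychometricError("psychometric fit failed to converge")

    m_hat, s_hat = float(best.x[0]), float(best.x[1])
    lapse_hat = float(best.x[2]) if lapse_free else lapse_fixed
    fit = PsychometricFit(
        m=m_hat,
        s=s_hat,
        guess=guess,
        lapse=lapse_hat,
        log_likelihood=-float(best.fun),
        threshold=None,
        family=family,
        boundary=boundary,
    )
    threshold = None if boundary else _solve_threshold(fit, x)
    return PsychometricFit(
        m=fit.m,
        s=fit.s,
        guess=fit.guess,
        lapse=fit.lapse,
        log_likelihood=fit.log_likelihood,
        threshold=threshold,
        family=family,
        boundary=boundary,
    )


def fit_psychometric(
    data: pd.DataFrame,
    guess: float = 0.0,
    lapse: float | Literal["free"] = 0.0,
    family: SigmoidFamily = "logistic",
    *,
    n_starts: int = 5,
    n_boot: int = 500,
    seed: int = 0,
) -> PsychometricFit:
    """Maximum-likelihood psychometric fit for one fish × one colour set.

    Binomial likelihood over ΔS levels; `n_starts` deterministic starting
    points (location quantiles of the tested levels) guard against local
    optima.  The bootstrap CI (percentile, seeded) resamples per-level
    binomial counts from the observed proportions; pass ``n_boot=0`` to skip
    it, e.g. inside large model scans.
    """
    agg = aggregate_trials(data)
    x = agg.delta_s.to_numpy(dtype=float)
    n = agg.n_trials.to_numpy(dtype=float)
    k = agg.n_correct.to_numpy(dtype=float)
    fit = fit_counts(x, n, k, guess=guess, lapse=lapse, family=family, n_starts=n_starts)
    ci = None
    if n_boot > 0 and fit.threshold is not None and not fit.boundary:
        rng = np.random.default_rng(seed)
        p_obs = np.clip(k / n, 0.0, 1.0)
        boot_thr = []
        for _ in range(n_boot):
            kb = rng.binomial(n.astype(int), p_obs).astype(float)
            try:
                bfit = fit_counts(
                    x, n, kb, guess=guess, lapse=lapse, family=family, n_starts=2
                )
            except PsychometricError:
                continue
            if bfit.threshold is not None:
                boot_thr.append(bfit.threshold)
        if len(boot_thr) >= max(20, n_boot // 10):
            ci = (
                float(np.percentile(boot_thr, 2.5)),
                float(np.percentile(boot_thr, 97.5)),
            )
    return PsychometricFit(
        m=fit.m,
        s=fit.s,
        guess=fit.guess,
        lapse=fit.lapse,
        log_likelihood=fit.log_likelihood,
        threshold=fit.threshold,
        ci=ci,
        family=family,
        boundary=fit.boundary,
    )


def _solve_threshold(fit: PsychometricFit, x: np.ndarray, tol: float = 1e-6) -> float | None:
    upper = fit.guess + (1.0 - fit.guess - fit.lapse)
    if upper <= 0.5 or fit.guess >= 0.5:
        return None
    span = max(x.max() - x.min(), 1.0)
    lo = float(min(x.min(), fit.m) - 10 * span)
    hi = float(max(x.max(), fit.m) + 10 * span)
    f = lambda v: float(fit.predict(v)) - 0.5
    if f(lo) >= 0 or f(hi) <= 0:
        return None
    return float(brentq(f, lo, hi, xtol=tol))


def threshold_from_fit(fit: PsychometricFit, tol: float = 1e-6) -> float:
    """ΔS at which the fitted curve crosses P = 0.5 (bisection, tol 1e-6).

    Equals m exactly when γ = λ = 0.  Errors if the curve's asymptotes pin
    it away from 0.5 (upper asymptote <= 0.5, or guess floor >= 0.5).
    """
    upper = fit.guess + (1.0 - fit.guess - fit.lapse)
    if upper <= 0.5:
        raise PsychometricError(f"upper asymptote {upper:.3f} <= 0.5; threshold undefined")
    if fit.guess >= 0.5:
        raise PsychometricError(f"guess floor {fit.guess:.3f} >= 0.5; threshold degenerate")
    span = max(10.0 * fit.s, 10.0)
    lo, hi = fit.m - span, fit.m + span
    f = lambda v: float(fit.predict(v)) - 0.5
    while f(lo) >= 0:
        lo -= span
    while f(hi) <= 0:
        hi += span
    return float(brentq(f, lo, hi, xtol=tol))


def summarise_thresholds(
    fits: pd.DataFrame,
    angles: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-colour-set threshold summary: mean ± s.e.m. across fish.

    ``fits`` needs columns (fish_id, colour_set, threshold).  If ``angles``
    (colour_set, theta, phi) is given, each set's hue angles and its UV sign
    (uv_positive: elevation Θ > 0, i.e. net UV-cone excitation) are attached.
    """
    if fits.empty:
        raise PsychometricError("no fits to summarise")
    rows = []
    for cset, grp in fits.groupby("colour_set", sort=False):
        thr = grp.threshold.dropna().to_numpy(dtype=float)
        if thr.size == 0:
            raise PsychometricError(f"colour set {cset!r} has no finite thresholds")
        mean = float(thr.mean())
        sem = float(thr.std(ddof=1) / np.sqrt(thr.size)) if thr.size > 1 else np.nan
        rows.append({"colour_set": cset, "n_fish": thr.size, "mean": mean, "sem": sem})
    out = pd.DataFrame(rows)
    if angles is not None:
        out = out.merge(angles[["colour_set", "theta", "phi"]], on="colour_set", how="left")
        out["uv_positive"] = out.theta > 0
    return out
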