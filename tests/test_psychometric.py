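import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from anemonevision.psychometric import (
    PsychometricError,
    PsychometricFit,
    aggregate_trials,
    fit_counts,
    fit_psychometric,
    summarise_thresholds,
    threshold_from_fit,
)


def _levels(n=8, top=2.0):
    return np.linspace(top / n, top, n)


def _exact_counts(m, s, levels, n_per=1000, guess=0.0, lapse=0.0):
    p = guess + (1 - guess - lapse) * expit((levels - m) / s)
    k = np.round(p * n_per)
    return pd.DataFrame({"delta_s": levels, "n_trials": n_per, "n_correct": k})


class TestFit:
    def test_noiseless_recovery(self):
        data = _exact_counts(1.5, 0.3, _levels(top=3.0))
        fit = fit_psychometric(data, n_boot=0)
        assert fit.m == pytest.approx(1.5, abs=0.01)
        assert fit.threshold == pytest.approx(1.5, abs=0.01)

    def test_guess_and_lapse_shift_threshold(self):
        # with a lapse the 0.5 crossing moves beyond m; closed-form oracle:
        # 0.8*F((x-1)/0.2) = 0.5  =>  x = 1 + 0.2*ln(5/3)
        fit = PsychometricFit(
            m=1.0, s=0.2, guess=0.0, lapse=0.2, log_likelihood=0.0, threshold=None
        )
        expected = 1.0 + 0.2 * np.log((0.5 / 0.8) / (1 - 0.5 / 0.8))
        assert threshold_from_fit(fit) == pytest.approx(expected, abs=1e-6)

    def test_threshold_equals_m_without_guess_or_lapse(self):
        fit = PsychometricFit(
            m=1.0, s=0.2, guess=0.0, lapse=0.0, log_likelihood=0.0, threshold=None
        )
        assert threshold_from_fit(fit) == pytest.approx(1.0, abs=1e-6)

    def test_floor_at_half_is_degenerate(self):
        fit = PsychometricFit(
            m=1.0, s=0.2, guess=0.5, lapse=0.0, log_likelihood=0.0, threshold=None
        )
        with pytest.raises(PsychometricError):
            threshold_from_fit(fit)

    def test_asymptote_below_half_undefined(self):
        fit = PsychometricFit(
            m=1.0, s=0.2, guess=0.0, lapse=0.6, log_likelihood=0.0, threshold=None
        )
        with pytest.raises(PsychometricError):
            threshold_from_fit(fit)

    def test_all_correct_flags_boundary(self):
        data = pd.DataFrame({"delta_s": _levels(), "n_trials": 10, "n_correct": 10})
        fit = fit_psychometric(data, n_boot=0)
        assert fit.boundary and fit.threshold is None

    def test_low_performance_no_threshold(self):
        data = pd.DataFrame({"delta_s": _levels(), "n_trials": 10, "n_correct": 4})
        fit = fit_psychometric(data, n_boot=0)
        assert fit.boundary and fit.threshold is None

    def test_row_order_and_aggregation_invariance(self):
        rng = np.random.default_rng(0)
        levels = _levels()
        rows = []
        for ds in levels:
            p = expit((ds - 0.9) / 0.25)
            for _ in range(10):
                rows.append({"delta_s": ds, "correct": int(rng.random() < p)})
        raw = pd.DataFrame(rows)
        shuffled = raw.sample(frac=1.0, random_state=1)
        agg = aggregate_trials(raw)
        f1 = fit_psychometric(raw, n_boot=0)
        f2 = fit_psychometric(shuffled, n_boot=0)
        f3 = fit_psychometric(agg, n_boot=0)
        assert f1.m == pytest.approx(f2.m, abs=1e-9)
        assert f1.m == pytest.approx(f3.m, abs=1e-9)

    def test_bootstrap_ci_reproducible_and_covers(self):
        rng = np.random.default_rng(3)
        levels = _levels()
        k = rng.binomial(10, expit((levels - 0.8) / 0.2))
        data = pd.DataFrame({"delta_s": levels, "n_trials": 10, "n_correct": k})
        f1 = fit_psychometric(data, n_boot=200, seed=7)
        f2 = fit_psychometric(data, n_boot=200, seed=7)
        assert f1.ci == f2.ci
        assert f1.ci[0] <= f1.threshold <= f1.ci[1]

    def test_recovery_accuracy_over_simulations(self):
        # median absolute error across planted locations
        rng = np.random.default_rng(11)
        errs = []
        levels = _levels()
        for m in np.linspace(0.4, 1.6, 40):
            k = rng.binomial(10, expit((levels - m) / 0.2))
            try:
                fit = fit_counts(levels, np.full(8, 10.0), k.astype(float))
            except PsychometricError:
                continue
            if fit.threshold is not None:
                errs.append(abs(fit.threshold - m))
        assert np.median(errs) < 0.1


class TestSummary:
    def test_mean_and_sem(self):
        fits = pd.DataFrame(
            {
                "fish_id": ["a", "b", "c"],
                "colour_set": ["blue"] * 3,
                "threshold": [1.4, 1.5, 1.6],
            }
        )
        out = summarise_thresholds(fits)
        assert out.loc[0, "mean"] == pytest.approx(1.5)
        assert out.loc[0, "sem"] == pytest.approx(0.1 / np.sqrt(3), abs=1e-6)

    def test_single_fish_sem_missing(self):
        fits = pd.DataFrame(
            {"fish_id": ["a"], "colour_set": ["red"], "threshold": [1.0]}
        )
        out = summarise_thresholds(fits)
        assert np.isnan(out.loc[0, "sem"])

    def test_attaches_hue_angles_and_uv_sign(self):
        fits = pd.DataFrame(
            {
                "fish_id": ["a", "a"],
                "colour_set": ["UV", "blue"],
                "threshold": [0.8, 1.5],
            }
        )
        angles = pd.DataFrame(
            {"colour_set": ["UV", "blue"], "theta": [81.0, -45.0], "phi": [127.0, 150.0]}
        )
        out = summarise_thresholds(fits, angles)
        uv = out.set_index("colour_set")
        assert bool(uv.loc["UV", "uv_positive"]) is True
        assert bool(uv.loc["blue", "uv_positive"]) is False

    def test_empty_errors(self):
        with pytest.raises(PsychometricError):
            summarise_thresholds(pd.DataFrame(columns=["fish_id", "colour_set", "threshold"]))
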