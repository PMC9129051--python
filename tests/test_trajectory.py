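"""Trajectory-mixture likelihood, EM fitting, selection, posteriors."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kneephen.synthetic import two_group_panel
from kneephen.trajectory import (
    MODEL_MONTHS,
    GbtmModel,
    TIME_SCALE,
    fit_gbtm,
    gbtm_loglik,
    group_proportion_ci,
    posterior_assign,
    select_model,
)


def toy_panel():
    """5 knees, 3 model visits, fully observed; values chosen by hand."""
    rows = []
    vals = {
        "k1": [0.1, 0.4, 1.0],
        "k2": [-0.2, 0.1, 0.3],
        "k3": [2.0, 3.5, 5.1],
        "k4": [1.8, 3.2, 4.9],
        "k5": [0.0, 0.2, 0.5],
    }
    for kid, ys in vals.items():
        rows.append({"knee_id": kid, "month": 0, "value": 0.0})
        for m, y in zip([12, 48, 96], ys):
            rows.append({"knee_id": kid, "month": m, "value": y})
    return pd.DataFrame(rows)


def brute_force_loglik(model, panel):
    """Direct per-knee summation of the mixture likelihood."""
    total = 0.0
    for kid, sub in panel[panel["month"] > 0].groupby("knee_id"):
        like = 0.0
        for g in range(model.G):
            term = model.pi[g]
            for _, r in sub.iterrows():
                t = r["month"] / TIME_SCALE
                mu = sum(b * t**p for p, b in enumerate(model.beta[g]))
                term *= stats.norm.pdf(r["value"], mu, model.sigma)
            like += term
        total += np.log(like)
    return total


class TestLoglik:
    def test_matches_bruteforce_on_toy_panel(self):
        panel = toy_panel()
        model = GbtmModel(
            G=2,
            beta=[np.array([0.0, 0.5]), np.array([1.0, 4.0])],
            sigma=0.8,
            pi=np.array([0.6, 0.4]),
            dropout_coef=None,
            loglik=0.0,
            bic=0.0,
            n_knees=5,
            converged=True,
            n_iter=0,
        )
        assert gbtm_loglik(model, panel) == pytest.approx(
            brute_force_loglik(model, panel), abs=1e-8
        )

    def test_single_group_equals_gaussian_regression_loglik(self):
        panel = toy_panel()
        m = fit_gbtm(panel, G=1, degrees=1)
        # ordinary Gaussian log-likelihood of the fitted line
        t = panel.loc[panel["month"] > 0, "month"].to_numpy() / TIME_SCALE
        y = panel.loc[panel["month"] > 0, "value"].to_numpy()
        mu = m.beta[0][0] + m.beta[0][1] * t
        direct = stats.norm.logpdf(y, mu, m.sigma).sum()
        assert m.loglik == pytest.approx(direct, abs=1e-6)

    def test_duplicating_knees_doubles_loglik(self):
        panel = toy_panel()
        model = fit_gbtm(panel, G=1, degrees=1)
        dup = panel.copy()
        dup["knee_id"] = dup["knee_id"] + "_copy"
        both = pd.concat([panel, dup], ignore_index=True)
        assert gbtm_loglik(model, both) == pytest.approx(
            2 * gbtm_loglik(model, panel), abs=1e-8
        )

    def test_group_relabeling_leaves_loglik_unchanged(self):
        panel = toy_panel()
        m = fit_gbtm(panel, G=2, degrees=1, seed=0, n_starts=3)
        swapped = GbtmModel(
            G=2,
            beta=m.beta[::-1],
            sigma=m.sigma,
            pi=m.pi[::-1].copy(),
            dropout_coef=None,
            loglik=0.0,
            bic=0.0,
            n_knees=m.n_knees,
            converged=True,
            n_iter=0,
        )
        assert gbtm_loglik(m, panel) == pytest.approx(
            gbtm_loglik(swapped, panel), abs=1e-10
        )


class TestFit:
    def test_single_group_matches_ols_polyfit(self):
        panel = toy_panel()
        m = fit_gbtm(panel, G=1, degrees=2)
        t = panel.loc[panel["month"] > 0, "month"].to_numpy() / TIME_SCALE
        y = panel.loc[panel["month"] > 0, "value"].to_numpy()
        ols = np.polyfit(t, y, 2)[::-1]
        np.testing.assert_allclose(m.beta[0], ols, atol=1e-6)

    def test_two_group_parameter_recovery(self):
        panel, truth = two_group_panel(seed=4)
        m = fit_gbtm(panel, G=2, degrees=1, seed=0, n_starts=4)
        pis = np.sort(m.pi)[::-1]
        assert abs(pis[0] - 0.7) < 0.05
        # group means at every visit within 0.3 of the planted curves
        months = np.asarray(MODEL_MONTHS, dtype=float)
        fitted = sorted(
            [m.mean_trajectory(g) for g in range(2)], key=lambda v: abs(v[-1])
        )
        np.testing.assert_allclose(fitted[0], np.zeros(6), atol=0.3)
        np.testing.assert_allclose(fitted[1], 5.0 * months / TIME_SCALE, atol=0.3)

    def test_em_loglik_monotone(self):
        panel, _ = two_group_panel(seed=9, n=200)
        m = fit_gbtm(panel, G=2, degrees=1, seed=1, n_starts=2, debug=True)
        hist = np.array(m.loglik_history)
        assert np.all(np.diff(hist) >= -1e-8)

    def test_bic_consistent_with_parameter_count(self):
        panel, _ = two_group_panel(seed=2, n=200)
        m = fit_gbtm(panel, G=2, degrees=1, seed=0, n_starts=2)
        k = (2 - 1) + 2 * 2 + 1
        assert m.bic == pytest.approx(-2 * m.loglik + k * np.log(m.n_knees))

    def test_dropout_extension_adds_parameters(self):
        panel, _ = two_group_panel(seed=2, n=200)
        # impose monotone dropout by truncating half the knees at month 48
        kept = panel[~((panel["knee_id"] % 2 == 0) & (panel["month"] > 48))]
        m = fit_gbtm(kept, G=2, degrees=1, dropout=True, seed=0, n_starts=2)
        assert m.dropout_coef is not None and len(m.dropout_coef) == 2
        assert np.isfinite(m.loglik)
        k = (2 - 1) + 2 * 2 + 1 + 2 * 2
        assert m.bic == pytest.approx(-2 * m.loglik + k * np.log(m.n_knees))


class TestSelection:
    def test_linear_group_pruned_from_cubic_start(self):
        panel, _ = two_group_panel(seed=6)
        m = select_model(panel, G_max=2, seed=0, n_starts=3)
        assert m.G == 2
        assert max(m.degrees) <= 1  # quadratic and cubic terms pruned
        assert m.selection_path  # path logged

    def test_gmax_one_returns_single_group(self):
        panel, _ = two_group_panel(seed=5, n=150)
        m = select_model(panel, G_max=1, seed=0, n_starts=2)
        assert m.G == 1
        assert m.pi[0] == pytest.approx(1.0)


class TestPosterior:
    def test_rows_sum_to_one_and_good_fit_rule(self):
        panel, _ = two_group_panel(seed=3, n=200)
        m = fit_gbtm(panel, G=2, degrees=1, seed=0, n_starts=3)
        a = posterior_assign(m, panel)
        np.testing.assert_allclose(a.posterior.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_array_equal(a.good_fit, a.max_prob >= 0.8)

    def test_knee_on_group_mean_gets_high_posterior(self):
        panel, _ = two_group_panel(seed=3, n=200)
        m = fit_gbtm(panel, G=2, degrees=1, seed=0, n_starts=3)
        rising = int(np.argmax([abs(m.mean_trajectory(g)[-1]) for g in range(2)]))
        probe = pd.DataFrame(
            {
                "knee_id": [999999] * 7,
                "month": [0] + list(MODEL_MONTHS),
                "value": [0.0] + list(m.mean_trajectory(rising)),
            }
        )
        a = posterior_assign(m, probe)
        assert a.posterior[0, rising] > 0.99

    def test_mean_posterior_matches_mixing_weights(self):
        panel, _ = two_group_panel(seed=8, n=300)
        m = fit_gbtm(panel, G=2, degrees=1, seed=0, n_starts=3)
        a = posterior_assign(m, panel)
        np.testing.assert_allclose(a.posterior.mean(axis=0), m.pi, atol=1e-4)


class TestProportionCI:
    def test_single_group_degenerate(self):
        panel, _ = two_group_panel(seed=1, n=100)
        m = fit_gbtm(panel, G=1, degrees=1)
        assert group_proportion_ci(m) == [(1.0, 1.0, 1.0)]

    def test_bounds_and_coverage_of_estimate(self):
        panel, _ = two_group_panel(seed=7)
        m = fit_gbtm(panel, G=2, degrees=1, seed=0, n_starts=3)
        cis = group_proportion_ci(m)
        for est, lo, hi in cis:
            assert 0.0 <= lo <= est <= hi <= 1.0
            assert hi - lo < 0.3

    def test_width_shrinks_with_sample_size(self):
        widths = []
        for n in (200, 800):
            panel, _ = two_group_panel(seed=10, n=n)
            m = fit_gbtm(panel, G=2, degrees=1, seed=0, n_starts=3)
            lo, hi = group_proportion_ci(m)[0][1:]
            widths.append(hi - lo)
        ratio = widths[0] / widths[1]
        assert 1.3 < ratio < 3.5  # expect about sqrt(800/200) = 2


class TestPanelHandling:
    def test_knee_without_postbaseline_visits_excluded(self):
        panel = toy_panel()
        extra = pd.DataFrame([{"knee_id": "k6", "month": 0, "value": 0.0}])
        m = fit_gbtm(pd.concat([panel, extra]), G=1, degrees=1)
        assert m.n_knees == 5
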