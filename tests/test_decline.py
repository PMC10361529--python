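"""Decline model: q formula, posterior composition, gradients, fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from odmobility import (
    PriorConfig,
    SimConfig,
    build_decline_data,
    compute_q,
    fit_decline,
    generate_city,
    negative_log_posterior,
    simulate_decline_panel,
)
from odmobility.decline import _core_nll_grad
from odmobility.io_prep import build_covariates

from conftest import make_weekly_panel


class TestComputeQ:
    def test_zero_decrements_give_unit_q(self):
        q = compute_q(np.zeros(5), np.zeros(3), 0.0, np.zeros(3), t=7)
        assert q == 1.0

    def test_baseline_weeks_pinned_at_one(self):
        q = compute_q(np.full(5, 0.3), np.ones(2), 0.5, np.ones(2), t=3)
        assert q == 1.0

    def test_cumulative_sum_evaluates_directly(self):
        # beta = 0: q = exp(-sum of decrements up to t)
        c = np.array([0.1, 0.1, 0.1, 0.1, 0.1])
        q = compute_q(c, np.zeros(2), 0.0, np.zeros(2), t=7)
        assert q == pytest.approx(np.exp(-0.3), rel=1e-12)

    def test_monotone_decreasing_in_linear_predictor(self):
        c = np.full(5, 0.1)
        x = np.array([1.0, 0.5])
        qs = [compute_q(c, np.array([b, 0.2]), 0.0, x, t=9) for b in (0.0, 0.5, 1.0)]
        assert qs[0] > qs[1] > qs[2]


def _micro_city_and_panel():
    """Two zips, one age group, 6 weeks: small enough to compose by hand."""
    import pandas as pd

    from odmobility import ZipTable

    df = pd.DataFrame(
        {
            "lat": [0.0, 0.0],
            "lon": [0.0, 0.5],
            "pop_total": [1000.0, 1500.0],
            "median_income": [50000.0, 60000.0],
            "county_id": ["C1", "C1"],
            "subs_18_34": [100.0, 150.0],
            "subs_35_54": [1.0, 1.0],
            "subs_55p": [1.0, 1.0],
            "prop_higher_income": [0.4, 0.6],
        },
        index=pd.Index(["A", "B"], name="zip_id"),
    )
    zt = ZipTable(df)
    counts = [400, 420, 380, 400, 300, 250]
    records = [("A", "B", "18-34", w, c) for w, c in enumerate(counts, start=1)]
    panel = make_weekly_panel(records, censor_threshold=0)
    return zt, panel


class TestNegativeLogPosterior:
    def test_single_route_matches_hand_composition(self):
        zt, panel = _micro_city_and_panel()
        # distance quartiles need >= 2 distinct routes; inject a fixed map
        from odmobility import CovariateSet

        covs = CovariateSet(
            quartile_of_pair={("A", "B"): 4},
            quartile_bounds=(10.0, 20.0, 30.0),
            zip_static=pd.DataFrame(
                {"prop_higher_income": [0.4, 0.6], "median_income_std": [-1.0, 1.0]},
                index=pd.Index(["A", "B"], name="zip_id"),
            ),
            rel_case=None,
        )
        D = build_decline_data(panel, covs, zt, baseline_weeks=4)
        priors = PriorConfig()
        log_r = np.array([np.log(400.0 / 250.0)])
        log_c = np.log([0.08, 0.1])
        beta = np.array([0.1, -0.2, 0.3, 0.25, 0.05])  # q1,q3,q4,prop,med
        x = np.concatenate([log_r, log_c, beta])
        val, _ = negative_log_posterior(x, D, priors)

        # independent composition: pooled rate, both directions share r
        r = float(np.exp(log_r[0]))
        c = np.exp(log_c)
        ll = 0.0
        counts = {1: 400, 2: 420, 3: 380, 4: 400, 5: 300, 6: 250}
        xa = np.array([0.0, 0.0, 1.0, 0.4, -1.0])  # origin A
        xb = np.array([0.0, 0.0, 1.0, 0.6, 1.0])  # origin B
        for w, y in counts.items():
            csum = c[: max(w - 4, 0)].sum()
            qa = np.exp(-np.exp(xa @ beta) * csum)
            qb = np.exp(-np.exp(xb @ beta) * csum)
            mu = 100 * r * qa + 150 * r * qb
            ll += stats.poisson.logpmf(y, mu)
        prior = stats.norm.logpdf(log_r[0], D.log_r_init[0], 1.0)
        prior += stats.norm.logpdf(log_c, -3.0, 1.5).sum()
        prior += stats.norm.logpdf(beta, 0.0, 1.0).sum()
        assert val == pytest.approx(-(ll + prior), abs=1e-10)

    def test_flat_priors_equal_pure_likelihood_oracle(self, city8):
        # dense scipy Poisson pmf summation on an uncensored panel
        zt, _, _ = city8
        cfg = SimConfig(n_zips=8, seed=42, censor_threshold=0)
        panel, truth = simulate_decline_panel(zt, cfg)
        D = build_decline_data(panel, truth["covariates"], zt)
        x = np.concatenate(
            [D.log_r_init, np.log([0.1] * D.n_c), np.zeros(D.X1.shape[1]), np.zeros(2)]
        )
        val, _ = negative_log_posterior(x, D, PriorConfig.flat_priors())
        nll, *_ = _core_nll_grad(
            x[: D.n_r], x[D.n_r : D.n_r + D.n_c],
            x[D.n_r + D.n_c : D.n_r + D.n_c + D.X1.shape[1]],
            x[-2:], D,
        )
        assert val == pytest.approx(nll, rel=1e-12)
        # oracle: recompute mu independently cell by cell and sum dense pmfs
        beta_a = np.array([0.0, 0.0, 0.0])
        c = np.exp(x[D.n_r : D.n_r + D.n_c])
        oracle = 0.0
        for k in range(D.n_cells):
            csum = c[: D.cum_idx[k] + 1].sum() if D.cum_idx[k] >= 0 else 0.0
            q1 = np.exp(-np.exp(beta_a[D.age_idx[k]]) * csum)
            mu = np.exp(D.logp1[k] + x[D.idx1[k]]) * q1 + np.exp(
                D.logp2[k] + x[D.idx2[k]]
            ) * q1
            oracle -= stats.poisson.logpmf(D.y[k], mu)
        assert val == pytest.approx(oracle, rel=1e-8)

    def test_swap_of_route_endpoints_leaves_value_unchanged(self, city8):
        zt, panel, truth = city8
        D = build_decline_data(panel, truth["covariates"], zt, rate_structure="directed")
        rng = np.random.default_rng(0)
        log_r = D.log_r_init + rng.normal(0, 0.1, D.n_r)
        log_c = np.log(np.full(D.n_c, 0.1))
        beta = rng.normal(0, 0.2, D.X1.shape[1])
        ba = rng.normal(0, 0.1, 2)
        nll, *_ = _core_nll_grad(log_r, log_c, beta, ba, D)
        # swap roles: (i, j), (p_ia, p_ja), (r_ija, r_jia), (X_i, X_j)
        import dataclasses

        Ds = dataclasses.replace(
            D, idx1=D.idx2, idx2=D.idx1, logp1=D.logp2, logp2=D.logp1,
            X1=D.X2, X2=D.X1,
        )
        nll_s, *_ = _core_nll_grad(log_r, log_c, beta, ba, Ds)
        assert nll == pytest.approx(nll_s, rel=1e-13)

    def test_subscriber_rate_scale_confounding(self, city8):
        # doubling subscriber counts while halving rates leaves the
        # likelihood unchanged: only the product p * r enters the mean
        zt, panel, truth = city8
        D = build_decline_data(panel, truth["covariates"], zt)
        import dataclasses

        log_r = D.log_r_init.copy()
        log_c = np.log(np.full(D.n_c, 0.1))
        beta = np.zeros(D.X1.shape[1])
        ba = np.zeros(2)
        nll, *_ = _core_nll_grad(log_r, log_c, beta, ba, D)
        D2 = dataclasses.replace(
            D, logp1=D.logp1 + np.log(2), logp2=D.logp2 + np.log(2)
        )
        nll2, *_ = _core_nll_grad(log_r - np.log(2), log_c, beta, ba, D2)
        assert nll == pytest.approx(nll2, rel=1e-13)


@pytest.mark.parametrize("rate_structure", ["pooled", "directed"])
def test_gradient_matches_finite_differences(city8, rate_structure):
    zt, panel, truth = city8
    D = build_decline_data(panel, truth["covariates"], zt, rate_structure=rate_structure)
    rng = np.random.default_rng(1)
    x = np.concatenate(
        [
            D.log_r_init + rng.normal(0, 0.1, D.n_r),
            np.log([0.1] * D.n_c) + rng.normal(0, 0.1, D.n_c),
            rng.normal(0, 0.2, D.X1.shape[1]),
            rng.normal(0, 0.1, 2),
        ]
    )
    priors = PriorConfig()
    _, g = negative_log_posterior(x, D, priors)
    check = list(range(D.n_r - 2, len(x))) + [0, D.n_r // 2]
    for k in check:
        h = 1e-6 * max(1, abs(x[k]))
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        fd = (
            negative_log_posterior(xp, D, priors)[0]
            - negative_log_posterior(xm, D, priors)[0]
        ) / (2 * h)
        assert g[k] == pytest.approx(fd, rel=5e-5, abs=1e-7)


class TestFitDecline:
    def test_truth_is_stationary_under_flat_priors(self):
        # noiseless mean-mode panel, directed structure containing the truth
        cfg = SimConfig(n_zips=8, seed=3, censor_threshold=0)
        zt = generate_city(cfg)
        panel, truth = simulate_decline_panel(zt, cfg, mode="mean")
        D = build_decline_data(panel, truth["covariates"], zt, rate_structure="directed")
        x0 = np.concatenate(
            [
                truth["log_r"].loc[list(D.r_index)].to_numpy(),
                np.log(truth["c"]),
                truth["beta"].to_numpy(),
                truth["beta_a"].to_numpy(),
            ]
        )
        fit = fit_decline(
            panel, truth["covariates"], zt, priors=PriorConfig.flat_priors(),
            init=x0, compute_sds=False, data=D,
        )
        assert fit.grad_norm < 1e-6
        np.testing.assert_allclose(fit.x, x0, atol=1e-4)

    def test_recovery_within_three_laplace_sds(self, city8):
        zt, panel, truth = city8
        fit = fit_decline(panel, truth["covariates"], zt, max_week=9)
        z = (fit.estimates["beta"] - truth["beta"]) / fit.sds["beta"]
        assert (z.abs() < 3.5).all()
        assert fit.converged

    def test_fitted_q_monotone_in_time(self, city8):
        zt, panel, truth = city8
        fit = fit_decline(panel, truth["covariates"], zt, max_week=9, compute_sds=False)
        c = fit.estimates["c"].to_numpy()
        assert (c >= 0).all()
        beta = fit.estimates["beta"].to_numpy()
        x = np.array([0.0, 0.0, 1.0, 0.5, 1.0, 0.2])
        qs = [compute_q(c, beta, 0.0, x, t) for t in range(1, 10)]
        assert all(a >= b - 1e-12 for a, b in zip(qs, qs[1:]))

    def test_bic_identity(self, city8):
        zt, panel, truth = city8
        fit = fit_decline(panel, truth["covariates"], zt, compute_sds=False)
        assert fit.bic == pytest.approx(
            fit.n_params * np.log(fit.n_obs) - 2 * fit.loglik, rel=1e-12
        )
        assert fit.n_obs == len(panel.df)

    def test_covariates_from_io_prep_pipeline_recover_truth(self, city8):
        # build covariates from the panel itself (baseline-week weighting)
        # rather than from the generative truth object
        zt, panel, truth = city8
        covs = build_covariates(
            panel, zt, truth["cases"], quartile_period={1, 2, 3, 4}
        )
        fit = fit_decline(panel, covs, zt, max_week=9)
        z = (fit.estimates["beta"] - truth["beta"]) / fit.sds["beta"]
        assert (z.abs() < 4.0).all()

    def test_fit_result_json_round_trip(self, city8, tmp_path):
        from odmobility import FitResult

        zt, panel, truth = city8
        fit = fit_decline(panel, truth["covariates"], zt, compute_sds=False)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = FitResult.from_json(path)
        assert back.loglik == fit.loglik
        pd.testing.assert_series_equal(back.estimates["beta"], fit.estimates["beta"])
        assert back.n_params == fit.n_params
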