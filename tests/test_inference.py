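"""Tests for the binding-parameter fits and Monte Carlo uncertainty machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sabre_kd.equilibria import (
    BindingConstants,
    SampleComposition,
    mix_and_dilute,
    solve_binary_equilibrium,
    solve_coupled_equilibria,
)
from sabre_kd.inference import (
    FitResult,
    MonteCarloConfig,
    MonteCarloError,
    TitrationDataset,
    TitrationPoint,
    _predict_protein_obs,
    fit_catalyst_titration,
    fit_competitor_kd,
    fit_reporter_kd,
    monte_carlo,
    narrowest_interval,
)
from sabre_kd.relaxation_model import RelaxationRates, predict_r2_catalyst

from .oracles import exhaustive_narrowest_interval

TRUTH = {"r2_f": 0.231, "r2_cl": 2.92, "k_eq": 0.050}


def make_titration(truth=TRUTH, c_tots=(1.0, 5.0, 10.0), l_tot=10.0, ratios=False):
    rates = RelaxationRates(r2_f=truth["r2_f"], r2_cl=truth["r2_cl"])
    pts = []
    for c in c_tots:
        eq = solve_binary_equilibrium(c, l_tot, truth["k_eq"])
        pts.append(
            TitrationPoint(
                composition=SampleComposition(c_tot=c, l_tot=l_tot),
                r2_obs=predict_r2_catalyst(eq, rates),
                cl_over_l=(eq.cl / eq.l_free) if ratios else None,
            )
        )
    return TitrationDataset(points=tuple(pts))


def diluted_compositions():
    """Final compositions after the 6x protein-injection dilution."""
    stock = SampleComposition(c_tot=1.0, l_tot=10.0, col_tot=10.0, volume=0.25)
    protein = SampleComposition(p_tot=0.040, volume=1.25)
    with_s = SampleComposition(p_tot=0.040, s_tot=17.28, volume=1.25)
    return mix_and_dilute(stock, protein), mix_and_dilute(stock, with_s)


class TestCatalystTitration:
    def test_noiseless_round_trip(self, catalyst_truth):
        fit = fit_catalyst_titration(make_titration())
        for k, v in catalyst_truth.items():
            assert fit.estimates[k] == pytest.approx(v, rel=1e-4), k
        assert fit.rss < 1e-20

    def test_round_trip_with_ratio_residuals(self, catalyst_truth):
        fit = fit_catalyst_titration(make_titration(ratios=True))
        for k, v in catalyst_truth.items():
            assert fit.estimates[k] == pytest.approx(v, rel=1e-4), k

    def test_no_binding_limit(self):
        """Flat titration data: the free rate is identified as the common
        level; binding parameters carry no information (k_eq collapses)."""
        truth = {"r2_f": 0.4, "r2_cl": 0.4, "k_eq": 1e-9}
        fit = fit_catalyst_titration(make_titration(truth=truth))
        obs_mean = np.mean([p.r2_obs for p in make_titration(truth=truth).points])
        assert fit.estimates["r2_f"] == pytest.approx(obs_mean, rel=1e-6)
        assert fit.rss < 1e-16

    def test_underdetermined_rejected(self):
        data = TitrationDataset(points=make_titration().points[:2])
        with pytest.raises(ValueError, match="underdetermined"):
            fit_catalyst_titration(data)

    def test_round_trip_identifiability_random_parameters(self, rng):
        """Noiseless generate-fit round trips across random physical
        parameter sets recover every parameter to 0.1%.  Five titration
        levels are used: three points admit a second exact interpolant
        (weak- vs strong-binding branch), five do not."""
        c_tots = (0.5, 1.0, 2.0, 5.0, 10.0)
        for _ in range(25):
            truth = {
                "r2_f": rng.uniform(0.05, 1.0),
                "r2_cl": rng.uniform(1.5, 20.0),
                "k_eq": rng.uniform(0.01, 1.0),
            }
            fit = fit_catalyst_titration(make_titration(truth=truth, c_tots=c_tots))
            for k, v in truth.items():
                assert abs(fit.estimates[k] - v) / v < 1e-3, (k, truth)

    def test_three_point_degeneracy_resolved_by_ratio_data(self):
        """With only three titration levels a strong-binding branch fits the
        rates exactly too; attaching [CL]/[L] ratio observations makes the
        weak-binding truth the unique optimum."""
        fit = fit_catalyst_titration(make_titration(ratios=True))
        assert fit.estimates["k_eq"] == pytest.approx(TRUTH["k_eq"], rel=1e-4)

    def test_median_unbiased_under_noise(self, rng):
        """10% observation noise: medians over 150 refits stay within a
        couple of SEs of the generating values."""
        data = make_titration()
        obs = np.array([p.r2_obs for p in data.points])
        ests = {"r2_f": [], "r2_cl": [], "k_eq": []}
        warm = (TRUTH["r2_f"], TRUTH["r2_cl"], TRUTH["k_eq"])
        for _ in range(150):
            pts = tuple(
                TitrationPoint(composition=p.composition,
                               r2_obs=float(max(o * (1 + rng.normal(0, 0.10)), 1e-4)))
                for p, o in zip(data.points, obs)
            )
            fit = fit_catalyst_titration(TitrationDataset(points=pts), init=warm)
            for k in ests:
                ests[k].append(fit.estimates[k])
        for k, v in TRUTH.items():
            med = np.median(ests[k])
            se = np.std(ests[k], ddof=1) / math.sqrt(len(ests[k]))
            assert abs(med - v) < max(4 * se, 0.05 * v), k


class TestReporterKd:
    KD_TRUTH = 141.1
    R2PL_TRUTH = 40.0
    KD2_BENZAMIDINE = 18.0

    def _observations(self, kd=KD_TRUTH, r2_pl=R2PL_TRUTH, catalyst_fit=None):
        comp_a, comp_b = diluted_compositions()
        r2_a = _predict_protein_obs(comp_a, kd, None, r2_pl, catalyst_fit)
        r2_b = _predict_protein_obs(comp_b, kd, self.KD2_BENZAMIDINE, r2_pl, catalyst_fit)
        return r2_a, r2_b, comp_a, comp_b

    def test_noiseless_round_trip(self, catalyst_fit):
        r2_a, r2_b, comp_a, comp_b = self._observations(catalyst_fit=catalyst_fit)
        fit = fit_reporter_kd(r2_a, r2_b, comp_a, comp_b, self.KD2_BENZAMIDINE, catalyst_fit)
        assert fit.estimates["k_d"] == pytest.approx(self.KD_TRUTH, rel=1e-3)
        assert fit.estimates["r2_pl"] == pytest.approx(self.R2PL_TRUTH, rel=1e-3)
        assert fit.rss < 1e-12

    def test_null_binding_detected_at_bound(self, catalyst_fit):
        """Observations with no protein contribution push KD to its upper
        bound (no binding detectable)."""
        comp_a, comp_b = diluted_compositions()
        r2_a = _predict_protein_obs(comp_a, 1e7, None, 0.0, catalyst_fit)
        r2_b = _predict_protein_obs(comp_b, 1e7, self.KD2_BENZAMIDINE, 0.0, catalyst_fit)
        fit = fit_reporter_kd(r2_a, r2_b, comp_a, comp_b, self.KD2_BENZAMIDINE, catalyst_fit)
        assert "k_d" in fit.at_bounds or fit.estimates["k_d"] > 1e5

    def test_kd2_perturbation_shifts_kd_monotonically(self, catalyst_fit):
        """Refitting the same observations under a mis-specified competitor
        constant moves the recovered KD monotonically."""
        r2_a, r2_b, comp_a, comp_b = self._observations(catalyst_fit=catalyst_fit)
        kds = []
        for kd2 in (9.0, 18.0, 27.0):
            fit = fit_reporter_kd(r2_a, r2_b, comp_a, comp_b, kd2, catalyst_fit)
            kds.append(fit.estimates["k_d"])
        assert kds == sorted(kds) or kds == sorted(kds, reverse=True)
        assert kds[1] == pytest.approx(self.KD_TRUTH, rel=1e-3)

    def test_invalid_kd2_rejected(self, catalyst_fit):
        comp_a, comp_b = diluted_compositions()
        with pytest.raises(ValueError):
            fit_reporter_kd(1.0, 0.5, comp_a, comp_b, -5.0, catalyst_fit)


class TestCompetitorKd:
    KD2_TRUTH = 170.0

    def test_noiseless_round_trip(self, catalyst_fit):
        _, comp = diluted_compositions()
        obs = _predict_protein_obs(comp, 141.1, self.KD2_TRUTH, 40.0, catalyst_fit)
        fit = fit_competitor_kd(obs, comp, 141.1, 40.0, catalyst_fit)
        assert fit.estimates["k_d2"] == pytest.approx(self.KD2_TRUTH, rel=1e-3)

    def test_inert_competitor_hits_upper_bound(self, catalyst_fit):
        """An observation equal to the protein-only prediction implies the
        competitor displaced nothing: KD,2 runs to its upper bound."""
        comp_a, comp_b = diluted_compositions()
        obs = _predict_protein_obs(comp_a, 141.1, None, 40.0, catalyst_fit)
        fit = fit_competitor_kd(obs, comp_b, 141.1, 40.0, catalyst_fit)
        assert fit.estimates["k_d2"] >= 1e6 or "k_d2" in fit.at_bounds

    def test_predicted_rate_monotone_in_kd2(self, catalyst_fit):
        _, comp = diluted_compositions()
        grid = [10.0, 30.0, 100.0, 300.0, 1000.0, 1e4]
        preds = [
            _predict_protein_obs(comp, 141.1, kd2, 40.0, catalyst_fit) for kd2 in grid
        ]
        assert all(b > a for a, b in zip(preds, preds[1:]))

    def test_unattainably_low_observation_flagged(self, catalyst_fit):
        _, comp = diluted_compositions()
        fit = fit_competitor_kd(0.01, comp, 141.1, 40.0, catalyst_fit)
        assert "k_d2" in fit.at_bounds


class TestNarrowestInterval:
    def test_brute_force_example(self):
        assert narrowest_interval([0, 1, 2, 3, 100], mass=0.8) == (0.0, 3.0)

    def test_degenerate_sample(self):
        assert narrowest_interval(np.full(20, 5.0)) == (5.0, 5.0)

    def test_matches_central_interval_for_symmetric_sample(self, rng):
        x = rng.normal(size=100_000)
        lo, hi = narrowest_interval(x, mass=0.90)
        qlo, qhi = np.quantile(x, [0.05, 0.95])
        assert lo == pytest.approx(qlo, abs=0.05)
        assert hi == pytest.approx(qhi, abs=0.05)

    @given(
        st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=10, max_size=12),
        st.floats(0.2, 0.95),
    )
    @settings(max_examples=300, deadline=None)
    def test_equals_exhaustive_oracle(self, samples, mass):
        assert narrowest_interval(samples, mass) == exhaustive_narrowest_interval(
            samples, mass
        )

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            narrowest_interval([1.0])


class TestMonteCarlo:
    def test_zero_noise_gives_zero_width_interval(self):
        cfg = MonteCarloConfig(n_draws=100, seed=7)
        fr = monte_carlo(lambda y: {"mu": float(np.mean(y))},
                         np.array([1.0, 2.0, 3.0]), 0.0, cfg)
        assert fr.ci_low["mu"] == fr.ci_high["mu"] == pytest.approx(2.0)

    def test_seed_determinism(self):
        cfg = MonteCarloConfig(n_draws=200, seed=42)
        args = (lambda y: {"mu": float(np.mean(y))}, np.zeros(5), 1.0, cfg)
        a = monte_carlo(*args)
        b = monte_carlo(*args)
        assert a.mc_mean == b.mc_mean
        assert a.ci_low == b.ci_low and a.ci_high == b.ci_high

    def test_failure_fraction_enforced(self):
        calls = {"n": 0}

        def flaky(y):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise RuntimeError("diverged")
            return {"mu": float(np.mean(y))}

        cfg = MonteCarloConfig(n_draws=100, seed=0)
        with pytest.raises(MonteCarloError):
            monte_carlo(flaky, np.zeros(3), 1.0, cfg)

    def test_boundary_draws_counted_not_dropped(self):
        def refit(y):
            m = float(np.mean(y))
            out = {"mu": max(m, 0.0)}
            if m < 0.0:
                out["_at_bound"] = 1.0
            return out

        cfg = MonteCarloConfig(n_draws=500, seed=3)
        fr = monte_carlo(refit, np.zeros(4), 1.0, cfg)
        assert fr.n_boundary_draws > 100  # mean(y) < 0 roughly half the time
        assert fr.n_failed_draws == 0

    def test_mean_outside_interval_is_representable(self):
        """A heavy one-sided tail can pull the Monte Carlo mean outside the
        narrowest-90% region; the summary must not clip it back inside."""

        def refit(y):
            m = float(np.mean(y))
            return {"theta": m if m < 1.5 else m * 1e4}

        cfg = MonteCarloConfig(n_draws=2000, seed=11)
        fr = monte_carlo(refit, np.array([0.0]), 1.0, cfg)
        assert fr.mc_mean["theta"] > fr.ci_high["theta"]


class TestFitResultInvariants:
    def test_ci_ordering_validated(self):
        with pytest.raises(ValueError):
            FitResult(estimates={"a": 1.0}, rss=0.0,
                      ci_low={"a": 2.0}, ci_high={"a": 1.0})

    def test_equilibrium_concentrations_never_exceed_totals(self, rng):
        """Every equilibrium evaluated during a fit respects the totals —
        spot-check the states behind random prediction calls."""
        comp_a, comp_b = diluted_compositions()
        for _ in range(50):
            k = BindingConstants(
                k_eq=rng.uniform(0.001, 2.0),
                k_d=rng.uniform(1.0, 1e4),
                k_d2=rng.uniform(1.0, 1e4),
            )
            eq = solve_coupled_equilibria(comp_b, k)
            assert eq.cl <= min(comp_b.c_tot, comp_b.l_tot) + 1e-9
            assert eq.pl + eq.ps <= comp_b.p_tot + 1e-9
            assert eq.l_free + eq.cl + eq.pl <= comp_b.l_tot + 1e-9
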