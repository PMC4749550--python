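"""One-choice diffusion model: closed-form oracles, simulation, fitting."""

import numpy as np
import pytest
from scipy import stats

from postdecision import ddm


def table1_params(**kw):
    base = dict(a=0.21, v=0.45, eta=0.45, t_nd=0.20, deadline=1.17)
    base.update(kw)
    return ddm.SubjectParams(**base)


class TestClosedForm:
    def test_mean_first_passage_is_bound_over_drift(self):
        law = ddm.fpt_closed_form(0.45, 0.21)
        assert law.p_absorb == 1.0
        assert law.mean_t == pytest.approx(0.21 / 0.45)

    def test_negative_drift_absorption_probability(self):
        law = ddm.fpt_closed_form(-0.05, 0.21, s=0.1)
        assert law.p_absorb == pytest.approx(np.exp(-2.1))
        assert law.mean_undefined

    def test_zero_drift_certain_absorption_infinite_mean(self):
        law = ddm.fpt_closed_form(0.0, 0.21)
        assert law.p_absorb == 1.0
        assert np.isinf(law.mean_t) and law.mean_undefined
        # reflection-principle CDF increases toward 1
        assert law.cdf(1e6) > 0.99

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ddm.fpt_closed_form(0.4, -1.0)


class TestSimulateFpt:
    def test_noise_free_ramp_hits_bound_at_a_over_v(self):
        p = table1_params(eta=0.0, s=1e-6, deadline=2.0)
        detected, rt = ddm.simulate_fpt(p, 20, seed=0)
        assert detected.all()
        assert rt == pytest.approx(0.21 / 0.45 + 0.20, abs=2e-3)

    def test_absorption_probability_matches_closed_form(self):
        n = 4000
        p = table1_params(v=-0.05, eta=0.0, t_nd=0.0, deadline=np.inf)
        detected, _ = ddm.simulate_fpt(p, n, dt=1e-3, seed=3, horizon=40.0)
        target = np.exp(-2.1)
        se = np.sqrt(target * (1 - target) / n)
        assert abs(detected.mean() - target) < 3 * se + 0.01

    def test_first_passage_matches_inverse_gaussian(self):
        n = 4000
        p = table1_params(eta=0.0, t_nd=0.0, deadline=np.inf)
        detected, rt = ddm.simulate_fpt(p, n, dt=5e-4, seed=4, horizon=3.0)
        law = ddm.fpt_closed_form(0.45, 0.21)
        d = stats.ks_1samp(rt[detected], law.cdf)
        assert d.statistic < 0.03

    def test_deadline_censors_detection(self):
        p = table1_params()
        detected, rt = ddm.simulate_fpt(p, 2000, seed=5)
        assert np.all(rt[detected] <= p.deadline)
        assert np.isnan(rt[~detected]).all()

    def test_scale_invariance_of_detection(self):
        # scaling (s, a, v, eta) by a common factor scales every path by
        # the same factor, so outcomes are identical draw-for-draw
        p1 = table1_params()
        p2 = ddm.SubjectParams(a=0.42, v=0.90, eta=0.90, t_nd=0.20,
                               deadline=1.17, s=0.2)
        d1, r1 = ddm.simulate_fpt(p1, 3000, seed=11)
        d2, r2 = ddm.simulate_fpt(p2, 3000, seed=11)
        assert np.array_equal(d1, d2)
        np.testing.assert_allclose(r1[d1], r2[d2], atol=1e-12)

    def test_detected_fraction_monotone_in_drift(self):
        sim = ddm._CrnSimulator(4000, 1.17, 1e-3, seed=9)
        fracs = [sim.run(0.21, v, 0.45, 0.20, 1.17)[0].mean()
                 for v in (0.1, 0.3, 0.5, 0.7)]
        assert np.all(np.diff(fracs) >= 0)

    def test_dt_validation(self):
        with pytest.raises(ValueError):
            ddm.simulate_fpt(table1_params(deadline=0.5), 10, dt=0.5)


class TestDeadlineEstimate:
    def test_no_trimming_returns_max(self):
        assert ddm.estimate_deadline([0.9, 1.0, 1.1]) == pytest.approx(1.1)

    def test_single_pass_trims_extreme_outlier(self):
        rng = np.random.default_rng(0)
        rts = np.concatenate([rng.normal(1.0, 0.05, 20), [3.0]])
        dl = ddm.estimate_deadline(rts)
        assert dl < 1.3  # outlier removed; deadline = slowest remaining

    def test_zero_variance(self):
        assert ddm.estimate_deadline([1.0] * 5) == pytest.approx(1.0)

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            ddm.estimate_deadline([1.0])


class TestDefectiveBins:
    def test_counts_follow_stated_proportions(self):
        q, O = ddm.defective_quantile_bins(np.linspace(0.5, 1.0, 10), 15)
        np.testing.assert_allclose(O, [1, 2, 2, 2, 2, 1, 5])
        assert O.sum() == 15
        assert np.all(np.diff(q) >= 0)

    def test_all_detected_empty_last_bin(self):
        _, O = ddm.defective_quantile_bins(np.linspace(0.4, 1.2, 20), 20)
        assert O[-1] == 0

    def test_too_few_detected_fails(self):
        with pytest.raises(ValueError):
            ddm.defective_quantile_bins([0.5] * 5, 20)


class TestChiSquare:
    def test_hand_computed_two_bin_value(self):
        assert ddm.chi2_from_counts([2, 2], [1, 3]) == pytest.approx(1 + 1 / 3)

    def test_zero_when_expected_equals_observed(self):
        assert ddm.chi2_from_counts([3, 4], [3, 4]) == 0.0

    def test_common_random_numbers_make_objective_deterministic(self):
        p = table1_params()
        q = np.array([0.45, 0.55, 0.65, 0.8, 1.0])
        O = np.array([7, 14, 14, 14, 14, 7, 30.0])
        v1 = ddm.chi2_objective(p, q, O, 100, n_sim=2000, seed=21)
        v2 = ddm.chi2_objective(p, q, O, 100, n_sim=2000, seed=21)
        assert v1 == v2

    def test_chi2_zero_when_observed_generated_by_model(self):
        # O taken from the model's own expected counts under the same
        # common random numbers must give an exact zero
        p = table1_params()
        sim = ddm._CrnSimulator(2000, p.deadline, 1e-3, seed=5)
        det, rt = sim.run(p.a, p.v, p.eta, p.t_nd, p.deadline)
        q = np.quantile(rt[det], ddm.FIT_QUANTILES)
        O = ddm.expected_counts(rt, det, q, 100)
        assert ddm.chi2_objective(p, q, O, 100, n_sim=2000, seed=5) == 0.0


class TestFit:
    def test_df_convention(self):
        # 7 bins - 1, minus 4 fitted parameters, minus 1 for the
        # empirically fixed deadline
        p = table1_params()
        det, rt = ddm.simulate_fpt(p, 400, seed=1)
        q, O = ddm.defective_quantile_bins(rt[det], 400)
        fit = ddm.fit_pso(O, q, 400, 1.17,
                          ddm.FitConfig(n_sim=1500, n_iter=15, seed=2))
        assert fit.df == 1
        assert fit.chi2 >= 0
        assert np.isfinite(fit.drift_ratio)
        assert fit.O.sum() == pytest.approx(fit.E.sum(), rel=0.02)

    def test_fit_is_deterministic(self):
        p = table1_params()
        det, rt = ddm.simulate_fpt(p, 300, seed=3)
        q, O = ddm.defective_quantile_bins(rt[det], 300)
        cfg = ddm.FitConfig(n_sim=800, n_iter=8, seed=4)
        f1 = ddm.fit_pso(O, q, 300, 1.17, cfg)
        f2 = ddm.fit_pso(O, q, 300, 1.17, cfg)
        assert f1.chi2 == f2.chi2
        assert f1.params == f2.params


class TestDecisionVariable:
    def test_noise_free_trajectory_shape(self):
        p = ddm.SubjectParams(a=0.21, v=0.45, eta=0.0, t_nd=0.20,
                              deadline=1.17, s=1e-6)
        traj = ddm.simulate_decision_variable(p, rt_bins=1, n_sim=50, seed=0)
        tr = traj.detected[0]
        t = traj.times
        onset = p.t_nd - 0.09
        assert np.allclose(tr[t < onset - 1e-3], 0.0)
        ramp = (t > onset + 0.05) & (t < onset + 0.35)
        slopes = np.gradient(tr, t)[ramp]
        assert np.allclose(slopes, 0.45, rtol=0.05)
        assert tr.max() == pytest.approx(0.21, rel=0.02)
        # decays back to baseline after the bound
        assert tr[-1] == pytest.approx(0.0, abs=1e-6)

    def test_peak_times_ordered_across_rt_bins(self):
        traj = ddm.simulate_decision_variable(table1_params(), rt_bins=3,
                                              n_sim=1500, seed=1)
        peaks = [traj.times[np.argmax(tr)] for tr in traj.detected]
        assert peaks[0] < peaks[1] < peaks[2]
        assert np.all(np.diff(traj.bin_mean_rt) > 0)

    def test_undetected_average_trends_downward_late(self):
        traj = ddm.simulate_decision_variable(table1_params(), rt_bins=3,
                                              n_sim=2000, seed=2)
        late = traj.times > 0.8
        mid = (traj.times > 0.3) & (traj.times < 0.5)
        assert traj.undetected[late].mean() < traj.undetected[mid].mean()

    def test_small_tnd_warns(self):
        p = ddm.SubjectParams(a=0.2, v=0.5, eta=0.1, t_nd=0.05, deadline=1.0)
        with pytest.warns(UserWarning):
            ddm.simulate_decision_variable(p, rt_bins=2, n_sim=100, seed=0)
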