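import itertools
import math

import numpy as np
import pytest

import bufferguts as bg
from bufferguts.calibration import PARAM_RANGE, Replicate, Treatment, _LikelihoodEngine


def make_curve(times, s_values):
    return {"": (np.asarray(times, float), np.asarray(s_values, float))}


def single_treatment_dataset(times, n_alive, n0, label=""):
    rep = Replicate(np.asarray(times, float), np.asarray(n_alive, int), n0)
    return bg.SurvivalDataset([Treatment(label=label, replicates=[rep])])


class TestDatasetValidation:
    def test_increasing_counts_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            Replicate([1.0, 2.0], [5, 7], 10)

    def test_counts_above_n0_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, n0\]"):
            Replicate([1.0], [11], 10)

    def test_missing_control_detected(self, sd_dataset):
        no_control = bg.SurvivalDataset(
            [t for t in sd_dataset.treatments if not t.is_control]
        )
        with pytest.raises(ValueError, match="control"):
            no_control.validate(require_control=True)
        sd_dataset.validate(require_control=True)


class TestLikelihood:
    def test_certain_survival_gives_zero(self):
        ds = single_treatment_dataset([1.0, 2.0], [10, 10], 10)
        ll = bg.log_likelihood(ds, make_curve([1.0, 2.0], [1.0, 1.0]))
        assert ll == pytest.approx(0.0, abs=1e-9)

    def test_single_interval_binomial(self):
        # n0=10, S(t1)=0.8, 8 alive: log C(10,2) 0.8^8 0.2^2
        ds = single_treatment_dataset([1.0], [8], 10)
        ll = bg.log_likelihood(ds, make_curve([1.0], [0.8]))
        expected = math.log(math.comb(10, 2) * 0.8**8 * 0.2**2)
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_brute_force_enumeration_two_intervals(self):
        """Exact agreement with full enumeration of death patterns, n0 <= 3."""
        s1, s2 = 0.7, 0.4
        p1, p2, ps = 1 - s1, s1 - s2, s2
        for n0 in (1, 2, 3):
            total = 0.0
            for d1, d2 in itertools.product(range(n0 + 1), repeat=2):
                if d1 + d2 > n0:
                    continue
                surv = n0 - d1 - d2
                prob = (
                    math.factorial(n0)
                    / (math.factorial(d1) * math.factorial(d2) * math.factorial(surv))
                    * p1**d1 * p2**d2 * ps**surv
                )
                total += prob
                ds = single_treatment_dataset([1.0, 2.0], [n0 - d1, surv], n0)
                ll = bg.log_likelihood(ds, make_curve([1.0, 2.0], [s1, s2]))
                assert ll == pytest.approx(math.log(prob), rel=1e-12)
            assert total == pytest.approx(1.0, rel=1e-12)

    def test_interval_structure_matters(self):
        """Two intervals vs collapsed data with the same totals differ
        unless the survival path is flat in between."""
        two = single_treatment_dataset([1.0, 2.0], [8, 6], 10)
        collapsed = single_treatment_dataset([2.0], [6], 10)
        curve = make_curve([1.0, 2.0], [0.85, 0.6])
        ll_two = bg.log_likelihood(two, curve)
        ll_one = bg.log_likelihood(collapsed, curve)
        assert ll_two != pytest.approx(ll_one)

    def test_missing_curve_rejected(self):
        ds = single_treatment_dataset([1.0], [8], 10, label="T1")
        with pytest.raises(KeyError):
            bg.log_likelihood(ds, make_curve([1.0], [0.8]))

    def test_engine_matches_public_likelihood(self, sd_dataset, sd_params):
        engine = _LikelihoodEngine("BUFFER_SD", sd_dataset)
        ll_fast = engine.loglik_vector(sd_params.to_vector())
        S = engine.survival(sd_params)
        curves = {
            t.label: (engine.t, S[k]) for k, t in enumerate(sd_dataset.treatments)
        }
        ll_ref = bg.log_likelihood(sd_dataset, curves)
        assert ll_fast == pytest.approx(ll_ref, rel=1e-9)


class TestPreliminaryFit:
    def test_medians_within_order_of_magnitude(self, sd_dataset, sd_params):
        prior = bg.preliminary_fit("BUFFER_SD", sd_dataset, seed=7)
        assert not prior.broad
        truth = np.log(sd_params.to_vector())
        assert np.all(np.abs(prior.mu - truth) < np.log(10.0))

    def test_prior_support_within_global_range(self, sd_dataset):
        prior = bg.preliminary_fit("BUFFER_SD", sd_dataset, seed=7)
        lo, hi = np.log(PARAM_RANGE[0]), np.log(PARAM_RANGE[1])
        assert prior.logpdf(np.array([lo - 1.0] * 4)) == -np.inf
        assert prior.logpdf(np.array([hi + 1.0] * 4)) == -np.inf
        assert np.isfinite(prior.logpdf(prior.mu))

    def test_all_survive_falls_back_to_broad(self, contact_design):
        immortal = bg.TKTDParams(kd=0.5, hb=0.0, mechanism="SD", z=1e3, b_kill=0.0)
        ds = bg.simulate_dataset(contact_design, "BUFFER_SD", immortal, seed=1)
        assert ds.total_deaths == 0
        with pytest.warns(UserWarning, match="broad"):
            prior = bg.preliminary_fit("BUFFER_SD", ds, seed=1)
        assert prior.broad


class TestCalibrate:
    def test_recovery_smoke(self, sd_result, sd_params):
        truth = sd_params.to_vector()
        inside = sum(
            sd_result.summary[n]["ci_lo"] <= truth[i] <= sd_result.summary[n]["ci_hi"]
            for i, n in enumerate(sd_result.param_names)
        )
        assert inside >= 3
        for i, n in enumerate(sd_result.param_names):
            assert truth[i] / 3 <= sd_result.summary[n]["median"] <= truth[i] * 3

    def test_credible_intervals_contain_median(self, sd_result):
        for n in sd_result.param_names:
            s = sd_result.summary[n]
            assert s["ci_lo"] <= s["median"] <= s["ci_hi"]

    def test_diagnostics_recorded(self, sd_result):
        d = sd_result.diagnostics
        assert set(d["rhat"]) == set(sd_result.param_names)
        assert set(d["ess"]) == set(sd_result.param_names)
        assert len(d["acceptance_rates"]) == sd_result.settings.chains
        assert d["divergences"] == 0
        assert isinstance(d["flags"], list)

    def test_control_only_hb_concentrates(self):
        rng = np.random.default_rng(11)
        hb_true = 0.1
        t_obs = np.arange(1.0, 11.0)
        reps = []
        for _ in range(3):
            s = np.exp(-hb_true * t_obs)
            p = np.concatenate([[1.0], s])
            cells = np.append(-np.diff(p), s[-1])
            deaths = rng.multinomial(10, cells / cells.sum())
            reps.append(Replicate(t_obs, 10 - np.cumsum(deaths[:-1]), 10))
        ds = bg.SurvivalDataset([Treatment(label="control", replicates=reps)])
        res = bg.calibrate(
            "RED_SD", ds, settings=bg.MCMCSettings(chains=2, tune=600, draws=600),
            seed=11,
        )
        alive0 = sum(r.n0 for r in reps)
        alive_end = sum(r.n_alive[-1] for r in reps)
        hb_mle = -np.log(alive_end / alive0) / 10.0  # analytic oracle
        assert res.summary["hb"]["median"] == pytest.approx(hb_mle, rel=0.5)

    def test_seed_reproducibility(self, sd_dataset, quick_settings):
        a = bg.calibrate("BUFFER_SD", sd_dataset, settings=quick_settings, seed=4)
        b = bg.calibrate("BUFFER_SD", sd_dataset, settings=quick_settings, seed=4)
        assert np.array_equal(a.samples, b.samples)

    def test_two_seeds_overlapping_posteriors(self, sd_dataset, quick_settings):
        import arviz as az

        a = bg.calibrate("BUFFER_SD", sd_dataset, settings=quick_settings, seed=21)
        b = bg.calibrate("BUFFER_SD", sd_dataset, settings=quick_settings, seed=22)
        merged = np.concatenate([np.log(a.samples), np.log(b.samples)], axis=0)
        ds = az.convert_to_dataset({"x": merged[:, :, 0]})
        assert float(az.rhat(ds)["x"].values) < 1.3


class TestPosteriorPredict:
    def test_intervals_integer_and_bounded(self, sd_result, sd_dataset):
        pred = bg.posterior_predict(sd_result, sd_dataset, seed=0)
        for col in ("predicted_lo", "predicted_median", "predicted_hi"):
            assert pred[col].dtype.kind == "i"
            assert (pred[col] >= 0).all()
            assert (pred[col] <= pred["n_initial"]).all()
        assert (pred["predicted_lo"] <= pred["predicted_median"]).all()
        assert (pred["predicted_median"] <= pred["predicted_hi"]).all()

    def test_point_posterior_collapses_to_binomial(self, sd_dataset, sd_params):
        from scipy.stats import binom

        point = np.tile(sd_params.to_vector(), (1, 200, 1))
        result = bg.CalibrationResult(
            model=bg.ModelVariant.BUFFER_SD,
            param_names=sd_params.names,
            samples=point,
            summary={n: {"median": v, "ci_lo": v, "ci_hi": v}
                     for n, v in zip(sd_params.names, sd_params.to_vector())},
            diagnostics={"flags": []},
            settings=bg.MCMCSettings(chains=1, tune=0, draws=200),
            seed=0,
        )
        pred = bg.posterior_predict(result, sd_dataset, seed=3, max_draws=4000)
        engine = _LikelihoodEngine("BUFFER_SD", sd_dataset)
        S = engine.survival(sd_params)
        # check the first observation of the first replicate
        k, idx, rep = engine.replicate_slices[0]
        s1 = S[k, idx[0]]
        row = pred.iloc[0]
        lo = binom.ppf(0.025, rep.n0, s1)
        hi = binom.ppf(0.975, rep.n0, s1)
        assert abs(row["predicted_lo"] - lo) <= 1
        assert abs(row["predicted_hi"] - hi) <= 1

    def test_coverage_near_nominal(self, contact_design, sd_params):
        """Observations simulated from the truth fall inside point-posterior
        95% intervals at roughly the nominal rate."""
        point = np.tile(sd_params.to_vector(), (1, 100, 1))
        ds0 = bg.simulate_dataset(contact_design, "BUFFER_SD", sd_params, seed=0)
        result = bg.CalibrationResult(
            model=bg.ModelVariant.BUFFER_SD, param_names=sd_params.names,
            samples=point, summary={}, diagnostics={"flags": []},
            settings=bg.MCMCSettings(1, 0, 100), seed=0,
        )
        pred = bg.posterior_predict(result, ds0, seed=1, max_draws=2000)
        inside_frac = []
        for sim_seed in range(10):
            ds = bg.simulate_dataset(contact_design, "BUFFER_SD", sd_params,
                                     seed=100 + sim_seed)
            obs = np.concatenate(
                [r.n_alive for t in ds.treatments for r in t.replicates]
            )
            inside = (obs >= pred["predicted_lo"].to_numpy()) & (
                obs <= pred["predicted_hi"].to_numpy()
            )
            inside_frac.append(inside.mean())
        assert 0.88 <= np.mean(inside_frac) <= 1.0
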