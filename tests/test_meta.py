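"""Random-effects meta-analysis: sampler correctness against conjugate
oracles, Savage-Dickey Bayes factors, sensitivity sweeps and the
synthetic effect generator."""

import math

import numpy as np
import pytest
from scipy import stats

from pwimeta.errors import PrecisionError
from pwimeta.meta import (
    MetaModelSpec,
    SamplerSettings,
    SyntheticMetaConfig,
    bayes_factor_savage_dickey,
    fit_random_effects,
    sensitivity_sweep,
    simulate_study_effects,
)
from pwimeta.study import StudyEffect

FAST = SamplerSettings(seed=7, n_warmup=300, n_draws=500)


def effects_of(ys, ses):
    return [StudyEffect(f"s{i}", "q", float(y), float(se), 5) for i, (y, se) in enumerate(zip(ys, ses))]


class TestFitRandomEffects:
    def test_needs_studies_and_positive_se(self):
        with pytest.raises(ValueError):
            fit_random_effects([], MetaModelSpec(), FAST)
        with pytest.raises(ValueError):
            fit_random_effects(effects_of([10], [0.0]), MetaModelSpec(), FAST)

    def test_fixed_effect_conjugate_oracle(self):
        """With tau pinned near 0 the posterior must match the closed-form
        precision-weighted normal posterior."""
        k = 20
        eff = effects_of([10.0] * k, [1.0] * k)
        spec = MetaModelSpec(effect_prior_sd=100.0, tau_prior_sd=1e-3)
        summary = fit_random_effects(eff, spec, FAST)
        prec = k / 1.0**2 + 1 / 100.0**2
        expect_mean = (k * 10.0) / prec
        expect_sd = math.sqrt(1 / prec)
        mcse = expect_sd / math.sqrt(summary.diagnostics.ess_min)
        assert summary.pooled_mean == pytest.approx(expect_mean, abs=3 * mcse)
        assert summary.pooled_sd == pytest.approx(expect_sd, rel=0.15)
        assert summary.cri_95[0] < summary.pooled_mean < summary.cri_95[1]

    def test_single_study_tiny_se_with_pinned_tau_recovers_y(self):
        eff = effects_of([20.0], [0.001])
        spec = MetaModelSpec(effect_prior_sd=100.0, tau_prior_sd=1e-3)
        summary = fit_random_effects(eff, spec, FAST)
        assert summary.pooled_mean == pytest.approx(20.0, abs=0.1)

    def test_shrinkage_toward_prior_mean(self):
        """Posterior mean lies between 0 (prior mean) and the data mean."""
        eff = effects_of([30.0] * 5, [5.0] * 5)
        spec = MetaModelSpec(effect_prior_sd=20.0, tau_prior_sd=1e-3)
        summary = fit_random_effects(eff, spec, FAST)
        assert 0.0 < summary.pooled_mean < 30.0

    def test_tau_recovered_on_heterogeneous_data(self, rng):
        eff = effects_of(rng.normal(20, 15, 60), [1.0] * 60)
        summary = fit_random_effects(eff, MetaModelSpec(), FAST)
        assert 10.0 < summary.tau_mean < 20.0
        assert summary.tau_cri_95[0] >= 0.0

    def test_diagnostics_reported(self):
        summary = fit_random_effects(effects_of([5, 7, 9], [1, 1, 1]), MetaModelSpec(), FAST)
        d = summary.diagnostics
        assert d.rhat_max < 1.01 and d.ess_min >= 400 and d.seed == 7

    def test_same_seed_same_summary(self):
        eff = effects_of([5, 7, 9, 11], [1, 1, 1, 1])
        a = fit_random_effects(eff, MetaModelSpec(), FAST)
        b = fit_random_effects(eff, MetaModelSpec(), FAST)
        assert a.pooled_mean == b.pooled_mean and a.tau_mean == b.tau_mean


class TestSavageDickey:
    def test_no_data_limit_is_one(self, rng):
        """Draws from the prior itself must give BF10 of 1 up to KDE error."""
        spec = MetaModelSpec(effect_prior_sd=100.0)
        draws = rng.normal(0, 100, 40_000)
        bf, bounded = bayes_factor_savage_dickey(draws, spec)
        assert not bounded
        assert bf == pytest.approx(1.0, rel=0.1)

    def test_closed_form_null_example(self):
        """Posterior N(0, 1) against prior N(0, 100): density ratio at zero
        is about 0.3989/0.003989, i.e. BF10 about 0.01."""
        eff = effects_of([0.0], [1.0])
        spec = MetaModelSpec(effect_prior_sd=100.0, tau_prior_sd=1e-3)
        summary = fit_random_effects(eff, spec, SamplerSettings(seed=11, n_warmup=300, n_draws=2000))
        expected = stats.norm.pdf(0, 0, 100) / stats.norm.pdf(0, 0, 1)
        assert summary.bf10 == pytest.approx(expected, rel=0.2)

    def test_overwhelming_evidence_is_bounded(self):
        eff = effects_of([50.0], [1.0])
        spec = MetaModelSpec(effect_prior_sd=100.0, tau_prior_sd=1e-3)
        summary = fit_random_effects(eff, spec, FAST)
        assert summary.bf10_is_lower_bound
        assert summary.bf10_display.startswith(">")

    def test_monotone_in_data_mean(self):
        spec = MetaModelSpec(effect_prior_sd=100.0, tau_prior_sd=1e-3)
        bfs = []
        for y in (0.5, 1.0, 2.0):
            s = fit_random_effects(effects_of([y], [1.0]), spec, FAST)
            bfs.append(s.bf10)
        assert bfs[0] < bfs[1] < bfs[2]

    def test_too_few_draws(self):
        with pytest.raises(PrecisionError):
            bayes_factor_savage_dickey(np.zeros(100), MetaModelSpec())


class TestSensitivitySweep:
    def test_needs_two_specs(self):
        with pytest.raises(ValueError):
            sensitivity_sweep(effects_of([5], [1]), [MetaModelSpec()], FAST)

    def test_wide_priors_agree_on_identified_data(self):
        eff = effects_of([20.0] * 15, [1.0] * 15)
        sweep = sensitivity_sweep(
            eff,
            [MetaModelSpec(100.0, 1.0), MetaModelSpec(1000.0, 1.0)],
            FAST,
        )
        means = [s.pooled_mean for s in sweep.summaries]
        assert abs(means[0] - means[1]) < 0.2

    def test_tau_prior_divergence_on_heterogeneous_data(self, rng):
        # tau_true = 15 with unequal SEs: pinning tau near 0 collapses the
        # model to fixed-effect weighting, which shifts the pooled mean
        ses = [0.5] * 20 + [8.0] * 20
        ys = rng.normal(20, 15, 40) + np.array([3.0] * 20 + [-3.0] * 20)
        sweep = sensitivity_sweep(
            effects_of(ys, ses),
            [MetaModelSpec(100.0, 1e-3), MetaModelSpec(100.0, 100.0)],
            FAST,
        )
        taus = [s.tau_mean for s in sweep.summaries]
        assert taus[1] > taus[0] + 5.0
        assert not sweep.stable

    def test_per_spec_errors_do_not_abort(self):
        eff = effects_of([5, 7], [1, 1])
        bad = object.__new__(MetaModelSpec)  # bypass validation to force a fit error
        object.__setattr__(bad, "effect_prior_sd", -1.0)
        object.__setattr__(bad, "tau_prior_sd", 1.0)
        sweep = sensitivity_sweep(eff, [MetaModelSpec(), bad], FAST)
        assert sweep.summaries[0] is not None
        assert sweep.summaries[1] is None and sweep.errors[1] is not None


class TestSimulateStudyEffects:
    def test_degenerate_tau_gives_common_truth(self):
        cfg = SyntheticMetaConfig(theta_true=20.0, tau_true=0.0, n_studies=2000,
                                  se_generator=1.0, seed=5)
        eff = simulate_study_effects(cfg)
        y = np.array([e.y for e in eff])
        assert y.std() == pytest.approx(1.0, rel=0.05)
        assert y.mean() == pytest.approx(20.0, abs=0.1)

    def test_tau_spread_matches_law_of_large_numbers(self):
        cfg = SyntheticMetaConfig(theta_true=0.0, tau_true=10.0, n_studies=10_000,
                                  se_generator=1e-9, seed=6)
        y = np.array([e.y for e in simulate_study_effects(cfg)])
        assert y.std() == pytest.approx(10.0, rel=0.02)

    def test_seed_determinism_and_callable_se(self):
        gen = lambda rng, n: rng.uniform(1.0, 3.0, n)
        cfg = SyntheticMetaConfig(theta_true=5.0, tau_true=2.0, n_studies=20,
                                  se_generator=gen, seed=9)
        a = simulate_study_effects(cfg)
        b = simulate_study_effects(cfg)
        assert [(e.y, e.se) for e in a] == [(e.y, e.se) for e in b]
        assert all(1.0 <= e.se <= 3.0 for e in a)
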