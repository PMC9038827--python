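"""Fisher-z machinery, per-study quintile effects and slope-effect correlations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pwimeta.core_data import TrialTable
from pwimeta.errors import InsufficientDataError
from pwimeta.study import (
    correlation_effect,
    fisher_z,
    fisher_z_inverse,
    fisher_z_se,
    quintile_effects,
    read_effects,
    slope_effect_correlation,
    write_effects,
)
from test_delta import profile_from_means


class TestFisherZ:
    @pytest.mark.parametrize(
        "r, expected",
        [(0.0, 0.0), (0.5, 0.5 * math.log(3)), (-0.5, -0.5 * math.log(3))],
    )
    def test_known_values(self, r, expected):
        assert fisher_z(r) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("r", [1.0, -1.0, 1.5])
    def test_domain_error(self, r):
        with pytest.raises(ValueError):
            fisher_z(r)

    @given(st.floats(min_value=-0.999, max_value=0.999))
    @settings(max_examples=80, deadline=None)
    def test_round_trip_and_oddness(self, r):
        assert fisher_z_inverse(fisher_z(r)) == pytest.approx(r, abs=1e-12)
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    def test_strictly_increasing(self):
        grid = np.linspace(-0.99, 0.99, 199)
        z = [fisher_z(r) for r in grid]
        assert np.all(np.diff(z) > 0)

    @pytest.mark.parametrize("n, expected", [(4, 1.0), (103, 0.1), (28, 0.2)])
    def test_se_formula(self, n, expected):
        assert fisher_z_se(n) == pytest.approx(expected)

    def test_se_needs_four_units(self):
        with pytest.raises(InsufficientDataError):
            fisher_z_se(3)


def _table_with_deltas(per_participant_deltas: list[list[float]]) -> TrialTable:
    """One trial per quintile per condition: sorted related RTs are
    unrelated RTs plus the requested deltas, so per-quintile deltas are
    exact."""
    base = [500.0, 550.0, 600.0, 660.0, 790.0]
    rows = []
    for p, deltas in enumerate(per_participant_deltas):
        for q in range(5):
            rows.append(("s1", f"p{p}", f"i{q}", "unrelated", base[q], True))
            rows.append(("s1", f"p{p}", f"i{q}", "related", base[q] + deltas[q], True))
    frame = pd.DataFrame(rows, columns=["study", "participant", "item", "condition", "rt", "correct"])
    return TrialTable(data=frame)


class TestQuintileEffects:
    def test_identical_participants_zero_se_with_warning(self, caplog):
        table = _table_with_deltas([[10, 10, 20, 40, 60]] * 3)
        with caplog.at_level("WARNING"):
            effects = quintile_effects(table)
        assert [e.y for e in effects] == [10, 10, 20, 40, 60]
        assert all(e.se == 0.0 for e in effects)
        assert any("variance" in r.message for r in caplog.records)

    def test_two_participant_mean_and_se(self):
        table = _table_with_deltas([[0, 0, 0, 0, 40], [0, 0, 0, 0, 60]])
        effects = quintile_effects(table)
        q5 = effects[4]
        assert q5.y == pytest.approx(50.0)
        # sample sd of {40, 60} is sqrt(200); se = sd / sqrt(2) = 10
        assert q5.se == pytest.approx(10.0)
        assert q5.n_units == 2

    def test_single_participant_errors(self):
        table = _table_with_deltas([[10, 10, 20, 40, 60]])
        with pytest.raises(InsufficientDataError):
            quintile_effects(table)

    def test_se_shrinks_with_more_participants(self, rng):
        deltas = [list(rng.normal(20, 10, 5)) for _ in range(8)]
        few = quintile_effects(_table_with_deltas(deltas))
        many = quintile_effects(_table_with_deltas(deltas * 4))
        # direct-recomputation oracle: replicating participants 4x scales
        # se by sqrt(var_ratio / 4) with the ddof-1 variance of the stack
        for q in range(5):
            col = [d[q] for d in deltas]
            expect = np.std(col * 4, ddof=1) / math.sqrt(len(col) * 4)
            assert many[q].se == pytest.approx(expect, rel=1e-9)
            assert many[q].se < few[q].se

    def test_effect_rises_across_quintiles_under_generative_defaults(self):
        # Monte-Carlo oracle over replicated full-size simulated studies
        from pwimeta.simulate import SimulationConfig, simulate_experiment

        wins = 0
        n_rep = 20
        for s in range(n_rep):
            table = simulate_experiment(SimulationConfig(seed=1000 + s))
            effects = quintile_effects(table)
            wins += effects[4].y > effects[0].y
        assert wins >= int(0.9 * n_rep)


class TestSlopeEffectCorrelation:
    def _linear_profiles(self, slopes_effects):
        # deltas split symmetrically across conditions so the combined
        # quintile means stay at [505, 555, 610, 680, 820] for every unit
        profiles = []
        for slope, effect in slopes_effects:
            d4 = 10.0
            d5 = d4 + slope * 140.0
            bases = [505.0, 555.0, 610.0, 680.0, 820.0]
            deltas = [10.0, 10.0, 20.0, d4, d5]
            related = [b + d / 2.0 for b, d in zip(bases, deltas)]
            unrelated = [b - d / 2.0 for b, d in zip(bases, deltas)]
            profiles.append(profile_from_means(related, unrelated, mean_effect=effect))
        return profiles

    def test_perfect_linearity(self):
        pairs = [(0.1 * e / 50.0, e) for e in (10.0, 20.0, 30.0, 40.0, 50.0)]
        res = slope_effect_correlation(self._linear_profiles(pairs), "slowest")
        assert res.r == pytest.approx(1.0)
        assert not math.isfinite(res.z)

    def test_constant_effects_are_degenerate(self):
        pairs = [(s, 25.0) for s in (0.05, 0.1, 0.15, 0.2, 0.25)]
        with pytest.raises(InsufficientDataError, match="zero variance"):
            slope_effect_correlation(self._linear_profiles(pairs), "slowest")

    def test_matches_definitional_sums(self):
        pairs = [(0.12, 31.0), (0.03, 12.0), (-0.08, 4.0), (0.22, 55.0), (0.05, 18.0), (0.15, 40.0)]
        res = slope_effect_correlation(self._linear_profiles(pairs), "slowest")
        s = np.array([p[0] for p in pairs])
        e = np.array([p[1] for p in pairs])
        n = len(pairs)
        num = n * np.sum(s * e) - s.sum() * e.sum()
        den = math.sqrt(n * np.sum(s**2) - s.sum() ** 2) * math.sqrt(n * np.sum(e**2) - e.sum() ** 2)
        assert res.r == pytest.approx(num / den, abs=1e-9)
        assert res.n == n

    def test_too_few_units(self):
        pairs = [(0.1, 10.0), (0.2, 20.0), (0.3, 30.0)]
        with pytest.raises(InsufficientDataError):
            slope_effect_correlation(self._linear_profiles(pairs), "slowest")

    def test_location_invariance_of_effects(self):
        pairs = [(0.12, 31.0), (0.03, 12.0), (-0.08, 4.0), (0.22, 55.0), (0.05, 18.0)]
        base = slope_effect_correlation(self._linear_profiles(pairs), "slowest")
        shifted_pairs = [(s, e + 100.0) for s, e in pairs]
        shifted = slope_effect_correlation(self._linear_profiles(shifted_pairs), "slowest")
        assert shifted.r == pytest.approx(base.r, abs=1e-12)

    def test_infinite_z_rejected_from_meta_input(self):
        pairs = [(0.1 * e / 50.0, e) for e in (10.0, 20.0, 30.0, 40.0, 50.0)]
        res = slope_effect_correlation(self._linear_profiles(pairs), "slowest")
        with pytest.raises(ValueError, match="infinite"):
            correlation_effect(res, "s1", "slowest")


def test_effects_table_round_trip(tmp_path, rng):
    from conftest import balanced_table

    effects = quintile_effects(balanced_table(6, 10, rng))
    path = tmp_path / "effects.csv"
    write_effects(effects, path)
    again = read_effects(path)
    assert [(e.study_id, e.quantity, e.n_units) for e in again] == [
        (e.study_id, e.quantity, e.n_units) for e in effects
    ]
    np.testing.assert_allclose([e.y for e in again], [e.y for e in effects])
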