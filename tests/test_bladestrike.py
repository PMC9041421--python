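"""Blade-strike models: deterministic formula, Monte Carlo engine, sensitivity."""

import math

import numpy as np
import pytest

from pshpassage.bladestrike import (
    CollinearInputsWarning,
    FishGeometry,
    StochasticSpec,
    TurbineConfig,
    apparent_length,
    deterministic_scenarios,
    interpolate_discharge,
    normal_velocity,
    run_stochastic,
    sensitivity,
    strike_probability,
    survival_from_strike,
)
from pshpassage.shear import DEFAULT_LIFE_STAGES, LifeStage, LifeStageSpec


def _fixed_length_stage(length: float, name=LifeStage.juvenile) -> LifeStageSpec:
    return LifeStageSpec(name, 10e-3, length, 0.0, length, length, 1)


class TestApparentLength:
    @pytest.mark.parametrize(
        "orientation, expected",
        [(0.0, 0.10), (90.0, 0.0), (45.0, 0.10 * math.sqrt(2) / 2)],
    )
    def test_projection(self, orientation, expected):
        assert apparent_length(FishGeometry(0.10, orientation)) == pytest.approx(
            expected, abs=1e-9
        )

    def test_orientation_out_of_range(self):
        with pytest.raises(ValueError):
            FishGeometry(0.1, 91.0)
        with pytest.raises(ValueError):
            FishGeometry(0.1, -1.0)


class TestNormalVelocity:
    def test_radial_inflow_closure(self, round_turbine):
        # Q/(πDB) with Q=120, D=5, B=1.2
        assert normal_velocity(round_turbine, 120.0) == pytest.approx(6.3662, abs=1e-4)

    def test_linearity_in_discharge(self, round_turbine):
        assert normal_velocity(round_turbine, 240.0) == pytest.approx(
            2 * normal_velocity(round_turbine, 120.0), rel=1e-12
        )

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            TurbineConfig(13, 300.0, 5.0, 0.0, ((10, 100), (20, 120), (30, 150)))


class TestStrikeProbability:
    def test_point_particle(self, round_turbine):
        assert strike_probability(round_turbine, 0.0, 120.0) == 0.0

    def test_hand_computed_value(self, round_turbine):
        # (13·300/60)·0.02/6.3662
        assert strike_probability(round_turbine, 0.02, 120.0) == pytest.approx(
            0.20420, abs=1e-5
        )

    def test_cap_at_one(self, round_turbine):
        assert strike_probability(round_turbine, 10.0, 120.0) == 1.0

    def test_monotone_in_apparent_length(self, round_turbine):
        ps = [strike_probability(round_turbine, l, 120.0) for l in np.linspace(0, 0.2, 25)]
        assert all(b >= a for a, b in zip(ps, ps[1:]))

    def test_monotone_in_blades_and_rpm(self, round_turbine):
        def with_blades(n):
            return TurbineConfig(n, 300.0, 5.0, 1.2, round_turbine.operating_table)

        ps = [strike_probability(with_blades(n), 0.005, 120.0) for n in range(1, 20)]
        assert all(b >= a for a, b in zip(ps, ps[1:]))


class TestSurvivalTransform:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (0.0, 1.0),
            (0.1731, 0.8269),  # most strike-prone stage: larger adults
            (0.0023, 0.9977),  # egg-scale strike probability
        ],
    )
    def test_complement(self, p, expected):
        assert survival_from_strike(p) == pytest.approx(expected, abs=1e-12)

    def test_mutilation_ratio_scales_lethality(self):
        assert survival_from_strike(0.5, mutilation_ratio=0.4) == pytest.approx(0.8)

    def test_identity_s_plus_mr_p(self):
        for p in np.linspace(0, 1, 11):
            for mr in (0.0, 0.3, 1.0):
                assert survival_from_strike(p, mr) + mr * p == pytest.approx(1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            survival_from_strike(1.2)
        with pytest.raises(ValueError):
            survival_from_strike(0.5, mutilation_ratio=-0.1)


class TestInterpolateDischarge:
    def test_node_identity(self, round_turbine):
        for angle, q in round_turbine.operating_table:
            assert interpolate_discharge(round_turbine, angle) == q

    def test_midpoint_linearity(self, round_turbine):
        assert interpolate_discharge(round_turbine, 15.0) == pytest.approx(110.0)

    def test_no_extrapolation(self, round_turbine):
        with pytest.raises(ValueError):
            interpolate_discharge(round_turbine, 5.0)
        with pytest.raises(ValueError):
            interpolate_discharge(round_turbine, 31.0)


class TestDeterministicScenarios:
    def test_grid_size(self, round_turbine, juvenile_spec):
        assert len(deterministic_scenarios(round_turbine, juvenile_spec)) == 9

    def test_zero_length_stage_survives_everywhere(self, round_turbine):
        stage = LifeStageSpec(LifeStage.egg, 1e-3, 0.0, 0.0, 0.0, 0.0, 1)
        for r in deterministic_scenarios(round_turbine, stage):
            assert r.strike_probability == 0.0
            assert r.survival == 1.0

    def test_strike_linear_in_apparent_length(self, round_turbine):
        expect = {0.01: 0.10210, 0.02: 0.20420, 0.03: 0.30630}
        for l_app, p in expect.items():
            assert strike_probability(round_turbine, l_app, 120.0) == pytest.approx(
                p, abs=1e-5
            )

    def test_missing_scenarios_rejected(self):
        with pytest.raises(ValueError):
            TurbineConfig(13, 300.0, 5.0, 1.2, ((10, 100), (20, 120)))


class TestRunStochastic:
    def test_degenerate_collapses_to_deterministic(self, round_turbine):
        stage = _fixed_length_stage(0.08)
        spec = StochasticSpec(
            seed=11, n_realizations=500,
            gate_angle_min=20.0, gate_angle_max=20.0,
            orientation_min=30.0, orientation_max=30.0,
        )
        res = run_stochastic(round_turbine, stage, spec)
        l_app = 0.08 * math.cos(math.radians(30.0))
        det = strike_probability(round_turbine, l_app, 120.0)
        assert res.mean_strike_probability == pytest.approx(det, abs=1e-12)

    def test_seed_determinism(self, round_turbine, juvenile_spec):
        spec = StochasticSpec(seed=42, n_realizations=2000)
        a = run_stochastic(round_turbine, juvenile_spec, spec)
        b = run_stochastic(round_turbine, juvenile_spec, spec)
        assert a.mean_strike_probability == b.mean_strike_probability
        assert a.realization_quantiles == b.realization_quantiles
        assert a.draws.equals(b.draws)

    def test_uniform_orientation_matches_cosine_expectation(self, round_turbine):
        """E[cos θ] over uniform [0°, 90°] is 2/π, so the Monte Carlo mean of P
        must match the broadside deterministic value scaled by 2/π."""
        stage = _fixed_length_stage(0.05)
        spec = StochasticSpec(
            seed=7, n_realizations=10_000,
            gate_angle_min=20.0, gate_angle_max=20.0,
        )
        res = run_stochastic(round_turbine, stage, spec)
        p_broadside = strike_probability(round_turbine, 0.05, 120.0)
        assert p_broadside < 1.0  # cap must not bind
        expected = p_broadside * 2 / math.pi
        mc_se = res.draws["strike_probability"].std() / math.sqrt(10_000)
        assert abs(res.mean_strike_probability - expected) < 3 * mc_se

    def test_mc_standard_error_scales_inverse_sqrt_n(self, round_turbine, juvenile_spec):
        ses = {}
        for n in (100, 1_000, 10_000):
            res = run_stochastic(
                round_turbine, juvenile_spec, StochasticSpec(seed=5, n_realizations=n)
            )
            ses[n] = res.draws["strike_probability"].std() / math.sqrt(n)
        assert ses[100] / ses[10_000] == pytest.approx(10.0, rel=0.25)
        assert ses[1_000] / ses[10_000] == pytest.approx(math.sqrt(10), rel=0.25)

    def test_life_stage_ordering(self, round_turbine):
        """Stages with ordered length distributions have ordered strike risk."""
        means = []
        for stage in (LifeStage.egg, LifeStage.larva_12_18, LifeStage.larva_28_30,
                      LifeStage.juvenile, LifeStage.adult):
            res = run_stochastic(
                round_turbine,
                DEFAULT_LIFE_STAGES[stage],
                StochasticSpec(seed=3, n_realizations=4000),
            )
            means.append(res.mean_strike_probability)
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_inconsistent_gate_bounds_rejected(self, round_turbine, juvenile_spec):
        spec = StochasticSpec(seed=1, gate_angle_min=5.0, gate_angle_max=40.0)
        with pytest.raises(ValueError):
            run_stochastic(round_turbine, juvenile_spec, spec)

    def test_probabilities_always_in_unit_interval(self, round_turbine):
        res = run_stochastic(
            round_turbine,
            DEFAULT_LIFE_STAGES[LifeStage.adult],
            StochasticSpec(seed=2, n_realizations=3000),
        )
        p = res.draws["strike_probability"]
        assert ((0 <= p) & (p <= 1)).all()
        assert 0 <= res.mean_survival <= 1


class TestSensitivity:
    def test_single_driver_dominates(self, round_turbine):
        """With orientation fixed and a closure ignoring discharge, P is linear
        in length only: its standardized coefficient is 1, gate angle's is 0."""
        stage = LifeStageSpec(LifeStage.juvenile, 10e-3, 0.08, 0.01, 0.05, 0.11, 1)
        spec = StochasticSpec(
            seed=9, n_realizations=5000, orientation_min=0.0, orientation_max=0.0
        )
        res = run_stochastic(
            round_turbine, stage, spec, closure=lambda t, q: 50.0
        )
        assert abs(res.sensitivity["length"]) == pytest.approx(1.0, abs=0.02)
        assert abs(res.sensitivity["gate_angle"]) == pytest.approx(0.0, abs=0.02)

    def test_constant_output_is_undefined(self):
        coefs, defined = sensitivity(
            {"x": np.arange(10.0)}, np.ones(10)
        )
        assert not defined
        assert np.isnan(coefs["x"])

    def test_collinear_inputs_warn(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        y = 2 * x + rng.normal(size=100) * 0.1
        with pytest.warns(CollinearInputsWarning):
            sensitivity({"a": x, "b": 3 * x}, y)

    def test_constant_input_gets_zero_coefficient(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        coefs, defined = sensitivity({"x": x, "c": np.full(200, 7.0)}, 2 * x)
        assert defined
        assert coefs["c"] == 0.0
        assert coefs["x"] == pytest.approx(1.0, abs=1e-9)
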