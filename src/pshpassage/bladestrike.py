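"""Blade-strike probability models for a reversible Francis turbine.

The deterministic model is the classical passage-time argument: a fish of
apparent (flow-normal projected) length ``L·cosθ`` crossing the runner plane
at water velocity ``V`` is exposed to blades passing at rate ``n·N/60``
(blades × revolutions per second), giving a strike probability

    P = min(1, (n · N / 60) · L·cosθ / V)

Survival is the complement ``S = 1 − MR·P``, where the mutilation ratio MR
is the fraction of strikes that are lethal (1 by default: every strike is
assumed fatal, a conservative choice).

The stochastic model propagates operational and biological variability by
Monte Carlo: wicket-gate angle uniform over the operating range (discharge
linearly interpolated from the machine's operating table), fish orientation
uniform on [0°, 90°], and fish length truncated-normal.  Input importance is
summarized by standardized (z-scored) multiple-regression coefficients of
strike probability on the drawn inputs.

Turbine geometry and operating tables for real machines are typically
proprietary; they enter only through :class:`TurbineConfig`, and
:func:`pshpassage.synth.gen_turbine_config` generates plausible stand-ins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pshpassage.shear import LifeStage, LifeStageSpec


class CollinearInputsWarning(UserWarning):
    """Raised when sensitivity inputs are rank-deficient (collinear)."""


@dataclass(frozen=True)
class TurbineConfig:
    """Reversible Francis runner geometry and operating table.

    ``operating_table`` maps wicket-gate opening angle (degrees) to machine
    discharge (m³ s⁻¹) and must be strictly increasing in both columns, with
    at least entries for minimum, mid-point and maximum flow.
    """

    n_blades: int
    rotation_speed_rpm: float
    runner_inlet_diameter: float  # m
    runner_inlet_height: float  # m (distributor height B)
    operating_table: tuple[tuple[float, float], ...]  # (gate angle deg, Q m3/s)

    def __post_init__(self) -> None:
        if self.n_blades < 1:
            raise ValueError("n_blades must be >= 1")
        if self.rotation_speed_rpm <= 0:
            raise ValueError("rotation_speed_rpm must be > 0")
        if self.runner_inlet_diameter <= 0 or self.runner_inlet_height <= 0:
            raise ValueError("runner geometry must be strictly positive")
        if len(self.operating_table) < 3:
            raise ValueError("operating_table needs min, mid and max flow entries")
        angles = [a for a, _ in self.operating_table]
        flows = [q for _, q in self.operating_table]
        if any(b <= a for a, b in zip(angles, angles[1:])):
            raise ValueError("gate angles must be strictly increasing")
        if any(b <= a for a, b in zip(flows, flows[1:])):
            raise ValueError("discharge must be strictly increasing with gate angle")
        if flows[0] <= 0:
            raise ValueError("discharges must be positive")

    @property
    def gate_angle_range(self) -> tuple[float, float]:
        return self.operating_table[0][0], self.operating_table[-1][0]

    def scenario_discharges(self) -> dict[str, float]:
        """Minimum, mid-point and maximum flow from the operating table."""
        flows = [q for _, q in self.operating_table]
        return {
            "min": flows[0],
            "mid": flows[len(flows) // 2],
            "max": flows[-1],
        }


@dataclass(frozen=True)
class FishGeometry:
    """A fish presented to the runner: body length and orientation to flow.

    Orientation 0° is broadside (full length exposed to the blade plane);
    90° is head-on (zero projected length).
    """

    length: float  # m
    orientation: float  # degrees in [0, 90]

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("length must be >= 0")
        if not 0.0 <= self.orientation <= 90.0:
            raise ValueError("orientation must lie in [0, 90] degrees")


@dataclass(frozen=True)
class StrikeResult:
    """Deterministic strike outcome for one flow scenario and fish size."""

    flow_scenario: str  # min | mid | max
    length_scenario: str  # min | mean | max
    strike_probability: float
    survival: float
    apparent_length: float  # m
    normal_velocity: float  # m s⁻¹
    discharge: float  # m³ s⁻¹


@dataclass(frozen=True)
class StochasticSpec:
    """Monte Carlo specification for the stochastic strike model.

    All three inputs are random: gate angle ~ Uniform(min, max), orientation
    ~ Uniform(0°, 90°), length ~ Normal(mean, sd) truncated to
    [length_min, length_max].  The seed is mandatory; there is no implicit
    global random state.
    """

    seed: int
    n_realizations: int = 10_000
    gate_angle_min: float | None = None  # default: operating-table span
    gate_angle_max: float | None = None
    orientation_min: float = 0.0
    orientation_max: float = 90.0
    mutilation_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if not 0.0 <= self.orientation_min <= self.orientation_max <= 90.0:
            raise ValueError("orientation bounds must satisfy 0 <= min <= max <= 90")
        if not 0.0 <= self.mutilation_ratio <= 1.0:
            raise ValueError("mutilation_ratio must lie in [0, 1]")


@dataclass(frozen=True)
class StochasticStrikeResult:
    """Monte Carlo summary: means, quantiles, sensitivity, and the draws."""

    life_stage: LifeStage
    mean_strike_probability: float
    mean_survival: float
    realization_quantiles: tuple[float, float, float]  # 2.5%, 50%, 97.5% of P
    sensitivity: Mapping[str, float]
    sensitivity_defined: bool
    n_realizations: int
    draws: pd.DataFrame = field(repr=False, compare=False)


NormalVelocityClosure = Callable[[TurbineConfig, float], float]


def normal_velocity(turbine: TurbineConfig, discharge: float) -> float:
    """Water velocity normal to the runner entrance plane, m s⁻¹.

    Default closure: radial inflow through the runner entrance cylinder,
    ``V = Q / (π D B)`` with D the runner inlet diameter and B the
    distributor height.  Alternative closures (e.g. a full Francis velocity
    triangle) can be passed wherever a closure is accepted.
    """
    if discharge <= 0:
        raise ValueError("discharge must be > 0")
    if turbine.runner_inlet_diameter <= 0 or turbine.runner_inlet_height <= 0:
        raise ValueError("runner geometry must be strictly positive")
    return discharge / (
        math.pi * turbine.runner_inlet_diameter * turbine.runner_inlet_height
    )


def apparent_length(fish: FishGeometry) -> float:
    """Projected fish length normal to the flow: L·cos(orientation)."""
    return fish.length * math.cos(math.radians(fish.orientation))


def strike_probability(
    turbine: TurbineConfig,
    apparent_length_m: float,
    discharge: float,
    closure: NormalVelocityClosure = normal_velocity,
) -> float:
    """Probability that a blade passes while the fish crosses the blade plane.

    ``P = min(1, (n·N/60) · L_app / V)`` — the ratio of fish transit time
    ``L_app/V`` to blade-passing period ``60/(n·N)``, capped at 1.
    """
    if apparent_length_m < 0:
        raise ValueError("apparent_length must be >= 0")
    v = closure(turbine, discharge)
    if v <= 0:
        raise ZeroDivisionError("normal velocity must be > 0 (degenerate flow)")
    blade_rate = turbine.n_blades * turbine.rotation_speed_rpm / 60.0
    return min(1.0, blade_rate * apparent_length_m / v)


def survival_from_strike(p: float, mutilation_ratio: float = 1.0) -> float:
    """Survival S = 1 − MR·P, with MR the fraction of strikes that are lethal."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("strike probability must lie in [0, 1]")
    if not 0.0 <= mutilation_ratio <= 1.0:
        raise ValueError("mutilation_ratio must lie in [0, 1]")
    return 1.0 - mutilation_ratio * p


def interpolate_discharge(turbine: TurbineConfig, gate_angle: float) -> float:
    """Discharge at a wicket-gate angle, piecewise-linear over the table.

    No extrapolation: angles outside the table span raise.
    """
    lo, hi = turbine.gate_angle_range
    if not lo <= gate_angle <= hi:
        raise ValueError(f"gate angle {gate_angle} outside table span [{lo}, {hi}]")
    angles = np.array([a for a, _ in turbine.operating_table])
    flows = np.array([q for _, q in turbine.operating_table])
    return float(np.interp(gate_angle, angles, flows))


def deterministic_scenarios(
    turbine: TurbineConfig,
    stage: LifeStageSpec,
    orientation: float = 45.0,
    mutilation_ratio: float = 1.0,
    closure: NormalVelocityClosure = normal_velocity,
) -> list[StrikeResult]:
    """The 3 × 3 deterministic block: {min, mid, max} flow × {min, mean, max} length.

    Orientation is fixed (default 45°, the midpoint of the admissible range,
    since a deterministic run yields a single estimate per input combination).
    """
    discharges = turbine.scenario_discharges()
    lengths = {
        "min": stage.length_min,
        "mean": stage.length_mean,
        "max": stage.length_max,
    }
    out: list[StrikeResult] = []
    for flow_name, q in discharges.items():
        v = closure(turbine, q)
        for len_name, length in lengths.items():
            l_app = apparent_length(FishGeometry(length, orientation))
            p = strike_probability(turbine, l_app, q, closure=closure)
            out.append(
                StrikeResult(
                    flow_scenario=flow_name,
                    length_scenario=len_name,
                    strike_probability=p,
                    survival=survival_from_strike(p, mutilation_ratio),
                    apparent_length=l_app,
                    normal_velocity=v,
                    discharge=q,
                )
            )
    return out


def _draw_truncnorm(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    """Truncated-normal draws on [lo, hi]; degenerate sd collapses to the mean."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return np.full(n, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def run_stochastic(
    turbine: TurbineConfig,
    stage: LifeStageSpec,
    spec: StochasticSpec,
    closure: NormalVelocityClosure = normal_velocity,
) -> StochasticStrikeResult:
    """Monte Carlo strike model for one life stage.

    Per realization, draw (gate angle, orientation, length), interpolate
    discharge, and evaluate the deterministic strike probability.  Identical
    seeds give identical output.
    """
    lo, hi = turbine.gate_angle_range
    a_min = spec.gate_angle_min if spec.gate_angle_min is not None else lo
    a_max = spec.gate_angle_max if spec.gate_angle_max is not None else hi
    if not lo <= a_min <= a_max <= hi:
        raise ValueError(
            f"gate-angle distribution [{a_min}, {a_max}] inconsistent with "
            f"operating table span [{lo}, {hi}]"
        )

    rng = np.random.default_rng(spec.seed)
    n = spec.n_realizations
    gate = rng.uniform(a_min, a_max, n) if a_max > a_min else np.full(n, a_min)
    orient = (
        rng.uniform(spec.orientation_min, spec.orientation_max, n)
        if spec.orientation_max > spec.orientation_min
        else np.full(n, spec.orientation_min)
    )
    length = _draw_truncnorm(
        rng, stage.length_mean, stage.length_sd, stage.length_min, stage.length_max, n
    )

    angles = np.array([a for a, _ in turbine.operating_table])
    flows = np.array([q for _, q in turbine.operating_table])
    discharge = np.interp(gate, angles, flows)
    l_app = length * np.cos(np.radians(orient))
    blade_rate = turbine.n_blades * turbine.rotation_speed_rpm / 60.0
    v = np.array([closure(turbine, q) for q in discharge])
    p = np.minimum(1.0, blade_rate * l_app / v)
    s = 1.0 - spec.mutilation_ratio * p

    draws = pd.DataFrame(
        {
            "realization": np.arange(n),
            "gate_angle_deg": gate,
            "discharge_m3_s": discharge,
            "orientation_deg": orient,
            "length_m": length,
            "strike_probability": p,
        }
    )
    sens, defined = sensitivity(
        {"length": length, "gate_angle": gate, "orientation": orient}, p
    )
    q025, q50, q975 = np.quantile(p, [0.025, 0.5, 0.975])
    return StochasticStrikeResult(
        life_stage=stage.name,
        mean_strike_probability=float(p.mean()),
        mean_survival=float(s.mean()),
        realization_quantiles=(float(q025), float(q50), float(q975)),
        sensitivity=sens,
        sensitivity_defined=defined,
        n_realizations=n,
        draws=draws,
    )


def sensitivity(
    inputs: Mapping[str, np.ndarray], outputs: np.ndarray
) -> tuple[dict[str, float], bool]:
    """Standardized regression coefficients of the output on each input.

    Inputs and output are z-scored and the coefficients come from one joint
    ordinary-least-squares fit; a coefficient near ±1 marks the dominant
    driver, near 0 an irrelevant one.  Constant inputs get coefficient 0
    (they cannot drive anything).  A constant output leaves every
    coefficient undefined (NaN, flagged via the second return value), and
    collinear non-constant inputs trigger :class:`CollinearInputsWarning`
    with minimum-norm coefficients.
    """
    names = list(inputs)
    arrays = [np.asarray(inputs[k], dtype=float) for k in names]
    y = np.asarray(outputs, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 realizations for sensitivity")
    if np.std(y) == 0:
        return {k: float("nan") for k in names}, False

    yz = (y - y.mean()) / y.std()
    cols, active = [], []
    for k, x in zip(names, arrays):
        sd = x.std()
        if sd == 0:
            continue
        cols.append((x - x.mean()) / sd)
        active.append(k)
    coefs = dict.fromkeys(names, 0.0)
    if cols:
        X = np.column_stack(cols)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            warnings.warn(
                "sensitivity inputs are collinear; coefficients are the "
                "minimum-norm least-squares solution",
                CollinearInputsWarning,
                stacklevel=2,
            )
        beta, *_ = np.linalg.lstsq(X, yz, rcond=None)
        for k, b in zip(active, beta):
            coefs[k] = float(b)
    return coefs, True


def results_to_frame(
    deterministic: Mapping[LifeStage, Sequence[StrikeResult]],
    stochastic: Mapping[LifeStage, StochasticStrikeResult] | None = None,
) -> pd.DataFrame:
    """Combine per-stage deterministic and stochastic blocks into one table.

    Mirrors the usual reporting layout: strike probability and survival per
    (flow scenario × length scenario) plus Monte Carlo means and the
    standardized sensitivity coefficients.
    """
    rows = []
    for stage, results in deterministic.items():
        for r in results:
            rows.append(
                {
                    "life_stage": stage.value,
                    "model": "deterministic",
                    "flow_scenario": r.flow_scenario,
                    "length_scenario": r.length_scenario,
                    "strike_probability": r.strike_probability,
                    "survival": r.survival,
                    "sensitivity_length": np.nan,
                    "sensitivity_gate_angle": np.nan,
                }
            )
        if stochastic and stage in stochastic:
            s = stochastic[stage]
            rows.append(
                {
                    "life_stage": stage.value,
                    "model": "stochastic",
                    "flow_scenario": "mc",
                    "length_scenario": "mc",
                    "strike_probability": s.mean_strike_probability,
                    "survival": s.mean_survival,
                    "sensitivity_length": s.sensitivity.get("length", np.nan),
                    "sensitivity_gate_angle": s.sensitivity.get("gate_angle", np.nan),
                }
            )
    return pd.DataFrame(rows)
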