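"""Shear-flume hydraulics and the shear treatment grid.

A submerged-jet flume generates fluid shear by accelerating flow through a
conical nozzle (15 cm inlet to 5 cm outlet).  A pressure gauge upstream of
the nozzle gives the head differential ``H``; Bernoulli's relation
``H = v²/(2g)`` converts it to the jet velocity, and the exposure metric is
the characteristic shear strain rate

    e = v / y   [s⁻¹]

where ``y`` is the body width of the test organism (egg diameter, larval or
juvenile body width) taken as the distance perpendicular to the force.  The
same four jet velocities therefore map to a different strain-rate ladder for
each life stage: small organisms resolve the velocity gradient over a
shorter distance and experience higher strain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

#: Height of a water column exerting 1 psi, fresh water at 4 °C [m/psi].
PSI_TO_M_WATER = 0.703070

#: Standard gravitational acceleration [m s⁻²].
STANDARD_GRAVITY = 9.81


class LifeStage(str, Enum):
    """Developmental stages assessed for PSH passage survival."""

    egg = "egg"
    larva_12_18 = "larva_12_18"  # 12-18 days post-hatching
    larva_28_30 = "larva_28_30"  # 28-30 days post-hatching
    juvenile = "juvenile"
    adult = "adult"


@dataclass(frozen=True)
class FlumeConfig:
    """Geometry and instrumentation of the shear flume.

    Parameters
    ----------
    gravitational_acceleration : float
        Local gravity, m s⁻².
    gauge_range_psi : tuple of float
        (min, max) readable gauge pressure in psi.
    nozzle_inlet_diameter : float
        Nozzle entry diameter, m.
    nozzle_outlet_diameter : float
        Nozzle exit (jet) diameter, m; must be smaller than the inlet.
    """

    gravitational_acceleration: float = STANDARD_GRAVITY
    gauge_range_psi: tuple[float, float] = (0.0, 45.0)
    nozzle_inlet_diameter: float = 0.15
    nozzle_outlet_diameter: float = 0.05

    def __post_init__(self) -> None:
        if self.gravitational_acceleration <= 0:
            raise ValueError("gravitational_acceleration must be > 0")
        lo, hi = self.gauge_range_psi
        if lo < 0 or hi <= lo:
            raise ValueError("gauge_range_psi must satisfy 0 <= min < max")
        if not 0 < self.nozzle_outlet_diameter < self.nozzle_inlet_diameter:
            raise ValueError("nozzle outlet diameter must be in (0, inlet diameter)")


@dataclass(frozen=True)
class LifeStageSpec:
    """Biometrics of one life stage.

    ``characteristic_width_y`` is the body width used as the shear length
    scale; the length fields parameterize the (truncated normal) size
    distribution used by the blade-strike models.  Units are metres.
    """

    name: LifeStage
    characteristic_width_y: float
    length_mean: float
    length_sd: float
    length_min: float
    length_max: float
    n_per_replicate: int

    def __post_init__(self) -> None:
        if self.characteristic_width_y <= 0:
            raise ValueError("characteristic_width_y must be > 0")
        if not self.length_min <= self.length_mean <= self.length_max:
            raise ValueError("require length_min <= length_mean <= length_max")
        if self.length_sd < 0:
            raise ValueError("length_sd must be >= 0")
        if self.n_per_replicate < 1:
            raise ValueError("n_per_replicate must be >= 1")


@dataclass(frozen=True)
class ShearTreatment:
    """One cell of the shear exposure design: a life stage at one strain rate."""

    life_stage: LifeStage
    jet_velocity: float  # m s⁻¹
    strain_rate: float  # s⁻¹
    is_control: bool

    def __post_init__(self) -> None:
        if self.is_control and self.strain_rate != 0.0:
            raise ValueError("control treatments must have strain_rate == 0")


DEFAULT_FLUME = FlumeConfig()

# Body widths y: 1.5 mm (egg diameter), 1 mm (larvae 12-18 DPH),
# 2 mm (larvae 28-30 DPH), 10 mm (juveniles).  Length distributions and the
# adult width are synthetic stand-ins on the scale of Perca fluviatilis
# biometrics (raw measurement tables are not public).
DEFAULT_LIFE_STAGES: dict[LifeStage, LifeStageSpec] = {
    LifeStage.egg: LifeStageSpec(
        LifeStage.egg, characteristic_width_y=1.5e-3,
        length_mean=1.5e-3, length_sd=0.1e-3, length_min=1.2e-3,
        length_max=1.8e-3, n_per_replicate=25,
    ),
    LifeStage.larva_12_18: LifeStageSpec(
        LifeStage.larva_12_18, characteristic_width_y=1.0e-3,
        length_mean=7.0e-3, length_sd=1.0e-3, length_min=4.5e-3,
        length_max=9.5e-3, n_per_replicate=15,
    ),
    LifeStage.larva_28_30: LifeStageSpec(
        LifeStage.larva_28_30, characteristic_width_y=2.0e-3,
        length_mean=12.0e-3, length_sd=1.5e-3, length_min=8.0e-3,
        length_max=16.0e-3, n_per_replicate=10,
    ),
    LifeStage.juvenile: LifeStageSpec(
        LifeStage.juvenile, characteristic_width_y=10.0e-3,
        length_mean=0.080, length_sd=0.010, length_min=0.055,
        length_max=0.105, n_per_replicate=1,
    ),
    LifeStage.adult: LifeStageSpec(
        LifeStage.adult, characteristic_width_y=30.0e-3,
        length_mean=0.25, length_sd=0.03, length_min=0.17,
        length_max=0.33, n_per_replicate=1,
    ),
}

#: The four jet velocities of the exposure design, m s⁻¹.  Reconstructed from
#: the published per-stage strain-rate ladders (e = v/y): every printed strain
#: for every stage is one of these velocities divided by that stage's width.
DEFAULT_JET_VELOCITIES: tuple[float, ...] = (5.05, 12.61, 16.87, 18.53)

#: Stages exposed in the flume (adults are too large for the delivery tube).
SHEAR_TESTED_STAGES: tuple[LifeStage, ...] = (
    LifeStage.egg,
    LifeStage.larva_12_18,
    LifeStage.larva_28_30,
    LifeStage.juvenile,
)


def velocity_from_head(head: float, flume: FlumeConfig = DEFAULT_FLUME) -> float:
    """Jet velocity from the head differential across the nozzle.

    Bernoulli's equation with the gauge static head converted to velocity
    head: ``v = sqrt(2 g H)``.

    Parameters
    ----------
    head : float
        Head differential in metres of water, >= 0.

    Returns
    -------
    float
        Jet velocity, m s⁻¹.
    """
    if head < 0:
        raise ValueError(f"head must be >= 0, got {head}")
    return math.sqrt(2.0 * flume.gravitational_acceleration * head)


def head_from_gauge(gauge_reading_psi: float, flume: FlumeConfig = DEFAULT_FLUME) -> float:
    """Convert a gauge reading (psi) to head in metres of water.

    Raises
    ------
    ValueError
        If the reading lies outside the gauge's readable range.
    """
    lo, hi = flume.gauge_range_psi
    if not lo <= gauge_reading_psi <= hi:
        raise ValueError(
            f"gauge reading {gauge_reading_psi} psi outside gauge range [{lo}, {hi}]"
        )
    return gauge_reading_psi * PSI_TO_M_WATER


def strain_rate(jet_velocity: float, life_stage: LifeStageSpec) -> float:
    """Characteristic shear strain rate e = v/y for one life stage, s⁻¹.

    The jet velocity gradient is resolved over the organism's body width
    ``y``, so at a shared velocity smaller stages experience proportionally
    higher strain.
    """
    if jet_velocity < 0:
        raise ValueError("jet_velocity must be >= 0")
    if life_stage.characteristic_width_y <= 0:
        raise ValueError("characteristic_width_y must be > 0")
    return jet_velocity / life_stage.characteristic_width_y


def design_treatments(
    velocities: Sequence[float] = DEFAULT_JET_VELOCITIES,
    stages: Iterable[LifeStageSpec] | None = None,
) -> list[ShearTreatment]:
    """Build the full shear treatment grid.

    One treatment per (velocity × stage) plus one 0 s⁻¹ control per stage.
    The same velocities are shared across stages; each stage's strain ladder
    is the velocity grid divided by its characteristic width.
    """
    stages = list(stages) if stages is not None else [
        DEFAULT_LIFE_STAGES[s] for s in SHEAR_TESTED_STAGES
    ]
    velocities = list(velocities)
    if not velocities or not stages:
        raise ValueError("need at least one velocity and one life stage")
    if any(v < 0 for v in velocities):
        raise ValueError("velocities must be non-negative")
    if len(set(velocities)) != len(velocities):
        raise ValueError("velocities must be distinct")

    out: list[ShearTreatment] = []
    for stage in stages:
        out.append(ShearTreatment(stage.name, 0.0, 0.0, is_control=True))
        for v in velocities:
            out.append(
                ShearTreatment(stage.name, v, strain_rate(v, stage), is_control=False)
            )
    return out


def treatments_to_frame(treatments: Sequence[ShearTreatment]) -> pd.DataFrame:
    """Tabulate a treatment grid (full precision; round for display only)."""
    return pd.DataFrame(
        {
            "life_stage": [t.life_stage.value for t in treatments],
            "jet_velocity_m_s": [t.jet_velocity for t in treatments],
            "strain_rate_per_s": [t.strain_rate for t in treatments],
            "is_control": [t.is_control for t in treatments],
        }
    )
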