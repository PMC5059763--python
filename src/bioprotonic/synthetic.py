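"""Synthetic chronoamperometry traces for the five device conditions.

No experimental traces are deposited with the study, so testing the
dynamics and the permeability fit requires a stand-in: this module
generates seeded, noisy current-density time series from the forward
model itself, one preset per experimental condition:

========================  ====================================================
``slb``                   bare DOPC bilayer (P = 0.006)
``slb_gA``                bilayer with gramicidin A, always open (P = 0.58)
``slb_gA_ca_block``       gA preset with the channel blocked by Ca²⁺
``slb_alm``               bilayer with alamethicin, ±60 mV gated (P = 0.74)
``slb_alm_urea``          ALM preset with the channels disrupted by urea
========================  ====================================================

Protocols mirror the chronoamperometry experiments: −200 mV and 0 mV
steps of 10 min each for the gA-family devices, plus a +100 mV step for
the ALM-family devices. Noise is additive i.i.d. Gaussian on the
measured current only (the simplest model consistent with RMS error
bars); pH and membrane-flux columns stay clean.

The preset electrode parameters (i0 = 10 A m⁻², α = 0.5, V0 = 0 V) are
calibration choices of this package, not measured values: they put the
contact in the regime where reduction initially outpaces membrane
transport at −200 mV and the two currents then converge, which is the
qualitative regime the device model is meant to exhibit. In particular
V0 = 0 replaces the nominal Pd/Ag-AgCl offset of −0.22233 V, which
would put the contact at a weakly positive overpotential at −200 mV/pH 7
(oxidation where reduction is observed); see docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .dynamics import DeviceSystem, Trace, VoltageProtocol, integrate_protocol
from .transport import (
    DEFAULT_CONSTANTS,
    PHOSPHATE_5MM,
    CellGeometry,
    ChannelGating,
    ElectrodeSpec,
    MembraneSpec,
    SolutionSpec,
    electrode_current_density,
)

__all__ = [
    "CONDITION_NAMES",
    "DeviceCondition",
    "NoiseSpec",
    "condition_config",
    "generate_trace",
    "generate_iv_sweep",
]

CONDITION_NAMES = ("slb", "slb_gA", "slb_gA_ca_block", "slb_alm", "slb_alm_urea")

#: Fitted device-scale permeabilities (printed in s⁻¹): bare bilayer,
#: bilayer + gramicidin A, bilayer + alamethicin.
P_SLB = 0.006
P_GA = 0.58
P_ALM = 0.74

_STEP_S = 600.0  # 10 min per protocol segment


@dataclass(frozen=True)
class DeviceCondition:
    """One experimental condition, optionally with parameter overrides.

    ``overrides`` maps dotted attribute paths on the device system
    (e.g. ``"electrode.i0"`` or ``"geometry.D_IL"``) to replacement
    values.
    """

    name: str
    overrides: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        if self.name not in CONDITION_NAMES:
            raise ValueError(
                f"unknown condition {self.name!r}; valid names are {', '.join(CONDITION_NAMES)}"
            )


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian measurement noise on the current column.

    sigma
        Noise standard deviation; in mA cm⁻² for mode ``"absolute"``, or
        as a fraction of max |i| for mode ``"fraction_of_max"``.
    seed
        Seed for the random generator; identical seeds give identical
        traces.
    """

    sigma: float = 0.0
    seed: int = 0
    mode: str = "absolute"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.mode not in ("absolute", "fraction_of_max"):
            raise ValueError(f"noise mode must be 'absolute' or 'fraction_of_max', got {self.mode!r}")


def _membrane_for(name: str) -> MembraneSpec:
    if name == "slb":
        return MembraneSpec(P_base=P_SLB, P_channel=P_SLB)
    if name == "slb_gA":
        return MembraneSpec(P_base=P_SLB, P_channel=P_GA)
    if name == "slb_gA_ca_block":
        return MembraneSpec(P_base=P_SLB, P_channel=P_GA, block_factor=0.0)
    gating = ChannelGating(mode="voltage_threshold", v_threshold_pos=0.06, v_threshold_neg=0.06)
    if name == "slb_alm":
        return MembraneSpec(P_base=P_SLB, P_channel=P_ALM, gating=gating)
    return MembraneSpec(P_base=P_SLB, P_channel=P_ALM, gating=gating, block_factor=0.0)


def _apply_override(system: DeviceSystem, path: str, value: Any) -> DeviceSystem:
    parts = path.split(".")
    if len(parts) < 2:
        raise ValueError(f"override path {path!r} must be dotted, e.g. 'electrode.i0'")

    def rebuild(obj: Any, keys: list[str]) -> Any:
        if len(keys) == 1:
            if not hasattr(obj, keys[0]):
                raise ValueError(f"override path {path!r}: no field {keys[0]!r} on {type(obj).__name__}")
            return dataclasses.replace(obj, **{keys[0]: value})
        child = getattr(obj, keys[0])
        return dataclasses.replace(obj, **{keys[0]: rebuild(child, keys[1:])})

    return rebuild(system, parts)


def condition_config(
    condition: DeviceCondition | str,
    sample_dt: float = 1.0,
) -> tuple[DeviceSystem, VoltageProtocol]:
    """Device system and voltage protocol for one experimental condition.

    All presets share the solution (pH 7, 5 mol m⁻³ phosphate buffer),
    geometry (D_IL = 0.5 nm, 100 µm² contact) and electrode calibration
    (i0 = 10 A m⁻², α = 0.5, V0 = 0 V, 50 nm Pd). gA-family conditions
    run −200 mV / 0 mV (10 min each); ALM-family conditions add a
    +100 mV segment.
    """
    if isinstance(condition, str):
        condition = DeviceCondition(condition)
    system = DeviceSystem(
        solution=SolutionSpec(pH_B=7.0, buffer=PHOSPHATE_5MM),
        membrane=_membrane_for(condition.name),
        electrode=ElectrodeSpec(i0=10.0, alpha=0.5, V0=0.0),
        geometry=CellGeometry(D_IL=0.5e-9, contact_area=1e-10),
        constants=DEFAULT_CONSTANTS,
    )
    for path, value in (condition.overrides or {}).items():
        system = _apply_override(system, path, value)
    if condition.name in ("slb_alm", "slb_alm_urea"):
        steps = ((_STEP_S, -0.2), (_STEP_S, 0.0), (_STEP_S, 0.1))
    else:
        steps = ((_STEP_S, -0.2), (_STEP_S, 0.0))
    return system, VoltageProtocol(steps=steps, sample_dt=sample_dt)


def generate_trace(
    condition: DeviceCondition | str,
    noise: NoiseSpec | None = None,
    sample_dt: float = 1.0,
) -> Trace:
    """Simulate one condition and add seeded Gaussian noise to i only."""
    if isinstance(condition, str):
        condition = DeviceCondition(condition)
    noise = noise or NoiseSpec()
    system, protocol = condition_config(condition, sample_dt=sample_dt)
    trace = integrate_protocol(system, protocol)
    sigma = noise.sigma
    if noise.mode == "fraction_of_max":
        sigma = noise.sigma * float(np.max(np.abs(trace.i)))
    if sigma > 0:
        rng = np.random.default_rng(noise.seed)
        trace.i = trace.i + rng.normal(0.0, sigma, size=trace.i.shape)
    trace.metadata.update(
        {
            "condition": condition.name,
            "seed": noise.seed,
            "sigma_mA_cm2": sigma,
            "dt": sample_dt,
        }
    )
    return trace


def generate_iv_sweep(
    electrode: ElectrodeSpec,
    v_span: tuple[float, float] | None = None,
    scan_rate: float = 0.005,
    n_points: int = 201,
    constants=DEFAULT_CONSTANTS,
) -> Trace:
    """Slow low-voltage I–V sweep of a bare contact (no membrane).

    Used to extract the Tafel parameters (i0, α): with the membrane
    absent the IL equilibrates with the bulk, V_N = 0, and the measured
    current is pure Butler–Volmer kinetics. The default span is ±100 mV
    about the equilibrium potential V0, swept at 5 mV s⁻¹.
    """
    if v_span is None:
        v_span = (electrode.V0 - 0.1, electrode.V0 + 0.1)
    v = np.linspace(v_span[0], v_span[1], n_points)
    t = np.abs(v - v[0]) / scan_rate
    i = np.array(
        [electrode_current_density(electrode, vk, 0.0, True, constants) for vk in v]
    )
    return Trace(
        t=t,
        V=v,
        i=i / 10.0,
        metadata={"kind": "iv_sweep", "scan_rate_V_s": scan_rate},
    )
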