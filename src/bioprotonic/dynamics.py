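"""Time integration of the coupled membrane / electrode / IL-pH model.

The isolation layer (IL) is a single well-mixed compartment of thickness
D_IL. Conservation of mass couples the membrane current density j (GHK)
and the electrode current density i (Butler–Volmer): the net areal proton
source into the IL is r = (i − j)/F mol m⁻² s⁻¹, and the buffered pH
responds as

    dpH_IL/dt = −r / (β(pH_IL) · D_IL)

with β the Van Slyke buffer capacity. The Pd hydride inventory Q_H
(mol m⁻²) grows with reduction and shrinks with oxidation,
dQ_H/dt = −i/F; the anodic branch of the electrode kinetics is available
only while Q_H > 0 (a freshly prepared film holds no H to oxidize).

Because the IL reservoir β·D_IL is of order 1e−9 mol m⁻² per pH unit
while the protocols last hundreds of seconds, the pH equation is stiff
by many orders of magnitude; each constant-voltage protocol segment is
integrated with a stiffness-switching solver (LSODA) at tight tolerance.
A cumulative proton-source state is co-integrated so that mass-balance
bookkeeping can be audited against the closed-form titratable proton
content (see :func:`proton_balance_residual`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .transport import (
    DEFAULT_CONSTANTS,
    CellGeometry,
    ElectrodeSpec,
    MembraneSpec,
    PhysicalConstants,
    SolutionSpec,
    _buffer_capacity_unchecked,
    bulk_concentration_from_pH,
    effective_permeability,
    electrode_current_density,
    ghk_current_density,
    nernst_potential,
    proton_content,
)

__all__ = [
    "VoltageProtocol",
    "SimulationState",
    "Trace",
    "DeviceSystem",
    "step_update",
    "integrate_protocol",
    "membrane_limited_current",
    "quasi_steady_pH",
    "proton_balance_residual",
]

logger = logging.getLogger(__name__)

#: Regularization scale (mol m⁻²) over which the anodic branch turns off
#: as the hydride inventory approaches zero; keeps the ODE right-hand
#: side continuous at Q_H = 0.
HYDRIDE_REGULARIZATION = 1e-10

#: Default solver tolerances.
DEFAULT_RTOL = 1e-8


@dataclass(frozen=True)
class VoltageProtocol:
    """Ordered piecewise-constant applied-voltage steps.

    steps
        Tuple of ``(duration s, applied voltage V)`` pairs.
    sample_dt
        Output sampling interval in seconds; must not exceed the
        shortest step duration.
    """

    steps: tuple[tuple[float, float], ...]
    sample_dt: float = 1.0

    def __post_init__(self) -> None:
        steps = tuple((float(d), float(v)) for d, v in self.steps)
        object.__setattr__(self, "steps", steps)
        if not steps:
            raise ValueError("protocol must contain at least one step")
        for k, (dur, v) in enumerate(steps):
            if not math.isfinite(dur) or dur <= 0:
                raise ValueError(f"step {k}: duration must be positive, got {dur}")
            if not math.isfinite(v):
                raise ValueError(f"step {k}: voltage must be finite")
        if not (0 < self.sample_dt <= min(d for d, _ in steps)):
            raise ValueError(
                f"sample_dt must be in (0, shortest step duration], got {self.sample_dt}"
            )

    @property
    def total_duration(self) -> float:
        return sum(d for d, _ in self.steps)

    def boundaries(self) -> list[float]:
        """Cumulative step edges [0, t1, ..., total]."""
        edges = [0.0]
        for dur, _ in self.steps:
            edges.append(edges[-1] + dur)
        return edges

    def voltage_at(self, t: float) -> float:
        """Applied voltage at time t (right-continuous at step edges)."""
        edges = self.boundaries()
        if t < 0 or t > edges[-1]:
            raise ValueError(f"t={t} outside protocol span [0, {edges[-1]}]")
        for (dur, v), lo in zip(self.steps, edges):
            if t < lo + dur:
                return v
        return self.steps[-1][1]


@dataclass(frozen=True)
class DeviceSystem:
    """Full parameterization of one device."""

    solution: SolutionSpec = field(default_factory=SolutionSpec)
    membrane: MembraneSpec = field(default_factory=MembraneSpec)
    electrode: ElectrodeSpec = field(default_factory=ElectrodeSpec)
    geometry: CellGeometry = field(default_factory=CellGeometry)
    constants: PhysicalConstants = field(default_factory=lambda: DEFAULT_CONSTANTS)


@dataclass(frozen=True)
class SimulationState:
    """Instantaneous simulation state.

    t        time, s
    pH_IL    isolation-layer pH
    Q_H      areal hydride inventory, mol m⁻² (>= 0)
    """

    t: float
    pH_IL: float
    Q_H: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.pH_IL):
            raise ValueError("pH_IL must be finite")
        if self.Q_H < 0:
            raise ValueError(f"Q_H must be >= 0, got {self.Q_H}")

    @property
    def c_IL(self) -> float:
        """IL H+ concentration, mol m⁻³, derived exactly from pH_IL."""
        return bulk_concentration_from_pH(self.pH_IL)

    def hydride_ratio(self, electrode: ElectrodeSpec) -> float:
        """Hydride ratio x = Q_H / areal Pd inventory."""
        return self.Q_H / electrode.pd_areal_inventory


@dataclass
class Trace:
    """Sampled time series of one simulated (or measured) experiment.

    Current densities are in mA cm⁻² (the reporting unit); everything
    internal to the model is SI and converted at this boundary (÷10 from
    A m⁻²).
    """

    t: np.ndarray
    V: np.ndarray
    i: np.ndarray
    j: np.ndarray | None = None
    pH_IL: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)
    final_state: SimulationState | None = field(default=None, repr=False, compare=False)
    #: (integrated net proton source mol m⁻², closed-form IL content change)
    balance: tuple[float, float] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if self.j is not None:
            self.j = np.asarray(self.j, dtype=float)
        if self.pH_IL is not None:
            self.pH_IL = np.asarray(self.pH_IL, dtype=float)
        n = self.t.size
        if n == 0:
            raise ValueError("trace must contain at least one sample")
        for name in ("V", "i", "j", "pH_IL"):
            arr = getattr(self, name)
            if arr is not None and arr.size != n:
                raise ValueError(f"column {name} has length {arr.size}, expected {n}")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            bad = int(np.argmin(np.diff(self.t) > 0))
            raise ValueError(f"trace times must be strictly increasing (first violation at row {bad + 1})")
        for name in ("t", "V", "i", "j", "pH_IL"):
            arr = getattr(self, name)
            if arr is not None and not np.all(np.isfinite(arr)):
                raise ValueError(f"trace column {name} contains non-finite values")

    def __len__(self) -> int:
        return int(self.t.size)

    def to_dataframe(self):
        """Trace as a pandas DataFrame with canonical column names."""
        import pandas as pd

        data = {"time_s": self.t, "voltage_V": self.V, "i_mA_cm2": self.i}
        if self.j is not None:
            data["j_mA_cm2"] = self.j
        if self.pH_IL is not None:
            data["pH_IL"] = self.pH_IL
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Right-hand side of the coupled ODE system
# ---------------------------------------------------------------------------

def _instantaneous_currents(
    system: DeviceSystem, V: float, pH_IL: float, Q_H: float
) -> tuple[float, float]:
    """(i, j) in A m⁻² at the given state; anodic branch scaled smoothly
    by hydride availability."""
    c_B = system.solution.c_B
    c_IL = bulk_concentration_from_pH(pH_IL)
    P_eff = effective_permeability(system.membrane, V)
    j = ghk_current_density(P_eff, V, c_B, c_IL, system.constants)
    V_N = nernst_potential(c_IL, c_B, system.constants)
    avail = min(max(Q_H / HYDRIDE_REGULARIZATION, 0.0), 1.0)
    i = electrode_current_density(system.electrode, V, V_N, avail, system.constants)
    return i, j


def _make_rhs(system: DeviceSystem, V: float):
    F = system.constants.faraday
    D_IL = system.geometry.D_IL
    buffer = system.solution.buffer

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        pH, Q_H = y[0], y[1]
        i, j = _instantaneous_currents(system, V, pH, Q_H)
        r = (i - j) / F  # net areal proton source into the IL
        beta = _buffer_capacity_unchecked(buffer, pH)
        return [-r / (beta * D_IL), -i / F, r]

    return rhs


def _solver_atol() -> list[float]:
    # per-state absolute tolerances: pH, Q_H, cumulative source
    return [1e-12, 1e-16, 1e-18]


def step_update(
    state: SimulationState,
    system: DeviceSystem,
    V: float,
    dt: float,
    rtol: float = DEFAULT_RTOL,
) -> SimulationState:
    """Advance the state by dt at constant applied voltage V.

    The buffered pH equation is advanced with an adaptive stiff solver;
    the hydride inventory is co-integrated and floored at zero.
    """
    if not math.isfinite(dt) or dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    beta0 = _buffer_capacity_unchecked(system.solution.buffer, state.pH_IL)
    if beta0 <= 0:
        raise ValueError("buffer capacity must be positive (configuration error)")
    rhs = _make_rhs(system, V)
    sol = solve_ivp(
        rhs,
        (state.t, state.t + dt),
        [state.pH_IL, state.Q_H, 0.0],
        method="LSODA",
        rtol=rtol,
        atol=_solver_atol(),
    )
    if not sol.success:  # pragma: no cover - solver failure is exceptional
        raise RuntimeError(f"integration failed at t={state.t}: {sol.message}")
    pH, q = float(sol.y[0, -1]), float(sol.y[1, -1])
    return SimulationState(t=state.t + dt, pH_IL=pH, Q_H=max(q, 0.0))


def integrate_protocol(
    system: DeviceSystem,
    protocol: VoltageProtocol,
    initial_pH_IL: float | None = None,
    initial_Q_H: float = 0.0,
    rtol: float = DEFAULT_RTOL,
) -> Trace:
    """Integrate the device model over a voltage protocol.

    Samples are emitted on the uniform grid k·sample_dt (a sample on a
    step edge reports the newly applied voltage). Deterministic: no
    randomness anywhere. The returned trace carries the final state and
    a mass-balance audit pair (see :func:`proton_balance_residual`).
    """
    pH0 = system.solution.pH_B if initial_pH_IL is None else float(initial_pH_IL)
    if initial_Q_H < 0:
        raise ValueError("initial_Q_H must be >= 0")
    beta0 = _buffer_capacity_unchecked(system.solution.buffer, pH0)
    if beta0 <= 0:
        raise ValueError("buffer capacity must be positive (configuration error)")

    dt = protocol.sample_dt
    total = protocol.total_duration
    n_samples = int(round(total / dt))
    grid = np.arange(n_samples + 1) * dt
    grid = grid[grid <= total + 1e-9 * max(total, 1.0)]

    edges = protocol.boundaries()
    y = np.array([pH0, float(initial_Q_H), 0.0])
    ts: list[np.ndarray] = []
    vs: list[np.ndarray] = []
    i_cols: list[np.ndarray] = []
    j_cols: list[np.ndarray] = []
    ph_cols: list[np.ndarray] = []
    max_q = float(initial_Q_H)

    for k, (dur, V) in enumerate(protocol.steps):
        t_lo, t_hi = edges[k], edges[k + 1]
        last = k == len(protocol.steps) - 1
        if last:
            mask = (grid >= t_lo - 1e-12) & (grid <= t_hi + 1e-12)
        else:
            mask = (grid >= t_lo - 1e-12) & (grid < t_hi - 1e-12)
        t_eval = np.clip(grid[mask], t_lo, t_hi)
        # always integrate to the segment end to hand the state over
        eval_pts = np.unique(np.concatenate([t_eval, [t_hi]]))
        rhs = _make_rhs(system, V)
        try:
            sol = solve_ivp(
                rhs,
                (t_lo, t_hi),
                y,
                method="LSODA",
                t_eval=eval_pts,
                rtol=rtol,
                atol=_solver_atol(),
            )
        except (ValueError, RuntimeError) as exc:
            raise RuntimeError(f"integration failed in protocol step {k} (V={V} V): {exc}") from exc
        if not sol.success:
            raise RuntimeError(f"integration failed in protocol step {k} (V={V} V): {sol.message}")
        y = sol.y[:, -1].copy()
        y[1] = max(y[1], 0.0)
        max_q = max(max_q, float(np.max(sol.y[1])))

        keep = np.isin(sol.t, t_eval)
        t_seg = sol.t[keep]
        pH_seg = sol.y[0, keep]
        q_seg = sol.y[1, keep]
        i_seg = np.empty_like(t_seg)
        j_seg = np.empty_like(t_seg)
        for m in range(t_seg.size):
            i_seg[m], j_seg[m] = _instantaneous_currents(system, V, pH_seg[m], q_seg[m])
        ts.append(t_seg)
        vs.append(np.full_like(t_seg, V))
        i_cols.append(i_seg / 10.0)  # A m⁻² -> mA cm⁻²
        j_cols.append(j_seg / 10.0)
        ph_cols.append(pH_seg)

    final = SimulationState(t=total, pH_IL=float(y[0]), Q_H=max(float(y[1]), 0.0))
    x_peak = max_q / system.electrode.pd_areal_inventory
    if x_peak > system.electrode.x_max:
        logger.warning(
            "hydride ratio x peaked at %.3g, beyond the nominal PdHx limit x_max=%.2g; "
            "the inventory is tracked but not clamped",
            x_peak,
            system.electrode.x_max,
        )

    content_change = system.geometry.D_IL * (
        proton_content(system.solution.buffer, final.pH_IL)
        - proton_content(system.solution.buffer, pH0)
    )
    trace = Trace(
        t=np.concatenate(ts),
        V=np.concatenate(vs),
        i=np.concatenate(i_cols),
        j=np.concatenate(j_cols),
        pH_IL=np.concatenate(ph_cols),
        metadata={"sample_dt_s": dt, "initial_pH_IL": pH0, "x_peak": x_peak},
        final_state=final,
        balance=(float(y[2]), content_change),
    )
    return trace


def proton_balance_residual(trace: Trace) -> float:
    """Relative mass-balance residual of a simulated trace.

    Compares the independently integrated net proton source
    ∫(i−j)/F dt with the closed-form change in the IL's titratable
    proton content D_IL·ΔT(pH); the two routes agree at the level of the
    solver's truncation error only, so this is a genuine audit.
    """
    if trace.balance is None:
        raise ValueError("trace carries no balance diagnostics (not produced by integrate_protocol?)")
    integrated, content = trace.balance
    scale = max(abs(integrated), abs(content))
    if scale == 0.0:
        return 0.0
    return abs(integrated - content) / scale


def membrane_limited_current(
    membrane: MembraneSpec,
    V: float,
    c_B: float,
    c_IL: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Steady membrane-limited current density in mA cm⁻².

    When the electrode kinetics are fast the electrode current settles
    to the membrane (GHK) flux; this helper evaluates that flux with the
    gated effective permeability and converts to reporting units.
    """
    P_eff = effective_permeability(membrane, V)
    return ghk_current_density(P_eff, V, c_B, c_IL, constants) / 10.0


def quasi_steady_pH(
    system: DeviceSystem,
    V: float,
    hydride_available: float = 1.0,
    bracket: tuple[float, float] = (0.5, 13.5),
) -> float:
    """IL pH at which the electrode and membrane currents balance (i = j).

    This is the fixed point the fast pH dynamics relax to at constant
    applied voltage.
    """

    def imbalance(pH: float) -> float:
        c_IL = bulk_concentration_from_pH(pH)
        c_B = system.solution.c_B
        P_eff = effective_permeability(system.membrane, V)
        j = ghk_current_density(P_eff, V, c_B, c_IL, system.constants)
        V_N = nernst_potential(c_IL, c_B, system.constants)
        i = electrode_current_density(system.electrode, V, V_N, hydride_available, system.constants)
        return i - j

    lo, hi = bracket
    f_lo, f_hi = imbalance(lo), imbalance(hi)
    if f_lo * f_hi > 0:
        raise ValueError("no current balance in the bracket; widen it or check the parameters")
    return float(brentq(imbalance, lo, hi, xtol=1e-12, rtol=8.9e-16))
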