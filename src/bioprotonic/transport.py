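"""Closed-form physics of the four-layer bioprotonic stack.

The device is modelled as four layers in series: bulk solution (B), a
supported lipid bilayer (SLB, optionally carrying gramicidin A or
alamethicin channels), a nanometre-scale aqueous isolation layer (IL)
trapped between the bilayer and the contact, and the Pd/PdHx contact
itself. This module holds the pointwise physics:

* Goldman–Hodgkin–Katz (GHK) constant-field current through the membrane,
  parameterized by an effective permeability;
* the Nernst potential generated by the H+ concentration difference
  between IL and bulk;
* Butler–Volmer electrode kinetics at the Pd/solution interface (the
  two-branch form whose large-overpotential limit is the Tafel law);
* Van Slyke buffer capacity of the IL solution;
* voltage gating / chemical block of the channel contribution to the
  membrane permeability.

Sign conventions (used consistently throughout the package):

* membrane current density ``j`` > 0 means H+ flows from the IL into the
  bulk; j < 0 means H+ enters the IL from the bulk;
* electrode current density ``i`` > 0 is oxidation (H released from PdHx
  into the IL as H+), i < 0 is reduction (H+ consumed from the IL);
* the applied voltage ``V`` is Pd vs. Ag/AgCl, and the full membrane
  potential drop is taken as V (the bulk series resistance is negligible
  next to the GΩ-scale membrane resistance).

Units: SI throughout (A m⁻², mol m⁻³, V, s). Permeabilities are the
device-scale values as conventionally printed in s⁻¹; dimensionally they
enter the GHK current equation as m s⁻¹ with concentrations in mol m⁻³
(see docs/methods.md for the unit discussion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "PhysicalConstants",
    "BufferSpec",
    "SolutionSpec",
    "ChannelGating",
    "MembraneSpec",
    "ElectrodeSpec",
    "CellGeometry",
    "DEFAULT_CONSTANTS",
    "ghk_current_density",
    "nernst_potential",
    "electrode_current_density",
    "buffer_capacity",
    "proton_content",
    "effective_permeability",
    "thermal_voltage_factor",
    "bulk_concentration_from_pH",
]

#: Gas constant, J mol⁻¹ K⁻¹.
R_GAS = 8.314462618

#: Molar density of Pd metal, mol m⁻³ (12.02 g cm⁻³ / 106.42 g mol⁻¹);
#: converts a Pd film thickness into an areal Pd inventory for the
#: hydride ratio x = H/Pd.
PD_MOLAR_DENSITY = 1.1296e5

#: Water autoprotolysis product in (mol m⁻³)²: Kw = 1e-14 M² × (1e3)².
KW_SI = 1.0e-8

#: Exponent clamp applied before every exponential (overflow guard).
EXP_CLAMP = 50.0

_LN10 = math.log(10.0)


def _clamped_exp(x: float) -> float:
    return math.exp(min(max(x, -EXP_CLAMP), EXP_CLAMP))


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants of the model.

    faraday
        Charge per mole of protons, C mol⁻¹.
    f_thermal
        F/RT in V⁻¹. The conventional device value 38.66 V⁻¹ corresponds
        to T ≈ 300.2 K.
    elementary_charge
        C.
    """

    faraday: float = 96485.0
    f_thermal: float = 38.66
    elementary_charge: float = 1.602176634e-19

    def __post_init__(self) -> None:
        for name in ("faraday", "f_thermal", "elementary_charge"):
            v = getattr(self, name)
            _require_finite(name, v)
            if v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")


DEFAULT_CONSTANTS = PhysicalConstants()


def thermal_voltage_factor(temperature_K: float, faraday: float = 96485.0) -> float:
    """F/RT in V⁻¹ at the given absolute temperature."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return faraday / (R_GAS * temperature_K)


def bulk_concentration_from_pH(pH: float) -> float:
    """Convert pH to H+ concentration in mol m⁻³ (1000 × 10^(−pH))."""
    _require_finite("pH", pH)
    return 1000.0 * 10.0 ** (-pH)


@dataclass(frozen=True)
class BufferSpec:
    """pH buffer composition of the solution.

    species
        Tuple of ``(total concentration mol m⁻³, pKa)`` pairs of weak
        acid/base buffer species (e.g. 5 mol m⁻³ phosphate, pKa 7.21).
    include_water
        Include the water autoprotolysis terms [H+] + Kw/[H+] in the
        buffer capacity.
    beta_override
        If set, a fixed buffer capacity (mol m⁻³ per pH unit) returned
        verbatim regardless of pH.
    """

    species: tuple[tuple[float, float], ...] = ()
    include_water: bool = True
    beta_override: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple((float(c), float(pka)) for c, pka in self.species))
        for conc, _pka in self.species:
            if conc < 0:
                raise ValueError(f"buffer species concentration must be >= 0, got {conc}")
        if self.beta_override is not None and self.beta_override <= 0:
            raise ValueError("beta_override must be > 0 when set")


#: 5 mol m⁻³ (5 mM) potassium phosphate at pKa2 = 7.21 — the K-PBS
#: working buffer of the devices.
PHOSPHATE_5MM = BufferSpec(species=((5.0, 7.21),))


@dataclass(frozen=True)
class SolutionSpec:
    """Bulk-solution composition: pH and buffer."""

    pH_B: float = 7.0
    buffer: BufferSpec = field(default_factory=lambda: PHOSPHATE_5MM)

    def __post_init__(self) -> None:
        _require_finite("pH_B", self.pH_B)

    @property
    def c_B(self) -> float:
        """Bulk H+ concentration, mol m⁻³ (1e-4 at pH 7)."""
        return bulk_concentration_from_pH(self.pH_B)


@dataclass(frozen=True)
class ChannelGating:
    """Voltage dependence of the channel contribution to permeability.

    ``always_open`` describes gramicidin A; ``voltage_threshold``
    describes alamethicin, which opens when the applied voltage magnitude
    exceeds an (asymmetric) threshold of ~60 mV of either sign.
    smoothing_width > 0 replaces the hard step with a logistic sigmoid of
    that width in volts.
    """

    mode: str = "always_open"
    v_threshold_pos: float = 0.06
    v_threshold_neg: float = 0.06
    smoothing_width: float = 0.0

    _MODES = ("always_open", "voltage_threshold")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"gating mode must be one of {self._MODES}, got {self.mode!r}")
        if self.v_threshold_pos < 0 or self.v_threshold_neg < 0:
            raise ValueError("gating thresholds must be >= 0")
        if self.smoothing_width < 0:
            raise ValueError("smoothing_width must be >= 0")

    def open_fraction(self, V: float) -> float:
        """Fraction of the channel population open at applied voltage V."""
        if self.mode == "always_open":
            return 1.0
        w = self.smoothing_width
        if w == 0.0:
            return 1.0 if (V >= self.v_threshold_pos or V <= -self.v_threshold_neg) else 0.0
        pos = 1.0 / (1.0 + _clamped_exp(-(V - self.v_threshold_pos) / w))
        neg = 1.0 / (1.0 + _clamped_exp((V + self.v_threshold_neg) / w))
        return min(1.0, pos + neg)


@dataclass(frozen=True)
class MembraneSpec:
    """Membrane permeability: bare bilayer plus gated/blockable channels.

    P_base
        Bare-bilayer H+ permeability (device scale, as printed in s⁻¹).
    P_channel
        Permeability with the channel population fully open and unblocked.
    gating
        Voltage gating of the channel contribution.
    block_factor
        Multiplier in [0, 1] on the channel contribution: 1 = unblocked,
        0 = fully blocked (Ca²⁺ on gramicidin, urea-disrupted alamethicin).
    """

    P_base: float = 0.006
    P_channel: float = 0.006
    gating: ChannelGating = field(default_factory=ChannelGating)
    block_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.P_base <= self.P_channel):
            raise ValueError(
                f"require 0 <= P_base <= P_channel, got P_base={self.P_base}, P_channel={self.P_channel}"
            )
        if not (0.0 <= self.block_factor <= 1.0):
            raise ValueError(f"block_factor must lie in [0, 1], got {self.block_factor}")


@dataclass(frozen=True)
class ElectrodeSpec:
    """Pd/PdHx contact kinetics and hydride inventory parameters.

    i0
        Exchange current density, A m⁻² (equal forward/reverse H/H+
        current at zero net current).
    alpha
        Transfer coefficient in (0, 1).
    V0
        Fixed redox offset between Pd and the Ag/AgCl reference, V.
    hydride_capacity
        Optional maximal areal H inventory, mol m⁻². When None, the
        nominal capacity x_max × (Pd areal molar inventory) is used for
        the hydride-ratio diagnostic only; the inventory is not clamped.
    pd_thickness
        Pd film thickness, m.
    x_max
        Maximal hydride ratio x in PdHx.
    """

    i0: float = 10.0
    alpha: float = 0.5
    V0: float = -0.22233
    hydride_capacity: float | None = None
    pd_thickness: float = 50e-9
    x_max: float = 0.6

    def __post_init__(self) -> None:
        if self.i0 <= 0:
            raise ValueError(f"i0 must be > 0, got {self.i0}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not (0.0 < self.x_max <= 1.0):
            raise ValueError(f"x_max must lie in (0, 1], got {self.x_max}")
        if self.pd_thickness <= 0:
            raise ValueError("pd_thickness must be > 0")
        if self.hydride_capacity is not None and self.hydride_capacity <= 0:
            raise ValueError("hydride_capacity must be > 0 when set")

    @property
    def pd_areal_inventory(self) -> float:
        """Moles of Pd per unit contact area, mol m⁻²."""
        return self.pd_thickness * PD_MOLAR_DENSITY

    @property
    def nominal_capacity(self) -> float:
        """Areal hydride capacity x_max·[Pd], mol m⁻² (or the override)."""
        if self.hydride_capacity is not None:
            return self.hydride_capacity
        return self.x_max * self.pd_areal_inventory


@dataclass(frozen=True)
class CellGeometry:
    """Isolation-layer thickness and contact area."""

    D_IL: float = 0.5e-9
    contact_area: float = 1e-10

    def __post_init__(self) -> None:
        if self.D_IL <= 0:
            raise ValueError(f"D_IL must be > 0, got {self.D_IL}")
        if self.contact_area <= 0:
            raise ValueError(f"contact_area must be > 0, got {self.contact_area}")


# ---------------------------------------------------------------------------
# Membrane flux: GHK constant-field current
# ---------------------------------------------------------------------------

def ghk_current_density(
    P_eff: float,
    V_m: float,
    c_B: float,
    c_IL: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """GHK electrical current density of H+ through the membrane, A m⁻².

    j = P·F·f·V_m·(c_IL − c_B·e^{−f·V_m}) / (1 − e^{−f·V_m})

    with j > 0 meaning H+ flow from the isolation layer into the bulk.
    The f·V_m → 0 limit j = P·F·(c_IL − c_B) is taken via a series
    expansion for |f·V_m| < 1e-6; the expression is evaluated in a
    numerically stable form for either sign of V_m.
    """
    for name, v in (("P_eff", P_eff), ("V_m", V_m), ("c_B", c_B), ("c_IL", c_IL)):
        _require_finite(name, v)
    if P_eff < 0:
        raise ValueError(f"P_eff must be >= 0, got {P_eff}")
    if c_B <= 0 or c_IL <= 0:
        raise ValueError(f"concentrations must be > 0, got c_B={c_B}, c_IL={c_IL}")

    F = constants.faraday
    u = constants.f_thermal * V_m
    if abs(u) < 1e-6:
        # second-order series about u = 0; the u^3 remainder is < 1e-19 rel.
        delta = c_IL - c_B
        return F * P_eff * (delta + u * (c_B + 0.5 * delta) + u * u * delta / 12.0)
    if u > 0:
        # e^{-u} <= 1: direct evaluation is stable.
        return F * P_eff * u * (c_IL - c_B * math.exp(-min(u, EXP_CLAMP))) / (-math.expm1(-u))
    # u < 0: multiply through by e^{u} to avoid overflow.
    return F * P_eff * u * (c_IL * math.exp(max(u, -EXP_CLAMP)) - c_B) / math.expm1(u)


# ---------------------------------------------------------------------------
# Nernst potential across the membrane
# ---------------------------------------------------------------------------

def nernst_potential(
    c_IL: float,
    c_B: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Nernst potential V_N = ln(c_IL/c_B)/f, in volts.

    Acidification of the isolation layer (c_IL up) raises V_N, which
    lowers the electrode overpotential and favours reduction at the Pd
    contact.
    """
    _require_finite("c_IL", c_IL)
    _require_finite("c_B", c_B)
    if c_IL <= 0 or c_B <= 0:
        raise ValueError(f"concentrations must be > 0, got c_IL={c_IL}, c_B={c_B}")
    # log difference (not log of the quotient) makes the antisymmetry
    # V_N(a, b) = -V_N(b, a) exact in floating point
    return (math.log(c_IL) - math.log(c_B)) / constants.f_thermal


# ---------------------------------------------------------------------------
# Electrode kinetics at the Pd/solution interface
# ---------------------------------------------------------------------------

def electrode_current_density(
    electrode: ElectrodeSpec,
    V: float,
    V_N: float,
    hydride_available: bool | float = True,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Butler–Volmer current density at the Pd contact, A m⁻².

    With overpotential η = V − V0 − V_N:

        i = i0·[a·e^{α f η} − e^{−(1−α) f η}]

    where ``a`` is the hydride availability (1 when PdHx holds H to
    oxidize, 0 when the film is empty; fractional values scale the anodic
    branch smoothly). i > 0 is oxidation (H+ released into the IL),
    i < 0 is reduction. Exponent arguments are clamped to ±50.
    """
    _require_finite("V", V)
    _require_finite("V_N", V_N)
    avail = float(hydride_available)
    if not (0.0 <= avail <= 1.0):
        raise ValueError(f"hydride availability must lie in [0, 1], got {avail}")
    f = constants.f_thermal
    eta = V - electrode.V0 - V_N
    anodic = avail * _clamped_exp(electrode.alpha * f * eta)
    cathodic = _clamped_exp(-(1.0 - electrode.alpha) * f * eta)
    return electrode.i0 * (anodic - cathodic)


# ---------------------------------------------------------------------------
# Buffer capacity and titratable proton content
# ---------------------------------------------------------------------------

def _check_buffer(buffer: BufferSpec) -> None:
    if buffer.beta_override is None and not buffer.include_water and not buffer.species:
        raise ValueError(
            "buffer with no species and include_water=False has zero capacity; "
            "the pH dynamics would be singular"
        )


def buffer_capacity(buffer: BufferSpec, pH: float) -> float:
    """Van Slyke buffer capacity β in mol m⁻³ per pH unit.

    β = ln10·([H+] + Kw/[H+] + Σ C·Ka·[H+]/(Ka + [H+])²)

    with all concentrations in mol m⁻³ (Kw = 1e-8 (mol m⁻³)²). The water
    terms are included only when ``include_water`` is set; a
    ``beta_override`` short-circuits the computation.
    """
    _require_finite("pH", pH)
    if not (0.0 <= pH <= 14.0):
        raise ValueError(f"pH must lie in [0, 14], got {pH}")
    _check_buffer(buffer)
    return _buffer_capacity_unchecked(buffer, pH)


def _buffer_capacity_unchecked(buffer: BufferSpec, pH: float) -> float:
    # Hot path for the integrator: no range check, so solver trial steps
    # slightly outside [0, 14] do not abort the integration.
    if buffer.beta_override is not None:
        return buffer.beta_override
    h = 1000.0 * 10.0 ** (-pH)
    beta = 0.0
    if buffer.include_water:
        beta += h + KW_SI / h
    for c_tot, pka in buffer.species:
        ka = 1000.0 * 10.0 ** (-pka)
        beta += c_tot * ka * h / (ka + h) ** 2
    return _LN10 * beta


def proton_content(buffer: BufferSpec, pH: float) -> float:
    """Titratable proton content T(pH) of the solution, mol m⁻³.

    T(pH) = [H+] − Kw/[H+] + Σ C·[H+]/(Ka + [H+])

    is the closed-form antiderivative of −β with respect to pH
    (dT/dpH = −β), so β·ΔpH bookkeeping can be checked exactly without
    numerical quadrature of β. With ``beta_override`` the content is the
    linear −β·pH.
    """
    _require_finite("pH", pH)
    _check_buffer(buffer)
    if buffer.beta_override is not None:
        return -buffer.beta_override * pH
    h = 1000.0 * 10.0 ** (-pH)
    total = 0.0
    if buffer.include_water:
        total += h - KW_SI / h
    for c_tot, pka in buffer.species:
        ka = 1000.0 * 10.0 ** (-pka)
        total += c_tot * h / (ka + h)
    return total


# ---------------------------------------------------------------------------
# Effective permeability with gating and block
# ---------------------------------------------------------------------------

def effective_permeability(membrane: MembraneSpec, V: float) -> float:
    """Effective membrane permeability at applied voltage V (device scale).

    P_eff = P_base + (P_channel − P_base)·block_factor·g(V), where g(V)
    is the gating open fraction. Always lies in [P_base, P_channel].
    """
    _require_finite("V", V)
    g = membrane.gating.open_fraction(V)
    return membrane.P_base + (membrane.P_channel - membrane.P_base) * membrane.block_factor * g
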