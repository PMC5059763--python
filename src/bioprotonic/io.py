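"""Trace CSV reading/writing and flat-text run configuration.

Trace files are plain CSV with a canonical column order

    time_s, voltage_V, i_mA_cm2 [, j_mA_cm2, pH_IL]

preceded by ``#``-prefixed comment lines carrying ``key=value`` metadata.
Numbers use a decimal point and 13 significant digits, which makes a
write/read round trip faithful to ~5e-13 relative and the byte output of
a given trace deterministic.

Run configurations are flat text files of ``key = value`` lines with
dotted key nesting (``electrode.i0_A_m2 = 10``). Every physical key
carries its unit in the name. Unknown keys are rejected so a typo cannot
silently fall back to a default.
"""

from __future__ import annotations

import io as _io
import math
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .dynamics import DeviceSystem, Trace, VoltageProtocol
from .fitting import FitConfig
from .synthetic import NoiseSpec, condition_config
from .transport import (
    DEFAULT_CONSTANTS,
    BufferSpec,
    CellGeometry,
    ChannelGating,
    ElectrodeSpec,
    MembraneSpec,
    SolutionSpec,
)

__all__ = ["read_trace", "write_trace", "read_config", "build_system", "build_protocol", "build_fit_config", "build_noise", "ConfigError"]

REQUIRED_COLUMNS = ("time_s", "voltage_V", "i_mA_cm2")
OPTIONAL_COLUMNS = ("j_mA_cm2", "pH_IL")
_FLOAT_FMT = "%.13g"


class ConfigError(ValueError):
    """Malformed or unknown configuration content."""


# ---------------------------------------------------------------------------
# Trace CSV
# ---------------------------------------------------------------------------

def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace as CSV with '#' metadata comments.

    Byte-deterministic for a given trace: fixed column order, fixed
    float formatting (13 significant digits), metadata sorted by key.
    """
    if len(trace) == 0:
        raise ValueError("refusing to write an empty trace")
    path = Path(path)
    lines: list[str] = []
    for key in sorted(trace.metadata):
        lines.append(f"# {key}={trace.metadata[key]}")
    columns = [("time_s", trace.t), ("voltage_V", trace.V), ("i_mA_cm2", trace.i)]
    if trace.j is not None:
        columns.append(("j_mA_cm2", trace.j))
    if trace.pH_IL is not None:
        columns.append(("pH_IL", trace.pH_IL))
    lines.append(",".join(name for name, _ in columns))
    arrays = [arr for _, arr in columns]
    for row in zip(*arrays):
        lines.append(",".join(_FLOAT_FMT % x for x in row))
    path.write_text("\n".join(lines) + "\n")


def read_trace(path: str | Path) -> Trace:
    """Read a trace CSV written by :func:`write_trace` (or equivalent)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    metadata: dict[str, Any] = {}
    data_lines: list[str] = []
    for line in path.read_text().splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                metadata[key.strip()] = _parse_scalar(value.strip())
            continue
        data_lines.append(line)
    if not data_lines:
        raise ValueError(f"{path}: no header line found")
    df = pd.read_csv(_io.StringIO("\n".join(data_lines)))
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    unknown = [c for c in df.columns if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS]
    if unknown:
        raise ValueError(f"{path}: unknown columns {unknown}")
    if len(df) == 0:
        raise ValueError(f"{path}: header only, trace has no samples")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size > 1:
        diffs = np.diff(t)
        if not np.all(diffs > 0):
            row = int(np.flatnonzero(diffs <= 0)[0]) + 1
            raise ValueError(f"{path}: time not strictly increasing at data row {row}")
    return Trace(
        t=t,
        V=df["voltage_V"].to_numpy(dtype=float),
        i=df["i_mA_cm2"].to_numpy(dtype=float),
        j=df["j_mA_cm2"].to_numpy(dtype=float) if "j_mA_cm2" in df.columns else None,
        pH_IL=df["pH_IL"].to_numpy(dtype=float) if "pH_IL" in df.columns else None,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# Flat-text configuration
# ---------------------------------------------------------------------------

def _parse_scalar(text: str) -> Any:
    low = text.lower()
    if low in ("true", "yes", "on"):
        return True
    if low in ("false", "no", "off"):
        return False
    if low in ("none", ""):
        return None
    try:
        value = float(text)
    except ValueError:
        return text
    if value.is_integer() and "." not in text and "e" not in low:
        return int(value)
    return value


def _parse_value(text: str) -> Any:
    text = text.strip()
    if "," in text:
        return tuple(_parse_scalar(part.strip()) for part in text.split(","))
    return _parse_scalar(text)


#: Recognized configuration keys. Units are part of the key names;
#: permeabilities are on the device scale conventionally printed in s⁻¹.
KNOWN_KEYS = {
    "condition",
    "solution.pH_B",
    "solution.buffer.species",            # "conc@pKa" pairs, comma separated
    "solution.buffer.include_water",
    "solution.buffer.beta_override_mol_m3",
    "membrane.P_base_per_s",
    "membrane.P_channel_per_s",
    "membrane.block_factor",
    "membrane.gating.mode",
    "membrane.gating.v_threshold_pos_V",
    "membrane.gating.v_threshold_neg_V",
    "membrane.gating.smoothing_width_V",
    "electrode.i0_A_m2",
    "electrode.alpha",
    "electrode.V0_V",
    "electrode.hydride_capacity_mol_m2",
    "electrode.pd_thickness_nm",
    "electrode.x_max",
    "geometry.D_IL_nm",
    "geometry.contact_area_um2",
    "protocol.voltages_V",
    "protocol.durations_s",
    "protocol.sample_dt_s",
    "initial.pH_IL",
    "initial.Q_H_mol_m2",
    "fit.P_lower_per_s",
    "fit.P_upper_per_s",
    "fit.tol",
    "fit.max_iter",
    "noise.sigma_mA_cm2",
    "noise.sigma_fraction_of_max",
    "noise.seed",
}


def read_config(path: str | Path) -> dict[str, Any]:
    """Parse a flat ``key = value`` configuration file.

    Lines starting with '#' are comments. Keys must be known; values are
    booleans, numbers, comma lists or bare strings.
    """
    path = Path(path)
    cfg: dict[str, Any] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in KNOWN_KEYS:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        if key in cfg:
            raise ConfigError(f"{path}:{lineno}: duplicate key {key!r}")
        cfg[key] = _parse_value(value)
    return cfg


def _as_tuple(value: Any) -> tuple:
    return value if isinstance(value, tuple) else (value,)


def _buffer_from_config(cfg: dict[str, Any], base: BufferSpec) -> BufferSpec:
    species = base.species
    if "solution.buffer.species" in cfg:
        parsed = []
        for item in _as_tuple(cfg["solution.buffer.species"]):
            text = str(item)
            if "@" not in text:
                raise ConfigError(
                    f"buffer species {text!r} must be 'conc_mol_m3@pKa', e.g. 5.0@7.21"
                )
            conc, _, pka = text.partition("@")
            parsed.append((float(conc), float(pka)))
        species = tuple(parsed)
    return BufferSpec(
        species=species,
        include_water=cfg.get("solution.buffer.include_water", base.include_water),
        beta_override=cfg.get("solution.buffer.beta_override_mol_m3", base.beta_override),
    )


def build_system(cfg: dict[str, Any]) -> DeviceSystem:
    """Device system from a parsed configuration.

    A ``condition`` key selects a preset as the baseline; any other keys
    then override individual fields.
    """
    if "condition" in cfg:
        base, _ = condition_config(str(cfg["condition"]))
    else:
        base = DeviceSystem()
    sol = base.solution
    solution = SolutionSpec(
        pH_B=float(cfg.get("solution.pH_B", sol.pH_B)),
        buffer=_buffer_from_config(cfg, sol.buffer),
    )
    mem = base.membrane
    gating = mem.gating
    gating = ChannelGating(
        mode=str(cfg.get("membrane.gating.mode", gating.mode)),
        v_threshold_pos=float(cfg.get("membrane.gating.v_threshold_pos_V", gating.v_threshold_pos)),
        v_threshold_neg=float(cfg.get("membrane.gating.v_threshold_neg_V", gating.v_threshold_neg)),
        smoothing_width=float(cfg.get("membrane.gating.smoothing_width_V", gating.smoothing_width)),
    )
    membrane = MembraneSpec(
        P_base=float(cfg.get("membrane.P_base_per_s", mem.P_base)),
        P_channel=float(cfg.get("membrane.P_channel_per_s", mem.P_channel)),
        gating=gating,
        block_factor=float(cfg.get("membrane.block_factor", mem.block_factor)),
    )
    ele = base.electrode
    capacity = cfg.get("electrode.hydride_capacity_mol_m2", ele.hydride_capacity)
    electrode = ElectrodeSpec(
        i0=float(cfg.get("electrode.i0_A_m2", ele.i0)),
        alpha=float(cfg.get("electrode.alpha", ele.alpha)),
        V0=float(cfg.get("electrode.V0_V", ele.V0)),
        hydride_capacity=None if capacity is None else float(capacity),
        pd_thickness=float(cfg.get("electrode.pd_thickness_nm", ele.pd_thickness * 1e9)) * 1e-9,
        x_max=float(cfg.get("electrode.x_max", ele.x_max)),
    )
    geo = base.geometry
    geometry = CellGeometry(
        D_IL=float(cfg.get("geometry.D_IL_nm", geo.D_IL * 1e9)) * 1e-9,
        contact_area=float(cfg.get("geometry.contact_area_um2", geo.contact_area * 1e12)) * 1e-12,
    )
    return DeviceSystem(
        solution=solution,
        membrane=membrane,
        electrode=electrode,
        geometry=geometry,
        constants=DEFAULT_CONSTANTS,
    )


def build_protocol(cfg: dict[str, Any]) -> VoltageProtocol:
    """Voltage protocol from a parsed configuration."""
    if "condition" in cfg and "protocol.voltages_V" not in cfg:
        _, protocol = condition_config(str(cfg["condition"]))
        dt = float(cfg.get("protocol.sample_dt_s", protocol.sample_dt))
        return VoltageProtocol(steps=protocol.steps, sample_dt=dt)
    if "protocol.voltages_V" not in cfg or "protocol.durations_s" not in cfg:
        raise ConfigError("config must provide protocol.voltages_V and protocol.durations_s (or a condition)")
    voltages = _as_tuple(cfg["protocol.voltages_V"])
    durations = _as_tuple(cfg["protocol.durations_s"])
    if len(voltages) != len(durations):
        raise ConfigError(
            f"protocol.voltages_V has {len(voltages)} entries but protocol.durations_s has {len(durations)}"
        )
    steps = tuple((float(d), float(v)) for d, v in zip(durations, voltages))
    return VoltageProtocol(steps=steps, sample_dt=float(cfg.get("protocol.sample_dt_s", 1.0)))


def build_fit_config(cfg: dict[str, Any]) -> FitConfig:
    """Fit configuration from parsed config (defaults where unspecified)."""
    base = FitConfig()
    return FitConfig(
        p_lower=float(cfg.get("fit.P_lower_per_s", base.p_lower)),
        p_upper=float(cfg.get("fit.P_upper_per_s", base.p_upper)),
        tol=float(cfg.get("fit.tol", base.tol)),
        max_iter=int(cfg.get("fit.max_iter", base.max_iter)),
    )


def build_noise(cfg: dict[str, Any]) -> NoiseSpec:
    """Noise specification from parsed config."""
    if "noise.sigma_fraction_of_max" in cfg:
        return NoiseSpec(
            sigma=float(cfg["noise.sigma_fraction_of_max"]),
            seed=int(cfg.get("noise.seed", 0)),
            mode="fraction_of_max",
        )
    return NoiseSpec(
        sigma=float(cfg.get("noise.sigma_mA_cm2", 0.0)),
        seed=int(cfg.get("noise.seed", 0)),
        mode="absolute",
    )
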