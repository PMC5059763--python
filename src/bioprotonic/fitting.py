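"""Least-squares estimation of membrane permeability and Tafel parameters.

The permeability fit mirrors the study workflow: iterate the forward
model over the voltage protocol with a candidate membrane permeability
P, compare the simulated electrode current density against the observed
chronoamperometry trace, and minimize the sum of squared residuals over
P with a derivative-free bounded scalar search. The search runs in
log10(P) (the plausible range spans several decades) which makes the
convergence tolerance naturally relative.

Residuals are computed on the current density i only — it is the sole
experimentally observed quantity; pH_IL and j are model internals.

Tafel parameters (i0, α) of a bare contact are recovered separately
from a slow low-voltage I–V sweep by nonlinear least squares on the
Butler–Volmer expression.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .dynamics import DeviceSystem, Trace, VoltageProtocol, integrate_protocol
from .transport import electrode_current_density

__all__ = ["FitConfig", "FitResult", "FitError", "trace_residuals", "fit_permeability", "fit_electrode_params"]

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """Raised when a fit cannot produce a meaningful estimate."""


@dataclass(frozen=True)
class FitConfig:
    """Bounds and stopping rules for the permeability fit.

    p_lower, p_upper
        Permeability bounds (device scale).
    tol
        Relative convergence tolerance on the parameter.
    max_iter
        Maximal number of objective evaluations.
    """

    p_lower: float = 1e-4
    p_upper: float = 10.0
    tol: float = 1e-6
    max_iter: int = 200

    def __post_init__(self) -> None:
        if not (0 < self.p_lower < self.p_upper):
            raise ValueError(
                f"bounds must satisfy 0 < p_lower < p_upper, got [{self.p_lower}, {self.p_upper}]"
            )
        if self.tol <= 0:
            raise ValueError(f"tol must be > 0, got {self.tol}")
        if self.max_iter < 10:
            raise ValueError("max_iter must be at least 10")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a permeability fit."""

    P_hat: float
    sse: float
    n_obs: int
    converged: bool
    iterations: int
    at_bound: bool = False

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("sse must be >= 0")


def _membrane_with_P(system: DeviceSystem, P: float) -> DeviceSystem:
    """Device system with the candidate permeability installed.

    The channel-open permeability is set to P; the bare-bilayer floor is
    lowered to P when the candidate falls below it so the membrane spec
    stays ordered (relevant when fitting a bare-SLB trace).
    """
    membrane = replace(
        system.membrane,
        P_channel=P,
        P_base=min(system.membrane.P_base, P),
    )
    return replace(system, membrane=membrane)


def trace_residuals(
    P: float,
    observed: Trace,
    system: DeviceSystem,
    protocol: VoltageProtocol,
) -> tuple[np.ndarray, float]:
    """Residual vector (observed − simulated i, mA cm⁻²) and its SSE.

    The forward model is run with permeability P and its current is
    interpolated linearly onto the observed sample times.
    """
    if len(observed) == 0:
        raise ValueError("observed trace is empty")
    span = protocol.total_duration
    t = observed.t
    if t[0] < -1e-9 or t[-1] > span * (1 + 1e-9):
        raise ValueError(
            f"observed times [{t[0]}, {t[-1]}] fall outside the protocol span [0, {span}]"
        )
    sim = integrate_protocol(_membrane_with_P(system, P), protocol)
    i_sim = np.interp(t, sim.t, sim.i)
    residuals = observed.i - i_sim
    return residuals, float(np.dot(residuals, residuals))


def fit_permeability(
    observed: Trace,
    system: DeviceSystem,
    protocol: VoltageProtocol,
    config: FitConfig | None = None,
) -> FitResult:
    """Bounded scalar least-squares fit of the membrane permeability.

    Deterministic (derivative-free bounded minimization in log10 P, no
    randomness). A minimizer pinned at a bound is reported with
    ``at_bound=True`` and ``converged=False``.
    """
    config = config or FitConfig()
    lo, hi = math.log10(config.p_lower), math.log10(config.p_upper)
    n_eval = 0
    any_finite = False

    def objective(logP: float) -> float:
        nonlocal n_eval, any_finite
        n_eval += 1
        try:
            _, sse = trace_residuals(10.0 ** logP, observed, system, protocol)
        except (RuntimeError, FloatingPointError, OverflowError):
            return np.inf
        if math.isfinite(sse):
            any_finite = True
            return sse
        return np.inf

    res = minimize_scalar(
        objective,
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": config.tol / math.log(10.0), "maxiter": config.max_iter},
    )
    if not any_finite or not math.isfinite(res.fun):
        raise FitError("objective was non-finite everywhere in the bounds; fit failed")
    log_hat = float(res.x)
    margin = 1e-3 * (hi - lo)
    at_bound = (log_hat - lo) < margin or (hi - log_hat) < margin
    P_hat = min(max(10.0 ** log_hat, config.p_lower), config.p_upper)
    return FitResult(
        P_hat=P_hat,
        sse=float(res.fun),
        n_obs=len(observed),
        converged=bool(res.success) and not at_bound and n_eval <= config.max_iter,
        iterations=n_eval,
        at_bound=at_bound,
    )


def fit_electrode_params(sweep: Trace, system: DeviceSystem) -> tuple[float, float]:
    """Recover (i0, α) of the Pd contact from a low-voltage I–V sweep.

    Assumes the sweep was taken without a membrane (or with the channels
    fully open and the IL equilibrated), so V_N = 0 and the current is
    the bare Butler–Volmer expression. i0 is searched in log space to
    keep it positive; α is bounded to (0, 1).
    """
    if len(sweep) < 3:
        raise FitError("sweep must contain at least 3 points")
    i_obs = sweep.i * 10.0  # mA cm⁻² -> A m⁻²
    v = sweep.V
    if float(np.max(np.abs(i_obs))) == 0.0:
        raise FitError("sweep carries zero current everywhere; (i0, alpha) are unidentifiable")
    eta = v - system.electrode.V0
    if np.all(eta >= 0) or np.all(eta <= 0):
        warnings.warn(
            "I-V sweep covers only one sign of overpotential; the (i0, alpha) fit is ill-conditioned",
            RuntimeWarning,
            stacklevel=2,
        )

    electrode0 = system.electrode
    constants = system.constants

    def model(log10_i0: float, alpha: float) -> np.ndarray:
        e = replace(electrode0, i0=10.0 ** log10_i0, alpha=alpha)
        return np.array(
            [electrode_current_density(e, vk, 0.0, True, constants) for vk in v]
        )

    def residual(p: np.ndarray) -> np.ndarray:
        return model(p[0], p[1]) - i_obs

    scale = float(np.max(np.abs(i_obs)))
    p0 = np.array([math.log10(max(scale / 10.0, 1e-6)), 0.5])
    res = least_squares(
        residual,
        p0,
        bounds=([-12.0, 1e-3], [12.0, 1.0 - 1e-3]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    if not res.success and float(np.max(np.abs(res.fun))) > 1e-6 * scale:
        raise FitError(f"electrode parameter fit did not converge: {res.message}")
    i0_hat = 10.0 ** float(res.x[0])
    alpha_hat = float(res.x[1])
    return i0_hat, alpha_hat
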