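"""Integration of assembled systems to their long-run state.

The workhorse is a numba-compiled adaptive Dormand-Prince 5(4) stepper
(the same embedded Runge-Kutta pair as scipy's ``RK45``), specialised to the
Lotka-Volterra right-hand side so that the parameter sweep can afford
hundreds of thousands of integrations.  Any negative component produced by
floating-point error is clipped to zero immediately after each accepted
step, which keeps the extinction boundary absorbing.

A deliberately naive fixed-step forward-Euler integrator is provided as an
independent cross-check route; it shares nothing with the adaptive stepper
beyond the right-hand side definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from antagosim.model import AssembledSystem, InvalidParameterError, lv_derivative


class IntegrationFailureError(RuntimeError):
    """The adaptive solver failed (step-size underflow or step budget exceeded)."""

    def __init__(self, message: str, steps_taken: int, t_reached: float):
        super().__init__(message)
        self.steps_taken = steps_taken
        self.t_reached = t_reached


class DegenerateCommunityError(RuntimeError):
    """Every focal species went extinct; relative abundances are undefined."""


@dataclass(frozen=True)
class IntegrationSettings:
    """Solver configuration.

    ``t_end`` is a fixed time horizon; the adaptive stepper chooses its own
    steps within it.  ``convergence_tol`` thresholds the infinity norm of the
    derivative at ``t_end`` for the ``converged`` diagnostic.  Densities
    below ``readout_floor`` are treated as exactly 0 when compositions are
    read out.  ``initial_density`` is the common starting density used by the
    sweep engine (every species starts at the same strictly positive value).
    """

    t_end: float = 1000.0
    rel_tol: float = 1e-8
    abs_tol: float = 1e-8
    max_steps: int = 1_000_000
    convergence_tol: float = 1e-6
    readout_floor: float = 1e-12
    initial_density: float = 0.1

    def __post_init__(self) -> None:
        if not self.t_end > 0:
            raise InvalidParameterError(f"t_end must be > 0, got {self.t_end}")
        for name in ("rel_tol", "abs_tol", "convergence_tol"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if int(self.max_steps) != self.max_steps or self.max_steps < 1:
            raise InvalidParameterError(f"max_steps must be a positive integer, got {self.max_steps}")
        if self.readout_floor < 0:
            raise InvalidParameterError(f"readout_floor must be >= 0, got {self.readout_floor}")
        if not self.initial_density > 0:
            raise InvalidParameterError(
                f"initial_density must be > 0, got {self.initial_density}"
            )


@dataclass(frozen=True)
class EquilibriumState:
    """Densities at ``t_end`` plus convergence diagnostics."""

    densities: np.ndarray
    converged: bool
    t_end_used: float


@dataclass(frozen=True)
class CompositionVector:
    """Relative abundances of the focal species (nonnegative, sums to 1)."""

    proportions: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        object.__setattr__(self, "proportions", p)

    def __len__(self) -> int:
        return len(self.proportions)


# Dormand-Prince 5(4) tableau (exact rationals).
_DP_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_DP_A = np.zeros((7, 7))
_DP_A[1, 0] = 1 / 5
_DP_A[2, :2] = (3 / 40, 9 / 40)
_DP_A[3, :3] = (44 / 45, -56 / 15, 32 / 9)
_DP_A[4, :4] = (19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729)
_DP_A[5, :5] = (9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656)
_DP_A[6, :6] = (35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84)
_DP_B = _DP_A[6].copy()  # 5th-order solution weights (FSAL)
_DP_BHAT = np.array(
    [5179 / 57600, 0.0, 7571 / 16695, 393 / 640, -92097 / 339200, 187 / 2100, 1 / 40]
)
_DP_E = _DP_B - _DP_BHAT  # error estimator weights

_STATUS_OK = 0
_STATUS_MAX_STEPS = 1
_STATUS_UNDERFLOW = 2


@njit(cache=True)
def _lv_rhs(alpha, r, x, out):  # pragma: no cover - jitted
    N = x.shape[0]
    for i in range(N):
        s = 0.0
        for j in range(N):
            s += alpha[i, j] * x[j]
        out[i] = r[i] * x[i] * (1.0 - s)


@njit(cache=True)
def _dp5_core(alpha, r, x0, t_end, rtol, atol, max_steps, a, b, c, e):  # pragma: no cover - jitted
    N = x0.shape[0]
    x = x0.copy()
    k = np.empty((7, N))
    xs = np.empty(N)
    xnew = np.empty(N)
    _lv_rhs(alpha, r, x, k[0])

    # initial step: conservative fraction of the horizon
    h = min(1e-2, t_end * 1e-3)
    t = 0.0
    nsteps = 0
    while t < t_end:
        if nsteps >= max_steps:
            return x, t, _STATUS_MAX_STEPS, nsteps
        if h < 1e-14 * max(1.0, t):
            return x, t, _STATUS_UNDERFLOW, nsteps
        if t + h > t_end:
            h = t_end - t

        for s in range(1, 7):
            for i in range(N):
                acc = 0.0
                for q in range(s):
                    acc += a[s, q] * k[q, i]
                xs[i] = x[i] + h * acc
            _lv_rhs(alpha, r, xs, k[s])

        # 5th-order solution and embedded error estimate
        err = 0.0
        for i in range(N):
            acc = 0.0
            eacc = 0.0
            for s in range(7):
                acc += b[s] * k[s, i]
                eacc += e[s] * k[s, i]
            xnew[i] = x[i] + h * acc
            scale = atol + rtol * max(abs(x[i]), abs(xnew[i]))
            d = h * eacc / scale
            err += d * d
        err = np.sqrt(err / N)

        nsteps += 1
        if err <= 1.0:
            t += h
            clipped = False
            for i in range(N):
                if xnew[i] < 0.0:
                    xnew[i] = 0.0
                    clipped = True
            x[:] = xnew
            if clipped:
                _lv_rhs(alpha, r, x, k[0])
            else:
                k[0] = k[6]  # FSAL
            if err == 0.0:
                factor = 10.0
            else:
                factor = min(10.0, max(0.2, 0.9 * err ** -0.2))
            h *= factor
        else:
            h *= max(0.2, 0.9 * err ** -0.2)
    return x, t, _STATUS_OK, nsteps


def integrate(
    system: AssembledSystem,
    x0: np.ndarray,
    settings: IntegrationSettings = IntegrationSettings(),
) -> EquilibriumState:
    """Integrate the system to ``settings.t_end`` with adaptive RK 5(4).

    Parameters
    ----------
    system : AssembledSystem
    x0 : array
        Strictly positive initial densities, length ``system.size``.
    settings : IntegrationSettings

    Returns
    -------
    EquilibriumState
        Final densities (componentwise >= 0) with a ``converged`` flag set
        when the infinity norm of the derivative at ``t_end`` is below
        ``settings.convergence_tol``.

    Raises
    ------
    IntegrationFailureError
        On step-size underflow or when ``max_steps`` is exhausted; the error
        carries ``steps_taken`` and ``t_reached``.
    """
    x0 = np.ascontiguousarray(x0, dtype=float)
    if x0.shape != (system.size,):
        raise InvalidParameterError(
            f"x0 must have length {system.size}, got shape {x0.shape}"
        )
    if not np.all(x0 > 0):
        raise InvalidParameterError("x0 must be strictly positive")
    x, t, status, nsteps = _dp5_core(
        np.ascontiguousarray(system.alpha),
        np.ascontiguousarray(system.r),
        x0,
        float(settings.t_end),
        float(settings.rel_tol),
        float(settings.abs_tol),
        int(settings.max_steps),
        _DP_A,
        _DP_B,
        _DP_C,
        _DP_E,
    )
    if status == _STATUS_MAX_STEPS:
        raise IntegrationFailureError(
            f"max_steps={settings.max_steps} exhausted at t={t:.6g}", nsteps, t
        )
    if status == _STATUS_UNDERFLOW:
        raise IntegrationFailureError(
            f"step size underflow at t={t:.6g}", nsteps, t
        )
    densities = np.clip(x, 0.0, None)
    deriv = lv_derivative(densities, system)
    converged = bool(np.max(np.abs(deriv)) < settings.convergence_tol)
    return EquilibriumState(densities=densities, converged=converged, t_end_used=t)


def integrate_euler(
    system: AssembledSystem, x0: np.ndarray, t_end: float, dt: float = 1e-3
) -> np.ndarray:
    """Fixed-step forward Euler reference integrator.

    Deliberately simple and independent of the adaptive path: one explicit
    Euler step per ``dt``, with negative densities clipped to 0.  Intended
    for small systems and cross-checking only.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (system.size,):
        raise InvalidParameterError(
            f"x0 must have length {system.size}, got shape {x0.shape}"
        )
    if not (t_end > 0 and dt > 0):
        raise InvalidParameterError("t_end and dt must be > 0")
    n_steps = int(round(t_end / dt))
    alpha, r = system.alpha, system.r
    x = x0.copy()
    for _ in range(n_steps):
        x = x + dt * (r * x * (1.0 - alpha @ x))
        np.clip(x, 0.0, None, out=x)
    return x


def focal_relative_abundances(
    state: EquilibriumState,
    system: AssembledSystem,
    settings: IntegrationSettings = IntegrationSettings(),
) -> CompositionVector:
    """Normalize the focal densities into a composition vector.

    Densities below ``settings.readout_floor`` are zeroed first.  Raises
    :class:`DegenerateCommunityError` if every focal species is extinct.
    """
    densities = np.asarray(state.densities, dtype=float)
    if densities.shape != (system.size,):
        raise InvalidParameterError(
            f"state has length {densities.shape}, system expects {system.size}"
        )
    focal = densities[: system.n_focal].copy()
    focal[focal < settings.readout_floor] = 0.0
    total = focal.sum()
    if total <= 0.0:
        raise DegenerateCommunityError(
            "all focal species extinct; composition undefined"
        )
    return CompositionVector(proportions=focal / total)
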