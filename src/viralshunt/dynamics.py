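"""Consumer-resource model of lysogen growth, lysis, and lysate recycling.

The model tracks four kinds of state in a well-mixed batch culture, all in
OD600-equivalent units (biomass yield Y = 1) with time in hours:

* glucose ``C_g``, the externally supplied resource,
* lysate ``C_l``, an effective pool of cellular material released by lysis,
* wild-type (non-lysing) lysogen biomass ``B_WT``,
* temperature-sensitive (lysing) lysogen biomass partitioned into ``k``
  sequential compartments ``B_TS,1..k``.

Growth on either resource follows Monod kinetics.  Induction-to-lysis timing
is modeled with the linear-chain trick: TS biomass advances through the k
compartments at rate ``k*delta``, so the time from induction to lysis is
Erlang(k, k*delta) distributed with mean ``1/delta`` and variance
``1/(k*delta**2)``.  Biomass leaving the terminal compartment lyses and feeds
the lysate pool with recycling efficiency ``epsilon``; the remaining fraction
``1 - epsilon`` is lost.  Optical density is the sum of live biomass
(``B_WT`` plus total TS); lysate does not contribute to OD.

Two model variants are exposed via ``ModelParams.ts_lysate_growth``:

* ``False`` (default): TS compartments grow on glucose only.  Lysate is
  still drawn down by total biomass, so TS uptake of lysate is booked as a
  pure sink.  This makes a TS-only culture's biomass trajectory independent
  of the lysate parameters, which is what makes the staged parametrization
  (see :mod:`viralshunt.inference`) exactly self-consistent.
* ``True``: TS compartments also grow on lysate, closing the mass balance
  (with ``epsilon = 1`` the system conserves total mass exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint

try:  # optional acceleration; the numpy path is the reference implementation
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "ModelParams",
    "InitialState",
    "SolverConfig",
    "Trajectory",
    "IntegrationError",
    "monod_rate",
    "model_rhs",
    "simulate",
    "observable_od",
    "wt_net_growth_rate",
    "erlang_lysis_moments",
    "conservation_audit",
]


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the time at which the solver gave up."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (t = {t_fail:g} h)")
        self.t_fail = t_fail


@dataclass(frozen=True)
class ModelParams:
    """Rate, affinity, and recycling parameters of the consumer-resource model.

    Parameters
    ----------
    mu_g_max : float
        Maximum growth rate on glucose, h^-1.
    K_S_g : float
        Glucose half-saturation constant, OD-equivalent units.
    mu_l_max : float
        Maximum growth rate on lysate, h^-1.
    K_S_l : float
        Lysate half-saturation constant, OD-equivalent units.
    delta : float
        Lysis rate, h^-1; the mean induction-to-lysis time is ``1/delta``.
    k : int
        Number of sequential TS compartments (>= 1); larger k narrows the
        lysis-time distribution at fixed mean.
    epsilon : float
        Biomass recycling efficiency in [0, 1]: the fraction of lysed
        biomass that enters the lysate pool (yield on lysate).
    ts_lysate_growth : bool
        Whether TS compartments also grow on lysate (see module docstring).
    """

    mu_g_max: float
    K_S_g: float
    mu_l_max: float
    K_S_l: float
    delta: float
    k: int
    epsilon: float
    ts_lysate_growth: bool = False

    def __post_init__(self):
        for name in ("mu_g_max", "K_S_g", "mu_l_max", "K_S_l", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not float(self.k).is_integer() or self.k < 1:
            raise ValueError(f"k must be a positive integer, got {self.k}")
        object.__setattr__(self, "k", int(self.k))
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must lie in [0, 1], got {self.epsilon}")

    def with_(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


#: Defaults used throughout the analysis scripts and the synthetic-data
#: generator.  Chosen once to reproduce the qualitative batch regime of the
#: study system (TS decline within the first hour of induction, a transient
#: WT growth-rate boost of ~10-15% peaking a few hours in, and partial
#: biomass compensation of the 19WT-81TS mix); see docs/methods.md.
DEFAULT_PARAMS = ModelParams(
    mu_g_max=0.7,
    K_S_g=0.01,
    mu_l_max=0.8,
    K_S_l=0.05,
    delta=0.9,
    k=6,
    epsilon=0.4,
)

#: Default initial glucose pool, OD-equivalent.  Matches the convention that
#: glucose equals the saturation OD minus the inoculum OD of a WT-only
#: culture grown on the same medium (saturation ~0.46 from an OD 0.01 start).
DEFAULT_GLUCOSE_OD = 0.45


@dataclass(frozen=True)
class InitialState:
    """Initial condition: all TS biomass starts in compartment 1."""

    B_WT0: float
    TS0: float
    C_g0: float = DEFAULT_GLUCOSE_OD
    C_l0: float = 0.0

    def __post_init__(self):
        for name in ("B_WT0", "TS0", "C_g0", "C_l0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    def state_vector(self, k: int) -> np.ndarray:
        """Flat state vector ``[C_g, C_l, B_WT, B_TS_1..k]``."""
        y0 = np.zeros(3 + k)
        y0[0] = self.C_g0
        y0[1] = self.C_l0
        y0[2] = self.B_WT0
        y0[3] = self.TS0
        return y0


@dataclass(frozen=True)
class SolverConfig:
    """Integrator settings (LSODA via scipy, stiff-capable, adaptive)."""

    rtol: float = 1e-8
    atol: float = 1e-10
    grid_step: float = 0.02  # h, spacing of the dense output grid


@dataclass(frozen=True)
class Trajectory:
    """Time-resolved model state on a strictly increasing grid.

    ``B_TS`` has shape ``(n_times, k)``; ``od`` is the derived observable
    ``B_WT + sum_i B_TS_i`` (lysate never contributes).
    """

    times: np.ndarray
    C_g: np.ndarray
    C_l: np.ndarray
    B_WT: np.ndarray
    B_TS: np.ndarray
    params: ModelParams = field(repr=False)

    @property
    def B_TS_total(self) -> np.ndarray:
        return self.B_TS.sum(axis=1)

    @property
    def od(self) -> np.ndarray:
        return self.B_WT + self.B_TS_total

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: time_h, C_g, C_l, B_WT, B_TS_total, od."""
        return pd.DataFrame(
            {
                "time_h": self.times,
                "C_g": self.C_g,
                "C_l": self.C_l,
                "B_WT": self.B_WT,
                "B_TS_total": self.B_TS_total,
                "od": self.od,
            }
        )


def monod_rate(mu_max, K_S, C):
    """Monod growth rate ``mu_max * C / (C + K_S)``.

    Accepts scalars or arrays.  Nondecreasing in ``C`` and bounded by
    ``mu_max``.  The degenerate case ``K_S = C = 0`` returns 0 by convention.
    Negative inputs raise ``ValueError``.
    """
    mu_max = np.asarray(mu_max, dtype=float)
    K_S = np.asarray(K_S, dtype=float)
    C = np.asarray(C, dtype=float)
    if np.any(mu_max < 0) or np.any(K_S < 0) or np.any(C < 0):
        raise ValueError("monod_rate requires nonnegative mu_max, K_S, and C")
    denom = C + K_S
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(denom > 0, mu_max * C / np.where(denom > 0, denom, 1.0), 0.0)
    if rate.ndim == 0:
        return float(rate)
    return rate


def _rhs(y: np.ndarray, params: ModelParams) -> np.ndarray:
    """Time derivative of the flat state vector (clipping small negatives)."""
    y = np.maximum(y, 0.0)
    C_g, C_l, B_WT = y[0], y[1], y[2]
    B_TS = y[3:]
    B_TS_tot = B_TS.sum()
    B_tot = B_WT + B_TS_tot
    dg = C_g + params.K_S_g
    mu_g = params.mu_g_max * C_g / dg if dg > 0 else 0.0
    dl = C_l + params.K_S_l
    mu_l = params.mu_l_max * C_l / dl if dl > 0 else 0.0
    kdelta = params.k * params.delta

    out = np.empty_like(y)
    out[0] = -mu_g * B_tot
    out[1] = -mu_l * B_tot + params.epsilon * kdelta * B_TS[-1]
    out[2] = (mu_g + mu_l) * B_WT
    mu_ts = mu_g + (mu_l if params.ts_lysate_growth else 0.0)
    d_ts = (mu_ts - kdelta) * B_TS
    d_ts[1:] += kdelta * B_TS[:-1]
    out[3:] = d_ts
    return out


if _HAVE_NUMBA:

    @_njit(cache=False)
    def _rhs_kernel(y, mu_g_max, ksg, mu_l_max, ksl, kdelta, eps, tsg):
        # jitted mirror of _rhs; kept in lockstep with the numpy version
        n = y.shape[0]
        out = np.empty(n)
        C_g = y[0] if y[0] > 0.0 else 0.0
        C_l = y[1] if y[1] > 0.0 else 0.0
        B_WT = y[2] if y[2] > 0.0 else 0.0
        B_TS_tot = 0.0
        for i in range(3, n):
            if y[i] > 0.0:
                B_TS_tot += y[i]
        B_tot = B_WT + B_TS_tot
        dg = C_g + ksg
        mu_g = mu_g_max * C_g / dg if dg > 0.0 else 0.0
        dl = C_l + ksl
        mu_l = mu_l_max * C_l / dl if dl > 0.0 else 0.0
        out[0] = -mu_g * B_tot
        last = y[n - 1] if y[n - 1] > 0.0 else 0.0
        out[1] = -mu_l * B_tot + eps * kdelta * last
        out[2] = (mu_g + mu_l) * B_WT
        mu_ts = mu_g + mu_l if tsg else mu_g
        prev = 0.0
        for i in range(3, n):
            b = y[i] if y[i] > 0.0 else 0.0
            out[i] = (mu_ts - kdelta) * b + kdelta * prev
            prev = b
        return out

    def _make_ode_func(params: ModelParams):
        kdelta = float(params.k * params.delta)
        return lambda y, t: _rhs_kernel(
            y, params.mu_g_max, params.K_S_g, params.mu_l_max, params.K_S_l,
            kdelta, params.epsilon, params.ts_lysate_growth,
        )

else:  # pragma: no cover

    def _make_ode_func(params: ModelParams):
        return lambda y, t: _rhs(y, params)


def model_rhs(state: Sequence[float], params: ModelParams) -> np.ndarray:
    """Derivative of ``[C_g, C_l, B_WT, B_TS_1..k]`` under the model.

    Raises ``ValueError`` if the state length does not match ``3 + k``.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (3 + params.k,):
        raise ValueError(
            f"state vector has length {y.size}, expected 3 + k = {3 + params.k}"
        )
    return _rhs(y, params)


def simulate(
    params: ModelParams,
    init: InitialState,
    t_end: float,
    solver_cfg: SolverConfig | None = None,
    t_eval: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the model from ``init`` to ``t_end``.

    Parameters
    ----------
    t_eval : array, optional
        Explicit output grid (must start at 0 and increase).  By default a
        dense uniform grid with ``solver_cfg.grid_step`` spacing is used.

    Raises
    ------
    IntegrationError
        If the solver's step size collapses; the exception carries the
        failing time.
    """
    cfg = solver_cfg or SolverConfig()
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if t_eval is None:
        n = max(int(round(t_end / cfg.grid_step)), 1) + 1
        times = np.linspace(0.0, t_end, n)
    else:
        times = np.asarray(t_eval, dtype=float)
        if times[0] != 0.0 or np.any(np.diff(times) <= 0):
            raise ValueError("t_eval must start at 0 and be strictly increasing")
    y0 = init.state_vector(params.k)
    sol, info = odeint(
        _make_ode_func(params),
        y0,
        times,
        rtol=cfg.rtol,
        atol=cfg.atol,
        full_output=True,
        mxstep=10000,
    )
    if info["message"] != "Integration successful.":
        t_fail = float(info["tcur"][-1]) if len(info["tcur"]) else float("nan")
        raise IntegrationError(info["message"], t_fail)
    return Trajectory(
        times=times,
        C_g=sol[:, 0],
        C_l=sol[:, 1],
        B_WT=sol[:, 2],
        B_TS=sol[:, 3:],
        params=params,
    )


def observable_od(traj: Trajectory) -> np.ndarray:
    """Optical density: live biomass ``B_WT + sum_i B_TS_i`` (no lysate)."""
    return traj.od


def wt_net_growth_rate(traj: Trajectory, params: ModelParams | None = None) -> np.ndarray:
    """Per-capita WT net growth rate ``mu_g(C_g) + mu_l(C_l)`` along a run.

    Equals ``(dB_WT/dt) / B_WT`` since WT has no loss terms.
    """
    p = params or traj.params
    return monod_rate(p.mu_g_max, p.K_S_g, np.maximum(traj.C_g, 0.0)) + monod_rate(
        p.mu_l_max, p.K_S_l, np.maximum(traj.C_l, 0.0)
    )


def erlang_lysis_moments(delta: float, k: int) -> tuple[float, float]:
    """Mean and variance of the Erlang(k, k*delta) induction-to-lysis time.

    Returns ``(1/delta, 1/(k*delta**2))``.  The variance shrinks as ``1/k``
    at fixed mean, which is how the chain length tunes lysis synchrony.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if not float(k).is_integer() or k < 1:
        raise ValueError("k must be a positive integer")
    return 1.0 / delta, 1.0 / (k * delta**2)


def conservation_audit(traj: Trajectory, params: ModelParams | None = None) -> np.ndarray:
    """Mass-balance deficit series; ~0 everywhere for a correct model.

    With yield Y = 1 the only unbooked flows out of the total pool
    ``C_g + C_l + B_WT + sum B_TS`` are the non-recycled fraction of lysis,
    ``(1 - epsilon) * k * delta * B_TS_k``, and — in the default
    ``ts_lysate_growth=False`` variant — TS lysate uptake
    ``mu_l(C_l) * B_TS``, which is drawn down without a growth credit.  The
    audit evaluates d/dt(total) from the model right-hand side at every grid
    point and adds those sinks back; the result is zero up to floating-point
    error, independent of the solver.
    """
    p = params or traj.params
    deficit = np.empty_like(traj.times)
    for j in range(traj.times.size):
        y = np.concatenate(([traj.C_g[j], traj.C_l[j], traj.B_WT[j]], traj.B_TS[j]))
        dtotal = _rhs(y, p).sum()
        sink = (1.0 - p.epsilon) * p.k * p.delta * max(traj.B_TS[j, -1], 0.0)
        if not p.ts_lysate_growth:
            sink += monod_rate(p.mu_l_max, p.K_S_l, max(traj.C_l[j], 0.0)) * np.maximum(
                traj.B_TS[j], 0.0
            ).sum()
        deficit[j] = dtotal + sink
    return deficit
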