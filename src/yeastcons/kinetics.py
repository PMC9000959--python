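"""Single-strain ODE models: Hill transfer stages and stiff-capable simulation.

Every strain is described phenomenologically by a chain of first-order stages.

Model 1 (one input, three states)::

    dx1/dt = u - d1*x1                    # input sensing
    dx2/dt = V*hill(x1; K, n) - d2*x2     # signal processing (Hill stage)
    dx3/dt = k3*x2 + c0 - d3*x3           # output synthesis + basal leak

Model 2 (two inputs, five states) duplicates the sensing and processing stages
per input branch and combines the two normalized branch activities in the
output stage. By default the combination is a product of normalized branch
activities (either branch can veto the output); an additive rule is available
via ``combine="sum"``.

Time is in hours, extracellular inputs in nM, intracellular states and
fluorescence in arbitrary units.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .species import Transfer

__all__ = [
    "Model1Params",
    "Model2Params",
    "TimeCourse",
    "DoseResponse",
    "hill",
    "simulate_model1",
    "steady_state_model1",
    "simulate_model2",
    "steady_state_model2",
    "dose_response",
]

#: Default solver tolerances (stiff-capable LSODA).
RTOL = 1e-8
ATOL = 1e-10


def hill(x, K: float, n: float, mode: Transfer | str = Transfer.ACTIVATING):
    """Hill transfer function, bounded in [0, 1].

    Parameters
    ----------
    x : float or array-like, >= 0
        Input level (concentration-like).
    K : float, > 0
        Half-maximal input.
    n : float, > 0
        Hill coefficient (cooperativity).
    mode : {"activating", "repressing"}
        ``activating`` returns x^n / (K^n + x^n); ``repressing`` its complement.
    """
    if K <= 0 or n <= 0:
        raise ValueError(f"K and n must be positive (got K={K}, n={n})")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)) or np.any(x < 0):
        raise ValueError("hill input must be finite and non-negative")
    mode = Transfer(mode)
    # compute in a scale-free way to avoid overflow for large x/K
    with np.errstate(over="ignore"):
        r = (x / K) ** n
    act = np.where(np.isinf(r), 1.0, r / (1.0 + r))
    out = act if mode is Transfer.ACTIVATING else 1.0 - act
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Model1Params:
    """Kinetic parameters of the three-stage single-input model.

    The sensing influx coefficient is fixed to 1 (its scale is absorbed into
    ``K``), leaving eight free parameters.
    """

    d1: float  # sensing-complex turnover (1/h)
    V: float  # max processor synthesis (a.u./h)
    K: float  # half-maximal sensed level (sensed-state units; EC50 = K*d1 in nM)
    n: float  # Hill coefficient
    d2: float  # processor turnover (1/h)
    k3: float  # output synthesis per processor (1/h)
    c0: float  # basal output synthesis (a.u./h or nM/h)
    d3: float  # output turnover (1/h)

    NAMES = ("d1", "V", "K", "n", "d2", "k3", "c0", "d3")

    def __post_init__(self) -> None:
        for name in self.NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"Model1Params.{name} must be finite")
            if name == "c0":
                if v < 0:
                    raise ValueError("c0 must be >= 0")
            elif v <= 0:
                raise ValueError(f"Model1Params.{name} must be > 0 (got {v})")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in self.NAMES], dtype=float)

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "Model1Params":
        return cls(**dict(zip(cls.NAMES, map(float, a))))

    def replace(self, **kw) -> "Model1Params":
        return replace(self, **kw)

    @property
    def ec50(self) -> float:
        """Input concentration at half-maximal processing (nM)."""
        return self.K * self.d1

    @property
    def x2_sat(self) -> float:
        """Saturating processor level V/d2."""
        return self.V / self.d2


@dataclass(frozen=True)
class Model2Params:
    """Parameters of the two-input, five-state model (branches a and b)."""

    d1a: float
    d1b: float
    Va: float
    Ka: float
    na: float
    d2a: float
    Vb: float
    Kb: float
    nb: float
    d2b: float
    k5: float
    c0: float
    d5: float

    NAMES = (
        "d1a", "d1b", "Va", "Ka", "na", "d2a",
        "Vb", "Kb", "nb", "d2b", "k5", "c0", "d5",
    )

    def __post_init__(self) -> None:
        for name in self.NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"Model2Params.{name} must be finite")
            if name == "c0":
                if v < 0:
                    raise ValueError("c0 must be >= 0")
            elif v <= 0:
                raise ValueError(f"Model2Params.{name} must be > 0 (got {v})")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in self.NAMES], dtype=float)

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "Model2Params":
        return cls(**dict(zip(cls.NAMES, map(float, a))))

    def replace(self, **kw) -> "Model2Params":
        return replace(self, **kw)


@dataclass
class TimeCourse:
    """Trajectories of a simulated system on a common time grid."""

    t: np.ndarray  # hours, strictly increasing
    y: np.ndarray  # (n_states, n_times)
    labels: list[str]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (len(self.labels), self.t.size):
            raise ValueError("TimeCourse shape mismatch between t, y and labels")

    def state(self, label: str) -> np.ndarray:
        return self.y[self.labels.index(label)]

    def endpoint(self, label: str) -> float:
        return float(self.state(label)[-1])


@dataclass
class DoseResponse:
    """Output read at a fixed time as a function of input dose."""

    dose: np.ndarray  # nM, unique and sorted
    response: np.ndarray  # a.u.
    read_time: float  # hours

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.dose.size != self.response.size:
            raise ValueError("dose and response must have equal length")
        if self.dose.size and (np.any(np.diff(self.dose) <= 0)):
            raise ValueError("doses must be unique and sorted ascending")


InputProfile = Callable[[float], float]


def _as_profile(u) -> InputProfile:
    """Accept a constant or a callable input profile; validate non-negativity lazily."""
    if callable(u):
        return u
    u = float(u)
    if u < 0:
        raise ValueError("input concentration must be >= 0")
    return lambda t: u


def _integrate(rhs, y0, t_grid, method="LSODA", rtol=RTOL, atol=ATOL):
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D grid")
    sol = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
        method=method, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    # clip tiny negative values from solver error
    y = np.where((sol.y < 0) & (sol.y > -10 * atol), 0.0, sol.y)
    return y


def rest_state_model1(params: Model1Params, transfer: Transfer | str) -> np.ndarray:
    """Steady state at zero input (the default initial condition)."""
    transfer = Transfer(transfer)
    h0 = 0.0 if transfer is Transfer.ACTIVATING else 1.0
    x2 = params.V * h0 / params.d2
    x3 = (params.k3 * x2 + params.c0) / params.d3
    return np.array([0.0, x2, x3])


def simulate_model1(
    params: Model1Params,
    transfer: Transfer | str,
    u,
    t_grid,
    y0: Sequence[float] | None = None,
    method: str = "LSODA",
    rtol: float = RTOL,
    atol: float = ATOL,
) -> TimeCourse:
    """Integrate the three-state single-input model.

    ``u`` may be a constant (nM) or a callable ``u(t)`` for piecewise-constant
    input schedules. The initial state defaults to the zero-input rest state.
    """
    transfer = Transfer(transfer)
    uf = _as_profile(u)
    p = params
    if y0 is None:
        y0 = rest_state_model1(p, transfer)

    def rhs(t, x):
        ut = uf(t)
        if ut < 0:
            raise ValueError("input concentration must be >= 0")
        h = hill(x[0] if x[0] > 0 else 0.0, p.K, p.n, transfer)
        return [
            ut - p.d1 * x[0],
            p.V * h - p.d2 * x[1],
            p.k3 * x[1] + p.c0 - p.d3 * x[2],
        ]

    y = _integrate(rhs, np.asarray(y0, float), t_grid, method, rtol, atol)
    return TimeCourse(np.asarray(t_grid, float), y, ["x1", "x2", "x3"])


def steady_state_model1(params: Model1Params, transfer: Transfer | str, u: float) -> float:
    """Closed-form steady-state output for a constant input ``u`` (nM)."""
    if u < 0:
        raise ValueError("input concentration must be >= 0")
    p = params
    h = hill(u / p.d1, p.K, p.n, Transfer(transfer))
    return (p.k3 * (p.V / p.d2) * h + p.c0) / p.d3


def rest_state_model2(params: Model2Params, transfers) -> np.ndarray:
    ta, tb = (Transfer(t) for t in transfers)
    p = params
    ha = 0.0 if ta is Transfer.ACTIVATING else 1.0
    hb = 0.0 if tb is Transfer.ACTIVATING else 1.0
    x3 = p.Va * ha / p.d2a
    x4 = p.Vb * hb / p.d2b
    x5 = (p.k5 * ha * hb + p.c0) / p.d5  # normalized activities at rest
    return np.array([0.0, 0.0, x3, x4, x5])


def simulate_model2(
    params: Model2Params,
    transfers,
    uA,
    uB,
    t_grid,
    y0: Sequence[float] | None = None,
    combine: str = "product",
    method: str = "LSODA",
    rtol: float = RTOL,
    atol: float = ATOL,
) -> TimeCourse:
    """Integrate the five-state two-input model.

    States: x1, x2 (sensing a, b); x3, x4 (processing a, b); x5 (output).
    The output stage drives synthesis with the product (default) or mean of
    the normalized branch activities x3/(Va/d2a) and x4/(Vb/d2b).
    """
    ta, tb = (Transfer(t) for t in transfers)
    p = params
    ua, ub = _as_profile(uA), _as_profile(uB)
    if combine not in ("product", "sum"):
        raise ValueError("combine must be 'product' or 'sum'")
    if y0 is None:
        y0 = rest_state_model2(p, (ta, tb))
    sat_a = p.Va / p.d2a
    sat_b = p.Vb / p.d2b

    def rhs(t, x):
        ha = hill(max(x[0], 0.0), p.Ka, p.na, ta)
        hb = hill(max(x[1], 0.0), p.Kb, p.nb, tb)
        za = max(x[2], 0.0) / sat_a
        zb = max(x[3], 0.0) / sat_b
        drive = za * zb if combine == "product" else 0.5 * (za + zb)
        return [
            ua(t) - p.d1a * x[0],
            ub(t) - p.d1b * x[1],
            p.Va * ha - p.d2a * x[2],
            p.Vb * hb - p.d2b * x[3],
            p.k5 * drive + p.c0 - p.d5 * x[4],
        ]

    y = _integrate(rhs, np.asarray(y0, float), t_grid, method, rtol, atol)
    return TimeCourse(np.asarray(t_grid, float), y, ["x1", "x2", "x3", "x4", "x5"])


def steady_state_model2(
    params: Model2Params, transfers, uA: float, uB: float, combine: str = "product"
) -> float:
    """Closed-form steady-state output for constant inputs."""
    ta, tb = (Transfer(t) for t in transfers)
    p = params
    za = hill(uA / p.d1a, p.Ka, p.na, ta)
    zb = hill(uB / p.d1b, p.Kb, p.nb, tb)
    drive = za * zb if combine == "product" else 0.5 * (za + zb)
    return (p.k5 * drive + p.c0) / p.d5


def dose_response(
    params: Model1Params,
    transfer: Transfer | str,
    doses,
    read_time: float,
    n_points: int = 61,
) -> DoseResponse:
    """Simulate one time course per dose and sample the output at ``read_time``.

    All doses are integrated as one stacked (decoupled) ODE system, which is
    markedly faster than per-dose calls when fitting.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ValueError("dose list must be non-empty")
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0")
    order = np.argsort(doses)
    if np.any(np.diff(doses[order]) == 0):
        raise ValueError("doses must be unique")
    transfer = Transfer(transfer)
    p = params
    m = doses.size
    t_grid = np.linspace(0.0, read_time, max(2, n_points))
    y0 = np.tile(rest_state_model1(p, transfer), m)

    def rhs(t, x):
        x = x.reshape(m, 3)
        h = hill(np.maximum(x[:, 0], 0.0), p.K, p.n, transfer)
        dx = np.empty_like(x)
        dx[:, 0] = doses - p.d1 * x[:, 0]
        dx[:, 1] = p.V * h - p.d2 * x[:, 1]
        dx[:, 2] = p.k3 * x[:, 1] + p.c0 - p.d3 * x[:, 2]
        return dx.ravel()

    y = _integrate(rhs, y0, t_grid)
    resp = y[:, -1].reshape(m, 3)[:, 2]
    return DoseResponse(doses[order], resp[order], read_time)


def timecourse_tensor_model1(
    params: Model1Params,
    transfer: Transfer | str,
    doses,
    times,
) -> np.ndarray:
    """Output x3 sampled on a (dose, time) grid, all doses stacked in one solve.

    ``times`` must start at 0 or will be prepended with 0 internally; returns an
    array of shape (n_doses, n_times).
    """
    doses = np.asarray(doses, dtype=float)
    times = np.asarray(times, dtype=float)
    transfer = Transfer(transfer)
    p = params
    m = doses.size
    prepend = times[0] > 0
    t_grid = np.concatenate([[0.0], times]) if prepend else times
    y0 = np.tile(rest_state_model1(p, transfer), m)

    def rhs(t, x):
        x = x.reshape(m, 3)
        h = hill(np.maximum(x[:, 0], 0.0), p.K, p.n, transfer)
        dx = np.empty_like(x)
        dx[:, 0] = doses - p.d1 * x[:, 0]
        dx[:, 1] = p.V * h - p.d2 * x[:, 1]
        dx[:, 2] = p.k3 * x[:, 1] + p.c0 - p.d3 * x[:, 2]
        return dx.ravel()

    y = _integrate(rhs, y0, t_grid, rtol=1e-7, atol=1e-9)
    out = y.reshape(m, 3, t_grid.size)[:, 2, :]
    return out[:, 1:] if prepend else out
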