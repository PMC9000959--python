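"""The four-strain mutual-repression bistable switch.

Two signaling arms repress each other: alpha-factor lowers auxin (pathway
repression by the alpha-sensing auxin synthesizer plus GH3.3 expression from
an alpha-sensing attenuator strain) and auxin lowers alpha-factor (pathway
repression plus BAR1 expression). At steady state the two medium
concentrations satisfy

    I = f(A) = K1*(c_I + V_I * th1^n1 / (th1^n1 + A^n1))
               / (delta_I + K3*gamma_G * A / (th_G + A))
    A = g(I) = K2*(c_A + V_A * th2^n2 / (th2^n2 + I^n2))
               / (delta_A + K4*gamma_B * I / (th_B + I))

where K1..K4 are the four strains' gains (fold-changes of cell density
relative to the reference concentration). Both maps are strictly decreasing;
their intersections are the equilibria. n1 > 2 is a necessary condition for
three equilibria.

The clearance rates delta absorb the time-averaged effect of the periodic
1:3 medium dilution used experimentally (a 1:3 dilution every 40 min is a
first-order loss of ln(3)/(2/3 h) ~ 1.65/h for continuously produced
signals); exogenous stimulus boluses are tracked as separate pools that decay
through the discrete dilution events, so spikes fall below the sensor's
detection range within a few hours, as in the switch protocol.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .composition import DilutionSchedule, Spike
from .kinetics import Model1Params, TimeCourse, Transfer, hill, rest_state_model1
from .library import StrainSpec
from .species import Signal

__all__ = [
    "Model3Params",
    "EquilibriumSet",
    "BistabilityMap",
    "MetabolicLoadParams",
    "model3_balance",
    "find_equilibria",
    "scan_gains",
    "select_operating_point",
    "simulate_switch",
    "default_switch_params",
]

GAIN_NAMES = ("K1", "K2", "K3", "K4")


@dataclass(frozen=True)
class Model3Params:
    """Steady-state parameters of the mutual-repression switch.

    Strain gains: K1 multiplies the auxin producer (senses alpha-factor,
    represses auxin synthesis), K2 the alpha-factor producer, K3 the GH3.3
    arm (alpha-sensing auxin attenuator), K4 the BAR1 arm (auxin-sensing
    alpha-factor attenuator).
    """

    V_A: float  # max alpha-factor production (nM/h)
    V_I: float  # max auxin production (nM/h)
    c_A: float  # basal alpha-factor production (nM/h)
    c_I: float  # basal auxin production (nM/h)
    th1: float  # alpha-factor threshold repressing auxin production (nM)
    n1: float  # Hill coefficient of that repression
    th2: float  # auxin threshold repressing alpha-factor production (nM)
    n2: float
    delta_A: float  # alpha-factor clearance (1/h, dilution-averaged)
    delta_I: float  # auxin clearance (1/h)
    gamma_B: float  # max extra alpha-factor clearance from BAR1 (1/h)
    th_B: float  # auxin level half-activating the BAR1 arm (nM)
    gamma_G: float  # max extra auxin clearance from GH3.3 (1/h)
    th_G: float  # alpha-factor level half-activating the GH3.3 arm (nM)
    K1: float = 1.0
    K2: float = 1.0
    K3: float = 1.0
    K4: float = 1.0

    def __post_init__(self) -> None:
        for name in ("V_A", "V_I", "th1", "n1", "th2", "n2", "delta_A",
                     "delta_I", "th_B", "th_G", "K1", "K2", "K3", "K4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Model3Params.{name} must be > 0")
        for name in ("c_A", "c_I", "gamma_B", "gamma_G"):
            if getattr(self, name) < 0:
                raise ValueError(f"Model3Params.{name} must be >= 0")

    def with_gains(self, **gains: float) -> "Model3Params":
        unknown = set(gains) - set(GAIN_NAMES)
        if unknown:
            raise ValueError(f"unknown gain(s): {sorted(unknown)}")
        return replace(self, **gains)

    @property
    def gains(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in GAIN_NAMES}


def default_switch_params() -> Model3Params:
    """Shipped switch parameter set (dilution-averaged clearances, n1 = 3)."""
    return Model3Params(
        V_A=250.0, V_I=900.0, c_A=1.0, c_I=5.0,
        th1=25.0, n1=3.0, th2=150.0, n2=1.5,
        delta_A=1.65, delta_I=1.65,
        gamma_B=8.0, th_B=300.0, gamma_G=8.0, th_G=25.0,
    )


def model3_balance(params: Model3Params):
    """Return the two steady-state maps ``f: A -> I`` and ``g: I -> A``.

    Both are vectorized and strictly decreasing in their argument.
    """
    p = params

    def f(A):
        A = np.asarray(A, dtype=float)
        prod = p.K1 * (p.c_I + p.V_I * p.th1 ** p.n1 / (p.th1 ** p.n1 + A ** p.n1))
        clear = p.delta_I + p.K3 * p.gamma_G * A / (p.th_G + A)
        out = prod / clear
        return float(out) if out.ndim == 0 else out

    def g(I):
        I = np.asarray(I, dtype=float)
        prod = p.K2 * (p.c_A + p.V_A * p.th2 ** p.n2 / (p.th2 ** p.n2 + I ** p.n2))
        clear = p.delta_A + p.K4 * p.gamma_B * I / (p.th_B + I)
        out = prod / clear
        return float(out) if out.ndim == 0 else out

    return f, g


@dataclass
class EquilibriumSet:
    """Located equilibria of the switch with stability labels."""

    points: list[tuple[float, float]]  # (A*, I*) in nM
    stability: list[str]  # "stable" | "unstable"

    def __post_init__(self) -> None:
        if len(self.points) != len(self.stability):
            raise ValueError("points/stability length mismatch")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def stable_points(self) -> list[tuple[float, float]]:
        return [p for p, s in zip(self.points, self.stability) if s == "stable"]

    @property
    def bistable(self) -> bool:
        return len(self.stable_points) >= 2


def _numeric_slope(fn, x: float, rel: float = 1e-6) -> float:
    h = max(abs(x), 1e-12) * rel
    return (fn(x + h) - fn(x - h)) / (2 * h)


def find_equilibria(
    params: Model3Params,
    domain: tuple[float, float] | None = None,
    n_grid: int = 400,
    tol: float = 1e-10,
) -> EquilibriumSet:
    """Locate all intersections of the two balance maps.

    Sign-change bracketing of ``h(A) = g(f(A)) - A`` on a log grid over
    ``domain`` (defaults to [1e-6, 1.1 * g(0)], which covers both asymptotes),
    followed by Brent root polishing. Stability comes from the Jacobian of
    the induced relaxation dynamics dA/dt = delta_A*(g(I) - A),
    dI/dt = delta_I*(f(A) - I): an equilibrium is stable iff
    f'(A*) * g'(I*) < 1.
    """
    f, g = model3_balance(params)
    a_max = float(g(0.0))
    if domain is None:
        domain = (min(1e-6, a_max * 1e-6), a_max * 1.1)
    lo, hi = domain
    if lo <= 0 or hi <= lo:
        raise ValueError("domain must be positive with hi > lo")
    grid = np.geomspace(lo, hi, n_grid)
    h = g(f(grid)) - grid
    roots: list[float] = []
    sign = np.sign(h)
    for i in range(len(grid) - 1):
        if sign[i] == 0:
            roots.append(float(grid[i]))
        elif sign[i] * sign[i + 1] < 0:
            try:
                r = brentq(lambda a: float(g(f(a))) - a, grid[i], grid[i + 1],
                           xtol=tol, rtol=8.9e-16)
            except ValueError as e:
                raise RuntimeError(
                    f"bracketing failed on [{grid[i]:g}, {grid[i+1]:g}]; "
                    "try a finer grid"
                ) from e
            roots.append(float(r))
    if sign[-1] == 0:
        roots.append(float(grid[-1]))
    # dedupe near-identical roots
    uniq: list[float] = []
    for r in sorted(roots):
        if not uniq or abs(r - uniq[-1]) > 1e-6 * max(1.0, r):
            uniq.append(r)
    points, stability = [], []
    for a in uniq:
        i = float(f(a))
        fp = _numeric_slope(lambda x: float(f(x)), a)
        gp = _numeric_slope(lambda x: float(g(x)), i)
        stability.append("stable" if fp * gp < 1.0 else "unstable")
        points.append((a, i))
    return EquilibriumSet(points=points, stability=stability)


@dataclass
class BistabilityMap:
    """Equilibrium counts and ON/OFF fold-change over a gain grid."""

    axes: tuple[str, str]
    grid_x: np.ndarray
    grid_y: np.ndarray
    n_equilibria: np.ndarray  # (len(grid_x), len(grid_y)) ints
    fold_change: np.ndarray  # NaN where not bistable
    base: Model3Params

    @property
    def bistable_mask(self) -> np.ndarray:
        return self.n_equilibria >= 3

    def cells(self):
        for i, j in itertools.product(range(self.grid_x.size), range(self.grid_y.size)):
            yield i, j, self.grid_x[i], self.grid_y[j]


def scan_gains(
    params: Model3Params,
    axes: tuple[str, str] = ("K1", "K2"),
    grid_x: Sequence[float] = (),
    grid_y: Sequence[float] = (),
    n_grid: int = 300,
) -> BistabilityMap:
    """Map equilibrium count and predicted ON/OFF fold-change over two gains.

    The fold-change is the ratio of the reporter-relevant signal (auxin)
    between the two stable states, defined only where three equilibria exist.
    """
    gx = np.asarray(grid_x, dtype=float)
    gy = np.asarray(grid_y, dtype=float)
    if gx.size < 2 or gy.size < 2:
        raise ValueError("each gain axis needs >= 2 grid values")
    for ax in axes:
        if ax not in GAIN_NAMES:
            raise ValueError(f"unknown gain axis {ax!r}")
    n_eq = np.zeros((gx.size, gy.size), dtype=int)
    fold = np.full((gx.size, gy.size), np.nan)
    for i, vx in enumerate(gx):
        for j, vy in enumerate(gy):
            p = params.with_gains(**{axes[0]: float(vx), axes[1]: float(vy)})
            eq = find_equilibria(p, n_grid=n_grid)
            n_eq[i, j] = eq.n
            if eq.n >= 3 and eq.bistable:
                iaa = [pt[1] for pt in eq.stable_points]
                fold[i, j] = max(iaa) / max(min(iaa), 1e-12)
    return BistabilityMap(tuple(axes), gx, gy, n_eq, fold, params)


def select_operating_point(bmap: BistabilityMap) -> dict[str, float]:
    """Pick the bistable cell maximizing the separation between stable states.

    Separation is the minimum pairwise distance between stable equilibria in
    log-concentration space; ties break toward the centroid of the bistable
    region. Returns a gain assignment for the scanned axes.
    """
    mask = bmap.bistable_mask
    if not mask.any():
        raise ValueError("no bistable cell in the scanned gain region")
    ii, jj = np.where(mask)
    centroid = (ii.mean(), jj.mean())
    best, best_key = None, None
    for i, j in zip(ii, jj):
        p = bmap.base.with_gains(**{
            bmap.axes[0]: float(bmap.grid_x[i]),
            bmap.axes[1]: float(bmap.grid_y[j]),
        })
        eq = find_equilibria(p)
        pts = eq.stable_points
        if len(pts) < 2:
            continue
        dists = [
            np.hypot(np.log(a1) - np.log(a2), np.log(i1) - np.log(i2))
            for (a1, i1), (a2, i2) in itertools.combinations(pts, 2)
        ]
        sep = min(dists)
        tie = -np.hypot(i - centroid[0], j - centroid[1])
        key = (sep, tie)
        if best_key is None or key > best_key:
            best_key = key
            best = {bmap.axes[0]: float(bmap.grid_x[i]),
                    bmap.axes[1]: float(bmap.grid_y[j])}
    if best is None:
        raise ValueError("no bistable cell with two stable equilibria")
    return best


@dataclass(frozen=True)
class MetabolicLoadParams:
    """Growth-rate penalty proportional to normalized circuit expression."""

    rho: float  # 0 = no impact, 1 = no growth at maximal expression
    mu0: float = 0.4  # baseline growth rate (1/h), log-phase yeast

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [0, 1]")
        if self.mu0 <= 0:
            raise ValueError("mu0 must be > 0")


def simulate_switch(
    params: Model3Params,
    gains: dict[str, float] | None = None,
    stimuli: Sequence[Spike] = (),
    dilution: DilutionSchedule | None = None,
    load: MetabolicLoadParams | None = None,
    sensor: StrainSpec | None = None,
    t_end: float = 30.0,
    n_points: int = 301,
    y0: tuple[float, float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> TimeCourse:
    """Dynamic counterpart of the steady-state switch model.

    States: circuit-internal alpha-factor ``A`` and auxin ``I`` pools,
    exogenous stimulus pools ``A_exo``/``I_exo`` (fed by spikes, decaying
    through dilution events only), the optional auxin sensor readout, and,
    with metabolic load, one population per strain. Strain gains scale with
    relative population size N_i / mean(N), so uniform growth leaves the
    circuit unchanged while load-dependent growth differences drift the
    gains.
    """
    p = params if gains is None else params.with_gains(**gains)
    if sensor is not None:
        sp = sensor.params
        if not isinstance(sp, Model1Params):
            raise ValueError("switch sensor must be a single-input strain")
        s_transfer = sensor.transfer[0]
    with_load = load is not None and load.rho > 0
    n_states = 4 + (3 if sensor is not None else 0) + (4 if with_load else 0)
    labels = ["alpha_factor", "auxin", "alpha_factor_exo", "auxin_exo"]
    if sensor is not None:
        labels += ["sensor.x1", "sensor.x2", "fluorescence"]
    if with_load:
        labels += ["N1", "N2", "N3", "N4"]

    def rhs(t, y):
        A, I = max(y[0], 0.0), max(y[1], 0.0)
        A_tot = A + max(y[2], 0.0)
        I_tot = I + max(y[3], 0.0)
        if with_load:
            N = np.maximum(y[-4:], 1e-12)
            rel = N / N.mean()
        else:
            rel = np.ones(4)
        K1, K2, K3, K4 = p.K1 * rel[0], p.K2 * rel[1], p.K3 * rel[2], p.K4 * rel[3]
        rep1 = p.th1 ** p.n1 / (p.th1 ** p.n1 + A_tot ** p.n1)  # A represses I prod
        rep2 = p.th2 ** p.n2 / (p.th2 ** p.n2 + I_tot ** p.n2)  # I represses A prod
        act_G = A_tot / (p.th_G + A_tot)  # GH3 arm activity
        act_B = I_tot / (p.th_B + I_tot)  # BAR1 arm activity
        dy = np.zeros(n_states)
        dy[0] = K2 * (p.c_A + p.V_A * rep2) - (p.delta_A + K4 * p.gamma_B * act_B) * y[0]
        dy[1] = K1 * (p.c_I + p.V_I * rep1) - (p.delta_I + K3 * p.gamma_G * act_G) * y[1]
        # exogenous pools: no production; extra enzymatic clearance still applies
        dy[2] = -(K4 * p.gamma_B * act_B) * y[2]
        dy[3] = -(K3 * p.gamma_G * act_G) * y[3]
        if sensor is not None:
            x1, x2, x3 = y[4], y[5], y[6]
            h = hill(max(x1, 0.0), sp.K, sp.n, s_transfer)
            dy[4] = I_tot - sp.d1 * x1
            dy[5] = sp.V * h - sp.d2 * x2
            dy[6] = sp.k3 * x2 + sp.c0 - sp.d3 * x3
        if with_load:
            e = np.array([rep1, rep2, act_G, act_B])
            dy[-4:] = load.mu0 * (1.0 - load.rho * e) * np.maximum(y[-4:], 0.0)
        return dy

    y_init = np.zeros(n_states)
    if y0 is not None:
        y_init[0], y_init[1] = y0
    else:
        eq = find_equilibria(p)
        a0, i0 = max(eq.points, key=lambda pt: pt[0])  # start on the high-A branch
        y_init[0], y_init[1] = a0, i0
    if sensor is not None:
        # pre-equilibrate the sensor to the ambient auxin level
        y_init[4] = y_init[1] / sp.d1
        h0 = hill(y_init[4], sp.K, sp.n, s_transfer)
        y_init[5] = sp.V * h0 / sp.d2
        y_init[6] = (sp.k3 * y_init[5] + sp.c0) / sp.d3
    if with_load:
        y_init[-4:] = 1.0

    t_grid = np.linspace(0.0, t_end, n_points)
    events: list[tuple[float, str, object]] = []
    if dilution is not None:
        for te in dilution.events(0.0, t_end):
            events.append((float(te), "dilute", dilution.retention))
    for spk in stimuli:
        if spk.amount < 0:
            raise ValueError("spike amount must be >= 0")
        if 0.0 < spk.time <= t_end:
            events.append((spk.time, "spike", spk))
    events.sort(key=lambda e: e[0])

    ts = [np.array([0.0])]
    ys = [y_init.reshape(-1, 1).copy()]
    y = y_init.copy()
    seg = 0.0

    def run(a, b, yy):
        inner = t_grid[(t_grid > a + 1e-12) & (t_grid < b - 1e-12)]
        t_eval = np.unique(np.concatenate([inner, [b]]))
        sol = solve_ivp(rhs, (a, b), yy, t_eval=t_eval, method="LSODA",
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"switch integration failed: {sol.message}")
        keep = np.isin(sol.t, inner)
        if keep.any():
            ts.append(sol.t[keep])
            ys.append(sol.y[:, keep])
        return sol.y[:, -1]

    for te, kind, payload in events:
        if te > seg + 1e-12:
            y = run(seg, te, y)
            seg = te
        y = y.copy()
        if kind == "dilute":
            y[2] *= payload
            y[3] *= payload
        else:
            idx = 2 if payload.species is Signal.ALPHA_FACTOR else 3
            y[idx] += payload.amount
        if np.isclose(t_grid, seg).any():
            ts.append(np.array([seg]))
            ys.append(y.reshape(-1, 1).copy())
    if t_end > seg + 1e-12:
        y = run(seg, t_end, y)
        ts.append(np.array([t_end]))
        ys.append(y.reshape(-1, 1).copy())

    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)
    order = np.argsort(t_all, kind="stable")
    t_all, y_all = t_all[order], y_all[:, order]
    out = np.empty((n_states, t_grid.size))
    for j, tq in enumerate(t_grid):
        hits = np.where(np.isclose(t_all, tq, rtol=0, atol=1e-9))[0]
        out[:, j] = y_all[:, hits[-1]]
    return TimeCourse(t_grid, np.maximum(out, 0.0), labels)
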