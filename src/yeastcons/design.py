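"""Automated enumerate-score-optimize search for consortium behaviors.

The search space is every unordered combination of 2, 3 or 4 strains from the
16-strain enumeration pool, each paired with one sensor strain. Each candidate
circuit is simulated over 12 hours against a grid of input concentrations,
its sensor endpoint is normalized to the sensor's own steady-state dynamic
range, and the normalized responses are scored against the target behavior:

* **logic gates** (AND / OR / NAND / NOR): score = min(ON) / max(OFF) over
  the four truth-table corners (no input vs highest grid concentration).
  A score above 1 means every expected-ON output exceeds every expected-OFF
  output; the higher, the better the separation.
* **time pulses**: the non-monotonicity of the output time series — the
  distance between an interior extremum and the more extreme of the first
  and last values; 0 for monotone responses.
* **band-pass / band-stop filters**: the same metric across the dose axis at
  the 12-hour endpoint.

Top candidates are refined by simplex optimization of the strain gains
(fold-changes of cell concentration, bounded in [0.1, 10] by default).
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import minimize

from .composition import compose, consortium_endpoint
from .kinetics import Model1Params, steady_state_model1
from .library import StrainLibrary, StrainSpec
from .species import Signal

__all__ = [
    "Topology",
    "InputGrid",
    "TruthTable",
    "DesignCandidate",
    "ScreenResult",
    "enumerate_topologies",
    "default_input_grids",
    "sensed_species",
    "simulate_response_tensor",
    "sensor_dynamic_range",
    "normalize_outputs",
    "gate_score",
    "nonmonotonicity_score",
    "screen",
    "optimize_gains",
]

GATE_NAMES = ("AND", "OR", "NAND", "NOR")
EPS = 1e-6


@dataclass(frozen=True)
class Topology:
    """An unordered set of pool strains plus one sensor."""

    members: tuple[str, ...]
    sensor: str

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError("topology members must be distinct")
        object.__setattr__(self, "members", tuple(sorted(self.members)))

    @property
    def size(self) -> int:
        return len(self.members)

    def signal_graph(self, library: StrainLibrary) -> nx.DiGraph:
        """Directed graph of species -> strain -> species/output edges."""
        g = nx.DiGraph()
        for sid in (*self.members, self.sensor):
            s = library[sid]
            for sp, tr in zip(s.inputs, s.transfer):
                g.add_edge(sp.value, sid, sign=tr.value)
            out = s.output
            target = out.signal.value if out.signal else out.value
            g.add_edge(sid, target, kind=out.output_class)
        return g


def enumerate_topologies(
    pool: Sequence[StrainSpec],
    k: int,
    sensors: Sequence[StrainSpec],
) -> list[Topology]:
    """All unordered k-subsets of the pool, crossed with each sensor.

    Deterministic: pool and sensors are iterated in id-sorted order.
    """
    if k not in (2, 3, 4):
        raise ValueError(f"network size k must be 2, 3 or 4 (got {k})")
    pool_ids = sorted(s.id for s in pool)
    sensor_ids = sorted(s.id for s in sensors)
    if not sensor_ids:
        raise ValueError("at least one sensor strain is required")
    return [
        Topology(members=combo, sensor=sid)
        for combo in itertools.combinations(pool_ids, k)
        for sid in sensor_ids
    ]


@dataclass(frozen=True)
class InputGrid:
    """Ordered per-species input concentration lists (nM), each starting at 0."""

    levels: dict[Signal, tuple[float, ...]]

    def __post_init__(self) -> None:
        for sp, lv in self.levels.items():
            if not lv or lv[0] != 0.0:
                raise ValueError(f"grid for {sp} must start at 0")
            if any(b <= a for a, b in zip(lv, lv[1:])):
                raise ValueError(f"grid for {sp} must be strictly increasing")

    def __getitem__(self, sp: Signal) -> tuple[float, ...]:
        return self.levels[Signal(sp)]

    def max_level(self, sp: Signal) -> float:
        return self.levels[Signal(sp)][-1]


def default_input_grids() -> InputGrid:
    """The screening grids: alpha-factor 0-1000 nM, auxin 0-5000 nM,
    beta-estradiol 0-100 nM."""
    return InputGrid({
        Signal.ALPHA_FACTOR: (0.0, 1.0, 5.0, 10.0, 50.0, 200.0, 1000.0),
        Signal.AUXIN: (0.0, 100.0, 500.0, 1000.0, 5000.0),
        Signal.BETA_ESTRADIOL: (0.0, 1.0, 5.0, 10.0, 100.0),
    })


def sensed_species(topology: Topology, library: StrainLibrary) -> list[Signal]:
    """Species sensed by any strain in the circuit (sorted by name)."""
    seen: set[Signal] = set()
    for sid in (*topology.members, topology.sensor):
        seen.update(library[sid].inputs)
    return sorted(seen, key=lambda s: s.value)


@dataclass
class ResponseTensor:
    """Sensor-output time series per input combination."""

    species: list[Signal]  # input axes, in order
    combos: list[tuple[float, ...]]  # one level per species
    t: np.ndarray
    series: dict[tuple[float, ...], np.ndarray]  # combo -> fluorescence(t)
    failures: list[tuple[tuple[float, ...], str]] = field(default_factory=list)

    def endpoint(self, combo: tuple[float, ...]) -> float:
        return float(self.series[combo][-1])


def simulate_response_tensor(
    topology: Topology,
    library: StrainLibrary,
    grids: InputGrid | None = None,
    gains: dict[str, float] | None = None,
    horizon: float = 12.0,
    n_times: int = 49,
    rtol: float = 1e-6,
    _cache: dict | None = None,
) -> ResponseTensor:
    """Simulate the circuit against every input combination it can sense.

    The input axes are restricted to the species the topology actually
    senses (a circuit sensing only alpha-factor is simulated against the
    7 alpha-factor levels, not the full 7x5x5 product). Per-combination
    integration failures are recorded, not fatal.
    """
    from scipy.integrate import solve_ivp

    grids = grids or default_input_grids()
    gains = gains or {}
    species = sensed_species(topology, library)
    members = [(library[m], float(gains.get(m, 1.0))) for m in topology.members]
    sensor = library[topology.sensor]
    model = compose(members, sensor, exogenous={sp: 0.0 for sp in species})
    t = np.linspace(0.0, horizon, n_times)
    combos = list(itertools.product(*[grids[sp] for sp in species]))
    key = None
    if _cache is not None:
        key = (topology.members, topology.sensor,
               tuple(sorted(gains.items())), tuple(species), horizon)
        if key in _cache:
            series, failures = _cache[key]
            return ResponseTensor(species=species, combos=combos, t=t,
                                  series=series, failures=failures)
    # all combinations are decoupled copies of the same (non-stiff) system,
    # so they integrate as one stacked batch
    B = len(combos)
    exo = {
        sp: np.array([c[i] for c in combos])
        for i, sp in enumerate(species)
    }
    y0 = np.tile(model.initial_state()[:, None], (1, B))
    n_states = model.n_states

    def rhs(tt, yy):
        return model.rhs_batch(tt, yy.reshape(n_states, B), exo).ravel()

    series: dict[tuple[float, ...], np.ndarray] = {}
    failures: list[tuple[tuple[float, ...], str]] = []
    sol = solve_ivp(rhs, (0.0, horizon), y0.ravel(), t_eval=t, method="RK45",
                    rtol=rtol, atol=1e-9)
    if not sol.success:  # pragma: no cover - solver failure path
        failures = [(c, sol.message) for c in combos]
    else:
        out = sol.y.reshape(n_states, B, t.size)
        fl = out[model.labels.index(model.sensor_label)]
        for j, combo in enumerate(combos):
            if np.all(np.isfinite(fl[j])):
                series[combo] = np.maximum(fl[j], 0.0)
            else:
                failures.append((combo, "non-finite trajectory"))
    if _cache is not None:
        _cache[key] = (series, failures)
    return ResponseTensor(species=species, combos=combos, t=t,
                          series=series, failures=failures)


def sensor_dynamic_range(sensor: StrainSpec) -> tuple[float, float]:
    """(min, max) steady-state output of a sensor over its full input range."""
    p = sensor.params
    if not isinstance(p, Model1Params):
        raise ValueError("dynamic range is defined for single-input sensors")
    lo = steady_state_model1(p, sensor.transfer[0], 0.0)
    hi = steady_state_model1(p, sensor.transfer[0], 1e12)
    return (min(lo, hi), max(lo, hi))


def normalize_outputs(values, sensor: StrainSpec):
    """Affine map of raw sensor outputs onto [0, 1] by the sensor's own
    steady-state dynamic range, clipped. Repressing sensors are not
    sign-flipped: ON/OFF is defined on fluorescence."""
    lo, hi = sensor_dynamic_range(sensor)
    if hi - lo <= 0:
        raise ValueError(f"sensor {sensor.id} has zero dynamic range")
    v = np.asarray(values, dtype=float)
    out = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TruthTable:
    """Boolean target over two inputs at levels {0, max}."""

    gate: str
    inputs: tuple[Signal, Signal]

    def __post_init__(self) -> None:
        if self.gate not in GATE_NAMES:
            raise ValueError(f"gate must be one of {GATE_NAMES}")

    def expected(self, hi_a: bool, hi_b: bool) -> bool:
        if self.gate == "AND":
            return hi_a and hi_b
        if self.gate == "OR":
            return hi_a or hi_b
        if self.gate == "NAND":
            return not (hi_a and hi_b)
        return not (hi_a or hi_b)  # NOR

    @property
    def rows(self) -> list[tuple[bool, bool, bool]]:
        return [(a, b, self.expected(a, b))
                for a, b in itertools.product((False, True), repeat=2)]


def gate_score(corner_outputs: dict[tuple[bool, bool], float],
               table: TruthTable) -> float:
    """Separation score min(ON) / max(OFF) on normalized corner outputs.

    Returns < 1 whenever any expected-OFF output reaches an expected-ON
    output; scale-invariant (ratio of outputs).
    """
    missing = [c for c in itertools.product((False, True), repeat=2)
               if c not in corner_outputs]
    if missing:
        raise ValueError(f"missing truth-table corner(s): {missing}")
    on = [corner_outputs[(a, b)] for a, b in itertools.product((False, True), repeat=2)
          if table.expected(a, b)]
    off = [corner_outputs[(a, b)] for a, b in itertools.product((False, True), repeat=2)
           if not table.expected(a, b)]
    return min(on) / max(max(off), EPS)


def nonmonotonicity_score(series) -> float:
    """Distance of an interior extremum beyond the first/last values.

    peak = max interior value minus the larger endpoint; dip = the smaller
    endpoint minus the min interior value; the score is the larger of the
    two, floored at 0. Monotone (and constant) series score exactly 0.
    """
    s = np.asarray(series, dtype=float)
    if s.ndim != 1 or s.size < 3:
        raise ValueError("series must be 1-D with length >= 3")
    interior = s[1:-1]
    peak = float(interior.max() - max(s[0], s[-1]))
    dip = float(min(s[0], s[-1]) - interior.min())
    return max(peak, dip, 0.0)


@dataclass
class DesignCandidate:
    """A scored circuit: topology + gains + behavior metric."""

    topology: Topology
    gains: dict[str, float]
    metric: str
    score: float
    optimized: bool = False
    improved: bool = False
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be >= 0")


def _score_gate(tensor: ResponseTensor, sensor: StrainSpec, gate: str,
                grids: InputGrid) -> tuple[float, dict]:
    """Best gate score over every pair of sensed species; NaN detail if < 2."""
    species = tensor.species
    if len(species) < 2:
        return 0.0, {"skipped": "single-input circuit cannot host a 2-input gate"}
    best, best_detail = 0.0, {}
    for ia, ib in itertools.combinations(range(len(species)), 2):
        corners = {}
        ok = True
        for hi_a, hi_b in itertools.product((False, True), repeat=2):
            combo = [0.0] * len(species)
            combo[ia] = grids.max_level(species[ia]) if hi_a else 0.0
            combo[ib] = grids.max_level(species[ib]) if hi_b else 0.0
            key = tuple(combo)
            if key not in tensor.series:
                ok = False
                break
            corners[(hi_a, hi_b)] = float(
                normalize_outputs(tensor.endpoint(key), sensor))
        if not ok:
            continue
        table = TruthTable(gate, (species[ia], species[ib]))
        sc = gate_score(corners, table)
        if sc > best:
            best = sc
            best_detail = {"inputs": (species[ia].value, species[ib].value),
                           "corners": {f"{int(a)}{int(b)}": v
                                       for (a, b), v in corners.items()}}
    return best, best_detail


def _score_pulse(tensor: ResponseTensor, sensor: StrainSpec) -> tuple[float, dict]:
    """Max time-axis non-monotonicity over input combinations."""
    best, arg = 0.0, None
    for combo, ts in tensor.series.items():
        sc = nonmonotonicity_score(normalize_outputs(ts, sensor))
        if sc > best:
            best, arg = sc, combo
    return best, {"at_inputs": arg}


def _score_bandpass(tensor: ResponseTensor, sensor: StrainSpec,
                    grids: InputGrid) -> tuple[float, dict]:
    """Max dose-axis non-monotonicity of normalized endpoints."""
    species = tensor.species
    best, arg = 0.0, None
    for ax, sp in enumerate(species):
        others = [0.0] * len(species)
        doses = grids[sp]
        if len(doses) < 3:
            continue
        vals = []
        ok = True
        for d in doses:
            combo = list(others)
            combo[ax] = d
            key = tuple(combo)
            if key not in tensor.series:
                ok = False
                break
            vals.append(tensor.endpoint(key))
        if not ok:
            continue
        sc = nonmonotonicity_score(normalize_outputs(np.array(vals), sensor))
        if sc > best:
            best, arg = sc, sp.value
    return best, {"dose_axis": arg}


def _score_candidate(
    topology: Topology,
    library: StrainLibrary,
    behavior: str,
    grids: InputGrid,
    gains: dict[str, float],
    horizon: float,
    cache: dict | None,
) -> DesignCandidate:
    sensor = library[topology.sensor]
    tensor = simulate_response_tensor(
        topology, library, grids, gains, horizon=horizon, _cache=cache)
    if behavior in GATE_NAMES:
        score, detail = _score_gate(tensor, sensor, behavior, grids)
    elif behavior == "time_pulse":
        score, detail = _score_pulse(tensor, sensor)
    elif behavior == "band_pass":
        score, detail = _score_bandpass(tensor, sensor, grids)
    else:
        raise ValueError(f"unknown behavior {behavior!r}")
    if tensor.failures:
        score, detail = 0.0, {"failed": len(tensor.failures)}
    return DesignCandidate(
        topology=topology, gains=dict(gains), metric=behavior,
        score=score, detail=detail,
    )


@dataclass
class ScreenResult:
    """Ranked screen output plus summary statistics."""

    behavior: str
    candidates: list[DesignCandidate]  # ranked, best first
    n_topologies: int
    fraction_nonzero: float

    def top(self, n: int = 10) -> list[DesignCandidate]:
        return self.candidates[:n]

    def selected(self) -> list[DesignCandidate]:
        """Candidates forwarded to optimization: gates with score > 1, or the
        best pulse/band-pass candidate per non-beta-estradiol sensor type."""
        if self.behavior in GATE_NAMES:
            return [c for c in self.candidates if c.score > 1.0]
        best: dict[str, DesignCandidate] = {}
        for c in self.candidates:
            sid = c.topology.sensor
            if sid.startswith("bE_"):
                continue
            if c.score > 0 and (sid not in best or c.score > best[sid].score):
                best[sid] = c
        return sorted(best.values(), key=lambda c: -c.score)


def screen(
    library: StrainLibrary,
    behavior: str,
    sizes: Iterable[int] = (2, 3, 4),
    grids: InputGrid | None = None,
    sensors: Sequence[StrainSpec] | None = None,
    pool: Sequence[StrainSpec] | None = None,
    gains: float | dict[str, float] = 1.0,
    horizon: float = 12.0,
) -> ScreenResult:
    """Score every topology of the requested sizes at unit (or given) gains.

    Deterministic: identical configurations produce identical rankings
    (ties break by topology member ids, then sensor id).
    """
    grids = grids or default_input_grids()
    pool = list(pool) if pool is not None else library.pool_strains()
    sensors = list(sensors) if sensors is not None else library.sensors
    cache: dict = {}
    candidates: list[DesignCandidate] = []
    for k in sizes:
        for topo in enumerate_topologies(pool, k, sensors):
            g = dict(gains) if isinstance(gains, dict) else {
                m: float(gains) for m in topo.members}
            candidates.append(
                _score_candidate(topo, library, behavior, grids, g, horizon, cache))
    candidates.sort(key=lambda c: (-c.score, c.topology.members, c.topology.sensor))
    nonzero = sum(1 for c in candidates if c.score > 0)
    return ScreenResult(
        behavior=behavior, candidates=candidates,
        n_topologies=len(candidates),
        fraction_nonzero=nonzero / max(len(candidates), 1),
    )


def optimize_gains(
    candidate: DesignCandidate,
    library: StrainLibrary,
    grids: InputGrid | None = None,
    bounds: tuple[float, float] = (0.1, 10.0),
    seed: int = 0,
    n_restarts: int = 3,
    max_evals: int = 200,
    horizon: float = 12.0,
) -> DesignCandidate:
    """Maximize a candidate's metric over its strain gains (log-scale simplex).

    Proposals outside ``bounds`` are clipped, so final gains always lie
    within bounds. Deterministic per seed. The returned candidate's score is
    never below the input's; if no restart improves it, the input gains are
    kept and the candidate is flagged ``improved=False``.
    """
    if bounds[0] <= 0 or bounds[1] <= bounds[0]:
        raise ValueError("bounds must be positive with upper > lower")
    grids = grids or default_input_grids()
    members = candidate.topology.members
    lo, hi = math.log(bounds[0]), math.log(bounds[1])
    x0 = np.array([
        math.log(np.clip(candidate.gains.get(m, 1.0), *bounds)) for m in members
    ])

    def objective(x):
        g = dict(zip(members, np.exp(np.clip(x, lo, hi))))
        cand = _score_candidate(candidate.topology, library, candidate.metric,
                                grids, g, horizon, None)
        return -cand.score

    rng = np.random.default_rng(seed)
    best_x, best_neg = x0, objective(x0)
    starts = [x0] + [
        np.clip(x0 + rng.uniform(-1.0, 1.0, x0.size), lo, hi)
        for _ in range(max(0, n_restarts - 1))
    ]
    for s in starts:
        res = minimize(objective, s, method="Nelder-Mead",
                       options={"maxfev": max_evals, "xatol": 1e-3,
                                "fatol": 1e-4, "adaptive": True})
        if res.fun < best_neg:
            best_neg, best_x = float(res.fun), res.x
    new_gains = dict(zip(members, np.exp(np.clip(best_x, lo, hi))))
    new_score = -best_neg
    if new_score > candidate.score:
        return replace(candidate, gains=new_gains, score=new_score,
                       optimized=True, improved=True)
    return replace(candidate, optimized=True, improved=False)
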