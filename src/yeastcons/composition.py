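"""Compose single-strain models into consortium ODE systems.

Strains communicate only through shared extracellular signal pools: each
member keeps its sensing and processing states, but its output stage is
replaced by a flux ``K * (k3*x2 + c0)`` into the medium pool of its output
species (or into an enzyme pool for attenuator strains), where ``K`` is the
strain's gain — its fold-change in initial cell concentration relative to the
reference density (30 events/uL). The sensor strain keeps its fluorescence
output stage and is the circuit readout.

Medium pools have first-order clearance; attenuator enzymes act
multiplicatively on the sensed input of downstream strains through
``attenuation_factor``. Exogenous inputs come in two flavors: *held* levels
(clamped piecewise-constant schedules, the default for dose-response and
screening experiments) and *spikes* (instantaneous additions to the medium
pool, which then decay through clearance and dilution — the bistable-switch
stimulus protocol).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .kinetics import (
    Model1Params,
    Model2Params,
    TimeCourse,
    Transfer,
    hill,
    rest_state_model1,
    rest_state_model2,
)
from .library import StrainLibrary, StrainSpec
from .species import SECRETABLE, OutputKind, Signal

__all__ = [
    "GainAssignment",
    "DilutionSchedule",
    "Spike",
    "ConsortiumModel",
    "CompositionError",
    "attenuation_factor",
    "compose",
    "simulate_consortium",
    "consortium_endpoint",
    "compare_cascade_modularity",
]

log = logging.getLogger(__name__)

#: Default first-order clearance of medium signal pools (1/h).
DEFAULT_CLEARANCE = 0.05
#: Default enzyme level at which attenuation halves the sensed signal (a.u.).
DEFAULT_K_E = 100.0

GainAssignment = dict[str, float]


class CompositionError(ValueError):
    """Raised when a consortium cannot be assembled."""


def attenuation_factor(E, K_E: float = DEFAULT_K_E):
    """Fraction of a signal still visible downstream given enzyme pool ``E``.

    First-order (n=1) repressing Hill stage: K_E / (K_E + E), in (0, 1].
    """
    if K_E <= 0:
        raise ValueError("K_E must be positive")
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("enzyme pool must be >= 0")
    out = K_E / (K_E + E)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DilutionSchedule:
    """Periodic partial medium replacement.

    ``retention`` is the fraction of each medium concentration kept per event
    (a 1:3 dilution keeps 1/3).
    """

    period: float  # hours between events
    retention: float
    start: float = 0.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("dilution period must be positive")
        if not (0.0 < self.retention < 1.0):
            raise ValueError("retention must be in (0, 1)")

    def events(self, t0: float, t1: float) -> np.ndarray:
        """Event times strictly inside (t0, t1]."""
        if t1 <= self.start:
            return np.array([])
        k0 = int(np.ceil((t0 - self.start) / self.period + 1e-12))
        k0 = max(k0, 0)
        if self.start + k0 * self.period <= t0:
            k0 += 1
        times = []
        k = k0
        while (t := self.start + k * self.period) <= t1 + 1e-12:
            if t > t0:
                times.append(min(t, t1))
            k += 1
        return np.array(times)


@dataclass(frozen=True)
class Spike:
    """An instantaneous addition of ``amount`` nM of ``species`` at ``time`` h."""

    time: float
    species: Signal
    amount: float

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("spike amount must be >= 0")


def _held_level(schedule, t: float) -> float:
    """Evaluate a held exogenous schedule: constant or [(time, level), ...]."""
    if isinstance(schedule, (int, float)):
        return float(schedule)
    level = 0.0
    for tt, lv in schedule:
        if t >= tt - 1e-12:
            level = lv
    return level


def _schedule_breaks(schedule) -> list[float]:
    if isinstance(schedule, (int, float)):
        return []
    return [tt for tt, _ in schedule]


@dataclass
class _MemberBlock:
    strain: StrainSpec
    gain: float
    offset: int  # index of first state
    n_states: int
    is_sensor: bool


@dataclass
class ConsortiumModel:
    """A composed multi-strain ODE system coupled through medium pools."""

    members: list[tuple[StrainSpec, float]]
    sensor: StrainSpec
    exogenous: dict[Signal, object] = field(default_factory=dict)
    spikes: list[Spike] = field(default_factory=list)
    clearance: float | dict[Signal, float] = DEFAULT_CLEARANCE
    K_E: float = DEFAULT_K_E

    # derived layout, filled in __post_init__
    blocks: list[_MemberBlock] = field(init=False)
    pool_species: list[Signal] = field(init=False)
    enzyme_species: list[Signal] = field(init=False)
    labels: list[str] = field(init=False)
    n_states: int = field(init=False)

    def __post_init__(self) -> None:
        if self.sensor.output is not OutputKind.GFP:
            raise CompositionError(
                f"sensor strain {self.sensor.id!r} must have GFP output"
            )
        produced = {
            s.output.signal for s, _ in self.members if s.output.signal is not None
        }
        spiked = {sp.species for sp in self.spikes}
        for sp in self.spikes:
            if sp.species not in SECRETABLE and sp.species is not Signal.BETA_ESTRADIOL:
                raise CompositionError(f"cannot spike species {sp.species}")
        self.pool_species = sorted(produced | spiked, key=lambda s: s.value)
        self.enzyme_species = sorted(
            {
                s.output.attenuates
                for s, _ in self.members
                if s.output.attenuates is not None
            },
            key=lambda s: s.value,
        )
        # warn (not fail) when a strain senses a species that can never be
        # nonzero; only meaningful once exogenous inputs have been declared
        if self.exogenous:
            reachable = set(self.pool_species) | {
                sp for sp, sched in self.exogenous.items() if sched is not None
            }
            for strain, _ in list(self.members) + [(self.sensor, 1.0)]:
                for sp in strain.inputs:
                    if sp not in reachable:
                        log.warning(
                            "strain %s senses %s which is neither produced nor exogenous",
                            strain.id, sp.value,
                        )
        # state layout: member blocks, sensor block, pools, enzymes
        self.blocks = []
        off = 0
        for i, (strain, gain) in enumerate(self.members):
            if gain <= 0:
                raise CompositionError(f"gain for {strain.id!r} must be > 0")
            ns = 2 if isinstance(strain.params, Model1Params) else 4
            self.blocks.append(_MemberBlock(strain, gain, off, ns, False))
            off += ns
        ns = 3 if isinstance(self.sensor.params, Model1Params) else 5
        self.blocks.append(_MemberBlock(self.sensor, 1.0, off, ns, True))
        off += ns
        self._pool_offset = off
        off += len(self.pool_species)
        self._enzyme_offset = off
        off += len(self.enzyme_species)
        self.n_states = off
        self.labels = []
        for i, b in enumerate(self.blocks):
            tag = f"{b.strain.id}" if b.is_sensor else f"{b.strain.id}[{i}]"
            if b.n_states == 2:
                self.labels += [f"{tag}.x1", f"{tag}.x2"]
            elif b.n_states == 4:
                self.labels += [f"{tag}.x1a", f"{tag}.x1b", f"{tag}.x2a", f"{tag}.x2b"]
            elif b.n_states == 3:
                self.labels += [f"{tag}.x1", f"{tag}.x2", f"{tag}.fluorescence"]
            else:
                self.labels += [
                    f"{tag}.x1a", f"{tag}.x1b", f"{tag}.x2a", f"{tag}.x2b",
                    f"{tag}.fluorescence",
                ]
        self.labels += [f"medium.{sp.value}" for sp in self.pool_species]
        self.labels += [f"enzyme.{sp.value}" for sp in self.enzyme_species]

    # -- helpers -----------------------------------------------------------

    def clearance_of(self, sp: Signal) -> float:
        """First-order clearance rate of the pool for species ``sp`` (1/h)."""
        if isinstance(self.clearance, dict):
            return float(self.clearance.get(sp, DEFAULT_CLEARANCE))
        return float(self.clearance)

    def pool_index(self, sp: Signal) -> int | None:
        if sp in self.pool_species:
            return self._pool_offset + self.pool_species.index(sp)
        return None

    def enzyme_index(self, sp: Signal) -> int | None:
        if sp in self.enzyme_species:
            return self._enzyme_offset + self.enzyme_species.index(sp)
        return None

    @property
    def sensor_label(self) -> str:
        return f"{self.sensor.id}.fluorescence"

    def sensed_level(self, sp: Signal, y: np.ndarray, t: float) -> float:
        """Effective input concentration of species ``sp`` seen by a strain."""
        level = 0.0
        pi = self.pool_index(sp)
        if pi is not None:
            level += max(y[pi], 0.0)
        if sp in self.exogenous:
            level += _held_level(self.exogenous[sp], t)
        ei = self.enzyme_index(sp)
        if ei is not None:
            level *= attenuation_factor(max(y[ei], 0.0), self.K_E)
        return level

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(self.n_states)
        for b in self.blocks:
            p = b.strain.params
            if isinstance(p, Model1Params):
                rest = rest_state_model1(p, b.strain.transfer[0])
                y0[b.offset : b.offset + b.n_states] = rest[: b.n_states]
            else:
                rest = rest_state_model2(p, b.strain.transfer)
                idx = [0, 1, 2, 3, 4][: b.n_states]
                y0[b.offset : b.offset + b.n_states] = rest[idx]
        return y0

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        pool_flux = {sp: 0.0 for sp in self.pool_species}
        enz_flux = {sp: 0.0 for sp in self.enzyme_species}
        for b in self.blocks:
            p = b.strain.params
            o = b.offset
            if isinstance(p, Model1Params):
                u = self.sensed_level(b.strain.inputs[0], y, t)
                x1, x2 = y[o], y[o + 1]
                h = hill(max(x1, 0.0), p.K, p.n, b.strain.transfer[0])
                dy[o] = u - p.d1 * x1
                dy[o + 1] = p.V * h - p.d2 * x2
                out_flux = b.gain * (p.k3 * max(x2, 0.0) + p.c0)
                if b.is_sensor:
                    x3 = y[o + 2]
                    dy[o + 2] = p.k3 * x2 + p.c0 - p.d3 * x3
                    continue
            else:
                uA = self.sensed_level(b.strain.inputs[0], y, t)
                uB = self.sensed_level(b.strain.inputs[1], y, t)
                x1a, x1b, x2a, x2b = y[o : o + 4]
                ha = hill(max(x1a, 0.0), p.Ka, p.na, b.strain.transfer[0])
                hb = hill(max(x1b, 0.0), p.Kb, p.nb, b.strain.transfer[1])
                dy[o] = uA - p.d1a * x1a
                dy[o + 1] = uB - p.d1b * x1b
                dy[o + 2] = p.Va * ha - p.d2a * x2a
                dy[o + 3] = p.Vb * hb - p.d2b * x2b
                za = max(x2a, 0.0) / (p.Va / p.d2a)
                zb = max(x2b, 0.0) / (p.Vb / p.d2b)
                out_flux = b.gain * (p.k5 * za * zb + p.c0)
                if b.is_sensor:
                    x5 = y[o + 4]
                    dy[o + 4] = p.k5 * za * zb + p.c0 - p.d5 * x5
                    continue
            out = b.strain.output
            if out.signal is not None:
                pool_flux[out.signal] += out_flux
            elif out.attenuates is not None:
                enz_flux[out.attenuates] += out_flux
        for j, sp in enumerate(self.pool_species):
            i = self._pool_offset + j
            dy[i] = pool_flux[sp] - self.clearance_of(sp) * y[i]
        for j, sp in enumerate(self.enzyme_species):
            i = self._enzyme_offset + j
            dy[i] = enz_flux[sp] - self.clearance_of(sp) * y[i]
        return dy

    def rhs_batch(self, t: float, Y: np.ndarray, exo: dict) -> np.ndarray:
        """Vectorized right-hand side over a batch of held input conditions.

        ``Y`` has shape (n_states, B); ``exo`` maps species to a length-B
        array of held exogenous levels (overriding the model's schedules).
        Used by the design screen, where every input combination shares the
        same structure and only the clamped inputs differ.
        """
        B = Y.shape[1]
        dY = np.zeros_like(Y)
        pool_flux = {sp: np.zeros(B) for sp in self.pool_species}
        enz_flux = {sp: np.zeros(B) for sp in self.enzyme_species}

        def sensed(sp):
            level = np.zeros(B)
            pi = self.pool_index(sp)
            if pi is not None:
                level += np.maximum(Y[pi], 0.0)
            if sp in exo:
                level = level + exo[sp]
            ei = self.enzyme_index(sp)
            if ei is not None:
                level = level * (self.K_E / (self.K_E + np.maximum(Y[ei], 0.0)))
            return level

        def hill_arr(x, K, n, transfer):
            with np.errstate(over="ignore"):
                r = (np.maximum(x, 0.0) / K) ** n
            a = np.where(np.isinf(r), 1.0, r / (1.0 + r))
            return a if Transfer(transfer) is Transfer.ACTIVATING else 1.0 - a

        for b in self.blocks:
            p = b.strain.params
            o = b.offset
            if isinstance(p, Model1Params):
                u = sensed(b.strain.inputs[0])
                x1, x2 = Y[o], Y[o + 1]
                h = hill_arr(x1, p.K, p.n, b.strain.transfer[0])
                dY[o] = u - p.d1 * x1
                dY[o + 1] = p.V * h - p.d2 * x2
                out_flux = b.gain * (p.k3 * np.maximum(x2, 0.0) + p.c0)
                if b.is_sensor:
                    dY[o + 2] = p.k3 * x2 + p.c0 - p.d3 * Y[o + 2]
                    continue
            else:
                uA = sensed(b.strain.inputs[0])
                uB = sensed(b.strain.inputs[1])
                x1a, x1b, x2a, x2b = Y[o], Y[o + 1], Y[o + 2], Y[o + 3]
                ha = hill_arr(x1a, p.Ka, p.na, b.strain.transfer[0])
                hb = hill_arr(x1b, p.Kb, p.nb, b.strain.transfer[1])
                dY[o] = uA - p.d1a * x1a
                dY[o + 1] = uB - p.d1b * x1b
                dY[o + 2] = p.Va * ha - p.d2a * x2a
                dY[o + 3] = p.Vb * hb - p.d2b * x2b
                za = np.maximum(x2a, 0.0) / (p.Va / p.d2a)
                zb = np.maximum(x2b, 0.0) / (p.Vb / p.d2b)
                out_flux = b.gain * (p.k5 * za * zb + p.c0)
                if b.is_sensor:
                    dY[o + 4] = p.k5 * za * zb + p.c0 - p.d5 * Y[o + 4]
                    continue
            out = b.strain.output
            if out.signal is not None:
                pool_flux[out.signal] += out_flux
            elif out.attenuates is not None:
                enz_flux[out.attenuates] += out_flux
        for j, sp in enumerate(self.pool_species):
            i = self._pool_offset + j
            dY[i] = pool_flux[sp] - self.clearance_of(sp) * Y[i]
        for j, sp in enumerate(self.enzyme_species):
            i = self._enzyme_offset + j
            dY[i] = enz_flux[sp] - self.clearance_of(sp) * Y[i]
        return dY

    def diluted_indices(self) -> np.ndarray:
        """State indices subject to dilution events (medium + enzyme pools)."""
        return np.arange(self._pool_offset, self.n_states)


def compose(
    members: Sequence[tuple[StrainSpec, float]] | Sequence[StrainSpec],
    sensor: StrainSpec,
    library: StrainLibrary | None = None,
    exogenous: dict | None = None,
    spikes: Sequence[Spike] = (),
    clearance: float = DEFAULT_CLEARANCE,
    K_E: float = DEFAULT_K_E,
) -> ConsortiumModel:
    """Assemble a consortium model from member strains (with optional gains).

    ``members`` is a list of StrainSpec or (StrainSpec, gain) pairs; gains
    default to 1 (the reference cell density). Exogenous held inputs are given
    per species as a constant level or a [(time, level), ...] schedule.
    """
    norm: list[tuple[StrainSpec, float]] = []
    for m in members:
        if isinstance(m, StrainSpec):
            norm.append((m, 1.0))
        else:
            strain, gain = m
            norm.append((strain, float(gain)))
    if library is not None:
        for strain, _ in norm + [(sensor, 1.0)]:
            if strain.id not in library:
                raise CompositionError(f"strain {strain.id!r} not in library")
    exo = {Signal(k): v for k, v in (exogenous or {}).items()}
    return ConsortiumModel(
        members=norm, sensor=sensor, exogenous=exo, spikes=list(spikes),
        clearance=clearance, K_E=K_E,
    )


def simulate_consortium(
    model: ConsortiumModel,
    t_grid,
    dilution: DilutionSchedule | None = None,
    y0: np.ndarray | None = None,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> TimeCourse:
    """Integrate a consortium, applying spike and dilution events.

    Integration is segmented at every event time; at a dilution event the
    medium and enzyme pools are multiplied by the retention fraction, and at
    a spike the named pool jumps by the spike amount.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    t0, t1 = t_grid[0], t_grid[-1]
    events: list[tuple[float, str, object]] = []
    if dilution is not None:
        for te in dilution.events(t0, t1):
            events.append((te, "dilute", dilution.retention))
    for sp in model.spikes:
        if t0 < sp.time <= t1:
            events.append((sp.time, "spike", sp))
    for sig, sched in model.exogenous.items():
        for tb in _schedule_breaks(sched):
            if t0 < tb < t1:
                events.append((tb, "break", None))
    events.sort(key=lambda e: e[0])

    y = model.initial_state() if y0 is None else np.asarray(y0, dtype=float).copy()
    ts_out: list[np.ndarray] = []
    ys_out: list[np.ndarray] = []
    seg_start = t0
    if np.isclose(t_grid[0], seg_start):
        ts_out.append(np.array([t_grid[0]]))
        ys_out.append(y.reshape(-1, 1).copy())

    def run_segment(a: float, b: float, y_in: np.ndarray) -> np.ndarray:
        inner = t_grid[(t_grid > a + 1e-12) & (t_grid < b - 1e-12)]
        t_eval = np.concatenate([inner, [b]])
        t_eval = np.unique(t_eval)
        sol = solve_ivp(
            model.rhs, (a, b), y_in, t_eval=t_eval, method=method,
            rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"consortium integration failed on [{a:g}, {b:g}] h: {sol.message}"
            )
        keep = np.isin(sol.t, inner)
        if keep.any():
            ts_out.append(sol.t[keep])
            ys_out.append(sol.y[:, keep])
        return sol.y[:, -1]

    for i, (te, kind, payload) in enumerate(events):
        if te > seg_start + 1e-12:
            y = run_segment(seg_start, te, y)
            seg_start = te
        if kind == "dilute":
            y = y.copy()
            y[model.diluted_indices()] *= payload
        elif kind == "spike":
            y = y.copy()
            idx = model.pool_index(payload.species)
            if idx is None:
                raise RuntimeError(
                    f"spike event {i}: no medium pool for {payload.species}"
                )
            y[idx] += payload.amount
        if np.isclose(t_grid, seg_start).any():
            ts_out.append(np.array([seg_start]))
            ys_out.append(y.reshape(-1, 1).copy())
    if t1 > seg_start + 1e-12:
        y = run_segment(seg_start, t1, y)
        ts_out.append(np.array([t1]))
        ys_out.append(y.reshape(-1, 1).copy())

    t_all = np.concatenate(ts_out)
    y_all = np.concatenate(ys_out, axis=1)
    order = np.argsort(t_all, kind="stable")
    t_all, y_all = t_all[order], y_all[:, order]
    # collapse to the requested grid (keep post-event values at event times)
    out = np.empty((model.n_states, t_grid.size))
    for j, tq in enumerate(t_grid):
        hits = np.where(np.isclose(t_all, tq, rtol=0, atol=1e-9))[0]
        out[:, j] = y_all[:, hits[-1]]
    y_clipped = np.where((out < 0) & (out > -1e-8), 0.0, out)
    return TimeCourse(t_grid, y_clipped, list(model.labels))


def consortium_endpoint(
    model: ConsortiumModel,
    inputs: dict,
    t_end: float = 12.0,
    n_points: int = 49,
    dilution: DilutionSchedule | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> TimeCourse:
    """Simulate with held input levels over ``[0, t_end]`` hours.

    ``inputs`` maps species to a constant exogenous concentration; it is merged
    over the model's existing exogenous schedule.
    """
    exo = dict(model.exogenous)
    exo.update({Signal(k): float(v) for k, v in inputs.items()})
    m = ConsortiumModel(
        members=model.members, sensor=model.sensor, exogenous=exo,
        spikes=model.spikes, clearance=model.clearance, K_E=model.K_E,
    )
    t_grid = np.linspace(0.0, t_end, n_points)
    return simulate_consortium(m, t_grid, dilution=dilution, rtol=rtol, atol=atol)


@dataclass
class ModularityReport:
    """Prediction-vs-reference comparison for a composed cascade."""

    doses: np.ndarray
    predicted: np.ndarray
    reference: np.ndarray
    rmse: float
    relative_bias: float  # mean signed relative error
    biased: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        tag = "BIASED" if self.biased else "ok"
        return (
            f"ModularityReport(rmse={self.rmse:.4g}, "
            f"relative_bias={self.relative_bias:+.3%}, {tag})"
        )


def compare_cascade_modularity(
    predicted: ConsortiumModel,
    reference: ConsortiumModel,
    species: Signal,
    doses,
    t_end: float = 12.0,
    bias_threshold: float = 0.05,
) -> ModularityReport:
    """Compare a composed prediction against a reference cascade.

    Both models are driven with the same held input doses of ``species`` and
    their sensor endpoints at ``t_end`` are compared. A systematic relative
    bias beyond ``bias_threshold`` flags the composition as non-modular
    (e.g. a corrupted sender gain).
    """
    doses = np.asarray(doses, dtype=float)
    pred = np.empty(doses.size)
    ref = np.empty(doses.size)
    for i, d in enumerate(doses):
        tc_p = consortium_endpoint(predicted, {species: d}, t_end=t_end)
        tc_r = consortium_endpoint(reference, {species: d}, t_end=t_end)
        pred[i] = tc_p.endpoint(predicted.sensor_label)
        ref[i] = tc_r.endpoint(reference.sensor_label)
    rel = (pred - ref) / np.maximum(np.abs(ref), 1e-12)
    bias = float(np.mean(rel))
    return ModularityReport(
        doses=doses, predicted=pred, reference=ref,
        rmse=float(np.sqrt(np.mean((pred - ref) ** 2))),
        relative_bias=bias, biased=abs(bias) > bias_threshold,
    )
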