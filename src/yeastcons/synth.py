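"""Synthetic cytometry-style datasets with known ground truth.

These generators emulate the statistical structure of processed
flow-cytometry measurements — per-condition mean fluorescence, a background
offset, multiplicative lognormal noise and three biological replicates — so
the whole fitting pipeline can be exercised and validated without any
external data. Every generator is seed-deterministic: regenerating from the
recorded provenance yields bit-identical tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .bistability import Model3Params, find_equilibria, simulate_switch
from .composition import (
    ConsortiumModel,
    DilutionSchedule,
    Spike,
    compose,
    simulate_consortium,
)
from .fitting import MeasurementTable
from .kinetics import Model1Params, Transfer, timecourse_tensor_model1
from .library import StrainSpec
from .species import Signal

__all__ = [
    "NoiseModel",
    "SyntheticDataset",
    "generate_sensor_dataset",
    "generate_cascade_dataset",
    "generate_switch_dataset",
    "DEFAULT_DOSES",
    "DEFAULT_TIMES",
]

#: Default design matrix mirroring the sensor-characterization experiments:
#: eight doses covering the dynamic range; six time points from the early
#: sensing transient (0.5 h) to output saturation (12 h, >3.5 output
#: half-lives at the default turnover of 0.3/h).
DEFAULT_DOSES = (0.0, 1.0, 5.0, 10.0, 50.0, 200.0, 1000.0, 5000.0)
DEFAULT_TIMES = (0.5, 1.0, 2.0, 4.0, 8.0, 12.0)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: y_obs = y * LogNormal(mean 1, cv) + background."""

    background: float = 0.0  # additive offset (a.u.)
    cv: float = 0.05  # multiplicative coefficient of variation
    replicate_count: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")

    def apply(self, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Noisy observation of the clean signal ``y``."""
        if self.cv == 0:
            return y + self.background
        sigma2 = np.log1p(self.cv ** 2)
        factors = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=y.shape)
        return y * factors + self.background


@dataclass
class SyntheticDataset:
    """Generated tables plus the ground truth and generator provenance."""

    truth: dict
    tables: dict[str, MeasurementTable]
    provenance: dict

    @property
    def table(self) -> MeasurementTable:
        """The single table, for single-output datasets."""
        if len(self.tables) != 1:
            raise ValueError("dataset has multiple tables; access by name")
        return next(iter(self.tables.values()))


def _rows_from_grid(clean: np.ndarray, doses, times, species: str,
                    noise: NoiseModel, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for r in range(1, noise.replicate_count + 1):
        obs = noise.apply(clean, rng)
        for i, d in enumerate(doses):
            for j, t in enumerate(times):
                rows.append({
                    "time": float(t), f"dose_{species}": float(d),
                    "value": float(obs[i, j]), "replicate": r,
                })
    return pd.DataFrame(rows)


def generate_sensor_dataset(
    params: Model1Params,
    transfer: Transfer | str,
    doses: Sequence[float] = DEFAULT_DOSES,
    times: Sequence[float] = DEFAULT_TIMES,
    noise: NoiseModel = NoiseModel(),
    species: Signal | str = Signal.AUXIN,
    strain_id: str = "synthetic_sensor",
) -> SyntheticDataset:
    """Time-course fluorescence tables for a single sensor strain.

    Simulates the three-stage model at every (dose, time) point and applies
    the noise model independently per replicate.
    """
    species = Signal(species)
    rng = np.random.default_rng(noise.seed)
    clean = timecourse_tensor_model1(params, transfer, np.asarray(doses, float),
                                     np.asarray(times, float))
    df = _rows_from_grid(clean, doses, times, species.value, noise, rng)
    table = MeasurementTable(df, strain_id=strain_id, background=noise.background,
                             background_subtracted=noise.background == 0)
    return SyntheticDataset(
        truth={"params": params, "transfer": str(Transfer(transfer))},
        tables={strain_id: table},
        provenance={
            "generator": "generate_sensor_dataset", "seed": noise.seed,
            "doses": list(map(float, doses)), "times": list(map(float, times)),
            "cv": noise.cv, "background": noise.background,
            "replicates": noise.replicate_count, "species": species.value,
        },
    )


def generate_cascade_dataset(
    chain: Sequence[tuple[StrainSpec, float]] | Sequence[StrainSpec],
    sensor: StrainSpec,
    input_species: Signal | str,
    doses: Sequence[float],
    times: Sequence[float] = DEFAULT_TIMES,
    noise: NoiseModel = NoiseModel(),
    clearance: float | dict = 0.3,
    split: bool = False,
) -> SyntheticDataset:
    """Downstream-sensor fluorescence for a signaling cascade.

    ``chain`` lists the upstream strains (optionally with gains) feeding the
    sensor. With ``split=True`` the doses are interleaved into a fitting half
    and a validation half (the four-point fit / four-point validation layout).
    """
    if not list(chain):
        raise ValueError("cascade chain must contain at least one strain")
    input_species = Signal(input_species)
    rng = np.random.default_rng(noise.seed)
    model = compose(list(chain), sensor, clearance=clearance)
    times = np.asarray(times, dtype=float)
    t_grid = np.unique(np.concatenate([[0.0], times]))
    doses = np.asarray(doses, dtype=float)
    clean = np.empty((doses.size, times.size))
    for i, d in enumerate(doses):
        exo = dict(model.exogenous)
        exo[input_species] = float(d)
        m = ConsortiumModel(members=model.members, sensor=model.sensor,
                            exogenous=exo, clearance=model.clearance, K_E=model.K_E)
        tc = simulate_consortium(m, t_grid, rtol=1e-7, atol=1e-9)
        fl = tc.state(m.sensor_label)
        tmap = {t: j for j, t in enumerate(tc.t)}
        clean[i] = [fl[tmap[t]] for t in times]
    df = _rows_from_grid(clean, doses, times, input_species.value, noise, rng)
    table = MeasurementTable(df, strain_id=sensor.id, background=noise.background,
                             background_subtracted=noise.background == 0)
    tables = {"cascade": table}
    if split:
        fit_doses = doses[::2]
        val_doses = doses[1::2]
        dcol = f"dose_{input_species.value}"
        tables = {
            "fit": MeasurementTable(
                df[df[dcol].isin(fit_doses)].reset_index(drop=True),
                sensor.id, noise.background, noise.background == 0),
            "validation": MeasurementTable(
                df[df[dcol].isin(val_doses)].reset_index(drop=True),
                sensor.id, noise.background, noise.background == 0),
        }
    return SyntheticDataset(
        truth={
            "chain": [(s.id, g) for s, g in model.members],
            "sensor": sensor.id, "clearance": clearance,
        },
        tables=tables,
        provenance={
            "generator": "generate_cascade_dataset", "seed": noise.seed,
            "doses": doses.tolist(), "times": times.tolist(),
            "cv": noise.cv, "background": noise.background,
            "replicates": noise.replicate_count, "split": split,
        },
    )


def generate_switch_dataset(
    params: Model3Params,
    sensor: StrainSpec,
    stimuli: Sequence[Spike] = (),
    dilution: DilutionSchedule | None = None,
    noise: NoiseModel = NoiseModel(),
    t_end: float = 30.0,
    sample_every: float = 0.5,
) -> SyntheticDataset:
    """Sensor-readout time series for the bistable switch protocol.

    Warns (but still generates) when the supplied truth is monostable, since
    state-toggling detection is only meaningful for a bistable circuit.
    """
    import warnings

    eq = find_equilibria(params)
    if not eq.bistable:
        warnings.warn("switch truth parameters are monostable", stacklevel=2)
    rng = np.random.default_rng(noise.seed)
    n_points = int(round(t_end / sample_every)) + 1
    tc = simulate_switch(params, stimuli=list(stimuli), dilution=dilution,
                         sensor=sensor, t_end=t_end, n_points=n_points)
    clean = tc.state("fluorescence")
    rows = []
    for r in range(1, noise.replicate_count + 1):
        obs = noise.apply(clean, rng)
        for t, v in zip(tc.t, obs):
            rows.append({
                "time": float(t), "dose_auxin": 0.0,
                "value": float(v), "replicate": r,
            })
    table = MeasurementTable(pd.DataFrame(rows), strain_id=sensor.id,
                             background=noise.background,
                             background_subtracted=noise.background == 0)
    return SyntheticDataset(
        truth={"params": params, "equilibria": eq.points, "stability": eq.stability,
               "clean_trace": clean, "t": tc.t},
        tables={"switch": table},
        provenance={
            "generator": "generate_switch_dataset", "seed": noise.seed,
            "t_end": t_end, "sample_every": sample_every, "cv": noise.cv,
            "background": noise.background, "replicates": noise.replicate_count,
            "stimuli": [(s.time, s.species.value, s.amount) for s in stimuli],
            "dilution": None if dilution is None else
                (dilution.period, dilution.retention, dilution.start),
        },
    )


def count_state_switches(trace: np.ndarray, low: float, high: float) -> int:
    """Count threshold crossings of a readout between hysteresis bands.

    ``low``/``high`` bracket the two states; a switch is counted each time
    the trace crosses from one band into the other.
    """
    if low >= high:
        raise ValueError("low must be < high")
    state = None
    switches = 0
    for v in np.asarray(trace, dtype=float):
        if v <= low:
            s = "low"
        elif v >= high:
            s = "high"
        else:
            continue
        if state is not None and s != state:
            switches += 1
        state = s
    return switches
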