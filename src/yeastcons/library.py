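"""The strain vocabulary: definition, validation, persistence and queries.

The default library holds 24 single-input strains built from three inputs
(alpha-factor, auxin, beta-estradiol), two transfer signs and five outputs:

* 6 **sensors** expressing GFP (one per input x sign),
* 12 **synthesizers** secreting alpha-factor or auxin,
* 6 **attenuators** expressing BAR1 (degrades alpha-factor) or GH3.3
  (inactivates auxin).

Four synthesizers sense and secrete the same molecule and are the positive /
negative feedback strains. The ``enumeration_pool`` lists the 16 non-sensor
strains eligible for the automated design search (the non-sensors minus the
two self-negative feedback synthesizers); membership is configurable in the
library file.

Strain ids follow ``input_sign_output`` (e.g. ``aF_act_IAA``) so enumeration
order is deterministic.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .kinetics import Model1Params, Model2Params
from .species import EXOGENOUS_ONLY, OutputKind, Signal, Transfer

__all__ = [
    "StrainSpec",
    "StrainLibrary",
    "LibraryValidationError",
    "load_library",
    "save_library",
    "default_library",
    "default_library_path",
]

SCHEMA_VERSION = 1

_ROLE_COUNTS = {"sensor": 6, "synthesizer": 12, "attenuator": 6}
POOL_SIZE = 16


class LibraryValidationError(ValueError):
    """A strain-library config violated the schema or an invariant."""


@dataclass(frozen=True)
class StrainSpec:
    """One vocabulary entry: what it senses, how it transfers, what it makes."""

    id: str
    inputs: tuple[Signal, ...]  # 1 or 2 sensed species
    transfer: tuple[Transfer, ...]  # per-input sign
    output: OutputKind
    role: str  # sensor | synthesizer | attenuator
    params: Model1Params | Model2Params
    feedback: str = "none"  # none | self_positive | self_negative

    def __post_init__(self) -> None:
        if len(self.inputs) not in (1, 2):
            raise LibraryValidationError(f"{self.id}: strains sense 1 or 2 inputs")
        if len(self.transfer) != len(self.inputs):
            raise LibraryValidationError(f"{self.id}: one transfer sign per input")
        if self.role not in _ROLE_COUNTS:
            raise LibraryValidationError(f"{self.id}: unknown role {self.role!r}")
        if self.role == "sensor" and self.output is not OutputKind.GFP:
            raise LibraryValidationError(f"{self.id}: sensors must output GFP")
        if self.role == "synthesizer" and self.output.signal is None:
            raise LibraryValidationError(f"{self.id}: synthesizers must output a signal")
        if self.role == "attenuator" and self.output.attenuates is None:
            raise LibraryValidationError(f"{self.id}: attenuators must output BAR1 or GH3.3")
        if self.output.signal in EXOGENOUS_ONLY:
            raise LibraryValidationError(f"{self.id}: beta-estradiol is exogenous-only")
        if self.feedback not in ("none", "self_positive", "self_negative"):
            raise LibraryValidationError(f"{self.id}: bad feedback flag {self.feedback!r}")
        if self.feedback == "self_positive" and self.output.signal != self.inputs[0]:
            raise LibraryValidationError(
                f"{self.id}: self_positive strains must sense and secrete the same species"
            )
        wants2 = isinstance(self.params, Model2Params)
        if wants2 != (len(self.inputs) == 2):
            raise LibraryValidationError(
                f"{self.id}: parameter model does not match the number of inputs"
            )

    @property
    def is_sensor(self) -> bool:
        return self.role == "sensor"

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)


@dataclass
class StrainLibrary:
    """A validated set of strains plus the design-search enumeration pool."""

    strains: list[StrainSpec]
    enumeration_pool: list[str] = field(default_factory=list)
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        ids = [s.id for s in self.strains]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise LibraryValidationError(f"duplicate strain id(s): {sorted(dup)}")
        if not self.strains:
            raise LibraryValidationError("library must contain at least one strain")
        index = {s.id: s for s in self.strains}
        for sid in self.enumeration_pool:
            if sid not in index:
                raise LibraryValidationError(f"pool member {sid!r} is not in the library")
            if index[sid].is_sensor:
                raise LibraryValidationError(f"pool member {sid!r} is a sensor strain")
        if len(set(self.enumeration_pool)) != len(self.enumeration_pool):
            raise LibraryValidationError("enumeration pool contains duplicates")

    def __len__(self) -> int:
        return len(self.strains)

    def __getitem__(self, sid: str) -> StrainSpec:
        for s in self.strains:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def __contains__(self, sid: str) -> bool:
        return any(s.id == sid for s in self.strains)

    def by_role(self, role: str) -> list[StrainSpec]:
        return [s for s in self.strains if s.role == role]

    @property
    def sensors(self) -> list[StrainSpec]:
        return self.by_role("sensor")

    def pool_strains(self) -> list[StrainSpec]:
        """The non-sensor strains eligible for topology enumeration, sorted by id."""
        return [self[sid] for sid in sorted(self.enumeration_pool)]


def enumeration_pool(library: StrainLibrary) -> list[StrainSpec]:
    """Return the enumeration-pool strains in stable (id-sorted) order."""
    if not library.strains:
        raise LibraryValidationError("empty library")
    return library.pool_strains()


# ---------------------------------------------------------------------------
# serialization


def _params_to_dict(p: Model1Params | Model2Params) -> dict:
    model = "model1" if isinstance(p, Model1Params) else "model2"
    d = {"model": model}
    d.update({k: float(getattr(p, k)) for k in p.NAMES})
    return d


def _params_from_dict(d: dict, where: str):
    d = dict(d)
    model = d.pop("model", "model1")
    try:
        if model == "model1":
            return Model1Params(**d)
        if model == "model2":
            return Model2Params(**d)
    except (TypeError, ValueError) as e:
        raise LibraryValidationError(f"{where}: bad parameter block ({e})") from e
    raise LibraryValidationError(f"{where}: unknown model {model!r}")


def _strain_to_dict(s: StrainSpec) -> dict:
    return {
        "id": s.id,
        "inputs": [i.value for i in s.inputs],
        "transfer": [t.value for t in s.transfer],
        "output": s.output.value,
        "role": s.role,
        "feedback": s.feedback,
        "params": _params_to_dict(s.params),
    }


def _strain_from_dict(d: dict) -> StrainSpec:
    where = d.get("id", "<missing id>")
    try:
        inputs = tuple(Signal(i) for i in d["inputs"])
        transfer = tuple(Transfer(t) for t in d["transfer"])
        output = OutputKind(d["output"])
    except KeyError as e:
        raise LibraryValidationError(f"{where}: missing field {e}") from e
    except ValueError as e:
        raise LibraryValidationError(f"{where}: {e}") from e
    return StrainSpec(
        id=d["id"],
        inputs=inputs,
        transfer=transfer,
        output=output,
        role=d.get("role", "sensor"),
        feedback=d.get("feedback", "none"),
        params=_params_from_dict(d.get("params", {}), where),
    )


def library_to_dict(library: StrainLibrary) -> dict:
    return {
        "schema_version": library.schema_version,
        "strains": [_strain_to_dict(s) for s in library.strains],
        "enumeration_pool": list(library.enumeration_pool),
    }


def save_library(library: StrainLibrary, path) -> None:
    Path(path).write_text(yaml.safe_dump(library_to_dict(library), sort_keys=False))


def load_library(path, strict_counts: bool | None = None) -> StrainLibrary:
    """Load and validate a strain-library YAML/JSON file.

    ``strict_counts`` additionally enforces the default-vocabulary invariants
    (6 sensors / 12 synthesizers / 6 attenuators, pool of exactly 16). When
    left as None it is enforced only for 24-strain libraries, so reduced test
    libraries remain loadable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "strains" not in raw:
        raise LibraryValidationError(f"{path}: not a strain-library file")
    strains = [_strain_from_dict(d) for d in raw["strains"]]
    lib = StrainLibrary(
        strains=strains,
        enumeration_pool=list(raw.get("enumeration_pool", [])),
        schema_version=int(raw.get("schema_version", SCHEMA_VERSION)),
    )
    if strict_counts is None:
        strict_counts = len(lib.strains) == sum(_ROLE_COUNTS.values())
    if strict_counts:
        validate_default_invariants(lib)
    return lib


def validate_default_invariants(lib: StrainLibrary) -> None:
    """Check the full-vocabulary invariants (role counts and pool size)."""
    for role, want in _ROLE_COUNTS.items():
        got = len(lib.by_role(role))
        if got != want:
            raise LibraryValidationError(f"expected {want} {role} strains, found {got}")
    if len(lib.enumeration_pool) != POOL_SIZE:
        raise LibraryValidationError(
            f"enumeration pool must have exactly {POOL_SIZE} strains "
            f"(found {len(lib.enumeration_pool)}); "
            f"C({POOL_SIZE},k) reproduces the 120/560/1820 combination counts"
        )


def default_library_path() -> Path:
    return Path(__file__).parent / "data" / "default_library.yaml"


def default_library() -> StrainLibrary:
    """Load the shipped 24-strain vocabulary."""
    return load_library(default_library_path(), strict_counts=True)
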