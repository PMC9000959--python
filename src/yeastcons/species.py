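"""Signal species and output vocabulary for the strain library.

Three extracellular signals drive all circuits: the yeast mating pheromone
alpha-factor, the plant hormone auxin (IAA), and beta-estradiol. Alpha-factor
and auxin can be synthesized and secreted by engineered strains and enzymatically
attenuated (BAR1 protease, GH3.3 conjugase); beta-estradiol can only be supplied
exogenously. All extracellular concentrations are in nM.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Signal(str, Enum):
    """One of the three extracellular signaling species."""

    ALPHA_FACTOR = "alpha_factor"
    AUXIN = "auxin"
    BETA_ESTRADIOL = "beta_estradiol"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Species that engineered strains can synthesize and secrete.
SECRETABLE: frozenset[Signal] = frozenset({Signal.ALPHA_FACTOR, Signal.AUXIN})

#: Species that can only be added to the medium by the experimenter.
EXOGENOUS_ONLY: frozenset[Signal] = frozenset({Signal.BETA_ESTRADIOL})


class OutputKind(str, Enum):
    """What a strain produces: a reporter, a signal, or an attenuating enzyme."""

    GFP = "GFP"
    ALPHA_FACTOR = "alpha_factor"
    AUXIN = "auxin"
    BAR1 = "BAR1"
    GH3 = "GH3.3"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def output_class(self) -> str:
        if self is OutputKind.GFP:
            return "reporter"
        if self in (OutputKind.ALPHA_FACTOR, OutputKind.AUXIN):
            return "signal"
        return "attenuator_enzyme"

    @property
    def signal(self) -> Signal | None:
        """The secreted signal, for signal outputs."""
        if self is OutputKind.ALPHA_FACTOR:
            return Signal.ALPHA_FACTOR
        if self is OutputKind.AUXIN:
            return Signal.AUXIN
        return None

    @property
    def attenuates(self) -> Signal | None:
        """The signal an attenuator enzyme depletes (BAR1 -> alpha-factor, GH3.3 -> auxin)."""
        if self is OutputKind.BAR1:
            return Signal.ALPHA_FACTOR
        if self is OutputKind.GH3:
            return Signal.AUXIN
        return None


class Transfer(str, Enum):
    """Sign of a strain's monotone input-output transfer function."""

    ACTIVATING = "activating"
    REPRESSING = "repressing"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class SpeciesInfo:
    """Static description of one signal species."""

    signal: Signal
    unit: str = "nM"

    @property
    def secretable(self) -> bool:
        return self.signal in SECRETABLE


ALL_SPECIES: tuple[SpeciesInfo, ...] = tuple(SpeciesInfo(s) for s in Signal)
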