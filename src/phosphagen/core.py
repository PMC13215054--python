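"""Domain types, physical constants and the resting equilibrium state.

The model tracks six metabolites in a volume-averaged nerve terminal:
ATP, ADP, AMP, arginine (Arg), phosphoarginine (ArgP) and inorganic
phosphate (Pi), all in mM.  Two near-equilibrium enzymes couple them:

* adenylate kinase (AK):      AMP + ATP  <->  2 ADP,   K_Ad = [ADP]^2 / ([ATP][AMP])
* arginine kinase (ArgK):     ADP + ArgP <->  ATP + Arg, K_Ph = [ATP][Arg] / ([ADP][ArgP])

The resting ADP and AMP concentrations are not free parameters: they are
derived from these relations given the measured resting ATP, Arg and ArgP
pools.  The regulatory signal for ATP production is the energy state
ES = [ATP] / ([ADP][Pi]) (in 1/mM), and the free energy of ATP hydrolysis
is dG = dG0 + RT ln([ADP][Pi]/[ATP]) with concentrations in mM (this mM
convention is what reproduces the reported resting magnitude of ~38 kJ/mol;
dG is negative, the "available" energy is its magnitude).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AVOGADRO_PER_UM3_PER_MM",
    "COMPONENTS",
    "MetabolicState",
    "EquilibriumConstants",
    "ThermoConstants",
    "TerminalParams",
    "InitialConditions",
    "InvalidParameterError",
    "initial_state_from_equilibrium",
    "free_energy",
    "energy_state",
]

#: Molecules per um^3 corresponding to 1 mM.
#: 1 mM = 6.02214076e20 molecules/L; 1 L = 1e15 um^3, hence
#: 1 molecule/um^3 = 1/602.214 uM ~= 1.6605e-6 mM.
AVOGADRO_PER_UM3_PER_MM = 6.02214076e5

#: The activity-driven ATP consumption components: Na+ extrusion, Ca2+
#: extrusion, and three processes tied to neurotransmitter release
#: (vesicle recycling/refilling on distinct time scales).
COMPONENTS = ("Na", "Ca", "NT1", "NT2", "NT3")


class InvalidParameterError(ValueError):
    """A physically inadmissible parameter or concentration."""


@dataclass(frozen=True)
class MetabolicState:
    """Concentrations (mM) of the six tracked metabolites."""

    atp: float
    adp: float
    amp: float
    arg: float
    argp: float
    pi: float

    def __post_init__(self) -> None:
        for name in ("atp", "adp", "amp", "arg", "argp", "pi"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def adenine_pool(self) -> float:
        """ATP + ADP + AMP; invariant under AK/ArgK equilibration."""
        return self.atp + self.adp + self.amp

    @property
    def guanidino_pool(self) -> float:
        """Arg + ArgP; invariant under equilibration."""
        return self.arg + self.argp

    @property
    def phosphoryl_tally(self) -> float:
        """3·ATP + 2·ADP + AMP + ArgP; invariant under equilibration."""
        return 3.0 * self.atp + 2.0 * self.adp + self.amp + self.argp

    def as_array(self) -> np.ndarray:
        return np.array([self.atp, self.adp, self.amp, self.arg, self.argp, self.pi])

    @classmethod
    def from_array(cls, a) -> "MetabolicState":
        return cls(*(float(x) for x in a))

    def replace(self, **kw) -> "MetabolicState":
        return replace(self, **kw)


@dataclass(frozen=True)
class EquilibriumConstants:
    """Dimensionless equilibrium constants of the two kinases.

    ``k_ad`` for adenylate kinase (default 1) and ``k_ph`` for arginine
    kinase (default 39.6, squid axon).
    """

    k_ad: float = 1.0
    k_ph: float = 39.6

    def __post_init__(self) -> None:
        if self.k_ad <= 0 or self.k_ph <= 0:
            raise InvalidParameterError("equilibrium constants must be > 0")


@dataclass(frozen=True)
class ThermoConstants:
    """Constants of the ATP hydrolysis free-energy formula.

    delta_g0 is the standard free energy of ATP hydrolysis (kJ/mol,
    negative), gas_constant in kJ/mol/K, temperature in K.
    """

    delta_g0: float = -30.6
    gas_constant: float = 8.31445e-3
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise InvalidParameterError("temperature must be > 0")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature


@dataclass(frozen=True)
class TerminalParams:
    """Energetic parameters of one motor-neuron terminal.

    n_atp[j] is the number of ATP molecules consumed per action potential
    by component j, which decays with time constant tau[j] (s).  base_rate
    (mM/s) is the constant non-signalling consumption.  volume (um^3)
    converts molecule counts to concentrations.  The maximum ATP
    production rate is max_rate_per_density (mM/s per 1% mitochondrial
    volume density) times mito_density (%).
    """

    name: str
    n_atp: dict = field(default_factory=dict)
    tau: dict = field(default_factory=dict)
    base_rate: float = 0.05
    volume: float = 300.0
    mito_density: float = 6.3
    max_rate_per_density: float = 0.154
    phosphagen_present: bool = True

    def __post_init__(self) -> None:
        missing = [c for c in COMPONENTS if c not in self.n_atp or c not in self.tau]
        if missing:
            raise InvalidParameterError(f"missing consumption components: {missing}")
        if any(self.n_atp[c] < 0 for c in COMPONENTS):
            raise InvalidParameterError("per-AP ATP costs must be >= 0")
        if any(self.tau[c] <= 0 for c in COMPONENTS):
            raise InvalidParameterError("decay constants must be > 0")
        if self.base_rate < 0:
            raise InvalidParameterError("base_rate must be >= 0")
        if self.volume <= 0:
            raise InvalidParameterError("volume must be > 0")
        if not (0 < self.mito_density <= 100):
            raise InvalidParameterError("mito_density must be in (0, 100] %")
        if self.max_rate_per_density <= 0:
            raise InvalidParameterError("max_rate_per_density must be > 0")

    @property
    def max_rate(self) -> float:
        """Production cap in mM/s: max_rate_per_density · mito_density."""
        return self.max_rate_per_density * self.mito_density

    def deposit_mm(self, component: str) -> float:
        """Per-AP ATP cost of one component expressed in mM."""
        return self.n_atp[component] / (self.volume * AVOGADRO_PER_UM3_PER_MM)

    def per_ap_cost_mm(self) -> float:
        """Total per-AP signalling cost in mM (all components)."""
        return sum(self.deposit_mm(c) for c in COMPONENTS)


@dataclass(frozen=True)
class InitialConditions:
    """Measured resting pools (mM) from which ADP and AMP are derived."""

    atp0: float = 2.16
    argp0: float = 7.5
    arg0: float = 3.3
    pi0: float = 3.8

    def __post_init__(self) -> None:
        if self.atp0 <= 0 or self.argp0 <= 0 or self.pi0 <= 0:
            raise InvalidParameterError("atp0, argp0 and pi0 must be > 0")
        if self.arg0 < 0:
            raise InvalidParameterError("arg0 must be >= 0")


def initial_state_from_equilibrium(
    ic: InitialConditions, k: EquilibriumConstants
) -> MetabolicState:
    """Resting state with ADP and AMP set by the two kinase equilibria.

    ADP follows from the ArgK relation, [ADP] = [ATP][Arg]/(K_Ph [ArgP]),
    and AMP from the AK relation, [AMP] = [ADP]^2/(K_Ad [ATP]).  With the
    default squid-axon pools this gives [ADP] = 24.0 uM and
    [AMP] = 0.27 uM at rest.
    """
    adp = ic.atp0 * ic.arg0 / (k.k_ph * ic.argp0)
    amp = adp * adp / (k.k_ad * ic.atp0)
    return MetabolicState(atp=ic.atp0, adp=adp, amp=amp, arg=ic.arg0, argp=ic.argp0, pi=ic.pi0)


def free_energy(state: MetabolicState, th: ThermoConstants = ThermoConstants()) -> float:
    """Free energy of ATP hydrolysis, dG0 + RT ln([ADP][Pi]/[ATP]), kJ/mol.

    Concentrations enter the logarithm in mM.  The result is negative;
    the energy "available" is its magnitude.
    """
    if state.atp <= 0 or state.adp <= 0 or state.pi <= 0:
        raise InvalidParameterError("free_energy requires atp, adp, pi > 0")
    return th.delta_g0 + th.rt * math.log(state.adp * state.pi / state.atp)


def energy_state(state: MetabolicState) -> float:
    """Energy state ES = [ATP]/([ADP][Pi]) in 1/mM — the production signal."""
    if state.adp <= 0 or state.pi <= 0:
        raise InvalidParameterError("energy_state requires adp, pi > 0")
    return state.atp / (state.adp * state.pi)
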