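"""Energy-state-regulated ATP production with rest calibration and a soft cap.

Production responds to the energy state ES = [ATP]/([ADP][Pi]) through a
mitochondrial turnover function pcc(ES).  The absolute scale of the
electron-transport chain (cytochrome c content etc.) is never needed:
production is calibrated so that at the resting energy state it exactly
balances the terminal's resting consumption,

    p(ES) = base_rate · pcc(ES) / pcc(base_ES),

so only turnover *ratios* matter and any strictly decreasing pcc keeps
the rest state a balanced steady state.  pcc must decrease with ES — a
terminal that runs down (ADP and Pi rise, ES falls) stimulates
production; this negative feedback is what makes the rest state stable.
The uncapped rate is then limited by the maximum oxidative capacity
max_rate (mM/s) through a soft minimum,

    p_capped = (p^-5 + max_rate^-5)^(-1/5),

which tracks p when demand is modest and saturates smoothly at max_rate.

The exact turnover function of the respiratory-chain model the rest
calibration absorbs is pluggable: any strictly decreasing callable of ES
can be supplied.  The shipped default is a Hill function of the inverse
energy state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core import InvalidParameterError, MetabolicState, TerminalParams, energy_state

__all__ = [
    "HillInverseTurnover",
    "ProductionModel",
    "production_rate",
    "cap_production",
    "production_acceleration",
    "build_production_model",
]


@dataclass(frozen=True)
class HillInverseTurnover:
    """Default turnover: Hill function of the inverse energy state.

    pcc(ES) = u^h / (k_half^h + u^h) with u = 1/ES.  ``k_half`` (1/mM) is
    the inverse-ES at half-maximal turnover and ``h`` the Hill
    coefficient.  With k_half = 0.5 1/mM and h = 2 the resting turnover
    sits low on the curve (~0.7% of maximum at the default resting
    ES ≈ 23.7 mM^-1), leaving two orders of magnitude of headroom for
    stimulation before the hard capacity cap engages.
    """

    k_half: float = 0.5
    h: float = 2.0

    def __call__(self, es):
        es = np.asarray(es, dtype=float)
        u = 1.0 / es
        val = u**self.h / (self.k_half**self.h + u**self.h)
        return float(val) if val.ndim == 0 else val


@dataclass(frozen=True)
class ProductionModel:
    """Calibrated, capped production model.

    turnover: strictly decreasing callable pcc(ES); base_es (1/mM): the
    resting energy state at which production equals base_rate (mM/s);
    max_rate (mM/s): oxidative capacity, typically
    max_rate_per_density · mito_density; cap_exponent: sharpness of the
    soft cap.
    """

    turnover: Callable = field(default_factory=HillInverseTurnover)
    base_es: float = 23.684
    base_rate: float = 0.05
    max_rate: float = 0.97
    cap_exponent: float = 5.0

    def __post_init__(self) -> None:
        if self.base_es <= 0 or self.base_rate < 0 or self.max_rate <= 0:
            raise InvalidParameterError("base_es, max_rate must be > 0; base_rate >= 0")
        if self.cap_exponent <= 0:
            raise InvalidParameterError("cap_exponent must be > 0")
        if self.base_rate >= self.max_rate:
            raise InvalidParameterError(
                "rest consumption meets or exceeds the production cap; the "
                "terminal has no viable rest state")

    @property
    def calibrated_base(self) -> float:
        """Uncapped rest production such that the *capped* rest production
        equals base_rate exactly, keeping the rest state a true fixed point.

        Inverse of the soft cap at base_rate: base_rate/(1 - r^e)^(1/e)
        with r = base_rate/max_rate; differs from base_rate by a relative
        r^e/e (~1e-7 for typical terminals).
        """
        if self.base_rate == 0.0:
            return 0.0
        r = self.base_rate / self.max_rate
        e = self.cap_exponent
        return self.base_rate / (1.0 - r**e) ** (1.0 / e)


def cap_production(p: float, max_rate: float, exponent: float = 5.0) -> float:
    """Soft minimum (p^-e + max_rate^-e)^(-1/e), computed overflow-safely.

    Strictly below min(p, max_rate) for p > 0; equals 0 at p = 0;
    approaches p for p << max_rate and max_rate for p >> max_rate.
    """
    if p < 0 or max_rate <= 0:
        raise InvalidParameterError("require p >= 0 and max_rate > 0")
    if p == 0.0:
        return 0.0
    # (p^-e + m^-e)^(-1/e) = s / (1 + r^e)^(1/e) with s the smaller and
    # r = s/l <= 1, avoiding overflow for extreme p.
    s, l = (p, max_rate) if p <= max_rate else (max_rate, p)
    r = s / l
    return s / (1.0 + r**exponent) ** (1.0 / exponent)


def production_rate(state: MetabolicState, m: ProductionModel, capped: bool = True) -> float:
    """ATP production rate (mM/s) at a metabolic state.

    Calibrated as base_rate · pcc(ES)/pcc(base_ES) with the prefactor
    pre-compensated for the soft cap (``calibrated_base``), so the capped
    rate at the resting state equals base_rate exactly for any turnover
    function.
    """
    es = energy_state(state)
    p = m.calibrated_base * m.turnover(es) / m.turnover(m.base_es)
    if not capped:
        return p
    return cap_production(p, m.max_rate, m.cap_exponent)


def production_acceleration(series, dt: float) -> np.ndarray:
    """Time derivative of a uniformly sampled production-rate series (mM/s^2).

    Centred finite differences with one-sided endpoints; requires at
    least three samples.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 3:
        raise InvalidParameterError("need at least 3 samples for a derivative")
    return np.gradient(series, dt)


def build_production_model(
    terminal: TerminalParams,
    rest_state: MetabolicState,
    turnover: Callable | None = None,
    cap_exponent: float = 5.0,
) -> ProductionModel:
    """Production model calibrated to a terminal's rest state."""
    return ProductionModel(
        turnover=turnover if turnover is not None else HillInverseTurnover(),
        base_es=energy_state(rest_state),
        base_rate=terminal.base_rate,
        max_rate=terminal.max_rate,
        cap_exponent=cap_exponent,
    )
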