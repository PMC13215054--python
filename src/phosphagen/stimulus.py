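"""Firing protocols, spike trains and the activity-driven ATP consumption rate.

A protocol fires trains of action potentials (APs) in repeating cycles:
within each *full cycle* (s), spikes occur at the firing rate for the
*duty* portion of the cycle and the terminal is silent for the rest.  By
convention a spike lands at the start of the duty window and — when
duty·rate is integral — at its end as well, so a 10 Hz train with a 0.6 s
duty produces 7 spikes, 100 ms apart.

Each AP triggers instantaneous ATP costs that decay exponentially: a
component j costing N_j molecules with time constant tau_j contributes a
spike of height N_j/tau_j (molecules/s) that decays as exp(-dt/tau_j),
and successive APs summate.  A constant non-signalling base rate applies
throughout.  Rates are expressed in mM/s using the terminal volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import COMPONENTS, InvalidParameterError, TerminalParams

__all__ = [
    "FiringProtocol",
    "SpikeTrain",
    "spike_times",
    "consumption_rate",
    "integrated_cost",
]

_ENDPOINT_TOL = 1e-9


@dataclass(frozen=True)
class FiringProtocol:
    """A cyclic stimulation protocol.

    rate (Hz), duty (s, firing portion of each cycle), full_cycle (s),
    n_cycles, t_start (s).  ``include_endpoint`` keeps the spike that
    falls exactly at the end of the duty window (the convention matching
    the worked counts of 7, 8160 and 6060 APs); switch it off to drop
    that terminal spike (e.g. to read "80 Hz x 10 s" as 800 APs).
    """

    rate: float
    duty: float
    full_cycle: float
    n_cycles: int = 1
    t_start: float = 0.0
    include_endpoint: bool = True

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise InvalidParameterError("rate must be > 0")
        if self.duty < 0:
            raise InvalidParameterError("duty must be >= 0")
        if self.duty > self.full_cycle:
            raise InvalidParameterError("duty cannot exceed full_cycle")
        if self.n_cycles < 1:
            raise InvalidParameterError("n_cycles must be >= 1")

    @classmethod
    def single_train(
        cls, rate: float, n_spikes: int, t_start: float = 0.0
    ) -> "FiringProtocol":
        """One train of exactly ``n_spikes`` APs at ``rate`` Hz."""
        if n_spikes < 1:
            raise InvalidParameterError("n_spikes must be >= 1")
        duty = (n_spikes - 1) / rate
        return cls(rate=rate, duty=duty, full_cycle=max(duty, 1.0 / rate),
                   n_cycles=1, t_start=t_start)

    @property
    def spikes_per_cycle(self) -> int:
        k = math.floor(self.duty * self.rate + _ENDPOINT_TOL)
        if not self.include_endpoint and k > 0:
            # drop the terminal spike only when it sits exactly on the
            # duty-window edge
            if abs(self.duty * self.rate - round(self.duty * self.rate)) < _ENDPOINT_TOL:
                k -= 1
        return k + 1

    @property
    def n_spikes(self) -> int:
        return self.n_cycles * self.spikes_per_cycle

    @property
    def duration(self) -> float:
        """Time from t_start to the end of the last full cycle."""
        return self.n_cycles * self.full_cycle


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times (s)."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise InvalidParameterError("spike times must be one-dimensional")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise InvalidParameterError("spike times must be strictly increasing")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.times.size


def spike_times(p: FiringProtocol) -> SpikeTrain:
    """Spike times of a protocol: per cycle c, t_start + c·full_cycle + k/rate."""
    per = p.spikes_per_cycle
    k = np.arange(per) / p.rate
    starts = p.t_start + np.arange(p.n_cycles) * p.full_cycle
    return SpikeTrain((starts[:, None] + k[None, :]).ravel())


def consumption_rate(t, train: SpikeTrain, params: TerminalParams):
    """Total ATP consumption rate (mM/s) at time(s) ``t``.

    base_rate plus, for every past spike t_s <= t and component j,
    (N_j/tau_j)·exp((t_s - t)/tau_j), volume-converted to mM/s.  Before
    the first spike the rate is exactly the base rate.  This is the
    explicit-sum reference evaluator; the simulator uses running decay
    accumulators that agree with it to round-off.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.full(t_arr.shape, params.base_rate, dtype=float)
    ts = train.times
    if ts.size:
        for c in COMPONENTS:
            h = params.deposit_mm(c) / params.tau[c]  # spike height, mM/s
            if h == 0.0:
                continue
            # sum over spikes with t_s <= t
            dt = t_arr[:, None] - ts[None, :]
            contrib = np.where(dt >= 0, np.exp(-np.maximum(dt, 0.0) / params.tau[c]), 0.0)
            out += h * contrib.sum(axis=1)
    return out if np.ndim(t) else float(out[0])


def integrated_cost(train: SpikeTrain, params: TerminalParams, t_end: float) -> float:
    """Total ATP consumed (mM) from t = 0 to t_end (closed-form integral).

    Equals base_rate·t_end plus, per spike and component, the fraction of
    the per-AP budget N_j already released by t_end; as t_end grows it
    converges to base_rate·t_end + n_spikes·sum_j N_j (in mM).
    """
    total = params.base_rate * t_end
    ts = train.times[train.times <= t_end]
    for c in COMPONENTS:
        n_mm = params.deposit_mm(c)
        if n_mm and ts.size:
            total += n_mm * float(np.sum(1.0 - np.exp((ts - t_end) / params.tau[c])))
    return total
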