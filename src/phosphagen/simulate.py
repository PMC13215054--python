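"""Time-stepping simulator for presynaptic ATP dynamics.

Each step applies operator splitting in the order the model defines:
first [ATP], [ADP] and [Pi] are updated with the net of the capped
production rate and the activity-driven consumption rate (consumption
converts ATP -> ADP + Pi; production the reverse), then the AK/ArgK
equilibration redistributes the adenine and guanidino pools.  Spikes
deposit their instantaneous cost into per-component decay accumulators
at the grid point nearest their firing time.

Steps that would drive a concentration negative are subdivided locally
(up to 10 halvings) so that exhaustion scenarios degrade gracefully
instead of producing negative concentrations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._kernels import _equilibrate_kernel, _simulate_loop
from .core import (
    COMPONENTS,
    EquilibriumConstants,
    InitialConditions,
    InvalidParameterError,
    MetabolicState,
    TerminalParams,
    ThermoConstants,
    initial_state_from_equilibrium,
)
from .equilibration import (
    ConvergenceError,
    EquilibrationOptions,
    InfeasibleStateError,
)
from .production import (
    HillInverseTurnover,
    ProductionModel,
    build_production_model,
    cap_production,
    production_acceleration,
)
from .stimulus import FiringProtocol, SpikeTrain, consumption_rate, spike_times

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "StepSizeError",
    "VolatilitySummary",
    "step",
    "simulate",
    "compare_phosphagen",
    "volatility",
    "count_action_potentials",
]

CSV_COLUMNS = [
    "time_s", "atp_mM", "adp_mM", "amp_mM", "arg_mM", "argp_mM", "pi_mM",
    "consumption_mM_s", "production_mM_s", "es_per_mM", "atp_adp", "dG_kJ_mol",
]


class StepSizeError(RuntimeError):
    """A step drove a concentration negative even after local subdivision."""


@dataclass(frozen=True)
class SimulationConfig:
    """Everything one run needs.

    ``production=None`` builds a default model calibrated to the initial
    state; ``equil=None`` builds default options with the phosphagen
    enforced iff ``terminal.phosphagen_present``.  ``production_on`` /
    ``equilibration_on`` switch those processes off entirely (mainly for
    analytic checks).  ``t_end=None`` runs to the end of the protocol
    plus one full cycle of settling.
    """

    terminal: TerminalParams
    protocol: FiringProtocol
    dt: float = 1e-4
    t_end: float | None = None
    initial_state: MetabolicState | None = None
    production: ProductionModel | None = None
    equil: EquilibrationOptions | None = None
    k: EquilibriumConstants = field(default_factory=EquilibriumConstants)
    thermo: ThermoConstants = field(default_factory=ThermoConstants)
    record_stride: int = 10
    production_on: bool = True
    equilibration_on: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidParameterError("dt must be > 0")
        if self.record_stride < 1:
            raise InvalidParameterError("record_stride must be >= 1")
        min_tau = min(self.terminal.tau[c] for c in COMPONENTS)
        if self.dt > min_tau / 10.0:
            warnings.warn(
                f"dt={self.dt} exceeds min(tau)/10={min_tau / 10:.3g}; "
                "transients may be under-resolved", stacklevel=2)

    def resolved_initial_state(self) -> MetabolicState:
        if self.initial_state is not None:
            return self.initial_state
        return initial_state_from_equilibrium(InitialConditions(), self.k)

    def resolved_production(self) -> ProductionModel:
        if self.production is not None:
            return self.production
        return build_production_model(self.terminal, self.resolved_initial_state())

    def resolved_equil(self) -> EquilibrationOptions:
        if self.equil is not None:
            return self.equil
        return EquilibrationOptions(
            enforce_phosphagen=self.terminal.phosphagen_present)

    def resolved_t_end(self) -> float:
        if self.t_end is not None:
            return self.t_end
        return self.protocol.t_start + self.protocol.duration + self.protocol.full_cycle


@dataclass(frozen=True)
class VolatilitySummary:
    """Two volatility summaries of one recorded series.

    per_cycle_ptp: peak-to-trough excursion within each complete firing
    cycle; mean_ptp: their mean; detrended_std: standard deviation after
    removing a linear trend from the whole series.
    """

    per_cycle_ptp: np.ndarray
    mean_ptp: float
    detrended_std: float


@dataclass
class SimulationResult:
    """Recorded trajectory plus derived series.

    All series share the uniform recorded time grid.  ``free_energy`` is
    the signed dG (negative); headers of the CSV output state the sign
    convention.
    """

    time: np.ndarray
    states: np.ndarray           # (n, 6): atp, adp, amp, arg, argp, pi
    consumption: np.ndarray
    production: np.ndarray
    config: SimulationConfig

    @property
    def atp(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def adp(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def es(self) -> np.ndarray:
        return self.states[:, 0] / (self.states[:, 1] * self.states[:, 5])

    @property
    def atp_adp_ratio(self) -> np.ndarray:
        return self.states[:, 0] / self.states[:, 1]

    @property
    def free_energy(self) -> np.ndarray:
        th = self.config.thermo
        return th.delta_g0 + th.rt * np.log(
            self.states[:, 1] * self.states[:, 5] / self.states[:, 0])

    @property
    def production_acceleration(self) -> np.ndarray:
        dt_rec = self.time[1] - self.time[0]
        return production_acceleration(self.production, dt_rec)

    def state_at(self, i: int) -> MetabolicState:
        return MetabolicState.from_array(self.states[i])

    def volatility(self, series: np.ndarray) -> VolatilitySummary:
        p = self.config.protocol
        return volatility(self.time, series, p.full_cycle, p.t_start)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time,
            "atp_mM": self.states[:, 0],
            "adp_mM": self.states[:, 1],
            "amp_mM": self.states[:, 2],
            "arg_mM": self.states[:, 3],
            "argp_mM": self.states[:, 4],
            "pi_mM": self.states[:, 5],
            "consumption_mM_s": self.consumption,
            "production_mM_s": self.production,
            "es_per_mM": self.es,
            "atp_adp": self.atp_adp_ratio,
            "dG_kJ_mol": self.free_energy,
        })

    def to_csv(self, path, metadata_path=None) -> None:
        """Tidy CSV (dG_kJ_mol is signed, negative at rest) plus an
        optional JSON run-metadata document."""
        self.to_frame().to_csv(path, index=False)
        if metadata_path is not None:
            with open(metadata_path, "w") as fh:
                json.dump(self.run_metadata(), fh, indent=2)

    def run_metadata(self) -> dict:
        from . import __version__
        cfg = self.config
        t = cfg.terminal
        p = cfg.protocol
        return {
            "tool": "phosphagen",
            "version": __version__,
            "sign_convention": "dG_kJ_mol is signed (negative); available energy is |dG|",
            "dt_s": cfg.dt,
            "t_end_s": cfg.resolved_t_end(),
            "record_stride": cfg.record_stride,
            "terminal": {
                "name": t.name,
                "n_atp": dict(t.n_atp),
                "tau_s": dict(t.tau),
                "base_rate_mM_s": t.base_rate,
                "volume_um3": t.volume,
                "mito_density_pct": t.mito_density,
                "max_rate_per_density_mM_s_pct": t.max_rate_per_density,
                "phosphagen_present": t.phosphagen_present,
            },
            "protocol": {
                "rate_hz": p.rate, "duty_s": p.duty, "full_cycle_s": p.full_cycle,
                "n_cycles": p.n_cycles, "t_start_s": p.t_start,
                "include_endpoint": p.include_endpoint,
            },
            "equilibrium_constants": {"k_ad": cfg.k.k_ad, "k_ph": cfg.k.k_ph},
            "phosphagen_enforced": cfg.resolved_equil().enforce_phosphagen,
        }


def step(state: MetabolicState, t: float, cfg: SimulationConfig,
         train: SpikeTrain | None = None, dt: float | None = None) -> MetabolicState:
    """One operator-split step from time t: produce/consume, then equilibrate.

    Reference single-step entry point (the batch simulator carries decay
    accumulators instead of re-summing past spikes).  Consumption is
    evaluated at t over the full spike history; a step that would go
    negative is locally subdivided up to 10 times before raising
    :class:`StepSizeError`.  ``dt`` overrides the configured step (0 is
    allowed and is an identity up to equilibration).
    """
    if dt is None:
        dt = cfg.dt
    if train is None:
        train = spike_times(cfg.protocol)
    cons = consumption_rate(t, train, cfg.terminal)
    prod_model = cfg.resolved_production() if cfg.production_on else None
    equil_opt = cfg.resolved_equil()

    from .production import production_rate  # local to avoid cycle at import

    for attempt in range(11):
        n_sub = 1 << attempt
        h = dt / n_sub
        s = state
        ok = True
        for _ in range(n_sub):
            p = production_rate(s, prod_model) if prod_model is not None else 0.0
            net = p - cons
            atp = s.atp + h * net
            adp = s.adp - h * net
            pi = s.pi - h * net
            if atp < 0 or adp < 0 or pi < 0:
                ok = False
                break
            s = s.replace(atp=atp, adp=adp, pi=pi)
            if cfg.equilibration_on:
                from .equilibration import equilibrate
                s = equilibrate(s, cfg.k, equil_opt)
        if ok:
            return s
    raise StepSizeError(f"step at t={t:.6g}s drove a concentration negative")


def _spike_grid_indices(train: SpikeTrain, dt: float, n_steps: int) -> np.ndarray:
    idx = np.rint(train.times / dt).astype(np.int64)
    if idx.size and (idx[0] < 0 or idx[-1] > n_steps):
        raise InvalidParameterError("protocol spikes fall outside [0, t_end]")
    return idx


def simulate(cfg: SimulationConfig) -> SimulationResult:
    """Run a full protocol and return the recorded trajectory.

    Deterministic.  The default production model (a Hill turnover of the
    inverse energy state) runs through a compiled kernel; any other
    turnover callable runs through an equivalent pure-Python loop.
    """
    t_end = cfg.resolved_t_end()
    train = spike_times(cfg.protocol)
    if train.times.size and t_end < train.times[-1]:
        raise InvalidParameterError(
            f"t_end={t_end} does not cover the protocol (last spike "
            f"{train.times[-1]:.6g}s)")
    n_steps = int(np.ceil(round(t_end / cfg.dt) / cfg.record_stride)) * cfg.record_stride
    if n_steps == 0:
        raise InvalidParameterError("t_end too short for one step")
    spike_idx = _spike_grid_indices(train, cfg.dt, n_steps)

    state0 = cfg.resolved_initial_state()
    if cfg.production_on:
        prod = cfg.resolved_production()
    else:  # placeholder; the kernels never evaluate it with production off
        prod = ProductionModel(base_rate=0.0, base_es=1.0, max_rate=1.0)
    equil_opt = cfg.resolved_equil()

    heights = np.array([cfg.terminal.deposit_mm(c) / cfg.terminal.tau[c]
                        for c in COMPONENTS])
    decays = np.exp(-cfg.dt / np.array([cfg.terminal.tau[c] for c in COMPONENTS]))

    if isinstance(prod.turnover, HillInverseTurnover):
        rec_states, rec_cons, rec_prod, status, err_step = _simulate_loop(
            n_steps, cfg.dt, spike_idx, heights, decays, cfg.terminal.base_rate,
            state0.as_array(), cfg.k.k_ad, cfg.k.k_ph,
            equil_opt.enforce_phosphagen, cfg.equilibration_on,
            equil_opt.tol, equil_opt.max_iter,
            prod.base_es, prod.turnover.k_half, prod.turnover.h,
            prod.calibrated_base, prod.max_rate, prod.cap_exponent,
            cfg.production_on, cfg.record_stride,
        )
    else:
        rec_states, rec_cons, rec_prod, status, err_step = _simulate_python(
            n_steps, cfg, spike_idx, heights, decays, state0, prod, equil_opt)

    t_err = err_step * cfg.dt
    if status == 1:
        raise ConvergenceError(f"equilibration did not converge at t={t_err:.6g}s")
    if status == 2:
        raise InfeasibleStateError(f"non-positive ADP or Pi at t={t_err:.6g}s")
    if status == 3:
        raise StepSizeError(f"negative concentration at t={t_err:.6g}s "
                            "despite local step subdivision")

    time = np.arange(rec_states.shape[0]) * (cfg.dt * cfg.record_stride)
    return SimulationResult(time=time, states=rec_states, consumption=rec_cons,
                            production=rec_prod, config=cfg)


def _simulate_python(n_steps, cfg, spike_idx, heights, decays, state0, prod,
                     equil_opt):
    """Pure-Python twin of the compiled loop for arbitrary turnover callables."""
    n_rec = n_steps // cfg.record_stride + 1
    rec_states = np.empty((n_rec, 6))
    rec_cons = np.empty(n_rec)
    rec_prod = np.empty(n_rec)
    atp, adp, amp, arg, argp, pi = state0.as_array()
    acc = np.zeros(len(COMPONENTS))
    sp = 0
    pcc_base = prod.turnover(prod.base_es)
    rec = 0

    def prod_rate(a, d, q):
        es = a / (d * q)
        p = prod.calibrated_base * prod.turnover(es) / pcc_base
        return cap_production(p, prod.max_rate, prod.cap_exponent)

    for i in range(n_steps + 1):
        if i > 0:
            acc *= decays
        while sp < spike_idx.size and spike_idx[sp] == i:
            acc += heights
            sp += 1
        cons = cfg.terminal.base_rate + acc.sum()
        if adp <= 0 or pi <= 0:
            return rec_states, rec_cons, rec_prod, 2, i
        p = prod_rate(atp, adp, pi) if cfg.production_on else 0.0
        if i % cfg.record_stride == 0:
            rec_states[rec] = (atp, adp, amp, arg, argp, pi)
            rec_cons[rec] = cons
            rec_prod[rec] = p
            rec += 1
        if i == n_steps:
            break
        done = False
        for attempt in range(11):
            n_sub = 1 << attempt
            h = cfg.dt / n_sub
            ta, td, tm, tg, tgp, tpi = atp, adp, amp, arg, argp, pi
            feasible = True
            for s in range(n_sub):
                if s == 0 and attempt == 0:
                    ps = p
                else:
                    if td <= 0 or tpi <= 0:
                        feasible = False
                        break
                    ps = prod_rate(ta, td, tpi) if cfg.production_on else 0.0
                net = ps - cons
                ta += h * net
                td -= h * net
                tpi -= h * net
                if ta < 0 or td < 0 or tpi < 0:
                    feasible = False
                    break
                if cfg.equilibration_on:
                    ta, td, tm, tg, tgp, st, _, _, _ = _equilibrate_kernel(
                        ta, td, tm, tg, tgp, cfg.k.k_ad, cfg.k.k_ph,
                        equil_opt.enforce_phosphagen, equil_opt.tol,
                        equil_opt.max_iter)
                    if st != 0:
                        return rec_states, rec_cons, rec_prod, st, i
            if feasible:
                atp, adp, amp, arg, argp, pi = ta, td, tm, tg, tgp, tpi
                done = True
                break
        if not done:
            return rec_states, rec_cons, rec_prod, 3, i
    return rec_states, rec_cons, rec_prod, 0, n_steps


def compare_phosphagen(cfg: SimulationConfig) -> tuple[SimulationResult, SimulationResult]:
    """Run the same configuration with and without the phosphagen system.

    Both runs start from the same initial state (derived with the
    phosphagen present), matching the model's convention for a fair
    comparison.  Returns (with_phosphagen, without_phosphagen).
    """
    on = replace(cfg, equil=EquilibrationOptions(
        tol=cfg.resolved_equil().tol, max_iter=cfg.resolved_equil().max_iter,
        enforce_phosphagen=True))
    off = replace(cfg, equil=EquilibrationOptions(
        tol=cfg.resolved_equil().tol, max_iter=cfg.resolved_equil().max_iter,
        enforce_phosphagen=False))
    return simulate(on), simulate(off)


def volatility(time: np.ndarray, series: np.ndarray, full_cycle: float,
               t_start: float = 0.0) -> VolatilitySummary:
    """Per-cycle peak-to-trough excursions and the detrended overall SD.

    Cycles are the protocol's full cycles; only complete cycles inside
    the time range are summarized.  The model has no printed volatility
    formula, so both a cycle-resolved and a global summary are reported.
    """
    time = np.asarray(time, dtype=float)
    series = np.asarray(series, dtype=float)
    ptps = []
    c = 0
    while True:
        lo = t_start + c * full_cycle
        hi = lo + full_cycle
        if hi > time[-1] + 1e-12:
            break
        m = (time >= lo - 1e-12) & (time <= hi + 1e-12)
        if m.sum() >= 2:
            ptps.append(float(series[m].max() - series[m].min()))
        c += 1
    ptps_arr = np.array(ptps) if ptps else np.zeros(0)
    # detrended SD: remove a linear trend over the whole series
    a, b = np.polyfit(time, series, 1)
    resid = series - (a * time + b)
    return VolatilitySummary(
        per_cycle_ptp=ptps_arr,
        mean_ptp=float(ptps_arr.mean()) if ptps_arr.size else 0.0,
        detrended_std=float(resid.std()),
    )


def count_action_potentials(protocols: FiringProtocol | Sequence[FiringProtocol]) -> int:
    """Total spike count over one protocol or a sequence of protocols."""
    if isinstance(protocols, FiringProtocol):
        protocols = [protocols]
    return int(sum(p.n_spikes for p in protocols))
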