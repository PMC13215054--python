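"""Synthetic inputs with known ground truth for every pipeline stage.

The study's per-terminal energetic parameters (per-AP costs, decay
constants, base rate, volume) come from a companion data set that is not
distributed with this package, and its raw imaging/electrophysiology
traces are likewise unavailable.  This module generates stand-ins —
SYNTHETIC terminal parameter sets whose magnitudes are anchored to the
published context (mM-scale concentrations, production caps of
0.079/0.154 mM/s per 1% mitochondrial density, type-Ib mitochondrial
densities near 6.3%), ratiometric traces with programmed bleaching and
responses, and EJP/mEJP amplitude samples with a known quantal content —
so every analysis is testable against ground truth without a download.
Anyone holding real terminal parameters can load them through
:mod:`phosphagen.config` instead.

All generators are pure functions of their spec (including the seed) and
draw from numpy's PCG64 via ``default_rng`` for cross-platform
reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import COMPONENTS, InvalidParameterError, TerminalParams
from .traces import AmplitudeSamples, RatiometricTrace

__all__ = [
    "GeneratorSpec",
    "TerminalRanges",
    "TraceSpec",
    "AmplitudeSpec",
    "gen_terminal_params",
    "gen_ratiometric_trace",
    "gen_amplitude_samples",
]

# Synthetic per-AP cost (molecules) and decay-constant (s) ranges.
# These are NOT the companion study's values; they are order-of-magnitude
# plausible draws for a type-Ib larval motor-neuron terminal.
_DEFAULT_N_ATP = {
    "Na": (2.0e5, 6.0e5),
    "Ca": (0.5e5, 1.5e5),
    "NT1": (0.5e5, 1.5e5),
    "NT2": (2.0e4, 8.0e4),
    "NT3": (1.0e4, 3.0e4),
}
_DEFAULT_TAU = {
    "Na": (3.0, 8.0),
    "Ca": (0.3, 0.8),
    "NT1": (0.05, 0.15),
    "NT2": (0.5, 2.0),
    "NT3": (5.0, 15.0),
}


@dataclass(frozen=True)
class TerminalRanges:
    """Uniform draw bounds for each TerminalParams field."""

    n_atp: dict = field(default_factory=lambda: dict(_DEFAULT_N_ATP))
    tau: dict = field(default_factory=lambda: dict(_DEFAULT_TAU))
    base_rate: tuple = (0.03, 0.07)       # mM/s
    volume: tuple = (200.0, 400.0)        # um^3
    mito_density: tuple = (5.0, 7.0)      # %, bracketing the type-Ib values
    max_rate_per_density: float = 0.154   # mM/s per 1% density

    def __post_init__(self) -> None:
        for name in ("base_rate", "volume", "mito_density"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise InvalidParameterError(f"{name} bounds out of order")
        for c in COMPONENTS:
            if self.n_atp[c][0] > self.n_atp[c][1] or self.tau[c][0] > self.tau[c][1]:
                raise InvalidParameterError(f"bounds out of order for component {c}")


@dataclass(frozen=True)
class TraceSpec:
    """Programmed features of a synthetic ratiometric trace.

    Emulates the acquisition cadence of the imaging protocols (four
    ratio estimates per second by default).  The stimulus-locked response
    multiplies the numerator channel and peaks at exactly
    ``response_amplitude`` in dR/R units (negative for a dip); both
    channels share a monoexponential bleach of time constant
    ``tau_bleach``; gaussian noise of SD ``noise_sigma`` (intensity
    units) is added to every channel independently.
    """

    tau_bleach: float = 60.0       # s
    response_amplitude: float = 0.3
    rise: float = 1.0              # s
    decay: float = 5.0             # s
    noise_sigma: float = 2.0       # intensity units
    sampling_rate: float = 4.0     # Hz
    t_start: float = -30.0         # s (relative to stimulus onset at 0)
    t_end: float = 40.0            # s
    stim_duration: float = 10.0    # s
    baseline_num: float = 1000.0
    baseline_den: float = 1000.0
    background_level: float = 100.0

    def __post_init__(self) -> None:
        if self.tau_bleach <= 0 or self.rise <= 0 or self.decay <= 0:
            raise InvalidParameterError("time constants must be > 0")
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise_sigma must be >= 0")
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be > 0")


@dataclass(frozen=True)
class AmplitudeSpec:
    """Programmed EJP/mEJP sample properties.

    mEJPs are drawn from a zero-truncated normal with the given mean and
    CV; EJP amplitudes are built from the true quantal content and then
    distorted by the inverse non-linear summation correction so that
    :func:`phosphagen.traces.quantal_content` recovers the truth.
    Sample sizes default to the study's minima (10 EJPs, 30 mEJPs).
    """

    mejp_mean: float = 1.0     # mV
    cv: float = 0.3
    quantal_count: float = 25.0
    n_ejp: int = 10
    n_mejp: int = 30
    driving: float = 90.0      # mV

    def __post_init__(self) -> None:
        if self.mejp_mean <= 0 or self.quantal_count <= 0 or self.driving <= 0:
            raise InvalidParameterError("means, counts and driving must be > 0")
        if self.cv < 0:
            raise InvalidParameterError("cv must be >= 0")
        if self.n_ejp < 1 or self.n_mejp < 1:
            raise InvalidParameterError("need at least one sample of each kind")


@dataclass(frozen=True)
class GeneratorSpec:
    """Seeded specification for all three generators."""

    seed: int = 0
    terminal: TerminalRanges = field(default_factory=TerminalRanges)
    trace: TraceSpec = field(default_factory=TraceSpec)
    amplitudes: AmplitudeSpec = field(default_factory=AmplitudeSpec)


def _rng(spec: GeneratorSpec, stream: int) -> np.random.Generator:
    # independent deterministic streams per generator
    return np.random.default_rng((int(spec.seed), stream))


def gen_terminal_params(spec: GeneratorSpec, phosphagen_present: bool = True) -> TerminalParams:
    """Draw a synthetic terminal parameter set (uniform within bounds)."""
    r = spec.terminal
    rng = _rng(spec, 1)
    n_atp = {c: float(rng.uniform(*r.n_atp[c])) for c in COMPONENTS}
    tau = {c: float(rng.uniform(*r.tau[c])) for c in COMPONENTS}
    return TerminalParams(
        name=f"synthetic-seed{spec.seed}",
        n_atp=n_atp,
        tau=tau,
        base_rate=float(rng.uniform(*r.base_rate)),
        volume=float(rng.uniform(*r.volume)),
        mito_density=float(rng.uniform(*r.mito_density)),
        max_rate_per_density=r.max_rate_per_density,
        phosphagen_present=phosphagen_present,
    )


def _response_profile(t: np.ndarray, ts: TraceSpec) -> np.ndarray:
    """Stimulus-locked profile peaking at exactly 1 at the end of the train."""
    prof = np.zeros_like(t)
    during = (t >= 0) & (t <= ts.stim_duration)
    after = t > ts.stim_duration
    peak = 1.0 - np.exp(-ts.stim_duration / ts.rise)
    prof[during] = (1.0 - np.exp(-t[during] / ts.rise)) / peak
    prof[after] = np.exp(-(t[after] - ts.stim_duration) / ts.decay)
    return prof


def gen_ratiometric_trace(spec: GeneratorSpec) -> tuple[RatiometricTrace, dict]:
    """Synthetic two-channel trace plus its ground-truth record.

    The numerator fluorophore bleaches as exp(-(t - t_start)/tau_bleach)
    while the denominator is photostable, so the *ratio* decays with
    exactly tau_bleach — the regime the monoexponential ratio correction
    addresses (a common-mode bleach would cancel in the ratio).  The
    numerator additionally carries the programmed stimulus-locked
    response; two constant background regions per channel receive
    independent noise.  Returns ``(trace, truth)`` with
    ``truth = {"tau_bleach", "peak_dr_over_r"}``.
    """
    ts = spec.trace
    rng = _rng(spec, 2)
    n = int(round((ts.t_end - ts.t_start) * ts.sampling_rate)) + 1
    t = ts.t_start + np.arange(n) / ts.sampling_rate
    bleach = np.exp(-(t - ts.t_start) / ts.tau_bleach)
    response = 1.0 + ts.response_amplitude * _response_profile(t, ts)

    sig_num = ts.baseline_num * bleach * response + ts.background_level
    sig_den = np.full(n, ts.baseline_den) + ts.background_level
    bg_num = np.full((2, n), ts.background_level)
    bg_den = np.full((2, n), ts.background_level)

    if ts.noise_sigma > 0:
        sig_num = sig_num + rng.normal(0, ts.noise_sigma, n)
        sig_den = sig_den + rng.normal(0, ts.noise_sigma, n)
        bg_num = bg_num + rng.normal(0, ts.noise_sigma, (2, n))
        bg_den = bg_den + rng.normal(0, ts.noise_sigma, (2, n))

    trace = RatiometricTrace(
        time=t, signal_num=sig_num, signal_den=sig_den,
        background_num=bg_num, background_den=bg_den,
        stim_start=0.0, stim_end=ts.stim_duration,
    )
    truth = {"tau_bleach": ts.tau_bleach, "peak_dr_over_r": ts.response_amplitude}
    return trace, truth


def _truncated_normal(rng, mean, cv, size):
    if cv == 0:
        return np.full(size, mean, dtype=float)
    out = rng.normal(mean, cv * mean, size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, cv * mean, int(bad.sum()))
        bad = out <= 0
    return out


def gen_amplitude_samples(spec: GeneratorSpec) -> tuple[AmplitudeSamples, float]:
    """Synthetic EJP/mEJP amplitudes plus the true quantal content.

    The true corrected mean EJP is quantal_count · mejp_mean (population
    mean); observed EJPs are drawn around its inverse-corrected value
    v = C/(1 + C/driving), so the analysis-side correction restores C.
    With cv = 0 the recovery is exact; with noise it is exact in
    expectation up to sampling error.
    """
    a = spec.amplitudes
    rng = _rng(spec, 3)
    mejp = _truncated_normal(rng, a.mejp_mean, a.cv, a.n_mejp)
    c_true = a.quantal_count * a.mejp_mean
    v = c_true / (1.0 + c_true / a.driving)
    ejp = _truncated_normal(rng, v, a.cv, a.n_ejp)
    samples = AmplitudeSamples(ejp=ejp, mejp=mejp, driving=a.driving)
    return samples, a.quantal_count
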