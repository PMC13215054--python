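"""Processing of ratiometric fluorescence traces and junctional potentials.

Covers the study's standard reduction steps: background-subtracted
two-channel ratios expressed as dR/R relative to the pre-stimulus
baseline, monoexponential photobleach correction fitted to pre-stimulus
ratio estimates, unscaled median-absolute-deviation outlier screening,
and quantal content from evoked/miniature junctional potential
amplitudes with the Martin non-linear summation correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .core import InvalidParameterError

__all__ = [
    "RatiometricTrace",
    "AmplitudeSamples",
    "BleachCorrection",
    "DegenerateTraceError",
    "CorrectionDomainError",
    "ratio_series",
    "delta_r_over_r",
    "bleach_correct",
    "mad_outlier_flags",
    "quantal_content",
]


class DegenerateTraceError(ValueError):
    """Background exceeds signal in the denominator channel."""


class CorrectionDomainError(ValueError):
    """Mean EJP amplitude at or above the driving force."""


@dataclass(frozen=True)
class RatiometricTrace:
    """Two-channel fluorescence time series with background regions.

    signal_num / signal_den are the bouton-ROI mean intensities of the
    numerator and denominator channels; background_num / background_den
    hold one or more background-ROI series per channel (1-D for a single
    region, 2-D ``(n_regions, n_samples)`` otherwise).  The stimulus runs
    from stim_start to stim_end (s).
    """

    time: np.ndarray
    signal_num: np.ndarray
    signal_den: np.ndarray
    background_num: np.ndarray
    background_den: np.ndarray
    stim_start: float
    stim_end: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        for name in ("signal_num", "signal_den", "background_num", "background_den"):
            a = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if a.shape[-1] != t.size:
                raise InvalidParameterError(f"{name} length does not match time")
            object.__setattr__(self, name, a if name.startswith("background") else a[0])
        object.__setattr__(self, "time", t)
        if not (t[0] <= self.stim_start < self.stim_end <= t[-1] + 1e-9):
            raise InvalidParameterError("stimulus window must lie within the time range")

    @property
    def pre_stimulus(self) -> np.ndarray:
        return self.time < self.stim_start


def ratio_series(trace: RatiometricTrace) -> np.ndarray:
    """Background-corrected ratio R(t).

    The per-frame average of the background regions is subtracted from
    the bouton signal in each channel before the ratio is formed.
    """
    num = trace.signal_num - trace.background_num.mean(axis=0)
    den = trace.signal_den - trace.background_den.mean(axis=0)
    if np.any(den <= 0):
        raise DegenerateTraceError("background >= signal in denominator channel")
    return num / den


def delta_r_over_r(trace: RatiometricTrace, ratio: np.ndarray | None = None) -> np.ndarray:
    """dR/R: the ratio relative to its pre-stimulus mean, minus one.

    ``ratio`` may be a pre-computed (e.g. bleach-corrected) ratio series,
    in which case NaN samples (outside a bleach-correction window) are
    ignored in the baseline and propagate to the output; otherwise the
    raw background-corrected ratio is used.  The output is invariant to
    any common gain applied to both channels and averages to ~0 before
    the stimulus.
    """
    r = ratio_series(trace) if ratio is None else np.asarray(ratio, dtype=float)
    pre = trace.pre_stimulus & np.isfinite(r)
    if not pre.any():
        raise InvalidParameterError("no (finite) pre-stimulus samples")
    r_rest = r[pre].mean()
    if r_rest == 0:
        raise DegenerateTraceError("zero pre-stimulus ratio")
    return r / r_rest - 1.0


@dataclass(frozen=True)
class BleachCorrection:
    """Result of the monoexponential bleach correction.

    ``corrected`` equals the input ratio divided by the fitted curve
    inside the correction window (re-normalized so the pre-stimulus mean
    is 1); outside the window (``~window_mask``) it is NaN — those
    samples are not corrected and must not be mixed with corrected ones.
    ``converged`` is False when the fit failed, in which case
    ``corrected`` is the uncorrected input everywhere.
    """

    corrected: np.ndarray
    tau: float
    amplitude: float
    offset: float
    converged: bool
    window_mask: np.ndarray


def bleach_correct(
    time: np.ndarray,
    ratio: np.ndarray,
    stim_start: float,
    pre_window: float = 20.0,
    window: tuple[float, float] = (-10.0, 40.0),
    with_offset: bool = True,
) -> BleachCorrection:
    """Fit a monoexponential to pre-stimulus ratio estimates and divide it out.

    The model a·exp(-t/tau) (+ c when ``with_offset``) is least-squares
    fitted to the ``pre_window`` seconds of ratio estimates preceding the
    stimulus, initialized from a log-linear regression.  The fitted curve
    then corrects the ratio between ``window[0]`` and ``window[1]``
    seconds relative to stimulus onset (defaults -10 to 40 s); the
    corrected series is re-normalized to a pre-stimulus mean of 1.  A
    non-convergent fit returns the input unchanged with
    ``converged=False`` and a warning.
    """
    time = np.asarray(time, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    fit_mask = (time >= stim_start - pre_window) & (time < stim_start)
    if fit_mask.sum() < (3 if with_offset else 2):
        raise InvalidParameterError("pre-stimulus window has too few samples")
    win_mask = (time >= stim_start + window[0]) & (time <= stim_start + window[1])

    t_fit = time[fit_mask]
    y_fit = ratio[fit_mask]

    # log-linear initialization on (ratio - floor)
    floor = y_fit.min()
    c0 = 0.9 * floor if with_offset else 0.0
    y_pos = np.clip(y_fit - c0, 1e-12 * max(abs(floor), 1.0), None)
    slope, intercept = np.polyfit(t_fit, np.log(y_pos), 1)
    tau0 = -1.0 / slope if slope < 0 else 10.0 * (t_fit[-1] - t_fit[0] + 1e-9)
    a0 = np.exp(intercept)

    try:
        if with_offset:
            def model(t, a, tau, c):
                return a * np.exp(-t / tau) + c
            popt, _ = curve_fit(model, t_fit, y_fit, p0=(a0, tau0, c0),
                                bounds=([0, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                                maxfev=10000)
            a, tau, c = popt
        else:
            def model(t, a, tau):
                return a * np.exp(-t / tau)
            popt, _ = curve_fit(model, t_fit, y_fit, p0=(a0, tau0),
                                bounds=([0, 1e-9], [np.inf, np.inf]), maxfev=10000)
            a, tau = popt
            c = 0.0
        fitted = a * np.exp(-time / tau) + c
        if np.any(fitted[win_mask] <= 0):
            raise RuntimeError("fitted bleach curve non-positive in window")
    except RuntimeError as exc:
        warnings.warn(f"bleach fit did not converge ({exc}); returning "
                      "uncorrected series", stacklevel=2)
        return BleachCorrection(corrected=ratio.copy(), tau=np.nan, amplitude=np.nan,
                                offset=np.nan, converged=False, window_mask=win_mask)

    corrected = np.full_like(ratio, np.nan)
    corrected[win_mask] = ratio[win_mask] / fitted[win_mask]
    pre_in_win = win_mask & (time < stim_start)
    norm = corrected[pre_in_win].mean() if pre_in_win.any() else 1.0
    corrected[win_mask] /= norm
    return BleachCorrection(corrected=corrected, tau=float(tau), amplitude=float(a),
                            offset=float(c), converged=True, window_mask=win_mask)


def mad_outlier_flags(values) -> np.ndarray:
    """Flag values beyond median ± 3·MAD (MAD unscaled; bounds inclusive).

    MAD is the median of absolute deviations from the median, used
    directly (no 1.4826 normal-consistency factor).  Values exactly on a
    bound are kept.  A zero MAD (more than half the values identical)
    flags everything different from the median and warns.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InvalidParameterError("need at least 3 values for the MAD screen")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        if np.any(x != med):
            warnings.warn("MAD is zero; flagging every value different from "
                          "the median", stacklevel=2)
        return x != med
    return (x < med - 3.0 * mad) | (x > med + 3.0 * mad)


@dataclass(frozen=True)
class AmplitudeSamples:
    """Evoked (EJP) and miniature (mEJP) amplitude samples in mV.

    ``driving`` is the effective driving force (mV) for the non-linear
    summation correction; it must be supplied explicitly.
    """

    ejp: np.ndarray
    mejp: np.ndarray
    driving: float

    def __post_init__(self) -> None:
        e = np.asarray(self.ejp, dtype=float)
        m = np.asarray(self.mejp, dtype=float)
        if e.size == 0 or m.size == 0:
            raise InvalidParameterError("ejp and mejp samples must be non-empty")
        if np.any(e <= 0) or np.any(m <= 0):
            raise InvalidParameterError("amplitudes must be > 0")
        if self.driving <= e.max():
            raise InvalidParameterError("driving force must exceed every EJP")
        object.__setattr__(self, "ejp", e)
        object.__setattr__(self, "mejp", m)


def quantal_content(s: AmplitudeSamples) -> float:
    """Quantal content: corrected mean EJP over mean mEJP.

    The mean EJP amplitude is corrected for non-linear summation with the
    Martin-type factor (unit correction constant),
    v_corr = v / (1 - v/driving); mEJP amplitudes are never corrected.
    """
    v = float(np.mean(s.ejp))
    if v >= s.driving:
        raise CorrectionDomainError("mean EJP amplitude >= driving force")
    corrected = v / (1.0 - v / s.driving)
    return corrected / float(np.mean(s.mejp))
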