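"""Per-channel signal conditioning.

The chain applied to every sensor channel is

1. zero-phase low-pass Butterworth filter (default 10 Hz, order 2),
2. ordinary least squares of the filtered sensor against the filtered
   isosbestic control, giving the motion/bleaching baseline
   ``F_fit = a * isosbestic + b``,
3. fractional change ``DF/F = (F_filtered - F_fit) / F_fit``,
4. ``Z = (DF/F - mu) / sigma`` with mu/sigma over the full recording
   (default) or a caller-chosen baseline window.

The isosbestic channel is excited at a wavelength where the sensors are
insensitive to ligand/calcium binding, so variance it shares with a sensor
channel is non-neuronal (motion, bleaching, fiber bending) and is removed by
the regression. One isosbestic trace serves both sensor channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import ISOSBESTIC, PhotometryRecording
from .errors import DegenerateDataError, ParameterError, ValidationError

__all__ = [
    "RegressionFit",
    "ProcessedChannel",
    "lowpass_filter",
    "fit_isosbestic",
    "compute_dff",
    "zscore_trace",
    "preprocess_recording",
]


@dataclass
class RegressionFit:
    """OLS fit of a sensor trace on the isosbestic regressor.

    ``fitted = a * isosbestic + b`` is the predicted non-neuronal baseline.
    """

    a: float
    b: float
    fitted: np.ndarray


@dataclass
class ProcessedChannel:
    """Full preprocessing stack for one channel.

    For the isosbestic role only ``raw`` and ``filtered`` are populated (it is
    the regressor, not a signal), so ``fit``/``dff``/``zscore`` are None.
    """

    role: str
    time: np.ndarray
    raw: np.ndarray
    filtered: np.ndarray
    fit: RegressionFit | None = None
    dff: np.ndarray | None = None
    zscore: np.ndarray | None = None
    mu: float | None = None
    sigma: float | None = None
    normalization_window: object = "full"
    sampling_rate: float = field(default=0.0)

    @property
    def dff_percent(self) -> np.ndarray | None:
        """DF/F expressed in percent (100 x DF/F)."""
        return None if self.dff is None else 100.0 * self.dff


def lowpass_filter(
    trace: np.ndarray,
    sampling_rate: float,
    cutoff: float = 10.0,
    order: int = 2,
    zero_phase: bool = True,
) -> np.ndarray:
    """Low-pass Butterworth filter with unit DC gain.

    Zero-phase (forward-backward) application is the default so that event
    alignment at time point 0 is not biased by group delay; the effective
    magnitude response is then |H|^2 of the single-pass filter.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ParameterError("trace must be 1-D")
    if not 0 < cutoff < sampling_rate / 2:
        raise ParameterError(
            f"cutoff must lie in (0, Nyquist={sampling_rate / 2} Hz), got {cutoff}"
        )
    if order < 1:
        raise ParameterError("filter order must be >= 1")
    if trace.size <= 3 * order:
        raise ParameterError(f"trace too short to filter: {trace.size} <= 3 x order")
    b, a = signal.butter(order, cutoff, btype="low", fs=sampling_rate)
    if zero_phase:
        padlen = min(3 * (order + 1), trace.size - 1)
        return signal.filtfilt(b, a, trace, padlen=padlen)
    return signal.lfilter(b, a, trace)


def fit_isosbestic(filtered_sensor: np.ndarray, isosbestic: np.ndarray) -> RegressionFit:
    """Two-parameter OLS of the filtered sensor on the filtered isosbestic.

    Closed form: a = cov(iso, sensor) / var(iso), b = mean(sensor) - a * mean(iso).
    """
    s = np.asarray(filtered_sensor, dtype=float)
    x = np.asarray(isosbestic, dtype=float)
    if s.shape != x.shape or s.ndim != 1:
        raise ValidationError(f"shape mismatch: sensor {s.shape} vs isosbestic {x.shape}")
    xm = x.mean()
    var = float(np.mean((x - xm) ** 2))
    if var == 0.0 or np.ptp(x) == 0.0:
        raise DegenerateDataError("isosbestic trace is constant; regression is undefined")
    a = float(np.mean((x - xm) * (s - s.mean())) / var)
    b = float(s.mean() - a * xm)
    return RegressionFit(a=a, b=b, fitted=a * x + b)


def compute_dff(
    filtered: np.ndarray, fit: RegressionFit, floor: float | None = None
) -> np.ndarray:
    """Fractional fluorescence change relative to the fitted baseline.

    ``floor`` guards the division; it defaults to 1e-12 x median(|fitted|)
    because demodulated fluorescence is strictly positive and a zero baseline
    would make DF/F undefined.
    """
    filtered = np.asarray(filtered, dtype=float)
    fitted = np.asarray(fit.fitted, dtype=float)
    if filtered.shape != fitted.shape:
        raise ValidationError("filtered and fitted traces differ in length")
    if floor is None:
        floor = 1e-12 * float(np.median(np.abs(fitted)))
    bad = np.abs(fitted) < floor
    if np.any(bad):
        raise DegenerateDataError(
            f"fitted baseline below floor ({floor:g}) at sample {int(np.argmax(bad))}"
        )
    return (filtered - fitted) / fitted


def zscore_trace(
    dff: np.ndarray,
    window: object = "full",
    time: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float]:
    """Standardize a DF/F trace.

    mu and sigma (population standard deviation, divide by n) are computed over
    ``window`` — "full" or a ``[t0, t1]`` baseline in seconds (requires
    ``time``) — and applied to the whole trace, so a baseline free of
    stimulation can anchor the scale while the entire trace stays comparable.
    """
    dff = np.asarray(dff, dtype=float)
    if isinstance(window, str):
        if window != "full":
            raise ParameterError(f"window must be 'full' or [t0, t1], got {window!r}")
        sel = dff
    else:
        t0, t1 = float(window[0]), float(window[1])
        if time is None:
            raise ParameterError("a [t0, t1] window requires the time array")
        time = np.asarray(time, dtype=float)
        if t0 >= t1 or t1 <= time[0] or t0 >= time[-1]:
            raise ParameterError(
                f"window [{t0}, {t1}] outside the time span [{time[0]}, {time[-1]}]"
            )
        mask = (time >= t0) & (time < t1)
        if not mask.any():
            raise ParameterError(f"window [{t0}, {t1}] contains no samples")
        sel = dff[mask]
    if np.ptp(sel) == 0.0:
        raise DegenerateDataError("zero variance in the normalization window")
    mu = float(sel.mean())
    sigma = float(sel.std(ddof=0))
    if sigma == 0.0:
        raise DegenerateDataError("zero variance in the normalization window")
    return (dff - mu) / sigma, mu, sigma


def preprocess_recording(
    rec: PhotometryRecording,
    *,
    cutoff: float = 10.0,
    order: int = 2,
    zero_phase: bool = True,
    zscore_window: object = "full",
    dff_floor: float | None = None,
    regression: bool = True,
) -> dict[str, ProcessedChannel]:
    """Run the full chain on every sensor channel of a recording.

    Returns a mapping role -> ProcessedChannel that includes the (filtered but
    not DF/F'd) isosbestic channel. All sensor channels share the single
    filtered isosbestic regressor. With ``regression=False`` the fitted
    baseline is the constant mean of the filtered trace instead (for rigs
    without a usable isosbestic).
    """
    if ISOSBESTIC not in rec.channels and regression:
        raise ValidationError("recording has no isosbestic_405 channel")
    sensors = rec.sensor_roles()
    if not sensors:
        raise ValidationError("recording has no sensor channel")

    out: dict[str, ProcessedChannel] = {}
    iso_filtered = None
    if ISOSBESTIC in rec.channels:
        try:
            iso_filtered = lowpass_filter(
                rec.channels[ISOSBESTIC], rec.sampling_rate, cutoff, order, zero_phase
            )
        except Exception as exc:
            raise type(exc)(f"channel {ISOSBESTIC}: {exc}") from exc
        out[ISOSBESTIC] = ProcessedChannel(
            role=ISOSBESTIC,
            time=rec.time,
            raw=rec.channels[ISOSBESTIC],
            filtered=iso_filtered,
            sampling_rate=rec.sampling_rate,
        )

    for role in sensors:
        try:
            filtered = lowpass_filter(
                rec.channels[role], rec.sampling_rate, cutoff, order, zero_phase
            )
            if regression:
                fit = fit_isosbestic(filtered, iso_filtered)
            else:
                fit = RegressionFit(a=0.0, b=float(filtered.mean()),
                                    fitted=np.full_like(filtered, filtered.mean()))
            dff = compute_dff(filtered, fit, floor=dff_floor)
            z, mu, sigma = zscore_trace(dff, zscore_window, rec.time)
        except Exception as exc:
            raise type(exc)(f"channel {role}: {exc}") from exc
        out[role] = ProcessedChannel(
            role=role,
            time=rec.time,
            raw=rec.channels[role],
            filtered=filtered,
            fit=fit,
            dff=dff,
            zscore=z,
            mu=mu,
            sigma=sigma,
            normalization_window=zscore_window,
            sampling_rate=rec.sampling_rate,
        )
    return out
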