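"""Fractional amplitude of low-frequency fluctuations (fALFF).

fALFF summarizes, per voxel, how much of the BOLD signal's spectral
amplitude falls inside a low-frequency band (0.01-0.08 Hz by default):
the sum of Fourier amplitudes over in-band frequencies divided by the
sum over all positive frequencies. Values lie in [0, 1], are invariant
to rescaling of the series and to added constants (the DC component is
excluded), and act as a proxy for local metabolic activity.

Nuisance cleaning (mean white-matter and CSF signals plus the 24-column
Friston motion expansion) is ordinary per-voxel OLS residualization and
is applied before the spectral ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "TimeSeriesSet",
    "FrequencyBand",
    "DEFAULT_BAND",
    "build_friston24",
    "nuisance_regress_timeseries",
    "compute_falff",
]


@dataclass
class FrequencyBand:
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")

    def validate_for_tr(self, tr_seconds: float) -> None:
        nyquist = 1.0 / (2.0 * tr_seconds)
        if self.high_hz > nyquist + 1e-12:
            raise ValueError(
                f"band upper edge {self.high_hz} Hz exceeds Nyquist {nyquist} Hz "
                f"for TR = {tr_seconds} s"
            )


DEFAULT_BAND = FrequencyBand(0.01, 0.08)


@dataclass
class TimeSeriesSet:
    """Voxel x time BOLD data plus optional nuisance series."""

    series: np.ndarray  # voxels x timepoints
    tr_seconds: float
    motion6: np.ndarray | None = None  # timepoints x 6
    wm_signal: np.ndarray | None = None
    csf_signal: np.ndarray | None = None

    def __post_init__(self):
        self.series = np.atleast_2d(np.asarray(self.series, dtype=float))
        if self.series.shape[1] < 16:
            raise ValueError("need at least 16 time points")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_voxels(self) -> int:
        return self.series.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.series.shape[1]

    def nuisance_regressors(self) -> np.ndarray | None:
        """Standard nuisance set: Friston-24 motion expansion + WM + CSF means."""
        cols = []
        if self.motion6 is not None:
            cols.append(build_friston24(self.motion6))
        if self.wm_signal is not None:
            cols.append(np.asarray(self.wm_signal, dtype=float).reshape(-1, 1))
        if self.csf_signal is not None:
            cols.append(np.asarray(self.csf_signal, dtype=float).reshape(-1, 1))
        if not cols:
            return None
        return np.hstack(cols)


def build_friston24(motion6: np.ndarray) -> np.ndarray:
    """Expand 6 rigid-body motion parameters into the Friston-24 set.

    Columns 0-5 are the parameters R(t), 6-11 the one-volume lags R(t-1)
    (zero at t = 0), 12-17 the squares R(t)^2 and 18-23 the lagged
    squares R(t-1)^2.
    """
    R = np.asarray(motion6, dtype=float)
    if R.ndim != 2 or R.shape[1] != 6:
        raise ValueError("motion parameters must be a time x 6 array")
    lag = np.vstack([np.zeros((1, 6)), R[:-1]])
    return np.hstack([R, lag, R**2, lag**2])


def nuisance_regress_timeseries(ts: TimeSeriesSet, regressors: np.ndarray) -> TimeSeriesSet:
    """Per-voxel OLS residuals of the series on intercept + regressors."""
    Z = np.asarray(regressors, dtype=float)
    if Z.ndim == 1:
        Z = Z.reshape(-1, 1)
    if Z.shape[0] != ts.n_volumes:
        raise ValueError("regressor rows must equal the number of time points")
    X = np.column_stack([np.ones(ts.n_volumes), Z])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"nuisance design is rank deficient (rank {rank} of {X.shape[1]} columns)"
        )
    beta, *_ = np.linalg.lstsq(X, ts.series.T, rcond=None)
    resid = ts.series.T - X @ beta
    return TimeSeriesSet(resid.T, ts.tr_seconds, ts.motion6, ts.wm_signal, ts.csf_signal)


def compute_falff(
    ts: TimeSeriesSet,
    band: FrequencyBand = DEFAULT_BAND,
    ratio: str = "amplitude_sum",
    detrend: bool = False,
) -> np.ndarray:
    """fALFF per voxel: in-band spectral amplitude over total amplitude.

    Each series is demeaned (optionally linearly detrended — note that
    detrending a trend-free series injects a small broadband amplitude
    that lowers the ratio, so it is off by default), Fourier
    transformed, and the amplitude spectrum ``|F(f)|`` evaluated at the
    positive DFT frequencies. ``ratio="amplitude_sum"`` (the convention
    of the resting-state toolbox lineage) returns
    ``sum(a_f, f in band) / sum(a_f, f > 0)`` with band edges inclusive;
    ``ratio="rms"`` returns the root-mean-square ratio
    ``sqrt(mean in-band power) / sqrt(mean total power)`` instead.
    Voxels with zero total amplitude are returned as NaN.
    """
    band.validate_for_tr(ts.tr_seconds)
    X = ts.series - ts.series.mean(axis=1, keepdims=True)
    if detrend:
        X = signal.detrend(X, axis=1, type="linear")
    amp = np.abs(np.fft.rfft(X, axis=1))
    freqs = np.fft.rfftfreq(ts.n_volumes, d=ts.tr_seconds)
    positive = freqs > 0
    in_band = positive & (freqs >= band.low_hz - 1e-12) & (freqs <= band.high_hz + 1e-12)
    if ratio == "amplitude_sum":
        num = amp[:, in_band].sum(axis=1)
        den = amp[:, positive].sum(axis=1)
    elif ratio == "rms":
        num = np.sqrt((amp[:, in_band] ** 2).mean(axis=1)) if in_band.any() else np.zeros(ts.n_voxels)
        den = np.sqrt((amp[:, positive] ** 2).mean(axis=1))
    else:
        raise ValueError(f"unknown ratio convention: {ratio!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out
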