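"""Signal conditioning before connectivity estimation.

Fixed order: per-ROI linear detrend, regression of the signal common to
all ROIs, zero-phase band-pass.  Detrend and common-signal regression
are least-squares projections (idempotent, linear); the band-pass is a
4th-order Butterworth applied forward-backward so it introduces no
group delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as spsig

from .timeseries import RoiTimeSeriesSet


@dataclass
class PreprocessConfig:
    """Which conditioning steps to run and the band edges in Hz.

    ``regress_common`` can be switched off to reproduce the
    sensitivity analysis without common-signal removal.  When
    ``cap_high_at_nyquist`` is set, an upper band edge at or above the
    Nyquist frequency is lowered to 99% of Nyquist (the filter then
    acts as a high-pass at ``low_hz``) instead of erroring.
    """

    detrend: bool = True
    regress_common: bool = True
    bandpass: bool = True
    low_hz: float = 0.018
    high_hz: float = 0.26
    order: int = 4
    design: str = "projection"
    cap_high_at_nyquist: bool = True


def detrend_linear(signal: np.ndarray) -> np.ndarray:
    """Residual of the least-squares intercept-plus-slope fit.

    Works on a 1-D signal or column-wise on a 2-D (time x ROI) array.
    The output has zero mean and is orthogonal to a linear ramp.
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 time points to detrend, got {n}")
    return spsig.detrend(signal, axis=0, type="linear")


def regress_common_signal(matrix: np.ndarray) -> np.ndarray:
    """Remove the across-ROI mean time course from every column.

    The common signal is the per-time-point mean of the input columns;
    each column is replaced by its residual from a least-squares
    regression on [intercept, common signal].  Residuals are exactly
    uncorrelated with the common signal.  If the common signal is
    constant (zero variance) the input is returned unchanged with a
    warning: there is nothing to regress out.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 ROI columns")
    common = matrix.mean(axis=1)
    centered = common - common.mean()
    denom = centered @ centered
    # relative guard: a common signal at numerical-noise level (e.g. after a
    # previous regression) must not re-fire the regression
    scale = np.mean(matrix.var(axis=0))
    if denom <= max(1e-12 * scale * matrix.shape[0], 1e-300):
        warnings.warn("common signal has (near-)zero variance; skipping regression")
        return matrix.copy()
    demeaned = matrix - matrix.mean(axis=0, keepdims=True)
    beta = (centered @ demeaned) / denom
    return demeaned - np.outer(centered, beta)


def bandpass(
    signal: np.ndarray,
    low_hz: float,
    high_hz: float,
    tr: float,
    order: int = 4,
    design: str = "projection",
) -> np.ndarray:
    """Zero-phase band-pass of a 1-D signal or 2-D (time x ROI) array.

    The default ``design="projection"`` removes, by least squares, the
    out-of-band Fourier modes together with an intercept and a linear
    ramp.  This is an orthogonal projection: exactly zero-phase, unit
    passband gain, and idempotent (refiltering is a no-op), which suits
    short records where a recursive filter's transition bands would
    keep eroding signal on reapplication.  ``design="butterworth"``
    gives the classical ``order``-th-order Butterworth applied
    forward-backward with reflect padding.
    """
    signal = np.asarray(signal, dtype=float)
    nyquist = 0.5 / tr
    if not (0.0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"upper band edge {high_hz} Hz is at or above Nyquist ({nyquist} Hz) for TR={tr}s"
        )
    if design == "butterworth":
        sos = spsig.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr, output="sos")
        n = signal.shape[0]
        padlen = min(3 * (2 * order + 1), n - 1)
        return spsig.sosfiltfilt(sos, signal, axis=0, padtype="even", padlen=padlen)
    if design != "projection":
        raise ValueError("design must be 'projection' or 'butterworth'")

    n = signal.shape[0]
    freqs = np.fft.rfftfreq(n, d=tr)
    excluded = np.flatnonzero((freqs < low_hz) | (freqs > high_hz))
    t = np.arange(n, dtype=float)
    columns = [np.ones(n), t - t.mean()]
    for k in excluded:
        if k == 0:
            continue  # DC is the intercept column
        phase = 2.0 * np.pi * k * t / n
        columns.append(np.cos(phase))
        if k != n - k:  # Nyquist bin has no sine component
            columns.append(np.sin(phase))
    basis = np.column_stack(columns)
    q, _ = np.linalg.qr(basis)
    flat = signal if signal.ndim == 2 else signal[:, None]
    residual = flat - q @ (q.T @ flat)
    return residual if signal.ndim == 2 else residual[:, 0]


def extract_roi_signal(
    volume_series: np.ndarray,
    center_index: tuple[int, int, int],
    half_width: int = 2,
) -> np.ndarray:
    """Average a detrended voxel cube into one ROI signal.

    ``volume_series`` is a 4-D array (time, x, y, z); the cube spans
    ``center +/- half_width`` along each spatial axis (default 5x5x5 =
    125 voxels).  Each voxel is linearly detrended before averaging,
    mirroring detrend-then-average ROI extraction.
    """
    volume_series = np.asarray(volume_series, dtype=float)
    if volume_series.ndim != 4:
        raise ValueError("volume_series must be 4-D (time, x, y, z)")
    cx, cy, cz = center_index
    shape = volume_series.shape[1:]
    lo = (cx - half_width, cy - half_width, cz - half_width)
    hi = (cx + half_width, cy + half_width, cz + half_width)
    if min(lo) < 0 or any(h >= s for h, s in zip(hi, shape)):
        raise ValueError(
            f"ROI cube around center {center_index} (half-width {half_width}) "
            f"extends outside volume bounds {shape}"
        )
    cube = volume_series[
        :, lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1
    ].reshape(volume_series.shape[0], -1)
    return detrend_linear(cube).mean(axis=1)


def preprocess_set(raw: RoiTimeSeriesSet, config: PreprocessConfig | None = None) -> RoiTimeSeriesSet:
    """Run the configured conditioning steps in fixed order.

    Steps run as detrend -> common-signal regression -> band-pass; the
    returned set's ``processing`` metadata records exactly which steps
    ran (including the band actually used).  Column order and names are
    never changed.
    """
    if config is None:
        config = PreprocessConfig()
    data = raw.data
    steps: list[str] = []
    if config.detrend:
        data = detrend_linear(data)
        steps.append("detrend_linear")
    if config.regress_common:
        data = regress_common_signal(data)
        steps.append("regress_common_signal")
    if config.bandpass:
        nyquist = 0.5 / raw.tr
        high = config.high_hz
        if high >= nyquist and config.cap_high_at_nyquist:
            high = 0.99 * nyquist
        data = bandpass(data, config.low_hz, high, raw.tr, order=config.order, design=config.design)
        steps.append(f"bandpass[{config.low_hz:g}-{high:g}Hz,{config.design}]")
    return raw.copy_with(data, steps)
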