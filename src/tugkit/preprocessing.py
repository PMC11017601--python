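"""Zero-lag low-pass filtering of the sensor channels.

The protocol filters every channel with a fourth-order Butterworth low-pass at
20 Hz applied forward-backward ("zero-lag"), which doubles the effective
magnitude order and cancels the phase.  Edge transients are controlled with
odd-reflection padding of three filter orders.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from ._errors import DataError, ParameterError
from .signal_model import BodyFrameSignals, IMURecording


@dataclass(frozen=True)
class FilterSpec:
    order: int = 4
    cutoff: float = 20.0  # Hz
    design: str = "butterworth"
    zero_lag: bool = True

    def __post_init__(self):
        if self.order < 1:
            raise ParameterError(f"filter order must be >= 1, got {self.order}")
        if self.cutoff <= 0:
            raise ParameterError(f"cutoff must be > 0 Hz, got {self.cutoff}")
        if self.design != "butterworth":
            raise ParameterError(f"unknown filter design {self.design!r}")


def lowpass_filter(x: np.ndarray, rate: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Apply the zero-lag Butterworth low-pass to a uniform series.

    Output has the same length as the input.  Raises ``ParameterError`` when
    the cutoff reaches Nyquist and ``DataError`` when the series is too short
    (length must exceed 3x the filter order).
    """
    x = np.asarray(x, dtype=float)
    if spec.cutoff >= rate / 2:
        raise ParameterError(
            f"cutoff {spec.cutoff} Hz must be below Nyquist ({rate / 2} Hz)"
        )
    padlen = 3 * spec.order
    if x.shape[-1] <= padlen:
        raise DataError(
            f"series of length {x.shape[-1]} too short for order-{spec.order} "
            f"zero-lag filtering (needs > {padlen} samples)"
        )
    sos = sps.butter(spec.order, spec.cutoff, btype="low", fs=rate, output="sos")
    if spec.zero_lag:
        return sps.sosfiltfilt(sos, x, padtype="odd", padlen=padlen)
    return sps.sosfilt(sos, x)


def filter_recording(rec: IMURecording, spec: FilterSpec = FilterSpec()) -> IMURecording:
    """Filter all accelerometer and gyroscope channels of a uniform recording."""
    acc = np.column_stack(
        [lowpass_filter(rec.acc[:, i], rec.nominal_rate, spec) for i in range(3)]
    )
    gyro = np.column_stack(
        [lowpass_filter(rec.gyro[:, i], rec.nominal_rate, spec) for i in range(3)]
    )
    return replace(rec, acc=acc, gyro=gyro)


def filter_body(body: BodyFrameSignals, spec: FilterSpec = FilterSpec()) -> BodyFrameSignals:
    """Filter all body-frame channels with the same spec."""
    return BodyFrameSignals(
        ML=lowpass_filter(body.ML, body.rate, spec),
        AP=lowpass_filter(body.AP, body.rate, spec),
        CC=lowpass_filter(body.CC, body.rate, spec),
        yaw_rate=lowpass_filter(body.yaw_rate, body.rate, spec),
        rate=body.rate,
        gyro=(
            np.column_stack(
                [lowpass_filter(body.gyro[:, i], body.rate, spec) for i in range(3)]
            )
            if body.gyro is not None
            else None
        ),
    )
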