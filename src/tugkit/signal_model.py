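"""Data model and I/O for raw lumbar-IMU recordings.

A recording is a timestamped 6-axis (accelerometer + gyroscope, optional
magnetometer) series captured by a smartphone strapped to the lower back
during the standardized mobility test (30 s quiet stance, cued 3 m walk,
turn-sit-stand, walk back).  This module owns

* the :class:`IMURecording` container and its CSV dialect,
* uniform resampling onto an exact time grid,
* the device-to-body axis mapping (ML / AP / CC) including gravity handling,
* the :class:`SubjectProfile` anthropometric/clinical record.

Axis conventions
----------------
Body axes are medial-lateral (ML), anterior-posterior (AP, forward positive)
and cranio-caudal (CC, upward positive).  With the device at rest the CC
accelerometer channel reads approximately ``-g`` (gravity included); gravity
removal is mean subtraction, not tilt compensation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from ._errors import ConfigError, DataError, ParameterError, SchemaError

G = 9.81  # m/s^2, standard gravity used throughout

#: body = MOUNTINGS[name] @ device, rows are (ML, AP, CC) in device coordinates.
#: All matrices are proper rotations (signed permutations with det = +1) so the
#: same matrix maps accelerometer and gyroscope vectors.
MOUNTINGS = {
    # Device fixed vertically on the lumbar belt, screen against the sacrum:
    # device X -> ML, device Y -> CC (up), device Z (out of screen, backward) -> -AP.
    "portrait_back": np.array(
        [[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]]
    ),
    # Device axes already coincide with the body axes (simulation convenience).
    "identity": np.eye(3),
}

_BASE_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
_MAG_COLUMNS = ["mx", "my", "mz"]


@dataclass
class IMURecording:
    """Raw 6-axis recording in the device frame, SI units.

    Parameters
    ----------
    timestamps : (n,) array, seconds since recording start, strictly increasing.
    acc : (n, 3) array, specific force in m/s^2 (gravity included).
    gyro : (n, 3) array, angular velocity in rad/s.
    mag : optional (n, 3) array, magnetometer in arbitrary units.
    nominal_rate : nominal sampling rate in Hz (protocol: 100).
    mounting : key of :data:`MOUNTINGS` describing how the device sits on the belt.
    """

    timestamps: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    mag: Optional[np.ndarray] = None
    nominal_rate: float = 100.0
    mounting: str = "portrait_back"

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.mag is not None:
            self.mag = np.asarray(self.mag, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.timestamps)
        if self.acc.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise DataError(
                f"acc/gyro must be (n, 3) with n = {n}; "
                f"got acc {self.acc.shape}, gyro {self.gyro.shape}"
            )
        if self.mag is not None and self.mag.shape != (n, 3):
            raise DataError(f"mag must be (n, 3) with n = {n}; got {self.mag.shape}")
        if self.nominal_rate <= 0:
            raise ParameterError(f"nominal_rate must be > 0, got {self.nominal_rate}")
        if n >= 2:
            dt = np.diff(self.timestamps)
            bad = np.nonzero(dt <= 0)[0]
            if bad.size:
                row = int(bad[0]) + 1  # first offending row (0-based in data order)
                raise DataError(
                    f"timestamps must be strictly increasing; "
                    f"violation at row {row} (t[{row}] = {self.timestamps[row]!r} "
                    f"<= t[{row - 1}] = {self.timestamps[row - 1]!r})"
                )
        if self.mounting not in MOUNTINGS:
            raise ConfigError(
                f"unknown mounting {self.mounting!r}; known: {sorted(MOUNTINGS)}"
            )

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0]) if len(self) else 0.0


@dataclass
class BodyFrameSignals:
    """Accelerations mapped onto the body axes, plus the yaw rate about CC.

    ``ML``/``AP``/``CC`` are acceleration series in m/s^2; ``yaw_rate`` is the
    angular velocity about the cranio-caudal axis in rad/s.  ``gyro`` keeps the
    full body-frame gyroscope for consumers that need roll/pitch rates.
    """

    ML: np.ndarray
    AP: np.ndarray
    CC: np.ndarray
    yaw_rate: np.ndarray
    rate: float
    gyro: Optional[np.ndarray] = None

    def __post_init__(self):
        n = len(self.ML)
        for name in ("AP", "CC", "yaw_rate"):
            if len(getattr(self, name)) != n:
                raise DataError(f"{name} length {len(getattr(self, name))} != ML length {n}")
        if self.rate <= 0:
            raise ParameterError(f"rate must be > 0, got {self.rate}")

    def __len__(self) -> int:
        return len(self.ML)

    def acc_matrix(self) -> np.ndarray:
        """Return the (n, 3) body-frame acceleration matrix (ML, AP, CC)."""
        return np.column_stack([self.ML, self.AP, self.CC])


@dataclass
class SubjectProfile:
    """Anthropometrics and clinical labels of one participant."""

    height: float  # m
    weight: float  # kg
    group: str = "control"  # {"stroke", "control"}
    mrs: Optional[int] = None  # modified Rankin scale, 0-5
    fachs: Optional[int] = None  # functional ambulation classification, 0-5
    age: Optional[float] = None
    sex: str = "unspecified"
    subject_id: str = ""

    def __post_init__(self):
        if not (1.2 < self.height < 2.2):
            raise ParameterError(f"height must lie in (1.2, 2.2) m, got {self.height}")
        if not (30 < self.weight < 200):
            raise ParameterError(f"weight must lie in (30, 200) kg, got {self.weight}")
        if self.group not in ("stroke", "control"):
            raise ParameterError(f"group must be 'stroke' or 'control', got {self.group!r}")
        if self.group == "stroke":
            # Study inclusion: ambulatory (FACHS >= 2) with no severe disability (mRS <= 3).
            if self.mrs is not None and not (0 <= self.mrs <= 3):
                raise ParameterError(
                    f"included stroke subjects require mRS <= 3, got {self.mrs}"
                )
            if self.fachs is not None and not (2 <= self.fachs <= 5):
                raise ParameterError(
                    f"included stroke subjects require FACHS >= 2, got {self.fachs}"
                )


# ---------------------------------------------------------------------------
# CSV I/O.  Canonical dialect: optional '#'-prefixed metadata lines, then one
# header line `t,ax,ay,az,gx,gy,gz[,mx,my,mz]`, SI units, '.' decimal, UTF-8.
# ---------------------------------------------------------------------------

def write_recording(rec: IMURecording, path) -> None:
    """Write a recording to ``path`` in the canonical CSV dialect.

    Values are written with 9 significant decimals, lossless to 1e-9 for
    signals in SI magnitude ranges.
    """
    cols = {"t": rec.timestamps}
    for i, name in enumerate(("ax", "ay", "az")):
        cols[name] = rec.acc[:, i]
    for i, name in enumerate(("gx", "gy", "gz")):
        cols[name] = rec.gyro[:, i]
    if rec.mag is not None:
        for i, name in enumerate(_MAG_COLUMNS):
            cols[name] = rec.mag[:, i]
    frame = pd.DataFrame(cols)
    buf = io.StringIO()
    buf.write("# units=SI t:s acc:m/s^2 gyro:rad/s\n")
    buf.write(f"# nominal_rate_hz={rec.nominal_rate!r} mounting={rec.mounting}\n")
    frame.to_csv(buf, index=False, float_format="%.9f")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_recording(path, dialect: str = "canonical") -> IMURecording:
    """Read a recording written in the canonical CSV dialect.

    Metadata lines (``# key=value``) restore the nominal rate and mounting.
    Raises :class:`SchemaError` on missing columns and :class:`DataError` on
    non-monotonic timestamps (naming the first offending row).
    """
    if dialect != "canonical":
        raise ConfigError(f"unknown CSV dialect {dialect!r}")
    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    lines = text.splitlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        for tok in line[1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
    frame = pd.read_csv(io.StringIO("\n".join(lines[body_start:])))
    missing = [c for c in _BASE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path}")
    has_mag = all(c in frame.columns for c in _MAG_COLUMNS)
    return IMURecording(
        timestamps=frame["t"].to_numpy(),
        acc=frame[["ax", "ay", "az"]].to_numpy(),
        gyro=frame[["gx", "gy", "gz"]].to_numpy(),
        mag=frame[_MAG_COLUMNS].to_numpy() if has_mag else None,
        nominal_rate=float(meta.get("nominal_rate_hz", 100.0)),
        mounting=meta.get("mounting", "portrait_back"),
    )


# ---------------------------------------------------------------------------
# Resampling and axis mapping
# ---------------------------------------------------------------------------

def resample_uniform(rec: IMURecording, rate: Optional[float] = None) -> IMURecording:
    """Linearly interpolate a recording onto an exact uniform grid at ``rate``.

    The output grid starts at the first timestamp and spans the input with
    spacing ``1/rate``; already-uniform input at the requested rate is
    returned unchanged (idempotence).
    """
    if rate is None:
        rate = rec.nominal_rate
    if rate <= 0:
        raise ParameterError(f"rate must be > 0, got {rate}")
    if len(rec) < 2:
        raise DataError("resampling requires at least 2 samples")
    t = rec.timestamps
    dt = 1.0 / rate
    n_out = int(np.floor((t[-1] - t[0]) * rate)) + 1
    grid = t[0] + np.arange(n_out) * dt
    if n_out == len(t) and np.allclose(t, grid, atol=1e-12 / rate + 1e-12):
        return replace(rec, timestamps=grid, nominal_rate=float(rate))

    def interp(block):
        return np.column_stack([np.interp(grid, t, block[:, i]) for i in range(3)])

    return IMURecording(
        timestamps=grid,
        acc=interp(rec.acc),
        gyro=interp(rec.gyro),
        mag=interp(rec.mag) if rec.mag is not None else None,
        nominal_rate=float(rate),
        mounting=rec.mounting,
    )


def map_device_to_body_axes(
    rec: IMURecording, remove_gravity: bool = False
) -> BodyFrameSignals:
    """Permute/sign the device axes into the ML/AP/CC body frame.

    ``remove_gravity`` subtracts the mean of each mapped acceleration axis
    (static-attitude gravity handling; downstream per-phase computations
    additionally detrend each analysis segment).
    """
    if rec.mounting not in MOUNTINGS:
        raise ConfigError(f"unknown mounting {rec.mounting!r}")
    m = MOUNTINGS[rec.mounting]
    acc_body = rec.acc @ m.T
    gyro_body = rec.gyro @ m.T
    if remove_gravity:
        acc_body = acc_body - acc_body.mean(axis=0, keepdims=True)
    return BodyFrameSignals(
        ML=acc_body[:, 0],
        AP=acc_body[:, 1],
        CC=acc_body[:, 2],
        yaw_rate=gyro_body[:, 2],
        rate=rec.nominal_rate,
        gyro=gyro_body,
    )
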