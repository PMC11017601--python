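"""The ten kinematic parameters of the standardized mobility test.

Per subject the pipeline reports, from the filtered body-frame signals and an
event set:

=================  ======  ====================================================
MLDisp, APDisp     mm      90th-percentile COM excursion during the 30 s stance
                           (medial-lateral / anterior-posterior), via a
                           least-squares inversion of the inverted-pendulum
                           measurement equation
CCrange, MLrange   mm      COM movement range while walking, averaged over the
                           out and back 3 m phases
PturnSit, Pstand   W       mean power of the turn+sit and the stand-up
                           transitions, m.g.dh / duration
RangeJerkSit/Stand m/s^3   max - min of the jerk (d|acc|/dt) during the gesture
total_time         s       sum of the four active-phase durations
reaction_time      s       acoustic cue to gait initiation (t1 - t0)
=================  ======  ====================================================

Displacement comes from double integration of acceleration performed in the
frequency domain (divide the spectrum by ``-(2*pi*f)**2``), which confines the
low-frequency drift that plagues time-domain cumulative integration to
explicitly zeroed bins below a high-pass cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import sparse
from scipy.integrate import cumulative_trapezoid
from scipy.sparse.linalg import spsolve

from ._errors import DataError, ParameterError
from .preprocessing import FilterSpec, filter_body
from .segmentation import EventSet, phase_slices
from .signal_model import BodyFrameSignals, G, IMURecording, SubjectProfile, map_device_to_body_axes, resample_uniform


@dataclass(frozen=True)
class IntegrationConfig:
    """Numerical choices for displacement reconstruction.

    High-pass cutoffs sit below the band of interest of each phase: 0.05 Hz
    for postural sway (0.1-1 Hz), 0.3 Hz for step oscillations (>= ~0.8 Hz),
    0.1 Hz for sit/stand transitions (their content lives at ~0.2-0.5 Hz).
    ``pendulum_ratio`` is the anthropometric COM height fraction
    (L = 0.53 * body height) of the stance inverted-pendulum model.
    """

    highpass_cutoff: float = 0.1  # Hz, generic double-integration cutoff
    stance_highpass: float = 0.05  # Hz
    gait_highpass: float = 0.3  # Hz
    transition_highpass: float = 0.1  # Hz; sit/stand content sits at ~0.2-0.5 Hz
    detrend: str = "constant"  # mean removal; "linear" available for comparison
    percentile: float = 90.0  # fixed by the parameter definitions
    pendulum_ratio: float = 0.53
    jerk_on: str = "magnitude"  # {"magnitude", "per_axis"}

    def __post_init__(self):
        if self.highpass_cutoff < 0 or self.stance_highpass < 0 or self.gait_highpass < 0:
            raise ParameterError("high-pass cutoffs must be >= 0")
        if self.detrend not in ("constant", "linear"):
            raise ParameterError(f"unknown detrend mode {self.detrend!r}")
        if self.jerk_on not in ("magnitude", "per_axis"):
            raise ParameterError(f"unknown jerk mode {self.jerk_on!r}")


@dataclass
class ParameterSet:
    """The ten per-subject outputs, in the units of the study's main table."""

    MLDisp: float  # mm
    APDisp: float  # mm
    CCrange: float  # mm
    MLrange: float  # mm
    PturnSit: float  # W
    Pstand: float  # W
    RangeJerkSit: float  # m/s^3
    RangeJerkStand: float  # m/s^3
    total_time: float  # s
    reaction_time: float  # s

    FIELDS = (
        "MLDisp",
        "APDisp",
        "CCrange",
        "MLrange",
        "PturnSit",
        "Pstand",
        "RangeJerkSit",
        "RangeJerkStand",
        "total_time",
        "reaction_time",
    )

    def __post_init__(self):
        for name in self.FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise DataError(f"parameter {name} must be finite and >= 0, got {v}")

    def as_dict(self) -> dict:
        return {name: float(getattr(self, name)) for name in self.FIELDS}


# ---------------------------------------------------------------------------
# Displacement reconstruction
# ---------------------------------------------------------------------------

def _spectral_displacement(
    acc_seg: np.ndarray, rate: float, highpass: float, detrend: str = "constant"
) -> np.ndarray:
    """Plain frequency-domain double integration to displacement in metres.

    Mean removal, FFT, division by ``-(2 pi f)^2`` with DC and bins below the
    high-pass cutoff zeroed, inverse FFT.  Mean removal (not a fitted line)
    is used by default: subtracting a fitted line from a finite window is a
    non-periodic perturbation whose sawtooth spectrum the low-frequency
    division amplifies enormously; the explicit low-bin zeroing already
    provides the drift control a detrend would aim for.
    """
    x = np.asarray(acc_seg, dtype=float)
    if x.size == 0:
        raise DataError("cannot integrate an empty segment")
    x = sps.detrend(x, type=detrend)
    n = x.size
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    denom = -((2.0 * np.pi * f) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_spec = np.where(np.abs(denom) > 0.0, spec / denom, 0.0)
    disp_spec[(f < highpass) | (f == 0.0)] = 0.0
    return np.fft.irfft(disp_spec, n=n)


#: interior margin (s) excluded from the stance quantiles (reconstruction
#: edges are least constrained by the measurement equations).
STANCE_EDGE_S = 1.0


def pendulum_displacement(
    acc_seg: np.ndarray,
    rate: float,
    pendulum_length: float,
    highpass: float = 0.05,
    ridge_alpha: float = 0.05,
) -> np.ndarray:
    """COM displacement (m) during stance via inverted-pendulum inversion.

    The horizontal sensor acceleration of a small-angle inverted pendulum is
    ``a = x'' + (g/L) x`` (tangential plus gravity-leak term), with
    ``w0^2 = g/L`` the pendulum rate.  This solves that measurement equation
    for the COM displacement x as a ridge-regularized least squares in the
    time domain (second differences, banded sparse solve):

        min_x || x'' + w0^2 x - a ||^2 + (ridge_alpha * w0^2)^2 ||x||^2

    No periodicity is assumed, so there is no spectral leakage; the ridge
    resolves the one genuine unidentifiability (free oscillations exactly at
    the pendulum resonance produce no measured acceleration) toward the
    minimum-norm solution, and its residual coherent part is projected out
    (sin/cos at w0).  The transfer is well conditioned at low frequency
    (gain 1/w0^2 at DC), so drift control reduces to the linear detrend of
    the input and output; ``highpass`` is retained as a config knob but the
    detrend dominates below it.
    """
    y = np.asarray(acc_seg, dtype=float)
    n = y.size
    if n < int(10 * rate):
        raise DataError("pendulum inversion needs at least 10 s of stance")
    a = sps.detrend(y, type="linear")
    dt = 1.0 / rate
    w0_sq = G / pendulum_length
    b = 1.0 / dt**2
    d = w0_sq - 2.0 / dt**2
    design = sparse.diags(
        [np.full(n - 2, b), np.full(n - 2, d), np.full(n - 2, b)],
        [0, 1, 2],
        shape=(n - 2, n),
        format="csr",
    )
    lam = (ridge_alpha * w0_sq) ** 2
    normal = (design.T @ design + lam * sparse.identity(n)).tocsc()
    x = spsolve(normal, design.T @ a[1 : n - 1])
    t = np.arange(n) * dt
    w0 = np.sqrt(w0_sq)
    basis = np.column_stack([np.sin(w0 * t), np.cos(w0 * t), np.ones_like(t), t])
    x = x - basis @ np.linalg.lstsq(basis, x, rcond=None)[0]
    nt = int(round(STANCE_EDGE_S * rate))
    return x[nt : n - nt]


def double_integrate_fft(
    acc_seg: np.ndarray, rate: float, cfg: IntegrationConfig = IntegrationConfig(),
    highpass: float | None = None,
) -> np.ndarray:
    """Double-integrate an acceleration segment to displacement in mm.

    Mean removal, FFT, division by ``-(2 pi f)^2`` with DC and bins below
    the high-pass cutoff zeroed, inverse FFT, scaled to millimetres.
    Requires at least one second of samples.
    """
    x = np.asarray(acc_seg, dtype=float)
    if x.size == 0:
        raise DataError("cannot integrate an empty segment")
    if x.size < rate:
        raise DataError(
            f"segment of {x.size} samples is shorter than 1 s at {rate} Hz"
        )
    hp = cfg.highpass_cutoff if highpass is None else highpass
    return 1000.0 * _spectral_displacement(x, rate, hp, detrend=cfg.detrend)


def excursion_p90(disp: np.ndarray) -> float:
    """90th-percentile excursion of a displacement series about its centre.

    Computed two-sidedly as half the 5th-to-95th percentile spread, which for
    symmetric signals equals the 90th percentile of the absolute deviation
    from the median; translation-invariant and scale-equivariant.
    """
    disp = np.asarray(disp, dtype=float)
    if disp.size == 0:
        raise DataError("excursion of an empty series is undefined")
    p5, p95 = np.percentile(disp, [5.0, 95.0])
    return float((p95 - p5) / 2.0)


# ---------------------------------------------------------------------------
# Per-phase parameters
# ---------------------------------------------------------------------------

def stance_displacement(
    body: BodyFrameSignals,
    ev: EventSet,
    subject: SubjectProfile,
    cfg: IntegrationConfig = IntegrationConfig(),
    start_time: float = 0.0,
) -> tuple[float, float]:
    """(MLDisp, APDisp) in mm over the bipedal stance [start, t0).

    The horizontal accelerations are inverted through the inverted-pendulum
    transfer with pendulum length ``L = pendulum_ratio * height`` (the lumbar
    sensor rides at COM height), giving COM excursions directly.
    """
    i0, i1 = phase_slices(ev, body.rate, start_time)["stance"]
    if (i1 - i0) / body.rate < 10.0:
        raise DataError(
            f"stance phase of {(i1 - i0) / body.rate:.1f} s is too short (< 10 s)"
        )
    length = cfg.pendulum_ratio * subject.height
    out = []
    for series in (body.ML[i0:i1], body.AP[i0:i1]):
        disp_m = pendulum_displacement(
            series, body.rate, length, highpass=cfg.stance_highpass
        )
        out.append(excursion_p90(1000.0 * disp_m))
    return out[0], out[1]


def gait_ranges(
    body: BodyFrameSignals,
    ev: EventSet,
    cfg: IntegrationConfig = IntegrationConfig(),
    start_time: float = 0.0,
) -> tuple[float, float]:
    """(CCrange, MLrange) in mm, averaged over the out and back walks.

    The range is peak-to-peak-like: twice the 90th-percentile excursion of
    the double-integrated displacement.
    """
    slices = phase_slices(ev, body.rate, start_time)
    cc_vals, ml_vals = [], []
    for key in ("walk1", "walk2"):
        i0, i1 = slices[key]
        if (i1 - i0) / body.rate < 1.0:
            raise DataError(f"walk phase {key} shorter than 1 s")
        for series, acc_list in ((body.CC, cc_vals), (body.ML, ml_vals)):
            disp = double_integrate_fft(
                series[i0:i1], body.rate, cfg, highpass=cfg.gait_highpass
            )
            acc_list.append(2.0 * excursion_p90(disp))
    return float(np.mean(cc_vals)), float(np.mean(ml_vals))


def transition_power(
    body: BodyFrameSignals,
    seg: tuple[int, int],
    subject: SubjectProfile,
    cfg: IntegrationConfig = IntegrationConfig(),
) -> float:
    """Mean power P = m.g.dh / duration of a sit or stand transition, in W.

    dh is the vertical COM excursion: max - min of the cranio-caudal
    displacement within the segment, capped at 0.3 * body height.  A
    transition is rest-to-rest (it starts and ends in a protocol pause), so
    the displacement comes from time-domain cumulative-trapezoid double
    integration with zero initial velocity of the mean-removed acceleration
    (mean removal enforces zero net velocity change over the segment) —
    unlike the periodic frequency-domain inversion, this preserves the net
    monotone drop/rise that defines dh.
    """
    i0, i1 = seg
    duration = (i1 - i0) / body.rate
    if duration <= 0.3:
        raise DataError(f"transition segment of {duration:.2f} s is too short")
    acc = sps.detrend(body.CC[i0:i1], type="constant")
    vel = cumulative_trapezoid(acc, dx=1.0 / body.rate, initial=0.0)
    disp = cumulative_trapezoid(vel, dx=1.0 / body.rate, initial=0.0)
    dh = min(float(disp.max() - disp.min()), 0.3 * subject.height)
    return subject.weight * G * dh / duration


def jerk_range(
    body: BodyFrameSignals, seg: tuple[int, int], rate: float | None = None,
    cfg: IntegrationConfig = IntegrationConfig(),
) -> float:
    """max - min of the jerk within a segment, in m/s^3.

    Jerk is the central finite difference of the (already low-pass-filtered)
    acceleration magnitude, which is orientation-independent; a per-axis mode
    (resultant of the per-axis jerk ranges' maximum) is available via config.
    """
    if rate is None:
        rate = body.rate
    i0, i1 = seg
    if i1 - i0 < 3:
        raise DataError("jerk requires a segment of at least 3 samples")
    if cfg.jerk_on == "magnitude":
        mag = np.linalg.norm(body.acc_matrix()[i0:i1], axis=1)
        jerk = np.gradient(mag, 1.0 / rate)
        return float(jerk.max() - jerk.min())
    ranges = []
    for series in (body.ML, body.AP, body.CC):
        jerk = np.gradient(series[i0:i1], 1.0 / rate)
        ranges.append(jerk.max() - jerk.min())
    return float(max(ranges))


def timing_parameters(ev: EventSet) -> tuple[float, float]:
    """(total_time, reaction_time) in seconds.

    total_time sums the four active splits (walks, turn+sit, stand);
    reaction_time is cue-to-gait-initiation.
    """
    total = (ev.t2 - ev.t1) + (ev.t4 - ev.t3) + (ev.t6 - ev.t5) + (ev.t8 - ev.t7)
    return float(total), float(ev.t1 - ev.t0)


def compute_all_parameters(
    rec: IMURecording,
    ev: EventSet,
    subject: SubjectProfile,
    cfg: IntegrationConfig = IntegrationConfig(),
    filter_spec: FilterSpec = FilterSpec(),
) -> ParameterSet:
    """Full per-subject computation: filter -> axis map -> per-phase parameters."""
    try:
        rec = resample_uniform(rec)
        body = filter_body(map_device_to_body_axes(rec), filter_spec)
    except (DataError, ParameterError) as exc:
        raise type(exc)(f"preprocessing: {exc}") from exc
    start_time = float(rec.timestamps[0])
    slices = phase_slices(ev, body.rate, start_time)

    def staged(stage, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (DataError, ParameterError) as exc:
            raise type(exc)(f"{stage}: {exc}") from exc

    ml_disp, ap_disp = staged(
        "stance", stance_displacement, body, ev, subject, cfg, start_time
    )
    cc_range, ml_range = staged("gait", gait_ranges, body, ev, cfg, start_time)
    p_turnsit = staged("turnsit", transition_power, body, slices["turnsit"], subject, cfg)
    p_stand = staged("stand", transition_power, body, slices["stand"], subject, cfg)
    jerk_sit = staged("turnsit", jerk_range, body, slices["turnsit"], body.rate, cfg)
    jerk_stand = staged("stand", jerk_range, body, slices["stand"], body.rate, cfg)
    total, reaction = timing_parameters(ev)
    return ParameterSet(
        MLDisp=ml_disp,
        APDisp=ap_disp,
        CCrange=cc_range,
        MLrange=ml_range,
        PturnSit=p_turnsit,
        Pstand=p_stand,
        RangeJerkSit=jerk_sit,
        RangeJerkStand=jerk_stand,
        total_time=total,
        reaction_time=reaction,
    )
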