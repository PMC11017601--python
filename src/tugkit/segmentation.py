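"""Event detection: the nine times t0..t8 partitioning the mobility test.

The protocol fixes t0 (the acoustic cue ending the 30 s stance).  The other
events bound the active phases:

* t1-t2   walk out (3 m),
* t3-t4   turn + sit down,
* t5-t6   stand up,
* t7-t8   walk back (t7 may coincide with t6 when there is no pause).

Detection is threshold-based: a centred moving-RMS of the baseline-referenced
acceleration magnitude is compared against the quiet-stance baseline
(mean + k.SD over the final 5 s of stance), combined with a yaw-rate activity
gate for the turning phase, and the resulting activity bursts are assigned to
phases in order.  The reference analysis segmented recordings manually from
signal plots; all thresholds here are configurable and validated against the
synthetic generator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import uniform_filter1d

from ._errors import DataError, ParameterError, SegmentationError
from .orientation import OrientationSeries
from .signal_model import BodyFrameSignals

_EVENT_NAMES = tuple(f"t{i}" for i in range(9))
#: consecutive-pair comparisons; True means equality is allowed (t2<=t3, t6<=t7)
_ALLOW_EQUAL = (False, False, True, False, False, False, True, False)


@dataclass
class EventSet:
    """The nine segmentation times in seconds, plus provenance."""

    times: np.ndarray  # (9,) = t0..t8
    cue_time: float = 30.0
    source: str = "auto"  # {"auto", "manual"}

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (9,):
            raise ParameterError(
                f"an EventSet needs exactly 9 times t0..t8, got {self.times.shape[0]}"
            )
        if self.source not in ("auto", "manual"):
            raise ParameterError(f"source must be 'auto' or 'manual', got {self.source!r}")
        for i, allow_eq in enumerate(_ALLOW_EQUAL):
            a, b = self.times[i], self.times[i + 1]
            ok = a <= b if allow_eq else a < b
            if not ok:
                op = "<=" if allow_eq else "<"
                raise DataError(
                    f"event ordering violated: require t{i} {op} t{i + 1}, "
                    f"got (t{i}, t{i + 1}) = ({a}, {b})"
                )
        if not np.isclose(self.times[0], self.cue_time):
            raise DataError(
                f"t0 must equal the cue time {self.cue_time}, got {self.times[0]}"
            )

    def __getattr__(self, name):
        if name in _EVENT_NAMES:
            return float(self.times[int(name[1:])])
        raise AttributeError(name)

    def as_dict(self) -> Dict[str, float]:
        return {name: float(t) for name, t in zip(_EVENT_NAMES, self.times)}


@dataclass(frozen=True)
class SegmentationConfig:
    rms_window: float = 0.25  # s, centred moving-RMS window
    onset_k: float = 3.0  # baseline-SD multiples above the baseline mean
    sustain: float = 0.2  # s, minimum supra-threshold duration
    yaw_rate_threshold: float = 0.52  # rad/s (~30 deg/s)
    pause_expected: float = 3.0  # s, protocol pause (expectation, not a constraint)
    merge_gap: float = 0.4  # s, sub-threshold dips shorter than this stay in a burst
    baseline_window: float = 5.0  # s of stance immediately before the cue
    cue_time: float = 30.0  # s

    def __post_init__(self):
        for name in (
            "rms_window",
            "onset_k",
            "sustain",
            "yaw_rate_threshold",
            "pause_expected",
            "merge_gap",
            "baseline_window",
            "cue_time",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")


def apply_manual_events(times: Sequence[float], cue_time: float = 30.0) -> EventSet:
    """Validate nine manually determined event times into an EventSet."""
    times = np.asarray(list(times), dtype=float)
    if times.shape != (9,):
        raise ParameterError(f"expected 9 event times t0..t8, got {times.shape[0]}")
    return EventSet(times=times, cue_time=float(times[0]) if cue_time is None else cue_time, source="manual")


def phase_slices(
    ev: EventSet, rate: float, start_time: float = 0.0
) -> Dict[str, Tuple[int, int]]:
    """Half-open sample ranges [i0, i1) for the five analysed phases."""

    def idx(t):
        return int(round((t - start_time) * rate))

    return {
        "stance": (idx(start_time), idx(ev.t0)),
        "walk1": (idx(ev.t1), idx(ev.t2)),
        "turnsit": (idx(ev.t3), idx(ev.t4)),
        "stand": (idx(ev.t5), idx(ev.t6)),
        "walk2": (idx(ev.t7), idx(ev.t8)),
    }


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True in a boolean array."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    stops = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def detect_events(
    body: BodyFrameSignals,
    orient: Optional[OrientationSeries] = None,
    cfg: SegmentationConfig = SegmentationConfig(),
    start_time: float = 0.0,
) -> EventSet:
    """Detect t0..t8 from acceleration activity and yaw rate.

    ``orient`` is accepted for API symmetry with manual inspection workflows;
    turning activity is measured on the body-frame yaw rate, which carries the
    same information differentially.
    """
    rate = body.rate
    n = len(body)
    t = start_time + np.arange(n) / rate
    if t[-1] < cfg.cue_time + 10.0:
        raise DataError(
            f"recording must span the full protocol (>= {cfg.cue_time + 10.0} s), "
            f"ends at {t[-1]:.2f} s"
        )
    i_cue = int(round((cfg.cue_time - start_time) * rate))
    i_base0 = max(0, i_cue - int(round(cfg.baseline_window * rate)))

    # Baseline-referenced acceleration magnitude -> centred moving RMS.
    acc = body.acc_matrix()
    base_mean = acc[i_base0:i_cue].mean(axis=0, keepdims=True)
    dev = np.linalg.norm(acc - base_mean, axis=1)
    w = max(1, int(round(cfg.rms_window * rate)))
    rms = np.sqrt(uniform_filter1d(dev**2, size=w, mode="nearest"))

    mu = rms[i_base0:i_cue].mean()
    sd = rms[i_base0:i_cue].std()
    thr = mu + cfg.onset_k * sd + 1e-6

    yaw_act = uniform_filter1d(
        np.abs(body.yaw_rate - body.yaw_rate[i_base0:i_cue].mean()), size=w, mode="nearest"
    )
    active = (rms > thr) | (yaw_act > cfg.yaw_rate_threshold)
    active[:i_cue] = False

    min_run = max(1, int(round(cfg.sustain * rate)))
    gap = int(round(cfg.merge_gap * rate))
    runs = _runs(active)
    # Group supra-threshold runs separated by short dips into bursts, then
    # anchor each burst's boundaries on its first/last *sustained* run so
    # isolated noise blips cannot drag an onset early or an offset late.
    groups: list[list[tuple[int, int]]] = []
    for a, b in runs:
        if groups and a - groups[-1][-1][1] <= gap:
            groups[-1].append((a, b))
        else:
            groups.append([(a, b)])
    # Boundary refinement: the wide centred RMS window smears activity
    # outward by ~w/2; re-locate each burst edge with a short window.
    w_short = max(1, int(round(0.05 * rate)))
    rms_short = np.sqrt(uniform_filter1d(dev**2, size=w_short, mode="nearest"))
    act_short = (rms_short > thr) | (yaw_act > cfg.yaw_rate_threshold)

    def refine_start(a: int) -> int:
        # first short-window crossing at/after the smeared wide-window start
        hi = min(n, a + w)
        idx = np.nonzero(act_short[a:hi])[0]
        return a + int(idx[0]) if idx.size else a

    def refine_end(b: int) -> int:
        # last short-window crossing at/before the smeared wide-window end
        lo = max(i_cue, b - w)
        idx = np.nonzero(act_short[lo:b])[0]
        return lo + int(idx[-1]) + 1 if idx.size else b

    bursts = []
    for grp in groups:
        solid = [(a, b) for a, b in grp if b - a >= min_run]
        if solid:
            a, b = refine_start(solid[0][0]), refine_end(solid[-1][1])
            a = max(a, i_cue + 1)  # gait initiation is strictly after the cue
            if b - a >= min_run:
                bursts.append((a, b))

    if not bursts:
        raise SegmentationError("no walking onset: no sustained activity after the cue")
    if len(bursts) < 3:
        raise SegmentationError(
            f"expected at least 3 activity bursts after the cue, found {len(bursts)}",
            partial_events={"bursts_s": [(t[a], t[b - 1]) for a, b in bursts]},
        )
    if len(bursts) > 4:
        # Keep the four longest bursts, in temporal order.
        keep = sorted(sorted(bursts, key=lambda r: r[1] - r[0])[-4:])
        bursts = keep

    if len(bursts) == 4:
        (a1, b1), (a2, b2), (a3, b3), (a4, b4) = bursts
        tt = [cfg.cue_time, t[a1], t[b1 - 1], t[a2], t[b2 - 1], t[a3], t[b3 - 1], t[a4], t[b4 - 1]]
    else:
        # Stand-up and walk-back merged into one burst (t7 = t6): split the
        # final burst at its interior activity minimum.
        (a1, b1), (a2, b2), (a3, b3) = bursts
        lo = a3 + min_run
        hi = b3 - min_run
        if hi <= lo:
            split = (a3 + b3) // 2
        else:
            split = lo + int(np.argmin(rms[lo:hi]))
        tt = [cfg.cue_time, t[a1], t[b1 - 1], t[a2], t[b2 - 1], t[a3], t[split], t[split], t[b3 - 1]]

    try:
        return EventSet(times=np.array(tt), cue_time=cfg.cue_time, source="auto")
    except DataError as exc:
        raise SegmentationError(
            f"detected events violate ordering: {exc}",
            partial_events=dict(zip(_EVENT_NAMES, tt)),
        ) from exc
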