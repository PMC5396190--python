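"""Gait-like synthetic accelerometer traces and graded treadmill sessions.

The resultant-acceleration model per bout is deliberately simple so its MAD
is analytically checkable:

* locomotion at speed v:  r(t) = 1 g + A(v) * sin(2*pi*f(v)*t + phi) + noise,
  with step frequency f(v) = 1.4 + 0.4 v Hz and amplitude A(v) from the
  calibration map (MAD of a sinusoid over whole periods is 2A/pi);
* rest / sitting:  1 g plus postural-noise SD well above the non-wear
  detection threshold;
* non-wear:  1 g plus device noise at least 2x below the threshold;
* jumps:  1 g plus a half-sine impulse train whose MAD sits above the
  fastest running stage.

The calibration map is an explicit config object fitted once to the
speed-to-intensity anchors the downstream analysis targets: 2 m/s lands
mid-way in the 0.44-0.59 g MAD band, 1.5 m/s below it, 2.5 m/s above it.
The whole trace is written on the vertical axis (x = y = 0) and clipped to
the device range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import datetime

import numpy as np

from ..actigraphy import AccelRecording, NONWEAR_SD_G

__all__ = [
    "Bout",
    "BoutSchedule",
    "CalibrationMap",
    "DEFAULT_CALIBRATION",
    "DEFAULT_TREADMILL_SPEEDS",
    "TreadmillSession",
    "make_activity_day",
    "make_treadmill_session",
]

ACTIVITIES = ("rest", "sit", "walk", "run", "jump", "nonwear")

#: Bout noise SDs (g).  Non-wear sits >= 2x below the 0.024 g detector
#: threshold; rest/sit sit >= 2x above it so wear hours are unambiguous.
NOISE_SD = {
    "nonwear": 0.005,
    "rest": 0.06,
    "sit": 0.09,
    "gait": 0.02,
    "jump": 0.05,
}
JUMP_AMPLITUDE_G = 4.0
JUMP_FREQ_HZ = 2.0


@dataclass(frozen=True)
class CalibrationMap:
    """Monotone speed -> target epoch-MAD map for the gait generator.

    ``mad(v) = anchor_mad + slope * (v - anchor_speed)`` and the sinusoid
    amplitude is ``A(v) = (pi/2) * mad(v)`` (inverting MAD = 2A/pi).
    Defaults put 2 m/s at 0.515 g (mid 0.44-0.59 band), 1.5 m/s at 0.405 g
    and 2.5 m/s at 0.625 g.
    """

    anchor_speed_mps: float = 2.0
    anchor_mad_g: float = 0.515
    slope_g_per_mps: float = 0.22
    speed_range_mps: tuple[float, float] = (0.4, 3.6)
    step_freq_intercept_hz: float = 1.4
    step_freq_slope: float = 0.4

    def target_mad(self, speed: float) -> float:
        lo, hi = self.speed_range_mps
        if not lo <= speed <= hi:
            raise ValueError(f"speed {speed} m/s outside calibration range [{lo}, {hi}]")
        return self.anchor_mad_g + self.slope_g_per_mps * (speed - self.anchor_speed_mps)

    def amplitude(self, speed: float) -> float:
        return np.pi / 2.0 * self.target_mad(speed)

    def step_freq(self, speed: float) -> float:
        return self.step_freq_intercept_hz + self.step_freq_slope * speed

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationMap":
        d = dict(d)
        if "speed_range_mps" in d:
            d["speed_range_mps"] = tuple(d["speed_range_mps"])
        return cls(**d)


DEFAULT_CALIBRATION = CalibrationMap()
DEFAULT_TREADMILL_SPEEDS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5)


@dataclass(frozen=True)
class Bout:
    activity: str
    duration_s: float
    speed_mps: float | None = None

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ValueError(f"unknown activity {self.activity!r}")
        if self.duration_s <= 0:
            raise ValueError("bout duration must be positive")
        if self.activity in ("walk", "run") and self.speed_mps is None:
            raise ValueError(f"{self.activity} bout needs a speed")


@dataclass(frozen=True)
class BoutSchedule:
    """Ordered bouts starting at ``day_start``; total <= 24 h."""

    bouts: tuple[Bout, ...]
    day_start: datetime
    fs_hz: float = 100.0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.bouts:
            raise ValueError("schedule is empty")
        if self.total_duration_s > 86400.0 + 1e-6:
            raise ValueError("schedule exceeds 24 h")

    @property
    def total_duration_s(self) -> float:
        return float(sum(b.duration_s for b in self.bouts))


def _bout_resultant(
    bout: Bout, fs: float, rng: np.random.Generator, calib: CalibrationMap
) -> np.ndarray:
    n = int(round(bout.duration_s * fs))
    t = np.arange(n) / fs
    if bout.activity == "nonwear":
        return 1.0 + rng.normal(0.0, NOISE_SD["nonwear"], n)
    if bout.activity in ("rest", "sit"):
        return 1.0 + rng.normal(0.0, NOISE_SD[bout.activity], n)
    if bout.activity == "jump":
        phi = rng.uniform(0.0, 2.0 * np.pi)
        impulse = JUMP_AMPLITUDE_G * np.maximum(
            0.0, np.sin(2.0 * np.pi * JUMP_FREQ_HZ * t + phi)
        )
        return 1.0 + impulse + rng.normal(0.0, NOISE_SD["jump"], n)
    # walk / run
    amp = calib.amplitude(bout.speed_mps)  # type: ignore[arg-type]
    freq = calib.step_freq(bout.speed_mps)  # type: ignore[arg-type]
    phi = rng.uniform(0.0, 2.0 * np.pi)
    r = 1.0 + amp * np.sin(2.0 * np.pi * freq * t + phi)
    r += rng.normal(0.0, NOISE_SD["gait"], n)
    return np.maximum(r, 0.0)  # the resultant is a magnitude


def make_activity_day(
    schedule: BoutSchedule,
    calibration: CalibrationMap = DEFAULT_CALIBRATION,
    seed: int = 0,
) -> AccelRecording:
    """Render a bout schedule into a triaxial recording.

    Deterministic in (schedule, calibration, seed).  The generated
    resultant rides on the vertical axis; lateral axes are zero.  Raises
    ``ValueError`` for speeds outside the calibration range.
    """
    rng = np.random.default_rng(seed)
    parts = [_bout_resultant(b, schedule.fs_hz, rng, calibration) for b in schedule.bouts]
    res = np.concatenate(parts)
    res = np.clip(res, -6.0, 6.0)
    xyz = np.zeros((res.size, 3))
    xyz[:, 2] = res
    return AccelRecording(start=schedule.day_start, fs_hz=schedule.fs_hz, xyz=xyz)


@dataclass
class TreadmillSession:
    """A graded-test recording plus its stage annotations."""

    recording: AccelRecording
    stages: list[tuple[str, float, float]]  # (label, start_s, end_s)


def make_treadmill_session(
    speeds_mps=DEFAULT_TREADMILL_SPEEDS,
    seconds_per_speed: float = 70.0,
    include_jumps: bool = False,
    calibration: CalibrationMap = DEFAULT_CALIBRATION,
    fs_hz: float = 100.0,
    start: datetime | None = None,
    seed: int = 0,
) -> TreadmillSession:
    """Graded treadmill test: one fixed-length stage per speed.

    Stage boundaries are recorded so the analysis can discard the first
    10 s of each stage.  With ``include_jumps`` a final jump stage of the
    same length is appended.
    """
    if seconds_per_speed < 5.0:
        raise ValueError("stages must cover at least one 5 s epoch")
    bouts = [Bout("run" if v >= 2.0 else "walk", seconds_per_speed, v) for v in speeds_mps]
    labels = [f"{v:g} m/s" for v in speeds_mps]
    if include_jumps:
        bouts.append(Bout("jump", seconds_per_speed))
        labels.append("jump")
    sched = BoutSchedule(
        bouts=tuple(bouts),
        day_start=start or datetime(2020, 1, 6, 9, 0, 0),
        fs_hz=fs_hz,
    )
    rec = make_activity_day(sched, calibration, seed)
    stages = []
    t = 0.0
    for label, bout in zip(labels, bouts):
        stages.append((label, t, t + bout.duration_s))
        t += bout.duration_s
    return TreadmillSession(recording=rec, stages=stages)
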