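"""Raw-accelerometry intensity profiling via the mean amplitude deviation (MAD).

A hip-worn triaxial recording (nominally 100 Hz, +/-6 g) is reduced to the
resultant acceleration r_i = sqrt(x_i^2 + y_i^2 + z_i^2) (no smoothing),
summarised in non-overlapping 5 s epochs by

    MAD = (1/n) * sum_i |r_i - rbar|,

segmented into 24 h days starting at 06:00 local time, screened for
non-wear (any clock hour with resultant SD < 0.024 g), reduced per day to a
histogram over 98 logarithmically equidistant bins spanning 0–2.5 g, and
averaged over valid days (>= 10 h wear; subjects need >= 3 valid days to be
eligible).  The per-subject histogram therefore holds *mean wear epochs per
day* per intensity bin, and its counts sum exactly to the mean number of
wear epochs per valid day.

Strict log spacing cannot start at 0, so the first bin runs from 0 to a
configurable floor (default 0.01 g) and the remaining 97 edges are
geometric up to 2.5 g.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
from scipy import stats as _sps

__all__ = [
    "AccelRecording",
    "EpochSeries",
    "MADHistogram",
    "resultant",
    "epoch_mad",
    "detect_nonwear",
    "segment_days",
    "epoch_series",
    "mad_bins",
    "subject_profile",
    "treadmill_summary",
]

EPOCH_SECONDS = 5.0
NONWEAR_SD_G = 0.024
MIN_WEAR_HOURS = 10.0
MIN_VALID_DAYS = 3
N_BINS = 98
BIN_MAX_G = 2.5
#: Lower edge of the first geometric bin; [0, floor) forms bin 1.
BIN_FLOOR_G = 0.01
DAY_START_HOUR = 6
#: Seconds discarded at the start of every treadmill stage (acceleration to speed).
STAGE_TRIM_SECONDS = 10.0


@dataclass
class AccelRecording:
    """Uniformly sampled triaxial trace in g.

    ``start`` anchors sample 0 in local clock time; samples are x, y, z
    columns of one (n, 3) array.
    """

    start: datetime
    fs_hz: float
    xyz: np.ndarray  # (n, 3) in g
    device_range_g: float = 6.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be an (n, 3) array")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite acceleration samples")
        if np.any(np.abs(self.xyz) > self.device_range_g + 1e-9):
            raise ValueError("axis values exceed the device range")

    @property
    def n_samples(self) -> int:
        return int(self.xyz.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def resultant(self) -> np.ndarray:
        return resultant(self.xyz[:, 0], self.xyz[:, 1], self.xyz[:, 2])

    def seconds_from_day_grid(self) -> np.ndarray:
        """Sample offsets (s) from the most recent 06:00 at or before start."""
        anchor = self.start.replace(
            hour=DAY_START_HOUR, minute=0, second=0, microsecond=0
        )
        if self.start < anchor:
            anchor -= timedelta(days=1)
        off = (self.start - anchor).total_seconds()
        return off + np.arange(self.n_samples) / self.fs_hz


@dataclass
class EpochSeries:
    """Per-epoch MAD with wear flags and 6 am-grid day labels."""

    start_s: np.ndarray  # epoch starts, seconds from the 6 am grid anchor
    mad_g: np.ndarray
    wear: np.ndarray  # bool
    day: np.ndarray  # int day index on the 6 am grid
    epoch_s: float = EPOCH_SECONDS


@dataclass
class MADHistogram:
    """Per-subject activity-intensity histogram (mean wear epochs/day per bin)."""

    bin_edges_g: np.ndarray  # 99 edges -> 98 bins
    mean_epochs_per_day: np.ndarray  # (98,)
    total_counts: np.ndarray  # raw wear-epoch totals over valid days
    n_valid_days: int
    n_days_observed: int
    total_wear_hours: float
    eligible: bool
    subject_id: str | None = None

    @property
    def epochs_per_day(self) -> float:
        return float(self.mean_epochs_per_day.sum())


def resultant(x, y, z) -> np.ndarray:
    """Euclidean norm of the three axes per sample; no smoothing applied."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise ValueError("axis series must have equal length")
    return np.sqrt(x * x + y * y + z * z)


def epoch_mad(
    res: np.ndarray, fs_hz: float, epoch_s: float = EPOCH_SECONDS
) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping epoch MADs of a resultant series.

    Returns (epoch start offsets in seconds, MAD per epoch).  The trailing
    partial epoch is discarded; a series shorter than one epoch yields
    empty arrays.
    """
    res = np.asarray(res, dtype=float)
    n_per = int(round(fs_hz * epoch_s))
    if n_per < 2:
        raise ValueError("need at least 2 samples per epoch")
    n_epochs = res.size // n_per
    if n_epochs == 0:
        return np.empty(0), np.empty(0)
    blocks = res[: n_epochs * n_per].reshape(n_epochs, n_per)
    mad = np.abs(blocks - blocks.mean(axis=1, keepdims=True)).mean(axis=1)
    starts = np.arange(n_epochs) * epoch_s
    return starts, mad


def detect_nonwear(
    res: np.ndarray,
    fs_hz: float,
    offsets_s: np.ndarray,
    sd_threshold_g: float = NONWEAR_SD_G,
    min_hour_fraction: float = 0.5,
) -> dict[int, bool]:
    """Classify clock hours (on the 6 am grid) as wear / non-wear.

    An hour is non-wear when the population SD of its resultant samples is
    strictly below ``sd_threshold_g`` (SD exactly at the threshold is wear).
    Partial hours are evaluated when at least ``min_hour_fraction`` of their
    samples exist, and are otherwise excluded (absent from the result).

    Returns {hour index: wear flag}.
    """
    res = np.asarray(res, dtype=float)
    offsets_s = np.asarray(offsets_s, dtype=float)
    if res.shape != offsets_s.shape:
        raise ValueError("resultant and offsets must align")
    hour_idx = np.floor_divide(offsets_s, 3600.0).astype(int)
    full_hour = int(round(fs_hz * 3600.0))
    out: dict[int, bool] = {}
    for h in np.unique(hour_idx):
        sel = res[hour_idx == h]
        if sel.size < min_hour_fraction * full_hour:
            continue
        out[int(h)] = bool(sel.std(ddof=0) >= sd_threshold_g)
    return out


def segment_days(offsets_s: np.ndarray) -> np.ndarray:
    """Day index per sample on the 6 am grid (half-open [06:00, 06:00))."""
    return np.floor_divide(np.asarray(offsets_s, dtype=float), 86400.0).astype(int)


def epoch_series(
    rec: AccelRecording,
    epoch_s: float = EPOCH_SECONDS,
    nonwear_sd_g: float = NONWEAR_SD_G,
) -> EpochSeries:
    """Full epoching of a recording: MADs, wear flags, day labels.

    Epochs inherit the wear flag of the clock hour containing their start;
    epochs whose hour was unevaluable (too few samples) count as non-wear.
    """
    res = rec.resultant()
    offsets = rec.seconds_from_day_grid()
    starts_rel, mad = epoch_mad(res, rec.fs_hz, epoch_s)
    starts = offsets[0] + starts_rel
    hour_wear = detect_nonwear(res, rec.fs_hz, offsets, nonwear_sd_g)
    hours = np.floor_divide(starts, 3600.0).astype(int)
    wear = np.array([hour_wear.get(int(h), False) for h in hours])
    day = segment_days(starts)
    return EpochSeries(start_s=starts, mad_g=mad, wear=wear, day=day, epoch_s=epoch_s)


def mad_bins(
    n_bins: int = N_BINS, max_g: float = BIN_MAX_G, floor_g: float = BIN_FLOOR_G
) -> np.ndarray:
    """Edges of the logarithmically equidistant MAD histogram.

    ``n_bins + 1`` edges: 0, then ``n_bins`` geometrically spaced edges from
    ``floor_g`` to ``max_g`` — so bin 1 collects [0, floor_g) and the edge
    ratio is constant from the floor up.
    """
    if n_bins < 2 or floor_g <= 0 or max_g <= floor_g:
        raise ValueError("need n_bins >= 2 and 0 < floor_g < max_g")
    return np.concatenate([[0.0], np.geomspace(floor_g, max_g, n_bins)])


def subject_profile(
    series: EpochSeries,
    bin_edges_g: np.ndarray | None = None,
    min_wear_hours: float = MIN_WEAR_HOURS,
    min_valid_days: int = MIN_VALID_DAYS,
    subject_id: str | None = None,
) -> MADHistogram:
    """Per-subject intensity histogram averaged over valid days.

    Wear time per day is the wear-epoch count times the epoch length; days
    under ``min_wear_hours`` are dropped.  Subjects with fewer than
    ``min_valid_days`` valid days are flagged ineligible — the histogram is
    still computed.  MADs above the top edge are folded into the last bin so
    that counts always sum to the mean wear epochs per valid day.
    """
    edges = mad_bins() if bin_edges_g is None else np.asarray(bin_edges_g, dtype=float)
    n_bins = edges.size - 1

    days = np.unique(series.day)
    day_hists = []
    total = np.zeros(n_bins)
    total_wear_epochs = 0
    for d in days:
        sel = (series.day == d) & series.wear
        wear_hours = sel.sum() * series.epoch_s / 3600.0
        if wear_hours < min_wear_hours:
            continue
        mads = np.minimum(series.mad_g[sel], np.nextafter(edges[-1], 0.0))
        counts, _ = np.histogram(mads, bins=edges)
        day_hists.append(counts)
        total += counts
        total_wear_epochs += int(sel.sum())

    n_valid = len(day_hists)
    mean_counts = total / n_valid if n_valid else np.zeros(n_bins)
    return MADHistogram(
        bin_edges_g=edges,
        mean_epochs_per_day=mean_counts,
        total_counts=total,
        n_valid_days=n_valid,
        n_days_observed=int(days.size),
        total_wear_hours=total_wear_epochs * series.epoch_s / 3600.0,
        eligible=n_valid >= min_valid_days,
        subject_id=subject_id,
    )


def treadmill_summary(
    rec: AccelRecording,
    stages: list[tuple[str, float, float]],
    epoch_s: float = EPOCH_SECONDS,
    trim_s: float = STAGE_TRIM_SECONDS,
    confidence: float = 0.95,
) -> list[dict]:
    """Per-stage MAD summary of an annotated graded test.

    ``stages`` holds (label, start_s, end_s) relative to the recording
    start.  The first ``trim_s`` seconds of each stage (getting up to speed)
    are discarded, the remainder epoched at ``epoch_s``, and the epoch MADs
    summarised as mean with a t-based confidence interval (width 0 when the
    epochs are identical).

    Raises ``ValueError`` for stages too short to yield an epoch after
    trimming.
    """
    res = rec.resultant()
    out = []
    for label, start_s, end_s in stages:
        if end_s - start_s < trim_s + epoch_s:
            raise ValueError(
                f"stage {label!r} is {end_s - start_s:.1f} s; needs at least "
                f"{trim_s + epoch_s:.1f} s"
            )
        i0 = int(round((start_s + trim_s) * rec.fs_hz))
        i1 = int(round(end_s * rec.fs_hz))
        _, mads = epoch_mad(res[i0:i1], rec.fs_hz, epoch_s)
        mean = float(mads.mean())
        sd = float(mads.std(ddof=1)) if mads.size > 1 else 0.0
        if sd == 0.0 or mads.size < 2:
            lo = hi = mean
        else:
            half = _sps.t.ppf(0.5 + confidence / 2.0, mads.size - 1) * sd / np.sqrt(
                mads.size
            )
            lo, hi = mean - half, mean + half
        out.append(
            {
                "stage": label,
                "n_epochs": int(mads.size),
                "mean_mad_g": mean,
                "ci_low_g": float(lo),
                "ci_high_g": float(hi),
            }
        )
    return out
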