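"""Synthetic three-group cohorts with plantable outcome and activity effects.

A cohort mirrors the study design the pipeline targets: a non-sporting
referent group and two running groups (20-40 km/week joggers, 50+ km/week
long-distance runners), each with a gender split, a nucleus-T2 outcome
drawn around ``referent mean * (1 + planted fractional effect)``, a
disc:vertebra height-ratio outcome built the same way, and a group-specific
daily activity mix (runners add running bouts at group-typical speeds).

Raw per-subject recordings are generated lazily (one day at a time) —
a week of 100 Hz data per subject is large, and most analyses only need
the epoch series or the histogram.  ``make_histogram_cohort`` generates
per-subject 98-bin MAD histograms *directly*, with an association between
the outcome and a chosen contiguous bin band planted via a shared latent
factor; it backs the bin-wise correlation studies where raw traces would
add nothing but runtime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from ..actigraphy import EpochSeries, epoch_series, mad_bins
from .accel import (
    Bout,
    BoutSchedule,
    CalibrationMap,
    DEFAULT_CALIBRATION,
    make_activity_day,
)

__all__ = [
    "GROUPS",
    "GroupActivity",
    "CohortDesign",
    "Cohort",
    "make_cohort",
    "make_histogram_cohort",
]

GROUPS = ("no-sport", "jogger", "long-distance")
GENDERS = ("female", "male")


@dataclass(frozen=True)
class GroupActivity:
    """Daily activity mix parameters for one group."""

    run_minutes_mean: float
    run_minutes_sd: float
    run_speed_mps: float
    walk_minutes_mean: float = 60.0
    walk_minutes_sd: float = 15.0
    walk_speed_mps: float = 1.3


DEFAULT_ACTIVITY = {
    "no-sport": GroupActivity(0.0, 0.0, 2.5, walk_minutes_mean=45.0),
    "jogger": GroupActivity(30.0, 8.0, 2.5),
    "long-distance": GroupActivity(60.0, 12.0, 3.2),
}


@dataclass(frozen=True)
class CohortDesign:
    """Cohort layout and planted ground-truth effects.

    Fractional effects are increases over the referent group mean; the
    defaults plant the magnitudes the pipeline is meant to detect at this
    sample size.  ``outcome_sd_frac`` is the between-subject SD as a
    fraction of the referent mean (same absolute SD in every group).
    """

    group_sizes: tuple[int, int, int] = (24, 30, 25)
    female_fraction: float = 0.5
    referent_nucleus_t2_ms: float = 120.0
    t2_effects: dict = field(
        default_factory=lambda: {"no-sport": 0.0, "jogger": 0.092, "long-distance": 0.114}
    )
    referent_height_ratio: float = 0.25
    ratio_effects: dict = field(
        default_factory=lambda: {"no-sport": 0.0, "jogger": 0.03, "long-distance": 0.06}
    )
    outcome_sd_frac: float = 0.08
    activity: dict = field(default_factory=lambda: dict(DEFAULT_ACTIVITY))
    n_days: int = 7
    fs_hz: float = 100.0
    first_day: datetime = datetime(2020, 1, 6, 6, 0, 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes):
            raise ValueError("each group needs >= 2 subjects for any comparison")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0, 1]")
        if self.outcome_sd_frac < 0:
            raise ValueError("SDs must be nonnegative")
        for g in GROUPS:
            if self.referent_nucleus_t2_ms * (1.0 + self.t2_effects.get(g, 0.0)) <= 0:
                raise ValueError(f"planted T2 effect for {g!r} makes T2 nonpositive")
            if self.referent_height_ratio * (1.0 + self.ratio_effects.get(g, 0.0)) <= 0:
                raise ValueError(f"planted ratio effect for {g!r} makes the ratio nonpositive")


@dataclass
class Cohort:
    """Subject table plus lazy per-subject recording generation."""

    table: pd.DataFrame
    design: CohortDesign
    ground_truth: dict
    calibration: CalibrationMap = DEFAULT_CALIBRATION

    def _subject_row(self, subject_id: str) -> pd.Series:
        rows = self.table[self.table.subject_id == subject_id]
        if rows.empty:
            raise KeyError(f"unknown subject {subject_id!r}")
        return rows.iloc[0]

    def schedule_for(self, subject_id: str, day: int) -> BoutSchedule:
        """Deterministic bout schedule for one subject-day."""
        row = self._subject_row(subject_id)
        if not 0 <= day < self.design.n_days:
            raise ValueError(f"day {day} outside 0..{self.design.n_days - 1}")
        params: GroupActivity = self.design.activity[row.group]
        rng = np.random.default_rng(
            np.random.SeedSequence([self.design.seed, int(row.idx), day, 1])
        )
        return _build_day_schedule(
            rng,
            params,
            day_start=self.design.first_day + timedelta(days=day),
            fs_hz=self.design.fs_hz,
        )

    def recording_for(self, subject_id: str, day: int):
        """Render one subject-day trace (lazy; day-long at the design fs)."""
        row = self._subject_row(subject_id)
        sched = self.schedule_for(subject_id, day)
        seed = int(
            np.random.SeedSequence([self.design.seed, int(row.idx), day, 2]).generate_state(1)[0]
            % (2**31)
        )
        return make_activity_day(sched, self.calibration, seed)

    def epoch_series_for(self, subject_id: str) -> EpochSeries:
        """Concatenated epoch series over every design day (memory-light)."""
        parts = []
        for day in range(self.design.n_days):
            es = epoch_series(self.recording_for(subject_id, day))
            parts.append(
                EpochSeries(
                    start_s=es.start_s + day * 86400.0,
                    mad_g=es.mad_g,
                    wear=es.wear,
                    day=es.day + day,
                    epoch_s=es.epoch_s,
                )
            )
        return EpochSeries(
            start_s=np.concatenate([p.start_s for p in parts]),
            mad_g=np.concatenate([p.mad_g for p in parts]),
            wear=np.concatenate([p.wear for p in parts]),
            day=np.concatenate([p.day for p in parts]),
            epoch_s=parts[0].epoch_s,
        )


def _build_day_schedule(
    rng: np.random.Generator,
    params: GroupActivity,
    day_start: datetime,
    fs_hz: float,
) -> BoutSchedule:
    """One 24 h day: 16 h of wear from 06:00, night-time non-wear.

    Wear time is filled with sitting/rest blocks, a walking budget and (for
    runners) one continuous run, shuffled into a plausible order.
    """
    wear_s = 16.0 * 3600.0
    bouts: list[Bout] = []
    run_s = max(rng.normal(params.run_minutes_mean, params.run_minutes_sd), 0.0) * 60.0
    run_s = min(run_s, 0.25 * wear_s)
    if run_s >= 60.0:
        bouts.append(Bout("run", run_s, params.run_speed_mps))
    walk_s = max(rng.normal(params.walk_minutes_mean, params.walk_minutes_sd), 5.0) * 60.0
    for dur in _split_durations(rng, min(walk_s, 0.25 * wear_s), 5 * 60.0, 15 * 60.0):
        bouts.append(Bout("walk", dur, params.walk_speed_mps))
    remaining = wear_s - sum(b.duration_s for b in bouts)
    for dur in _split_durations(rng, remaining, 20 * 60.0, 50 * 60.0):
        bouts.append(Bout(rng.choice(["sit", "rest"]), dur))
    order = rng.permutation(len(bouts))
    bouts = [bouts[i] for i in order]
    bouts.append(Bout("nonwear", 86400.0 - wear_s))
    return BoutSchedule(bouts=tuple(bouts), day_start=day_start, fs_hz=fs_hz)


def _split_durations(
    rng: np.random.Generator, total_s: float, lo_s: float, hi_s: float
) -> list[float]:
    out: list[float] = []
    left = total_s
    while left > lo_s:
        d = float(min(rng.uniform(lo_s, hi_s), left))
        out.append(d)
        left -= d
    if left > 1.0:
        out.append(left)
    return out


def make_cohort(design: CohortDesign) -> Cohort:
    """Draw a cohort: subject table, planted group means, activity mixes.

    Deterministic in ``design`` (including ``design.seed``).  The returned
    ``ground_truth`` maps each group to its true outcome means.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0]))
    sd_t2 = design.outcome_sd_frac * design.referent_nucleus_t2_ms
    sd_ratio = design.outcome_sd_frac * design.referent_height_ratio

    rows = []
    idx = 0
    truth = {}
    for group, n in zip(GROUPS, design.group_sizes):
        mu_t2 = design.referent_nucleus_t2_ms * (1.0 + design.t2_effects.get(group, 0.0))
        mu_ratio = design.referent_height_ratio * (1.0 + design.ratio_effects.get(group, 0.0))
        truth[group] = {"nucleus_t2_ms": mu_t2, "height_ratio": mu_ratio}
        n_female = int(round(design.female_fraction * n))
        for k in range(n):
            rows.append(
                {
                    "subject_id": f"S{idx:03d}",
                    "idx": idx,
                    "group": group,
                    "gender": GENDERS[0] if k < n_female else GENDERS[1],
                    "nucleus_t2_ms": rng.normal(mu_t2, sd_t2),
                    "height_ratio": rng.normal(mu_ratio, sd_ratio),
                }
            )
            idx += 1
    table = pd.DataFrame(rows)
    if (table.nucleus_t2_ms <= 0).any() or (table.height_ratio <= 0).any():
        raise ValueError("drawn outcomes include nonpositive values; lower the SD")
    return Cohort(table=table, design=design, ground_truth=truth)


def make_histogram_cohort(
    n_subjects: int = 70,
    band: tuple[int, int] = (40, 56),
    assoc: float = 0.8,
    outcome_mean: float = 120.0,
    outcome_sd: float = 9.6,
    subject_loading: float = 0.3,
    band_loading: float = 0.5,
    bin_noise: float = 0.4,
    bin_edges_g: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histogram-level cohort with an association planted in a bin band.

    Per-subject bin counts are log-normal around a smooth decreasing
    baseline profile, with a subject-level total-activity factor loading on
    every bin and a latent band factor ``a_i`` loading only on bins in
    ``band`` (half-open index range).  The outcome shares the band factor:

        outcome_i = mean + sd * (assoc * a_i + sqrt(1 - assoc^2) * e_i)

    so ``assoc = 0`` yields an exact null (outcome independent of every
    bin).  Returns (counts (n_subjects, n_bins), outcome, bin_edges).
    """
    if not 0.0 <= assoc <= 1.0:
        raise ValueError("assoc must be in [0, 1]")
    edges = mad_bins() if bin_edges_g is None else np.asarray(bin_edges_g, dtype=float)
    n_bins = edges.size - 1
    lo, hi = band
    if not 0 <= lo < hi <= n_bins:
        raise ValueError(f"band {band} outside 0..{n_bins}")
    rng = np.random.default_rng(seed)
    base = np.log(3000.0) - 5.0 * np.arange(n_bins) / (n_bins - 1)
    u = rng.normal(size=n_subjects)
    a = rng.normal(size=n_subjects)
    eps = rng.normal(size=(n_subjects, n_bins))
    log_counts = base[None, :] + subject_loading * u[:, None] + bin_noise * eps
    if assoc > 0.0:
        log_counts[:, lo:hi] += band_loading * a[:, None]
    counts = np.exp(log_counts)
    e = rng.normal(size=n_subjects)
    outcome = outcome_mean + outcome_sd * (assoc * a + np.sqrt(1.0 - assoc**2) * e)
    return counts, outcome, edges
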