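"""Seeded synthetic actigraphy cohorts.

Each subject is a multi-day per-minute count series with the gross
statistical structure wrist actigraphy shows: a diurnal activity profile
(smooth daytime envelope scaled by a subject/day amplitude with
multiplicative noise) and a nightly sleep block whose floor is zero,
interrupted by sparse movement bursts ("peaks") separated by zeros.
Peaks arrive as two Poisson processes — frequent small-amplitude bursts
and rarer large-amplitude ones — with geometric run lengths and
gamma-distributed amplitudes; these are the simplest processes that
reproduce zero-separated nocturnal burst trains.

Group effects are multiplicative knobs on the profile (daytime
amplitude, per-class peak rate/length/amplitude, day-to-day regularity),
so case/control cohorts with known, recoverable signal can be generated
for end-to-end tests. Two named presets encode the phenotypes the
pipeline is meant to separate: ``psf_like`` (longer small-amplitude
bursts, sparser large ones) and ``cs_like`` (globally reduced, more
rigidly regular activity).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ingest import EpochSeries

__all__ = [
    "SubjectProfile",
    "GroupEffect",
    "identity_effect",
    "psf_like",
    "cs_like",
    "PRESETS",
    "generate_subject",
    "generate_cohort",
]

MIN_PER_DAY = 1440


@dataclass(frozen=True)
class SubjectProfile:
    """Baseline generative parameters for one subject."""

    days: int = 10
    day_amp: float = 250.0            # mean daytime counts/min
    night_floor: float = 0.0
    sleep_start_min: float = 1380.0   # 23:00, minutes after midnight
    sleep_start_sd: float = 30.0
    sleep_len_min: float = 450.0      # 7.5 h
    sleep_len_sd: float = 40.0
    peak_rate: float = 6.0            # peaks per hour of sleep, all classes
    peak_len_mean: float = 2.0        # epochs, geometric
    peak_amp_mean: float = 40.0       # counts, gamma (all-peak mean)
    large_peak_frac: float = 0.5
    large_amp_factor: float = 4.0     # large amp mean / small amp mean
    circadian_noise_sd: float = 0.25  # lognormal day-level amplitude jitter
    epoch_noise_shape: float = 3.0    # gamma shape of within-day noise
    subject_sd: float = 0.2           # lognormal between-subject spread of
                                      # amplitude/rate/length parameters

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if self.sleep_len_min >= 900:
            raise ValueError("mean sleep length must stay below the 15 h validity cap")
        for name in ("day_amp", "peak_len_mean", "peak_amp_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative group-level modifiers; all default to 1 (identity)."""

    day_amp_mult: float = 1.0
    small_peak_rate_mult: float = 1.0
    large_peak_rate_mult: float = 1.0
    small_peak_len_mult: float = 1.0
    large_peak_len_mult: float = 1.0
    small_peak_amp_mult: float = 1.0
    large_peak_amp_mult: float = 1.0
    sleep_len_mult: float = 1.0
    regularity_mult: float = 1.0      # scales day-to-day jitter SDs; <1 = steadier

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")


def identity_effect() -> GroupEffect:
    return GroupEffect()


def psf_like() -> GroupEffect:
    """Positive-schizotypy-like phenotype: longer small-amplitude
    nocturnal bursts, reduced density of large ones."""
    return GroupEffect(small_peak_len_mult=1.5, large_peak_rate_mult=0.7)


def cs_like() -> GroupEffect:
    """Chronic-schizophrenia-like phenotype: reduced daytime activity
    with a more rigid (more repeatable) rest-activity rhythm."""
    return GroupEffect(day_amp_mult=0.6, regularity_mult=0.4)


PRESETS = {"identity": identity_effect, "psf_like": psf_like, "cs_like": cs_like}


def _diurnal_envelope() -> np.ndarray:
    """Smooth daytime shape over minute-of-day: low overnight, a broad
    raised-cosine hump between ~06:30 and ~23:30."""
    m = np.arange(MIN_PER_DAY)
    rise, fall = 390.0, 1410.0  # 06:30 and 23:30
    u = np.clip((m - rise) / (fall - rise), 0.0, 1.0)
    return 0.35 + 0.65 * np.sin(np.pi * u) ** 1.5


def _sample_peaks(rng, night_len: int, rate_per_h: float, len_mean: float,
                  amp_mean: float, amp_shape: float, out: np.ndarray) -> None:
    n = rng.poisson(rate_per_h * night_len / 60.0)
    if n == 0 or night_len == 0:
        return
    starts = rng.integers(0, night_len, size=n)
    lengths = rng.geometric(min(1.0, 1.0 / max(len_mean, 1.0)), size=n)
    amps = rng.gamma(amp_shape, amp_mean / amp_shape, size=n)
    for s, l, a in zip(starts, lengths, amps):
        e = min(night_len, s + max(1, int(l)))
        out[s:e] = np.maximum(out[s:e], a)


def generate_subject(
    profile: SubjectProfile = SubjectProfile(),
    effect: GroupEffect = GroupEffect(),
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "synthetic",
    missing_days: tuple[int, ...] = (),
) -> EpochSeries:
    """One subject's per-minute series, fully determined by the seed.

    ``missing_days`` zeroes whole calendar days, emulating device
    shut-off / off-wrist days for the validity-filter path.
    """
    rng = np.random.default_rng(seed)
    p = profile
    # subject-level trait multipliers: real cohorts differ between
    # subjects far more than a subject differs between their own days
    def trait() -> float:
        return float(np.exp(rng.normal(0.0, p.subject_sd) - p.subject_sd**2 / 2))

    p = replace(
        p,
        day_amp=p.day_amp * trait(),
        peak_rate=p.peak_rate * trait(),
        peak_len_mean=p.peak_len_mean * trait(),
        peak_amp_mean=p.peak_amp_mean * trait(),
        sleep_len_min=p.sleep_len_min * float(np.exp(rng.normal(0.0, p.subject_sd / 2))),
    )
    n_min = p.days * MIN_PER_DAY
    counts = np.zeros(n_min)

    # daytime layer: envelope x day amplitude x day jitter x epoch noise
    env = np.tile(_diurnal_envelope(), p.days)
    jitter_sd = p.circadian_noise_sd * effect.regularity_mult
    day_mult = np.repeat(
        np.exp(rng.normal(0.0, jitter_sd, size=p.days) - jitter_sd**2 / 2), MIN_PER_DAY
    )
    noise = rng.gamma(p.epoch_noise_shape, 1.0 / p.epoch_noise_shape, size=n_min)
    counts = p.day_amp * effect.day_amp_mult * env * day_mult * noise
    counts = np.maximum(counts + p.night_floor, 0.0)

    # nightly sleep blocks (night -1 covers the early hours of day 0)
    small_amp = p.peak_amp_mean / (
        1 - p.large_peak_frac + p.large_peak_frac * p.large_amp_factor
    )
    large_amp = small_amp * p.large_amp_factor
    small_rate = p.peak_rate * (1 - p.large_peak_frac)
    large_rate = p.peak_rate * p.large_peak_frac
    start_sd = p.sleep_start_sd * effect.regularity_mult
    len_sd = p.sleep_len_sd * effect.regularity_mult
    for night in range(-1, p.days):
        start = night * MIN_PER_DAY + rng.normal(p.sleep_start_min, start_sd)
        length = rng.normal(p.sleep_len_min * effect.sleep_len_mult, len_sd)
        s = max(0, int(round(start)))
        e = min(n_min, int(round(start + max(60.0, length))))
        if e <= s:
            continue
        block = np.full(e - s, p.night_floor)
        # tight amplitude shapes keep the two burst populations separable
        # by a night-level median split, which is what the peak taxonomy
        # downstream relies on
        _sample_peaks(rng, e - s, small_rate * effect.small_peak_rate_mult,
                      p.peak_len_mean * effect.small_peak_len_mult,
                      small_amp * effect.small_peak_amp_mult, 3.0, block)
        _sample_peaks(rng, e - s, large_rate * effect.large_peak_rate_mult,
                      p.peak_len_mean * effect.large_peak_len_mult,
                      large_amp * effect.large_peak_amp_mult, 6.0, block)
        counts[s:e] = block

    for d in missing_days:
        counts[d * MIN_PER_DAY : (d + 1) * MIN_PER_DAY] = 0.0

    return EpochSeries(
        counts=counts,
        subject_id=subject_id,
        start_time=pd.Timestamp("2000-01-03 00:00:00"),
        epoch_len_s=60,
    )


def generate_cohort(
    n_control: int = 25,
    n_case: int = 22,
    base_profile: SubjectProfile = SubjectProfile(),
    effect: GroupEffect = GroupEffect(),
    seed: int = 0,
) -> tuple[list[EpochSeries], pd.Series]:
    """A labelled two-arm cohort (default arm sizes 25 controls / 22
    cases). Controls come from the base profile, cases from the base
    profile with the group effect applied; per-subject seeds are spawned
    from the cohort seed."""
    if n_control < 2 or n_case < 2:
        raise ValueError("need at least 2 subjects per arm")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_control + n_case)
    subjects: list[EpochSeries] = []
    labels = {}
    for i in range(n_control):
        sid = f"ctrl_{i:03d}"
        subjects.append(generate_subject(base_profile, identity_effect(),
                                         seed=children[i], subject_id=sid))
        labels[sid] = 0
    for i in range(n_case):
        sid = f"case_{i:03d}"
        subjects.append(generate_subject(base_profile, effect,
                                         seed=children[n_control + i], subject_id=sid))
        labels[sid] = 1
    return subjects, pd.Series(labels, name="label")
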