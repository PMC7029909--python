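"""Synthetic flocks of annotated sheep-day IMU recordings.

Real ear-tag deployments on sheep are expensive and the field recordings
behind this analysis are not publicly deposited, so every downstream stage
is exercised against a simulator that emulates the documented behavioural
differences between lame and non-lame sheep:

- **walking** — a rhythmic gait oscillation; lame sheep walk at a shifted
  gait frequency and show a phase-jittered head-nod component locked to
  half the stride rate, which raises the spectral entropy of the signal;
- **standing** — low-amplitude postural noise with sparse movement bursts;
  lame sheep shift weight between legs more often and more vigorously;
- **lying** — near-still baseline with rare restlessness events, again
  more frequent and more vigorous in lame sheep.

A single non-negative ``effect_size`` scales every lameness perturbation;
at ``effect_size=0`` the lame and non-lame generators are
distributionally identical, which gives the downstream classifiers a
well-defined null.

Units follow the ear-tag convention: accelerometer channels in g,
gyroscope channels in degrees per second, 16 Hz sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ACTIVITIES = ("walking", "standing", "lying")

#: lameness scores >= 2 define the lame class (0-6 locomotion scale)
LAME_SCORE_THRESHOLD = 2

#: ethogram minimum duration for a walking bout, seconds
MIN_WALKING_BOUT_S = 2.0

SENSOR_COLUMNS = ["timestamp_s", "ax_g", "ay_g", "az_g", "gx_dps", "gy_dps", "gz_dps"]
ANNOTATION_COLUMNS = ["sheep_id", "start_s", "end_s", "activity", "lameness_score"]

# Internal signal-scale constants (see docs/methods.md for rationale).
_WALK_ACCEL_AMP = 0.35       # g, fundamental gait oscillation
_WALK_ACCEL_HARMONIC = 0.08  # g, second harmonic
_WALK_GYRO_AMP = 40.0        # deg/s, fundamental
_WALK_GYRO_HARMONIC = 8.0    # deg/s
_GAIT_PHASE_WALK_SD = 0.2    # rad/sample random-walk phase drift of the gait
_WALK_EXTRA_NOISE = 3.0      # multiplier on base noise while walking
_NOD_GYRO_PER_G = 250.0      # deg/s of head-nod rotation per g of nod accel
_NOD_PHASE_JITTER_SD = 0.9   # rad, per-nod-cycle phase jitter
_STAND_NOISE_FACTOR = 2.0    # multiplier on base accel/gyro noise
_LIE_NOISE_FACTOR = 0.5
_BURST_ACCEL_AMP = 0.25      # g, standing weight-shift burst
_BURST_GYRO_AMP = 35.0       # deg/s
_REST_ACCEL_AMP = 0.12       # g, lying restlessness event
_REST_GYRO_AMP = 18.0        # deg/s
_LAME_EVENT_AMP_GAIN = 0.3   # amplitude gain per unit effect size for events


@dataclass(frozen=True)
class SheepProfile:
    """Static description of one sheep-day used to drive the simulator.

    ``activity_budget`` gives the expected proportion of recording time
    spent walking / standing / lying; ``effect_size`` scales all lameness
    perturbations (0 = indistinguishable from sound, 1 = nominal).
    """

    sheep_id: str
    lameness_score: int
    activity_budget: dict[str, float] = field(
        default_factory=lambda: {"walking": 0.32, "standing": 0.37, "lying": 0.31}
    )
    gait_frequency: float = 1.9  # Hz
    effect_size: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.lameness_score <= 6):
            raise ValueError(
                f"lameness_score must be in 0..6, got {self.lameness_score}"
            )
        if set(self.activity_budget) != set(ACTIVITIES):
            raise ValueError(
                f"activity_budget must cover exactly {ACTIVITIES}, "
                f"got {sorted(self.activity_budget)}"
            )
        props = np.array([self.activity_budget[a] for a in ACTIVITIES])
        if (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("activity_budget proportions must be >= 0 and sum to 1")
        if self.gait_frequency <= 0:
            raise ValueError("gait_frequency must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")

    @property
    def is_lame(self) -> bool:
        return self.lameness_score >= LAME_SCORE_THRESHOLD


@dataclass(frozen=True)
class SimulationConfig:
    """Flock-level simulation parameters.

    Defaults mirror the deployment this pipeline models: 16 Hz sampling
    and a 23-recording flock split 10 non-lame / 13 lame.  Bout durations
    are compressed relative to free-ranging sheep so that a desk-scale
    recording still contains many bouts of every activity.
    """

    sampling_rate: float = 16.0  # Hz
    recording_duration: float = 1800.0  # seconds
    bout_duration_range: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "walking": (8.0, 30.0),
            "standing": (20.0, 80.0),
            "lying": (30.0, 90.0),
        }
    )
    n_lame: int = 13
    n_nonlame: int = 10
    noise_sd_accel: float = 0.01  # g
    noise_sd_gyro: float = 2.0  # deg/s
    lame_frequency_shift: float = 0.15  # Hz per unit effect size
    headnod_amplitude: float = 0.12  # g per unit effect size
    burst_rate_standing: float = 8.0  # events/min (non-lame baseline)
    restlessness_rate_lying: float = 6.0  # events/min (non-lame baseline)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.recording_duration <= 0:
            raise ValueError("recording_duration must be positive")
        if set(self.bout_duration_range) != set(ACTIVITIES):
            raise ValueError(f"bout_duration_range must cover {ACTIVITIES}")
        for act, (lo, hi) in self.bout_duration_range.items():
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid bout_duration_range for {act}: ({lo}, {hi})")
        if self.n_lame < 0 or self.n_nonlame < 0:
            raise ValueError("flock counts must be non-negative")
        for name in (
            "noise_sd_accel",
            "noise_sd_gyro",
            "lame_frequency_shift",
            "headnod_amplitude",
            "burst_rate_standing",
            "restlessness_rate_lying",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TriaxialRecording:
    """One sheep-day of 6-channel sensor data plus behaviour annotations.

    ``annotations`` is a list of ``(start_s, end_s, activity,
    lameness_score)`` tuples covering non-overlapping intervals of the
    recording.
    """

    sheep_id: str
    timestamps: np.ndarray  # seconds, uniform grid
    accel: np.ndarray  # (n, 3) in g
    gyro: np.ndarray  # (n, 3) in deg/s
    annotations: list[tuple[float, float, str, int]]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = len(self.timestamps)
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError(
                f"accel/gyro must be ({n}, 3); got {self.accel.shape}, {self.gyro.shape}"
            )
        if n >= 2:
            steps = np.diff(self.timestamps)
            if (steps <= 0).any() or not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise ValueError("timestamps must be strictly increasing with a constant step")
        duration = self.duration
        prev_end = None
        for i, (start, end, activity, score) in enumerate(self.annotations):
            if activity not in ACTIVITIES:
                raise ValueError(f"annotation {i}: unknown activity {activity!r}")
            if end < start:
                raise ValueError(f"annotation {i}: end {end} < start {start}")
            if start < -1e-9 or end > duration + 1e-9:
                raise ValueError(f"annotation {i}: interval [{start}, {end}] outside recording")
            if prev_end is not None and start < prev_end - 1e-9:
                raise ValueError(f"annotation {i}: overlaps previous interval (starts {start} < {prev_end})")
            prev_end = end

    @property
    def sampling_rate(self) -> float:
        if len(self.timestamps) < 2:
            raise ValueError("need >= 2 samples to infer a sampling rate")
        return 1.0 / (self.timestamps[1] - self.timestamps[0])

    @property
    def duration(self) -> float:
        if len(self.timestamps) == 0:
            return 0.0
        return float(self.timestamps[-1]) + 1.0 / self.sampling_rate

    @property
    def lameness_score(self) -> int:
        if not self.annotations:
            raise ValueError("recording has no annotations")
        return self.annotations[0][3]

    @property
    def is_lame(self) -> bool:
        return self.lameness_score >= LAME_SCORE_THRESHOLD


def default_profiles(
    config: SimulationConfig,
    effect_size: float = 1.0,
    rng: np.random.Generator | None = None,
) -> list[SheepProfile]:
    """Build the default flock: ``n_nonlame`` sheep with locomotion scores
    in {0, 1} and ``n_lame`` with scores in {2, 3} (the range seen in the
    field), all sharing the default activity budget and gait frequency."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    profiles = []
    for i in range(config.n_nonlame):
        profiles.append(
            SheepProfile(
                sheep_id=f"sheep{i:03d}",
                lameness_score=int(rng.integers(0, 2)),
                effect_size=effect_size,
            )
        )
    for i in range(config.n_lame):
        profiles.append(
            SheepProfile(
                sheep_id=f"sheep{config.n_nonlame + i:03d}",
                lameness_score=int(rng.integers(2, 4)),
                effect_size=effect_size,
            )
        )
    return profiles


def _smooth_pulse(n: int) -> np.ndarray:
    """Unit-amplitude raised-cosine pulse of n samples."""
    if n <= 1:
        return np.ones(max(n, 0))
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / (n - 1)))


def _event_train(
    n: int,
    f_s: float,
    rate_per_min: float,
    accel_amp: float,
    gyro_amp: float,
    dur_range_s: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sparse Poisson train of smooth movement pulses on the main axis."""
    accel = np.zeros(n)
    gyro = np.zeros(n)
    if rate_per_min <= 0 or n == 0:
        return accel, gyro
    # events are stereotyped (fixed amplitude and duration per type) and
    # arrive as a jittered-regular renewal process rather than a Poisson
    # train: per-event shape variability and Poisson count dispersion
    # would give individual sheep distinctive realised statistics that a
    # classifier could memorise even with no lameness effect present
    width = max(int(round(sum(dur_range_s) / 2.0 * f_s)), 2)
    pulse = _smooth_pulse(width)
    spacing = 60.0 * f_s / rate_per_min  # samples between events
    pos = spacing * rng.uniform(0.0, 1.0)
    while pos < n:
        start = int(round(pos))
        sign = rng.choice([-1.0, 1.0])
        accel[start : start + width] += sign * accel_amp * pulse[: n - start]
        gyro[start : start + width] += sign * gyro_amp * pulse[: n - start]
        pos += spacing * rng.uniform(0.7, 1.3)
    return accel, gyro


def _jittered_nod(
    n: int, f_s: float, nod_freq: float, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Sinusoid at the head-nod frequency with per-cycle phase jitter.

    The jitter de-coheres the nod from cycle to cycle, smearing its
    spectral line and raising the spectral entropy of lame walking.
    """
    t = np.arange(n) / f_s
    cycle = np.floor(t * nod_freq).astype(int)
    n_cycles = int(cycle.max()) + 1 if n else 0
    jitter = rng.normal(0.0, _NOD_PHASE_JITTER_SD, size=max(n_cycles, 1))
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    return amplitude * np.sin(2.0 * np.pi * nod_freq * t + phase0 + jitter[cycle])


def generate_activity_bout(
    activity: str,
    profile: SheepProfile,
    duration: float,
    rng: np.random.Generator,
    config: SimulationConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one bout of 6-channel signal for a single activity.

    Returns ``(accel, gyro)`` arrays of shape ``(n, 3)`` with the dominant
    dynamic component on axis 0 (the axis that later carries the 1 g
    gravity offset, so that the magnitude signal inherits the dynamics
    linearly).  Walking requires ``duration >= 2`` s, the ethogram minimum.
    """
    if activity not in ACTIVITIES:
        raise ValueError(f"unknown activity {activity!r}; expected one of {ACTIVITIES}")
    if config is None:
        config = SimulationConfig()
    if duration <= 0:
        raise ValueError("bout duration must be positive")
    if activity == "walking" and duration < MIN_WALKING_BOUT_S:
        raise ValueError(
            f"walking bouts must last >= {MIN_WALKING_BOUT_S} s (ethogram minimum), got {duration}"
        )
    f_s = config.sampling_rate
    n = int(round(duration * f_s))
    t = np.arange(n) / f_s
    e = profile.effect_size if profile.is_lame else 0.0

    accel = rng.normal(0.0, config.noise_sd_accel, size=(n, 3))
    gyro = rng.normal(0.0, config.noise_sd_gyro, size=(n, 3))

    if activity == "walking":
        f_gait = max(profile.gait_frequency - e * config.lame_frequency_shift, 0.5)
        phase = rng.uniform(0.0, 2.0 * np.pi, size=4)
        # the stride is not phase-locked over a bout: a slow random-walk
        # phase drift decorrelates windows within a bout while keeping the
        # spectral line far narrower than one DFT bin of a 7 s window
        drift = np.cumsum(rng.normal(0.0, _GAIT_PHASE_WALK_SD, size=n))
        stride = 2 * np.pi * f_gait * t + drift
        # the harmonic and cross-axis components drift relative to the
        # stride as well: a bout-constant relative phase would imprint a
        # persistent waveform shape (e.g. skewness) on every window of
        # the bout, an identity cue rather than a lameness cue
        psi_h = np.cumsum(rng.normal(0.0, _GAIT_PHASE_WALK_SD, size=n))
        psi_y = np.cumsum(rng.normal(0.0, _GAIT_PHASE_WALK_SD, size=n))
        accel[:, 0] += _WALK_ACCEL_AMP * np.sin(stride + phase[0])
        accel[:, 0] += _WALK_ACCEL_HARMONIC * np.sin(2 * stride + psi_h + phase[1])
        accel[:, 1] += 0.3 * _WALK_ACCEL_AMP * np.sin(stride + psi_y + phase[2])
        gyro[:, 0] += _WALK_GYRO_AMP * np.sin(stride + phase[0])
        gyro[:, 0] += _WALK_GYRO_HARMONIC * np.sin(2 * stride + psi_h + phase[1])
        gyro[:, 1] += 0.3 * _WALK_GYRO_AMP * np.sin(stride + psi_y + phase[3])
        accel += rng.normal(0.0, (_WALK_EXTRA_NOISE - 1) * config.noise_sd_accel, size=(n, 3))
        gyro += rng.normal(0.0, (_WALK_EXTRA_NOISE - 1) * config.noise_sd_gyro, size=(n, 3))
        nod_amp = e * config.headnod_amplitude
        if nod_amp > 0:
            nod = _jittered_nod(n, f_s, f_gait / 2.0, 1.0, rng)
            accel[:, 0] += nod_amp * nod
            gyro[:, 0] += nod_amp * _NOD_GYRO_PER_G * nod
    elif activity == "standing":
        accel += rng.normal(
            0.0, (_STAND_NOISE_FACTOR - 1) * config.noise_sd_accel, size=(n, 3)
        )
        gyro += rng.normal(0.0, (_STAND_NOISE_FACTOR - 1) * config.noise_sd_gyro, size=(n, 3))
        rate = config.burst_rate_standing * (1.0 + e)
        amp_gain = 1.0 + _LAME_EVENT_AMP_GAIN * e
        ev_a, ev_g = _event_train(
            n, f_s, rate, _BURST_ACCEL_AMP * amp_gain, _BURST_GYRO_AMP * amp_gain,
            (0.5, 1.5), rng,
        )
        accel[:, 0] += ev_a
        gyro[:, 0] += ev_g
    else:  # lying
        accel *= _LIE_NOISE_FACTOR
        gyro *= _LIE_NOISE_FACTOR
        rate = config.restlessness_rate_lying * (1.0 + e)
        amp_gain = 1.0 + _LAME_EVENT_AMP_GAIN * e
        ev_a, ev_g = _event_train(
            n, f_s, rate, _REST_ACCEL_AMP * amp_gain, _REST_GYRO_AMP * amp_gain,
            (1.0, 2.0), rng,
        )
        accel[:, 0] += ev_a
        gyro[:, 0] += ev_g
    return accel, gyro


def _schedule_bouts(
    profile: SheepProfile, config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[float, float, str]]:
    """Alternating-renewal bout schedule tracking the activity budget.

    At each transition the activity with the largest time deficit relative
    to its budget is entered (a quota scheduler), which keeps realised
    time shares within a bout length of the target budget; bout lengths
    are uniform in the per-activity range.
    """
    T = config.recording_duration
    spent = {a: 0.0 for a in ACTIVITIES}
    bouts: list[tuple[float, float, str]] = []
    t = 0.0
    while t < T - 1e-9:
        remaining = T - t
        candidates = list(ACTIVITIES)
        if remaining < MIN_WALKING_BOUT_S:
            candidates = [a for a in candidates if a != "walking"]
        deficits = {
            a: profile.activity_budget[a] * (t + 1.0) - spent[a] for a in candidates
        }
        activity = max(candidates, key=lambda a: deficits[a])
        lo, hi = config.bout_duration_range[activity]
        dur = min(rng.uniform(lo, hi), remaining)
        if activity == "walking" and dur < MIN_WALKING_BOUT_S:
            dur = min(MIN_WALKING_BOUT_S, remaining)
        bouts.append((t, t + dur, activity))
        spent[activity] += dur
        t += dur
    return bouts


def generate_recording(
    profile: SheepProfile, config: SimulationConfig, rng: np.random.Generator
) -> TriaxialRecording:
    """Simulate one sheep-day recording for a single profile."""
    f_s = config.sampling_rate
    n_total = int(round(config.recording_duration * f_s))
    accel = np.zeros((n_total, 3))
    gyro = np.zeros((n_total, 3))
    annotations: list[tuple[float, float, str, int]] = []

    gravity_axis = int(rng.integers(0, 3))
    bouts = _schedule_bouts(profile, config, rng)
    i = 0
    for start_s, end_s, activity in bouts:
        j = min(int(round(end_s * f_s)), n_total)
        if j <= i:
            continue
        dur = (j - i) / f_s
        seg_a, seg_g = generate_activity_bout(activity, profile, dur, rng, config)
        accel[i:j] = seg_a[: j - i]
        gyro[i:j] = seg_g[: j - i]
        annotations.append((i / f_s, j / f_s, activity, profile.lameness_score))
        i = j

    # ear-tag orientation fixed per recording: static 1 g on one axis,
    # aligned with the main dynamic component so the magnitude signal
    # carries the dynamics linearly
    accel = np.roll(accel, gravity_axis, axis=1)
    gyro = np.roll(gyro, gravity_axis, axis=1)
    accel[:, gravity_axis] += 1.0

    timestamps = np.arange(n_total) / f_s
    return TriaxialRecording(
        sheep_id=profile.sheep_id,
        timestamps=timestamps,
        accel=accel,
        gyro=gyro,
        annotations=annotations,
    )


def generate_flock(
    config: SimulationConfig, profiles: list[SheepProfile] | None = None
) -> list[TriaxialRecording]:
    """Generate one recording per profile, reproducibly.

    With ``profiles=None`` the default flock (``config.n_nonlame`` sound,
    ``config.n_lame`` lame sheep) is used.  The same config + profiles +
    seed reproduce bit-identical output: each recording draws from an
    independent child stream of ``config.rng_seed``.
    """
    seed_seq = np.random.SeedSequence(config.rng_seed)
    if profiles is None:
        profiles = default_profiles(
            config, rng=np.random.default_rng(seed_seq.spawn(1)[0])
        )
    if not profiles:
        raise ValueError("profiles must be non-empty")
    child_seqs = seed_seq.spawn(len(profiles) + 1)[1:]
    return [
        generate_recording(profile, config, np.random.default_rng(child))
        for profile, child in zip(profiles, child_seqs)
    ]


def write_recording(
    recording: TriaxialRecording, sensor_path, annotation_path
) -> None:
    """Write a recording to a sensor CSV and an annotation CSV.

    Floats are written at full precision so that a read round-trips the
    recording exactly.
    """
    sensor = pd.DataFrame(
        {
            "timestamp_s": recording.timestamps,
            "ax_g": recording.accel[:, 0],
            "ay_g": recording.accel[:, 1],
            "az_g": recording.accel[:, 2],
            "gx_dps": recording.gyro[:, 0],
            "gy_dps": recording.gyro[:, 1],
            "gz_dps": recording.gyro[:, 2],
        }
    )
    sensor.to_csv(sensor_path, index=False)
    ann = pd.DataFrame(
        [
            {
                "sheep_id": recording.sheep_id,
                "start_s": start,
                "end_s": end,
                "activity": activity,
                "lameness_score": score,
            }
            for start, end, activity, score in recording.annotations
        ],
        columns=ANNOTATION_COLUMNS,
    )
    ann.to_csv(annotation_path, index=False)


def read_recording(sensor_path, annotation_path) -> TriaxialRecording:
    """Read a recording from disk, validating and canonicalizing.

    Annotation rows may appear in any order on disk and are sorted by
    start time; malformed rows (end < start, overlaps, unknown activity)
    and non-monotone sensor timestamps are rejected with row-level
    diagnostics.
    """
    sensor = pd.read_csv(sensor_path, float_precision="round_trip")
    missing = set(SENSOR_COLUMNS) - set(sensor.columns)
    if missing:
        raise ValueError(f"sensor CSV missing columns {sorted(missing)}")
    ts = sensor["timestamp_s"].to_numpy(dtype=float)
    if len(ts) >= 2 and (np.diff(ts) <= 0).any():
        bad = int(np.argmax(np.diff(ts) <= 0))
        raise ValueError(f"non-monotone timestamps at sensor row {bad + 1}")

    ann = pd.read_csv(annotation_path, float_precision="round_trip")
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns {sorted(missing)}")
    for idx, row in ann.iterrows():
        if row["end_s"] < row["start_s"]:
            raise ValueError(
                f"annotation row {idx}: end_s {row['end_s']} < start_s {row['start_s']}"
            )
        if row["activity"] not in ACTIVITIES:
            raise ValueError(f"annotation row {idx}: unknown activity {row['activity']!r}")
    ann = ann.sort_values("start_s", kind="stable").reset_index(drop=True)
    ends = ann["end_s"].to_numpy(dtype=float)
    starts = ann["start_s"].to_numpy(dtype=float)
    overlap = np.nonzero(starts[1:] < ends[:-1] - 1e-9)[0]
    if overlap.size:
        i = int(overlap[0]) + 1
        raise ValueError(
            f"annotation row {i}: interval starting {starts[i]} overlaps previous end {ends[i - 1]}"
        )
    sheep_ids = ann["sheep_id"].unique()
    if len(sheep_ids) > 1:
        raise ValueError(f"annotation CSV mixes sheep ids {sorted(map(str, sheep_ids))}")
    sheep_id = str(sheep_ids[0]) if len(sheep_ids) else "unknown"
    annotations = [
        (float(r["start_s"]), float(r["end_s"]), str(r["activity"]), int(r["lameness_score"]))
        for _, r in ann.iterrows()
    ]
    return TriaxialRecording(
        sheep_id=sheep_id,
        timestamps=ts,
        accel=sensor[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float),
        gyro=sensor[["gx_dps", "gy_dps", "gz_dps"]].to_numpy(dtype=float),
        annotations=annotations,
    )


def config_from_mapping(mapping: dict) -> SimulationConfig:
    """Build a SimulationConfig from a flat mapping (e.g. parsed YAML)."""
    mapping = dict(mapping)
    if "bout_duration_range" in mapping:
        mapping["bout_duration_range"] = {
            act: tuple(rng) for act, rng in mapping["bout_duration_range"].items()
        }
    return replace(SimulationConfig(), **mapping)
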