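"""Synthetic wearable-band sensor streams for personal-risk detection.

Emulates the multi-rate recording of a wrist band worn continuously: motion
sensors (accelerometer, gyroscope) at 8 Hz, vitals and cumulative counters at
1 Hz, skin temperature every 30 s and ultraviolet exposure every 60 s.  A
cohort consists of, per user, one *normal-conditions* stream (ordinary diurnal
activity, a rest/active semi-Markov mixture) and five *anomaly-conditions*
streams staged from stress scenarios: sprinting, stair climbing, boxing,
falls and breath holding.

The generator is deliberately simple — a two-state gait model plus
mean-reverting vitals — but it reproduces the statistical structure the
downstream pipeline relies on: windowed motion energy separates rest, walking
and high-intensity scenarios; heart rate shifts with exertion; counters are
cumulative and monotone; every sensor keeps its own readout interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DAY_START_HOUR = 7.0
DAY_END_HOUR = 22.0

#: Gait parameters of the ordinary "walk" regime; scenario intensity is
#: expressed relative to these.
WALK_AMPLITUDE_G = 0.25
WALK_CADENCE_HZ = 1.95
WALK_GYRO_AMP = 40.0  # deg/s
ACTIVE_HR_RISE = 25.0  # bpm above baseline while walking


@dataclass(frozen=True)
class SensorSpec:
    """One sensor of the band: named channels read out at a fixed interval."""

    name: str
    channels: tuple[str, ...]
    readout_interval: float  # seconds
    units: str

    def __post_init__(self):
        if self.readout_interval <= 0:
            raise ValueError("readout_interval must be positive")
        if not self.channels:
            raise ValueError("a sensor needs at least one channel")


#: The default band schema: exactly eight sensors.
SENSORS: dict[str, SensorSpec] = {
    s.name: s
    for s in (
        SensorSpec("accelerometer", ("x", "y", "z"), 0.125, "g"),
        SensorSpec(
            "gyroscope",
            ("accel_x", "accel_y", "accel_z", "angvel_x", "angvel_y", "angvel_z"),
            0.125,
            "g / deg/s",
        ),
        SensorSpec("distance", ("distance_cm", "speed_cm_s", "pace_ms_m"), 1.0, "cm, cm/s, ms/m"),
        SensorSpec("heart_rate", ("bpm",), 1.0, "bpm"),
        SensorSpec("pedometer", ("steps",), 1.0, "steps"),
        SensorSpec("calories", ("kcal",), 1.0, "kcal"),
        SensorSpec("skin_temperature", ("celsius",), 30.0, "deg C"),
        SensorSpec("ultraviolet", ("uv_index",), 60.0, "index"),
    )
}

SCENARIO_KINDS = ("run", "stairs", "boxing", "falls", "breath_hold")

#: Realistic session lengths (s): a 100 m sprint lasts tens of seconds, a
#: boxing episode two minutes, falls and breath holds are staged with pauses.
DEFAULT_SCENARIO_DURATIONS = {
    "run": 30.0,
    "stairs": 60.0,
    "boxing": 120.0,
    "falls": 90.0,
    "breath_hold": 90.0,
}

DEFAULT_PROFILE_RANGES: dict[str, tuple[float, float]] = {
    "age": (21.0, 52.0),
    "height": (1.56, 1.86),
    "weight": (42.0, 101.0),
    "exercise_hours_per_week": (0.0, 10.0),
    "baseline_heart_rate": (55.0, 75.0),
    "baseline_skin_temp": (32.5, 34.5),
}


@dataclass
class UserProfile:
    user_id: str
    age: float
    height: float
    weight: float
    exercise_hours_per_week: float
    baseline_heart_rate: float
    baseline_skin_temp: float
    #: diurnal mixture: target active fraction by day/night and mean bout lengths
    activity_rhythm_params: dict = field(default_factory=dict)


@dataclass
class ScenarioSpec:
    """One staged stress scenario and its intensity.

    ``motion_multiplier`` scales gait amplitude/cadence relative to ordinary
    walking (1.0 -> indistinguishable from a walk); ``hr_delta`` is the peak
    heart-rate shift in bpm; ``fall_impulse`` the impact magnitude in g added
    on top of rest motion for the ``falls`` scenario; breath holding follows a
    rise-then-drop heart-rate trajectory scaled by ``hr_delta``.
    """

    kind: str
    duration: float | None = None
    motion_multiplier: float = 3.0
    hr_delta: float = 40.0
    fall_impulse: float = 4.0

    def __post_init__(self):
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}; expected one of {SCENARIO_KINDS}")
        if self.duration is None:
            self.duration = DEFAULT_SCENARIO_DURATIONS[self.kind]
        if self.duration <= 0:
            raise ValueError("scenario duration must be positive")


def default_scenarios(motion_multiplier=3.0, hr_delta=40.0, fall_impulse=4.0) -> list[ScenarioSpec]:
    """The five-scenario battery at a common intensity setting."""
    return [
        ScenarioSpec(kind, motion_multiplier=motion_multiplier, hr_delta=hr_delta, fall_impulse=fall_impulse)
        for kind in SCENARIO_KINDS
    ]


@dataclass
class SensorStream:
    """Time-ordered multi-sensor recording of one user session.

    ``frames`` maps sensor name to a DataFrame with a ``timestamp_ms`` column
    (integer milliseconds from session start) plus one column per channel.
    """

    user_id: str
    session_label: str  # "normal" or a scenario kind
    frames: dict[str, pd.DataFrame]
    start_hour: float = 8.0

    @property
    def n_records(self) -> int:
        """Number of readout events (one per sensor readout, not per channel)."""
        return sum(len(f) for f in self.frames.values())

    @property
    def duration_s(self) -> float:
        ends = [
            (f["timestamp_ms"].iloc[-1] / 1000.0) + SENSORS[name].readout_interval
            for name, f in self.frames.items()
            if len(f)
        ]
        return max(ends) if ends else 0.0

    def to_long(self) -> pd.DataFrame:
        """Long-form view: one row per channel value."""
        parts = []
        for name, f in self.frames.items():
            melted = f.melt(id_vars="timestamp_ms", var_name="channel", value_name="value")
            melted.insert(1, "sensor", name)
            parts.append(melted)
        out = pd.concat(parts, ignore_index=True)
        return out.sort_values(["timestamp_ms", "sensor", "channel"], kind="stable").reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path, user_id: str, session_label: str, start_hour: float = 8.0) -> "SensorStream":
        long = pd.read_csv(path)
        frames = {}
        for name, grp in long.groupby("sensor"):
            wide = grp.pivot_table(index="timestamp_ms", columns="channel", values="value").reset_index()
            wide.columns.name = None
            cols = ["timestamp_ms"] + [c for c in SENSORS[name].channels if c in wide.columns]
            frames[name] = wide[cols]
        return cls(user_id=user_id, session_label=session_label, frames=frames, start_hour=start_hour)


def make_profile(seed, ranges=None, user_id: str | None = None) -> UserProfile:
    """Draw a user profile uniformly within demographic ranges.

    Deterministic given ``seed``; ``ranges`` overrides any subset of
    :data:`DEFAULT_PROFILE_RANGES`.
    """
    merged = dict(DEFAULT_PROFILE_RANGES)
    if ranges:
        merged.update(ranges)
    for name, (lo, hi) in merged.items():
        if lo > hi:
            raise ValueError(f"inverted range for {name!r}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    draw = {name: rng.uniform(lo, hi) for name, (lo, hi) in merged.items()}
    rhythm = {
        # daytime locomotion share of an errand-filled day; matches the
        # scenario battery's locomotor share so a zero-intensity cohort is an
        # exchangeability control for the detector
        "active_fraction_day": rng.uniform(0.48, 0.60),
        "active_fraction_night": rng.uniform(0.01, 0.04),
        # short bouts keep the rest/active mix stable across fifths of a session
        "mean_active_bout_s": rng.uniform(45.0, 90.0),
        "mean_rest_bout_s": rng.uniform(90.0, 180.0),
        # personal gait signature: regular patterns with small variations
        "gait_amplitude_g": rng.normal(WALK_AMPLITUDE_G, 0.03),
        "gait_cadence_hz": rng.normal(WALK_CADENCE_HZ, 0.05),
    }
    if user_id is None:
        user_id = f"user{seed}" if np.isscalar(seed) else "user"
    return UserProfile(
        user_id=user_id,
        age=draw["age"],
        height=draw["height"],
        weight=draw["weight"],
        exercise_hours_per_week=draw["exercise_hours_per_week"],
        baseline_heart_rate=draw["baseline_heart_rate"],
        baseline_skin_temp=draw["baseline_skin_temp"],
        activity_rhythm_params=rhythm,
    )


# ---------------------------------------------------------------------------
# per-second regime descriptions


@dataclass
class _Regime:
    """Per-second arrays steering the signal synthesiser."""

    amp: np.ndarray  # gait amplitude, g (0 at rest)
    cadence: np.ndarray  # gait cadence, Hz
    gyro_amp: np.ndarray  # angular-velocity amplitude, deg/s
    hr_target: np.ndarray  # bpm
    steps_rate: np.ndarray  # steps per second
    impulses: list[tuple[int, float]] = field(default_factory=list)  # (8 Hz sample idx, magnitude g)
    #: HR tracking rate: slow metabolic integration for ordinary days; fast
    #: (vagal/sympathetic) tracking for scenario trajectories that already
    #: encode the acute response shape
    hr_theta: float = 0.025

    @property
    def n(self) -> int:
        return len(self.amp)


def _normal_regime(profile: UserProfile, duration: int, rng, start_hour: float) -> _Regime:
    p = profile.activity_rhythm_params
    f_day = p.get("active_fraction_day", 0.35)
    f_night = p.get("active_fraction_night", 0.02)
    ma = p.get("mean_active_bout_s", 120.0)
    mr = p.get("mean_rest_bout_s", 300.0)

    gait_amp = p.get("gait_amplitude_g", WALK_AMPLITUDE_G)
    gait_cad = p.get("gait_cadence_hz", WALK_CADENCE_HZ)

    active = np.zeros(duration, dtype=bool)
    amp = np.zeros(duration)
    cadence = np.full(duration, gait_cad)
    hr_rise = np.zeros(duration)
    t = 0
    while t < duration:
        hour = (start_hour + t / 3600.0) % 24.0
        f = f_day if DAY_START_HOUR <= hour < DAY_END_HOUR else f_night
        # bout-type probability giving long-run active fraction f
        p_act = f * mr / ((1.0 - f) * ma + f * mr)
        is_active = rng.random() < p_act
        mean = ma if is_active else mr
        dur = int(np.clip(rng.exponential(mean), 15.0, 900.0))
        end = min(t + dur, duration)
        if is_active:
            active[t:end] = True
            # the personal gait signature varies only slightly bout to bout,
            # but the cardiac cost of a bout varies a lot (load, slope, pace)
            amp[t:end] = max(0.05, gait_amp + rng.normal(0.0, 0.01))
            cadence[t:end] = gait_cad + rng.normal(0.0, 0.03)
            hr_rise[t:end] = max(5.0, rng.normal(ACTIVE_HR_RISE, 8.0))
        t = end
    gyro_amp = np.where(active, WALK_GYRO_AMP * gait_amp / WALK_AMPLITUDE_G, 0.0)
    hr_target = profile.baseline_heart_rate + hr_rise
    steps_rate = np.where(active, cadence, 0.0)
    return _Regime(amp, cadence, gyro_amp, hr_target, steps_rate)


def _scenario_regime(profile: UserProfile, spec: ScenarioSpec, rng) -> _Regime:
    n = int(spec.duration)
    base_hr = profile.baseline_heart_rate
    m = spec.motion_multiplier
    rhythm = profile.activity_rhythm_params
    gait_amp = rhythm.get("gait_amplitude_g", WALK_AMPLITUDE_G)
    gait_gyro = WALK_GYRO_AMP * gait_amp / WALK_AMPLITUDE_G
    # Intensity parameterises a DEVIATION from the user's normal repertoire:
    # at multiplier 1 and zero deltas every scenario collapses to an ordinary
    # behaviour (the user's own walk, or rest), so a zero-effect cohort is an
    # exchangeability control for the downstream detector.
    beta = float(np.clip(m - 1.0, 0.0, 1.0))  # scenario character, fully developed by m = 2
    # a session is one bout: it carries the same bout-level variability as an
    # ordinary bout (gait jitter, variable cardiac cost), so a zero-intensity
    # session is statistically a regular bout, not an idealised one
    gait_amp = max(0.05, gait_amp + rng.normal(0.0, 0.01))
    cad = (rhythm.get("gait_cadence_hz", WALK_CADENCE_HZ) + rng.normal(0.0, 0.03)) * (1.0 + 0.3 * (m - 1.0))
    walk_hr = base_hr + max(5.0, rng.normal(ACTIVE_HR_RISE, 8.0))  # natural response to locomotion
    zeros = np.zeros(n)
    if spec.kind == "run":
        reg = _Regime(
            amp=np.full(n, gait_amp * m),
            cadence=np.full(n, cad),
            gyro_amp=np.full(n, gait_gyro * m),
            hr_target=np.full(n, walk_hr + spec.hr_delta),
            steps_rate=np.full(n, cad),
        )
    elif spec.kind == "stairs":
        c = 1.0 - 0.1 * beta  # slightly slower, choppier than level walking
        reg = _Regime(
            amp=np.full(n, c * gait_amp * m),
            cadence=np.full(n, c * cad),
            gyro_amp=np.full(n, c * gait_gyro * m),
            hr_target=np.full(n, walk_hr + 0.9 * spec.hr_delta),
            steps_rate=np.full(n, c * cad),
        )
    elif spec.kind == "boxing":
        # bursts of arm strikes without locomotion, a bouncing guard stance
        # in between; burstiness and step suppression are scenario character
        duty = np.where(rng.random(n) < 1.0 - 0.3 * beta, 1.0, 0.0)
        stance = (1.0 - duty) * (1.0 - 0.75 * beta)
        reg = _Regime(
            amp=gait_amp * m * (duty * (1.0 - 0.2 * beta) + stance),
            cadence=np.full(n, (1.0 + 0.2 * beta) * cad),
            gyro_amp=gait_gyro * m * (duty * (1.0 + 0.5 * beta) + stance),
            hr_target=np.full(n, walk_hr + 0.8 * spec.hr_delta),
            steps_rate=(1.0 - beta) * cad * duty,
        )
    elif spec.kind == "falls":
        # falling back and forth: an impact roughly every 4 s with
        # getting-up motion (but no locomotion) in between
        n_falls = max(1, n // 4)
        times = np.sort(rng.choice(np.arange(8, n * 8 - 8), size=n_falls, replace=False))
        impulses = [(int(t8), spec.fall_impulse) for t8 in times]
        recovery = 0.075 * spec.fall_impulse  # tumbling amplitude in g, off when the impulse is zero
        reg = _Regime(
            amp=np.full(n, recovery),
            cadence=np.full(n, 0.8 * WALK_CADENCE_HZ),
            gyro_amp=np.full(n, recovery / WALK_AMPLITUDE_G * WALK_GYRO_AMP),
            hr_target=np.full(n, base_hr + 0.6 * spec.hr_delta),
            steps_rate=zeros,
            impulses=impulses,
        )
    elif spec.kind == "breath_hold":
        # heart rate climbs briefly, then the diving reflex drives a deep
        # bradycardia for the rest of the hold, recovering at release; late in
        # a maximal hold, involuntary diaphragmatic contractions add a faint
        # strain tremor on top of otherwise near-rest motion
        t = np.arange(n) / max(n - 1, 1)
        traj = np.where(
            t < 0.15,
            0.4 * spec.hr_delta * (t / 0.15),
            np.where(
                t < 0.35,
                0.4 * spec.hr_delta - 1.05 * spec.hr_delta * (t - 0.15) / 0.2,
                np.where(
                    t < 0.9,
                    -0.65 * spec.hr_delta,
                    -0.65 * spec.hr_delta * (1.0 - (t - 0.9) / 0.1),
                ),
            ),
        )
        tremor = 0.04 * max(m - 1.0, 0.0) * np.clip((t - 0.15) / 0.4, 0.0, 1.0)
        reg = _Regime(
            amp=tremor,
            cadence=np.full(n, 1.0),
            gyro_amp=tremor / WALK_AMPLITUDE_G * 0.3 * WALK_GYRO_AMP,
            hr_target=base_hr + traj,
            steps_rate=zeros,
        )
    else:  # pragma: no cover - guarded by ScenarioSpec
        raise ValueError(f"unknown scenario kind {spec.kind!r}")
    # acute (vagal/sympathetic) HR tracking develops with scenario intensity;
    # a zero-intensity session keeps the ordinary metabolic dynamics
    reg.hr_theta = 0.025 + 0.095 * beta
    return reg


# ---------------------------------------------------------------------------
# signal synthesis


def _ar1(target: np.ndarray, theta: float, sigma: float, init: float, rng) -> np.ndarray:
    """Mean-reverting (OU-like) series x_t = x_{t-1} + theta (target - x) + noise."""
    from scipy.signal import lfilter

    noise = rng.normal(0.0, sigma, len(target))
    drive = theta * target + noise
    out = lfilter([1.0], [1.0, -(1.0 - theta)], drive, zi=[(1.0 - theta) * init])[0]
    return out


def _synthesize(profile: UserProfile, regime: _Regime, seed, label: str, start_hour: float) -> SensorStream:
    rng = np.random.default_rng(seed)
    n = regime.n
    n8 = n * 8

    amp8 = np.repeat(regime.amp, 8)
    cad8 = np.repeat(regime.cadence, 8)
    gamp8 = np.repeat(regime.gyro_amp, 8)
    # phase noise decoheres the gait oscillation: real wrist motion is not a
    # clean sinusoid, and window means must not swing with sampling phase
    phase = np.cumsum(2.0 * np.pi * cad8 / 8.0 + rng.normal(0.0, 0.12, n8))
    moving = amp8 > 0

    def osc(amplitude, offset, noise_floor, noise_scale):
        sigma = noise_floor + noise_scale * amp8
        return amplitude * np.sin(phase + offset) + rng.normal(0.0, 1.0, n8) * sigma

    # rest is never perfectly still: fidgeting keeps a noise floor of a few
    # hundredths of a g on every axis, rising only mildly with activity
    ax = 0.02 + osc(0.5 * amp8, 1.1, 0.025, 0.04)
    ay = -0.01 + osc(0.4 * amp8, 2.3, 0.025, 0.04)
    az = 1.0 + osc(amp8, 0.0, 0.030, 0.05)
    # the gyroscope's own accelerometer channels: same body motion, different noise
    gax = 0.02 + osc(0.45 * amp8, 0.6, 0.028, 0.045)
    gay = -0.02 + osc(0.45 * amp8, 1.9, 0.028, 0.045)
    gaz = 1.0 + osc(0.9 * amp8, 0.3, 0.032, 0.055)
    wnoise = 2.5 + 0.10 * gamp8
    wx = gamp8 * np.sin(phase + 0.4) + rng.normal(0.0, 1.0, n8) * wnoise
    wy = 0.8 * gamp8 * np.sin(phase + 1.7) + rng.normal(0.0, 1.0, n8) * wnoise
    wz = 0.6 * gamp8 * np.sin(phase + 2.9) + rng.normal(0.0, 1.0, n8) * wnoise

    for t8, mag in regime.impulses:
        shape = mag * np.array([0.3, 1.0, -0.6])
        az[t8 : t8 + 3] += shape[: max(0, min(3, n8 - t8))]
        ax[t8 : t8 + 3] += 0.5 * shape[: max(0, min(3, n8 - t8))]
        gaz[t8 : t8 + 3] += 0.8 * shape[: max(0, min(3, n8 - t8))]
        wx[t8 : t8 + 3] += 80.0 * mag * np.array([1.0, -0.7, 0.2])[: max(0, min(3, n8 - t8))]

    ts8 = np.arange(n8, dtype=np.int64) * 125
    accel = pd.DataFrame({"timestamp_ms": ts8, "x": ax, "y": ay, "z": az})
    gyro = pd.DataFrame(
        {
            "timestamp_ms": ts8,
            "accel_x": gax,
            "accel_y": gay,
            "accel_z": gaz,
            "angvel_x": wx,
            "angvel_y": wy,
            "angvel_z": wz,
        }
    )

    ts1 = np.arange(n, dtype=np.int64) * 1000
    # heart rate integrates exertion over tens of seconds, so it lags the
    # instantaneous activity signal rather than tracking it beat for beat
    hr = _ar1(regime.hr_target, theta=regime.hr_theta, sigma=0.3, init=profile.baseline_heart_rate, rng=rng)
    # slow autonomous variability (stress, posture, digestion) independent of motion
    hr = hr + _ar1(np.zeros(n), theta=0.01, sigma=0.8, init=0.0, rng=rng)
    hr = hr + rng.normal(0.0, 1.0, n)  # sensor/beat-to-beat noise
    hr = np.clip(hr, 35.0, 220.0)

    # steps accumulate deterministically from cadence (a steady walker takes
    # 1-2 steps each second); the counter itself is integer-valued
    steps = np.floor(np.cumsum(np.maximum(regime.steps_rate, 0.0)))
    steps_inc = np.diff(steps, prepend=0.0)
    stride_cm = 41.0 * profile.height  # rough stride length from stature
    dist_inc = steps_inc * stride_cm * (1.0 + rng.normal(0.0, 0.03, n))
    distance = np.cumsum(dist_inc)
    speed = dist_inc.copy()  # cm moved in the last second
    with np.errstate(divide="ignore"):
        pace = np.where(speed > 1e-9, 1e5 / np.maximum(speed, 1e-9), 0.0)  # ms per metre
    pace = np.minimum(pace, 5000.0)
    cal_inc = np.maximum(
        0.018 + 0.0009 * profile.weight * (regime.amp / WALK_AMPLITUDE_G) + rng.normal(0.0, 0.001, n), 0.0
    )
    calories = np.cumsum(cal_inc)

    heart = pd.DataFrame({"timestamp_ms": ts1, "bpm": hr})
    pedo = pd.DataFrame({"timestamp_ms": ts1, "steps": steps.astype(float)})
    dist = pd.DataFrame({"timestamp_ms": ts1, "distance_cm": distance, "speed_cm_s": speed, "pace_ms_m": pace})
    cal = pd.DataFrame({"timestamp_ms": ts1, "kcal": calories})

    ts30 = np.arange(0, n, 30, dtype=np.int64) * 1000
    hour30 = (start_hour + ts30 / 3.6e6) % 24.0
    skin = profile.baseline_skin_temp + 0.2 * np.sin(2.0 * np.pi * (hour30 - 4.0) / 24.0)
    skin = skin + rng.normal(0.0, 0.12, len(ts30))
    skin_df = pd.DataFrame({"timestamp_ms": ts30, "celsius": skin})

    ts60 = np.arange(0, n, 60, dtype=np.int64) * 1000
    hour60 = (start_hour + ts60 / 3.6e6) % 24.0
    sun = np.clip(np.sin(np.pi * (hour60 - 7.0) / 12.0), 0.0, None)
    # UV reads zero whenever the wearer is indoors, at any hour; outdoor
    # spells come in bouts of a few minutes
    outdoor = np.zeros(len(ts60), dtype=bool)
    i = 0
    while i < len(ts60):
        is_out = rng.random() < 0.35
        span = max(1, int(rng.exponential(5.0)))
        outdoor[i : i + span] = is_out
        i += span
    uv = rng.poisson(1.5 * sun).astype(float) * outdoor
    uv_df = pd.DataFrame({"timestamp_ms": ts60, "uv_index": uv})

    frames = {
        "accelerometer": accel,
        "gyroscope": gyro,
        "distance": dist,
        "heart_rate": heart,
        "pedometer": pedo,
        "calories": cal,
        "skin_temperature": skin_df,
        "ultraviolet": uv_df,
    }
    return SensorStream(user_id=profile.user_id, session_label=label, frames=frames, start_hour=start_hour)


def simulate_normal(profile: UserProfile, duration: float, seed, start_hour: float = 8.0) -> SensorStream:
    """One normal-conditions session of ``duration`` seconds (>= 2 s)."""
    if duration < 2:
        raise ValueError("duration must be at least 2 s (one complete window plus a predecessor)")
    rng = np.random.default_rng(seed)
    regime = _normal_regime(profile, int(duration), rng, start_hour)
    return _synthesize(profile, regime, rng, "normal", start_hour)


def simulate_scenario(profile: UserProfile, scenario: ScenarioSpec, seed, start_hour: float = 11.0) -> SensorStream:
    """One anomaly-conditions session for a staged scenario."""
    rng = np.random.default_rng(seed)
    regime = _scenario_regime(profile, scenario, rng)
    return _synthesize(profile, regime, rng, scenario.kind, start_hour)


@dataclass
class CohortEntry:
    profile: UserProfile
    ncds: SensorStream
    acds: dict[str, SensorStream]


def build_cohort(
    n_users: int,
    days: float | None = 1.0,
    seed=0,
    ncds_seconds: float | None = None,
    scenarios: list[ScenarioSpec] | None = None,
    ranges=None,
    start_hour: float = 8.0,
) -> dict[str, CohortEntry]:
    """A reproducible cohort: per user one normal stream plus all five scenarios.

    ``ncds_seconds`` overrides ``days`` (``days * 86400`` s) for shorter runs.
    Child seeds are spawned from the root seed, so the same (config, seed)
    always yields byte-identical streams.
    """
    if n_users < 1:
        raise ValueError("n_users must be >= 1")
    duration = float(ncds_seconds) if ncds_seconds is not None else float(days) * 86400.0
    if scenarios is None:
        scenarios = default_scenarios()
    root = np.random.SeedSequence(seed)
    cohort: dict[str, CohortEntry] = {}
    for i, child in enumerate(root.spawn(n_users)):
        uid = f"user{i + 1:02d}"
        seeds = child.spawn(2 + len(scenarios))
        profile = make_profile(seeds[0], ranges=ranges, user_id=uid)
        ncds = simulate_normal(profile, duration, seeds[1], start_hour=start_hour)
        acds = {
            spec.kind: simulate_scenario(profile, spec, s)
            for spec, s in zip(scenarios, seeds[2:])
        }
        cohort[uid] = CohortEntry(profile=profile, ncds=ncds, acds=acds)
    return cohort


def export_cohort(cohort: dict[str, CohortEntry], out_dir) -> list[str]:
    """Write one long-form CSV per user per session; returns the paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for uid, entry in cohort.items():
        path = os.path.join(out_dir, f"{uid}_normal.csv")
        entry.ncds.to_csv(path)
        paths.append(path)
        for kind, stream in entry.acds.items():
            path = os.path.join(out_dir, f"{uid}_{kind}.csv")
            stream.to_csv(path)
            paths.append(path)
    return paths
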