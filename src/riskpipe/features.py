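"""Window segmentation and time/frequency feature extraction.

Raw multi-rate streams are cut into non-overlapping one-second windows
``[t, t+1)``.  Motion sensors (8 Hz) contribute eight samples per window;
sensors read out at 1 s contribute their value for that second; slower sensors
(skin temperature, ultraviolet) carry their most recent prior value forward.

Two vectors are derived per window:

* the 26-dimensional *time-domain* vector — mean and sample standard
  deviation (n-1 denominator) of each of the nine motion axes, the absolute
  heart-rate / skin-temperature / pace / speed / ultraviolet values, and the
  per-window increments of the cumulative step, distance and calorie counters;
* the 98-dimensional *extended* vector — ten frequency-domain descriptors of
  the one-sided 8-point DFT for each motion axis (90 features) plus the eight
  non-motion features above.

Feature identity is tracked by name throughout; column order is a fixed
convention (per-axis blocks of ten descriptors, then the non-motion tail
ending with ultraviolet).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MOTION_FS = 8.0  # Hz
SAMPLES_PER_WINDOW = 8

#: canonical motion-axis order: gyroscope accelerometer, gyroscope angular
#: velocity, then the dedicated accelerometer, x/y/z each.
MOTION_AXES = (
    "gyro_accel_x",
    "gyro_accel_y",
    "gyro_accel_z",
    "gyro_angvel_x",
    "gyro_angvel_y",
    "gyro_angvel_z",
    "accel_x",
    "accel_y",
    "accel_z",
)

NON_MOTION_TIME = (
    "heart_rate",
    "skin_temperature",
    "pace",
    "speed",
    "ultraviolet",
    "delta_steps",
    "delta_distance",
    "delta_calories",
)

#: 26 time-domain feature names: mean/std per motion axis, then absolutes and deltas.
TIME_FEATURES: tuple[str, ...] = tuple(
    name for ax in MOTION_AXES for name in (f"mean_{ax}", f"std_{ax}")
) + NON_MOTION_TIME

#: the ten frequency-domain descriptors, in canonical within-block order
SPECTRAL_DESCRIPTORS = (
    "fft_energy",
    "fft_mean_energy",
    "fft_std_energy",
    "peak_power",
    "peak_dft_bin",
    "spectral_entropy",
    "peak_magnitude",
    "entropy",
    "peak_frequency",
    "peak_energy",
)

NON_MOTION_EXTENDED = (
    "heart_rate",
    "skin_temperature",
    "pace",
    "speed",
    "delta_steps",
    "delta_distance",
    "delta_calories",
    "ultraviolet",
)

#: 98 extended feature names: 9 axes x 10 descriptors, then the non-motion tail.
EXTENDED_FEATURES: tuple[str, ...] = tuple(
    f"{d}_{ax}" for ax in MOTION_AXES for d in SPECTRAL_DESCRIPTORS
) + NON_MOTION_EXTENDED


@dataclass
class Window:
    """One complete one-second window of a user's stream."""

    user_id: str
    index: int  # 0-based window ordinal within the session
    start: float  # seconds from session start
    motion: np.ndarray  # (8 samples, 9 axes) in MOTION_AXES order
    scalars: dict  # heart_rate, skin_temperature, pace, speed, ultraviolet
    cumulative: dict  # steps, distance, calories (session-cumulative values)
    n: int = SAMPLES_PER_WINDOW
    fs: float = MOTION_FS


@dataclass
class WindowSet:
    """All complete windows of one session, as batch arrays."""

    user_id: str
    session_label: str
    index: np.ndarray  # original window ordinals (may skip rejected windows)
    motion: np.ndarray  # (n_windows, 8, 9)
    scalars: dict[str, np.ndarray]
    cumulative: dict[str, np.ndarray]

    @property
    def n_windows(self) -> int:
        return len(self.index)

    def __len__(self) -> int:
        return self.n_windows

    def __getitem__(self, i: int) -> Window:
        return Window(
            user_id=self.user_id,
            index=int(self.index[i]),
            start=float(self.index[i]),
            motion=self.motion[i],
            scalars={k: float(v[i]) for k, v in self.scalars.items()},
            cumulative={k: float(v[i]) for k, v in self.cumulative.items()},
        )

    def __iter__(self):
        for i in range(self.n_windows):
            yield self[i]


def _carry_forward(frame: pd.DataFrame | None, channel: str, starts_ms: np.ndarray) -> np.ndarray:
    """Value of ``channel`` in force at each window start (last reading <= start)."""
    if frame is None or len(frame) == 0:
        logger.warning("no readings for channel %s; filling 0", channel)
        return np.zeros(len(starts_ms))
    ts = frame["timestamp_ms"].to_numpy()
    vals = frame[channel].to_numpy(dtype=float)
    pos = np.searchsorted(ts, starts_ms, side="right") - 1
    pos = np.clip(pos, 0, len(ts) - 1)  # windows before the first reading back-fill it
    return vals[pos]


def segment_windows(stream) -> WindowSet:
    """Cut a stream into complete one-second windows.

    A window is complete when both motion sensors delivered all eight samples
    inside ``[t, t+1)``; the incomplete trailing second is dropped and any
    interior incomplete window is rejected with a logged reason.
    """
    accel = stream.frames.get("accelerometer")
    gyro = stream.frames.get("gyroscope")
    if accel is None or gyro is None or len(accel) == 0 or len(gyro) == 0:
        return _empty_window_set(stream)

    def per_window(frame, channels):
        ts = frame["timestamp_ms"].to_numpy()
        order = np.argsort(ts, kind="stable")
        ts = ts[order]
        widx = (ts // 1000).astype(np.int64)
        n_max = int(widx[-1]) + 1
        counts = np.bincount(widx, minlength=n_max)
        data = frame[list(channels)].to_numpy(dtype=float)[order]
        return widx, counts, data

    a_idx, a_counts, a_data = per_window(accel, ("x", "y", "z"))
    g_idx, g_counts, g_data = per_window(
        gyro, ("accel_x", "accel_y", "accel_z", "angvel_x", "angvel_y", "angvel_z")
    )
    n_max = min(len(a_counts), len(g_counts))
    complete = (a_counts[:n_max] == SAMPLES_PER_WINDOW) & (g_counts[:n_max] == SAMPLES_PER_WINDOW)
    valid = np.flatnonzero(complete)
    n_rejected = n_max - len(valid)
    if n_rejected:
        logger.info(
            "%s/%s: rejected %d incomplete window(s)", stream.user_id, stream.session_label, n_rejected
        )
    if len(valid) == 0:
        return _empty_window_set(stream)

    def gather(widx, data, n_channels):
        keep = np.isin(widx, valid)
        kept = data[keep]
        return kept.reshape(len(valid), SAMPLES_PER_WINDOW, n_channels)

    a_arr = gather(a_idx, a_data, 3)
    g_arr = gather(g_idx, g_data, 6)
    # MOTION_AXES order: gyro accel xyz, gyro angvel xyz, accel xyz
    motion = np.concatenate([g_arr, a_arr], axis=2)

    starts_ms = valid * 1000
    frames = stream.frames
    scalars = {
        "heart_rate": _carry_forward(frames.get("heart_rate"), "bpm", starts_ms),
        "skin_temperature": _carry_forward(frames.get("skin_temperature"), "celsius", starts_ms),
        "pace": _carry_forward(frames.get("distance"), "pace_ms_m", starts_ms),
        "speed": _carry_forward(frames.get("distance"), "speed_cm_s", starts_ms),
        "ultraviolet": _carry_forward(frames.get("ultraviolet"), "uv_index", starts_ms),
    }
    cumulative = {
        "steps": _carry_forward(frames.get("pedometer"), "steps", starts_ms),
        "distance": _carry_forward(frames.get("distance"), "distance_cm", starts_ms),
        "calories": _carry_forward(frames.get("calories"), "kcal", starts_ms),
    }
    return WindowSet(
        user_id=stream.user_id,
        session_label=stream.session_label,
        index=valid,
        motion=motion,
        scalars=scalars,
        cumulative=cumulative,
    )


def _empty_window_set(stream) -> WindowSet:
    return WindowSet(
        user_id=stream.user_id,
        session_label=stream.session_label,
        index=np.zeros(0, dtype=np.int64),
        motion=np.zeros((0, SAMPLES_PER_WINDOW, len(MOTION_AXES))),
        scalars={k: np.zeros(0) for k in ("heart_rate", "skin_temperature", "pace", "speed", "ultraviolet")},
        cumulative={k: np.zeros(0) for k in ("steps", "distance", "calories")},
    )


# ---------------------------------------------------------------------------
# time domain


def time_features(w: Window, prev: Window | None = None) -> pd.Series:
    """The 26-dimensional time-domain vector of one window."""
    if w.motion.shape != (SAMPLES_PER_WINDOW, len(MOTION_AXES)):
        raise ValueError(f"window motion block must be {SAMPLES_PER_WINDOW}x{len(MOTION_AXES)}")
    values = {}
    means = w.motion.mean(axis=0)
    stds = w.motion.std(axis=0, ddof=1)
    for j, ax in enumerate(MOTION_AXES):
        values[f"mean_{ax}"] = means[j]
        values[f"std_{ax}"] = stds[j]
    for k in ("heart_rate", "skin_temperature", "pace", "speed", "ultraviolet"):
        values[k] = w.scalars[k]
    prev_cum = prev.cumulative if prev is not None else None
    for k, name in (("steps", "delta_steps"), ("distance", "delta_distance"), ("calories", "delta_calories")):
        values[name] = w.cumulative[k] - prev_cum[k] if prev_cum is not None else 0.0
    return pd.Series(values, index=list(TIME_FEATURES))


def _delta(cum: np.ndarray) -> np.ndarray:
    # increment vs the previous retained window; 0 at the session's first window
    if len(cum) == 0:
        return cum.copy()
    return np.diff(cum, prepend=cum[:1])


def _time_matrix(ws: WindowSet) -> pd.DataFrame:
    cols = {}
    means = ws.motion.mean(axis=1)
    stds = ws.motion.std(axis=1, ddof=1)
    for j, ax in enumerate(MOTION_AXES):
        cols[f"mean_{ax}"] = means[:, j]
        cols[f"std_{ax}"] = stds[:, j]
    for k in ("heart_rate", "skin_temperature", "pace", "speed", "ultraviolet"):
        cols[k] = ws.scalars[k]
    cols["delta_steps"] = _delta(ws.cumulative["steps"])
    cols["delta_distance"] = _delta(ws.cumulative["distance"])
    cols["delta_calories"] = _delta(ws.cumulative["calories"])
    return pd.DataFrame(cols, columns=list(TIME_FEATURES))


# ---------------------------------------------------------------------------
# frequency domain


def _spectral_block(X: np.ndarray, fs: float = MOTION_FS) -> np.ndarray:
    """The ten frequency-domain descriptors for each row of ``X`` (n_windows, 8).

    Uses the one-sided DFT magnitude spectrum (bins 0..n/2, i.e. five bins for
    n = 8) and the per-bin power ``P = |DFT|^2``.  Entropies use the
    ``0 * log 0 := 0`` convention and are 0 for an all-zero signal; the peak
    frequency excludes the DC bin so constant signals report 0 Hz.
    """
    n = X.shape[1]
    F = np.fft.rfft(X, axis=1)
    mag = np.abs(F)  # (n_windows, n/2 + 1)
    P = mag**2

    total_p = P.sum(axis=1)
    total_m = mag.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_share = np.where(total_p[:, None] > 0, P / np.where(total_p[:, None] > 0, total_p[:, None], 1.0), 0.0)
        m_share = np.where(total_m[:, None] > 0, mag / np.where(total_m[:, None] > 0, total_m[:, None], 1.0), 0.0)

    def share_entropy(share):
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(share > 0, share * np.log(share), 0.0)
        return -terms.sum(axis=1)

    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    nondc = P[:, 1:]
    any_nondc = nondc.max(axis=1) > 0
    peak_freq = np.where(any_nondc, freqs[1:][np.argmax(nondc, axis=1)], 0.0)

    out = np.empty((X.shape[0], len(SPECTRAL_DESCRIPTORS)))
    out[:, 0] = P.sum(axis=1)  # fft_energy
    out[:, 1] = P.mean(axis=1)  # fft_mean_energy
    out[:, 2] = P.std(axis=1, ddof=1)  # fft_std_energy (sample std of per-bin power)
    out[:, 3] = p_share.max(axis=1)  # peak_power: largest normalised power share
    out[:, 4] = np.argmax(mag, axis=1)  # peak_dft_bin (0-based)
    out[:, 5] = share_entropy(p_share)  # spectral_entropy (power shares, nats)
    out[:, 6] = mag.max(axis=1)  # peak_magnitude
    out[:, 7] = share_entropy(m_share)  # entropy (magnitude shares, nats)
    out[:, 8] = peak_freq  # peak_frequency (Hz, DC excluded)
    out[:, 9] = P.max(axis=1)  # peak_energy: largest per-bin squared magnitude
    return out


def spectral_features(axis_samples, fs: float = MOTION_FS) -> pd.Series:
    """The ten frequency-domain descriptors of one 8-sample motion-axis window."""
    x = np.asarray(axis_samples, dtype=float)
    if x.shape != (SAMPLES_PER_WINDOW,):
        raise ValueError(f"expected {SAMPLES_PER_WINDOW} samples, got shape {x.shape}")
    vals = _spectral_block(x[None, :], fs=fs)[0]
    return pd.Series(vals, index=list(SPECTRAL_DESCRIPTORS))


def extended_vector(w: Window, prev: Window | None = None) -> pd.Series:
    """The 98-dimensional extended vector: 90 spectral + 8 non-motion features."""
    tf = time_features(w, prev)
    values = {}
    for j, ax in enumerate(MOTION_AXES):
        block = _spectral_block(w.motion[:, j][None, :])[0]
        for d, v in zip(SPECTRAL_DESCRIPTORS, block):
            values[f"{d}_{ax}"] = v
    for k in NON_MOTION_EXTENDED:
        values[k] = tf[k]
    return pd.Series(values, index=list(EXTENDED_FEATURES))


def _extended_matrix(ws: WindowSet) -> pd.DataFrame:
    tf = _time_matrix(ws)
    cols = {}
    for j, ax in enumerate(MOTION_AXES):
        block = _spectral_block(ws.motion[:, :, j])
        for k, d in enumerate(SPECTRAL_DESCRIPTORS):
            cols[f"{d}_{ax}"] = block[:, k]
    for k in NON_MOTION_EXTENDED:
        cols[k] = tf[k].to_numpy()
    return pd.DataFrame(cols, columns=list(EXTENDED_FEATURES))


# ---------------------------------------------------------------------------
# feature matrices


META_COLUMNS = ("user_id", "window_index", "session", "label")


class FeatureMatrix:
    """Windows x named features for one user, with labels and provenance.

    Wraps a DataFrame whose first columns are ``user_id, window_index,
    session, label`` followed by the feature columns.  ``label`` is
    ``"normal"`` or ``"anomaly"``; ``dataset_id`` records which dataset
    variant (DS-1..DS-4) the matrix represents.
    """

    def __init__(self, df: pd.DataFrame, feature_names, dataset_id: str | None = None):
        feature_names = list(feature_names)
        missing = [c for c in (*META_COLUMNS, *feature_names) if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        self.df = df[[*META_COLUMNS, *feature_names]].reset_index(drop=True)
        self.feature_names = feature_names
        self.dataset_id = dataset_id

    def __len__(self) -> int:
        return len(self.df)

    @property
    def X(self) -> np.ndarray:
        return self.df[self.feature_names].to_numpy(dtype=float)

    @property
    def features(self) -> pd.DataFrame:
        return self.df[self.feature_names]

    @property
    def labels(self) -> np.ndarray:
        """0 = normal, 1 = anomaly."""
        return (self.df["label"].to_numpy() == "anomaly").astype(int)

    def normal(self) -> "FeatureMatrix":
        return FeatureMatrix(self.df[self.df["label"] == "normal"], self.feature_names, self.dataset_id)

    def anomalous(self) -> "FeatureMatrix":
        return FeatureMatrix(self.df[self.df["label"] == "anomaly"], self.feature_names, self.dataset_id)

    def rows(self, idx) -> "FeatureMatrix":
        return FeatureMatrix(self.df.iloc[idx], self.feature_names, self.dataset_id)

    def drop_features(self, names, dataset_id: str | None = None) -> "FeatureMatrix":
        names = set(names)
        unknown = names - set(self.feature_names)
        if unknown:
            raise KeyError(f"unknown feature(s): {sorted(unknown)}")
        kept = [f for f in self.feature_names if f not in names]
        return FeatureMatrix(self.df, kept, dataset_id or self.dataset_id)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, dataset_id: str | None = None) -> "FeatureMatrix":
        df = pd.read_csv(path)
        feature_names = [c for c in df.columns if c not in META_COLUMNS]
        return cls(df, feature_names, dataset_id)


def extract_matrix(streams, mode: str = "time", dataset_id: str | None = None) -> FeatureMatrix:
    """Row-per-window feature matrix from one user's streams.

    ``mode`` selects the 26-dim time-domain vector (``"time"``) or the 98-dim
    extended vector (``"extended"``); labels come from each stream's session
    label (``normal`` vs any scenario).
    """
    if mode not in ("time", "extended"):
        raise ValueError("mode must be 'time' or 'extended'")
    names = list(TIME_FEATURES if mode == "time" else EXTENDED_FEATURES)
    builder = _time_matrix if mode == "time" else _extended_matrix
    parts = []
    user_ids = set()
    for stream in streams:
        user_ids.add(stream.user_id)
        ws = segment_windows(stream)
        feats = builder(ws)
        feats.insert(0, "user_id", stream.user_id)
        feats.insert(1, "window_index", ws.index)
        feats.insert(2, "session", stream.session_label)
        feats.insert(3, "label", "normal" if stream.session_label == "normal" else "anomaly")
        parts.append(feats)
    if len(user_ids) > 1:
        raise ValueError("extract_matrix expects streams from a single user")
    if not parts:
        df = pd.DataFrame(columns=[*META_COLUMNS, *names])
        return FeatureMatrix(df, names, dataset_id)
    df = pd.concat(parts, ignore_index=True)
    return FeatureMatrix(df, names, dataset_id)
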