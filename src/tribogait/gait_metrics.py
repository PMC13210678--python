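"""Per-trial gait outcome measures from an aligned insole + IMU trial.

Implements the outcome measures of the insole analysis:

* **CoP-like loading proxy** — each sensor is a unit vector at a fixed
  angle; at every sample the normalized sensor values are turned into
  convex weights w_i = v_i / sum_j v_j and the weighted resultant
  (x, y) = (sum w_i cos(theta_i), sum w_i sin(theta_i)) traces the
  mediolateral/anteroposterior distribution of plantar loading.  It is a
  plantar-load proxy, not a whole-body center-of-mass estimate.
* **Left-right asymmetry index** — A(t) = 100 (R - L)/(R + L) on
  stride-scale smoothed per-side load sums (positive = right-dominant),
  summarized over the trial by mean/SD/min/max.  The smoothing envelope is
  what makes the time-average recover an injected amplitude asymmetry:
  on raw alternating stance signals the single-support samples saturate at
  +/-100 and cancel, hiding the amplitude imbalance.
* **Temporal events** — per-side step detection by peak-picking on the
  (low-passed) ipsilateral gyro or heel channel, cadence
  60 (n-1)/(t_last - t_first), and stride segmentation onto a 100-point
  normalized gait cycle.
* **Arch / flatfoot features** — arch index = midfoot share of the
  (forefoot + midfoot + heel) trial-mean load, lateral share of total load
  over the configured lateral region set, and a threshold OR-classifier
  for flatfoot-type loading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, filtfilt, find_peaks

from .ingest import AlignedTrial, normalize_insole
from .sensor_model import REGIONS, SensorGeometry

__all__ = [
    "CopTrace",
    "AsymmetrySummary",
    "GaitMetrics",
    "compute_cop_proxy",
    "asymmetry_index",
    "detect_steps",
    "cadence",
    "segment_strides",
    "composite_waveform",
    "arch_metrics",
    "compute_gait_metrics",
]

EPS_LOAD = 1e-6  # zero-load guard, in units of full-scale normalized load


# ---------------------------------------------------------------------------
# CoP-like loading proxy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CopTrace:
    """Unit-circle loading resultant per time point.

    x is mediolateral (positive = lateral in per-foot scope, subject's
    right in bilateral scope), y anteroposterior (positive = anterior).
    Samples with total load below the guard are flagged undefined (NaN
    coordinates), never fabricated.
    """

    x_ml: np.ndarray
    y_ap: np.ndarray
    defined: np.ndarray

    @property
    def mean_abs_x(self) -> float:
        return float(np.nanmean(np.abs(self.x_ml))) if self.defined.any() else float("nan")

    @property
    def mean_y(self) -> float:
        return float(np.nanmean(self.y_ap)) if self.defined.any() else float("nan")


def _cop_from_values(values: np.ndarray, angles_deg: np.ndarray,
                     eps: float) -> CopTrace:
    theta = np.deg2rad(angles_deg)
    total = values.sum(axis=1)
    defined = total > eps
    with np.errstate(invalid="ignore", divide="ignore"):
        w = values / total[:, None]
    x = w @ np.cos(theta)
    y = w @ np.sin(theta)
    x[~defined] = np.nan
    y[~defined] = np.nan
    return CopTrace(x_ml=x, y_ap=y, defined=defined)


def compute_cop_proxy(trial: AlignedTrial, geometry: SensorGeometry,
                      scope: str = "bilateral", eps: float = EPS_LOAD):
    """Weighted unit-circle resultant of the normalized sensor values.

    ``scope='bilateral'`` maps all 8 channels onto one circle in the body
    frame (+x = subject's right); ``scope='per_foot'`` returns a dict of
    per-foot traces in each foot's local frame (+x = lateral).  The weights
    are scale-invariant: multiplying all loads by a constant leaves the
    trace unchanged.
    """
    cols = geometry.column_names()
    missing = [c for c in cols if c not in trial.insole_norm.columns]
    if missing:
        raise ValueError(f"trial is missing insole channel(s): {missing}")
    if scope == "bilateral":
        channels = sorted(geometry.channels, key=lambda c: c.channel_id)
        values = trial.insole_norm[[f"ch{c.channel_id}" for c in channels]].to_numpy()
        angles = np.array([c.angle_deg for c in channels])
        return _cop_from_values(values, angles, eps)
    if scope == "per_foot":
        out = {}
        for side in ("left", "right"):
            channels = sorted(geometry.foot(side), key=lambda c: c.channel_id)
            values = trial.insole_norm[
                [f"ch{c.channel_id}" for c in channels]].to_numpy()
            angles = np.array([c.local_angle_deg for c in channels])
            out[side] = _cop_from_values(values, angles, eps)
        return out
    raise ValueError("scope must be 'bilateral' or 'per_foot'")


# ---------------------------------------------------------------------------
# Asymmetry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AsymmetrySummary:
    """Signed percent left-right imbalance (positive = right-dominant)."""

    series: np.ndarray
    mean_pct: float
    sd_pct: float
    min_pct: float
    max_pct: float


def _side_sum(trial: AlignedTrial, geometry: SensorGeometry, side: str
              ) -> np.ndarray:
    cols = [f"ch{c.channel_id}" for c in geometry.foot(side)]
    return trial.insole_norm[cols].to_numpy().sum(axis=1)


def asymmetry_index(trial: AlignedTrial, geometry: SensorGeometry | None = None,
                    smooth_window_s: float = 1.5, eps: float = EPS_LOAD
                    ) -> AsymmetrySummary:
    """Global left-right asymmetry A(t) = 100 (R - L)/(R + L), percent.

    Per-side sums are first smoothed with a moving-average envelope of
    ``smooth_window_s`` seconds (roughly one stride) so the time-average
    reflects amplitude dominance rather than alternating single-support
    saturation; set it to 0 for the raw instantaneous ratio.  Samples where
    R + L <= eps are excluded.  Exactly antisymmetric under a left/right
    channel swap.
    """
    geometry = geometry or SensorGeometry.default()
    left = _side_sum(trial, geometry, "left")
    right = _side_sum(trial, geometry, "right")
    if smooth_window_s > 0:
        size = max(1, int(round(smooth_window_s * trial.sample_rate)))
        left = uniform_filter1d(left, size=size, mode="nearest")
        right = uniform_filter1d(right, size=size, mode="nearest")
    total = left + right
    valid = total > eps
    if not valid.any():
        raise ValueError("trial carries no plantar load above the zero guard")
    series = 100.0 * (right[valid] - left[valid]) / total[valid]
    series = np.clip(series, -100.0, 100.0)  # guard float spill at the bounds
    if np.all(left[valid] <= eps) or np.all(right[valid] <= eps):
        warnings.warn("degenerate trial: one foot carries no load; "
                      "asymmetry saturates at +/-100", stacklevel=2)
    return AsymmetrySummary(
        series=series,
        mean_pct=float(series.mean()),
        sd_pct=float(series.std()),
        min_pct=float(series.min()),
        max_pct=float(series.max()),
    )


# ---------------------------------------------------------------------------
# Temporal events
# ---------------------------------------------------------------------------

class InsufficientStepsError(ValueError):
    pass


def _detect_side(signal: np.ndarray, sample_rate: float, min_separation_s: float,
                 prominence_k: float, lowpass_hz: float | None) -> np.ndarray:
    x = np.asarray(signal, dtype=float)
    if lowpass_hz is not None and 0 < lowpass_hz < sample_rate / 2:
        b, a = butter(4, lowpass_hz / (sample_rate / 2), btype="low")
        x = filtfilt(b, a, x)
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    # MAD floor alone under-thresholds sparse pulse trains (their MAD is
    # near zero between pulses), so also require a fraction of the robust
    # signal excursion.
    excursion = float(np.percentile(x, 99.5) - med)
    prominence = max(prominence_k * mad, 0.35 * excursion)
    if prominence <= 0:
        return np.array([], dtype=int)
    distance = max(1, int(round(min_separation_s * sample_rate)))
    idx, _ = find_peaks(x, height=med + 0.5 * excursion,
                        prominence=prominence, distance=distance)
    return idx


def detect_steps(trial: AlignedTrial, source: str = "imu",
                 geometry: SensorGeometry | None = None,
                 min_separation_s: float = 0.3, prominence_k: float = 3.0,
                 lowpass_hz: float = 6.0) -> dict:
    """Per-side step event times by peak detection.

    ``source='imu'`` picks one angular-velocity peak per ipsilateral step
    from the gyro channels; ``source='heel_sensor'`` uses the per-side heel
    insole channel.  Peaks require prominence >= prominence_k * MAD of the
    (low-passed) signal and at least ``min_separation_s`` spacing.
    """
    if trial.duration_s < 10.0:
        raise ValueError("need at least 10 s of signal for step detection")
    geometry = geometry or SensorGeometry.default()
    signals = {}
    if source == "imu":
        signals["left"] = trial.imu["gyro_l"].to_numpy()
        signals["right"] = trial.imu["gyro_r"].to_numpy()
    elif source == "heel_sensor":
        for side in ("left", "right"):
            ch = geometry.channel(side, "heel")
            signals[side] = trial.insole_norm[f"ch{ch.channel_id}"].to_numpy()
    else:
        raise ValueError("source must be 'imu' or 'heel_sensor'")
    events = {}
    total = 0
    for side, sig in signals.items():
        idx = _detect_side(sig, trial.sample_rate, min_separation_s,
                           prominence_k, lowpass_hz)
        events[side] = trial.time_s[idx]
        total += len(idx)
    if total < 4:
        raise InsufficientStepsError(
            f"only {total} step events detected; need >= 4")
    return events


def cadence(step_times, duration_s: float | None = None) -> float:
    """Steps per minute from detected events: 60 (n - 1) / (t_n - t_1).

    ``step_times`` may be a per-side dict (events are pooled) or a flat
    array of event times.
    """
    if isinstance(step_times, dict):
        times = np.sort(np.concatenate([np.asarray(v, dtype=float)
                                        for v in step_times.values()]))
    else:
        times = np.sort(np.asarray(step_times, dtype=float))
    if duration_s is not None and duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if times.size < 4:
        raise InsufficientStepsError("need at least 4 steps for cadence")
    span = float(times[-1] - times[0])
    if span <= 0:
        raise ValueError("step events span zero time")
    return 60.0 * (times.size - 1) / span


def segment_strides(trial: AlignedTrial, step_times: dict,
                    min_stride_s: float = 0.4, max_stride_s: float = 2.5,
                    n_points: int = 100) -> dict:
    """Per-side stride waveform matrices (strides x 100 cycle points x channels).

    A stride spans consecutive ipsilateral events; each insole channel is
    linearly resampled onto ``n_points`` of normalized gait cycle.  Strides
    outside the physiological duration window are dropped and counted.
    Returns {side: {"matrix", "channels", "n_invalid"}}.
    """
    channels = [c for c in trial.insole_norm.columns]
    data = trial.insole_norm.to_numpy()
    phase = np.linspace(0.0, 1.0, n_points)
    out = {}
    any_valid = False
    for side, times in step_times.items():
        times = np.asarray(times, dtype=float)
        if times.size < 2:
            out[side] = {"matrix": np.empty((0, n_points, len(channels))),
                         "channels": channels, "n_invalid": 0}
            continue
        strides = []
        n_invalid = 0
        for t_a, t_b in zip(times[:-1], times[1:]):
            dur = t_b - t_a
            if not (min_stride_s <= dur <= max_stride_s):
                n_invalid += 1
                continue
            sample_t = t_a + phase * dur
            resampled = np.column_stack([
                np.interp(sample_t, trial.time_s, data[:, j])
                for j in range(data.shape[1])])
            strides.append(resampled)
        matrix = (np.stack(strides) if strides
                  else np.empty((0, n_points, len(channels))))
        if len(strides):
            any_valid = True
        out[side] = {"matrix": matrix, "channels": channels,
                     "n_invalid": n_invalid}
    if not any_valid:
        raise ValueError("no valid strides within the duration window")
    return out


def composite_waveform(stride_matrix: np.ndarray,
                       channel_weights=None) -> np.ndarray:
    """Mean weighted-channel stride waveform, rescaled to peak 1.

    ``stride_matrix`` is (strides, cycle points, channels); the default
    weights combine all channels equally.  Intended for category-level
    morphology comparison, not absolute amplitudes.
    """
    matrix = np.asarray(stride_matrix, dtype=float)
    if matrix.ndim != 3 or matrix.shape[0] == 0:
        raise ValueError("stride matrix must be non-empty (strides, points, channels)")
    n_channels = matrix.shape[2]
    w = (np.full(n_channels, 1.0 / n_channels) if channel_weights is None
         else np.asarray(channel_weights, dtype=float))
    if w.shape != (n_channels,):
        raise ValueError("channel_weights length must match channel count")
    combined = matrix @ w              # (strides, points)
    mean_curve = combined.mean(axis=0)
    peak = np.abs(mean_curve).max()
    return mean_curve / peak if peak > 0 else mean_curve


# ---------------------------------------------------------------------------
# Arch / flatfoot features
# ---------------------------------------------------------------------------

def arch_metrics(trial: AlignedTrial, geometry: SensorGeometry,
                 t_arch_pct: float = 25.0, t_lat_pct: float = 50.0) -> dict:
    """Arch index, lateral load share and a flatfoot flag per foot.

    arch_index = 100 * midfoot / (forefoot + midfoot + heel) trial-mean
    loads; lateral_share = 100 * lateral-region load / total (lateral set
    from the geometry config).  A foot is flagged as flatfoot-type loading
    when arch_index >= t_arch_pct OR lateral_share >= t_lat_pct.  The index
    is a sensor-load stand-in for radiographic arch measures, not a claim
    of equivalence.
    """
    _, means = normalize_insole(trial)
    out = {}
    for side in ("left", "right"):
        load = {r: float(means[f"ch{geometry.channel(side, r).channel_id}"])
                for r in REGIONS}
        total = sum(load.values())
        if total <= EPS_LOAD:
            raise ValueError(f"{side} foot carries zero total load")
        tripod = load["forefoot"] + load["medial_arch"] + load["heel"]
        arch_index = 100.0 * load["medial_arch"] / tripod if tripod > 0 else 0.0
        lateral = sum(load[r] for r in geometry.lateral_regions)
        lateral_share = 100.0 * lateral / total
        out[side] = {
            "arch_index_pct": arch_index,
            "lateral_share_pct": lateral_share,
            "flatfoot_flag": bool(arch_index >= t_arch_pct
                                  or lateral_share >= t_lat_pct),
        }
    return out


# ---------------------------------------------------------------------------
# Trial summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaitMetrics:
    """All per-trial outcome measures in one record."""

    cadence: float
    n_strides_left: int
    n_strides_right: int
    asymmetry: AsymmetrySummary
    cop_mean_abs_x: float
    cop_mean_y: float
    arch_index_left: float
    arch_index_right: float
    lateral_share_left: float
    lateral_share_right: float
    flatfoot_left: bool
    flatfoot_right: bool
    composite: np.ndarray

    def to_dict(self) -> dict:
        return {
            "cadence": self.cadence,
            "n_strides_left": self.n_strides_left,
            "n_strides_right": self.n_strides_right,
            "asymmetry_mean_pct": self.asymmetry.mean_pct,
            "asymmetry_sd_pct": self.asymmetry.sd_pct,
            "asymmetry_min_pct": self.asymmetry.min_pct,
            "asymmetry_max_pct": self.asymmetry.max_pct,
            "cop_mean_abs_x": self.cop_mean_abs_x,
            "cop_mean_y": self.cop_mean_y,
            "arch_index_left": self.arch_index_left,
            "arch_index_right": self.arch_index_right,
            "lateral_share_left": self.lateral_share_left,
            "lateral_share_right": self.lateral_share_right,
            "flatfoot_left": self.flatfoot_left,
            "flatfoot_right": self.flatfoot_right,
            "composite": self.composite.tolist(),
        }


def compute_gait_metrics(trial: AlignedTrial,
                         geometry: SensorGeometry | None = None,
                         step_source: str = "imu") -> GaitMetrics:
    """Run the full per-trial outcome pipeline on an aligned trial."""
    geometry = geometry or SensorGeometry.default()
    events = detect_steps(trial, source=step_source, geometry=geometry)
    strides = segment_strides(trial, events)
    asym = asymmetry_index(trial, geometry)
    cop = compute_cop_proxy(trial, geometry, scope="bilateral")
    arch = arch_metrics(trial, geometry)
    matrices = [strides[s]["matrix"] for s in ("left", "right")
                if strides[s]["matrix"].shape[0] > 0]
    composite = composite_waveform(np.concatenate(matrices, axis=0))
    return GaitMetrics(
        cadence=cadence(events),
        n_strides_left=int(strides["left"]["matrix"].shape[0]),
        n_strides_right=int(strides["right"]["matrix"].shape[0]),
        asymmetry=asym,
        cop_mean_abs_x=cop.mean_abs_x,
        cop_mean_y=cop.mean_y,
        arch_index_left=arch["left"]["arch_index_pct"],
        arch_index_right=arch["right"]["arch_index_pct"],
        lateral_share_left=arch["left"]["lateral_share_pct"],
        lateral_share_right=arch["right"]["lateral_share_pct"],
        flatfoot_left=arch["left"]["flatfoot_flag"],
        flatfoot_right=arch["right"]["flatfoot_flag"],
        composite=composite,
    )
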