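"""Reading, cleaning, alignment and normalization of raw sensor streams.

Insole and IMU streams arrive as independently timestamped CSV tables.  The
pipeline merges them onto a common fixed-rate timebase by linear
interpolation over the overlapping span, optionally filters each channel
(median despiking, Butterworth low-pass, or Savitzky-Golay smoothing), and
normalizes insole ADC counts by the 12-bit full scale (4095) so waveforms
live in [0, 1].  Trial-aggregate loading per channel is the sample mean of
the normalized series, i.e. sum(ADC) / (N * 4095).  Every step appends to a
provenance record so a processed trial can be audited or replayed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, medfilt, savgol_filter

__all__ = [
    "RawStream",
    "AlignedTrial",
    "read_stream",
    "raw_stream_from_frame",
    "align_streams",
    "filter_channels",
    "normalize_insole",
    "normalize_adc",
    "ADC_MAX",
]

ADC_MAX = 4095

SCHEMAS = {
    "insole": ["timestamp_s"] + [f"ch{i}" for i in range(8)],
    "imu": ["timestamp_s", "gyro_l", "gyro_r", "acc_l", "acc_r"],
}

MIN_OVERLAP_S = 10.0


def normalize_adc(values) -> np.ndarray:
    """Scale raw ADC counts to [0, 1] by the 12-bit full scale.

    Scale-exact: for unclipped inputs normalize_adc(k*x) = k*normalize_adc(x).
    """
    return np.asarray(values, dtype=float) / ADC_MAX


@dataclass(frozen=True)
class RawStream:
    """A cleaned raw stream: strictly increasing timestamps plus channels."""

    frame: pd.DataFrame
    kind: str
    n_clipped: int = 0
    n_deduplicated: int = 0
    source: str = "<memory>"

    @property
    def timestamps(self) -> np.ndarray:
        return self.frame["timestamp_s"].to_numpy(dtype=float)

    @property
    def channel_names(self) -> list[str]:
        return [c for c in self.frame.columns if c != "timestamp_s"]

    @property
    def span(self) -> tuple[float, float]:
        ts = self.timestamps
        return float(ts[0]), float(ts[-1])


def _clean_frame(frame: pd.DataFrame, kind: str, source: str) -> RawStream:
    cols = SCHEMAS[kind]
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"{kind} stream {source} is missing column(s): {missing}")
    if len(frame) == 0:
        raise ValueError(f"{kind} stream {source} is empty")
    frame = frame[cols].copy()
    n_clipped = 0
    if kind == "insole":
        data = frame[cols[1:]]
        n_clipped = int(((data < 0) | (data > ADC_MAX)).to_numpy().sum())
        frame[cols[1:]] = data.clip(0, ADC_MAX)
    frame = frame.sort_values("timestamp_s", kind="stable")
    before = len(frame)
    frame = frame.drop_duplicates(subset="timestamp_s", keep="first")
    frame = frame.reset_index(drop=True)
    return RawStream(frame=frame, kind=kind, n_clipped=n_clipped,
                     n_deduplicated=before - len(frame), source=source)


def read_stream(path, schema: str) -> RawStream:
    """Parse a stream CSV, clipping out-of-range ADC values and
    deduplicating timestamps (first occurrence wins); rows are re-sorted so
    timestamps come out strictly increasing."""
    if schema not in SCHEMAS:
        raise ValueError(f"schema must be one of {sorted(SCHEMAS)}")
    frame = pd.read_csv(path)
    return _clean_frame(frame, schema, source=str(path))


def raw_stream_from_frame(frame: pd.DataFrame, schema: str) -> RawStream:
    """In-memory counterpart of :func:`read_stream` (same cleaning rules)."""
    if schema not in SCHEMAS:
        raise ValueError(f"schema must be one of {sorted(SCHEMAS)}")
    return _clean_frame(frame, schema, source="<frame>")


@dataclass(frozen=True)
class AlignedTrial:
    """Timestamp-merged, resampled trial on a common fixed-rate timebase.

    ``insole_norm`` holds the 8 insole channels scaled to [0, 1];
    ``imu`` holds the IMU channels in their native units.  ``provenance``
    is an append-only record of every processing step applied.
    """

    time_s: np.ndarray
    insole_norm: pd.DataFrame
    imu: pd.DataFrame
    sample_rate: float
    provenance: tuple = ()

    def __post_init__(self) -> None:
        n = len(self.time_s)
        if len(self.insole_norm) != n or len(self.imu) != n:
            raise ValueError("all channels must share the common timebase length")

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    def with_step(self, **record) -> "AlignedTrial":
        return replace(self, provenance=self.provenance + (record,))


def _resample(frame: pd.DataFrame, src_t: np.ndarray, grid: np.ndarray
              ) -> pd.DataFrame:
    out = {}
    for col in frame.columns:
        if col == "timestamp_s":
            continue
        out[col] = np.interp(grid, src_t, frame[col].to_numpy(dtype=float))
    return pd.DataFrame(out)


def align_streams(insole: RawStream, imu: RawStream,
                  target_rate: float = 100.0) -> AlignedTrial:
    """Merge the two streams onto a common grid over their overlap.

    Both streams are linearly interpolated at ``target_rate`` over the
    overlapping time span; the trial is trimmed to the overlap.  Insole
    channels are normalized to [0, 1] on the way in.
    """
    if insole.kind != "insole" or imu.kind != "imu":
        raise ValueError("align_streams expects (insole, imu) streams")
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    t0 = max(insole.span[0], imu.span[0])
    t1 = min(insole.span[1], imu.span[1])
    if t1 - t0 < MIN_OVERLAP_S:
        raise ValueError(
            f"streams overlap for {max(t1 - t0, 0.0):.2f} s; "
            f"need >= {MIN_OVERLAP_S} s")
    n = int(np.floor((t1 - t0) * target_rate)) + 1
    grid = t0 + np.arange(n) / target_rate
    insole_rs = _resample(insole.frame, insole.timestamps, grid)
    insole_norm = insole_rs / ADC_MAX
    imu_rs = _resample(imu.frame, imu.timestamps, grid)
    provenance = ({
        "step": "align",
        "target_rate": target_rate,
        "overlap": [float(t0), float(t1)],
        "insole_source": insole.source,
        "imu_source": imu.source,
        "n_clipped": insole.n_clipped,
        "n_deduplicated": insole.n_deduplicated + imu.n_deduplicated,
    },)
    return AlignedTrial(time_s=grid, insole_norm=insole_norm, imu=imu_rs,
                        sample_rate=float(target_rate), provenance=provenance)


def _apply_filter(values: np.ndarray, method: str, sample_rate: float,
                  settings: dict) -> np.ndarray:
    if method == "median":
        window = int(settings.get("window", 5))
        if window % 2 == 0 or window < 1:
            raise ValueError("median filter window must be a positive odd integer")
        return medfilt(values, kernel_size=window)
    if method == "lowpass":
        cutoff = float(settings.get("cutoff_hz", 10.0))
        order = int(settings.get("order", 4))
        nyquist = sample_rate / 2.0
        if not (0 < cutoff < nyquist):
            raise ValueError(
                f"lowpass cutoff must satisfy 0 < cutoff < Nyquist ({nyquist} Hz)")
        b, a = butter(order, cutoff / nyquist, btype="low")
        return filtfilt(b, a, values)
    if method == "savitzky_golay":
        window = int(settings.get("window", 11))
        polyorder = int(settings.get("polyorder", 3))
        if window % 2 == 0 or window < 3:
            raise ValueError("Savitzky-Golay window must be an odd integer >= 3")
        if polyorder >= window:
            raise ValueError("Savitzky-Golay polyorder must be < window")
        return savgol_filter(values, window_length=window, polyorder=polyorder)
    raise ValueError(f"unknown filter method {method!r}")


def filter_channels(trial: AlignedTrial, method: str,
                    which: str = "all", **settings) -> AlignedTrial:
    """Apply a noise filter per channel; shape is preserved.

    ``method`` is one of median / lowpass / savitzky_golay; ``which``
    selects the channel group ('insole', 'imu', or 'all').  Settings:
    window (median, SG; odd), polyorder (SG), cutoff_hz + order (lowpass).
    """
    if which not in ("insole", "imu", "all"):
        raise ValueError("which must be 'insole', 'imu' or 'all'")
    insole = trial.insole_norm
    imu = trial.imu
    if which in ("insole", "all"):
        insole = insole.apply(lambda col: _apply_filter(
            col.to_numpy(), method, trial.sample_rate, settings))
    if which in ("imu", "all"):
        imu = imu.apply(lambda col: _apply_filter(
            col.to_numpy(), method, trial.sample_rate, settings))
    out = replace(trial, insole_norm=insole, imu=imu)
    return out.with_step(step="filter", method=method, which=which,
                         settings=dict(settings))


def aligned_trial_from_frames(insole: pd.DataFrame, imu: pd.DataFrame,
                              target_rate: float = 100.0) -> AlignedTrial:
    """Clean + align in-memory stream frames (e.g. straight from the
    simulator) into an AlignedTrial in one call."""
    return align_streams(raw_stream_from_frame(insole, "insole"),
                         raw_stream_from_frame(imu, "imu"),
                         target_rate=target_rate)


def normalize_insole(trial: AlignedTrial) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample normalized insole series and per-channel trial-mean loads.

    The per-sample series is ADC/4095 in [0, 1] (already the trial's
    representation); the trial-mean load per channel is sum(ADC)/(N*4095),
    the sample-count- and full-scale-normalized aggregate loading.
    """
    if len(trial.insole_norm) == 0:
        raise ValueError("trial has no samples")
    series = trial.insole_norm.copy()
    means = series.mean(axis=0)
    return series, means
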