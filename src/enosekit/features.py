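"""Stable-window extraction and subdivision-average features.

A raw recording carries calibration segments before and after the odor
pulse; classification uses only the plateau. The feature representation is
the per-sensor mean of k contiguous subdivisions of the stable window
(k = 8 by default, giving 64 features for an 8-sensor array). Passing
``k_subdivisions=1`` collapses each sensor to its whole-window mean — the
8-feature variant.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .core import AromaMeasurement, FeatureVector, StableWindow
from .exceptions import SizeError, ValidationError, WindowRangeError

__all__ = [
    "extract_stable_window",
    "subtract_baseline",
    "detect_plateau",
    "subdivide_and_average",
    "stacked_sensor_means",
    "features_to_frame",
    "frame_to_features",
]


def _span_end(t: np.ndarray) -> float:
    # the recording covers [t[0], t[-1] + dt): the last sample represents
    # one sampling interval, so a window ending there is still in range
    if len(t) > 1:
        return float(t[-1] + (t[-1] - t[-2]))
    return float(t[-1])


def extract_stable_window(
    m: AromaMeasurement, w: StableWindow = StableWindow()
) -> AromaMeasurement:
    """Return the sub-recording with ``w.start_s <= t < w.end_s``.

    The window must lie entirely inside the recording span; a window that
    extends beyond it raises :class:`WindowRangeError` rather than being
    silently clipped.
    """
    t = m.timestamps_s
    if w.start_s < t[0] or w.end_s > _span_end(t):
        raise WindowRangeError(
            f"window [{w.start_s}, {w.end_s}) outside recording span "
            f"[{t[0]}, {_span_end(t)})"
        )
    mask = (t >= w.start_s) & (t < w.end_s)
    meta = dict(m.metadata)
    meta["window_s"] = (w.start_s, w.end_s)
    return AromaMeasurement(
        timestamps_s=t[mask],
        voltages=m.voltages[mask],
        sensor_names=m.sensor_names,
        label=m.label,
        metadata=meta,
    )


def subtract_baseline(m: AromaMeasurement, baseline_seconds: float = 100.0) -> AromaMeasurement:
    """Optionally remove per-channel baseline offsets.

    Subtracts the mean of the first ``baseline_seconds`` of the recording
    (the pre-exposure calibration segment) from each channel. Off by
    default in the pipeline: absolute voltages carry class information too.
    """
    t = m.timestamps_s
    mask = t < t[0] + baseline_seconds
    if not mask.any():
        raise SizeError("no samples in the baseline segment")
    baseline = m.voltages[mask].mean(axis=0)
    meta = dict(m.metadata)
    meta["baseline_correction_v"] = baseline.tolist()
    return AromaMeasurement(
        timestamps_s=t,
        voltages=m.voltages - baseline,
        sensor_names=m.sensor_names,
        label=m.label,
        metadata=meta,
    )


def detect_plateau(
    m: AromaMeasurement,
    slope_threshold_v_per_s: float = 1e-3,
    smooth_s: float = 30.0,
) -> StableWindow:
    """Automatic plateau detector.

    Finds the longest run of samples where every channel's smoothed slope
    magnitude stays below ``slope_threshold_v_per_s``. This is an
    alternative to the fixed default window for recordings whose timing is
    unknown; the fixed [500, 1500) s window remains the default because the
    measurement protocol pins the exposure interval.
    """
    t = m.timestamps_s
    if len(t) < 3:
        raise SizeError("recording too short for plateau detection")
    dt = float(np.median(np.diff(t)))
    win = max(1, int(round(smooth_s / dt)))
    kernel = np.ones(win) / win
    ok = np.ones(len(t), dtype=bool)
    for c in range(m.n_sensors):
        slope = np.gradient(m.voltages[:, c], t)
        smoothed = np.convolve(slope, kernel, mode="same")
        ok &= np.abs(smoothed) < slope_threshold_v_per_s
    # longest contiguous True run
    best_len, best_start = 0, 0
    run_start = None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    if best_len == 0:
        raise ValidationError("no stable plateau found below the slope threshold")
    return StableWindow(start_s=float(t[best_start]), end_s=float(t[best_start + best_len - 1]) + dt)


def subdivide_and_average(m: AromaMeasurement, k_subdivisions: int = 8) -> FeatureVector:
    """Partition rows into k contiguous blocks and emit per-block channel means.

    When T is not divisible by k the first ``T mod k`` blocks get one extra
    row (the :func:`numpy.array_split` rule), a deterministic convention.
    Output ordering is sensor-major: sensor 0's k means, then sensor 1's...
    """
    if k_subdivisions < 1:
        raise ValidationError("k_subdivisions must be >= 1")
    if m.n_samples < k_subdivisions:
        raise SizeError(
            f"{m.n_samples} rows < k_subdivisions={k_subdivisions}"
        )
    blocks = np.array_split(m.voltages, k_subdivisions, axis=0)
    block_means = np.vstack([b.mean(axis=0) for b in blocks])  # k × S
    values = block_means.T.reshape(-1)  # sensor-major
    return FeatureVector(
        values=values,
        label=m.label,
        source_id=str(m.metadata.get("source_id", "")),
    )


def stacked_sensor_means(dataset: Sequence[AromaMeasurement]) -> pd.DataFrame:
    """Per-label × per-sensor mean voltage table.

    Each cell is the mean over all time samples of all recordings carrying
    that label — the summary behind a stacked-bar comparison of sensor
    responses across aroma classes.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValidationError("dataset must be non-empty")
    names = dataset[0].sensor_names
    for m in dataset:
        if m.sensor_names != names:
            raise ValidationError(
                f"inconsistent sensor names: {m.sensor_names} vs {names}"
            )
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for m in dataset:
        sums[m.label] = sums.get(m.label, 0) + m.voltages.sum(axis=0)
        counts[m.label] = counts.get(m.label, 0) + m.n_samples
    rows = {label: sums[label] / counts[label] for label in sums}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(names))


def features_to_frame(
    features: Sequence[FeatureVector],
    sensor_names: Sequence[str],
    k_subdivisions: int,
) -> pd.DataFrame:
    """Tabulate feature vectors: source_id, label, then f_<sensor>_<subdivision>."""
    features = list(features)
    if not features:
        raise ValidationError("no feature vectors")
    cols = [f"f_{s}_{k}" for s in sensor_names for k in range(k_subdivisions)]
    d = len(cols)
    for f in features:
        if len(f.values) != d:
            raise ValidationError(
                f"feature length {len(f.values)} != {d} for {len(sensor_names)} "
                f"sensors × {k_subdivisions} subdivisions"
            )
    df = pd.DataFrame([f.values for f in features], columns=cols)
    df.insert(0, "label", [f.label for f in features])
    df.insert(0, "source_id", [f.source_id for f in features])
    return df


def frame_to_features(df: pd.DataFrame) -> list[FeatureVector]:
    """Inverse of :func:`features_to_frame`."""
    value_cols = [c for c in df.columns if c.startswith("f_")]
    if not value_cols or "label" not in df.columns:
        raise ValidationError("not a feature table: need 'label' and f_* columns")
    return [
        FeatureVector(
            values=row[value_cols].to_numpy(dtype=float),
            label=str(row["label"]),
            source_id=str(row.get("source_id", "")),
        )
        for _, row in df.iterrows()
    ]
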