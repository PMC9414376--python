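"""Domain types for electronic-nose measurements.

The toolkit models an 8-channel metal-oxide-semiconductor (MOS) gas-sensor
array sampled at 1 Hz. Each aroma class (e.g. a coffee origin) is described
by a characteristic steady-state response pattern across the array; a
recording is a T×S voltage matrix with timestamps and a label.

Sensor kinetics, noise, drift and humidity coefficients are configurable
stand-ins: commercial datasheets do not pin them down for aroma mixtures,
so defaults were chosen to produce a realistic rise–plateau–decay
morphology with a stable plateau inside the nominal 500–1500 s window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .exceptions import DimensionError, ValidationError

__all__ = [
    "SENSOR_NAMES",
    "SensorSpec",
    "AromaProfile",
    "SimulationConfig",
    "AromaMeasurement",
    "StableWindow",
    "FeatureVector",
    "default_sensor_array",
    "default_profiles",
]

#: Channel order of the modeled array. TGS26xx are Figaro tin-dioxide
#: sensors; MQ135/MQ3/MQ7 target CO2/ethanol/carbon-monoxide respectively.
SENSOR_NAMES: tuple[str, ...] = (
    "TGS2600",
    "TGS2602",
    "TGS2610",
    "TGS2611",
    "TGS2620",
    "MQ135",
    "MQ3",
    "MQ7",
)


@dataclass(frozen=True)
class SensorSpec:
    """Static description of one gas-sensor channel.

    Parameters
    ----------
    name
        Channel identifier (conventionally one of :data:`SENSOR_NAMES`).
    baseline_v
        Clean-air output voltage, > 0.
    rise_tau_s, fall_tau_s
        First-order response/recovery time constants in seconds, > 0.
    noise_sd_v
        Standard deviation of per-sample additive Gaussian noise (V).
    drift_v_per_s
        Slow linear baseline drift rate (V/s); may be negative.
    humidity_coeff
        Fractional sensitivity loss per unit relative humidity, in [0, 1].
        At relative humidity ``h`` the effective response amplitude is
        ``A * (1 - humidity_coeff * h)``.
    """

    name: str
    baseline_v: float
    rise_tau_s: float = 60.0
    fall_tau_s: float = 120.0
    noise_sd_v: float = 0.01
    drift_v_per_s: float = 1e-5
    humidity_coeff: float = 0.2

    def __post_init__(self) -> None:
        if self.rise_tau_s <= 0 or self.fall_tau_s <= 0:
            raise ValidationError(
                f"sensor {self.name!r}: time constants must be positive"
            )
        if self.noise_sd_v < 0:
            raise ValidationError(f"sensor {self.name!r}: noise_sd_v must be >= 0")
        if self.baseline_v <= 0:
            raise ValidationError(f"sensor {self.name!r}: baseline_v must be > 0")
        if not 0.0 <= self.humidity_coeff <= 1.0:
            raise ValidationError(
                f"sensor {self.name!r}: humidity_coeff must be in [0, 1]"
            )


@dataclass(frozen=True)
class AromaProfile:
    """Steady-state response pattern of one aroma class.

    The pattern is the vector of plateau amplitudes (volts above baseline)
    the array settles to under sustained exposure — one amplitude per
    sensor, in array channel order. Distinct odors produce distinct
    patterns; the pattern, not any single channel, is the signature.
    """

    label: str
    amplitudes_v: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplitudes_v", tuple(float(a) for a in self.amplitudes_v))
        if not self.label:
            raise ValidationError("profile label must be non-empty")
        if any(a < 0 for a in self.amplitudes_v):
            raise ValidationError(f"profile {self.label!r}: amplitudes must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Timing, environment and seeding of one simulated recording.

    Defaults reproduce the measurement protocol: 2000 s per sample at
    1 Hz with the odor present from 500 s to 1500 s, the pre/post
    segments serving as calibration baseline.
    """

    duration_s: float = 2000.0
    sample_rate_hz: float = 1.0
    exposure_start_s: float = 500.0
    exposure_end_s: float = 1500.0
    relative_humidity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be > 0")
        if not (0 <= self.exposure_start_s < self.exposure_end_s <= self.duration_s):
            raise ValidationError(
                "require 0 <= exposure_start_s < exposure_end_s <= duration_s, got "
                f"{self.exposure_start_s}, {self.exposure_end_s}, {self.duration_s}"
            )
        if not 0.0 <= self.relative_humidity <= 1.0:
            raise ValidationError("relative_humidity must be in [0, 1]")

    def timestamps(self) -> np.ndarray:
        """Sample times in seconds: 0, 1/rate, ... up to (not including) duration."""
        n = int(round(self.duration_s * self.sample_rate_hz))
        return np.arange(n, dtype=float) / self.sample_rate_hz

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


@dataclass
class AromaMeasurement:
    """One recording: a T×S voltage matrix with timestamps and a label."""

    timestamps_s: np.ndarray
    voltages: np.ndarray
    sensor_names: tuple[str, ...]
    label: str = "unknown"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.sensor_names = tuple(self.sensor_names)
        if self.voltages.ndim != 2:
            raise DimensionError("voltages must be a T×S matrix")
        t, s = self.voltages.shape
        if self.timestamps_s.shape != (t,):
            raise DimensionError(
                f"timestamps length {self.timestamps_s.shape} != rows {t}"
            )
        if len(self.sensor_names) != s:
            raise DimensionError(
                f"{len(self.sensor_names)} sensor names for {s} columns"
            )
        if t > 1 and not np.all(np.diff(self.timestamps_s) > 0):
            raise ValidationError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.voltages.shape[1]


@dataclass(frozen=True)
class StableWindow:
    """Half-open time window [start_s, end_s) of the response plateau."""

    start_s: float = 500.0
    end_s: float = 1500.0

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.end_s:
            raise ValidationError(
                f"require 0 <= start_s < end_s, got [{self.start_s}, {self.end_s})"
            )


@dataclass
class FeatureVector:
    """Subdivision-average features of one recording.

    ``values`` is sensor-major: sensor 0's k subdivision means first, then
    sensor 1's, and so on — length k·S.
    """

    values: np.ndarray
    label: str
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DimensionError("feature values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature values must be finite")


def default_sensor_array() -> tuple[SensorSpec, ...]:
    """The default 8-sensor MOS array.

    Baselines span 0.5–1.5 V; kinetics are shared first-order constants
    (rise 60 s, recovery 120 s) so the 500–1500 s exposure window is a
    plateau. Humidity coefficients are larger for the MQ-series sensors,
    which are known to be more humidity-sensitive than the TGS26xx family.
    All values are configurable stand-ins, not datasheet measurements.
    """
    baselines = (0.55, 0.70, 0.85, 1.00, 1.15, 1.30, 0.90, 1.45)
    humidity = (0.10, 0.12, 0.10, 0.11, 0.13, 0.25, 0.22, 0.20)
    return tuple(
        SensorSpec(name=n, baseline_v=b, humidity_coeff=h)
        for n, b, h in zip(SENSOR_NAMES, baselines, humidity)
    )


def default_profiles() -> tuple[AromaProfile, ...]:
    """Response patterns for the nine benchmark coffee origins.

    Amplitudes are invented but respect two qualitative features of real
    roasted-coffee headspace measurements: the CO-sensitive MQ7 channel
    carries the largest response for every origin (roasting releases CO),
    and Mandheling's MQ7 response is the largest overall.
    """
    rows = {
        "La Flor del": (1.2, 0.9, 0.7, 0.6, 1.0, 1.1, 1.4, 2.2),
        "Kona": (0.8, 1.3, 0.6, 0.5, 1.2, 0.9, 1.1, 2.6),
        "Mandheling": (1.0, 1.1, 0.9, 0.8, 1.3, 1.5, 1.6, 3.4),
        "Sigri": (0.7, 0.8, 1.1, 0.9, 0.6, 1.2, 1.0, 2.0),
        "Bunum Wo": (1.4, 0.6, 0.8, 1.1, 0.9, 0.7, 1.2, 2.4),
        "Ipanema": (0.9, 1.2, 1.3, 0.7, 1.1, 1.0, 0.8, 2.8),
        "Yirgacheffe": (1.1, 1.0, 0.5, 1.2, 0.8, 1.3, 0.9, 3.0),
        "Dongshan": (0.6, 0.7, 1.0, 1.3, 1.4, 0.8, 1.3, 2.1),
        "Tolima": (1.3, 1.4, 1.2, 1.0, 0.7, 0.6, 0.5, 2.5),
    }
    return tuple(AromaProfile(label=k, amplitudes_v=v) for k, v in rows.items())
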