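"""Synthetic e-nose recordings.

The signal model is first-order exponential charge/discharge per channel —
the minimal model reproducing the rise–plateau–decay morphology of a MOS
sensor exposed to an odor pulse. For sensor i with baseline :math:`b_i`,
drift :math:`d_i`, effective amplitude :math:`A_i^{eff}` and time constants
:math:`\\tau_r, \\tau_f`, the noise-free trace is

.. math::

    v_i(t) = b_i + d_i t + \\begin{cases}
        0 & t < t_{on} \\\\
        A_i^{eff}\\,(1 - e^{-(t - t_{on})/\\tau_r}) & t_{on} \\le t < t_{off} \\\\
        P_i\\, e^{-(t - t_{off})/\\tau_f} & t \\ge t_{off}
    \\end{cases}

where :math:`P_i` is the plateau excess at :math:`t_{off}` (so the trace is
continuous there) and :math:`A_i^{eff} = A_i (1 - c_i h)` attenuates the
response multiplicatively with relative humidity :math:`h` — higher
humidity reduces MOS sensitivity. I.i.d. Gaussian noise is added per
sample.
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Sequence

import numpy as np

from .core import AromaMeasurement, AromaProfile, SensorSpec, SimulationConfig
from .exceptions import DimensionError, ValidationError

__all__ = ["noise_free_trace", "simulate_measurement", "generate_dataset"]


def noise_free_trace(
    sensor: SensorSpec, amplitude_v: float, config: SimulationConfig, t: np.ndarray
) -> np.ndarray:
    """Evaluate the piecewise deterministic response of one sensor at times ``t``."""
    t = np.asarray(t, dtype=float)
    t_on, t_off = config.exposure_start_s, config.exposure_end_s
    a_eff = amplitude_v * (1.0 - sensor.humidity_coeff * config.relative_humidity)

    v = sensor.baseline_v + sensor.drift_v_per_s * t
    during = (t >= t_on) & (t < t_off)
    v = np.where(
        during, v + a_eff * (1.0 - np.exp(-(t - t_on) / sensor.rise_tau_s)), v
    )
    # plateau excess at switch-off; reusing it makes the trace exactly continuous
    plateau = a_eff * (1.0 - np.exp(-(t_off - t_on) / sensor.rise_tau_s))
    after = t >= t_off
    v = np.where(after, v + plateau * np.exp(-(t - t_off) / sensor.fall_tau_s), v)
    return v


def simulate_measurement(
    profile: AromaProfile,
    sensors: Sequence[SensorSpec],
    config: SimulationConfig,
) -> AromaMeasurement:
    """Simulate one labeled recording of ``profile`` on the given array.

    The noise stream is fully determined by ``config.seed``: the same
    profile, sensors and config give a bit-identical voltage matrix.
    """
    sensors = tuple(sensors)
    if len(profile.amplitudes_v) != len(sensors):
        raise DimensionError(
            f"profile {profile.label!r} has {len(profile.amplitudes_v)} amplitudes "
            f"for {len(sensors)} sensors"
        )
    t = config.timestamps()
    clean = np.column_stack(
        [noise_free_trace(s, a, config, t) for s, a in zip(sensors, profile.amplitudes_v)]
    )
    rng = np.random.default_rng(config.seed)
    noise_sd = np.array([s.noise_sd_v for s in sensors])
    volts = clean + rng.standard_normal(clean.shape) * noise_sd
    return AromaMeasurement(
        timestamps_s=t,
        voltages=volts,
        sensor_names=tuple(s.name for s in sensors),
        label=profile.label,
        metadata={"seed": config.seed, "config": asdict(config), "source": "simulated"},
    )


def _sub_seed(master_seed: int, class_index: int, replicate_index: int) -> int:
    """Deterministic per-measurement seed, independent of generation order."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(class_index, replicate_index))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(
    profiles: Sequence[AromaProfile],
    n_per_class: int,
    sensors: Sequence[SensorSpec],
    config: SimulationConfig,
    seed: int,
) -> list[AromaMeasurement]:
    """Simulate ``n_per_class`` recordings for each profile.

    Each measurement gets an independent noise stream whose seed is derived
    from ``(seed, class index, replicate index)``, so datasets are
    reproducible and a given recording does not depend on how many others
    were generated.
    """
    profiles = tuple(profiles)
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    if not profiles:
        raise ValidationError("profiles must be non-empty")
    labels = [p.label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate profile labels: {sorted(labels)}")

    out: list[AromaMeasurement] = []
    for ci, profile in enumerate(profiles):
        for ri in range(n_per_class):
            sub = _sub_seed(seed, ci, ri)
            m = simulate_measurement(profile, sensors, config.with_seed(sub))
            m.metadata.update(
                {
                    "master_seed": int(seed),
                    "class_index": ci,
                    "replicate_index": ri,
                    "sub_seed": sub,
                    "source_id": f"{profile.label}/{ri:03d}",
                }
            )
            out.append(m)
    return out
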