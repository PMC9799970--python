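"""Synthetic wave-assay data with the statistical structure the analysis assumes.

The generator stands in for the optical-trap instrument: per-event pulse
amplitudes scatter about the tip-model prediction at each trap force with
Gaussian event-to-event noise (truncated at zero), and force-clamp traces
carry Gaussian baseline noise, a smooth rise to the pulse plateau
(100-400 ms) and a detachment step.  Everything is driven by one seed and
is reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bead_lever import LeverGeometry
from .pulse_detection import PulseTrace
from .tip_assembly import TipConfig, predicted_amplitude_curve

__all__ = ["Condition", "SyntheticConfig", "simulate_event_table", "simulate_trace"]


@dataclass(frozen=True)
class Condition:
    """A ground-truth experimental condition (one tip model)."""

    tip: TipConfig
    species: str = "bovine"
    mg_mM: float = 1.0
    treatment: str = "none"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study design for a synthetic wave-assay dataset.

    Defaults mirror the assay conditions the analysis targets: ~30 events
    per force level with an event-to-event amplitude SD of 8 nm, 2.5 nm
    baseline noise on 200 Hz traces, and 0.1-0.4 s pulse plateaus.
    """

    conditions: tuple
    lever: LeverGeometry = field(default_factory=LeverGeometry)
    trap_force_levels_pn: tuple = (1.0, 2.0, 3.0, 4.0, 6.0, 8.0)
    events_per_level: int = 30
    event_sd_nm: float = 8.0
    baseline_sd_nm: float = 2.5
    pulse_duration_range_s: tuple = (0.1, 0.4)
    sample_rate_hz: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.event_sd_nm < 0 or self.baseline_sd_nm < 0:
            raise ValueError("noise SDs must be nonnegative")
        lo, hi = self.pulse_duration_range_s
        if not 0 < lo <= hi:
            raise ValueError("invalid pulse duration range")


def _truncated_normal(rng, mean, sd, size):
    """Gaussian truncated at zero (proper truncation, not clipping)."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,))
    if sd == 0:
        return mean.copy()
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(
        a, np.inf, loc=mean, scale=sd, size=size, random_state=rng
    )


def simulate_event_table(cfg: SyntheticConfig) -> pd.DataFrame:
    """Draw per-event pulse amplitudes about the model prediction.

    Returns the event-table schema consumed by the inference stage
    (``species, mg_mM, treatment, trap_force_pn, amplitude_nm``) plus the
    generating ``seed`` column.  Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    frames = []
    for cond in cfg.conditions:
        forces = np.asarray(cfg.trap_force_levels_pn, dtype=float)
        pred = predicted_amplitude_curve(cond.tip, cfg.lever, forces).amplitude_nm
        for f, mu in zip(forces, pred):
            amps = _truncated_normal(rng, mu, cfg.event_sd_nm, cfg.events_per_level)
            frames.append(
                pd.DataFrame(
                    {
                        "species": cond.species,
                        "mg_mM": cond.mg_mM,
                        "treatment": cond.treatment,
                        "trap_force_pn": f,
                        "amplitude_nm": amps,
                        "seed": cfg.seed,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_trace(
    cfg: SyntheticConfig,
    event: dict,
    baseline_s: float = 1.0,
    rise_s: float = 0.03,
    tail_s: float = 0.3,
    rng=None,
) -> PulseTrace:
    """Synthesise one force-clamp record for an event.

    ``event`` needs ``amplitude_nm`` and ``trap_force_pn``; an optional
    ``duration_s`` overrides the sampled plateau duration.  The record is
    baseline, half-cosine rise, plateau at the event amplitude, then a
    detachment step far below baseline.  With zero baseline noise,
    :func:`pfwave.pulse_detection.measure_pulse` recovers the amplitude
    exactly.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    amplitude = float(event["amplitude_nm"])
    duration = float(
        event.get("duration_s")
        or rng.uniform(*cfg.pulse_duration_range_s)
    )
    dt = 1.0 / cfg.sample_rate_hz
    n_base = int(round(baseline_s / dt))
    n_rise = max(1, int(round(rise_s / dt)))
    n_plateau = int(round(duration / dt))
    n_tail = int(round(tail_s / dt))

    rise = amplitude * 0.5 * (1 - np.cos(np.linspace(0, math.pi, n_rise + 1)[1:]))
    clean = np.concatenate(
        [
            np.zeros(n_base),
            rise,
            np.full(n_plateau, amplitude),
            np.full(n_tail, -200.0),  # detachment: bead leaves the contact point
        ]
    )
    noise = rng.normal(0.0, cfg.baseline_sd_nm, clean.size)
    t = np.arange(clean.size) * dt
    force = np.full(clean.size, float(event["trap_force_pn"]))
    metadata = {
        k: event[k]
        for k in ("species", "mg_mM", "treatment", "trap_force_pn")
        if k in event
    }
    metadata.update(seed=cfg.seed, true_amplitude_nm=amplitude)
    return PulseTrace(
        time_s=t, position_nm=clean + noise, force_pn=force, metadata=metadata
    )
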