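"""Synthetic glucose/ketone tracking logs for testing and demonstration.

Emulates a subject who starts a ketogenic diet partway through a monitoring
period: glucose and β-OHB sit at pre-diet baselines (defaults 5.5 mM glucose,
0.2 mM β-OHB — a typical fed, non-ketotic state), then relax exponentially to
ketotic steady-state levels (defaults 4.0 mM glucose, 4.0 mM β-OHB, the deep
nutritional-ketosis range reported for patients after ~8 weeks on the diet)
with a configurable half-life.  Measurement noise is multiplicative lognormal
so simulated concentrations stay strictly positive.

This is a test harness, not a physiological model: there are no meals,
no circadian structure, and glucose and ketone noise are independent.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

import numpy as np

from .tracking import Measurement, TrackingLog
from .units import Analyte, Concentration, Unit, ValidationError

__all__ = ["SyntheticConfig", "generate_log", "mean_trajectory"]

# Fixed reading clock times: twice daily, 2-3 h postprandial.
_READING_HOURS = (8, 20, 12, 16)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the simulated diet transition.

    ``diet_start_day`` is the 0-based day index on which the diet begins;
    days before it sample the baseline state.  ``transition_halflife_days``
    sets the tempo of the exponential relaxation (default 3 days, so the
    transition is essentially complete within two to three weeks, matching
    the few-week transitions reported in patients).  ``noise_cv`` is the
    coefficient of variation of the lognormal measurement noise (default
    0.1, i.e. ~10% meter-level scatter).
    """

    n_days: int = 60
    readings_per_day: int = 2
    diet_start_day: int = 7
    baseline_glucose_mM: float = 5.5
    baseline_ketone_mM: float = 0.2
    ketotic_glucose_mM: float = 4.0
    ketotic_ketone_mM: float = 4.0
    transition_halflife_days: float = 3.0
    noise_cv: float = 0.1
    seed: int = 0
    start_date: dt.date = dt.date(2015, 3, 1)
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValidationError("n_days must be positive")
        if not 1 <= self.readings_per_day <= len(_READING_HOURS):
            raise ValidationError(
                f"readings_per_day must be between 1 and {len(_READING_HOURS)}"
            )
        for name in (
            "baseline_glucose_mM",
            "baseline_ketone_mM",
            "ketotic_glucose_mM",
            "ketotic_ketone_mM",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.transition_halflife_days <= 0:
            raise ValidationError("transition_halflife_days must be positive")
        if not 0 <= self.noise_cv < 1:
            raise ValidationError("noise_cv must be in [0, 1)")


def mean_trajectory(cfg: SyntheticConfig, t_days: float) -> tuple[float, float]:
    """Noise-free (glucose mM, ketone mM) at time ``t_days`` from day 0.

    Before the diet starts the trajectory is flat at baseline; afterwards
    each analyte relaxes toward its ketotic level as
    ``x(t) = x_ketotic + (x_baseline - x_ketotic) * 2**(-(t - t0)/halflife)``.
    """
    if t_days < cfg.diet_start_day:
        return cfg.baseline_glucose_mM, cfg.baseline_ketone_mM
    decay = 2.0 ** (-(t_days - cfg.diet_start_day) / cfg.transition_halflife_days)
    g = cfg.ketotic_glucose_mM + (cfg.baseline_glucose_mM - cfg.ketotic_glucose_mM) * decay
    k = cfg.ketotic_ketone_mM + (cfg.baseline_ketone_mM - cfg.ketotic_ketone_mM) * decay
    return g, k


def generate_log(cfg: SyntheticConfig = SyntheticConfig()) -> TrackingLog:
    """Generate a deterministic synthetic tracking log.

    Each reading multiplies the mean trajectory by an independent lognormal
    factor with unit mean and coefficient of variation ``cfg.noise_cv``
    (sigma² = ln(1 + cv²), mu = -sigma²/2).  The same seed always produces
    the identical log.
    """
    rng = np.random.default_rng(cfg.seed)
    sigma = math.sqrt(math.log(1.0 + cfg.noise_cv**2))
    hours = sorted(_READING_HOURS[: cfg.readings_per_day])

    measurements = []
    for day in range(cfg.n_days):
        date = cfg.start_date + dt.timedelta(days=day)
        for hour in hours:
            t = day + hour / 24.0
            g_mean, k_mean = mean_trajectory(cfg, t)
            if cfg.noise_cv > 0:
                g_mult, k_mult = np.exp(rng.normal(-sigma**2 / 2, sigma, size=2))
            else:
                g_mult = k_mult = 1.0
            measurements.append(
                Measurement(
                    timestamp=dt.datetime.combine(date, dt.time(hour)),
                    glucose=Concentration(Analyte.GLUCOSE, g_mean * g_mult, Unit.MM),
                    ketone=Concentration(
                        Analyte.BETA_HYDROXYBUTYRATE, k_mean * k_mult, Unit.MM
                    ),
                    postprandial_hours=2.5,
                )
            )
    return TrackingLog(cfg.subject_id, measurements)
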