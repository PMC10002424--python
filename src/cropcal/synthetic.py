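"""Synthetic inputs: arid-site weather, reference truth, noisy observations.

The generator emulates a single spring-maize season at an arid oasis
site (annual precipitation around 116 mm, potential evaporation roughly
twenty times larger).  A synthetic calibration experiment follows three
steps: draw a reference parameter vector from the uniform prior, run the
forward model to obtain noiseless soil-water-content observations, and
perturb them with i.i.d. Gaussian measurement error (sd 0.005 cm3/cm3 by
default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .forward import SurrogateModel, WeatherSeries
from .space import (ManagementSchedule, ObservationLayout, ParameterSpace,
                    build_default_space, build_observation_layout,
                    build_treatment_schedule, sample_prior)

__all__ = [
    "ObservationSet",
    "DEFAULT_NOISE_SD",
    "generate_weather",
    "generate_reference_truth",
    "perturb_observations",
    "SyntheticCase",
    "make_synthetic_case",
]

DEFAULT_NOISE_SD = 0.005  # cm3/cm3 measurement error sd

_SOWING_DOY = 102  # April 12
_ANNUAL_PRECIP_MM = 116.0
_SEASON_PRECIP_SHARE = 0.52  # warm-season share of the annual total
_ET_TO_PRECIP_RATIO = 20.0
_SEASON_DAYS = 189


@dataclass(frozen=True)
class ObservationSet:
    """Observed soil water content with its Gaussian error model."""

    layout: ObservationLayout
    values: np.ndarray
    noise_sd: float
    reference_params: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self):
        if len(self.values) != self.layout.n_points:
            raise ValueError("values length must equal layout point count")

    @property
    def noise_cov(self) -> np.ndarray:
        """Diagonal measurement-error covariance CD."""
        return np.eye(self.layout.n_points) * self.noise_sd**2

    def subset(self, role: str) -> "ObservationSet":
        mask = self.layout.mask(role)
        return ObservationSet(layout=self.layout.subset(role),
                              values=self.values[mask],
                              noise_sd=self.noise_sd,
                              reference_params=self.reference_params,
                              seed=self.seed)

    def to_csv(self, path) -> None:
        """Write values as CSV plus a JSON sidecar with the error model."""
        path = Path(path)
        tab = self.layout.point_table()
        tab["theta"] = self.values
        tab.to_csv(path, index=False)
        sidecar = {"noise_sd": self.noise_sd, "seed": self.seed,
                   "days_after_sowing": list(self.layout.days_after_sowing)}
        if self.reference_params is not None:
            sidecar["reference_params"] = list(
                map(float, self.reference_params))
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path) -> "ObservationSet":
        path = Path(path)
        tab = pd.read_csv(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        days = tuple(sidecar["days_after_sowing"])
        depths, roles = [], []
        for d, grp in tab.groupby("depth_cm", sort=False):
            depths.append(int(d))
            roles.append(str(grp["role"].iloc[0]))
        layout = ObservationLayout(depths_cm=tuple(depths),
                                   days_after_sowing=days,
                                   roles=tuple(roles))
        ref = sidecar.get("reference_params")
        return cls(layout=layout, values=tab["theta"].to_numpy(float),
                   noise_sd=float(sidecar["noise_sd"]),
                   reference_params=None if ref is None else np.array(ref),
                   seed=sidecar.get("seed"))


def generate_weather(n_days: int, seed: int | np.random.Generator
                     ) -> WeatherSeries:
    """Seeded daily weather for an arid continental site.

    Rainfall falls on sparse random days and is rescaled so the seasonal
    total matches this site's share of the 116 mm annual precipitation
    (scaled to ``n_days``); reference ET follows a summer-peaked cycle
    rescaled so cumulative ET0 is twenty times cumulative precipitation.
    Mean temperature is a fixed sinusoidal annual cycle.
    """
    if n_days < 1:
        raise ValueError("n_days must be at least 1")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed

    doy = _SOWING_DOY + np.arange(n_days)
    cycle = np.sin(2 * np.pi * (doy - 105) / 365.25)
    tmean = 9.0 + 16.0 * cycle

    rain_day = rng.random(n_days) < 0.12
    amounts = rng.gamma(shape=3.0, scale=1.0, size=n_days) * rain_day
    season_total = (_ANNUAL_PRECIP_MM * _SEASON_PRECIP_SHARE
                    * n_days / _SEASON_DAYS)
    target = season_total * (0.8 + 0.4 * rng.random())
    total = amounts.sum()
    if total > 0:
        precip = amounts * (target / total)
    else:  # degenerate short series with no rain days
        precip = amounts

    et0_shape = np.maximum(4.0 + 3.5 * cycle, 0.3)
    et_target = _ET_TO_PRECIP_RATIO * precip.sum()
    if et_target == 0:  # keep evaporative demand even with zero rain
        et_target = _ET_TO_PRECIP_RATIO * target
    et0 = et0_shape * (et_target / et0_shape.sum())
    return WeatherSeries(precip_mm=precip, et0_mm=et0, tmean_c=tmean)


def generate_reference_truth(space: ParameterSpace,
                             schedule: ManagementSchedule,
                             weather: WeatherSeries,
                             layout: ObservationLayout,
                             seed: int | np.random.Generator
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Draw a reference vector from the prior and simulate its noiseless
    observation vector."""
    ref = sample_prior(space, 1, seed)[0]
    model = SurrogateModel(space, schedule, weather, layout)
    noiseless = model(ref[None, :])[0]
    return ref, noiseless


def perturb_observations(noiseless: np.ndarray, noise_sd: float,
                         seed: int | np.random.Generator,
                         layout: ObservationLayout,
                         reference_params: np.ndarray | None = None
                         ) -> ObservationSet:
    """Add i.i.d. N(0, noise_sd^2) measurement error.

    Perturbed values are kept as drawn (never clipped), so the declared
    diagonal covariance remains the exact error model.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    values = np.asarray(noiseless, float) + rng.normal(
        0.0, noise_sd, size=len(noiseless))
    return ObservationSet(layout=layout, values=values, noise_sd=noise_sd,
                          reference_params=reference_params,
                          seed=seed if isinstance(seed, int) else None)


@dataclass(frozen=True)
class SyntheticCase:
    """Everything a calibration run needs, generated from one seed."""

    space: ParameterSpace
    schedule: ManagementSchedule
    weather: WeatherSeries
    layout: ObservationLayout
    model: SurrogateModel
    reference_params: np.ndarray
    noiseless: np.ndarray
    observations: ObservationSet


def make_synthetic_case(seed: int, case: str = "synthetic",
                        treatment: str = "W1N1", year: int = 2008,
                        noise_sd: float = DEFAULT_NOISE_SD) -> SyntheticCase:
    """End-to-end seeded pipeline: weather -> truth -> noisy observations.

    One root seed drives independent streams for weather, the reference
    draw and the measurement noise, so the whole case is reproducible.
    """
    ss = np.random.SeedSequence(seed)
    rng_weather, rng_ref, rng_noise = (np.random.default_rng(c)
                                       for c in ss.spawn(3))
    space = build_default_space()
    schedule = build_treatment_schedule(treatment, year)
    layout = build_observation_layout(case)
    weather = generate_weather(schedule.n_days, rng_weather)
    ref, noiseless = generate_reference_truth(space, schedule, weather,
                                              layout, rng_ref)
    obs = perturb_observations(noiseless, noise_sd, rng_noise, layout,
                               reference_params=ref)
    obs = ObservationSet(layout=obs.layout, values=obs.values,
                         noise_sd=obs.noise_sd, reference_params=ref,
                         seed=seed)
    model = SurrogateModel(space, schedule, weather, layout)
    return SyntheticCase(space=space, schedule=schedule, weather=weather,
                         layout=layout, model=model, reference_params=ref,
                         noiseless=noiseless, observations=obs)
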