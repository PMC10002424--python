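"""Surrogate daily soil-crop forward model.

A deliberately simple, fast and exactly mass-conservative stand-in for a
full soil-water/heat/carbon/nitrogen simulator.  Water moves through the
8-layer profile as a tipping-bucket cascade: water enters layer 1, any
storage above field capacity drains to the layer below at a rate capped
by the layer's saturated conductivity, storage above saturation is
passed on immediately (surface excess becomes runoff), and bottom-layer
drainage leaves the profile.  Evapotranspiration is partitioned FAO-56
style into soil evaporation from the top layer and root-zone
transpiration driven by a crop-coefficient curve over growing degree
days.

Nitrogen pools (ammonium/nitrate) are stepped daily with Michaelis-
Menten nitrification, first-order volatilization and a saturation-excess
denitrification switch.  Nitrogen has no feedback on the water fluxes,
so soil-water observations are insensitive to the five nitrogen
parameters by construction — they are identified only through whatever
observations constrain them directly.

All 45 calibration parameters are consumed; the model is deterministic,
and the season loop is vectorized across ensemble members so a whole
500-member ensemble simulates in tens of milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .space import (LAYER_THICKNESS_CM, N_LAYERS, ManagementSchedule,
                    ObservationLayout, ParameterSpace, depth_to_layer)

__all__ = [
    "SoilProfile",
    "WeatherSeries",
    "SimulationResult",
    "InvalidParameterError",
    "crop_coefficient",
    "nitrogen_step",
    "simulate",
    "SurrogateModel",
]

GDD_BASE_C = 8.0  # maize base temperature for degree-day accumulation
MASS_BALANCE_TOL_CM = 1e-9
_EVAP_FRACTION = 0.3  # split of potential ET into soil evaporation
_INIT_NH4 = 5.0  # g/m3, initial ammonium pool
_INIT_NO3 = 20.0  # g/m3, initial nitrate pool
# Reference AMAX * mean-SLA used to normalize the transpiration-demand
# multiplier: the upper prior bounds, 54 kg/(hm2.h) and (36+12)/2 m2/kg.
_DEMAND_REF = 54.0 * 24.0
_DEMAND_FLOOR = 0.5


class InvalidParameterError(ValueError):
    """Parameter vector binds to a non-physical soil profile."""


@dataclass(frozen=True)
class SoilProfile:
    """Per-layer hydraulic properties bound from a parameter vector."""

    ks_cm_d: np.ndarray
    sat: np.ndarray
    fc: np.ndarray
    pwp: np.ndarray
    thickness_cm: float = LAYER_THICKNESS_CM

    def __post_init__(self):
        ok = (0 < self.pwp) & (self.pwp < self.fc) & (self.fc < self.sat) \
            & (self.sat < 1)
        if not np.all(ok):
            raise InvalidParameterError(
                "require 0 < PWP < FC < SAT < 1 in every layer")

    @classmethod
    def from_vector(cls, space: ParameterSpace,
                    values: np.ndarray) -> "SoilProfile":
        return cls(
            ks_cm_d=space.hydraulic("Ks", values).astype(float),
            sat=space.hydraulic("SAT", values).astype(float),
            fc=space.hydraulic("FC", values).astype(float),
            pwp=space.hydraulic("PWP", values).astype(float),
        )


@dataclass(frozen=True)
class WeatherSeries:
    """Daily forcing: precipitation, reference ET and mean temperature."""

    precip_mm: np.ndarray
    et0_mm: np.ndarray
    tmean_c: np.ndarray

    def __post_init__(self):
        n = len(self.precip_mm)
        if len(self.et0_mm) != n or len(self.tmean_c) != n:
            raise ValueError("weather series must share one length")
        if (self.precip_mm < 0).any() or (self.et0_mm < 0).any():
            raise ValueError("precipitation and ET0 must be non-negative")

    def __len__(self) -> int:
        return len(self.precip_mm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "day": np.arange(len(self)),
            "precip_mm": self.precip_mm,
            "et0_mm": self.et0_mm,
            "tmean_c": self.tmean_c,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WeatherSeries":
        df = pd.read_csv(path)
        return cls(df["precip_mm"].to_numpy(float),
                   df["et0_mm"].to_numpy(float),
                   df["tmean_c"].to_numpy(float))


@dataclass(frozen=True)
class SimulationResult:
    """Daily states plus the observation vector for a layout."""

    theta: np.ndarray  # (n_days, n_layers) volumetric water content
    observations: np.ndarray  # aligned to the layout's point order
    ledger: pd.DataFrame  # daily water balance, cm
    nh4: np.ndarray  # (n_days,) g/m3
    no3: np.ndarray  # (n_days,) g/m3

    def observations_frame(self, layout: ObservationLayout) -> pd.DataFrame:
        tab = layout.point_table()[["depth_cm", "day_after_sowing"]].copy()
        tab["theta"] = self.observations
        return tab


def crop_coefficient(gdd, tsum, kini, kmid, kend):
    """FAO-56-style piecewise-linear crop coefficient over thermal time.

    Kini up to 0.2*Tsum, linear rise to Kmid at 0.45*Tsum, plateau to
    0.75*Tsum, linear fall to Kend at Tsum, constant Kend afterwards.
    Accepts scalars or broadcastable arrays.
    """
    tsum = np.asarray(tsum, float)
    if np.any(tsum <= 0):
        raise ValueError("Tsum must be positive")
    gdd = np.asarray(gdd, float)
    if np.any(gdd < 0):
        raise ValueError("gdd must be non-negative")
    kini, kmid, kend = (np.asarray(v, float) for v in (kini, kmid, kend))
    f = gdd / tsum
    rise = kini + (kmid - kini) * (f - 0.2) / 0.25
    fall = kmid + (kend - kmid) * (f - 0.75) / 0.25
    kc = np.select(
        [f <= 0.2, f <= 0.45, f <= 0.75, f <= 1.0],
        [np.broadcast_to(kini, f.shape), rise,
         np.broadcast_to(kmid, f.shape), fall],
        default=np.broadcast_to(kend, f.shape))
    return float(kc) if kc.ndim == 0 else kc


def nitrogen_step(nh4, no3, theta, fc, sat, vn, kn, kd, ad, kv):
    """One explicit daily step of the ammonium/nitrate pools (g/m3).

    nitrification = Vn*nh4/(Kn+nh4); volatilization = Kv*nh4;
    denitrification = Kd*Ad*no3*s(theta) with s rising linearly from 0
    at field capacity to 1 at saturation.  Fluxes are capped so pools
    never go negative.  Accepts scalars or broadcastable arrays.
    """
    nh4 = np.asarray(nh4, float)
    no3 = np.asarray(no3, float)
    if np.any(nh4 < 0) or np.any(no3 < 0):
        raise ValueError("nitrogen pools must be non-negative")
    scalar = nh4.ndim == 0 and no3.ndim == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        nitr = np.where(nh4 > 0, vn * nh4 / (kn + nh4), 0.0)
        vol = kv * nh4
        out = nitr + vol
        scale = np.where(out > nh4, np.divide(
            nh4, out, out=np.ones_like(out), where=out > 0), 1.0)
    nitr = nitr * scale
    vol = vol * scale
    s = np.clip((np.asarray(theta, float) - fc) / (np.asarray(sat) - fc),
                0.0, 1.0)
    denit = np.minimum(kd * ad * no3 * s, no3)
    nh4_new = nh4 - nitr - vol
    no3_new = no3 + nitr - denit
    if scalar:
        return float(nh4_new), float(no3_new)
    return nh4_new, no3_new


def _observation_indices(layout: ObservationLayout) -> tuple[np.ndarray,
                                                             np.ndarray]:
    days = np.array([t for _ in layout.depths_cm
                     for t in layout.days_after_sowing])
    layers = np.array([depth_to_layer(d) - 1 for d in layout.depths_cm
                       for _ in layout.days_after_sowing])
    return days, layers


def _batch_season(P: np.ndarray, space: ParameterSpace,
                  schedule: ManagementSchedule, weather: WeatherSeries,
                  full_state: bool = False) -> dict:
    """Advance every member of a (n, 45) parameter matrix through one
    season together.  Returns daily theta and, when ``full_state`` is
    set, the nitrogen pools and the water-balance ledger."""
    P = np.atleast_2d(np.asarray(P, float))
    n = P.shape[0]
    n_days = len(weather)

    ks = space.hydraulic("Ks", P)
    sat = space.hydraulic("SAT", P)
    fc = space.hydraulic("FC", P)
    pwp = space.hydraulic("PWP", P)
    ok = np.all((0 < pwp) & (pwp < fc) & (fc < sat) & (sat < 1), axis=1)
    if not ok.all():
        raise InvalidParameterError(
            "require 0 < PWP < FC < SAT < 1 in every layer")

    vn, kn = space.scalar("Vn", P), space.scalar("Kn", P)
    kd, ad = space.scalar("Kd", P), space.scalar("Ad", P)
    kv = space.scalar("Kv", P)
    kini = space.scalar("Kini", P)
    kmid = space.scalar("Kmid", P)
    kend = space.scalar("Kend", P)
    tsum = space.scalar("Tsum", P)
    slamax = space.scalar("SLAmax", P)
    slamin = space.scalar("SLAmin", P)
    amax = space.scalar("AMAX", P)
    rmax = space.scalar("Rmax", P)

    dz = LAYER_THICKNESS_CM
    sat_cm, fc_cm, pwp_cm = sat * dz, fc * dz, pwp * dz
    layer_top = dz * np.arange(N_LAYERS)

    # crude leaf-area proxy scaling transpiration demand; bounded, smooth
    demand_mult = np.maximum(
        _DEMAND_FLOOR, amax * 0.5 * (slamax + slamin) / _DEMAND_REF)

    irrigation_cm = schedule.daily_irrigation_mm(n_days) / 10.0
    # kg Urea-N/ha over the 180 cm profile -> g N per m3 of soil
    fert_g_m3 = schedule.daily_fertilization_kg(n_days) * 0.1 / 1.8
    precip_cm = weather.precip_mm / 10.0
    et0_cm = weather.et0_mm / 10.0
    w_in_series = precip_cm + irrigation_cm
    gdd_series = np.cumsum(np.maximum(weather.tmean_c - GDD_BASE_C, 0.0))

    # phenology-driven quantities depend on thermal time and parameters
    # only, never on the water state, so precompute them for all days
    kc = crop_coefficient(gdd_series[:, None], tsum[None, :],
                          kini[None, :], kmid[None, :], kend[None, :])
    pet = kc * et0_cm[:, None] * demand_mult[None, :]  # (n_days, n)
    evap_demand = _EVAP_FRACTION * pet
    transp_demand = (1.0 - _EVAP_FRACTION) * pet
    root_depth = np.minimum(gdd_series[:, None] / tsum[None, :], 1.0) \
        * rmax[None, :]
    root_frac = np.clip((root_depth[:, :, None] - layer_top) / dz, 0.0, 1.0)

    water = fc_cm.copy()  # (n, 8); the season starts at field capacity
    nh4 = np.full(n, _INIT_NH4)
    no3 = np.full(n, _INIT_NO3)
    fc0, sat0 = fc[:, 0], sat[:, 0]
    sat_span0 = sat0 - fc0

    theta = np.empty((n, n_days, N_LAYERS))
    if full_state:
        nh4_hist = np.empty((n, n_days))
        no3_hist = np.empty((n, n_days))
        ledger = np.empty((n, n_days, 5))

    for t in range(n_days):
        if full_state:
            storage0 = water.sum(axis=1)

        # infiltration and tipping-bucket drainage cascade
        water[:, 0] += w_in_series[t]
        runoff = np.maximum(water[:, 0] - sat_cm[:, 0], 0.0)
        water[:, 0] -= runoff
        carry = 0.0
        for l in range(N_LAYERS):
            wl = water[:, l] + carry
            over_sat = np.maximum(wl - sat_cm[:, l], 0.0)
            over_fc = np.maximum(np.minimum(wl, sat_cm[:, l]) - fc_cm[:, l],
                                 0.0)
            carry = over_sat + np.minimum(over_fc, ks[:, l])
            water[:, l] = wl - carry
        drainage = carry

        # evapotranspiration: evaporation from layer 1, transpiration
        # over the root zone weighted by available water
        evap = np.minimum(evap_demand[t], water[:, 0])
        water[:, 0] -= evap
        avail = np.maximum(water - pwp_cm, 0.0)
        weights = root_frac[t] * avail
        wsum = weights.sum(axis=1)
        safe = np.where(wsum > 0, wsum, 1.0)
        uptake = np.minimum(transp_demand[t][:, None] * weights
                            / safe[:, None], avail)
        uptake[wsum <= 0] = 0.0
        water -= uptake

        # nitrogen pools (lean inline version of nitrogen_step)
        nh4 = nh4 + fert_g_m3[t]
        nitr = vn * nh4 / (kn + nh4)
        vol = kv * nh4
        flux_out = nitr + vol
        scale = np.where(flux_out > nh4,
                         nh4 / np.maximum(flux_out, 1e-300), 1.0)
        nitr = nitr * scale
        nh4 = nh4 - flux_out * scale
        s = np.clip((water[:, 0] / dz - fc0) / sat_span0, 0.0, 1.0)
        denit = np.minimum(kd * ad * no3 * s, no3)
        no3 = no3 + nitr - denit

        theta[:, t, :] = water
        if full_state:
            nh4_hist[:, t] = nh4
            no3_hist[:, t] = no3
            ledger[:, t, 0] = w_in_series[t]
            ledger[:, t, 1] = evap + uptake.sum(axis=1)
            ledger[:, t, 2] = drainage
            ledger[:, t, 3] = runoff
            ledger[:, t, 4] = water.sum(axis=1) - storage0
    theta /= dz

    out = {"theta": theta}
    if full_state:
        out.update(nh4=nh4_hist, no3=no3_hist, ledger=ledger)
    return out


def simulate(params: np.ndarray, space: ParameterSpace,
             schedule: ManagementSchedule, weather: WeatherSeries,
             layout: ObservationLayout) -> SimulationResult:
    """Run one growing season and extract the layout's observation vector.

    Raises :class:`InvalidParameterError` when the bound soil profile
    violates PWP < FC < SAT; samplers translate that into an infinite
    misfit.
    """
    if len(weather) <= max(layout.days_after_sowing):
        raise ValueError("weather series does not cover the observation days")
    state = _batch_season(np.asarray(params, float)[None, :], space,
                          schedule, weather, full_state=True)
    theta = state["theta"][0]
    ledger_df = pd.DataFrame(
        state["ledger"][0],
        columns=["input_cm", "et_cm", "drainage_cm", "runoff_cm",
                 "storage_change_cm"])
    days, layers = _observation_indices(layout)
    return SimulationResult(theta=theta, observations=theta[days, layers],
                            ledger=ledger_df, nh4=state["nh4"][0],
                            no3=state["no3"][0])


class SurrogateModel:
    """Vectorized forward operator: parameter matrix -> observation matrix.

    This is the callable interface the samplers consume.  Rows that bind
    to a non-physical profile come back as all-NaN predictions, which
    the samplers treat as infinite misfit.
    """

    def __init__(self, space: ParameterSpace, schedule: ManagementSchedule,
                 weather: WeatherSeries, layout: ObservationLayout):
        if len(weather) <= max(layout.days_after_sowing):
            raise ValueError(
                "weather series does not cover the observation days")
        self.space = space
        self.schedule = schedule
        self.weather = weather
        self.layout = layout
        self._days, self._layers = _observation_indices(layout)

    @property
    def n_obs(self) -> int:
        return self.layout.n_points

    @property
    def bounds(self) -> np.ndarray:
        return self.space.bounds

    def __call__(self, M: np.ndarray) -> np.ndarray:
        M = np.atleast_2d(np.asarray(M, dtype=float))
        sat = self.space.hydraulic("SAT", M)
        fc = self.space.hydraulic("FC", M)
        pwp = self.space.hydraulic("PWP", M)
        valid = np.all((0 < pwp) & (pwp < fc) & (fc < sat) & (sat < 1),
                       axis=1)
        out = np.full((M.shape[0], self.n_obs), np.nan)
        if valid.any():
            theta = _batch_season(M[valid], self.space, self.schedule,
                                  self.weather)["theta"]
            out[valid] = theta[:, self._days, self._layers]
        return out
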