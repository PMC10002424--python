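"""Parameter space, management schedules and observation layouts.

The calibration problem covers 45 parameters of a layered soil-crop
system: four hydraulic parameters (saturated conductivity Ks, saturation
SAT, field capacity FC, wilting point PWP) for each of 8 soil layers
spanning a 180 cm profile, five nitrogen-transformation parameters and
eight crop parameters.  Uniform priors on the boxes below define the
prior distribution everywhere in the toolkit.

The ordering of :func:`build_default_space` is canonical: every
parameter vector, ensemble matrix and MCMC chain indexes parameters in
this order (per-layer Ks, SAT, FC, PWP for layers 1..8, then nitrogen,
then crop).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParameterSpec",
    "ParameterSpace",
    "ManagementSchedule",
    "ObservationLayout",
    "build_default_space",
    "sample_prior",
    "build_treatment_schedule",
    "build_observation_layout",
    "OBSERVATION_DAYS",
    "PROFILE_DEPTH_CM",
    "N_LAYERS",
    "LAYER_THICKNESS_CM",
    "depth_to_layer",
]

PROFILE_DEPTH_CM = 180.0
N_LAYERS = 8
LAYER_THICKNESS_CM = PROFILE_DEPTH_CM / N_LAYERS  # 22.5 cm, equal layers

#: Days after sowing on which soil water content is observed (17 days).
OBSERVATION_DAYS = (41, 52, 54, 63, 70, 74, 82, 91, 95, 104, 109, 115,
                    124, 135, 146, 154, 160)

# Hydraulic prior bounds per layer: (Ks cm/d, SAT, FC, PWP), each (lo, hi).
_HYDRAULIC_BOUNDS = [
    ((56.59, 69.17), (0.30, 0.36), (0.20, 0.25), (0.11, 0.13)),
    ((72.58, 88.70), (0.32, 0.40), (0.18, 0.22), (0.09, 0.12)),
    ((46.22, 56.50), (0.32, 0.40), (0.18, 0.22), (0.08, 0.10)),
    ((63.50, 77.62), (0.23, 0.29), (0.18, 0.22), (0.06, 0.08)),
    ((29.81, 36.43), (0.26, 0.31), (0.16, 0.19), (0.06, 0.08)),
    ((31.10, 38.02), (0.24, 0.30), (0.15, 0.18), (0.04, 0.06)),
    ((37.37, 45.67), (0.23, 0.28), (0.14, 0.18), (0.04, 0.06)),
    ((56.38, 68.90), (0.22, 0.26), (0.10, 0.13), (0.06, 0.08)),
]

# Nitrogen-transformation and crop parameters: (symbol, unit, lo, hi).
_SCALAR_BOUNDS = [
    ("Vn", "g/(m3.d)", 5.0, 15.0),
    ("Kn", "g/m3", 25.0, 75.0),
    ("Kd", "-", 0.50, 1.50),
    ("Ad", "-", 0.05, 0.15),
    ("Kv", "1/d", 0.015, 0.045),
    ("Kini", "-", 0.36, 0.54),
    ("Kmid", "-", 1.0, 1.5),
    ("Kend", "-", 0.64, 0.96),
    ("Tsum", "degC.d", 1480.0, 2220.0),
    ("SLAmax", "m2/kg", 24.0, 36.0),
    ("SLAmin", "m2/kg", 8.0, 12.0),
    ("AMAX", "kg/(hm2.h)", 36.0, 54.0),
    ("Rmax", "cm", 96.0, 144.0),
]

_HYDRAULIC_SYMBOLS = ("Ks", "SAT", "FC", "PWP")
_HYDRAULIC_UNITS = {"Ks": "cm/d", "SAT": "cm3/cm3", "FC": "cm3/cm3",
                    "PWP": "cm3/cm3"}


@dataclass(frozen=True)
class ParameterSpec:
    """A single named, bounded, unit-carrying calibration parameter."""

    name: str
    symbol: str
    layer: int | None
    unit: str
    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower bound must be < upper")


@dataclass(frozen=True)
class ParameterSpace:
    """Ordered collection of :class:`ParameterSpec`.

    The order of ``specs`` defines vector index semantics for every
    ensemble matrix and chain in the toolkit.
    """

    specs: tuple[ParameterSpec, ...]

    def __post_init__(self):
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")

    def __len__(self) -> int:
        return len(self.specs)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def lower(self) -> np.ndarray:
        return np.array([s.lower for s in self.specs])

    @property
    def upper(self) -> np.ndarray:
        return np.array([s.upper for s in self.specs])

    @property
    def bounds(self) -> np.ndarray:
        """(d, 2) array of [lower, upper]."""
        return np.column_stack([self.lower, self.upper])

    def index(self, name: str) -> int:
        return self.names.index(name)

    def in_bounds(self, values: np.ndarray) -> np.ndarray:
        """Elementwise-all in-bounds flag for one vector or a matrix of rows."""
        v = np.asarray(values)
        ok = (v >= self.lower) & (v <= self.upper)
        return ok.all(axis=-1)

    def hydraulic(self, symbol: str, values: np.ndarray) -> np.ndarray:
        """Extract the 8 per-layer values of one hydraulic symbol."""
        idx = [self.index(f"{symbol}_{k}") for k in range(1, N_LAYERS + 1)]
        return np.asarray(values)[..., idx]

    def scalar(self, symbol: str, values: np.ndarray) -> float | np.ndarray:
        return np.asarray(values)[..., self.index(symbol)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [s.name for s in self.specs],
                "symbol": [s.symbol for s in self.specs],
                "layer": [s.layer if s.layer is not None else ""
                          for s in self.specs],
                "unit": [s.unit for s in self.specs],
                "lower": [s.lower for s in self.specs],
                "upper": [s.upper for s in self.specs],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ParameterSpace":
        df = pd.read_csv(path, keep_default_na=False)
        specs = []
        for row in df.itertuples(index=False):
            layer = int(row.layer) if str(row.layer).strip() else None
            specs.append(ParameterSpec(str(row.name), str(row.symbol), layer,
                                       str(row.unit), float(row.lower),
                                       float(row.upper)))
        return cls(tuple(specs))


def build_default_space() -> ParameterSpace:
    """The default 45-parameter space.

    Order: (Ks, SAT, FC, PWP) for layers 1..8, then Vn, Kn, Kd, Ad, Kv,
    then Kini, Kmid, Kend, Tsum, SLAmax, SLAmin, AMAX, Rmax.
    """
    specs: list[ParameterSpec] = []
    for layer, row in enumerate(_HYDRAULIC_BOUNDS, start=1):
        for symbol, (lo, hi) in zip(_HYDRAULIC_SYMBOLS, row):
            specs.append(ParameterSpec(
                name=f"{symbol}_{layer}", symbol=symbol, layer=layer,
                unit=_HYDRAULIC_UNITS[symbol], lower=lo, upper=hi))
    for symbol, unit, lo, hi in _SCALAR_BOUNDS:
        specs.append(ParameterSpec(name=symbol, symbol=symbol, layer=None,
                                   unit=unit, lower=lo, upper=hi))
    return ParameterSpace(tuple(specs))


def sample_prior(space: ParameterSpace, n: int,
                 seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. uniform vectors from the prior box.

    Returns an (n, d) array; reproducible for integer seeds.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    lo, hi = space.lower, space.upper
    return lo + (hi - lo) * rng.random((n, len(space)))


def depth_to_layer(depth_cm: float) -> int:
    """Map a measurement depth to its 1-based soil layer (22.5 cm layers).

    Depths on a layer boundary belong to the layer above.
    """
    if not 0 < depth_cm <= PROFILE_DEPTH_CM:
        raise ValueError(f"depth {depth_cm} cm outside the 180 cm profile")
    return int(np.ceil(depth_cm / LAYER_THICKNESS_CM))


# --- management schedules -------------------------------------------------

_SCHEDULE_DATES = {
    2008: ["2008-06-03", "2008-06-21", "2008-07-13", "2008-08-04",
           "2008-08-29"],
    2009: ["2009-06-01", "2009-06-22", "2009-07-13", "2009-08-01",
           "2009-08-23"],
}
_IRRIGATION_MM = {"W1": [150.0] * 5, "W2": [105.0, 105.0, 120.0, 120.0,
                                            120.0]}
_FERTILIZATION_KG = {"N1": 138.0, "N2": 92.0}
TREATMENTS = ("W1N1", "W1N2", "W2N1", "W2N2")


@dataclass(frozen=True)
class ManagementSchedule:
    """Season calendar plus irrigation and urea-N fertilization events."""

    year: int
    treatment: str
    sowing_day: _dt.date
    harvest_day: _dt.date
    irrigation_events: tuple[tuple[_dt.date, float], ...]  # (date, mm)
    fertilization_events: tuple[tuple[_dt.date, float], ...]  # (date, kg N/ha)

    def __post_init__(self):
        for d, _ in (*self.irrigation_events, *self.fertilization_events):
            if not self.sowing_day <= d <= self.harvest_day:
                raise ValueError(f"event date {d} outside the growing season")

    @property
    def n_days(self) -> int:
        """Days in the season with sowing as day 0 (inclusive of harvest)."""
        return (self.harvest_day - self.sowing_day).days + 1

    @property
    def total_irrigation_mm(self) -> float:
        return float(sum(a for _, a in self.irrigation_events))

    @property
    def total_fertilization_kg(self) -> float:
        return float(sum(a for _, a in self.fertilization_events))

    def day_of(self, date: _dt.date) -> int:
        return (date - self.sowing_day).days

    def daily_irrigation_mm(self, n_days: int | None = None) -> np.ndarray:
        n = n_days if n_days is not None else self.n_days
        out = np.zeros(n)
        for d, mm in self.irrigation_events:
            out[self.day_of(d)] += mm
        return out

    def daily_fertilization_kg(self, n_days: int | None = None) -> np.ndarray:
        n = n_days if n_days is not None else self.n_days
        out = np.zeros(n)
        for d, kg in self.fertilization_events:
            out[self.day_of(d)] += kg
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(d.isoformat(), "irrigation", mm, "mm")
                for d, mm in self.irrigation_events]
        rows += [(d.isoformat(), "fertilization", kg, "kg Urea-N/ha")
                 for d, kg in self.fertilization_events]
        return pd.DataFrame(rows, columns=["date", "kind", "amount", "unit"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_treatment_schedule(treatment: str, year: int) -> ManagementSchedule:
    """Build one of the four irrigation x fertilization treatments.

    Treatments combine a standard (W1: five 150 mm events, 750 mm total)
    or conserving (W2: 105/105/120/120/120 mm, 570 mm) irrigation regime
    with standard (N1: 138 kg Urea-N/ha) or conserving (N2: 92 kg)
    fertilization, applied at the first scheduled date.
    """
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}; "
                         f"expected one of {TREATMENTS}")
    if year not in _SCHEDULE_DATES:
        raise ValueError(f"unknown year {year}; expected 2008 or 2009")
    dates = [_dt.date.fromisoformat(s) for s in _SCHEDULE_DATES[year]]
    irr = _IRRIGATION_MM[treatment[:2]]
    fert = _FERTILIZATION_KG[treatment[2:]]
    return ManagementSchedule(
        year=year,
        treatment=treatment,
        sowing_day=_dt.date(year, 4, 12),
        harvest_day=_dt.date(year, 10, 18),
        irrigation_events=tuple(zip(dates, irr)),
        fertilization_events=((dates[0], fert),),
    )


# --- observation layouts --------------------------------------------------

_SYNTHETIC_DEPTHS = tuple(range(20, 180, 10))  # 16 depths, 20..170 cm
_CAL_DEPTHS = (20, 40, 60, 80, 100, 120, 140, 160)
_VAL_DEPTHS = (30, 50, 70, 90, 110, 130, 170)  # 150 cm unused


@dataclass(frozen=True)
class ObservationLayout:
    """Depth x day grid of soil-water-content observation points.

    Points are ordered depth-major (all days of the shallowest depth
    first).  ``roles`` assigns each depth to the calibration set, the
    validation set, or both.
    """

    depths_cm: tuple[int, ...]
    days_after_sowing: tuple[int, ...] = OBSERVATION_DAYS
    roles: tuple[str, ...] = field(default=())  # per depth

    def __post_init__(self):
        roles = self.roles or tuple("both" for _ in self.depths_cm)
        object.__setattr__(self, "roles", roles)
        if len(self.roles) != len(self.depths_cm):
            raise ValueError("one role per depth required")
        if any(r not in ("calibration", "validation", "both")
               for r in self.roles):
            raise ValueError("roles must be calibration|validation|both")

    @property
    def n_points(self) -> int:
        return len(self.depths_cm) * len(self.days_after_sowing)

    def point_table(self) -> pd.DataFrame:
        """Long-format (depth_cm, day_after_sowing, role) per point."""
        rows = [(d, t, r)
                for d, r in zip(self.depths_cm, self.roles)
                for t in self.days_after_sowing]
        return pd.DataFrame(rows, columns=["depth_cm", "day_after_sowing",
                                           "role"])

    def mask(self, role: str) -> np.ndarray:
        """Boolean mask of points belonging to ``role`` (both always counts)."""
        tab = self.point_table()
        return ((tab["role"] == role) | (tab["role"] == "both")).to_numpy()

    def subset(self, role: str) -> "ObservationLayout":
        keep = [(d, r) for d, r in zip(self.depths_cm, self.roles)
                if r == role or r == "both"]
        return ObservationLayout(
            depths_cm=tuple(d for d, _ in keep),
            days_after_sowing=self.days_after_sowing,
            roles=tuple(r for _, r in keep),
        )


def build_observation_layout(case: str) -> ObservationLayout:
    """Observation layout for the ``synthetic`` or ``practical`` case.

    synthetic: 16 depths (20..170 cm every 10 cm) x 17 days, all points
    used for calibration and validation alike (272 points).
    practical: 8 calibration depths (136 points) and 7 validation depths
    (119 points); 150 cm is unused.
    """
    if case == "synthetic":
        return ObservationLayout(depths_cm=_SYNTHETIC_DEPTHS)
    if case == "practical":
        depths = tuple(sorted(_CAL_DEPTHS + _VAL_DEPTHS))
        roles = tuple("calibration" if d in _CAL_DEPTHS else "validation"
                      for d in depths)
        return ObservationLayout(depths_cm=depths, roles=roles)
    raise ValueError(f"unknown case {case!r}; expected synthetic|practical")
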