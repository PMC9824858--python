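"""Stem water-content physics and immersion-experiment analytics.

Physics
-------
Longitudinal ultrasonic velocity in an elastic solid:

    v = sqrt( (E / rho) * (1 - sigma) / ((1 + sigma) * (1 - 2 sigma)) )

with modulus of elasticity ``E`` (Pa), density ``rho`` (kg/m^3) and
Poisson's ratio ``sigma``. For a stem whose elastic constants are roughly
fixed, water uptake raises ``rho`` and so lowers the velocity — the basis of
tracking stem water status by the echo time of flight: ``v = 2 D / t`` with
half-path ``D`` and round-trip echo time ``t``.

Moisture content
----------------
Volumetric moisture of an immersed sample with soaked mass ``m_A``, initial
mass ``m_B``, water density ``beta`` and sample volume ``V``:

    theta = (m_A - m_B) / (beta * V)

Mass moisture content is wet-basis: ``(m_A - m_B) / m_A``.

A bundled dataset (three cylindrical stem samples, diameters 6/7/10 cm,
15 immersion timepoints each, with measured velocities) ships with the
package; :func:`immersion_analysis` reproduces its derived rows and fits the
velocity-moisture relation per sample with a quadratic polynomial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ElasticMedium",
    "ImmersionRecord",
    "FitResult",
    "ImmersionAnalysis",
    "WATER_DENSITY_G_CM3",
    "longitudinal_velocity",
    "velocity_from_echo",
    "sample_volume",
    "bulk_density",
    "volumetric_moisture",
    "mass_moisture",
    "immersion_analysis",
    "track_correlation",
    "read_immersion_table",
    "load_bundled_immersion",
]

#: Default water density, g/cm^3.
WATER_DENSITY_G_CM3 = 1.0

IMMERSION_COLUMNS = (
    "sample_id",
    "shape",
    "dim1_cm",
    "dim2_cm",
    "dim3_cm",
    "timepoint_h",
    "mass_g",
    "velocity_m_s",
)


@dataclass(frozen=True)
class ElasticMedium:
    """Elastic constants of a propagation medium."""

    E: float  # modulus of elasticity, Pa
    rho: float  # density, kg/m^3
    sigma: float  # Poisson's ratio

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("modulus of elasticity must be positive")
        if self.rho <= 0:
            raise ValueError("density must be positive")
        if not 0 <= self.sigma < 0.5:
            raise ValueError("Poisson's ratio must lie in [0, 0.5)")


@dataclass(frozen=True)
class ImmersionRecord:
    """One sample at one immersion timepoint."""

    sample_id: str
    shape: str  # "cylinder" (diameter x height) or "cuboid" (3 edges)
    dims_cm: tuple[float, ...]
    timepoint_h: float
    mass_g: float
    velocity_m_s: float | None = None

    def __post_init__(self) -> None:
        if self.shape == "cylinder":
            if len(self.dims_cm) != 2:
                raise ValueError("cylinder needs (diameter, height)")
        elif self.shape == "cuboid":
            if len(self.dims_cm) != 3:
                raise ValueError("cuboid needs three edge lengths")
        else:
            raise ValueError(f"unknown shape {self.shape!r}")
        if any(d <= 0 for d in self.dims_cm):
            raise ValueError("dimensions must be positive")
        if self.mass_g <= 0:
            raise ValueError("mass must be positive")
        if self.timepoint_h < 0:
            raise ValueError("timepoint must be nonnegative")


@dataclass(frozen=True)
class FitResult:
    """Quadratic velocity-moisture fit for one sample."""

    coefficients: tuple[float, float, float]  # highest degree first
    correlation: float
    n_points: int


@dataclass(frozen=True)
class ImmersionAnalysis:
    """Derived per-timepoint table, per-sample fits and their mean correlation."""

    table: pd.DataFrame
    fits: dict[str, FitResult]
    mean_correlation: float


def longitudinal_velocity(medium: ElasticMedium) -> float:
    """Longitudinal wave velocity (m/s) from the elastic constants.

    Strictly increasing in E and strictly decreasing in rho: water uptake
    (higher density at fixed elastic constants) slows the wave.
    """
    e, rho, sig = medium.E, medium.rho, medium.sigma
    return float(np.sqrt((e / rho) * (1 - sig) / ((1 + sig) * (1 - 2 * sig))))


def velocity_from_echo(half_path_m: float, echo_time_s: float) -> float:
    """Velocity (m/s) from the round-trip echo time: ``v = 2 D / t``."""
    if half_path_m <= 0:
        raise ValueError("path length must be positive")
    if echo_time_s <= 0:
        raise ValueError("echo time must be positive")
    return 2.0 * half_path_m / echo_time_s


def sample_volume(rec: ImmersionRecord) -> float:
    """Sample volume in cm^3 (cylinder: pi (d/2)^2 h; cuboid: edge product)."""
    if rec.shape == "cylinder":
        d, h = rec.dims_cm
        return float(np.pi * (d / 2.0) ** 2 * h)
    a, b, c = rec.dims_cm
    return float(a * b * c)


def bulk_density(mass_g: float, volume_cm3: float) -> float:
    """Bulk density in g/cm^3."""
    if mass_g <= 0 or volume_cm3 <= 0:
        raise ValueError("mass and volume must be positive")
    return mass_g / volume_cm3


def volumetric_moisture(
    m_a: float, m_b: float, beta: float = WATER_DENSITY_G_CM3, volume_cm3: float = 1.0
) -> float:
    """Volumetric moisture fraction ``(m_A - m_B) / (beta * V)``."""
    if m_b <= 0:
        raise ValueError("initial mass must be positive")
    if m_a < m_b:
        raise ValueError(f"soaked mass {m_a} below initial mass {m_b}")
    if beta <= 0 or volume_cm3 <= 0:
        raise ValueError("water density and volume must be positive")
    return (m_a - m_b) / (beta * volume_cm3)


def mass_moisture(m_a: float, m_b: float) -> float:
    """Wet-basis mass moisture fraction ``(m_A - m_B) / m_A``."""
    if m_b <= 0:
        raise ValueError("initial mass must be positive")
    if m_a < m_b:
        raise ValueError(f"soaked mass {m_a} below initial mass {m_b}")
    return (m_a - m_b) / m_a


def _quadratic_fit(theta: np.ndarray, velocity: np.ndarray) -> FitResult:
    coef = np.polyfit(theta, velocity, 2)
    fitted = np.polyval(coef, theta)
    r = float(np.corrcoef(fitted, velocity)[0, 1])
    return FitResult(tuple(float(c) for c in coef), r, int(theta.size))


def immersion_analysis(
    records: Sequence[ImmersionRecord],
    beta: float = WATER_DENSITY_G_CM3,
) -> ImmersionAnalysis:
    """Derived quantities and velocity-moisture fits for an immersion series.

    Per timepoint: bulk density, wet-basis mass moisture and volumetric
    moisture (all from the mass series and the sample geometry). Per sample:
    a least-squares quadratic of measured velocity on volumetric moisture,
    scored by the Pearson correlation between fitted and observed velocities.
    Samples with fewer than 4 timepoints (or missing velocities) are excluded
    with a warning.
    """
    if not records:
        raise ValueError("no immersion records")
    rows = []
    fits: dict[str, FitResult] = {}
    by_sample: dict[str, list[ImmersionRecord]] = {}
    for rec in records:
        by_sample.setdefault(rec.sample_id, []).append(rec)

    for sample_id, recs in by_sample.items():
        recs = sorted(recs, key=lambda r: r.timepoint_h)
        times = [r.timepoint_h for r in recs]
        if len(set(times)) != len(times):
            raise ValueError(f"sample {sample_id}: duplicate timepoints")
        m0 = recs[0].mass_g
        volume = sample_volume(recs[0])
        for r in recs:
            rows.append(
                {
                    "sample_id": sample_id,
                    "timepoint_h": r.timepoint_h,
                    "mass_g": r.mass_g,
                    "density_g_cm3": bulk_density(r.mass_g, volume),
                    "mass_moisture": mass_moisture(r.mass_g, m0),
                    "volumetric_moisture": volumetric_moisture(r.mass_g, m0, beta, volume),
                    "velocity_m_s": r.velocity_m_s,
                }
            )
        have_velocity = [r for r in recs if r.velocity_m_s is not None]
        if len(have_velocity) < 4:
            warnings.warn(
                f"sample {sample_id}: {len(have_velocity)} velocity points, "
                "need >= 4 for a quadratic fit; excluded",
                stacklevel=2,
            )
            continue
        theta = np.array(
            [volumetric_moisture(r.mass_g, m0, beta, volume) for r in have_velocity]
        )
        velocity = np.array([r.velocity_m_s for r in have_velocity], dtype=float)
        fits[sample_id] = _quadratic_fit(theta, velocity)

    if not fits:
        raise ValueError("no sample had enough velocity points for a fit")
    mean_r = float(np.mean([f.correlation for f in fits.values()]))
    table = pd.DataFrame(rows).sort_values(["sample_id", "timepoint_h"]).reset_index(drop=True)
    return ImmersionAnalysis(table=table, fits=fits, mean_correlation=mean_r)


def track_correlation(
    pick_series: Sequence[tuple[float, float]],
    covariate_series: Sequence[tuple[float, float]],
    window: tuple[float, float] | None = None,
) -> float:
    """Pearson correlation between echo positions and a covariate over time.

    Series are sequences of ``(timestamp, value)``; pairs are aligned by
    exact timestamp match, optionally restricted to a closed time window.
    At least 3 aligned pairs with nonzero variance on both sides are needed.
    """
    picks = dict(pick_series)
    cov = dict(covariate_series)
    times = sorted(set(picks) & set(cov))
    if window is not None:
        lo, hi = window
        times = [t for t in times if lo <= t <= hi]
    if len(times) < 3:
        raise ValueError(f"no aligned points: need >= 3 shared timestamps, got {len(times)}")
    x = np.array([picks[t] for t in times], dtype=float)
    y = np.array([cov[t] for t in times], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: a series has zero variance")
    return float(stats.pearsonr(x, y).statistic)


def read_immersion_table(path: str | Path) -> list[ImmersionRecord]:
    """Read an immersion table (CSV, schema in :data:`IMMERSION_COLUMNS`)."""
    df = pd.read_csv(path, comment="#")
    missing = set(IMMERSION_COLUMNS) - {"dim3_cm", "velocity_m_s"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        shape = str(row["shape"]).strip()
        if shape == "cylinder":
            dims = (float(row["dim1_cm"]), float(row["dim2_cm"]))
        else:
            dims = (
                float(row["dim1_cm"]),
                float(row["dim2_cm"]),
                float(row.get("dim3_cm", np.nan)),
            )
        velocity = row.get("velocity_m_s")
        if velocity is not None and pd.isna(velocity):
            velocity = None
        try:
            records.append(
                ImmersionRecord(
                    sample_id=str(row["sample_id"]),
                    shape=shape,
                    dims_cm=dims,
                    timepoint_h=float(row["timepoint_h"]),
                    mass_g=float(row["mass_g"]),
                    velocity_m_s=None if velocity is None else float(velocity),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return records


def load_bundled_immersion() -> list[ImmersionRecord]:
    """The bundled three-cylinder immersion dataset (45 records)."""
    ref = resources.files("stemecho").joinpath("data/immersion_cylinders.csv")
    with resources.as_file(ref) as path:
        return read_immersion_table(path)
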