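"""Synthetic climate, yield, site-trial and regional fixtures.

Real regional runs require gridded climate, soil-survey and yield
statistics that are not shipped with the package.  These generators emulate
their statistical structure so every pipeline stage is testable offline:

* daily climate with a sinusoidal seasonal temperature cycle (southern
  hemisphere phase), Gaussian noise and rainfall from a two-state Markov
  occurrence chain with gamma-distributed amounts;
* annual wheat yields rising linearly to double the starting level over
  the simulated span, with multiplicative lognormal interannual noise;
* site trials simulated with the four-pool model itself, with sparse noisy
  observations, some degraded to 0-10 / 0-20 cm depths by the inverse
  depth coefficients so depth conversion is exactly invertible;
* five-region sets with the published wheat-belt areas and topsoil
  properties drawn within the published initial SOC density range.

All generators are pure functions of (spec, rng seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .evaluation import DEPTH_COEFFS, SiteTrial, SOCObservation
from .inputs import DEFAULT_RETENTION, CInputConfig, daily_input_series
from .pools import SIM_YEAR_DAYS, DecompositionParams, PoolState
from .regional import RegionInputs

CLIMATE_COLUMNS = (
    "date",
    "tmax_C",
    "tmin_C",
    "precip_mm",
    "radiation_MJ_m2",
    "rh_pct",
    "wind_m_s",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions emulated by the generators.

    Ranges mirror the study setting: annual mean temperature 16.8-21.4 °C
    and annual precipitation 467-685 mm across sites; initial topsoil SOC
    density 23-36 Mg C ha⁻¹; yields double over the 50-year span with
    substantial interannual variability (CV 0.25, typical of dryland wheat).
    """

    seed: int = 0
    n_years: int = 50
    start_year: int = 1960
    # climate
    mat_range_c: tuple[float, float] = (16.8, 21.4)
    precip_range_mm: tuple[float, float] = (467.0, 685.0)
    temp_amplitude_c: float = 7.0
    temp_noise_sd_c: float = 2.5
    diurnal_range_c: float = 11.0
    p_wet_after_dry: float = 0.25
    p_wet_after_wet: float = 0.55
    rain_gamma_shape: float = 0.8
    # yields
    yield_start_mg_ha: float = 1.0
    yield_cv: float = 0.25
    # soils and observations
    initial_soc_range: tuple[float, float] = (23.0, 36.0)
    soc_obs_cv: float = 0.05
    n_soil_cells: int = 25
    # regions (published wheat-belt areas)
    region_names: tuple[str, ...] = ("QLD", "NSW", "WA", "SA", "VIC")
    region_areas_mha: tuple[float, ...] = (0.86, 3.83, 5.28, 2.87, 2.24)

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise InputError("n_years must be >= 1")
        if not (0.0 <= self.yield_cv < 1.0) or not (0.0 <= self.soc_obs_cv < 1.0):
            raise InputError("CVs must lie in [0, 1)")
        if len(self.region_names) != len(self.region_areas_mha):
            raise InputError("region names and areas differ in length")


def _rng(spec: SyntheticSpec, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(spec.seed)


def gen_climate(
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    n_years: int | None = None,
    target_mat_c: float | None = None,
    target_precip_mm: float | None = None,
) -> pd.DataFrame:
    """Daily climate table (SILO-like columns) for ``n_years`` 365-day years.

    Expected annual mean temperature equals ``target_mat_c`` and expected
    annual rainfall equals ``target_precip_mm`` (defaults drawn uniformly
    from the spec ranges).
    """
    rng = _rng(spec, rng)
    ny = n_years if n_years is not None else spec.n_years
    if target_mat_c is None:
        target_mat_c = float(rng.uniform(*spec.mat_range_c))
    if target_precip_mm is None:
        target_precip_mm = float(rng.uniform(*spec.precip_range_mm))
    n = ny * SIM_YEAR_DAYS
    doy = np.arange(n) % SIM_YEAR_DAYS
    # southern-hemisphere phase: warmest in mid-January (doy ~ 15)
    seasonal = spec.temp_amplitude_c * np.cos(2 * np.pi * (doy - 15) / SIM_YEAR_DAYS)
    tmean = target_mat_c + seasonal
    if spec.temp_noise_sd_c > 0:
        tmean = tmean + rng.normal(0.0, spec.temp_noise_sd_c, n)
    tmax = tmean + spec.diurnal_range_c / 2.0
    tmin = tmean - spec.diurnal_range_c / 2.0

    # two-state occurrence chain with gamma amounts
    p01, p11 = spec.p_wet_after_dry, spec.p_wet_after_wet
    if p01 <= 0 and p11 <= 0:
        wet = np.zeros(n, dtype=bool)
    else:
        pi_wet = p01 / (1.0 + p01 - p11)  # stationary wet-day probability
        wet = np.empty(n, dtype=bool)
        draws = rng.random(n)
        state = draws[0] < pi_wet
        wet[0] = state
        for i in range(1, n):
            state = draws[i] < (p11 if state else p01)
            wet[i] = state
    precip = np.zeros(n)
    n_wet = int(wet.sum())
    if n_wet > 0:
        pi_wet = max(p01 / (1.0 + p01 - p11), 1e-12)
        mean_amount = target_precip_mm / (SIM_YEAR_DAYS * pi_wet)
        scale = mean_amount / spec.rain_gamma_shape
        precip[wet] = rng.gamma(spec.rain_gamma_shape, scale, n_wet)

    radiation = np.clip(
        22.0 + 7.0 * np.cos(2 * np.pi * (doy - 15) / SIM_YEAR_DAYS)
        - 6.0 * wet
        + rng.normal(0.0, 2.0, n),
        1.0,
        None,
    )
    rh = np.clip(45.0 + 25.0 * wet + rng.normal(0.0, 8.0, n), 5.0, 100.0)
    wind = np.clip(rng.gamma(2.0, 1.6, n), 0.0, None)

    years = spec.start_year + (np.arange(n) // SIM_YEAR_DAYS)
    dates = [f"{y}-{d + 1:03d}" for y, d in zip(years, doy)]  # year-dayofyear
    return pd.DataFrame(
        {
            "date": dates,
            "tmax_C": tmax,
            "tmin_C": tmin,
            "precip_mm": precip,
            "radiation_MJ_m2": radiation,
            "rh_pct": rh,
            "wind_m_s": wind,
        }
    )


def gen_yields(
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    n_years: int | None = None,
    start_level: float | None = None,
) -> np.ndarray:
    """Annual yields: linear trend doubling across the span, lognormal noise.

    The noise is mean-corrected so the expectation of each year's yield
    equals the trend value; with CV 0 the series is the trend itself, so
    final/initial = 2 exactly.
    """
    rng = _rng(spec, rng)
    ny = n_years if n_years is not None else spec.n_years
    y0 = start_level if start_level is not None else spec.yield_start_mg_ha
    trend = np.linspace(y0, 2.0 * y0, ny)
    if spec.yield_cv == 0:
        return trend
    sigma = np.sqrt(np.log1p(spec.yield_cv**2))
    noise = rng.lognormal(-0.5 * sigma**2, sigma, ny)  # E[noise] = 1
    return np.clip(trend * noise, 0.0, None)


def gen_site_trial(
    spec: SyntheticSpec,
    true_params: DecompositionParams | None = None,
    rng: np.random.Generator | None = None,
    name: str = "site",
    n_years: int = 25,
    obs_interval: int = 3,
    retention: float = 0.95,
    depths: tuple[str, ...] = ("0-30", "0-10", "0-20"),
    cinput_cfg: CInputConfig | None = None,
) -> SiteTrial:
    """Site trial with known generating parameters, for recovery tests.

    The true SOC trajectory is simulated with the four-pool model from a
    0.25/0.75 light/heavy split of a random initial density; observations
    every ``obs_interval`` years get multiplicative Gaussian noise
    (``spec.soc_obs_cv``) and cycle through the given measurement depths,
    depth-degraded by dividing the 0-30 cm truth by the conversion
    coefficient (so conversion back is exact at CV 0).
    """
    from .evaluation import simulate_trial  # local import to avoid cycle

    rng = _rng(spec, rng)
    params = true_params or DecompositionParams.modified()
    cfg = cinput_cfg or CInputConfig()
    initial_total = float(rng.uniform(*spec.initial_soc_range))
    initial_state = PoolState.from_total(initial_total)
    yields = gen_yields(spec, rng, n_years=n_years)
    u = daily_input_series(yields, cfg, retention)
    trial = SiteTrial(
        name=name,
        initial_state=initial_state,
        f_env=np.ones(n_years * SIM_YEAR_DAYS),
        input_labile=u[:, 0],
        input_resistant=u[:, 1],
        observations=[],
        true_params=params,
    )
    truth = simulate_trial(trial, params)
    obs_years = list(range(0, n_years + 1, obs_interval))
    observations = []
    for i, year in enumerate(obs_years):
        depth = depths[i % len(depths)]
        value = truth[year] / DEPTH_COEFFS[depth]
        if spec.soc_obs_cv > 0:
            value *= max(1.0 + spec.soc_obs_cv * rng.standard_normal(), 0.0)
        observations.append(SOCObservation(year=year, value=float(value), depth=depth))
    trial.observations = observations
    return trial


def gen_region_set(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> list[RegionInputs]:
    """Five synthetic regions emulating the wheat-belt states.

    Areas default to the published values (summing to 15.08 Mha); each
    region gets its own climate target, a soil grid with SOC densities
    drawn within the configured initial range, a yield series and the
    default retention fraction for its name.
    """
    rng = _rng(spec, rng)
    regions = []
    for name, area in zip(spec.region_names, spec.region_areas_mha):
        climate = gen_climate(spec, rng)
        n = spec.n_soil_cells
        clay = rng.uniform(0.10, 0.40, n)
        grid = pd.DataFrame(
            {
                "cell_id": np.arange(n),
                "soc_Mg_ha": rng.uniform(*spec.initial_soc_range, n),
                "total_n_g_kg": rng.uniform(0.8, 1.6, n),
                "clay_frac": clay,
                "sand_frac": rng.uniform(0.3, 0.9 - clay),
                "ph": rng.uniform(5.5, 8.5, n),
                "bulk_density_g_cm3": rng.uniform(1.2, 1.6, n),
            }
        )
        yields = gen_yields(spec, rng)
        retention = DEFAULT_RETENTION.get(name, 0.705)
        regions.append(
            RegionInputs(
                name=name,
                area_mha=area,
                soil_grid=grid,
                yields=yields,
                retention=retention,
                climate=climate,
            )
        )
    return regions
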