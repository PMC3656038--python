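"""Four-pool first-order soil organic carbon turnover model.

The model tracks four carbon pools in the 0-30 cm soil layer, all in
Mg C ha⁻¹:

* ``labile`` and ``resistant`` -- fast and slow fractions of fresh organic
  inputs (crop residue and roots);
* ``light`` -- biologically reactive soil organic carbon with a turnover of
  a few years;
* ``heavy`` -- decomposition-resistant soil organic carbon persisting for
  decades to centuries.

Each pool decomposes by first-order kinetics at a daily time step.  Carbon
flows follow three rules: a fraction of decomposed labile and resistant C
enters the light pool, a fraction of decomposed light C enters the heavy
pool, and decomposed heavy C leaves entirely as CO₂.  Reported "SOC
density" is the total over all four pools.

The daily operator is linear in the state, which gives closed forms for
steady states and makes a matrix-power oracle available for testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import (
    InputError,
    NoSteadyStateError,
    NumericError,
    ParameterError,
    StateError,
)

#: Days per year used for all rate <-> half-life conversions.  This value
#: (and only this value) reproduces the three published half-lives
#: (7.6, 73 and 105.4 y) from their rate constants on rounding.
DAYS_PER_YEAR = 365.25

#: Calendar length of one simulated year (no leap days).
SIM_YEAR_DAYS = 365

#: Half-life residence times (years) of the fresh-residue pools.
HALF_LIFE_LABILE_Y = 0.1
HALF_LIFE_RESISTANT_Y = 2.3

POOL_NAMES = ("labile", "resistant", "light", "heavy")


def half_life_years(k: float) -> float:
    """Half-life residence time (years) of a first-order pool.

    Parameters
    ----------
    k : decomposition rate constant in d⁻¹; must be positive.
    """
    if not (k > 0) or not math.isfinite(k):
        raise ParameterError(f"rate constant must be positive and finite, got {k!r}")
    return math.log(2.0) / (k * DAYS_PER_YEAR)


def rate_from_half_life(t_half_years: float) -> float:
    """Rate constant (d⁻¹) from a half-life residence time in years."""
    if not (t_half_years > 0) or not math.isfinite(t_half_years):
        raise ParameterError(
            f"half-life must be positive and finite, got {t_half_years!r}"
        )
    return math.log(2.0) / (t_half_years * DAYS_PER_YEAR)


@dataclass(frozen=True)
class PoolState:
    """Carbon densities of the four pools (Mg C ha⁻¹)."""

    labile: float = 0.0
    resistant: float = 0.0
    light: float = 0.0
    heavy: float = 0.0

    def __post_init__(self) -> None:
        for name in POOL_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise StateError(f"pool {name!r} is not finite: {v!r}")
            if v < 0:
                raise StateError(f"pool {name!r} is negative: {v!r}")

    def total(self) -> float:
        """Total SOC density, the sum of all four pools."""
        return self.labile + self.resistant + self.light + self.heavy

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.labile, self.resistant, self.light, self.heavy], dtype=float
        )

    @classmethod
    def from_array(cls, x: np.ndarray) -> "PoolState":
        x = np.asarray(x, dtype=float)
        if x.shape != (4,):
            raise StateError(f"expected shape (4,), got {x.shape}")
        # Clip tiny negative round-off; genuine negatives still raise.
        x = np.where((x < 0) & (x > -1e-12), 0.0, x)
        return cls(*(float(v) for v in x))

    @classmethod
    def from_total(cls, total: float, light_fraction: float = 0.25) -> "PoolState":
        """State with ``total`` split between light and heavy SOC only.

        The conventional initialisation assigns 25% of measured SOC to the
        light pool and 75% to the heavy pool, with empty residue pools.
        """
        if not (total >= 0):
            raise StateError(f"total SOC must be non-negative, got {total!r}")
        if not (0.0 <= light_fraction <= 1.0):
            raise ParameterError(f"light_fraction outside [0, 1]: {light_fraction!r}")
        return cls(0.0, 0.0, light_fraction * total, (1.0 - light_fraction) * total)


@dataclass(frozen=True)
class DecompositionParams:
    """Rate constants (d⁻¹) and transfer fractions of the four-pool model.

    ``f_labile_light`` / ``f_resistant_light`` are the fractions of
    decomposed labile / resistant C entering the light pool;
    ``f_light_heavy`` is the fraction of decomposed light C entering the
    heavy pool.  The complements are released as CO₂, as is all decomposed
    heavy C.
    """

    k_labile: float = field(default_factory=lambda: rate_from_half_life(HALF_LIFE_LABILE_Y))
    k_resistant: float = field(
        default_factory=lambda: rate_from_half_life(HALF_LIFE_RESISTANT_Y)
    )
    k_light: float = 2.5e-4
    k_heavy: float = 2.6e-5
    f_labile_light: float = 0.30
    f_resistant_light: float = 0.45
    f_light_heavy: float = 0.30

    def __post_init__(self) -> None:
        for name in ("k_labile", "k_resistant", "k_light", "k_heavy"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ParameterError(f"{name} must be positive and finite, got {v!r}")
        for name in ("f_labile_light", "f_resistant_light", "f_light_heavy"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} outside [0, 1]: {v!r}")

    @classmethod
    def modified(cls) -> "DecompositionParams":
        """Calibrated parameter set (default): heavy-C half-life 73 y, F_LH 0.3."""
        return cls()

    @classmethod
    def original(cls) -> "DecompositionParams":
        """Pre-calibration parameter set: heavy-C half-life 105.4 y, F_LH 0.45."""
        return cls(k_heavy=1.8e-5, f_light_heavy=0.45)

    def rates(self) -> np.ndarray:
        """Rate constants as an array in pool order."""
        return np.array(
            [self.k_labile, self.k_resistant, self.k_light, self.k_heavy], dtype=float
        )

    def replace(self, **kwargs) -> "DecompositionParams":
        return replace(self, **kwargs)

    def transfer_matrix(self, f_env: float = 1.0) -> np.ndarray:
        """One-day linear operator ``A`` such that ``x' = A x`` (no inputs).

        Row/column order follows :data:`POOL_NAMES`.  ``f_env`` is the
        environmental rate modifier applied multiplicatively to every rate.
        """
        if f_env < 0:
            raise ParameterError(f"f_env must be >= 0, got {f_env!r}")
        a = 1.0 - np.exp(-self.rates() * f_env)  # decomposed fraction per pool
        A = np.diag(1.0 - a)
        A[2, 0] = self.f_labile_light * a[0]
        A[2, 1] = self.f_resistant_light * a[1]
        A[3, 2] = self.f_light_heavy * a[2]
        return A


@dataclass(frozen=True)
class DailyFlux:
    """Carbon entering (fresh input) and leaving (CO₂) the soil in one day."""

    input_c: float
    co2_c: float

    def __post_init__(self) -> None:
        if self.input_c < 0 or self.co2_c < 0:
            raise StateError("daily fluxes must be non-negative")


# ---------------------------------------------------------------------------
# Environmental rate modifier
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnvModifierConfig:
    """Environmental control of decomposition rates.

    In ``neutral`` mode the modifier is identically 1 and the tabulated rate
    constants apply as-is.  In ``climate`` mode the modifier is the product
    of a Q10 temperature response (normalised to 1 at ``t_ref_c``) and a
    linear soil-moisture response (1 at saturation), both non-decreasing.
    Soil moisture is proxied by a single exponential-decay bucket driven by
    daily precipitation.
    """

    mode: str = "neutral"  # "neutral" | "climate"
    q10: float = 2.0
    t_ref_c: float = 25.0
    moisture_capacity_mm: float = 60.0
    moisture_retention: float = 0.9
    f_moisture_min: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in ("neutral", "climate"):
            raise ParameterError(f"unknown env-modifier mode {self.mode!r}")
        if self.q10 <= 0 or self.moisture_capacity_mm <= 0:
            raise ParameterError("q10 and moisture capacity must be positive")
        if not (0.0 <= self.moisture_retention < 1.0):
            raise ParameterError("moisture_retention outside [0, 1)")
        if not (0.0 <= self.f_moisture_min <= 1.0):
            raise ParameterError("f_moisture_min outside [0, 1]")


def env_modifier(tmean_c, moisture_fraction, config: EnvModifierConfig | None = None):
    """Daily decomposition-rate multiplier f_T · f_W.

    ``moisture_fraction`` is relative soil water content in [0, 1].  At the
    reference temperature with saturated moisture the modifier equals 1
    exactly; in neutral mode it is 1 regardless of climate.
    """
    cfg = config or EnvModifierConfig()
    t = np.asarray(tmean_c, dtype=float)
    if cfg.mode == "neutral":
        return np.ones_like(t) if t.ndim else 1.0
    f_t = cfg.q10 ** ((t - cfg.t_ref_c) / 10.0)
    f_w = np.clip(np.asarray(moisture_fraction, dtype=float), cfg.f_moisture_min, 1.0)
    out = f_t * f_w
    return out if out.ndim else float(out)


def env_series(climate, config: EnvModifierConfig | None = None) -> np.ndarray:
    """Daily modifier series from a climate table.

    ``climate`` is a DataFrame with at least ``tmax_C``, ``tmin_C`` and
    ``precip_mm`` columns.  Neutral mode returns an all-ones series.
    """
    cfg = config or EnvModifierConfig()
    n = len(climate)
    if cfg.mode == "neutral":
        return np.ones(n)
    tmean = (np.asarray(climate["tmax_C"], float) + np.asarray(climate["tmin_C"], float)) / 2.0
    precip = np.asarray(climate["precip_mm"], float)
    # one-bucket water balance: carry-over fraction r, capped at capacity
    w = np.empty(n)
    level = cfg.moisture_capacity_mm / 2.0
    for i in range(n):
        level = min(
            cfg.moisture_capacity_mm, cfg.moisture_retention * level + precip[i]
        )
        w[i] = level
    return np.asarray(env_modifier(tmean, w / cfg.moisture_capacity_mm, cfg))


# ---------------------------------------------------------------------------
# Daily update and trajectory engine
# ---------------------------------------------------------------------------


def step_day(
    state: PoolState,
    params: DecompositionParams,
    f_env: float = 1.0,
    input_labile: float = 0.0,
    input_resistant: float = 0.0,
) -> tuple[PoolState, DailyFlux]:
    """Advance the pool state by one day.

    Order of operations: fresh inputs are added to the labile/resistant
    pools, then each pool decomposes by ``1 - exp(-K·f_env)`` and the
    decomposed carbon is routed by the transfer fractions; the remainder is
    CO₂.  Mass balance (Δtotal = input − CO₂) holds to round-off.
    """
    if not math.isfinite(f_env) or f_env < 0:
        raise ParameterError(f"f_env must be finite and >= 0, got {f_env!r}")
    if input_labile < 0 or input_resistant < 0:
        raise InputError("carbon inputs must be non-negative")
    x = state.as_array()
    if not np.all(np.isfinite(x)):
        raise StateError("state contains non-finite values")
    x[0] += input_labile
    x[1] += input_resistant
    a = 1.0 - np.exp(-params.rates() * f_env)
    d = x * a
    x = x - d
    transfer_light = params.f_labile_light * d[0] + params.f_resistant_light * d[1]
    transfer_heavy = params.f_light_heavy * d[2]
    x[2] += transfer_light
    x[3] += transfer_heavy
    co2 = float(d.sum() - transfer_light - transfer_heavy)
    return PoolState.from_array(x), DailyFlux(input_labile + input_resistant, co2)


def _simulate(
    x0: np.ndarray,
    rates: np.ndarray,
    f_ll,
    f_rl,
    f_lh,
    f_env: np.ndarray,
    inputs: np.ndarray,
    scale: np.ndarray | None = None,
):
    """Batched daily simulation (internal engine).

    Parameters
    ----------
    x0 : (m, 4) initial states (copied).
    rates : (4,) shared or (m, 4) per-batch rate constants.
    f_ll, f_rl, f_lh : scalars or (m,) transfer fractions.
    f_env : (n_days,) environmental modifier series.
    inputs : (n_days, 2) daily labile/resistant inputs shared by the batch.
    scale : optional (m,) multiplier applied to the input series per batch
        element (Monte Carlo carbon-input scaling).

    Returns
    -------
    soc : (m, n_years + 1) pool totals at the start of each simulated year
        (365-day years) including day 0 and the final day.
    co2_annual : (m, n_years) CO₂ efflux summed within each year.
    x : (m, 4) final states.
    totals : (input_total, co2_total), each (m,), exact running sums for
        mass-balance checks.
    """
    x = np.array(x0, dtype=float)
    m = x.shape[0]
    f_env = np.asarray(f_env, dtype=float)
    u = np.asarray(inputs, dtype=float)
    n_days = len(f_env)
    if u.shape[0] < n_days:
        raise InputError(
            f"input series length {u.shape[0]} shorter than env series {n_days}"
        )
    n_years = n_days // SIM_YEAR_DAYS
    rates = np.asarray(rates, dtype=float)
    batched_rates = rates.ndim == 2

    const_env = n_days > 0 and np.all(f_env == f_env[0])
    if not batched_rates:
        # (n_days, 4) decomposed-fraction table, shared across the batch
        a_table = 1.0 - np.exp(-np.outer(f_env, rates))
    elif const_env and n_days > 0:
        a_const = 1.0 - np.exp(-rates * f_env[0])

    if scale is not None:
        scale = np.asarray(scale, dtype=float)

    soc = np.empty((m, n_years + 1))
    co2_annual = np.zeros((m, n_years))
    soc[:, 0] = x.sum(axis=1)
    co2_year = np.zeros(m)
    co2_total = np.zeros(m)
    input_total = np.zeros(m)

    year = 0
    for t in range(n_days):
        if scale is None:
            x[:, 0] += u[t, 0]
            x[:, 1] += u[t, 1]
            input_total += u[t, 0] + u[t, 1]
        else:
            x[:, 0] += u[t, 0] * scale
            x[:, 1] += u[t, 1] * scale
            input_total += (u[t, 0] + u[t, 1]) * scale
        if batched_rates:
            a = a_const if const_env else 1.0 - np.exp(-rates * f_env[t])
        else:
            a = a_table[t]
        d = x * a
        x -= d
        tl = f_ll * d[:, 0] + f_rl * d[:, 1]
        th = f_lh * d[:, 2]
        x[:, 2] += tl
        x[:, 3] += th
        co2 = d.sum(axis=1) - tl - th
        co2_year += co2
        co2_total += co2
        if (t + 1) % SIM_YEAR_DAYS == 0:
            year += 1
            soc[:, year] = x.sum(axis=1)
            co2_annual[:, year - 1] = co2_year
            co2_year[:] = 0.0
    if n_days % SIM_YEAR_DAYS != 0:
        # partial final year: record the final state in the last slot
        soc = np.concatenate([soc, x.sum(axis=1)[:, None]], axis=1)
    return soc, co2_annual, x, (input_total, co2_total)


@dataclass(frozen=True)
class TrajectoryResult:
    """Annual output of a daily simulation."""

    annual_soc: np.ndarray  # (n_years + 1,) pool totals at year boundaries
    annual_co2: np.ndarray  # (n_years,) CO₂ summed within each year
    final_state: PoolState
    total_input: float
    total_co2: float


def _coerce_inputs(inputs, n_days: int) -> np.ndarray:
    """Accept (n, 2) array or (labile, resistant) pair of daily series."""
    if isinstance(inputs, tuple) and len(inputs) == 2:
        u = np.column_stack(
            [np.asarray(inputs[0], float), np.asarray(inputs[1], float)]
        )
    else:
        u = np.asarray(inputs, dtype=float)
        if u.ndim != 2 or u.shape[1] != 2:
            raise InputError(f"inputs must have shape (n_days, 2), got {u.shape}")
    if u.shape[0] < n_days:
        raise InputError(
            f"input series covers {u.shape[0]} days, need at least {n_days}"
        )
    if np.any(u < 0):
        raise InputError("carbon inputs must be non-negative")
    return u


def run_trajectory(
    initial: PoolState,
    params: DecompositionParams,
    f_env,
    inputs,
    n_days: int | None = None,
) -> TrajectoryResult:
    """Run the daily model and return annual SOC / CO₂ series.

    ``f_env`` is a daily modifier series (or scalar, broadcast); ``inputs``
    is an ``(n_days, 2)`` array of daily labile/resistant inputs or a pair
    of series.  Cumulative mass balance Σinput − ΣCO₂ = ΔSOC holds to
    round-off and is asserted by the test suite.
    """
    f = np.asarray(f_env, dtype=float)
    if f.ndim == 0:
        if n_days is None:
            raise InputError("n_days required when f_env is scalar")
        f = np.full(n_days, float(f))
    if n_days is None:
        n_days = len(f)
    if len(f) < n_days:
        raise InputError(f"env series covers {len(f)} days, need {n_days}")
    f = f[:n_days]
    if np.any(f < 0) or not np.all(np.isfinite(f)):
        raise ParameterError("f_env series must be finite and >= 0")
    u = _coerce_inputs(inputs, n_days)[:n_days]
    soc, co2_annual, x, (inp_tot, co2_tot) = _simulate(
        initial.as_array()[None, :],
        params.rates(),
        params.f_labile_light,
        params.f_resistant_light,
        params.f_light_heavy,
        f,
        u,
    )
    return TrajectoryResult(
        annual_soc=soc[0],
        annual_co2=co2_annual[0],
        final_state=PoolState.from_array(x[0]),
        total_input=float(inp_tot[0]),
        total_co2=float(co2_tot[0]),
    )


def _cycle(series: np.ndarray, n: int) -> np.ndarray:
    """Repeat a series cyclically to length ``n`` (row-wise for 2-D)."""
    arr = np.asarray(series, dtype=float)
    if arr.shape[0] == 0:
        raise InputError("cannot cycle an empty series")
    reps = int(np.ceil(n / arr.shape[0]))
    return np.concatenate([arr] * reps, axis=0)[:n]


def spin_up(
    total_soc_start: float,
    params: DecompositionParams,
    f_env_series,
    input_series,
    n_years: int = 100,
    light_fraction: float = 0.25,
) -> PoolState:
    """Pre-simulation equilibration of pool proportions.

    Starts from the conventional light/heavy split (default 0.25/0.75) of
    ``total_soc_start``, runs ``n_years`` of the daily model with the
    forcing series recycled cyclically, then rescales all pools by a common
    factor so the total matches ``total_soc_start`` again.  Only the pool
    *proportions* produced by the spin-up are retained.
    """
    if not (total_soc_start > 0):
        raise InputError(f"total SOC must be positive, got {total_soc_start!r}")
    if n_years < 0:
        raise InputError(f"n_years must be >= 0, got {n_years}")
    x0 = PoolState.from_total(total_soc_start, light_fraction)
    if n_years == 0:
        return x0
    n_days = n_years * SIM_YEAR_DAYS
    f = _cycle(np.atleast_1d(np.asarray(f_env_series, float)), n_days)
    u = _cycle(_coerce_inputs(input_series, 1), n_days)
    _, _, x, _ = _simulate(
        x0.as_array()[None, :],
        params.rates(),
        params.f_labile_light,
        params.f_resistant_light,
        params.f_light_heavy,
        f,
        u,
    )
    final = x[0]
    tot = final.sum()
    if tot <= 0:
        raise NumericError("spin-up collapsed to zero total SOC")
    return PoolState.from_array(final * (total_soc_start / tot))


def steady_state(
    params: DecompositionParams,
    f_env: float,
    input_labile: float,
    input_resistant: float,
) -> PoolState:
    """Fixed point of the daily map under constant forcing.

    Solves ``(I − A) x = A u`` where ``A`` is the one-day transfer matrix
    and ``u`` the daily input vector.  The steady state is linear in the
    inputs.  With zero inputs the fixed point is the empty state; with
    positive inputs and ``f_env ≤ 0`` no steady state exists.
    """
    if input_labile < 0 or input_resistant < 0:
        raise InputError("inputs must be non-negative")
    if input_labile == 0 and input_resistant == 0:
        return PoolState()
    if f_env <= 0:
        raise NoSteadyStateError(
            "positive input with f_env <= 0 accumulates without bound"
        )
    A = params.transfer_matrix(f_env)
    u = np.array([input_labile, input_resistant, 0.0, 0.0])
    x = np.linalg.solve(np.eye(4) - A, A @ u)
    return PoolState.from_array(x)


def required_extra_input(
    current: PoolState,
    params: DecompositionParams,
    f_env_series,
    input_series,
    horizon_years: int,
    split_labile: float = 0.59,
    tol: float = 1e-3,
    max_extra: float = 64.0,
) -> float:
    """Smallest additional annual C input that halts SOC decline.

    Finds, by bisection to ``tol`` (Mg C ha⁻¹ yr⁻¹), the minimum extra
    annual input — spread uniformly over each year and split between the
    labile/resistant pools by ``split_labile`` — such that total SOC after
    ``horizon_years`` is at least the starting value.  Returns 0 when the
    baseline trajectory is already non-decreasing over the horizon.
    """
    if horizon_years < 1:
        raise InputError(f"horizon_years must be >= 1, got {horizon_years}")
    if not (0.0 <= split_labile <= 1.0):
        raise ParameterError(f"split_labile outside [0, 1]: {split_labile!r}")
    n_days = horizon_years * SIM_YEAR_DAYS
    f = _cycle(np.atleast_1d(np.asarray(f_env_series, float)), n_days)
    u = _cycle(_coerce_inputs(input_series, 1), n_days)
    start = current.total()
    x0 = current.as_array()[None, :]

    def end_total(extra_annual: float) -> float:
        daily = extra_annual / SIM_YEAR_DAYS
        ue = u + np.array([split_labile * daily, (1.0 - split_labile) * daily])
        _, _, x, _ = _simulate(
            x0,
            params.rates(),
            params.f_labile_light,
            params.f_resistant_light,
            params.f_light_heavy,
            f,
            ue,
        )
        return float(x[0].sum())

    if end_total(0.0) >= start:
        return 0.0
    lo, hi = 0.0, 0.5
    while end_total(hi) < start:
        lo = hi
        hi *= 2.0
        if hi > max_extra:
            raise NumericError(
                f"no extra input below {max_extra} Mg C ha⁻¹ yr⁻¹ halts the decline"
            )
    from scipy.optimize import brentq

    root = brentq(lambda e: end_total(e) - start, lo, hi, xtol=tol)
    return float(max(root, 0.0))
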