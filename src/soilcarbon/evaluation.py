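"""Model evaluation statistics, depth harmonisation and grid-search calibration.

SOC observations reported only for the top 10 or 20 cm are converted to the
0-30 cm layer with fixed coefficients from the cumulative vertical SOC
distribution (×2.35 for 0-10 cm, ×1.32 for 0-20 cm).

Model skill is summarised by the root mean squared error (RMSE), the
relative mean deviation (RMD, %), the model efficiency (EF; 1 = perfect,
0 = no better than the observed mean) and an OLS regression of predictions
on observations with t-tests of slope = 1 and intercept = 0.

Calibration is an exhaustive search over a Cartesian grid of the five key
parameters (light/heavy rate constants and the three transfer fractions),
minimising the absolute mean deviation pooled over all observations of all
site trials.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ParameterError, UndefinedStatisticError
from .pools import (
    SIM_YEAR_DAYS,
    DecompositionParams,
    PoolState,
    _simulate,
)

#: Multiplicative conversion of a measured SOC density to the 0-30 cm layer.
DEPTH_COEFFS = {"0-30": 1.0, "0-20": 1.32, "0-10": 2.35}

#: Canonical ordering of the five calibrated parameters (used for grid
#: iteration and deterministic lexicographic tie-breaking).
CALIBRATED_PARAMS = (
    "k_light",
    "k_heavy",
    "f_labile_light",
    "f_resistant_light",
    "f_light_heavy",
)


@dataclass(frozen=True)
class SOCObservation:
    """One SOC density measurement at a site.

    ``year`` is the observation year as an index into the trial's annual
    SOC series (0 = trial start); ``depth`` is the sampled layer.
    """

    year: int
    value: float
    depth: str = "0-30"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise InputError(f"SOC observation negative: {self.value!r}")
        if self.depth not in DEPTH_COEFFS:
            raise InputError(
                f"depth {self.depth!r} not one of {sorted(DEPTH_COEFFS)}"
            )


def soc_to_30cm(value: float, depth: str = "0-30") -> float:
    """Convert a measured SOC density to the 0-30 cm layer."""
    if value < 0:
        raise InputError(f"SOC value must be non-negative, got {value!r}")
    try:
        coeff = DEPTH_COEFFS[depth]
    except KeyError:
        raise InputError(f"unsupported depth {depth!r}") from None
    return value * coeff


def observation_to_30cm(obs: SOCObservation) -> float:
    return soc_to_30cm(obs.value, obs.depth)


# ---------------------------------------------------------------------------
# Evaluation statistics
# ---------------------------------------------------------------------------


def _paired(P, O):
    P = np.asarray(P, dtype=float)
    O = np.asarray(O, dtype=float)
    if P.shape != O.shape or P.ndim != 1:
        raise InputError(f"P and O must be equal-length 1-D series, got {P.shape} vs {O.shape}")
    if P.size == 0:
        raise InputError("empty series")
    return P, O


def mean_deviation(P, O) -> float:
    """Mean of P − O (Mg C ha⁻¹); the calibration objective is |mean deviation|."""
    P, O = _paired(P, O)
    return float(np.mean(P - O))


def rmse(P, O, normalized: bool = False) -> float:
    """Root mean squared error; ``normalized`` returns 100·RMSE/Ō (%)."""
    P, O = _paired(P, O)
    value = float(np.sqrt(np.mean((P - O) ** 2)))
    if normalized:
        obar = float(np.mean(O))
        if obar == 0:
            raise UndefinedStatisticError("normalized RMSE undefined for Ō = 0")
        value = 100.0 * value / obar
    return value


def rmd(P, O) -> float:
    """Relative mean deviation (%): 100·Σ(Pᵢ−Oᵢ)/(n·Ō)."""
    P, O = _paired(P, O)
    obar = float(np.mean(O))
    if obar == 0:
        raise UndefinedStatisticError("RMD undefined for Ō = 0")
    return 100.0 * float(np.mean(P - O)) / obar


def model_efficiency(P, O) -> float:
    """Model efficiency EF = 1 − Σ(Oᵢ−Pᵢ)²/Σ(Oᵢ−Ō)²; EF ≤ 1, = 1 iff P = O."""
    P, O = _paired(P, O)
    if P.size < 2:
        raise UndefinedStatisticError("EF needs at least two observations")
    denom = float(np.sum((O - O.mean()) ** 2))
    if denom == 0:
        raise UndefinedStatisticError("EF undefined for constant observations")
    return 1.0 - float(np.sum((O - P) ** 2)) / denom


@dataclass(frozen=True)
class RegressionResult:
    """OLS of predictions on observations with tests against the 1:1 line."""

    slope: float
    intercept: float
    r_squared: float
    p_slope_vs_1: float
    p_intercept_vs_0: float
    n: int
    alpha: float = 0.05

    @property
    def slope_differs_from_1(self) -> bool:
        return self.p_slope_vs_1 < self.alpha

    @property
    def intercept_differs_from_0(self) -> bool:
        return self.p_intercept_vs_0 < self.alpha


def regression_eval(P, O, alpha: float = 0.05) -> RegressionResult:
    """Regress P on O and test slope = 1 and intercept = 0 (two-sided t)."""
    P, O = _paired(P, O)
    n = P.size
    if n < 3:
        raise InputError(f"regression needs n >= 3, got {n}")
    if np.ptp(O) == 0:
        raise UndefinedStatisticError("regression undefined for constant O")
    res = stats.linregress(O, P)
    df = n - 2
    if res.stderr > 0:
        p_slope = 2.0 * stats.t.sf(abs((res.slope - 1.0) / res.stderr), df)
    else:
        p_slope = 1.0 if res.slope == 1.0 else 0.0
    if res.intercept_stderr > 0:
        t_int = res.intercept / res.intercept_stderr
        p_int = 2.0 * stats.t.sf(abs(t_int), df)
    else:
        p_int = 0.0 if res.intercept != 0 else 1.0
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_slope_vs_1=float(p_slope),
        p_intercept_vs_0=float(p_int),
        n=int(n),
        alpha=alpha,
    )


@dataclass(frozen=True)
class EvalStats:
    """Bundle of the evaluation statistics for one P/O comparison."""

    rmse: float
    rmd: float
    ef: float
    slope: float
    intercept: float
    r_squared: float
    n: int


def evaluate(P, O) -> EvalStats:
    reg = regression_eval(P, O)
    return EvalStats(
        rmse=rmse(P, O),
        rmd=rmd(P, O),
        ef=model_efficiency(P, O),
        slope=reg.slope,
        intercept=reg.intercept,
        r_squared=reg.r_squared,
        n=reg.n,
    )


# ---------------------------------------------------------------------------
# Site trials and calibration
# ---------------------------------------------------------------------------


@dataclass
class SiteTrial:
    """One long-term experiment prepared for simulation.

    Forcing is stored as daily series; observations index the annual SOC
    series produced by the model (year 0 = initial state).
    """

    name: str
    initial_state: PoolState
    f_env: np.ndarray  # (n_days,)
    input_labile: np.ndarray  # (n_days,)
    input_resistant: np.ndarray  # (n_days,)
    observations: list[SOCObservation] = field(default_factory=list)
    true_params: DecompositionParams | None = None

    def __post_init__(self) -> None:
        n = len(self.f_env)
        if len(self.input_labile) != n or len(self.input_resistant) != n:
            raise InputError("forcing series lengths differ")
        n_years = n // SIM_YEAR_DAYS
        for obs in self.observations:
            if not (0 <= obs.year <= n_years):
                raise InputError(
                    f"observation year {obs.year} outside trial span 0..{n_years}"
                )

    @property
    def n_days(self) -> int:
        return len(self.f_env)

    @property
    def n_years(self) -> int:
        return self.n_days // SIM_YEAR_DAYS

    def observed_30cm(self) -> np.ndarray:
        return np.array([observation_to_30cm(o) for o in self.observations])

    def observation_years(self) -> np.ndarray:
        return np.array([o.year for o in self.observations], dtype=int)


def simulate_trial(trial: SiteTrial, params: DecompositionParams) -> np.ndarray:
    """Annual SOC series (length n_years + 1) for one trial."""
    u = np.column_stack([trial.input_labile, trial.input_resistant])
    soc, _, _, _ = _simulate(
        trial.initial_state.as_array()[None, :],
        params.rates(),
        params.f_labile_light,
        params.f_resistant_light,
        params.f_light_heavy,
        trial.f_env,
        u,
    )
    return soc[0]


def predicted_observations(trial: SiteTrial, params: DecompositionParams) -> np.ndarray:
    """Model predictions at the trial's observation years (0-30 cm)."""
    return simulate_trial(trial, params)[trial.observation_years()]


@dataclass(frozen=True)
class SearchSpec:
    """Grid definition for calibration.

    ``ranges`` maps a parameter name (one of :data:`CALIBRATED_PARAMS`) to
    ``(lo, hi, n_steps)``; parameters not listed stay at their base values.
    """

    ranges: dict[str, tuple[float, float, int]]

    def __post_init__(self) -> None:
        for name, (lo, hi, n) in self.ranges.items():
            if name not in CALIBRATED_PARAMS:
                raise ParameterError(
                    f"{name!r} is not calibrated; choose from {CALIBRATED_PARAMS}"
                )
            if n < 1:
                raise ParameterError(f"{name}: steps must be >= 1, got {n}")
            if n > 1 and not (hi > lo):
                raise ParameterError(f"{name}: range must have positive width")

    def grid(self, name: str) -> np.ndarray:
        lo, hi, n = self.ranges[name]
        return np.linspace(lo, hi, n) if n > 1 else np.array([lo])

    def names(self) -> tuple[str, ...]:
        return tuple(p for p in CALIBRATED_PARAMS if p in self.ranges)

    def size(self) -> int:
        out = 1
        for name in self.names():
            out *= len(self.grid(name))
        return out


def default_search_spec() -> SearchSpec:
    """Broad default grids bracketing the calibrated parameter values."""
    return SearchSpec(
        {
            "k_light": (1e-4, 5e-4, 9),
            "k_heavy": (1e-5, 5e-5, 9),
            "f_labile_light": (0.1, 0.6, 11),
            "f_resistant_light": (0.2, 0.7, 11),
            "f_light_heavy": (0.1, 0.6, 11),
        }
    )


@dataclass(frozen=True)
class CalibrationResult:
    params: DecompositionParams
    objective: float  # |pooled mean deviation|, Mg C ha⁻¹
    table: pd.DataFrame  # one row per grid point with its objective


def grid_search_calibrate(
    spec: SearchSpec,
    trials: list[SiteTrial],
    base_params: DecompositionParams | None = None,
) -> CalibrationResult:
    """Exhaustive grid search minimising |pooled mean deviation|.

    Every combination on the Cartesian grid is evaluated by simulating all
    trials (batched over combinations); the objective pools the P − O
    differences over all observations of all trials.  Ties are broken by
    lexicographic parameter order, so the result is deterministic.
    """
    base = base_params or DecompositionParams.modified()
    if not trials:
        raise InputError("at least one trial required")
    if not any(t.observations for t in trials):
        raise InputError("trials carry no observations")
    names = spec.names()
    if not names:
        raise InputError("empty search grid")
    grids = [spec.grid(n) for n in names]
    combos = np.array(list(itertools.product(*grids)))  # (m, k) lexicographic
    m = combos.shape[0]

    values = {n: getattr(base, n) * np.ones(m) for n in CALIBRATED_PARAMS}
    for j, n in enumerate(names):
        values[n] = combos[:, j]
    rates = np.column_stack(
        [
            base.k_labile * np.ones(m),
            base.k_resistant * np.ones(m),
            values["k_light"],
            values["k_heavy"],
        ]
    )

    diffs_sum = np.zeros(m)
    n_obs = 0
    for trial in trials:
        if not trial.observations:
            continue
        u = np.column_stack([trial.input_labile, trial.input_resistant])
        x0 = np.tile(trial.initial_state.as_array(), (m, 1))
        soc, _, _, _ = _simulate(
            x0,
            rates,
            values["f_labile_light"],
            values["f_resistant_light"],
            values["f_light_heavy"],
            trial.f_env,
            u,
        )
        P = soc[:, trial.observation_years()]  # (m, n_obs_trial)
        O = trial.observed_30cm()
        diffs_sum += (P - O).sum(axis=1)
        n_obs += len(O)
    objective = np.abs(diffs_sum / n_obs)
    best = int(np.argmin(objective))  # first minimum = lexicographic winner

    table = pd.DataFrame(combos, columns=list(names))
    table["objective"] = objective
    winner = base.replace(**{n: float(values[n][best]) for n in CALIBRATED_PARAMS})
    return CalibrationResult(
        params=winner, objective=float(objective[best]), table=table
    )
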