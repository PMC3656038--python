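"""On-disk workspace: CSV/YAML round-trips for regions, trials and reports.

A workspace directory holds one subdirectory per region (``climate.csv``,
``soil_grid.csv``, ``yields.csv``, ``meta.yaml``) plus optional site-trial
directories and a top-level ``workspace.yaml`` index.  All files are plain
text so a demo workspace can be regenerated or inspected anywhere.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InputError
from .evaluation import SiteTrial, SOCObservation
from .pools import DecompositionParams, PoolState
from .regional import RegionalSummary, RegionInputs, loss_rates_and_shares
from .synthetic import SyntheticSpec, gen_region_set, gen_site_trial


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------


def save_region(region: RegionInputs, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    region.climate.to_csv(d / "climate.csv", index=False)
    region.soil_grid.to_csv(d / "soil_grid.csv", index=False)
    pd.DataFrame({"year_index": np.arange(len(region.yields)), "yield_Mg_per_ha": region.yields}).to_csv(
        d / "yields.csv", index=False
    )
    meta = {
        "name": region.name,
        "area_mha": float(region.area_mha),
        "retention": float(region.retention),
    }
    (d / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return d


def load_region(directory: str | Path) -> RegionInputs:
    d = Path(directory)
    meta = yaml.safe_load((d / "meta.yaml").read_text())
    return RegionInputs(
        name=meta["name"],
        area_mha=float(meta["area_mha"]),
        soil_grid=pd.read_csv(d / "soil_grid.csv"),
        yields=pd.read_csv(d / "yields.csv")["yield_Mg_per_ha"].to_numpy(),
        retention=float(meta["retention"]),
        climate=pd.read_csv(d / "climate.csv"),
    )


# ---------------------------------------------------------------------------
# Site trials
# ---------------------------------------------------------------------------


def save_trial(trial: SiteTrial, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "day": np.arange(trial.n_days),
            "f_env": trial.f_env,
            "input_labile": trial.input_labile,
            "input_resistant": trial.input_resistant,
        }
    ).to_csv(d / "forcing.csv", index=False)
    pd.DataFrame(
        [
            {"year": o.year, "soc_Mg_per_ha": o.value, "depth_cm": o.depth}
            for o in trial.observations
        ]
    ).to_csv(d / "observations.csv", index=False)
    meta: dict = {
        "name": trial.name,
        "initial_state": dataclasses.asdict(trial.initial_state),
    }
    if trial.true_params is not None:
        meta["true_params"] = dataclasses.asdict(trial.true_params)
    (d / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return d


def load_trial(directory: str | Path) -> SiteTrial:
    d = Path(directory)
    meta = yaml.safe_load((d / "meta.yaml").read_text())
    forcing = pd.read_csv(d / "forcing.csv")
    obs = pd.read_csv(d / "observations.csv")
    observations = [
        SOCObservation(year=int(r.year), value=float(r.soc_Mg_per_ha), depth=str(r.depth_cm))
        for r in obs.itertuples()
    ]
    true_params = (
        DecompositionParams(**meta["true_params"]) if "true_params" in meta else None
    )
    return SiteTrial(
        name=meta["name"],
        initial_state=PoolState(**meta["initial_state"]),
        f_env=forcing["f_env"].to_numpy(),
        input_labile=forcing["input_labile"].to_numpy(),
        input_resistant=forcing["input_resistant"].to_numpy(),
        observations=observations,
        true_params=true_params,
    )


# ---------------------------------------------------------------------------
# Fixture workspace
# ---------------------------------------------------------------------------


def make_fixtures(
    out_dir: str | Path,
    spec: SyntheticSpec | None = None,
    seed: int | None = None,
    n_trials: int = 4,
    trial_years: int = 25,
) -> Path:
    """Materialise a complete demo workspace (regions + site trials)."""
    spec = spec or SyntheticSpec()
    if seed is not None:
        spec = dataclasses.replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    regions = gen_region_set(spec, rng)
    for region in regions:
        save_region(region, out / "regions" / region.name)
    trial_names = []
    for i in range(n_trials):
        trial = gen_site_trial(
            spec, rng=rng, name=f"trial_{i:02d}", n_years=trial_years
        )
        save_trial(trial, out / "trials" / trial.name)
        trial_names.append(trial.name)
    index = {
        "seed": int(spec.seed),
        "n_years": int(spec.n_years),
        "start_year": int(spec.start_year),
        "regions": [r.name for r in regions],
        "trials": trial_names,
    }
    (out / "workspace.yaml").write_text(yaml.safe_dump(index, sort_keys=True))
    return out


def load_workspace(directory: str | Path) -> dict:
    d = Path(directory)
    index_path = d / "workspace.yaml"
    if not index_path.exists():
        raise InputError(f"{d} is not a workspace (no workspace.yaml)")
    return yaml.safe_load(index_path.read_text())


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def write_report(
    summaries: list[RegionalSummary],
    belt: RegionalSummary,
    out_dir: str | Path,
) -> Path:
    """Write the decadal accounting report (CSV) and a text summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = pd.concat([s.to_frame() for s in [*summaries, belt]], ignore_index=True)
    frame.to_csv(out / "report_decades.csv", index=False)
    totals = pd.DataFrame(
        [
            {
                "region": s.name,
                "area_Mha": s.area_mha,
                "initial_density_Mg_ha": s.initial_density,
                "total_change_Tg": s.total_change_tg,
                "total_change_lo": (s.total_change_ci or (np.nan, np.nan))[0],
                "total_change_hi": (s.total_change_ci or (np.nan, np.nan))[1],
                "density_decline_Mg_ha": s.density_decline,
            }
            for s in [*summaries, belt]
        ]
    )
    totals.to_csv(out / "report_totals.csv", index=False)
    (out / "summary.txt").write_text(format_text_summary(belt))
    return out


def format_ci(value: float, ci: tuple[float, float] | None, digits: int = 0) -> str:
    """Parenthetical value formatting, e.g. ``27 (21-33)``."""
    fmt = f"{{:.{digits}f}}"
    if ci is None:
        return fmt.format(value)
    return f"{fmt.format(value)} ({fmt.format(ci[0])}–{fmt.format(ci[1])})"


def format_text_summary(belt: RegionalSummary) -> str:
    rates = loss_rates_and_shares(belt)
    n_dec = len(belt.decades)
    lines = [
        f"Region: {belt.name} ({belt.area_mha:.2f} Mha)",
        f"Initial SOC density: {format_ci(belt.initial_density, belt.initial_ci)} Mg C ha-1",
        "",
        "Decade   density (Mg/ha)      C input   change (Tg)",
    ]
    for d in belt.decades:
        lines.append(
            f"{d.label:7s}  {format_ci(d.density, d.density_ci):18s}  "
            f"{d.c_input:7.2f}  {format_ci(d.change_tg, d.change_ci)}"
        )
    lines += [
        "",
        f"Total change: {format_ci(belt.total_change_tg, belt.total_change_ci)} Tg C "
        f"over {10 * n_dec} years",
        f"Mean annual rate: {rates.mean_annual_rate_tg_per_yr:.2f} Tg yr-1",
        "Decadal loss rates (Tg yr-1): "
        + ", ".join(f"{r:.1f}" for r in rates.rates_tg_per_yr),
        f"Share of change in first three decades: {rates.share_of_first(3):.1f}%",
        "",
    ]
    return "\n".join(lines)
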