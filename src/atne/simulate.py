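"""Scenario driver: burn-in, fishing phase, sensitivity suites, reporting.

A scenario runs the annual cycle — growth-season ODE integration, spawning
through the inheritance kernel, ageing, off-season decay — for a burn-in
period without fishing (letting biomasses and trait distributions reach
dynamic equilibrium) followed by a fishing phase in which both focal species
are harvested with their size-selective gears at a shared peak instantaneous
fishing mortality ``E``.  The sensitivity suite enumerates all level
combinations of ``(E, c_V, sigma_Linf, sigma_k)`` for one varied species
(the other held at its medium values), repeated per trait-correlation level.
"""

from __future__ import annotations

import itertools
import json
import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from atne.evolution import (
    ReproductionParams,
    TraitDistribution,
    TraitGrid,
    age_guilds,
    genotype_phenotype_variances,
    initial_trait_distribution,
    parent_distribution,
    spawn,
)
from atne.foodweb import (
    FoodWebConfig,
    SystemState,
    integrate_growth_season,
    off_season_step,
)
from atne.selectivity import SelectivityCurve

__all__ = [
    "default_reproduction",
    "ScenarioConfig",
    "ScenarioResult",
    "SensitivityLevels",
    "initial_state",
    "run_scenario",
    "sensitivity_suite",
    "relative_biomass_change",
    "equilibrium_check",
]


def default_reproduction(rho: float = -0.7) -> dict[str, ReproductionParams]:
    """Medium reproduction-model parameters for the two focal species
    (piscivore ``pred``, planktivore ``prey``)."""
    return {
        "pred": ReproductionParams(c_v=0.25, sigma_l_inf=3.0, sigma_k=0.030, rho=rho),
        "prey": ReproductionParams(c_v=0.25, sigma_l_inf=1.0, sigma_k=0.020, rho=rho),
    }


@dataclass
class ScenarioConfig:
    """One simulation scenario.

    ``E`` is the peak instantaneous fishing mortality (1/year), shared by all
    fished species; fishing is active only after ``burn_in_years``.
    ``repro`` and ``gears`` are per-species maps.  ``heritability_interval``
    sets how often (in years) the genotypic/phenotypic variance decomposition
    is recorded (0 disables it); it is diagnostic output and does not affect
    the dynamics.
    """

    burn_in_years: int = 100
    fishing_years: int = 100
    E: float = 1.0
    repro: dict[str, ReproductionParams] = field(default_factory=dict)
    gears: dict[str, SelectivityCurve] = field(default_factory=dict)
    seed: int = 0
    eps_pair: float = 1e-8
    merge_tol: float = 0.05
    heritability_interval: int = 10
    init_sd_frac: float = 0.15
    record_distributions: bool = False

    def __post_init__(self) -> None:
        if self.burn_in_years < 0 or self.fishing_years < 0:
            raise ValueError("year counts must be >= 0")
        if self.E < 0:
            raise ValueError("E must be >= 0")


@dataclass
class ScenarioResult:
    """Annual time series and final state of one scenario run."""

    biomass: pd.DataFrame          # year, guild, biomass (end of season)
    traits: pd.DataFrame           # year, species, guild scope, trait stats
    heritability: pd.DataFrame     # year, species, trait, v_g, v_p, h
    status: str
    final_state: SystemState | None = None
    final_distributions: dict[str, TraitDistribution] = field(default_factory=dict)
    config: ScenarioConfig | None = None


def initial_state(web: FoodWebConfig, scenario: ScenarioConfig | None = None) -> SystemState:
    """Starting biomasses: producers at half capacity, consumers at a third of
    the half-saturation density, fish age guilds declining with age, with
    focal-species cells spread by the initial trait distribution (a truncated
    normal centred on the grid)."""
    scenario = scenario or ScenarioConfig()
    biomass: dict[str, np.ndarray] = {}
    pools: dict[str, np.ndarray] = {}
    n_prod = sum(1 for g in web.guilds if g.role == "producer")
    for g in web.guilds:
        if g.role == "producer":
            biomass[g.id] = np.array([g.init_biomass if g.init_biomass is not None
                                      else 0.5 * web.K / n_prod])
        elif g.role == "consumer":
            biomass[g.id] = np.array([g.init_biomass if g.init_biomass is not None
                                      else web.B0 / 3.0])
        else:
            total = (g.init_biomass if g.init_biomass is not None
                     else 5.0 * np.exp(-0.5 * g.age))
            if g.species in web.grids:
                grid = web.grids[g.species]
                spec = web.species[g.species]
                center = (min(max(spec.traits.l_inf, grid.l_inf_bounds[0]),
                              grid.l_inf_bounds[1]),
                          min(max(spec.traits.k, grid.k_bounds[0]),
                              grid.k_bounds[1]))
                dist = initial_trait_distribution(grid, center=center,
                                                  sd_frac=scenario.init_sd_frac)
                biomass[g.id] = total * dist.mass.ravel()
                if g.mature:
                    pools[g.id] = np.zeros(grid.n_cells)
            else:
                biomass[g.id] = np.array([total])
                if g.mature:
                    pools[g.id] = np.zeros(1)
    return SystemState(biomass=biomass, pools=pools, year=0)


def _species_guild_ids(web: FoodWebConfig, sp: str) -> list[str]:
    ids = [(g.age, g.id) for g in web.guilds if g.role == "fish" and g.species == sp]
    return [gid for _, gid in sorted(ids)]


def _record_traits(web: FoodWebConfig, state: SystemState, year: int,
                   rows: list[dict]) -> None:
    for sp, grid in web.grids.items():
        gids = _species_guild_ids(web, sp)
        lc = np.repeat(grid.l_centers, grid.n_k)
        kc = np.tile(grid.k_centers, grid.n_l)
        for scope, arrs in (("all", [state.biomass[g] for g in gids]),
                            ("oldest", [state.biomass[gids[-1]]])):
            b = np.sum(arrs, axis=0)
            tot = b.sum()
            if tot <= 0:
                continue
            w = b / tot
            ml = float(w @ lc)
            mk = float(w @ kc)
            rows.append({
                "year": year, "species": sp, "scope": scope,
                "mean_l_inf": ml, "mean_k": mk,
                "var_l_inf": float(w @ (lc - ml) ** 2),
                "var_k": float(w @ (kc - mk) ** 2),
                "biomass": float(tot),
            })


def run_scenario(web: FoodWebConfig, scenario: ScenarioConfig,
                 state: SystemState | None = None,
                 start_year: int = 0) -> ScenarioResult:
    """Run the annual cycle for burn-in plus fishing years.

    The cycle per year: growth-season ODE integration (fishing active only
    after burn-in) -> spawning (reproductive pools through the inheritance
    kernel; stocked species receive their fixed input instead) -> ageing ->
    off-season decay.  Fully deterministic for a given configuration.  If a
    focal species goes extinct the run stops with a labelled status and the
    partial time series is returned.

    Years are absolute: the run covers ``[start_year, burn_in_years +
    fishing_years)`` with fishing active in ``[burn_in_years, burn_in_years +
    fishing_years)``, so a run can be continued from a saved state.
    """
    state = state.copy() if state is not None else initial_state(web, scenario)
    bio_rows: list[dict] = []
    trait_rows: list[dict] = []
    herit_rows: list[dict] = []
    status = "completed"
    end_year = scenario.burn_in_years + scenario.fishing_years
    total_years = end_year - start_year

    for year in range(start_year, end_year):
        fishing = scenario.burn_in_years <= year < end_year
        E_t = scenario.E if fishing else 0.0
        state = integrate_growth_season(state, web, scenario.gears if fishing else None,
                                        E_t)
        state.year = year
        for gid in state.biomass:
            bio_rows.append({"year": year, "guild": gid,
                             "biomass": float(state.biomass[gid].sum())})
        _record_traits(web, state, year, trait_rows)

        # reproduction and ageing, species by species
        larvae: dict[str, np.ndarray] = {}
        for sp, spec in web.species.items():
            gids = _species_guild_ids(web, sp)
            grid = web.grids.get(sp)
            if spec.stocked_biomass is not None:
                continue
            params = scenario.repro.get(sp, ReproductionParams())
            if grid is not None:
                pool_stack = np.array([
                    state.pools.get(gid, np.zeros(grid.n_cells)).reshape(grid.shape)
                    for gid in gids if web.guild(gid).mature])
                track_h = (scenario.heritability_interval > 0
                           and (year % scenario.heritability_interval == 0
                                or year == end_year - 1))
                if pool_stack.sum() > 0 and track_h:
                    parents = parent_distribution(pool_stack, grid)
                    (vg_l, vg_k), (vp_l, vp_k) = genotype_phenotype_variances(
                        parents, params, grid, scenario.eps_pair, scenario.merge_tol)
                    for trait, vg, vp in (("l_inf", vg_l, vp_l), ("k", vg_k, vp_k)):
                        herit_rows.append({
                            "year": year, "species": sp, "trait": trait,
                            "v_g": vg, "v_p": vp,
                            "h": vg / vp if vp > 0 else np.nan,
                        })
                larvae[sp] = spawn(pool_stack, params, grid,
                                   scenario.eps_pair, scenario.merge_tol).ravel()
            else:
                pool = sum(float(state.pools.get(gid, np.zeros(1)).sum())
                           for gid in gids if web.guild(gid).mature)
                larvae[sp] = np.array([params.u * pool])

        for sp, spec in web.species.items():
            gids = _species_guild_ids(web, sp)
            stack = np.array([state.biomass[gid] for gid in gids])
            if spec.stocked_biomass is not None:
                new_stack = age_guilds(stack, np.zeros_like(stack[0]))
                new_stack[spec.stock_age] = (
                    new_stack[spec.stock_age]
                    + spec.stocked_biomass / stack[0].size)
            else:
                new_stack = age_guilds(stack, larvae.get(sp, np.zeros_like(stack[0])))
            for a, gid in enumerate(gids):
                state.biomass[gid] = new_stack[a]
            for gid in gids:
                if gid in state.pools:
                    state.pools[gid][:] = 0.0

        state = off_season_step(state, web)

        extinct = [sp for sp in web.grids
                   if sum(state.biomass[g].sum() for g in _species_guild_ids(web, sp)) <= 0]
        if extinct:
            status = "extinct:" + ",".join(sorted(extinct))
            break

    final_dists: dict[str, TraitDistribution] = {}
    for sp, grid in web.grids.items():
        b = np.sum([state.biomass[g] for g in _species_guild_ids(web, sp)], axis=0)
        if b.sum() > 0:
            final_dists[sp] = TraitDistribution(grid, (b / b.sum()).reshape(grid.shape))
    return ScenarioResult(
        biomass=pd.DataFrame(bio_rows),
        traits=pd.DataFrame(trait_rows),
        heritability=pd.DataFrame(herit_rows),
        status=status,
        final_state=state,
        final_distributions=final_dists,
        config=scenario,
    )


# ---------------------------------------------------------------------------
# sensitivity suite


@dataclass(frozen=True)
class SensitivityLevels:
    """Low/medium/high levels for the varied parameters of one species.

    ``e_levels`` applies to the scenario-wide fishing mortality; the variance
    parameters apply to the varied species only.
    """

    e_levels: tuple[float, ...] = (0.5, 1.0, 2.0)
    c_v_levels: tuple[float, ...] = (0.125, 0.25, 0.5)
    sigma_l_levels: tuple[float, ...] = (1.5, 3.0, 6.0)
    sigma_k_levels: tuple[float, ...] = (0.015, 0.030, 0.060)

    def __post_init__(self) -> None:
        for name in ("e_levels", "c_v_levels", "sigma_l_levels", "sigma_k_levels"):
            vals = getattr(self, name)
            if len(vals) < 1 or list(vals) != sorted(vals):
                raise ValueError(f"{name} must be ascending")

    @property
    def medium(self) -> dict[str, float]:
        def mid(v):
            return v[len(v) // 2]
        return {"E": mid(self.e_levels), "c_v": mid(self.c_v_levels),
                "sigma_l_inf": mid(self.sigma_l_levels), "sigma_k": mid(self.sigma_k_levels)}

    def combinations(self):
        return list(itertools.product(self.e_levels, self.c_v_levels,
                                      self.sigma_l_levels, self.sigma_k_levels))


def _run_seed(master_seed: int, index: int) -> int:
    h = hashlib.sha256(f"{master_seed}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def sensitivity_suite(
    web: FoodWebConfig,
    levels: SensitivityLevels,
    rho_levels,
    varied_species: str,
    base_scenario: ScenarioConfig,
    other_levels: SensitivityLevels | None = None,
    out_dir=None,
) -> pd.DataFrame:
    """All level combinations of ``(E, c_V, sigma_Linf, sigma_k)`` for one
    species, the other species fixed at its medium values, per correlation
    level.

    Returns one row per (combination, rho) with final-state summaries.  With
    ``out_dir`` set, per-run results are written as CSV and completed runs
    are skipped on re-execution (the suite is resumable); per-run seeds
    derive from the master seed and combination index, so execution order
    does not matter.
    """
    from pathlib import Path

    other = [sp for sp in web.grids if sp != varied_species]
    if varied_species not in web.grids:
        raise ValueError(f"{varied_species} is not a focal species of this web")
    med_other = (other_levels or levels).medium
    rows = []
    combos = levels.combinations()
    for rho in rho_levels:
        for idx, (E, c_v, s_l, s_k) in enumerate(combos):
            run_id = f"rho{rho}_combo{idx:03d}"
            out_file = Path(out_dir) / f"{run_id}.csv" if out_dir else None
            if out_file is not None and out_file.exists():
                row = pd.read_csv(out_file).iloc[0].to_dict()
                rows.append(row)
                continue
            repro = dict(base_scenario.repro)
            repro[varied_species] = replace(
                repro.get(varied_species, ReproductionParams()),
                c_v=c_v, sigma_l_inf=s_l, sigma_k=s_k, rho=rho)
            for sp in other:
                repro[sp] = replace(
                    repro.get(sp, ReproductionParams()),
                    c_v=med_other["c_v"], sigma_l_inf=med_other["sigma_l_inf"],
                    sigma_k=med_other["sigma_k"], rho=rho)
            scen = replace(base_scenario, E=E, repro=repro,
                           seed=_run_seed(base_scenario.seed, idx))
            try:
                res = run_scenario(web, scen)
                row = {"run_id": run_id, "rho": rho, "combo": idx,
                       "E": E, "c_v": c_v, "sigma_l_inf": s_l, "sigma_k": s_k,
                       "status": res.status, "seed": scen.seed}
                tr = res.traits
                for sp in web.grids:
                    last = tr[(tr.species == sp) & (tr.scope == "oldest")]
                    if len(last):
                        final = last.iloc[-1]
                        row[f"{sp}_mean_l_inf"] = final["mean_l_inf"]
                        row[f"{sp}_mean_k"] = final["mean_k"]
                        row[f"{sp}_biomass"] = final["biomass"]
            except Exception as exc:   # record the failure, keep going
                row = {"run_id": run_id, "rho": rho, "combo": idx,
                       "E": E, "c_v": c_v, "sigma_l_inf": s_l, "sigma_k": s_k,
                       "status": f"failed:{exc}", "seed": _run_seed(base_scenario.seed, idx)}
            rows.append(row)
            if out_file is not None:
                out_file.parent.mkdir(parents=True, exist_ok=True)
                pd.DataFrame([row]).to_csv(out_file, index=False)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reporting


def relative_biomass_change(
    fished: ScenarioResult,
    reference: ScenarioResult,
    grouping: dict[str, str],
    window: int = 20,
) -> pd.DataFrame:
    """Percent biomass change of aggregate groups, fished vs unfished.

    Biomasses are averaged over the terminal ``window`` years of each run and
    summed within each aggregate group; the change is
    ``100 * (fished - reference) / reference``.
    """
    def terminal_means(res: ScenarioResult) -> pd.Series:
        df = res.biomass
        years = sorted(df.year.unique())
        if len(years) < 1:
            raise ValueError("run has no recorded years")
        sel = df[df.year.isin(years[-window:])]
        return sel.groupby("guild")["biomass"].mean()

    f = terminal_means(fished)
    r = terminal_means(reference)
    rows = []
    groups = sorted(set(grouping.values()))
    for grp in groups:
        gids = [g for g, gg in grouping.items() if gg == grp]
        fv = float(f.reindex(gids).fillna(0.0).sum())
        rv = float(r.reindex(gids).fillna(0.0).sum())
        if rv == 0:
            rows.append({"group": grp, "fished": fv, "reference": rv,
                         "pct_change": np.nan, "defined": False})
        else:
            rows.append({"group": grp, "fished": fv, "reference": rv,
                         "pct_change": 100.0 * (fv - rv) / rv, "defined": True})
    return pd.DataFrame(rows)


def equilibrium_check(
    biomass: pd.DataFrame,
    window: int = 20,
    cv_threshold: float = 0.05,
    slope_threshold: float | None = None,
) -> pd.DataFrame:
    """Stationarity diagnostic over the terminal window, per guild.

    Reports the coefficient of variation and the linear-trend slope
    (per year, relative to the mean) of each guild's biomass; a guild passes
    if CV is below ``cv_threshold`` (and, when given, the relative slope is
    below ``slope_threshold``).
    """
    years = sorted(biomass.year.unique())
    if window > len(years):
        raise ValueError("window longer than the recorded series")
    sel = biomass[biomass.year.isin(years[-window:])]
    rows = []
    for gid, grp in sel.groupby("guild"):
        vals = grp.sort_values("year")["biomass"].to_numpy()
        yrs = grp.sort_values("year")["year"].to_numpy(dtype=float)
        mean = vals.mean()
        cv = float(vals.std(ddof=0) / mean) if mean > 0 else np.inf
        if len(vals) > 1:
            slope = float(np.polyfit(yrs, vals, 1)[0])
        else:
            slope = 0.0
        rel_slope = slope / mean if mean > 0 else np.inf
        ok = cv < cv_threshold
        if slope_threshold is not None:
            ok = ok and abs(rel_slope) < slope_threshold
        rows.append({"guild": gid, "mean": mean, "cv": cv,
                     "slope": slope, "rel_slope": rel_slope, "pass": ok})
    return pd.DataFrame(rows)


def write_run(result: ScenarioResult, out_dir) -> None:
    """Write tidy CSV outputs and a small machine-readable manifest."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.biomass.to_csv(out / "biomass.csv", index=False)
    result.traits.to_csv(out / "traits.csv", index=False)
    result.heritability.to_csv(out / "heritability.csv", index=False)
    for sp, dist in result.final_distributions.items():
        grid = dist.grid
        df = pd.DataFrame({
            "l_inf": np.repeat(grid.l_centers, grid.n_k),
            "k": np.tile(grid.k_centers, grid.n_l),
            "mass": dist.mass.ravel(),
        })
        df.to_csv(out / f"trait_distribution_{sp}.csv", index=False)
    cfg = result.config
    manifest = {
        "status": result.status,
        "seed": cfg.seed if cfg else None,
        "E": cfg.E if cfg else None,
        "burn_in_years": cfg.burn_in_years if cfg else None,
        "fishing_years": cfg.fishing_years if cfg else None,
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
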