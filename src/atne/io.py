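"""Config serialisation (YAML) for food webs and scenarios."""

from __future__ import annotations

from dataclasses import asdict

import yaml

from atne.evolution import ReproductionParams, TraitGrid
from atne.foodweb import FoodWebConfig, Guild, Link, SpeciesSpec
from atne.growth import VBGMParams
from atne.selectivity import SelectivityCurve
from atne.simulate import ScenarioConfig

__all__ = [
    "foodweb_to_dict", "foodweb_from_dict", "write_foodweb", "read_foodweb",
    "scenario_to_dict", "scenario_from_dict", "write_scenario", "read_scenario",
]


def foodweb_to_dict(web: FoodWebConfig) -> dict:
    return {
        "guilds": [asdict(g) for g in web.guilds],
        "links": [asdict(ln) for ln in web.links],
        "species": {name: {**asdict(sp), "traits": asdict(sp.traits)}
                    for name, sp in web.species.items()},
        "grids": {name: {"l_inf_bounds": list(g.l_inf_bounds),
                         "k_bounds": list(g.k_bounds),
                         "n_l": g.n_l, "n_k": g.n_k}
                  for name, g in web.grids.items()},
        "constants": {"K": web.K, "B0": web.B0, "q": web.q,
                      "t_end": web.t_end, "eps_extinction": web.eps_extinction,
                      "ode_method": web.ode_method, "rtol": web.rtol,
                      "atol": web.atol},
    }


def foodweb_from_dict(d: dict) -> FoodWebConfig:
    species = {}
    for name, sd in d.get("species", {}).items():
        sd = dict(sd)
        sd["traits"] = VBGMParams(**sd["traits"])
        sd["mature_ages"] = tuple(sd.get("mature_ages", ()))
        species[name] = SpeciesSpec(**sd)
    grids = {name: TraitGrid(tuple(gd["l_inf_bounds"]), tuple(gd["k_bounds"]),
                             gd["n_l"], gd["n_k"])
             for name, gd in d.get("grids", {}).items()}
    consts = d.get("constants", {})
    return FoodWebConfig(
        guilds=[Guild(**g) for g in d["guilds"]],
        links=[Link(**ln) for ln in d["links"]],
        species=species,
        grids=grids,
        **consts,
    )


def write_foodweb(web: FoodWebConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(foodweb_to_dict(web), fh, sort_keys=False)


def read_foodweb(path) -> FoodWebConfig:
    with open(path) as fh:
        return foodweb_from_dict(yaml.safe_load(fh))


def scenario_to_dict(s: ScenarioConfig) -> dict:
    return {
        "burn_in_years": s.burn_in_years,
        "fishing_years": s.fishing_years,
        "E": s.E,
        "seed": s.seed,
        "eps_pair": s.eps_pair,
        "merge_tol": s.merge_tol,
        "heritability_interval": s.heritability_interval,
        "init_sd_frac": s.init_sd_frac,
        "repro": {sp: asdict(p) for sp, p in s.repro.items()},
        "gears": {sp: asdict(g) for sp, g in s.gears.items()},
    }


def scenario_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    d["repro"] = {sp: ReproductionParams(**p) for sp, p in d.get("repro", {}).items()}
    d["gears"] = {sp: SelectivityCurve(**g) for sp, g in d.get("gears", {}).items()}
    return ScenarioConfig(**d)


def write_scenario(s: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(s), fh, sort_keys=False)


def read_scenario(path) -> ScenarioConfig:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))
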