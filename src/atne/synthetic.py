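"""Synthetic data generators with known ground truth.

Everything the analysis consumes can be generated here: lognormal
length-at-age samples around a known von Bertalanffy curve, noisy
catch-biomass-by-length-class samples from a known selectivity bell, and a
reduced toy food web (producers -> zooplankton -> planktivorous fish age
guilds -> piscivorous fish age guilds) with two focal species carrying trait
grids.  All generators are reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from atne.evolution import TraitGrid
from atne.foodweb import FoodWebConfig, Guild, Link, SpeciesSpec
from atne.growth import VBGMParams, vbgm_length
from atne.selectivity import SelectivityCurve, selectivity_eval

__all__ = [
    "gen_length_at_age",
    "gen_catch_by_length",
    "toy_foodweb",
    "default_prey_spec",
    "default_predator_spec",
    "GILLNET_50MM",
    "TRAWL_SMALL_MESH",
]

# Fitted selectivity modes/widths for a 50-mm gillnet on the piscivore and a
# small-mesh trawl on the planktivore (cm).
GILLNET_50MM = SelectivityCurve(mu=46.72, sigma=3.44, delta=1.0)
TRAWL_SMALL_MESH = SelectivityCurve(mu=12.21, sigma=1.71, delta=1.0)


def default_age_sampler(rng: np.random.Generator, n: int) -> np.ndarray:
    """Fractional ages: uniform over {0.25, 0.5, ..., 12} plus within-quarter
    jitter, giving broad coverage of the growth curve."""
    base = rng.choice(np.arange(1, 49) * 0.25, size=n)
    return base + rng.uniform(0.0, 0.25, size=n)


def gen_length_at_age(
    truth: VBGMParams,
    sigma: float,
    n: int,
    seed: int | None = None,
    age_sampler=None,
    ages=None,
) -> pd.DataFrame:
    """Lognormal length-at-age records around a known growth curve.

    Lengths are drawn from ``Lognormal(mu_t, sigma)`` with location
    ``mu_t = ln(E[L_t]) - sigma^2/2`` so the sample mean at each age converges
    to the von Bertalanffy expectation.  ``ages`` fixes the ages directly;
    otherwise ``age_sampler(rng, n)`` draws them (default: broad coverage of
    0-12 years).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    if ages is not None:
        ages = np.broadcast_to(np.asarray(ages, dtype=float), (n,)).copy()
    else:
        sampler = age_sampler or default_age_sampler
        ages = np.asarray(sampler(rng, n), dtype=float)
    expected = vbgm_length(truth, ages)
    if sigma == 0:
        lengths = expected
    else:
        mu = np.log(expected) - 0.5 * sigma**2
        lengths = np.exp(rng.normal(mu, sigma))
    return pd.DataFrame({"fractional_age": ages, "length_cm": lengths})


def gen_catch_by_length(
    truth: SelectivityCurve,
    classes,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Noisy catch biomass per 1-cm length class under a known bell curve.

    Class biomass is the curve at the class midpoint plus Gaussian noise,
    clipped at zero (the least-squares fit assumes Gaussian residuals, so
    this is the matched generator).
    """
    classes = np.asarray(list(classes), dtype=float)
    if classes.size == 0:
        raise ValueError("need at least one length class")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    mid = classes + 0.5
    biomass = selectivity_eval(truth, mid)
    if noise_sd > 0:
        biomass = biomass + rng.normal(0.0, noise_sd, size=classes.shape)
    return pd.DataFrame({"class_lower_cm": classes.astype(int),
                         "biomass_g": np.maximum(biomass, 0.0)})


# ---------------------------------------------------------------------------
# toy food web fixture

# Fixture constants: a small pelagic web calibrated once so the unfished
# system holds a persistent, near-stationary equilibrium -- trait
# distributions included -- within a 100-year burn-in, and survives a century
# of fishing at E = 2/yr.  The species' point traits sit at the unfished
# trait equilibrium (the initial trait distribution is centred on them), and
# the relatively large lengths at birth keep the trait-insensitive early life
# short relative to the selection acting on older, food-limited stages.
# These are a test-bed design, not estimates of any particular lake.

_PREY_GRID = TraitGrid((10.0, 20.0), (0.45, 0.65), 40, 40)
_PRED_GRID = TraitGrid((70.0, 90.0), (0.10, 0.20), 40, 40)

_TOY_INIT_BIOMASS = {
    "phyto": 286.4, "zoo_grazer": 17.4, "zoo_invert": 1.35,
    "prey": (1.0, 25.9, 7.2, 2.6),
    "pred": (111.3, 165.4, 215.1, 205.2, 79.8, 68.9),
}


def default_prey_spec(fished: bool = True) -> SpeciesSpec:
    """A shoaling planktivore (4 age guilds, matures at 2)."""
    return SpeciesSpec(
        name="prey",
        traits=VBGMParams(l_inf=11.87, k=0.50, l0=4.0),
        n_ages=4,
        mature_ages=(2, 3),
        lw_a=0.005, lw_b=3.1,
        x_coef=0.12, y=4.0, fm=0.34, ra=0.010,
        fished=fished,
    )


def default_predator_spec(fished: bool = True) -> SpeciesSpec:
    """A piscivorous top predator (6 age guilds, matures at 3)."""
    return SpeciesSpec(
        name="pred",
        traits=VBGMParams(l_inf=79.8, k=0.1493, l0=15.0),
        n_ages=6,
        mature_ages=(3, 4, 5),
        lw_a=0.009, lw_b=3.0,
        x_coef=0.10, y=3.0, fm=0.25, ra=0.010,
        fished=fished,
    )


def toy_foodweb(
    n_producers: int = 1,
    n_zooplankton: int = 2,
    prey_spec: SpeciesSpec | None = None,
    pred_spec: SpeciesSpec | None = None,
    grid_shape: tuple[int, int] = (40, 40),
    seed: int = 0,
) -> FoodWebConfig:
    """A reduced, connected pelagic food web with two focal fish species.

    Producers are grazed by zooplankton; with ``n_zooplankton >= 2`` the last
    zooplankton guild is a scarcer predatory-zooplankton / pelagic-invertebrate
    guild feeding on the grazers.  Planktivore age 0 feeds on the grazers and
    the older planktivore guilds mostly on the predatory guild; young
    piscivores take zooplankton and the older piscivore guilds shift onto the
    planktivore age guilds.  Focal species resolve their age guilds on
    ``grid_shape`` trait grids.  Deterministic given ``seed`` (the seed only
    jitters producer growth and zooplankton metabolism by a few per cent so
    distinct replicate webs can be generated).
    """
    if n_producers < 1 or n_zooplankton < 1:
        raise ValueError("need at least one producer and one zooplankton guild")
    rng = np.random.default_rng(seed)
    prey = prey_spec or default_prey_spec()
    pred = pred_spec or default_predator_spec()
    if prey.n_ages < 3 or pred.n_ages < 3:
        raise ValueError("focal species need at least 3 age guilds")

    guilds: list[Guild] = []
    links: list[Link] = []
    for i in range(n_producers):
        r = 1.0 * (1 + rng.uniform(-0.02, 0.02))
        guilds.append(Guild(id=f"phyto_{i}", role="producer", r=r,
                            init_biomass=_TOY_INIT_BIOMASS["phyto"] / n_producers))
    n_grazers = n_zooplankton if n_zooplankton == 1 else n_zooplankton - 1
    grazer_ids = [f"zoo_{i}" for i in range(n_grazers)]
    for i in range(n_grazers):
        x = 0.10 * (1 + rng.uniform(-0.02, 0.02))
        guilds.append(Guild(id=f"zoo_{i}", role="consumer", x=x, y=5.0, fm=0.35,
                            body_mass_mgc=0.001,
                            init_biomass=_TOY_INIT_BIOMASS["zoo_grazer"] / n_grazers))
        for j in range(n_producers):
            links.append(Link(f"phyto_{j}", f"zoo_{i}", w=1.0 / n_producers, e=0.66))
    if n_zooplankton >= 2:
        inv_id = f"zoo_{n_zooplankton - 1}"
        x = 0.06 * (1 + rng.uniform(-0.02, 0.02))
        guilds.append(Guild(id=inv_id, role="consumer", x=x, y=4.0, fm=0.35,
                            body_mass_mgc=0.05,
                            init_biomass=_TOY_INIT_BIOMASS["zoo_invert"]))
        for z in grazer_ids:
            links.append(Link(z, inv_id, w=1.0 / len(grazer_ids), e=0.7))
    else:
        inv_id = grazer_ids[0]

    for sp in (prey, pred):
        inits = _TOY_INIT_BIOMASS.get(sp.name)
        for a in range(sp.n_ages):
            ib = inits[a] if inits is not None and a < len(inits) else None
            guilds.append(Guild(id=f"{sp.name}_a{a}", role="fish", species=sp.name,
                                age=a, mature=a in sp.mature_ages,
                                init_biomass=ib))

    def _split(zids, total):
        return [(z, total / len(zids)) for z in zids]

    # planktivore: age 0 on the grazer zooplankton, older ages mostly on the
    # scarcer predatory guild (food-limited adults)
    for a in range(prey.n_ages):
        if a == 0 or inv_id == grazer_ids[0]:
            for z, w in _split(grazer_ids, 1.0):
                links.append(Link(z, f"prey_a{a}", w=w, e=0.7))
        else:
            for z, w in _split(grazer_ids, 0.15):
                links.append(Link(z, f"prey_a{a}", w=w, e=0.7))
            links.append(Link(inv_id, f"prey_a{a}", w=0.85, e=0.7))
    # young piscivores on zooplankton
    for a in (0, 1):
        if inv_id == grazer_ids[0]:
            for z, w in _split(grazer_ids, 1.0):
                links.append(Link(z, f"pred_a{a}", w=w, e=0.7))
        else:
            for z, w in _split(grazer_ids, 0.3):
                links.append(Link(z, f"pred_a{a}", w=w, e=0.7))
            links.append(Link(inv_id, f"pred_a{a}", w=0.7, e=0.7))
    # older piscivores shift onto the planktivore age guilds with age
    prey_w = np.array([0.1, 0.2, 0.35, 0.35] + [0.05] * max(0, prey.n_ages - 4))
    prey_w = prey_w[:prey.n_ages] / prey_w[:prey.n_ages].sum()
    for a in range(2, pred.n_ages):
        zoo_share = 0.85 if a <= 3 else 0.7
        links.append(Link(inv_id, f"pred_a{a}", w=zoo_share, e=0.7))
        for pa in range(prey.n_ages):
            if prey_w[pa] > 0:
                links.append(Link(f"prey_a{pa}", f"pred_a{a}",
                                  w=float((1 - zoo_share) * prey_w[pa]), e=0.85))

    grids = {
        "prey": TraitGrid(_PREY_GRID.l_inf_bounds, _PREY_GRID.k_bounds, *grid_shape),
        "pred": TraitGrid(_PRED_GRID.l_inf_bounds, _PRED_GRID.k_bounds, *grid_shape),
    }
    return FoodWebConfig(
        guilds=guilds,
        links=links,
        species={"prey": prey, "pred": pred},
        grids=grids,
        K=300.0,
        B0=30.0,
        q=2.0,
    )
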