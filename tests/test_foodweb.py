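import math

import numpy as np
import pytest

from atne.evolution import TraitGrid
from atne.foodweb import (
    FoodWebConfig,
    Guild,
    Link,
    SpeciesSpec,
    SystemState,
    consumption_flux,
    fish_length_at,
    integrate_growth_season,
    length_to_carbon_mass,
    maintenance_loss,
    off_season_step,
    producer_gain,
    rhs,
    rhs_terms,
    _compiled,
)
from atne.growth import VBGMParams
from atne.selectivity import SelectivityCurve
from atne.synthetic import toy_foodweb


def producer_only_web(r=0.8, K=100.0):
    return FoodWebConfig(guilds=[Guild(id="p", role="producer", r=r)], links=[],
                         K=K, rtol=1e-9, atol=1e-12)


def constant_length_species(length, x_coef, fm, name="f", fished=False, **kw):
    """A fish whose length stays (numerically) constant at ``length``."""
    return SpeciesSpec(
        name=name,
        traits=VBGMParams(l_inf=length + 1e-9, k=1e-9, l0=length),
        n_ages=1, mature_ages=(), lw_a=1.0, lw_b=3.0,
        dry_frac=0.05, carbon_frac=0.02,
        x_coef=x_coef, fm=fm, ra=0.0, fished=fished, **kw)


def single_fish_web(spec, with_food_guild=True, **config_kw):
    guilds = [Guild(id="p", role="producer", r=0.5),
              Guild(id=f"{spec.name}_a0", role="fish", species=spec.name, age=0)]
    links = [Link("p", f"{spec.name}_a0", w=1.0, e=0.7)]
    return FoodWebConfig(guilds=guilds, links=links, species={spec.name: spec},
                         rtol=1e-10, atol=1e-14, **config_kw)


class TestLengthMass:
    def test_fish_length_at_endpoints(self, table_params):
        p = table_params
        assert fish_length_at(p.l_inf, p.k, p.l0, 2, 0.0) == pytest.approx(
            87 - 85.3 * math.exp(-0.248))
        # a full season accrues exactly one growth-year
        assert fish_length_at(p.l_inf, p.k, p.l0, 2, 90.0) == pytest.approx(
            87 - 85.3 * math.exp(-0.372))

    def test_fish_length_monotone_in_day(self, table_params):
        p = table_params
        days = np.linspace(0, 90, 10)
        L = [fish_length_at(p.l_inf, p.k, p.l0, 1, d) for d in days]
        assert np.all(np.diff(L) > 0)

    def test_cubic_scaling(self):
        spec = SpeciesSpec(name="s", traits=VBGMParams(50, 0.2, 1.0), lw_b=3.0)
        assert length_to_carbon_mass(20.0, spec) == pytest.approx(
            8 * length_to_carbon_mass(10.0, spec))

    def test_conversion_chain_by_hand(self):
        spec = SpeciesSpec(name="s", traits=VBGMParams(50, 0.2, 1.0),
                           lw_a=0.01, lw_b=3.0, dry_frac=0.2, carbon_frac=0.4)
        # 0.01 * 10^3 g fresh = 10 g = 10000 mg; x0.2 dry; x0.4 carbon
        assert length_to_carbon_mass(10.0, spec) == pytest.approx(800.0)


class TestProducerLogistic:
    def test_zero_biomass_fixed_point(self):
        web = producer_only_web()
        st = SystemState(biomass={"p": np.array([0.0])})
        assert producer_gain(web, st, "p") == 0.0

    def test_capacity_fixed_point(self):
        web = producer_only_web(K=100.0)
        st = SystemState(biomass={"p": np.array([100.0])})
        assert producer_gain(web, st, "p") == pytest.approx(0.0)

    def test_trajectory_matches_closed_form(self):
        r, K, b0 = 0.8, 100.0, 5.0
        web = producer_only_web(r=r, K=K)
        st = SystemState(biomass={"p": np.array([b0])})
        out = integrate_growth_season(st, web)
        t = web.t_end
        expected = K * b0 * math.exp(r * t) / (K + b0 * (math.exp(r * t) - 1))
        assert out.biomass["p"][0] == pytest.approx(expected, rel=1e-6)


class TestMaintenanceAndStarvation:
    def test_fm_zero_no_maintenance(self):
        spec = constant_length_species(10.0, x_coef=0.02, fm=0.0)
        web = single_fish_web(spec)
        st = SystemState(biomass={"p": np.array([0.0]), "f_a0": np.array([2.0])})
        assert maintenance_loss(web, st, "f_a0") == 0.0

    def test_starving_fish_decays_exponentially(self):
        # constant length 10 cm -> carbon mass 10^3 mg * 0.001 = 1 g? No:
        # lw_a=1, L=1 cm gives mass exactly 1 mg C, so x = x_coef exactly.
        spec = constant_length_species(1.0, x_coef=0.02, fm=0.4)
        web = single_fish_web(spec)
        b0 = 3.0
        st = SystemState(biomass={"p": np.array([0.0]), "f_a0": np.array([b0])})
        out = integrate_growth_season(st, web)
        expected = b0 * math.exp(-0.4 * 0.02 * 90)
        assert out.biomass["f_a0"][0] == pytest.approx(expected, rel=1e-7)

    def test_maintenance_linear_in_biomass(self):
        spec = constant_length_species(1.0, x_coef=0.02, fm=0.4)
        web = single_fish_web(spec)
        st1 = SystemState(biomass={"p": np.array([0.0]), "f_a0": np.array([1.0])})
        st2 = SystemState(biomass={"p": np.array([0.0]), "f_a0": np.array([5.0])})
        assert maintenance_loss(web, st2, "f_a0") == pytest.approx(
            5 * maintenance_loss(web, st1, "f_a0"))


class TestFishing:
    def _web_and_state(self, E_spec_fished=True):
        spec = constant_length_species(46.72, x_coef=0.02, fm=0.0,
                                       fished=E_spec_fished)
        web = single_fish_web(spec)
        st = SystemState(biomass={"p": np.array([0.0]), "f_a0": np.array([2.0])})
        return web, st

    def test_no_fishing_at_zero_e(self):
        web, st = self._web_and_state()
        gear = SelectivityCurve(46.72, 3.44)
        comp = _compiled(web)
        dy0 = rhs(web, comp.pack(st), 0.0, {"f": gear}, 0.0)
        dy1 = rhs(web, comp.pack(st), 0.0, None, 0.0)
        assert np.allclose(dy0, dy1)

    def test_season_survival_e_minus_one_at_gear_mode(self):
        web, st = self._web_and_state()
        gear = SelectivityCurve(46.72, 3.44)
        out = integrate_growth_season(st, web, {"f": gear}, E=1.0)
        assert out.biomass["f_a0"][0] == pytest.approx(2.0 * math.exp(-1.0),
                                                       rel=1e-7)

    def test_tail_length_unfished(self):
        spec = constant_length_species(10.0, x_coef=0.02, fm=0.0, fished=True)
        web = single_fish_web(spec)
        st = SystemState(biomass={"p": np.array([0.0]), "f_a0": np.array([2.0])})
        gear = SelectivityCurve(46.72, 3.44)   # 10 cm is ~10 sigma below mode
        out = integrate_growth_season(st, web, {"f": gear}, E=2.0)
        ref = integrate_growth_season(st, web, None, E=0.0)
        assert out.biomass["f_a0"][0] == pytest.approx(ref.biomass["f_a0"][0],
                                                       rel=1e-9)

    def test_missing_gear_raises(self):
        web, st = self._web_and_state()
        comp = _compiled(web)
        with pytest.raises(ValueError):
            rhs(web, comp.pack(st), 0.0, {}, 1.0)


class TestReproductionPools:
    def _web(self, E=0.0):
        grid = TraitGrid((40, 55), (0.05, 0.15), 2, 2)
        spec = SpeciesSpec(name="f", traits=VBGMParams(47.0, 0.1, 46.0),
                           n_ages=1, mature_ages=(0,), lw_a=1.0, lw_b=3.0,
                           dry_frac=0.05, carbon_frac=0.02,
                           x_coef=0.002, fm=0.0, ra=0.01, fished=True)
        guilds = [Guild(id="p", role="producer", r=0.5),
                  Guild(id="f_a0", role="fish", species="f", age=0, mature=True)]
        links = [Link("p", "f_a0", w=1.0, e=0.7)]
        return FoodWebConfig(guilds=guilds, links=links, species={"f": spec},
                             grids={"f": grid}, rtol=1e-10, atol=1e-14)

    def test_allocation_conserves_biomass_plus_pool(self):
        web = self._web()
        b0 = np.array([1.0, 2.0, 0.5, 0.25])
        st = SystemState(biomass={"p": np.array([0.0]), "f_a0": b0.copy()},
                         pools={"f_a0": np.zeros(4)})
        out = integrate_growth_season(st, web)
        total = out.biomass["f_a0"] + out.pools["f_a0"]
        assert np.allclose(total, b0, rtol=1e-8)

    def test_pool_depleted_by_fishing_fraction(self):
        # with fishing, B and B+ are depleted at the same per-biomass rate, so
        # the pool/biomass ratio matches the no-fishing run
        web = self._web()
        gear = SelectivityCurve(46.72, 3.44)
        b0 = np.array([1.0, 2.0, 0.5, 0.25])
        st = SystemState(biomass={"p": np.array([0.0]), "f_a0": b0.copy()},
                         pools={"f_a0": np.zeros(4)})
        out0 = integrate_growth_season(st, web, None, 0.0)
        out1 = integrate_growth_season(st, web, {"f": gear}, 1.0)
        ratio0 = out0.pools["f_a0"] / out0.biomass["f_a0"]
        ratio1 = out1.pools["f_a0"] / out1.biomass["f_a0"]
        assert np.allclose(ratio0, ratio1, rtol=1e-6)
        assert np.all(out1.biomass["f_a0"] < out0.biomass["f_a0"])


class TestRhsAssembly:
    def test_all_zero_state_is_fixed_point(self):
        web = toy_foodweb(grid_shape=(3, 3))
        comp = _compiled(web)
        y = np.zeros(comp.size)
        assert np.all(rhs(web, y) == 0.0)

    def test_nan_state_raises(self):
        web = toy_foodweb(grid_shape=(3, 3))
        comp = _compiled(web)
        y = np.zeros(comp.size)
        y[0] = np.nan
        with pytest.raises(FloatingPointError):
            rhs(web, y)

    def test_double_entry_audit(self):
        # every resource's predation loss equals the sum over its consumers of
        # (assimilated flux) / e, term by term
        web = toy_foodweb(grid_shape=(3, 3))
        comp = _compiled(web)
        rng = np.random.default_rng(0)
        st = SystemState(
            biomass={g.id: rng.uniform(0.5, 5.0, comp.slices[g.id].stop
                                       - comp.slices[g.id].start)
                     for g in web.guilds},
            pools={gid: np.zeros(sl.stop - sl.start)
                   for gid, sl in comp.pool_slices.items()})
        terms, _ = rhs_terms(web, comp.pack(st), t=10.0)
        for g in web.guilds:
            expected = 0.0
            for ln in web.links:
                if ln.resource == g.id:
                    expected += consumption_flux(web, st, ln.consumer, ln.resource,
                                                 t=10.0) / ln.e
            got = float(terms[g.id].get("predation_loss",
                                        np.zeros(1)).sum())
            assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_rhs_equals_signed_term_sum(self):
        web = toy_foodweb(grid_shape=(3, 3))
        comp = _compiled(web)
        rng = np.random.default_rng(1)
        y = rng.uniform(0.1, 3.0, comp.size)
        terms, pool_terms = rhs_terms(web, y, t=5.0)
        dy = rhs(web, y, t=5.0)
        for g in web.guilds:
            sl = comp.slices[g.id]
            acc = np.zeros(sl.stop - sl.start)
            tt = terms[g.id]
            for name, sign in (("growth", 1), ("consumption_gain", 1),
                               ("maintenance", -1), ("predation_loss", -1),
                               ("fishing", -1), ("reproduction", -1)):
                if name in tt:
                    acc += sign * tt[name]
            assert np.allclose(dy[sl], acc)

    def test_mass_balance_identity(self):
        # total biomass change = producer growth - unassimilated fractions
        #                        - maintenance  (no fishing, allocation goes
        #                        to pools which are part of the state)
        web = toy_foodweb(grid_shape=(3, 3))
        comp = _compiled(web)
        rng = np.random.default_rng(2)
        y = rng.uniform(0.1, 3.0, comp.size)
        terms, pool_terms = rhs_terms(web, y, t=0.0)
        dy = rhs(web, y, t=0.0)
        total_change = dy.sum()
        growth = sum(t["growth"].sum() for t in terms.values() if "growth" in t)
        maint = sum(t["maintenance"].sum() for t in terms.values()
                    if "maintenance" in t)
        gains = sum(t["consumption_gain"].sum() for t in terms.values()
                    if "consumption_gain" in t)
        pred = sum(t["predation_loss"].sum() for t in terms.values()
                   if "predation_loss" in t)
        assert total_change == pytest.approx(growth - maint - (pred - gains),
                                             rel=1e-9)

    def test_saturation_ceiling(self):
        # single resource at huge biomass: flux -> x*y*B_consumer
        spec = constant_length_species(1.0, x_coef=0.02, fm=0.0, y=4.0)
        web = single_fish_web(spec)
        st = SystemState(biomass={"p": np.array([1e12]), "f_a0": np.array([2.0])})
        flux = consumption_flux(web, st, "f_a0", "p")
        assert flux == pytest.approx(0.02 * 4.0 * 2.0, rel=1e-4)

    def test_equal_resources_get_equal_fluxes(self):
        guilds = [Guild(id="p1", role="producer", r=0.5),
                  Guild(id="p2", role="producer", r=0.5),
                  Guild(id="c", role="consumer", x=0.1, y=4.0, fm=0.2)]
        links = [Link("p1", "c", w=0.5, e=0.6), Link("p2", "c", w=0.5, e=0.6)]
        web = FoodWebConfig(guilds=guilds, links=links)
        st = SystemState(biomass={"p1": np.array([7.0]), "p2": np.array([7.0]),
                                  "c": np.array([1.0])})
        assert consumption_flux(web, st, "c", "p1") == pytest.approx(
            consumption_flux(web, st, "c", "p2"))


class TestSeasonIntegration:
    def test_t_end_zero_is_identity(self):
        web = toy_foodweb(grid_shape=(3, 3))
        web.t_end = 0.0
        from atne.simulate import initial_state
        st = initial_state(web)
        out = integrate_growth_season(st, web)
        for gid in st.biomass:
            assert np.allclose(out.biomass[gid], st.biomass[gid])

    def test_convergence_in_tolerance(self):
        web = toy_foodweb(grid_shape=(3, 3))
        from atne.simulate import initial_state
        st = initial_state(web)
        out1 = integrate_growth_season(st, web)
        web2 = toy_foodweb(grid_shape=(3, 3))
        web2.rtol, web2.atol = web.rtol / 2, web.atol / 2
        out2 = integrate_growth_season(st, web2)
        for gid in out1.biomass:
            a, b = out1.biomass[gid].sum(), out2.biomass[gid].sum()
            if b > 1e-9:
                assert abs(a - b) / b < 1e-3

    def test_non_negativity_and_extinction_threshold(self):
        web = toy_foodweb(grid_shape=(3, 3))
        from atne.simulate import initial_state
        st = initial_state(web)
        st.biomass["prey_a1"][:] = 1e-9      # below threshold after the season
        out = integrate_growth_season(st, web)
        for gid, b in out.biomass.items():
            assert np.all(b >= 0)


class TestOffSeason:
    def test_fm_zero_identity(self):
        spec = constant_length_species(1.0, x_coef=0.02, fm=0.0)
        web = single_fish_web(spec)
        st = SystemState(biomass={"p": np.array([3.0]), "f_a0": np.array([2.0])})
        out = off_season_step(st, web)
        assert out.biomass["f_a0"][0] == 2.0

    def test_closed_form_multiplier(self):
        # fm * x = 2/275 per day with t_end = 90 gives exactly e^-1
        fm = 0.4
        x_coef = 2.0 / (275.0 * fm)
        spec = constant_length_species(1.0, x_coef=x_coef, fm=fm)
        web = single_fish_web(spec)
        st = SystemState(biomass={"p": np.array([3.0]), "f_a0": np.array([2.0])})
        out = off_season_step(st, web)
        assert out.biomass["f_a0"][0] == pytest.approx(2.0 * math.exp(-1.0),
                                                       rel=1e-9)

    def test_non_fish_guilds_unchanged(self):
        web = toy_foodweb(grid_shape=(3, 3))
        from atne.simulate import initial_state
        st = initial_state(web)
        out = off_season_step(st, web)
        assert np.allclose(out.biomass["phyto_0"], st.biomass["phyto_0"])
        assert np.allclose(out.biomass["zoo_0"], st.biomass["zoo_0"])


class TestConfigValidation:
    def test_orphan_consumer_rejected(self):
        guilds = [Guild(id="p", role="producer", r=0.5),
                  Guild(id="c", role="consumer", x=0.1)]
        with pytest.raises(ValueError):
            FoodWebConfig(guilds=guilds, links=[])

    def test_preferences_must_sum_to_one(self):
        guilds = [Guild(id="p", role="producer", r=0.5),
                  Guild(id="c", role="consumer", x=0.1)]
        links = [Link("p", "c", w=0.5, e=0.6)]
        with pytest.raises(ValueError):
            FoodWebConfig(guilds=guilds, links=links)
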