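"""Gap-model dynamics: establishment, production, growth, mortality, conservation."""
import numpy as np
import pytest

from traitforest.dynamics import (
    GapModelParams,
    Patch,
    allocate_and_grow,
    annual_production,
    community_summary,
    death_probability,
    establish,
    mortality,
    partition_light,
    run_site,
    step_patch,
    stem_volume,
)
from traitforest.forcing import SitePlan, generate_forcing
from traitforest.herbivory import HerbivorySettings
from traitforest.traits import TraitBounds, TraitSet

from conftest import climate_year


class TestEstablish:
    def test_low_diversity_mode_has_zero_trait_variance(
        self, patch, bounds, local_curves, global_curves
    ):
        establish(patch, 500.0, "low_diversity", bounds, local_curves, global_curves, rng=1)
        assert patch.n_individuals > 0
        assert np.var(patch.sla) == 0.0
        assert np.var(patch.leaf_cn) == 0.0
        assert patch.sla[0] == bounds.sla_mid

    def test_zero_rate_adds_nothing(self, patch, bounds, local_curves):
        est_c = establish(patch, 0.0, "diversity", bounds, local_curves, rng=1)
        assert patch.n_individuals == 0 and est_c == 0.0

    def test_poisson_mean_matches_rate(self, params, bounds, local_curves):
        # rate 100 saplings/ha/yr on a 1-ha patch -> mean count 100
        rng = np.random.default_rng(8)
        counts = []
        for _ in range(400):
            p = Patch(area_m2=10_000.0, params=params)
            establish(p, 100.0, "diversity", bounds, local_curves, rng=rng)
            counts.append(p.n_individuals)
        se = np.sqrt(100.0 / len(counts))
        assert abs(np.mean(counts) - 100.0) < 4 * se

    def test_unknown_mode_rejected(self, patch, bounds, local_curves):
        with pytest.raises(ValueError, match="unknown"):
            establish(patch, 10.0, "mystery", bounds, local_curves)


class TestAnnualProduction:
    def _one(self, apar, f_n=1.0, f_p=1.0, tair=21.0, f_w=1.0, params=None):
        params = params or GapModelParams()
        return annual_production(
            c_leaf=1.0, c_wood=2.0, c_root=0.5, sla=150.0, leaf_cn=20.0,
            apar_mj=apar, tair_c=tair, f_water=f_w, f_n=f_n, f_p=f_p, params=params,
        )

    def test_dark_limit(self):
        gpp, npp, _ = self._one(apar=0.0)
        assert gpp == 0.0
        assert npp <= 0.0  # maintenance respiration still runs

    def test_gpp_linear_in_light(self):
        g1, _, _ = self._one(apar=500.0)
        g2, _, _ = self._one(apar=1000.0)
        assert g2 == pytest.approx(2.0 * g1, rel=1e-12)

    def test_nutrient_scalar_multiplies_gpp(self):
        g_full, _, _ = self._one(apar=800.0, f_n=1.0)
        g_half, _, _ = self._one(apar=800.0, f_n=0.5)
        assert g_half == pytest.approx(0.5 * g_full, rel=1e-12)

    def test_liebig_minimum_of_n_and_p(self):
        g_np, _, _ = self._one(apar=800.0, f_n=0.8, f_p=0.3)
        g_p, _, _ = self._one(apar=800.0, f_n=1.0, f_p=0.3)
        assert g_np == pytest.approx(g_p, rel=1e-12)


class TestAllocateAndGrow:
    def test_zero_npp_infinite_longevity_is_identity(self, params):
        # a tree whose leaf area sits inside its crown capacity
        out = allocate_and_grow(0.5, 50.0, 0.5, 150.0, 0.6, np.inf, 0.0, params)
        assert out["c_leaf"] == pytest.approx(0.5)
        assert out["c_wood"] == pytest.approx(50.0)
        assert out["c_root"] == pytest.approx(0.5)
        assert out["leaf_fall"] == 0.0 and out["carbon_stress"] == 0.0

    def test_leaf_turnover_definition(self, params):
        # 1 kg leaf C at 2-yr longevity sends 0.5 kg to litter
        out = allocate_and_grow(1.0, 50.0, 0.5, 100.0, 0.6, 2.0, 0.0, params)
        assert out["leaf_fall"] == pytest.approx(0.5)

    def test_crown_capacity_sheds_excess_leaf_area(self, params):
        # a sapling cannot hold 30 m² of leaf: the excess goes to litter
        out = allocate_and_grow(1.0, 2.0, 0.5, 150.0, 0.6, np.inf, 0.0, params)
        assert out["c_leaf"] < 1.0
        assert out["leaf_fall"] == pytest.approx(1.0 - out["c_leaf"])

    def test_light_wood_doubles_volume_growth(self, params):
        # same wood C increment, WSG 0.4 vs 0.8 -> exactly 2x the volume growth
        results = {}
        for wsg in (0.4, 0.8):
            v0 = float(stem_volume(10.0, wsg, params))
            out = allocate_and_grow(1.0, 10.0, 0.5, 100.0, wsg, np.inf, 1.0, params)
            v1 = float(stem_volume(out["c_wood"], wsg, params))
            results[wsg] = v1 - v0
        assert results[0.4] == pytest.approx(2.0 * results[0.8], rel=1e-12)

    def test_negative_npp_depletes_pools_and_records_stress(self, params):
        out = allocate_and_grow(0.2, 0.3, 0.1, 100.0, 0.6, np.inf, -10.0, params)
        total = out["c_leaf"] + out["c_wood"] + out["c_root"]
        assert total == pytest.approx(0.0, abs=1e-12)
        assert out["carbon_stress"] == pytest.approx(10.0 - 0.6)
        assert out["realized_npp"] == pytest.approx(-0.6)


class TestMortality:
    def test_vigorous_tree_with_no_background_hazard_survives(self):
        p = GapModelParams(mort_background=0.0)
        assert death_probability(1e7, 0.6, p) < 1e-6

    def test_background_hazard_decreases_with_wsg(self, params):
        light = death_probability(1e7, 0.4, params)
        dense = death_probability(1e7, 0.8, params)
        assert light > dense

    def test_constant_hazard_survivorship_curve(self):
        # death prob m per year: expect N0 (1-m)^t survivors
        m, n0, t = 0.1, 2000, 5
        p = GapModelParams(mort_background=m, mort_wsg_slope=0.0, mort_stress_max=0.0)
        rng = np.random.default_rng(17)
        alive = np.ones(n0, dtype=bool)
        greff = np.full(n0, 1.0)
        wsg = np.full(n0, 0.6)
        for _ in range(t):
            idx = np.flatnonzero(alive)
            alive[idx] &= mortality(greff[idx], wsg[idx], rng, p)
        expected = n0 * (1 - m) ** t
        se = np.sqrt(n0 * (1 - m) ** t * (1 - (1 - m) ** t))
        assert abs(alive.sum() - expected) < 4 * se


class TestLightPartitioning:
    def test_absorbed_never_exceeds_incident(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = rng.integers(1, 80)
            frac = partition_light(
                rng.uniform(1, 40, n), rng.uniform(0.1, 400, n), 1000.0, 0.5
            )
            assert np.all(frac >= 0)
            assert frac.sum() <= 1.0 + 1e-12

    def test_taller_tree_sees_undepleted_light(self):
        frac = partition_light([30.0, 5.0], [500.0, 500.0], 1000.0, 0.5)
        assert frac[0] > frac[1]


class TestStepPatch:
    def test_empty_patch_all_fluxes_zero(self, patch, bounds, local_curves, herb_settings):
        rec = step_patch(
            patch, climate_year(), herb_settings, "diversity", bounds, local_curves,
            None, np.random.default_rng(0), establishment_rate=0.0,
        )
        for key in ("gpp", "npp", "nppa", "litterfall", "herb_consumed", "rh", "est_c"):
            assert rec[key] == 0.0
        assert rec["lai"] == 0.0

    def test_carbon_identity_holds_over_50_years(
        self, patch, bounds, local_curves, global_curves, herb_settings
    ):
        rng = np.random.default_rng(21)
        for _ in range(50):
            rec = step_patch(
                patch, climate_year(), herb_settings, "diversity", bounds,
                local_curves, global_curves, rng,
            )
            assert abs(rec["c_balance_residual"]) <= 1e-9

    def test_same_seed_bit_identical_records(
        self, params, bounds, local_curves, global_curves, herb_settings
    ):
        def run():
            rng = np.random.default_rng(33)
            p = Patch(params=params)
            return [
                step_patch(p, climate_year(), herb_settings, "diversity", bounds,
                           local_curves, global_curves, rng)
                for _ in range(20)
            ]

        a, b = run(), run()
        for ra, rb in zip(a, b):
            assert ra == rb


class TestRunSite:
    def test_window_arithmetic(self):
        site = SitePlan("s", 1500.0, area_ha=0.1)
        forcing = generate_forcing(site, 30, rng_seed=1)
        run = run_site(site, forcing, "diversity", years=30, average_window=10, rng_seed=1)
        window_years = run.annual[run.annual.year > 20]["year"].unique()
        assert set(window_years) == set(range(21, 31))

    def test_patch_count_follows_area(self):
        assert SitePlan("s", 1000.0, area_ha=10.0).n_patches == 100
        assert SitePlan("s", 1000.0, area_ha=1.0).n_patches == 10

    def test_window_longer_than_run_rejected(self):
        site = SitePlan("s", 1500.0, area_ha=0.1)
        forcing = generate_forcing(site, 10, rng_seed=1)
        with pytest.raises(ValueError):
            run_site(site, forcing, "diversity", years=10, average_window=20)

    def test_patch_results_independent_of_other_patches(self):
        """Patch 0 of a 2-patch site equals the single patch of a 1-patch site."""
        forcing_site = SitePlan("s", 2000.0, area_ha=0.2)
        forcing = generate_forcing(forcing_site, 25, rng_seed=7)
        two = run_site(forcing_site, forcing, "diversity", years=25, average_window=5, rng_seed=9)
        one_site = SitePlan("s", 2000.0, area_ha=0.1)
        one = run_site(one_site, forcing, "diversity", years=25, average_window=5, rng_seed=9)
        a = two.annual[two.annual.patch == 0].reset_index(drop=True)
        b = one.annual[one.annual.patch == 0].reset_index(drop=True)
        assert a.equals(b)


class TestCommunitySummary:
    def _patch_with(self, slas, wsgs, leaf_c=None, params=None):
        p = Patch(params=params or GapModelParams())
        n = len(slas)
        ts = TraitSet(
            sla=np.asarray(slas, float), wsg=np.asarray(wsgs, float),
            leaf_cn=np.full(n, 20.0), leaf_cp=np.full(n, 300.0),
            leaf_longevity=np.full(n, 1.0),
        )
        leaf_c = np.full(n, 1.0) if leaf_c is None else np.asarray(leaf_c, float)
        p.add(ts, leaf_c, np.full(n, 100.0), np.full(n, 0.5))
        return p

    def test_equal_weight_mean(self):
        s = community_summary(self._patch_with([10.0, 20.0], [0.5, 0.7]), min_height_m=0.0)
        assert s.cwm_sla == pytest.approx(15.0)
        assert not s.cwm_missing

    def test_single_individual(self):
        s = community_summary(self._patch_with([42.0], [0.6]), min_height_m=0.0)
        assert s.cwm_sla == pytest.approx(42.0)
        assert s.sla_variance == 0.0

    def test_leaf_mass_weighting_against_brute_force(self):
        rng = np.random.default_rng(3)
        slas = rng.uniform(60, 250, 40)
        leaf_c = rng.uniform(0.1, 5.0, 40)
        p = self._patch_with(slas, np.full(40, 0.6), leaf_c=leaf_c)
        s = community_summary(p, weighting="leaf_mass", min_height_m=0.0)
        assert s.cwm_sla == pytest.approx(float((leaf_c * slas).sum() / leaf_c.sum()), abs=1e-12)

    def test_empty_community_flagged_missing(self, patch):
        s = community_summary(patch)
        assert s.cwm_missing and s.lai == 0.0 and np.isnan(s.cwm_sla)

    def test_cwm_bounded_by_trait_bounds(self, bounds):
        rng = np.random.default_rng(4)
        slas = rng.uniform(bounds.sla_min, bounds.sla_max, 30)
        s = community_summary(self._patch_with(slas, np.full(30, 0.6)), min_height_m=0.0)
        assert bounds.sla_min <= s.cwm_sla <= bounds.sla_max
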