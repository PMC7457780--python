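"""Generator contracts: determinism, variance structure, calibration."""

import numpy as np
import pandas as pd
import pytest

from noctura import (
    LightRegime,
    SimConfig,
    nd_ratio,
    run_selection_experiment,
    simulate_activity,
    simulate_parent_offspring,
    simulate_population,
)
from noctura.synthetic_data import SimIndividual, _T0_DEFAULT


class TestConfigValidation:
    def test_bad_h2_rejected(self):
        with pytest.raises(ValueError, match="h2"):
            SimConfig(h2=1.2)

    def test_oversized_selection_rejected(self):
        with pytest.raises(ValueError, match="n_selected"):
            SimConfig(n_pop=10, n_selected=20)

    def test_nonpositive_activity_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SimConfig(total_activity_per_day=0.0)


class TestSimulatePopulation:
    def test_same_seed_identical_populations(self):
        cfg = SimConfig(seed=7)
        a = simulate_population(cfg)
        b = simulate_population(cfg)
        assert [(i.id, i.g, i.e, i.tau) for i in a] == \
            [(i.id, i.g, i.e, i.tau) for i in b]

    def test_h2_zero_has_no_genetic_variance(self):
        pop = simulate_population(SimConfig(h2=0.0, seed=1))
        assert np.var([i.g for i in pop]) == 0.0

    def test_h2_one_phenotypic_variance_matches_vp(self):
        cfg = SimConfig(n_pop=5000, h2=1.0, vp=0.04, seed=2)
        pop = simulate_population(cfg)
        nd = np.array([i.true_nd for i in pop])
        assert nd.var() == pytest.approx(0.04, rel=0.05)

    def test_sexes_balanced_within_families(self):
        pop = simulate_population(SimConfig(n_pop=50, seed=3))
        fam = {}
        for ind in pop:
            fam.setdefault(ind.family_id, []).append(ind.sex)
        assert all(sorted(v) == ["F", "M"] for v in fam.values())

    def test_full_sib_mode_correlates_sibs(self):
        cfg = SimConfig(n_pop=4000, h2=1.0, full_sib_mates=True, seed=4)
        pop = simulate_population(cfg)
        g_m = np.array([i.g for i in pop if i.sex == "M"])
        g_f = np.array([i.g for i in pop if i.sex == "F"])
        r = np.corrcoef(g_m, g_f)[0, 1]
        assert r == pytest.approx(0.5, abs=0.05)


class TestSimulateActivity:
    def test_measured_nd_tracks_true_nd(self, rng):
        cfg = SimConfig(total_activity_per_day=3000.0)
        regime = LightRegime(8.0, 12.0)
        ind = SimIndividual(id="f", sex="M", g=0, e=0, true_nd=1.2,
                            tau=24.0, family_id="x")
        vals = []
        n_rep = 40
        for _ in range(n_rep):
            s = simulate_activity(ind, regime, 5, cfg, rng=rng,
                                  bin_minutes=30)
            vals.append(nd_ratio(s, pool_days=True)[0])
        # Poisson error on a pooled 5-day ratio at 3000 counts/day
        mc_sd = 1.2 * np.sqrt(2 / (0.5 * 5 * 3000)) / np.sqrt(n_rep)
        assert np.mean(vals) == pytest.approx(1.2, abs=3 * mc_sd)

    def test_measurement_noise_shrinks_with_activity(self, rng):
        cfg_lo = SimConfig(total_activity_per_day=300.0)
        cfg_hi = SimConfig(total_activity_per_day=10000.0)
        regime = LightRegime(8.0, 12.0)
        errs = {}
        for name, cfg in (("lo", cfg_lo), ("hi", cfg_hi)):
            sq = []
            for i in range(25):
                ind = SimIndividual(id=f"f{i}", sex="M", g=0, e=0,
                                    true_nd=1.1, tau=24.0, family_id="x")
                s = simulate_activity(ind, regime, 2, cfg, rng=rng,
                                      bin_minutes=30)
                sq.append((nd_ratio(s, pool_days=True)[0] - 1.1) ** 2)
            errs[name] = np.mean(sq)
        assert errs["hi"] < errs["lo"] / 5

    def test_stable_acrophase_when_entrained(self, rng):
        from noctura import acrophase

        cfg = SimConfig(total_activity_per_day=4000.0,
                        bump_phases=(6.0, 6.0))  # unimodal for a clean phase
        regime = LightRegime(8.0, 12.0)
        ind = SimIndividual(id="f", sex="M", g=0, e=0, true_nd=1.0,
                            tau=24.0, family_id="x")
        s = simulate_activity(ind, regime, 5, cfg, rng=rng, bin_minutes=30)
        res = acrophase(s)
        assert res.ci95_deg is not None
        assert res.ci95_deg < 10.0  # phase does not drift across days

    def test_invalid_days_rejected(self):
        cfg = SimConfig()
        ind = SimIndividual(id="f", sex="M", g=0, e=0, true_nd=1.0,
                            tau=24.0, family_id="x")
        with pytest.raises(ValueError, match="days"):
            simulate_activity(ind, LightRegime(8.0, 12.0), 0, cfg)


class TestSelectionExperiment:
    def test_determinism_under_seed(self):
        cfg = SimConfig(n_cycles=4, seed=5)
        rec_a, truth_a = run_selection_experiment(cfg)
        rec_b, truth_b = run_selection_experiment(cfg)
        assert [r.cum_R for r in rec_a] == [r.cum_R for r in rec_b]
        assert truth_a == truth_b

    def test_records_structurally_consistent(self):
        cfg = SimConfig(n_cycles=10, seed=6)
        rec, truth = run_selection_experiment(cfg, direction="nocturnal")
        assert len(rec) == 10
        assert truth["h2"] == cfg.h2
        np.testing.assert_allclose(np.cumsum([r.S for r in rec]),
                                   [r.cum_S for r in rec])
        assert all(r.n_selected == 25 and r.n_phenotyped == 300 for r in rec)

    def test_h2_zero_mean_response_is_null(self, rng):
        cfg = SimConfig(h2=0.0, n_cycles=5, seed=7)
        finals = [
            run_selection_experiment(cfg, rng=rng)[0][-1].cum_R
            for _ in range(100)
        ]
        se = np.std(finals) / np.sqrt(len(finals))
        assert abs(np.mean(finals)) < 3 * se + 1e-3

    def test_deterministic_limit_r_equals_s(self, rng):
        # h2=1 and e=0: the response realizes the differential exactly
        cfg = SimConfig(h2=1.0, n_cycles=3, seed=8)
        rec, _ = run_selection_experiment(cfg, rng=rng)
        for r in rec:
            assert r.R == pytest.approx(r.S, abs=3 * np.sqrt(
                2 * cfg.vp / cfg.n_pop) * 3)

    def test_directions_respond_with_opposite_signs(self):
        cfg = SimConfig(h2=0.3, n_cycles=5, seed=9)
        up, _ = run_selection_experiment(cfg, direction="nocturnal")
        down, _ = run_selection_experiment(cfg, direction="diurnal")
        assert up[-1].cum_R > 0 > down[-1].cum_R
        assert up[-1].cum_S > 0 > down[-1].cum_S

    def test_full_actogram_path_agrees_with_fast_path(self, rng):
        # tiny design: the Poisson-actogram phenotype path must track the
        # analytic one within measurement noise
        cfg = SimConfig(n_pop=30, n_selected=5, n_cycles=2, h2=0.3,
                        total_activity_per_day=2000.0, seed=10)
        rec, _ = run_selection_experiment(cfg, phenotype_path="full",
                                          rng=rng, days=2)
        assert len(rec) == 2
        assert abs(rec[0].pop_mean - cfg.nd_mean) < 0.15


class TestParentOffspring:
    def test_reproducible_tables(self):
        cfg = SimConfig(seed=11)
        a = simulate_parent_offspring(cfg, n_families=20)
        b = simulate_parent_offspring(cfg, n_families=20)
        for key in a:
            pd.testing.assert_frame_equal(a[key], b[key])

    def test_too_few_families_rejected(self):
        with pytest.raises(ValueError, match="three families"):
            simulate_parent_offspring(SimConfig(), n_families=2)

    def test_null_heritability_null_slope(self, rng):
        from noctura import parent_offspring_h2

        cfg = SimConfig(h2=0.0)
        t = simulate_parent_offspring(cfg, n_families=4000, rng=rng)
        est = parent_offspring_h2(
            t["midparent"][["midparent_nd", "midprogeny_nd"]].to_numpy())
        assert est.h2 == pytest.approx(0.0, abs=0.04)
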