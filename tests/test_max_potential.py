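"""Spur filter, shoot classification, Max selections, fruit diagnostics."""

import numpy as np
import pytest

import orchardgrowth as og
from orchardgrowth.growth_analysis import trajectory_rates
from orchardgrowth.max_potential import (
    classify_shoot_type,
    classify_shoots,
    filter_spurs,
    fruit_potential_curve,
    fruit_variability_analysis,
    select_max_shoots,
    select_max_trunk,
)
from orchardgrowth.synthetic_orchard import (
    OrchardConfig,
    latent_fruit_mass,
    trunk_circumference_mm,
    TreeParams,
    _make_fruit,
)
from tests.conftest import make_trajectory


def shoot(organ_id, final_length, final_mass=None, pruning_trace=False):
    gdd = np.array([0.0, 500.0, 1000.0])
    lengths = np.array([0.5, 0.8, 1.0]) * final_length
    obs = {"length": lengths}
    if final_mass is not None:
        obs["dry_mass"] = np.array([0.4, 0.7, 1.0]) * final_mass
    t = make_trajectory(organ_id=organ_id, gdd=gdd, **obs)
    t.pruning_trace = pruning_trace
    return t


class TestFilterSpurs:
    def test_strictly_longer_than_threshold(self):
        shoots = [shoot("a", 3.9), shoot("b", 4.0), shoot("c", 4.1)]
        kept = filter_spurs(shoots)
        assert [s.organ_id for s in kept] == ["c"]

    def test_all_long_is_identity(self):
        shoots = [shoot(f"s{i}", 10.0 + i) for i in range(4)]
        assert filter_spurs(shoots) == shoots

    def test_hand_counted_removal(self):
        lengths = [2.0, 3.0, 3.5, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
        shoots = [shoot(f"s{i}", L) for i, L in enumerate(lengths)]
        assert len(filter_spurs(shoots)) == 6

    def test_empty_result_warns(self):
        with pytest.warns(UserWarning):
            assert filter_spurs([shoot("a", 1.0)]) == []


class TestClassifyShootType:
    def test_pruning_trace_means_epicormic(self):
        assert classify_shoot_type(shoot("a", 10, pruning_trace=True)) == "epicormic"

    def test_no_trace_means_proleptic(self):
        assert classify_shoot_type(shoot("a", 10, pruning_trace=False)) == "proleptic"

    def test_missing_flag_is_unknown_with_warning(self):
        s = shoot("a", 10)
        s.pruning_trace = None
        with pytest.warns(UserWarning):
            assert classify_shoot_type(s) == "unknown"


class TestSelectMaxShoots:
    def _pool(self):
        # 7 proleptic shoots with distinct final masses 1..7 g
        shoots = [shoot(f"p{i}", 10.0 + i, final_mass=float(i)) for i in range(1, 8)]
        return classify_shoots(shoots)

    def test_top_five_by_final_mass(self):
        sel = select_max_shoots(self._pool())["proleptic"]
        assert sel.member_ids == ["p7", "p6", "p5", "p4", "p3"]

    def test_k_larger_than_population_returns_all(self):
        shoots = classify_shoots([shoot("a", 10, final_mass=1.0)])
        with pytest.warns(UserWarning):
            sel = select_max_shoots(shoots, k=5)["proleptic"]
        assert sel.member_ids == ["a"]

    def test_mass_tie_broken_by_final_length(self):
        pool = self._pool()
        # two candidates tied at rank 5: longer final length must win
        tie_a = shoot("tie_long", 30.0, final_mass=3.0)
        tie_b = shoot("tie_short", 20.0, final_mass=3.0)
        sel = select_max_shoots(classify_shoots(pool[3:] + [tie_a, tie_b]))["proleptic"]
        assert "tie_long" in sel.member_ids
        assert "tie_short" not in sel.member_ids

    def test_selection_mean_mass_at_least_population_mean(self):
        pool = self._pool()
        sel = select_max_shoots(pool)["proleptic"]
        pop_mean = np.mean([s.final_dry_mass for s in pool])
        sel_mean = np.mean(list(sel.selection_metric.values()))
        assert sel_mean >= pop_mean

    def test_filter_classify_select_idempotent(self):
        pool = classify_shoots(
            filter_spurs(
                [shoot(f"p{i}", 5.0 + i, final_mass=float(i)) for i in range(1, 10)]
            )
        )
        first = select_max_shoots(pool)["proleptic"]
        members = [s for s in pool if s.organ_id in first.member_ids]
        second = select_max_shoots(classify_shoots(filter_spurs(members)))["proleptic"]
        assert second.member_ids == first.member_ids

    def test_unknown_class_excluded(self):
        s = shoot("u", 10, final_mass=99.0)
        s.shoot_class = "unknown"
        sel = select_max_shoots(self._pool() + [s])["proleptic"]
        assert "u" not in sel.member_ids


def trunk_traj(organ_id, circs, gdd=(0.0, 500.0, 1000.0)):
    return make_trajectory(
        organ_id=organ_id, organ_type="trunk", gdd=gdd, circumference=circs
    )


class TestSelectMaxTrunk:
    def test_argmax_of_final_increment(self):
        trees = [
            trunk_traj("t1", [100.0, 104.0, 108.0]),
            trunk_traj("t2", [100.0, 106.0, 112.0]),
            trunk_traj("t3", [100.0, 105.0, 110.0]),
        ]
        sel = select_max_trunk(trees)
        assert sel.member_ids == ["t2"]
        assert sel.selection_metric["t2"] == pytest.approx(0.12)
        assert sel.trunk_fit is not None and sel.trunk_fit.slope > 0

    def test_single_tree_selected(self):
        sel = select_max_trunk([trunk_traj("only", [100.0, 101.0, 102.0])])
        assert sel.member_ids == ["only"]

    def test_no_eligible_tree_rejected(self):
        with pytest.raises(ValueError):
            select_max_trunk([])

    def test_monte_carlo_identifies_generated_max(self):
        # tree 3 is generated with the clearly largest trunk RGR; at the
        # collar's 1 mm precision it must be recovered nearly always
        config = OrchardConfig()
        rgrs = [5e-5, 6e-5, 9e-5, 5.5e-5, 6.5e-5]
        gdd = np.linspace(400.0, 2000.0, 8)
        hits = 0
        reps = 100
        rng = np.random.default_rng(123)
        for _ in range(reps):
            trees = []
            for i, r in enumerate(rgrs):
                p = TreeParams(f"t{i}", "DEF", r, 5000.0)
                circ = trunk_circumference_mm(p, gdd)
                circ = circ * rng.lognormal(0.0, config.circumference_cv, len(gdd))
                trees.append(trunk_traj(f"t{i}", circ, gdd=gdd))
            hits += select_max_trunk(trees).member_ids == ["t2"]
        assert hits >= 0.95 * reps


def thi_fruit_cohort(n=40, seed=0, measure_gdd=(150.0, 350.0, 900.0, 1900.0)):
    config = OrchardConfig(pest_damage_rate=0.0)
    rng = np.random.default_rng(seed)
    fruits = []
    for i in range(n):
        p = _make_fruit(config, "THI", "T", i, rng)
        mass = latent_fruit_mass(p, np.asarray(measure_gdd), config)
        fruits.append(
            make_trajectory(
                organ_id=p.fruit_id + str(i),
                organ_type="fruit",
                treatment="THI",
                gdd=measure_gdd,
                dry_mass=mass,
            )
        )
    return fruits


class TestFruitPotential:
    def test_all_damaged_yields_empty_curve(self):
        fruits = thi_fruit_cohort(3)
        for f in fruits:
            f.pest_damaged = True
        with pytest.warns(UserWarning):
            curve = fruit_potential_curve(fruits)
        assert curve.empty

    def test_single_fruit_curve_is_its_own_series(self):
        fruit = thi_fruit_cohort(1)[0]
        curve = fruit_potential_curve([fruit])
        series = trajectory_rates(fruit, "dry_mass")
        assert curve["mean"].to_numpy() == pytest.approx(series.rates)

    def test_cohort_mean_tracks_generating_curve(self):
        config = OrchardConfig(pest_damage_rate=0.0)
        fruits = thi_fruit_cohort(60, seed=5)
        curve = fruit_potential_curve(fruits)
        # generating-mean RGR at each interval from the latent expolinear
        # form with the cohort's central parameters
        from orchardgrowth.synthetic_orchard import FruitParams

        central = FruitParams(
            "c", "T", "THI",
            config.fruit_linear_rate_thi, config.fruit_max_rgr_thi,
            config.fruit_transition_gdd, 0.0, False,
        )
        gdd = np.array([150.0, 350.0, 900.0, 1900.0])
        w = latent_fruit_mass(central, gdd, config)
        expected = np.diff(np.log(w)) / np.diff(gdd)
        se = curve["sd"].to_numpy() / np.sqrt(curve["n"].to_numpy())
        assert np.all(np.abs(curve["mean"].to_numpy() - expected) < 3.5 * se)


class TestFruitVariability:
    def test_exact_proportional_masses(self):
        fruits = []
        rng = np.random.default_rng(0)
        for i in range(10):
            m0 = rng.uniform(0.5, 2.0)
            fruits.append(
                make_trajectory(
                    organ_id=f"f{i}",
                    organ_type="fruit",
                    gdd=[100.0, 600.0, 1900.0],
                    dry_mass=[m0, 3 * m0, 10 * m0],
                )
            )
        report = fruit_variability_analysis(fruits)
        assert report.slope_harvest_initial == pytest.approx(10.0)
        assert report.r2_harvest_initial == pytest.approx(1.0)

    def test_set_time_jitter_implies_negative_early_rgr_slope(self):
        report = fruit_variability_analysis(thi_fruit_cohort(40, seed=3))
        assert report.slope_initial_early_rgr < 0
        assert report.p_initial_early_rgr < 0.01
        assert report.slope_harvest_initial > 0

    def test_null_pairing_p_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(17)
        pvals = []
        for _ in range(200):
            # independently drawn initial and harvest masses: no relation
            fruits = []
            for i in range(12):
                m0 = rng.lognormal(0, 0.3)
                mh = 20 * rng.lognormal(0, 0.3)
                mid = np.sqrt(m0 * mh)
                fruits.append(
                    make_trajectory(
                        organ_id=f"f{i}",
                        organ_type="fruit",
                        gdd=[100.0, 900.0, 1900.0],
                        dry_mass=[m0, mid, mh],
                    )
                )
            pvals.append(fruit_variability_analysis(fruits).p_harvest_initial)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_too_few_fruits_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fruit_variability_analysis(thi_fruit_cohort(2))

    def test_constant_predictor_rejected(self):
        fruits = [
            make_trajectory(
                organ_id=f"f{i}",
                organ_type="fruit",
                gdd=[100.0, 1900.0],
                dry_mass=[1.0, 10.0 + i],
            )
            for i in range(5)
        ]
        with pytest.raises(ValueError, match="degenerate"):
            fruit_variability_analysis(fruits)


class TestAgainstGeneratorLabels:
    def test_classification_matches_generation(self, orchard, orchard_tables):
        import warnings

        from orchardgrowth.cli_io import measurements_to_trajectories

        measurements, _ = orchard_tables
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            trajs = measurements_to_trajectories(measurements, orchard.axis)
        truth = {s.shoot_id: s.shoot_class for s in orchard.shoots}
        shoots = classify_shoots(trajs["shoot"])
        for s in shoots:
            assert s.shoot_class == truth[s.organ_id]

    def test_max_trunk_recovers_generating_max(self, orchard, orchard_tables):
        import warnings

        from orchardgrowth.cli_io import measurements_to_trajectories

        measurements, _ = orchard_tables
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            trajs = measurements_to_trajectories(measurements, orchard.axis)
        defs = [t for t in trajs["trunk"] if t.treatment == "DEF"]
        sel = select_max_trunk(defs)
        truth = og.ground_truth(orchard).max_trunk_tree("DEF")
        assert sel.member_ids[0].replace("_T", "") == truth
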