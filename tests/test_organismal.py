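import numpy as np
import pytest

import _oracles
from phenokit.organismal import (
    Bouton,
    BoutonGraph,
    ClimbRecord,
    SurvivalCohort,
    classify_boutons,
    climbing_velocity,
    compare_climbing,
    km_median,
    logrank,
    pixels_to_cm,
    rescue_call,
)
from phenokit.simulate import simulate_boutons


class TestClimbing:
    def test_velocity_from_displacement(self):
        res = climbing_velocity(
            [ClimbRecord("f1", "wt", start_cm=0.0, pos5s_cm=7.5)]
        )
        assert res.velocities_cm_s == [pytest.approx(1.5)]
        assert res.displacements_cm == [pytest.approx(7.5)]

    def test_no_movement_zero_velocity(self):
        res = climbing_velocity(
            [ClimbRecord("f1", "wt", start_cm=2.0, pos5s_cm=2.0)]
        )
        assert res.velocities_cm_s == [0.0]

    def test_fall_gives_negative_velocity(self):
        res = climbing_velocity(
            [ClimbRecord("f1", "wt", start_cm=5.0, pos5s_cm=3.0)]
        )
        assert res.velocities_cm_s == [pytest.approx(-0.4)]

    def test_position_outside_vial_rejected(self):
        with pytest.raises(ValueError, match="outside vial"):
            ClimbRecord("f1", "wt", start_cm=0.0, pos5s_cm=16.0)

    def test_pixel_calibration_matches_hand_conversion(self):
        # 15 cm vial imaged over 600 px: 1 px = 0.025 cm
        px = [0.0, 120.0, 600.0]
        cm = pixels_to_cm(px, vial_length_px=600.0)
        assert cm == pytest.approx([0.0, 3.0, 15.0])
        rec = ClimbRecord("f1", "wt", start_cm=cm[0], pos5s_cm=cm[1])
        res = climbing_velocity([rec])
        assert res.velocities_cm_s == [pytest.approx(120.0 * 15.0 / 600.0 / 5.0)]


class TestCompareClimbing:
    def test_identical_groups(self):
        t, p = compare_climbing([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_extreme_separation(self):
        t, p = compare_climbing([0.0, 0.0, 0.0, 0.0], [5.0, 5.0, 5.0, 5.0001])
        assert abs(t) > 100
        assert p < 1e-6

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compare_climbing([1.0], [1.0, 2.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_welch_formula(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(1.0, 0.5, size=rng.integers(5, 20))
        b = rng.normal(1.3, 1.5, size=rng.integers(5, 20))
        t, p = compare_climbing(a, b)
        t_ref, p_ref = _oracles.welch_t(a, b)
        assert t == pytest.approx(t_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-10)


class TestClassifyBoutons:
    def test_three_bouton_chain_all_mature(self):
        g = BoutonGraph("j1", [Bouton(f"b{i}", branch="br", position=i)
                               for i in range(3)])
        cls = classify_boutons(g)
        assert cls.n_mature == 3 and cls.n_satellite == 0

    def test_chain_of_two_plus_sprout(self):
        g = BoutonGraph(
            "j1",
            [
                Bouton("b0", branch="br", position=0),
                Bouton("b1", branch="br", position=1),
                Bouton("s0", sprout_of="b0"),
            ],
        )
        cls = classify_boutons(g)
        assert cls.labels == {"b0": "mature", "b1": "mature", "s0": "satellite"}

    def test_isolated_on_branch_bouton_is_satellite(self):
        g = BoutonGraph(
            "j1",
            [
                Bouton("b0", branch="br", position=0),
                Bouton("b1", branch="br", position=1),
                Bouton("b5", branch="br", position=5),
            ],
        )
        cls = classify_boutons(g)
        assert cls.labels["b5"] == "satellite"
        assert cls.n_mature == 2

    def test_dangling_sprout_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            BoutonGraph("j1", [Bouton("s0", sprout_of="ghost")])

    def test_duplicate_position_rejected(self):
        with pytest.raises(ValueError, match="duplicate position"):
            BoutonGraph(
                "j1",
                [Bouton("a", branch="br", position=0),
                 Bouton("b", branch="br", position=0)],
            )

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_adjacency_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        chains = [int(c) for c in rng.integers(1, 6, size=rng.integers(1, 5))]
        sim = simulate_boutons(chains, n_satellites=int(rng.integers(0, 4)),
                               seed=seed)
        cls = classify_boutons(sim.graph)
        assert cls.labels == _oracles.bouton_labels_by_adjacency(sim.graph)
        assert cls.labels == sim.true_labels
        assert cls.n_mature + cls.n_satellite == len(sim.graph.boutons)

    def test_extending_chain_never_demotes(self):
        base = [Bouton("b0", branch="br", position=0),
                Bouton("b1", branch="br", position=1)]
        before = classify_boutons(BoutonGraph("j", list(base))).labels
        after = classify_boutons(
            BoutonGraph("j", base + [Bouton("b2", branch="br", position=2)])
        ).labels
        for bid, lab in before.items():
            if lab == "mature":
                assert after[bid] == "mature"


class TestKmMedian:
    def test_uncensored_simple(self):
        c = SurvivalCohort("g", days=[10, 20, 30], events=[1, 1, 1])
        assert km_median(c) == 20

    def test_all_same_day(self):
        c = SurvivalCohort("g", days=[7, 7, 7], events=[1, 1, 1])
        assert km_median(c) == 7

    def test_even_size_uncensored_lower_middle(self):
        # S(10) = 0.5 exactly -> product-limit median is the lower middle value
        c = SurvivalCohort("g", days=[10, 20], events=[1, 1])
        assert km_median(c) == 10

    def test_hand_computed_censored_table(self):
        # 6 subjects: censored at 5 and 15, deaths at 10 (x2), 20, 25
        # S(10) = 1 * (1 - 2/5) = 0.6 ; S(20) = 0.6 * (1 - 1/2) = 0.3 <= 0.5
        days = [5, 10, 10, 15, 20, 25]
        events = [0, 1, 1, 0, 1, 1]
        c = SurvivalCohort("g", days=days, events=events)
        curve = _oracles.km_survival_curve(days, events)
        assert curve == [(10, pytest.approx(0.6)), (20, pytest.approx(0.3)),
                         (25, pytest.approx(0.0))]
        assert km_median(c) == 20

    def test_undefined_median_errors(self):
        c = SurvivalCohort("g", days=[10, 20, 30, 40], events=[1, 0, 0, 0])
        with pytest.raises(ValueError, match="median undefined"):
            km_median(c)

    def test_uncensored_median_matches_sample_median_odd_n(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            days = rng.integers(1, 60, size=21).tolist()
            c = SurvivalCohort("g", days=days, events=[1] * 21)
            assert km_median(c) == float(np.median(days))


class TestLogrank:
    def test_identical_cohorts(self):
        a = SurvivalCohort("a", days=[5, 10, 15, 20], events=[1, 1, 1, 1])
        b = SurvivalCohort("b", days=[5, 10, 15, 20], events=[1, 1, 1, 1])
        stat, p = logrank(a, b)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_disjoint_early_late(self):
        a = SurvivalCohort("a", days=list(range(5, 15)), events=[1] * 10)
        b = SurvivalCohort("b", days=list(range(40, 50)), events=[1] * 10)
        stat, p = logrank(a, b)
        assert stat > 15
        assert p < 1e-4

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(9)
        a = SurvivalCohort("a", days=rng.integers(1, 40, 15).tolist(),
                           events=[1] * 15)
        b = SurvivalCohort("b", days=rng.integers(1, 50, 12).tolist(),
                           events=[1] * 12)
        assert logrank(a, b)[0] == pytest.approx(logrank(b, a)[0], rel=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_oe_formula_and_permutation(self, seed):
        rng = np.random.default_rng(seed)
        days_a = rng.integers(5, 40, size=20)
        days_b = rng.integers(10, 50, size=20)
        ev_a = (rng.random(20) < 0.9).astype(int)
        ev_b = (rng.random(20) < 0.9).astype(int)
        a = SurvivalCohort("a", days_a.tolist(), ev_a.tolist())
        b = SurvivalCohort("b", days_b.tolist(), ev_b.tolist())
        stat, p = logrank(a, b)
        ref = _oracles.logrank_oe(days_a, ev_a, days_b, ev_b)
        assert stat == pytest.approx(ref, rel=1e-9)
        p_perm = _oracles.logrank_permutation_p(
            days_a, ev_a, days_b, ev_b, n_perm=2000, seed=seed
        )
        # chi-square p and permutation p agree within Monte-Carlo error
        assert p == pytest.approx(p_perm, abs=4 * np.sqrt(p_perm * (1 - p_perm) / 2000) + 0.01)


class TestRescueCall:
    def _cohort(self, days, group="g"):
        return SurvivalCohort(group, days=days, events=[1] * len(days))

    def test_exactly_five_percent_not_rescued(self):
        control = self._cohort([10] * 5 + [20] * 5 + [30] * 5, "c")
        treatment = self._cohort([10] * 5 + [21] * 5 + [30] * 5, "t")
        res = rescue_call(control, treatment)
        assert res.median_control == 20 and res.median_treatment == 21
        assert res.median_increase_pct == pytest.approx(5.0)
        assert not res.rescued  # strict > 5%

    def test_ten_percent_with_significance_rescued(self):
        control = self._cohort([20] * 30, "c")
        treatment = self._cohort([22] * 30, "t")
        res = rescue_call(control, treatment)
        assert res.median_increase_pct == pytest.approx(10.0)
        assert res.p_value < 0.001
        assert res.rescued

    def test_ten_percent_without_significance_not_rescued(self):
        control = self._cohort([10, 20, 20, 30], "c")
        treatment = self._cohort([10, 22, 22, 30], "t")
        res = rescue_call(control, treatment)
        assert res.median_increase_pct == pytest.approx(10.0)
        assert res.p_value > 0.05
        assert not res.rescued

    def test_monotone_in_treatment_shift(self):
        control = self._cohort([18, 19, 20, 21, 22] * 6, "c")
        base_days = [20, 21, 22, 23, 24] * 6
        prev_increase = -np.inf
        for shift in [0, 2, 4, 8]:
            res = rescue_call(control, self._cohort([d + shift for d in base_days], "t"))
            assert res.median_increase_pct >= prev_increase
            prev_increase = res.median_increase_pct
            # once significant and above margin, larger shifts never flip it off
            if shift >= 4:
                assert res.rescued
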