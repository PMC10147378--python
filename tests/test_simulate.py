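import numpy as np
import pytest

from conftest import assert_trees_equal
from phenokit import morphometry, sholl, swc
from phenokit.organismal import km_median, rescue_call
from phenokit.simulate import (
    CohortSimParams,
    NeuronSimParams,
    simulate_boutons,
    simulate_coloc_pair,
    simulate_neuron,
    simulate_neuron_with_truth,
    simulate_population,
    simulate_puncta_image,
    simulate_survival,
)
from phenokit.imaging import detect_puncta, pearson_colocalization, size_frequency
from phenokit.organismal import classify_boutons


class TestSimulateNeuron:
    def test_straight_stems_closed_form(self):
        params = NeuronSimParams(k0=None, stems=4, p_branch=0.0, p_term=0.0,
                                 r_max=20.0, seed=5)
        tree = simulate_neuron(params)
        prof = sholl.sholl_profile(tree)
        assert np.all(prof.counts[:20] == 4)
        m = morphometry.summarize_morphometry(tree)
        assert m.primary_neurite_count == 4
        assert m.branch_point_count == 0

    def test_same_seed_identical(self):
        t1 = simulate_neuron(NeuronSimParams(seed=42))
        t2 = simulate_neuron(NeuronSimParams(seed=42))
        assert_trees_equal(t1, t2, coord_tol=0.0)

    def test_different_seeds_differ(self):
        t1 = simulate_neuron(NeuronSimParams(seed=1))
        t2 = simulate_neuron(NeuronSimParams(seed=2))
        assert len(t1) != len(t2) or any(
            a.x != b.x for a, b in zip(t1.nodes, t2.nodes)
        )

    def test_degenerate_params_rejected(self):
        with pytest.raises(ValueError, match="degenerate profile"):
            simulate_neuron(NeuronSimParams(r_max=2.0, step=1.0))
        with pytest.raises(ValueError, match="degenerate profile"):
            simulate_neuron(
                NeuronSimParams(k0=None, stems=1, p_term=1.0, p_branch=0.0)
            )

    @pytest.mark.parametrize("seed", range(15))
    def test_bookkeeping_matches_sholl_counts(self, seed):
        # conservation: the generator's live-segment count per radius equals
        # the circle-crossing count of the Sholl module
        tree, radii, counts = simulate_neuron_with_truth(
            NeuronSimParams(seed=seed)
        )
        prof = sholl.sholl_profile(tree, step=1.0)
        n = counts.size
        assert prof.counts[:n].tolist() == counts.tolist()
        assert np.all(prof.counts[n:] == 0)

    def test_generated_trees_are_valid(self):
        for seed in range(10):
            tree = simulate_neuron(NeuronSimParams(seed=seed))
            assert swc.validate_tree(tree) == []


class TestSimulatePopulation:
    def test_minimal_run_round_trips(self, tmp_path):
        pop = simulate_population(2, NeuronSimParams(r_max=10.0, seed=0))
        for i, tree in enumerate(pop.trees_a + pop.trees_b):
            path = tmp_path / f"t{i}.swc"
            swc.write_swc(tree, path)
            assert_trees_equal(tree, swc.read_swc(path))

    def test_identical_params_no_group_difference(self):
        ps = []
        for seed in range(8):
            params = NeuronSimParams(r_max=25.0, seed=seed)
            pop = simulate_population(10, params, params)
            tl_a = [morphometry.summarize_morphometry(t).total_path_length
                    for t in pop.trees_a]
            tl_b = [morphometry.summarize_morphometry(t).total_path_length
                    for t in pop.trees_b]
            ps.append(morphometry.compare_groups({"a": tl_a, "b": tl_b}).p_value)
        # identical generating process: p-values should look uniform, not small
        assert np.median(ps) > 0.1

    def test_doubled_decay_reduces_total_length(self):
        wins = 0
        for seed in range(10):
            pa = NeuronSimParams(k0=0.08, r_max=30.0, seed=seed)
            pb = NeuronSimParams(k0=0.16, r_max=30.0, seed=seed)
            pop = simulate_population(8, pa, pb)
            mean_a = np.mean(
                [morphometry.summarize_morphometry(t).total_path_length
                 for t in pop.trees_a]
            )
            mean_b = np.mean(
                [morphometry.summarize_morphometry(t).total_path_length
                 for t in pop.trees_b]
            )
            wins += mean_b < mean_a
        assert wins >= 9


class TestSimulateSurvival:
    def test_median_recovered_without_censoring(self):
        params = CohortSimParams(n_per_group=400,
                                 medians={"g": 20.0},
                                 censoring_fraction=0.0, seed=3)
        cohort = simulate_survival(params)["g"]
        assert abs(km_median(cohort) - 20.0) <= 1.0

    def test_deterministic(self):
        p = CohortSimParams(n_per_group=50, medians={"g": 15.0},
                            censoring_fraction=0.2, seed=9)
        c1 = simulate_survival(p)["g"]
        c2 = simulate_survival(p)["g"]
        assert c1.days == c2.days and c1.events == c2.events

    def test_censoring_fraction_applied(self):
        p = CohortSimParams(n_per_group=200, medians={"g": 20.0},
                            censoring_fraction=0.25, seed=1)
        c = simulate_survival(p)["g"]
        assert c.n - c.n_events == 50

    def test_power_for_thirty_percent_median_shift(self):
        hits = 0
        for seed in range(5):
            cohorts = simulate_survival(
                CohortSimParams(
                    n_per_group=100,
                    medians={"control": 20.0, "treatment": 26.0},
                    censoring_fraction=0.05, seed=seed,
                )
            )
            res = rescue_call(cohorts["control"], cohorts["treatment"])
            hits += res.rescued
        assert hits >= 4


class TestSimulateColoc:
    def test_rho_one_exact(self):
        ch1, ch2, roi = simulate_coloc_pair(rho_target=1.0, seed=0)
        res = pearson_colocalization(ch1, ch2, roi, thresholds=(0.0, 0.0))
        assert res.rho == 1.0

    @pytest.mark.parametrize("rho", [0.0, -0.8])
    def test_rho_recovered_within_sampling_error(self, rho):
        ch1, ch2, roi = simulate_coloc_pair(rho_target=rho, seed=2)
        res = pearson_colocalization(ch1, ch2, roi, thresholds=(0.0, 0.0))
        assert res.rho == pytest.approx(rho, abs=0.05)

    def test_channels_nonnegative(self):
        ch1, ch2, _ = simulate_coloc_pair(rho_target=-0.5, seed=3)
        assert ch1.data.min() >= 0 and ch2.data.min() >= 0


class TestSimulatePunctaImage:
    def test_five_disks_detected_with_centroids(self):
        spots = [((30.0, 30.0), 2.0), ((30.0, 100.0), 3.0), ((100.0, 30.0), 4.0),
                 ((100.0, 100.0), 2.5), ((64.0, 64.0), 3.5)]
        ch, truth = simulate_puncta_image(shape=(128, 128), puncta=spots,
                                          pixel_size=0.5, seed=0)
        found = detect_puncta(ch, threshold="otsu", min_area=4)
        assert len(found) == len(truth) == 5
        for t in truth.puncta:
            best = min(
                found.puncta,
                key=lambda p: (p.centroid[0] - t.centroid[0]) ** 2
                + (p.centroid[1] - t.centroid[1]) ** 2,
            )
            assert abs(best.centroid[0] - t.centroid[0]) <= 1.0
            assert abs(best.centroid[1] - t.centroid[1]) <= 1.0

    def test_empty_background_yields_no_detections(self):
        ch, truth = simulate_puncta_image(shape=(128, 128), puncta=[], seed=4)
        assert len(truth) == 0
        assert len(detect_puncta(ch, threshold="otsu", min_area=4)) == 0

    def test_constructed_diameters_hit_cutoff_fractions(self):
        spots = [((40.0, 40.0), 2.0), ((40.0, 120.0), 4.0), ((120.0, 80.0), 6.0)]
        ch, truth = simulate_puncta_image(shape=(160, 160), puncta=spots,
                                          pixel_size=0.5, seed=1)
        found = detect_puncta(ch, threshold="otsu", min_area=4)
        sf = size_frequency(found, cutoffs=[5.0, 10.0])
        assert sf.fractions[5.0] == pytest.approx(2 / 3)
        assert sf.fractions[10.0] == pytest.approx(1 / 3)

    def test_out_of_frame_rejected(self):
        with pytest.raises(ValueError, match="outside frame"):
            simulate_puncta_image(shape=(64, 64), puncta=[((60.0, 60.0), 4.0)],
                                  pixel_size=1.0)

    def test_overlap_rejected_unless_allowed(self):
        spots = [((32.0, 32.0), 4.0), ((34.0, 32.0), 4.0)]
        with pytest.raises(ValueError, match="overlaps"):
            simulate_puncta_image(shape=(64, 64), puncta=spots, pixel_size=1.0)
        ch, truth = simulate_puncta_image(shape=(64, 64), puncta=spots,
                                         pixel_size=1.0, allow_overlap=True)
        assert len(truth) == 2


class TestSimulateBoutons:
    def test_known_configuration(self):
        sim = simulate_boutons([3, 2], n_satellites=2, seed=0)
        cls = classify_boutons(sim.graph)
        assert cls.n_mature == 5 and cls.n_satellite == 2

    def test_single_bouton_chain_is_satellite(self):
        sim = simulate_boutons([1], seed=0)
        cls = classify_boutons(sim.graph)
        assert cls.n_mature == 0 and cls.n_satellite == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_label_recovery(self, seed):
        rng = np.random.default_rng(seed)
        chains = [int(c) for c in rng.integers(1, 7, size=rng.integers(1, 6))]
        sim = simulate_boutons(chains, n_satellites=int(rng.integers(0, 5)),
                               seed=seed)
        assert classify_boutons(sim.graph).labels == sim.true_labels
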