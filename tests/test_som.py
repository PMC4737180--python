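import numpy as np
import pytest

from fsomtype.dtw import dtw_distance
from fsomtype.som import (Neuron, SOMGrid, adjust_neuron, find_bmu,
                          init_grid, nmi, train)
from fsomtype.synthetic import ShapeSpec, default_shapes, make_profiles


def neuron(weights):
    w = np.asarray(weights, float)
    return Neuron(0, 0, w.copy(), np.zeros(w.shape[0]))


class TestInitGrid:
    def test_same_seed_identical_prototypes(self, four_family_mixture):
        profiles, _ = four_family_mixture
        g1 = init_grid(2, 2, profiles, seed=5)
        g2 = init_grid(2, 2, profiles, seed=5)
        for a, b in zip(g1.neurons, g2.neurons):
            np.testing.assert_array_equal(a.weights, b.weights)

    def test_grid_equal_to_n_profiles_is_permutation(self, four_family_mixture):
        profiles, _ = four_family_mixture
        subset = profiles[:6]
        g = init_grid(2, 3, subset, seed=1)
        chosen = {tuple(n.weights) for n in g.neurons}
        available = {tuple(p.values) for p in subset}
        assert chosen == available

    def test_sampling_without_replacement(self, four_family_mixture):
        profiles, _ = four_family_mixture
        g = init_grid(2, 2, profiles, seed=3)
        assert len({tuple(n.weights) for n in g.neurons}) == 4

    def test_too_few_profiles_rejected(self, four_family_mixture):
        profiles, _ = four_family_mixture
        with pytest.raises(ValueError, match="at least"):
            init_grid(3, 3, profiles[:5], seed=0)


class TestFindBMU:
    def grid_from(self, vectors, rows, cols):
        neurons = [Neuron(i // cols, i % cols, np.asarray(v, float),
                          np.zeros(len(v))) for i, v in enumerate(vectors)]
        return SOMGrid(rows=rows, cols=cols, neurons=neurons, band_radius=None)

    def test_exact_prototype_wins(self):
        g = self.grid_from([[0, 0], [1, 1], [0.5, 0.5], [0.2, 0.8]], 2, 2)
        bmu, d = find_bmu(g, np.array([1.0, 1.0]))
        assert (bmu.row, bmu.col) == (0, 1) and d == 0.0

    def test_all_identical_ties_to_first_row_major(self):
        g = self.grid_from([[0.5, 0.5]] * 4, 2, 2)
        bmu, _ = find_bmu(g, np.array([0.9, 0.9]))
        assert (bmu.row, bmu.col) == (0, 0)

    def test_bmu_minimizes_over_grid(self, four_family_mixture):
        profiles, _ = four_family_mixture
        g = init_grid(2, 2, profiles, seed=11)
        s = profiles[17].values
        _, d = find_bmu(g, s)
        for n in g.neurons:
            assert d <= dtw_distance(s, n.weights, g.band_radius) + 1e-12


class TestAdjustNeuron:
    def test_diagonal_value_update(self):
        n = neuron([0.0, 0.0])
        adjust_neuron(n, np.array([2.0, 2.0]), alpha=0.5, theta=1.0)
        np.testing.assert_allclose(n.weights, [1.0, 1.0])
        np.testing.assert_allclose(n.acc, [0.0, 0.0])

    def test_zero_alpha_is_noop(self):
        n = neuron([0.3, 0.7])
        adjust_neuron(n, np.array([1.0, 0.0, 1.0]), alpha=0.0, theta=1.0)
        np.testing.assert_array_equal(n.weights, [0.3, 0.7])
        np.testing.assert_array_equal(n.acc, [0.0, 0.0])

    def test_insertion_hand_trace(self):
        # under-long prototype (0,2) against input (0,1,2): the shrinking
        # step triggers one insertion and the result matches the input
        n = neuron([0.0, 2.0])
        adjust_neuron(n, np.array([0.0, 1.0, 2.0]), alpha=1.0, theta=1.0)
        np.testing.assert_allclose(n.weights, [0.0, 1.0, 2.0])
        np.testing.assert_allclose(n.acc, [0.0, 0.0, 0.0])

    def test_deletion_merges_with_successor(self):
        # over-long prototype against a shorter input: expansion steps
        # accumulate negative pressure and one merge fires
        n = neuron([0.0, 0.5, 1.0])
        adjust_neuron(n, np.array([0.0, 1.0]), alpha=1.0, theta=1.0)
        assert n.weights.shape[0] == 2

    def test_deletion_suppressed_at_minimal_length(self):
        n = neuron([0.0, 1.0])
        adjust_neuron(n, np.array([0.5]), alpha=1.0, theta=1.0)
        assert n.weights.shape[0] == 2
        np.testing.assert_array_equal(n.acc, [0.0, 0.0])

    def test_below_threshold_accumulates_without_shift(self):
        n = neuron([0.0, 2.0])
        adjust_neuron(n, np.array([0.0, 1.0, 2.0]), alpha=0.3, theta=1.0)
        assert n.weights.shape[0] == 2   # no trigger yet
        assert n.acc[0] == pytest.approx(0.3)

    def test_accumulator_bounded_by_alpha_times_path(self):
        rng = np.random.default_rng(2)
        n = neuron(rng.random(8))
        before = n.acc.copy()
        s = rng.random(12)
        adjust_neuron(n, s, alpha=0.2, theta=10.0)
        assert np.abs(n.acc - before[:len(n.acc)]).sum() <= 0.2 * (8 + 12)

    def test_full_force_equal_lengths_converges_to_input(self):
        n = neuron([0.1, 0.9, 0.4])
        s = np.array([0.3, 0.3, 0.3])
        adjust_neuron(n, s, alpha=1.0, theta=np.inf)
        np.testing.assert_allclose(n.weights, s)


class TestTrain:
    def test_single_neuron_full_force_absorbs_profile(self, four_family_mixture):
        profiles, _ = four_family_mixture
        p = profiles[0]
        grid = init_grid(1, 1, [p], seed=0, alpha0=1.0, alphaT=1.0,
                         theta=np.inf, band_radius=None)
        grid, assign = train(grid, [p], epochs=1)
        np.testing.assert_allclose(grid.neurons[0].weights, p.values)
        assert assign[p.event_id] == (0, 0)

    def test_two_families_two_neurons_perfect_split(self):
        shapes = default_shapes(("flat-low", "flat-high"), noise_sd=0.02)
        profiles, labels = make_profiles(shapes, 20, seed=3)
        grid = init_grid(1, 2, profiles, seed=3)
        grid, assign = train(grid, profiles)
        pred = [assign[p.event_id][1] for p in profiles]
        assert nmi(pred, labels) == 1.0

    def test_determinism(self, four_family_mixture):
        profiles, _ = four_family_mixture
        runs = []
        for _ in range(2):
            grid = init_grid(2, 2, profiles[:60], seed=9, epochs=5)
            grid, assign = train(grid, profiles[:60])
            runs.append((assign,
                         [n.weights.copy() for n in grid.neurons]))
        assert runs[0][0] == runs[1][0]
        for a, b in zip(runs[0][1], runs[1][1]):
            np.testing.assert_array_equal(a, b)

    def test_classical_som_regression_with_infinite_theta(self):
        """With theta=inf and diagonal-path inputs the FSOM trace equals a
        plain SOM update trace exactly.

        Strictly increasing ramps with noise far below the ramp step make
        every optimal warping path the main diagonal, so the flexible
        update must degenerate to the textbook rule.
        """
        import math

        from fsomtype.profiles import Profile

        rng = np.random.default_rng(21)
        base = np.linspace(0.05, 0.95, 12)
        data = base + rng.normal(0.0, 0.005, size=(14, 12))
        profiles = [Profile(f"e{i}", v.copy(), 6, 20, 3, 3)
                    for i, v in enumerate(data)]
        grid = init_grid(1, 2, profiles, seed=4, theta=np.inf,
                         band_radius=None, epochs=3)
        # independent classical SOM replica with the same schedules;
        # distances summed sequentially, matching IEEE operation order
        protos = [grid.neurons[0].weights.copy(),
                  grid.neurons[1].weights.copy()]
        T = 3
        rng2 = np.random.default_rng(grid.seed)
        for t in range(T):
            alpha_t = grid.alpha0 * (grid.alphaT / grid.alpha0) ** (t / T)
            sigma_t = grid.sigma0 * (grid.sigmaT / grid.sigma0) ** (t / T)
            h = math.ceil(sigma_t)
            for idx in rng2.permutation(len(profiles)):
                v = profiles[idx].values

                def seqdist(w):
                    acc = 0.0
                    for k in range(len(w)):
                        acc = (v[k] - w[k]) ** 2 + acc
                    return acc / len(w)

                b = 0 if seqdist(protos[0]) <= seqdist(protos[1]) else 1
                for c in range(2):
                    r = abs(c - b)
                    if r <= h:
                        force = alpha_t * math.exp(-(r * r) / (2 * sigma_t ** 2))
                        protos[c] = protos[c] + force * (v - protos[c])
        grid, _ = train(grid, profiles, epochs=3)
        np.testing.assert_array_equal(grid.neurons[0].weights, protos[0])
        np.testing.assert_array_equal(grid.neurons[1].weights, protos[1])

    def test_prototype_lengths_stay_bounded(self, four_family_mixture):
        profiles, _ = four_family_mixture
        grid = init_grid(2, 2, profiles[:80], seed=13, epochs=5)
        grid, _ = train(grid, profiles[:80])
        lengths = [n.weights.shape[0] for n in grid.neurons]
        max_in = max(len(p) for p in profiles[:80])
        assert all(2 <= L <= 2 * max_in for L in lengths)


class TestNMI:
    def test_identical_labelings_score_one(self):
        assert nmi([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_permuted_label_names_score_one(self):
        assert nmi([0, 0, 1, 1, 2], [5, 5, 3, 3, 9]) == 1.0

    def test_independent_partitions_score_zero(self):
        assert nmi([0, 0, 1, 1], [0, 1, 0, 1]) == 0.0

    def test_single_cluster_both_sides_defined_as_one(self):
        assert nmi([0, 0, 0], [1, 1, 1]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nmi([0, 1], [0, 1, 1])

    def test_matches_sklearn_arithmetic_variant(self):
        from sklearn.metrics import normalized_mutual_info_score
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 4, size=30)
            b = rng.integers(0, 3, size=30)
            expect = normalized_mutual_info_score(a, b,
                                                  average_method="arithmetic")
            assert nmi(a, b) == pytest.approx(expect, abs=1e-10)


def test_grid_size_stability_after_meta_merge(four_family_mixture):
    """Typings from a 2x2 and a 3x3 grid agree (NMI >= 0.7) once both are
    merged to four super-groups via median-profile meta-clustering."""
    from fsomtype.meta import median_profiles, meta_cluster

    profiles, _ = four_family_mixture

    def merged_labels(rows, cols, seed):
        grid = init_grid(rows, cols, profiles, seed=seed)
        grid, assignments = train(grid, profiles)
        med = median_profiles(assignments, profiles, sample="s",
                              min_members=5)
        grouping = meta_cluster(med, n_groups=4)
        cg = {(m.row, m.col): grouping.group_of[m.key] for m in med}
        return {e: cg[rc] for e, rc in assignments.items() if rc in cg}

    a = merged_labels(2, 2, 7)
    b = merged_labels(3, 3, 8)
    common = sorted(set(a) & set(b))
    assert len(common) >= 180  # min_members may drop a few events
    assert nmi([a[e] for e in common], [b[e] for e in common]) >= 0.7
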