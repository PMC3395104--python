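import numpy as np
import pandas as pd
import pytest

import somkit as sk
from somkit.supervised import encode_classes, percent_cc, predict, train_supervised

from conftest import two_cluster_data


def _ladder_codebook(n_cells=5, spacing=10.0):
    """A 1-row map whose cells sit at 0, 10, 20, ... on one axis, so map
    distance and feature distance agree and BMUs can be placed by hand."""
    grid = sk.GridSpec(1, n_cells)
    W = np.zeros((n_cells, 2))
    W[:, 0] = spacing * np.arange(n_cells)
    return sk.Codebook(W, grid)


class TestEncodeClasses:
    def test_one_hot_and_round_trip(self):
        labels = ["B", "A", "C", "A"]
        C = encode_classes(labels, ["A", "B", "C"])
        assert np.array_equal(C, [[0, 1, 0], [1, 0, 0], [0, 0, 1], [1, 0, 0]])
        decoded = [["A", "B", "C"][k] for k in C.argmax(axis=1)]
        assert decoded == labels

    def test_fuzzy_pass_through(self):
        fuzzy = np.array([[0.5, 0.5, 0.0], [0.2, 0.3, 0.5]])
        assert np.array_equal(encode_classes(fuzzy, ["A", "B", "C"]), fuzzy)
        with pytest.raises(ValueError):
            encode_classes(np.array([[1.5, 0.0]]), ["A", "B"])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="'D'"):
            encode_classes(["A", "D"], ["A", "B"])


class TestTrainSupervised:
    def test_zero_weight_is_bitwise_unsupervised(self, oils, small_schedule):
        grid = sk.GridSpec(8, 6)
        uns = sk.train(oils.data, grid=grid, schedule=small_schedule)
        sup = train_supervised(
            oils.data, oils.factors["class"], grid=grid, schedule=small_schedule, class_weight=0.0
        )
        assert np.array_equal(sup.codebook.W, uns.codebook.W)

    def test_invalid_weight_rejected(self, oils):
        with pytest.raises(ValueError):
            train_supervised(oils.data, oils.factors["class"], class_weight=1.5)

    def test_single_class_warns(self):
        data = sk.Dataset(np.random.default_rng(0).standard_normal((10, 3)))
        sched = sk.TrainingSchedule(T=50, sigma0=1, seed=0)
        with pytest.warns(UserWarning, match="single-class"):
            train_supervised(data, ["x"] * 10, grid=sk.GridSpec(3, 3),
                             schedule=sched, class_weight=0.5)

    def test_class_planes_stay_in_unit_interval(self):
        data, labels = two_cluster_data(0)
        sched = sk.TrainingSchedule(T=800, sigma0=2, seed=1)
        som = train_supervised(data, labels, grid=sk.GridSpec(5, 4), schedule=sched,
                               class_weight=0.7)
        assert som.class_planes.min() >= 0.0 and som.class_planes.max() <= 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_separable_classes_form_disjoint_regions(self, seed):
        data, labels = two_cluster_data(seed, gap=15.0)
        sched = sk.TrainingSchedule(T=1500, sigma0=2.5, seed=seed)
        som = train_supervised(data, labels, grid=sk.GridSpec(6, 5), schedule=sched,
                               class_weight=0.5)
        cells_a = set(som.training_bmus[labels == "a"])
        cells_b = set(som.training_bmus[labels == "b"])
        assert cells_a.isdisjoint(cells_b)

    def test_null_factor_training_cc_grows_with_class_weight(self, saliva):
        """On a factor with no real effect, heavier supervision inflates
        the training-set %CC (overfitting by construction)."""
        day = saliva.factors["day"].to_numpy()
        grid = sk.GridSpec(12, 8)
        means = []
        for w in (0.0, 0.5, 0.95):
            ccs = []
            for seed in range(3):
                sched = sk.TrainingSchedule(T=2000, sigma0=3, seed=seed)
                som = train_supervised(saliva.data, day, grid=grid, schedule=sched,
                                       class_weight=w)
                ccs.append(percent_cc(som.predict(saliva.data.X), day))
            means.append(np.mean(ccs))
        assert means[2] > means[0] + 10  # strong supervision inflates the fit
        assert means[2] > 80


class TestPredict:
    def test_equidistant_boundary_gives_fifty_fifty(self):
        cb = _ladder_codebook()
        training_bmus = np.array([0, 4])
        labels = np.array(["A", "B"])
        res = predict(cb, training_bmus, labels, cb.W[[2]])
        assert res.fractions.iloc[0]["A"] == pytest.approx(0.5)
        assert res.fractions.iloc[0]["B"] == pytest.approx(0.5)

    def test_training_sample_recovers_its_class(self):
        cb = _ladder_codebook()
        res = predict(cb, np.array([0, 4]), np.array(["A", "B"]), cb.W[[0]])
        assert res.fractions.iloc[0]["A"] == 1.0

    def test_fractions_match_class_map_at_test_bmu(self):
        rng = np.random.default_rng(11)
        grid = sk.GridSpec(6, 6)
        cb = sk.Codebook(rng.standard_normal((36, 4)) * 5, grid)
        bmus = rng.integers(0, 36, 12)
        labels = rng.choice(["A", "B", "C"], 12)
        X_test = rng.standard_normal((8, 4)) * 5
        res = predict(cb, bmus, labels, X_test)
        cm = sk.class_map(bmus, labels, grid)
        test_bmus = sk.assign_bmus(cb, X_test)
        assert np.allclose(res.fractions.to_numpy(), cm.F[test_bmus])

    def test_empty_test_set(self):
        cb = _ladder_codebook()
        res = predict(cb, np.array([0, 4]), np.array(["A", "B"]), np.zeros((0, 2)))
        assert len(res.fractions) == 0


class TestPercentCC:
    def test_perfect_assignment(self):
        f = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], columns=["A", "B"])
        res = sk.ClassificationResult(f, np.array([0, 1]))
        assert percent_cc(res, ["A", "B"]) == 100.0

    def test_hand_worked_apportioning(self):
        """Four samples: two fully right, one 50/50 tie, one fully wrong
        -> (1 + 1 + 0.5 + 0) / 4 * 100 = 62.5."""
        f = pd.DataFrame(
            [[1.0, 0.0], [0.0, 1.0], [0.5, 0.5], [1.0, 0.0]], columns=["A", "B"]
        )
        res = sk.ClassificationResult(f, np.arange(4))
        assert percent_cc(res, ["A", "B", "A", "B"]) == pytest.approx(62.5)

    def test_empty_rejected(self):
        f = pd.DataFrame(np.zeros((0, 2)), columns=["A", "B"])
        with pytest.raises(ValueError):
            percent_cc(sk.ClassificationResult(f, np.array([], dtype=int)), [])

    @pytest.mark.parametrize("seed", range(6))
    def test_separable_holdout_accuracy(self, seed):
        """Held-out %CC is high when the classes are genuinely separable
        (the oils-style four-class layout)."""
        sim = sk.gen_oils_like(seed=seed + 10)
        rng = np.random.default_rng(seed)
        labels = sim.factors["class"].to_numpy()
        test_idx = np.concatenate(
            [rng.choice(np.flatnonzero(labels == c), 2, replace=False)
             for c in np.unique(labels)]
        )
        train_mask = np.ones(sim.data.n_samples, bool)
        train_mask[test_idx] = False
        train_data = sk.Dataset(sim.data.X[train_mask])
        sched = sk.TrainingSchedule(T=3000, sigma0=3, seed=seed)
        som = train_supervised(train_data, labels[train_mask], grid=sk.GridSpec(14, 9),
                               schedule=sched, class_weight=0.5)
        cc = percent_cc(som.predict(sim.data.X[test_idx]), labels[test_idx])
        assert cc >= 95.0
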