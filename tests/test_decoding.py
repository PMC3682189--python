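"""Decoder core: searchlights, linear SVM, ECOC/Hamming, LOTO CV, leakage."""

import itertools

import numpy as np
import pytest

from mtldecode.core import RoiMask, TrialPatternSet
from mtldecode.decoding import (
    EcocCodebook,
    LinearClassifier,
    SearchlightDecoder,
    _run_fold,
    build_searchlights,
    ecoc_predict,
    ecoc_train,
    exhaustive_codebook,
    loto_crossval,
    score_searchlight,
    select_features,
    train_binary,
)
from tests.conftest import decode_single_roi


def _patterns(X, y, roi="HC", hemi="R"):
    X = np.asarray(X, dtype=float)
    coords = np.column_stack(
        [np.arange(X.shape[1]), np.zeros(X.shape[1], int), np.zeros(X.shape[1], int)]
    )
    return TrialPatternSet(X=X, y=np.asarray(y), voxel_coords=coords,
                           roi_label=roi, hemisphere=hemi)


class TestSearchlights:
    def test_single_voxel_roi(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        lights = build_searchlights(RoiMask("HC", "L", m))
        assert len(lights) == 1
        assert lights[0].members.tolist() == [0]
        assert lights[0].centre == (2, 2, 2)

    def test_interior_sphere_has_123_members(self):
        # oracle: enumerate integer lattice points with x^2+y^2+z^2 <= 9
        expected = sum(
            1
            for x, y, z in itertools.product(range(-3, 4), repeat=3)
            if x * x + y * y + z * z <= 9
        )
        assert expected == 123
        m = np.ones((9, 9, 9), dtype=bool)
        lights = build_searchlights(RoiMask("HC", "L", m), radius_voxels=3)
        centre_light = [l for l in lights if l.centre == (4, 4, 4)][0]
        assert centre_light.members.size == 123

    def test_corner_sphere_is_truncated(self):
        m = np.ones((9, 9, 9), dtype=bool)
        lights = build_searchlights(RoiMask("HC", "L", m), radius_voxels=3)
        corner = [l for l in lights if l.centre == (0, 0, 0)][0]
        assert corner.members.size < 123
        # oracle: octant of the sphere
        expected = sum(
            1
            for x, y, z in itertools.product(range(0, 4), repeat=3)
            if x * x + y * y + z * z <= 9
        )
        assert corner.members.size == expected

    def test_centre_always_member_and_members_in_roi(self):
        m = np.zeros((7, 7, 7), dtype=bool)
        m[2:5, 2:5, 2:5] = True
        lights = build_searchlights(RoiMask("HC", "L", m), radius_voxels=2)
        coords = np.argwhere(m)
        for l in lights:
            assert l.centre_index in l.members
            for idx in l.members:
                d2 = ((coords[idx] - np.array(l.centre)) ** 2).sum()
                assert d2 <= 4


class TestTrainBinary:
    def test_symmetric_margin_boundary_at_zero(self):
        clf = train_binary(np.array([[-1.0], [1.0]]), np.array([-1, 1]))
        assert clf.bias == pytest.approx(0.0, abs=1e-6)
        assert clf.weights[0] > 0
        assert clf.predict(np.array([[0.5]]))[0] == 1
        assert clf.predict(np.array([[-0.5]]))[0] == -1

    def test_duplicated_points_leave_boundary_unchanged(self, rng):
        # the margin depends on support vectors only, so duplicating
        # clearly non-support points cannot move the boundary
        X = rng.normal(size=(10, 3))
        y = np.where(X[:, 0] > 0, 1, -1)
        X[:, 0] += y * 2.0  # make separable with margin
        a = train_binary(X, y, tol=1e-8)
        margins = y * a.decision_values(X)
        far = np.argsort(margins)[-3:]  # farthest from the boundary
        b = train_binary(np.vstack([X, X[far]]), np.r_[y, y[far]], tol=1e-8)
        probe = rng.normal(size=(20, 3))
        np.testing.assert_allclose(
            a.decision_values(probe), b.decision_values(probe), atol=1e-5
        )

    def test_xor_not_linearly_separable(self):
        X = np.array([[0.0, 0], [1, 1], [0, 1], [1, 0]])
        y = np.array([1, 1, -1, -1])
        clf = train_binary(X, y)
        acc = np.mean(clf.predict(X) == y)
        assert acc <= 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_binary(np.array([[1.0], [2.0]]), np.array([1, 1]))

    def test_matches_sklearn_svc_decision_values(self, rng):
        """The fast LIBSVM path agrees with sklearn's SVC wrapper."""
        from sklearn.svm import SVC

        for _ in range(50):
            n = int(rng.integers(4, 30))
            p = int(rng.integers(1, 40))
            X = rng.normal(size=(n, p))
            y = np.where(rng.random(n) < 0.5, 1, -1)
            if len(np.unique(y)) < 2:
                continue
            C = float(rng.choice([0.1, 1.0, 10.0]))
            ours = train_binary(X, y, C)
            ref = SVC(kernel="linear", C=C).fit(X, y)
            np.testing.assert_allclose(
                ours.decision_values(X),
                ref.decision_function(X),
                atol=1e-6,
            )


class TestEcoc:
    def test_exhaustive_code_sizes(self):
        assert exhaustive_codebook([1, 2, 3]).n_dichotomies == 3
        assert exhaustive_codebook([1, 2]).n_dichotomies == 1
        assert exhaustive_codebook([1, 2, 3, 4]).n_dichotomies == 7

    def test_codebook_invariants_enforced(self):
        with pytest.raises(ValueError, match="constant"):
            EcocCodebook(np.array([1, 2]), np.array([[1, 1], [1, -1]]))
        with pytest.raises(ValueError, match="distinct"):
            EcocCodebook(
                np.array([1, 2, 3]),
                np.array([[1, -1], [-1, 1], [1, -1]]),
            )

    def test_train_produces_one_classifier_per_column(self, rng):
        # one-hot class features: every bipartition is linearly separable
        X = rng.normal(size=(12, 5)) * 0.01
        y = np.repeat([1, 2, 3], 4)
        for c in (1, 2, 3):
            X[y == c, c - 1] += 5.0
        cb = exhaustive_codebook([1, 2, 3])
        clfs = ecoc_train(X, y, cb)
        assert len(clfs) == 3
        # perfectly separable: each binary classifier is perfect in training
        for j, clf in enumerate(clfs):
            col = cb.code[:, j]
            yj = np.array([col[list(cb.classes).index(v)] for v in y])
            assert np.mean(clf.predict(X) == yj) == 1.0

    def test_empty_dichotomy_side_errors_with_column(self, rng):
        X = rng.normal(size=(6, 3))
        y = np.array([2, 2, 2, 3, 3, 3])  # class 1 missing
        cb = exhaustive_codebook([1, 2, 3])
        with pytest.raises(ValueError, match="column"):
            ecoc_train(X, y, cb)

    def test_predict_matches_brute_force_for_all_bit_patterns(self):
        """Hamming decoding oracle over all 2^3 bit vectors."""
        cb = exhaustive_codebook([1, 2, 3])
        for bits in itertools.product([-1, 1], repeat=3):
            # classifiers that output exactly these bits for x = [1]
            clfs = [
                LinearClassifier(weights=np.array([float(b)]), bias=0.0)
                for b in bits
            ]
            pred = ecoc_predict(clfs, cb, np.array([1.0]))
            dists = [(np.array(bits) != cb.code[i]).sum() for i in range(3)]
            best = min(dists)
            brute = cb.classes[min(i for i, d in enumerate(dists) if d == best)]
            assert pred == brute

    def test_tie_breaks_to_lowest_label(self):
        cb = exhaustive_codebook([1, 2, 3])
        # bits (-1,-1,-1): distance 3 to class 1, 1 to class 2 and class 3
        clfs = [LinearClassifier(np.array([-1.0]), 0.0) for _ in range(3)]
        assert ecoc_predict(clfs, cb, np.array([1.0])) == 2

    def test_consistent_bits_select_positive_dichotomy_class(self):
        cb = exhaustive_codebook([1, 2, 3])
        for i, label in enumerate(cb.classes):
            clfs = [
                LinearClassifier(np.array([float(cb.code[i, j])]), 0.0)
                for j in range(3)
            ]
            assert ecoc_predict(clfs, cb, np.array([1.0])) == label


class TestScoreSearchlight:
    def test_perfectly_separable_scores_one(self):
        y = np.repeat([1, 2, 3], 4)
        X = np.zeros((12, 3))
        for c in (1, 2, 3):
            X[y == c, c - 1] = 5.0  # one-hot: all dichotomies separable
        cb = exhaustive_codebook([1, 2, 3])
        assert score_searchlight(X, y, cb) == 1.0
        assert score_searchlight(X, y, cb, scoring="train") == 1.0

    def test_missing_class_rejected(self):
        cb = exhaustive_codebook([1, 2, 3])
        with pytest.raises(ValueError, match="absent"):
            score_searchlight(np.zeros((4, 2)), np.array([1, 1, 2, 2]), cb)

    def test_fast_path_equals_public_ops(self, rng):
        """The optimised nested loop reproduces ecoc_train/ecoc_predict."""
        cb = exhaustive_codebook([1, 2, 3])
        for trial in range(10):
            n_per = int(rng.integers(1, 5))
            y = np.repeat([1, 2, 3], n_per)
            X = rng.normal(size=(len(y), int(rng.integers(1, 6))))
            got = score_searchlight(X, y, cb)
            # reference route via the public operations
            correct = counted = 0
            for t in range(len(y)):
                tr = np.arange(len(y)) != t
                try:
                    clfs = ecoc_train(X[tr], y[tr], cb, allow_partial=True)
                except ValueError:
                    continue
                counted += 1
                correct += int(ecoc_predict(clfs, cb, X[t]) == y[t])
            expected = correct / counted if counted else 0.0
            assert got == pytest.approx(expected)

    def test_three_singleton_trials_score_three_degenerate_folds(self):
        # each nested fold trains on two classes only; the two usable
        # one-vs-rest columns can still point at the held-out class
        X = np.array([[0.0], [10.0], [-10.0]])
        y = np.array([1, 2, 3])
        cb = exhaustive_codebook([1, 2, 3])
        got = score_searchlight(X, y, cb)
        assert 0.0 <= got <= 1.0

    def test_permuted_labels_score_near_chance(self, rng):
        X = rng.normal(size=(18, 6))
        cb = exhaustive_codebook([1, 2, 3])
        accs = []
        for _ in range(60):
            y = rng.permutation(np.repeat([1, 2, 3], 6))
            accs.append(score_searchlight(X, y, cb))
        se = np.sqrt((1 / 3) * (2 / 3) / (60 * 18))
        assert abs(np.mean(accs) - 1 / 3) < 4 * se + 0.02


class TestSelectFeatures:
    def _lights(self, member_sets):
        from mtldecode.decoding import Searchlight

        return [
            Searchlight(centre=(i, 0, 0), members=np.asarray(m, dtype=int),
                        centre_index=i)
            for i, m in enumerate(member_sets)
        ]

    def test_single_searchlight_returned(self, rng):
        X = rng.normal(size=(9, 4))
        y = np.repeat([1, 2, 3], 3)
        lights = self._lights([[0, 1]])
        cb = exhaustive_codebook([1, 2, 3])
        assert select_features(X, y, lights, cb) is lights[0]

    def test_informative_sphere_wins(self, rng):
        y = np.repeat([1, 2, 3], 6)
        X = rng.normal(size=(18, 6))
        X[:, 4] = y * 10.0  # columns {4,5} carry the signal
        lights = self._lights([[0, 1], [2, 3], [4, 5]])
        cb = exhaustive_codebook([1, 2, 3])
        best = select_features(X, y, lights, cb)
        assert best.centre_index == 2

    def test_identical_spheres_tie_break_to_first(self, rng):
        X = rng.normal(size=(9, 2))
        y = np.repeat([1, 2, 3], 3)
        lights = self._lights([[0, 1], [0, 1], [0, 1]])
        cb = exhaustive_codebook([1, 2, 3])
        assert select_features(X, y, lights, cb).centre_index == 0


class TestLotoCrossval:
    def test_class_with_single_trial_rejected(self, rng):
        ps = _patterns(rng.normal(size=(5, 3)), [1, 1, 2, 2, 3])
        with pytest.raises(ValueError, match="fewer than 2"):
            loto_crossval(ps)

    def test_accuracy_definition_and_fold_count(self, rng):
        y = np.repeat([1, 2, 3], 4)
        X = rng.normal(size=(12, 3)) * 0.01
        for c in (1, 2, 3):
            X[y == c, c - 1] += 5.0
        res = loto_crossval(_patterns(X, y))
        assert res.n_folds == 12
        n_correct = sum(f.predicted_label == f.true_label for f in res.folds)
        assert res.accuracy == pytest.approx(n_correct / 12)
        assert res.accuracy == 1.0  # strongly separable

    def test_constant_features_decode_at_chance_level(self):
        y = np.repeat([1, 2, 3], 4)
        X = np.ones((12, 4))
        res = loto_crossval(_patterns(X, y))
        # no information: accuracy cannot exceed the majority/chance band
        assert res.accuracy <= 0.34

    def test_deterministic(self, signal_patterns):
        a = SearchlightDecoder(signal_patterns).fit()
        b = SearchlightDecoder(signal_patterns).fit()
        assert a.to_dict() == b.to_dict()

    def test_planted_signal_recovered(self, signal_patterns):
        res = SearchlightDecoder(signal_patterns).fit()
        assert res.accuracy > 0.8

    def test_result_serialises(self, tmp_path, signal_patterns):
        res = SearchlightDecoder(signal_patterns).fit()
        path = tmp_path / "res.json"
        res.save(path)
        import json

        loaded = json.loads(path.read_text())
        assert loaded["accuracy"] == res.accuracy
        assert len(loaded["folds"]) == res.n_folds
        assert "%" in res.summary()


class TestLeakageGuard:
    def test_heldout_trial_cannot_influence_its_fold(self, rng):
        """Mutating the held-out trial's features changes neither the
        selected searchlight nor the trained classifiers of that fold."""
        y = np.repeat([1, 2, 3], 4)
        X = rng.normal(size=(12, 6))
        ps = _patterns(X, y)
        lights = build_searchlights(ps.voxel_coords, radius_voxels=2)
        cb = exhaustive_codebook([1, 2, 3])
        for t in (0, 5, 11):
            sel_a, clfs_a, _ = _run_fold(X, y, t, lights, cb)
            X_mut = X.copy()
            X_mut[t] = rng.normal(size=6) * 1e6
            sel_b, clfs_b, _ = _run_fold(X_mut, y, t, lights, cb)
            assert sel_a.centre == sel_b.centre
            assert np.array_equal(sel_a.members, sel_b.members)
            for ca, cb_ in zip(clfs_a, clfs_b):
                np.testing.assert_array_equal(ca.weights, cb_.weights)
                assert ca.bias == cb_.bias


class TestCalibrationAndMonotonicity:
    def test_label_permutation_calibration(self, rng, null_patterns):
        """Mean LOTO accuracy over >= 200 label permutations of fixed
        pipeline-generated patterns stays within 3 SE of chance."""
        from mtldecode.core import TrialPatternSet

        ps0 = null_patterns
        n_perm = 200
        n = ps0.n_trials
        accs = []
        for _ in range(n_perm):
            y = rng.permutation(ps0.y.copy())
            ps = TrialPatternSet(
                X=ps0.X, y=y, voxel_coords=ps0.voxel_coords,
                roi_label=ps0.roi_label, hemisphere=ps0.hemisphere,
            )
            accs.append(loto_crossval(ps).accuracy)
        se = np.sqrt((1 / 3) * (2 / 3) / (n_perm * n))
        assert abs(np.mean(accs) - 1 / 3) < 3 * se

    def test_accuracy_monotone_in_signal_amplitude(self):
        """Mean accuracy over seeds is nondecreasing on an amplitude grid."""
        amplitudes = [0.0, 0.4, 1.0]
        means = []
        for amp in amplitudes:
            accs = [
                decode_single_roi(amp, seed, n_per_class=6).accuracy
                for seed in range(20)
            ]
            means.append(np.mean(accs))
        assert means[0] <= means[1] <= means[2]
        assert means[2] > means[0]  # signal genuinely helps
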