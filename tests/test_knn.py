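import numpy as np
import pytest
from sklearn.neighbors import KNeighborsClassifier

import rehabtrack as rt
from rehabtrack.errors import DegenerateGeometryError
from rehabtrack.knn import DEFAULT_EMBED_LANDMARKS, KnnResult
from rehabtrack.pose_io import N_LANDMARKS


def _shift_scale_frame(frame, shift=(0.0, 0.0), scale=1.0):
    lms = tuple(
        rt.Landmark3D(scale * lm.x + shift[0], scale * lm.y + shift[1], lm.z, lm.visibility)
        for lm in frame.landmarks
    )
    return rt.LandmarkFrame(frame.frame_index, frame.timestamp, lms)


class TestEmbedding:
    def test_translation_invariance(self, single_frame):
        e1 = rt.embed_pose(single_frame)
        e2 = rt.embed_pose(_shift_scale_frame(single_frame, shift=(0.3, 0.1)))
        assert np.allclose(e1.vector, e2.vector, atol=1e-9)

    def test_scale_invariance(self, single_frame):
        e1 = rt.embed_pose(single_frame)
        e2 = rt.embed_pose(_shift_scale_frame(single_frame, shift=(0.05, 0.02), scale=2.0))
        assert np.allclose(e1.vector, e2.vector, atol=1e-9)

    def test_zero_torso_is_degenerate(self):
        lms = tuple(rt.Landmark3D(0.5, 0.5) for _ in range(N_LANDMARKS))
        frame = rt.LandmarkFrame(0, 0.0, lms)
        with pytest.raises(DegenerateGeometryError):
            rt.embed_pose(frame)

    def test_embedding_length(self, single_frame):
        e = rt.embed_pose(single_frame)
        assert e.vector.shape == (2 * len(DEFAULT_EMBED_LANDMARKS),)


class TestEuclideanDistance:
    def test_identity_and_pythagoras(self):
        a = rt.PoseEmbedding(np.array([0.0, 0.0]), (), 2)
        b = rt.PoseEmbedding(np.array([3.0, 4.0]), (), 2)
        assert rt.euclidean_distance(a, a) == 0.0
        assert rt.euclidean_distance(a, b) == pytest.approx(5.0)
        assert rt.euclidean_distance(b, a) == pytest.approx(5.0)

    def test_dimension_mismatch(self):
        a = rt.PoseEmbedding(np.zeros(2), (), 2)
        b = rt.PoseEmbedding(np.zeros(3), (), 2)
        with pytest.raises(ValueError, match="mismatch"):
            rt.euclidean_distance(a, b)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            x, y, z = (rt.PoseEmbedding(rng.normal(size=4), (), 2) for _ in range(3))
            assert rt.euclidean_distance(x, z) <= (
                rt.euclidean_distance(x, y) + rt.euclidean_distance(y, z) + 1e-12
            )


def _random_dataset(rng, n, dim=3, k=None, n_classes=2):
    vecs = rng.normal(size=(n, dim))
    labels = rng.choice([f"c{i}" for i in range(n_classes)], size=n)
    samples = [
        rt.PoseSample(rt.PoseEmbedding(v, (), 2), str(l)) for v, l in zip(vecs, labels)
    ]
    k = k or min(10, n)
    return rt.PoseDataset(samples, k=k)


def brute_force_knn(query, data):
    """Exhaustive-search oracle with the documented tie-breaking rules."""
    dists = [
        (rt.euclidean_distance(query, s.embedding), i, s.label)
        for i, s in enumerate(data.samples)
    ]
    nearest = sorted(dists, key=lambda t: (t[0], t[1]))[: data.k]
    votes = {c: 0 for c in data.class_set}
    dsum = {c: 0.0 for c in data.class_set}
    for d, _, lab in nearest:
        votes[lab] += 1
        dsum[lab] += d
    best = max(votes.values())
    tied = sorted(
        (c for c, v in votes.items() if v == best),
        key=lambda c: (dsum[c] / votes[c], c),
    )
    return KnnResult(votes, {c: v / data.k for c, v in votes.items()}, tied[0])


class TestKnnClassify:
    def test_single_class_probability_one(self):
        rng = np.random.default_rng(0)
        vecs = rng.normal(size=(12, 2))
        data = rt.PoseDataset(
            [rt.PoseSample(rt.PoseEmbedding(v, (), 2), "up") for v in vecs], k=10
        )
        res = rt.knn_classify(rt.PoseEmbedding(np.zeros(2), (), 2), data)
        assert res.predicted == "up" and res.probabilities["up"] == 1.0

    def test_vote_fraction_probability(self):
        # 7 near "up" samples, 3 near "down", k = 10
        ups = [rt.PoseSample(rt.PoseEmbedding(np.array([0.0, i * 0.01]), (), 2), "up")
               for i in range(7)]
        downs = [rt.PoseSample(rt.PoseEmbedding(np.array([0.1, i * 0.01]), (), 2), "down")
                 for i in range(3)]
        data = rt.PoseDataset(ups + downs, k=10)
        res = rt.knn_classify(rt.PoseEmbedding(np.zeros(2), (), 2), data)
        assert res.probabilities == {"down": 0.3, "up": 0.7}
        assert res.predicted == "up"

    def test_fewer_samples_than_k_rejected(self):
        vecs = np.zeros((3, 2))
        samples = [rt.PoseSample(rt.PoseEmbedding(v, (), 2), "a") for v in vecs]
        with pytest.raises(ValueError, match="k="):
            rt.PoseDataset(samples, k=5)

    def test_matches_exhaustive_oracle_on_random_datasets(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = int(rng.integers(5, 51))
            data = _random_dataset(rng, n, k=int(rng.integers(1, min(10, n) + 1)),
                                   n_classes=int(rng.integers(2, 4)))
            for _ in range(5):
                q = rt.PoseEmbedding(rng.normal(size=3), (), 2)
                got = rt.knn_classify(q, data)
                want = brute_force_knn(q, data)
                assert got.votes == want.votes
                assert got.predicted == want.predicted
                assert sum(got.votes.values()) == data.k
                assert sum(got.probabilities.values()) == pytest.approx(1.0)

    def test_matches_sklearn_when_untied(self):
        rng = np.random.default_rng(4)
        data = _random_dataset(rng, 40, k=5)
        clf = KNeighborsClassifier(n_neighbors=5).fit(data.matrix, data.labels)
        for _ in range(20):
            q = rng.normal(size=3)
            res = rt.knn_classify(rt.PoseEmbedding(q, (), 2), data)
            votes = sorted(res.votes.values())
            if len(votes) > 1 and votes[-1] == votes[-2]:
                continue  # sklearn breaks exact vote ties differently
            assert res.predicted == clf.predict(q[None, :])[0]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        data = _random_dataset(rng, 30, k=7)
        perm = rng.permutation(30)
        shuffled = rt.PoseDataset([data.samples[i] for i in perm], k=7)
        for _ in range(10):
            q = rt.PoseEmbedding(rng.normal(size=3), (), 2)
            assert rt.knn_classify(q, data).predicted == rt.knn_classify(q, shuffled).predicted


class TestClassifySequence:
    def test_constant_training_pose_full_confidence(self, hip_flexion_session, pose_data):
        data, _ = pose_data
        # a sequence frozen at the resting pose must be "down" with 10 votes
        seq, _ = rt.generate_session(
            rt.MotionProfile(exercise="hip_flexion", reps=0, theta_start=170.0, theta_end=10.0)
        )
        trace = rt.classify_sequence(seq, data)
        down = [c for c in trace.classes if c.endswith("down")][0]
        assert all(p == down for p in trace.predicted)
        assert np.all(trace.votes[:, trace.classes.index(down)] == data.k)

    def test_alpha_one_is_identity(self, hip_flexion_session, pose_data):
        seq, _ = hip_flexion_session
        data, _ = pose_data
        sub = rt.LandmarkSequence(list(seq.frames[:30]), fps=seq.fps)
        trace = rt.classify_sequence(sub, data, smoothing_alpha=1.0)
        assert np.array_equal(trace.smoothed, trace.votes)

    def test_ten_rep_session_counts_ten(self, hip_flexion_session, pose_data):
        seq, truth = hip_flexion_session
        data, _ = pose_data
        trace = rt.classify_sequence(seq, data)
        up = [c for c in trace.classes if c.endswith("up")][0]
        assert rt.count_by_classification(trace, up) == truth.rep_count

    def test_vote_conservation_every_frame(self, hip_flexion_session, pose_data):
        seq, _ = hip_flexion_session
        data, _ = pose_data
        sub = rt.LandmarkSequence(list(seq.frames[:50]), fps=seq.fps)
        trace = rt.classify_sequence(sub, data)
        assert np.all(trace.votes.sum(axis=1) == data.k)


class TestCountByClassification:
    def _trace(self, conf):
        conf = np.asarray(conf, dtype=float)
        votes = np.stack([conf, 10 - conf], axis=1)
        return rt.ClassificationTrace(
            classes=("up", "down"), frame_index=np.arange(len(conf)),
            votes=votes, smoothed=votes, predicted=["up"] * len(conf), k=10,
        )

    def test_constant_full_confidence_counts_once(self):
        assert rt.count_by_classification(self._trace(np.full(20, 10.0)), "up") == 1

    def test_never_reaching_enter_threshold(self):
        assert rt.count_by_classification(self._trace(np.full(20, 5.0)), "up") == 0

    def test_thresholds_must_be_ordered(self):
        with pytest.raises(ValueError):
            rt.count_by_classification(self._trace(np.zeros(3)), "up", 2.0, 8.0)


class TestEvaluateClassifier:
    def test_train_equals_test_k1_is_perfect(self):
        rng = np.random.default_rng(1)
        data = _random_dataset(rng, 20, k=1)
        res = rt.evaluate_classifier(data, data.samples)
        assert res.accuracy == 1.0

    def test_separated_clusters_high_accuracy(self, pose_data):
        data, test = pose_data
        res = rt.evaluate_classifier(data, test)
        assert res.accuracy >= 0.99
        assert set(res.per_class.index) == set(data.class_set)
        assert res.confusion.to_numpy().sum() == len(test)

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(8)
        vecs = rng.normal(size=(200, 4))
        labels = np.array(["a", "b"] * 100)
        rng.shuffle(labels)
        samples = [rt.PoseSample(rt.PoseEmbedding(v, (), 2), str(l))
                   for v, l in zip(vecs, labels)]
        data = rt.PoseDataset(samples[:150], k=10)
        res = rt.evaluate_classifier(data, samples[150:])
        # binomial 95% band around 0.5 for n = 50 is roughly +/- 0.14
        assert 0.3 <= res.accuracy <= 0.7

    def test_empty_test_set_rejected(self):
        rng = np.random.default_rng(1)
        data = _random_dataset(rng, 20)
        with pytest.raises(ValueError, match="empty"):
            rt.evaluate_classifier(data, [])

    def test_dataset_csv_round_trip(self, tmp_path, pose_data):
        data, test = pose_data
        data.to_csv(tmp_path / "train.csv")
        back = rt.PoseDataset.from_csv(tmp_path / "train.csv", k=data.k)
        assert np.allclose(back.matrix, data.matrix)
        res = rt.evaluate_classifier(back, test)
        assert res.accuracy >= 0.99
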