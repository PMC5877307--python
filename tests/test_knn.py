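import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sedmine as sm
from sedmine.errors import ClassificationError, SplitError
from sedmine.knn import STAGE_LABELS, TrainingStore

finite = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False)
vec3 = st.lists(finite, min_size=3, max_size=3)


def brute_force_knn(query, store, k):
    """Exhaustive oracle: sort every (distance, insertion_index) pair."""
    scored = []
    for inst in store.instances:
        d = math.dist(list(query), list(inst.features))
        scored.append((d, inst.insertion_index, inst.label))
    scored.sort()
    top = scored[:k]
    counts = {}
    for _, _, lab in top:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    winners = [lab for lab, c in counts.items() if c == best]
    return top[0][2] if len(winners) > 1 else winners[0]


def random_store(stage, n, dim, seed):
    rng = np.random.default_rng(seed)
    labels = sorted(STAGE_LABELS[stage])
    store = TrainingStore(stage=stage)
    for i in range(n):
        store.add(rng.normal(size=dim), labels[int(rng.integers(len(labels)))])
    return store


class TestEuclidean:
    def test_identity(self):
        x = [1.2, -3.4, 5.6]
        assert sm.euclidean(x, x) == 0.0

    def test_3_4_5(self):
        assert sm.euclidean((0, 0), (3, 4)) == 5.0

    def test_length_mismatch(self):
        with pytest.raises(ClassificationError):
            sm.euclidean([1, 2], [1, 2, 3])

    @settings(max_examples=50, deadline=None)
    @given(vec3, vec3, vec3)
    def test_metric_axioms(self, x, y, z):
        assert sm.euclidean(x, y) == pytest.approx(sm.euclidean(y, x))
        assert sm.euclidean(x, z) <= sm.euclidean(x, y) + sm.euclidean(y, z) + 1e-6


class TestKnnClassify:
    def test_singleton_store(self):
        store = TrainingStore(stage="motion")
        store.add([1.0, 2.0], "still")
        label, idx, dists = sm.knn_classify([0.0, 0.0], store, k=3)
        assert label == "still"
        assert list(idx) == [0]
        assert dists[0] == pytest.approx(math.sqrt(5))

    def test_strict_majority(self):
        store = TrainingStore(stage="motion")
        store.add([0.0], "active")
        store.add([0.1], "active")
        store.add([0.2], "still")
        label, _, _ = sm.knn_classify([0.0], store, k=3)
        assert label == "active"

    def test_vote_tie_goes_to_nearest(self):
        store = TrainingStore(stage="audio")
        store.add([0.1], "tv")
        store.add([0.2], "pc")
        label, _, _ = sm.knn_classify([0.0], store, k=2)
        assert label == "tv"

    def test_distance_tie_goes_to_lower_insertion_index(self):
        store = TrainingStore(stage="motion")
        store.add([1.0], "still")
        store.add([-1.0], "active")
        label, idx, _ = sm.knn_classify([0.0], store, k=1)
        assert label == "still" and list(idx) == [0]

    def test_empty_store_rejected(self):
        with pytest.raises(ClassificationError):
            sm.knn_classify([0.0], TrainingStore(stage="motion"), k=3)

    def test_query_length_mismatch(self):
        store = TrainingStore(stage="motion")
        store.add([0.0, 1.0], "still")
        with pytest.raises(ClassificationError):
            sm.knn_classify([0.0], store)

    @pytest.mark.parametrize("dim", [6, 26])
    def test_matches_brute_force_oracle(self, dim):
        store = random_store("motion", 200, dim, seed=dim)
        rng = np.random.default_rng(dim + 1)
        for _ in range(50):
            q = rng.normal(size=dim)
            label, _, _ = sm.knn_classify(q, store, k=3)
            assert label == brute_force_knn(q, store, 3)

    def test_duplicate_of_true_nearest_never_flips(self):
        rng = np.random.default_rng(5)
        store = random_store("motion", 50, 6, seed=6)
        for _ in range(20):
            q = rng.normal(size=6)
            label, idx, _ = sm.knn_classify(q, store, k=3)
            nearest = store.instances[idx[0]]
            if nearest.label != label:
                continue
            grown = TrainingStore(stage="motion")
            for inst in store.instances:
                grown.add(inst.features, inst.label)
            grown.add(nearest.features, nearest.label)
            label2, _, _ = sm.knn_classify(q, grown, k=3)
            assert label2 == label

    def test_permutation_invariance_without_ties(self):
        store = random_store("audio", 100, 26, seed=17)
        perm = np.random.default_rng(18).permutation(100)
        shuffled = TrainingStore(stage="audio")
        for i in perm:
            shuffled.add(store.instances[i].features, store.instances[i].label)
        rng = np.random.default_rng(19)
        for _ in range(20):
            q = rng.normal(size=26)  # continuous features: exact ties have measure zero
            assert sm.knn_classify(q, store)[0] == sm.knn_classify(q, shuffled)[0]


class TestSplitDataset:
    @staticmethod
    def instances(counts):
        out = []
        for label, n in counts.items():
            out.extend((np.array([float(i)]), label) for i in range(n))
        return out

    def test_exact_sizes_for_ten(self):
        train, val, test = sm.split_dataset(self.instances({"still": 10}), seed=0)
        assert (len(train), len(val), len(test)) == (6, 1, 3)

    def test_stratified_two_classes(self):
        train, val, test = sm.split_dataset(
            self.instances({"still": 10, "active": 10}), seed=1
        )
        for part, per_class in [(train, 6), (val, 1), (test, 3)]:
            labels = [lab for _, lab in part]
            assert labels.count("still") == per_class
            assert labels.count("active") == per_class

    def test_deterministic(self):
        inst = self.instances({"still": 10, "active": 10})
        a = sm.split_dataset(inst, seed=7)
        b = sm.split_dataset(inst, seed=7)
        for pa, pb in zip(a, b):
            assert [(tuple(f), l) for f, l in pa] == [(tuple(f), l) for f, l in pb]

    def test_disjoint_and_exhaustive(self):
        inst = self.instances({"still": 13, "active": 17})
        train, val, test = sm.split_dataset(inst, seed=3)
        seen = sorted(float(f[0]) * 1000 + (lab == "still") for part in (train, val, test) for f, lab in part)
        expected = sorted(float(f[0]) * 1000 + (lab == "still") for f, lab in inst)
        assert seen == expected

    def test_small_class_rejected(self):
        with pytest.raises(SplitError):
            sm.split_dataset(self.instances({"still": 2, "active": 10}))

    def test_bad_ratios_rejected(self):
        with pytest.raises(SplitError):
            sm.split_dataset(self.instances({"still": 10}), ratios=(0.5, 0.1, 0.3))


class TestEvaluate:
    def test_training_points_perfectly_recalled(self):
        store = random_store("motion", 30, 6, seed=21)
        test_set = [(inst.features, inst.label) for inst in store.instances]
        accuracy, confusion = sm.evaluate(store, test_set, k=1)
        assert accuracy == 1.0
        assert np.trace(confusion["matrix"]) == 30

    def test_single_misclassification(self):
        store = TrainingStore(stage="motion")
        store.add([0.0], "still")
        accuracy, confusion = sm.evaluate(store, [(np.array([5.0]), "active")], k=1)
        assert accuracy == 0.0
        m = confusion["matrix"]
        labels = confusion["labels"]
        assert m[labels.index("active")][labels.index("still")] == 1
        assert m.sum() == 1


class TestSerialisation:
    def test_json_round_trip_bit_exact(self):
        store = random_store("audio", 20, 26, seed=33)
        text = store.to_json()
        clone = TrainingStore.from_json(text)
        assert clone.to_json() == text
        for a, b in zip(store.instances, clone.instances):
            assert np.array_equal(a.features, b.features)
            assert a.label == b.label

    def test_json_shape(self):
        store = random_store("motion", 3, 6, seed=34)
        payload = json.loads(store.to_json())
        assert payload["stage"] == "motion"
        assert payload["feature_length"] == 6
        assert len(payload["instances"]) == 3

    def test_wrong_label_for_stage_rejected(self):
        store = TrainingStore(stage="motion")
        with pytest.raises(ClassificationError):
            store.add([0.0], "tv")
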