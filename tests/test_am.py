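"""Associative-memory lifecycle: build, retrain, predict, confidence, ranking."""

import numpy as np
import pytest

import hdscreen as hd
from hdscreen import oracles


class TestBuild:
    def test_one_sample_per_class_prototypes_equal_samples(self, rng):
        s = hd.random_bipolar(32, rng, size=2)
        am = hd.build_associative_memory(s, [0, 1])
        np.testing.assert_array_equal(am.prototypes, s.astype(np.int64))

    def test_duplicating_samples_doubles_prototypes(self, small_binary_memory):
        am, samples, labels = small_binary_memory
        am2 = hd.build_associative_memory(
            np.vstack([samples, samples]), np.concatenate([labels, labels])
        )
        np.testing.assert_array_equal(am2.prototypes, 2 * am.prototypes)
        q = samples[0]
        for k in range(2):
            assert hd.cosine_similarity(am.prototypes[k], q) == pytest.approx(
                hd.cosine_similarity(am2.prototypes[k], q)
            )

    def test_matches_sum_by_label_oracle(self, rng):
        samples = hd.random_bipolar(256, rng, size=200)
        labels = rng.integers(0, 3, size=200)
        am = hd.build_associative_memory(samples, labels, classes=[0, 1, 2])
        np.testing.assert_array_equal(
            am.prototypes, oracles.bundle_by_label(samples, labels, [0, 1, 2])
        )

    def test_order_invariant(self, rng):
        samples = hd.random_bipolar(64, rng, size=30)
        labels = rng.integers(0, 2, size=30)
        perm = rng.permutation(30)
        am1 = hd.build_associative_memory(samples, labels)
        am2 = hd.build_associative_memory(samples[perm], labels[perm])
        np.testing.assert_array_equal(am1.prototypes, am2.prototypes)

    def test_empty_class_and_length_mismatch(self, rng):
        s = hd.random_bipolar(16, rng, size=4)
        with pytest.raises(ValueError, match="no training samples"):
            hd.build_associative_memory(s, [0, 0, 0, 0], classes=[0, 1])
        with pytest.raises(ValueError, match="labels"):
            hd.build_associative_memory(s, [0, 1, 0])


class TestPredict:
    def test_query_equal_to_prototype_wins(self, rng):
        s = hd.random_bipolar(10_000, rng, size=2)
        am = hd.build_associative_memory(s, [0, 1])
        res = hd.predict(am, s[1])
        assert res.predicted_class == 1
        assert res.similarities[1] == pytest.approx(1.0)

    def test_tie_breaks_to_lowest_class_index(self):
        # both prototypes identical -> exact similarity tie -> class 0
        proto = np.array([1, -1, 1, 1], dtype=np.int64)
        am = hd.AssociativeMemory(np.vstack([proto, proto]), np.array([0, 1]))
        assert hd.predict(am, proto.astype(np.int8)).predicted_class == 0

    def test_matches_argmax_cosine_oracle(self, rng):
        samples = hd.random_bipolar(128, rng, size=100)
        labels = rng.integers(0, 4, size=100)
        am = hd.build_associative_memory(samples, labels, classes=[0, 1, 2, 3])
        queries = hd.random_bipolar(128, rng, size=500)
        preds = hd.predict_batch(am, queries)
        for q, p in zip(queries, preds):
            assert p == oracles.argmax_cosine(am.prototypes, q)

    def test_zero_prototype_rejected(self):
        am = hd.AssociativeMemory(
            np.array([[0, 0], [1, -1]], dtype=np.int64), np.array([0, 1])
        )
        with pytest.raises(ValueError, match="retrain"):
            hd.predict(am, np.array([1, 1], dtype=np.int8))

    def test_batch_equals_single(self, small_binary_memory, rng):
        am, _, _ = small_binary_memory
        queries = hd.random_bipolar(256, rng, size=300)
        batched = hd.predict_batch(am, queries, batch_size=128)
        single = np.array([hd.predict(am, q).predicted_class for q in queries])
        np.testing.assert_array_equal(batched, single)


class TestRetrain:
    def test_zero_epochs_identity(self, small_binary_memory):
        am, samples, labels = small_binary_memory
        out, trace = hd.retrain(am, samples, labels, epochs=0)
        np.testing.assert_array_equal(out.prototypes, am.prototypes)
        assert trace == []

    def test_perfectly_classified_memory_is_fixed_point(self, rng):
        gen = hd.random_bipolar(512, rng, size=2)
        # noiseless copies: single-pass memory classifies them perfectly
        samples = np.repeat(gen, 10, axis=0)
        labels = np.repeat([0, 1], 10)
        am = hd.build_associative_memory(samples, labels)
        out, trace = hd.retrain(am, samples, labels, epochs=25)
        np.testing.assert_array_equal(out.prototypes, am.prototypes)
        assert trace[-1] == 1.0  # early-stopped after a clean epoch

    def test_single_error_update_matches_hand_trace(self):
        # memory that misclassifies exactly one sample; one epoch of updates
        h = np.array([1, 1, 1, 1], dtype=np.int8)
        protos = np.array([[3, 3, 3, 3], [-1, -1, -1, 3]], dtype=np.int64)
        am = hd.AssociativeMemory(protos.copy(), np.array([0, 1]))
        # h is closest to prototype 0 but labelled 1 -> proto1 += h, proto0 -= h
        out, _ = hd.retrain(am, h[None, :], [1], epochs=1)
        np.testing.assert_array_equal(out.prototypes[0], protos[0] - h)
        np.testing.assert_array_equal(out.prototypes[1], protos[1] + h)
        np.testing.assert_array_equal(am.prototypes, protos)  # input not mutated

    def test_retraining_does_not_hurt_separable_data(self):
        spec = hd.SyntheticSpec(n_per_class=100, noise_flip_prob=0.3, seed=3)
        samples, labels, _ = hd.generate_prototype_noise_data(spec, dim=1024)
        am0 = hd.build_associative_memory(samples, labels)
        single_pass_acc = (hd.predict_batch(am0, samples) == labels).mean()
        am1, _ = hd.retrain(am0, samples, labels, epochs=10)
        retrained_acc = (hd.predict_batch(am1, samples) == labels).mean()
        assert retrained_acc >= single_pass_acc


class TestConfidence:
    def test_equal_similarity_gives_half(self, rng):
        h = hd.random_bipolar(64, rng)
        am = hd.AssociativeMemory(
            np.vstack([h, h]).astype(np.int64), np.array([0, 1])
        )
        assert hd.confidence_score(am, h) == pytest.approx(0.5)

    def test_endpoints(self, rng):
        v = hd.random_bipolar(64, rng)
        am = hd.AssociativeMemory(
            np.vstack([hd.negate(v), v]).astype(np.int64), np.array([0, 1])
        )
        assert hd.confidence_score(am, v) == pytest.approx(1.0)
        assert hd.confidence_score(am, hd.negate(v)) == pytest.approx(0.0)

    def test_consistent_with_predict(self, small_binary_memory, rng):
        """Predicted class is 1 exactly when eta > 0.5 (ties go to class 0)."""
        am, _, _ = small_binary_memory
        queries = hd.random_bipolar(256, rng, size=200)
        etas = hd.confidence_scores(am, queries)
        preds = hd.predict_batch(am, queries)
        np.testing.assert_array_equal(preds == 1, etas > 0.5)

    def test_requires_binary_memory(self, rng):
        s = hd.random_bipolar(32, rng, size=3)
        am = hd.build_associative_memory(s, [0, 1, 2])
        with pytest.raises(ValueError, match="binary"):
            hd.confidence_score(am, s[0])


class TestRankCompounds:
    def test_positive_prototype_copy_ranks_first(self, rng):
        gen = hd.random_bipolar(10_000, rng, size=2)
        am = hd.AssociativeMemory(gen.astype(np.int64), np.array([0, 1]))
        decoys = hd.random_bipolar(10_000, rng, size=50)
        pool = np.vstack([decoys, gen[1][None, :]])
        ids = [f"d{i}" for i in range(50)] + ["active"]
        ranked = hd.rank_compounds(am, pool, ids=ids)
        assert ranked.ids[0] == "active"

    def test_permutation_of_ids_and_sorted_scores(self, small_binary_memory, rng):
        am, _, _ = small_binary_memory
        queries = hd.random_bipolar(256, rng, size=80)
        ids = [f"m{i}" for i in range(80)]
        ranked = hd.rank_compounds(am, queries, ids=ids)
        assert sorted(ranked.ids) == sorted(ids)
        assert np.all(np.diff(ranked.scores) <= 0)
        # matches an independent stable sort oracle
        etas = hd.confidence_scores(am, queries)
        oracle_order = sorted(range(80), key=lambda i: (-etas[i], i))
        np.testing.assert_array_equal(ranked.ids, [ids[i] for i in oracle_order])

    def test_empty_input_rejected(self, small_binary_memory):
        am, _, _ = small_binary_memory
        with pytest.raises(ValueError):
            hd.rank_compounds(am, np.empty((0, 256), dtype=np.int8))


class TestSerialization:
    def test_memory_round_trip(self, small_binary_memory, tmp_path):
        am, samples, _ = small_binary_memory
        am.meta = {"scheme": "decfp", "dim": "256"}
        path = tmp_path / "model.npz"
        am.save(path)
        loaded = hd.AssociativeMemory.load(path)
        np.testing.assert_array_equal(loaded.prototypes, am.prototypes)
        np.testing.assert_array_equal(loaded.class_labels, am.class_labels)
        assert loaded.meta["scheme"] == "decfp"
        np.testing.assert_array_equal(
            hd.predict_batch(loaded, samples), hd.predict_batch(am, samples)
        )
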