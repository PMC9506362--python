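"""Recognition, gender and attribute metrics against brute-force oracles."""

import numpy as np
import pytest

from gaitformer.evaluation import (attribute_r2, cross_view_rank1,
                                   extract_embeddings, gender_metrics, rank1)
from gaitformer.gaitformer_model import build


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


class TestExtractEmbeddings:
    def test_unit_norm_and_determinism(self, tiny_model_config, normalized_walker):
        model = build(tiny_model_config)
        emb = extract_embeddings(model, [normalized_walker, normalized_walker])
        np.testing.assert_allclose(np.linalg.norm(emb, axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(emb[0], emb[1])

    def test_only_center_crop_matters(self, tiny_model_config, normalized_walker):
        from gaitformer.skeleton_core import NormalizedSequence

        model = build(tiny_model_config)
        seq = normalized_walker
        L = len(seq)
        start = (L - 48) // 2
        corrupted = seq.data.copy()
        corrupted[:start] = 0.0            # outside the crop window
        corrupted[start + 48:] = 0.0
        a = extract_embeddings(model, [seq])
        b = extract_embeddings(model, [NormalizedSequence(corrupted, seq.ref_fps)])
        np.testing.assert_array_equal(a, b)

    def test_short_sequence_rejected(self, tiny_model_config, rng):
        from gaitformer.skeleton_core import unflatten

        model = build(tiny_model_config)
        with pytest.raises(ValueError):
            extract_embeddings(model, [unflatten(rng.normal(size=(30, 54)))])


class TestRank1:
    def test_probe_equals_gallery_is_perfect(self, rng):
        emb = unit(rng.normal(size=(10, 8)))
        ids = np.arange(10)
        assert rank1(emb, ids, emb, ids) == 100.0

    def test_cosine_example(self):
        gallery = np.array([[1.0, 0.0], [0.0, 1.0]])
        probe = unit([[0.9, 0.1]])
        assert rank1(gallery, ["A", "B"], probe, ["A"]) == 100.0
        assert rank1(gallery, ["A", "B"], probe, ["B"]) == 0.0

    def test_chance_level_for_random_embeddings(self):
        rng = np.random.default_rng(0)
        G = 20
        accs = []
        for _ in range(60):
            gallery = unit(rng.normal(size=(G, 32)))
            probe = unit(rng.normal(size=(50, 32)))
            accs.append(rank1(gallery, np.arange(G), probe,
                              rng.integers(0, G, size=50)))
        assert np.mean(accs) == pytest.approx(100.0 / G, abs=2.0)

    def test_rotation_invariance(self, rng):
        from scipy.stats import ortho_group

        gallery = unit(rng.normal(size=(6, 8)))
        probe = unit(rng.normal(size=(9, 8)))
        g_ids = np.arange(6)
        p_ids = rng.integers(0, 6, size=9)
        Q = ortho_group.rvs(8, random_state=1)
        assert rank1(gallery @ Q, g_ids, probe @ Q, p_ids) == rank1(
            gallery, g_ids, probe, p_ids)

    def test_matches_brute_force(self, rng):
        gallery = unit(rng.normal(size=(15, 8)))
        probe = unit(rng.normal(size=(25, 8)))
        g_ids = rng.integers(0, 7, size=15)
        p_ids = rng.integers(0, 7, size=25)
        hits = 0
        for i in range(25):
            best, best_sim = None, -np.inf
            for j in range(15):
                sim = float(probe[i] @ gallery[j])
                if sim > best_sim:
                    best, best_sim = j, sim
            hits += g_ids[best] == p_ids[i]
        assert rank1(gallery, g_ids, probe, p_ids) == pytest.approx(100 * hits / 25)

    def test_empty_gallery_rejected(self, rng):
        with pytest.raises(ValueError):
            rank1(np.empty((0, 8)), [], unit(rng.normal(size=(1, 8))), [0])


class TestCrossViewRank1:
    def test_view_invariant_embeddings_are_perfect(self, rng):
        base = unit(rng.normal(size=(5, 8)))
        emb = np.concatenate([base, base])
        subjects = np.tile(np.arange(5), 2)
        views = np.repeat(["a", "b"], 5)
        per_view, mean_acc, _ = cross_view_rank1(emb, subjects, views)
        assert per_view == {"a": 100.0, "b": 100.0}
        assert mean_acc == 100.0

    def test_matches_per_view_brute_force(self, rng):
        n, n_views = 12, 4
        emb = unit(rng.normal(size=(n * n_views, 8)))
        subjects = np.tile(np.arange(n), n_views)
        views = np.repeat(np.arange(n_views), n)
        per_view, mean_acc, _ = cross_view_rank1(emb, subjects, views)
        for v in range(n_views):
            probe = views == v
            gal = ~probe
            expected = rank1(emb[gal], subjects[gal], emb[probe], subjects[probe])
            assert per_view[v] == expected
        assert mean_acc == pytest.approx(np.mean(list(per_view.values())))

    def test_single_view_rejected(self, rng):
        emb = unit(rng.normal(size=(4, 8)))
        with pytest.raises(ValueError):
            cross_view_rank1(emb, [0, 1, 2, 3], ["v"] * 4)

    def test_uncovered_probe_skipped_with_warning(self, rng):
        emb = unit(rng.normal(size=(3, 8)))
        subjects = np.array([0, 0, 9])     # subject 9 only in view b
        views = np.array(["a", "b", "b"])
        with pytest.warns(UserWarning, match="skipped"):
            per_view, _, coverage = cross_view_rank1(emb, subjects, views)
        assert coverage["b"]["skipped"] == 1


class TestGenderMetrics:
    def test_perfect_predictions(self):
        p, r, f1 = gender_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert (p, r, f1) == (100.0, 100.0, 100.0)

    def test_confusion_matrix_worked_example(self):
        """Truth (1,1,0,0), preds (1,0,0,0): macro-F1 = (66.7 + 80) / 2."""
        p, r, f1 = gender_metrics([1, 1, 0, 0], [0.9, 0.1, 0.2, 0.3])
        assert p == pytest.approx((100 + 200 / 3) / 2, abs=0.01)
        assert r == pytest.approx((50 + 100) / 2, abs=0.01)
        assert f1 == pytest.approx((200 / 3 + 80) / 2, abs=0.05)

    def test_all_positive_predictor_macro_recall_50(self):
        _, r, _ = gender_metrics([0, 0, 1, 1], [0.9, 0.9, 0.9, 0.9])
        assert r == pytest.approx(50.0)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            gender_metrics([1, 1, 1], [0.2, 0.4, 0.9])


class TestAttributeR2:
    def test_perfect_prediction(self, rng):
        y = rng.uniform(size=(10, 42))
        np.testing.assert_allclose(attribute_r2(y, y), 1.0)

    def test_constant_mean_prediction_is_zero(self, rng):
        y = rng.uniform(size=(10, 5))
        pred = np.tile(y.mean(axis=0), (10, 1))
        np.testing.assert_allclose(attribute_r2(pred, y), 0.0, atol=1e-12)

    def test_two_point_closed_form(self):
        """targets (0, 1), preds (0.25, 0.75): R2 = 1 - 0.125/0.5 = 0.75."""
        y = np.array([[0.0], [1.0]])
        pred = np.array([[0.25], [0.75]])
        assert attribute_r2(pred, y)[0] == pytest.approx(0.75)

    def test_column_permutation_equivariant(self, rng):
        y = rng.uniform(size=(20, 6))
        pred = rng.uniform(size=(20, 6))
        perm = rng.permutation(6)
        np.testing.assert_allclose(attribute_r2(pred[:, perm], y[:, perm]),
                                   attribute_r2(pred, y)[perm])

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import r2_score

        y = rng.uniform(size=(30, 4))
        pred = rng.uniform(size=(30, 4))
        expected = r2_score(y, pred, multioutput="raw_values")
        np.testing.assert_allclose(attribute_r2(pred, y), expected, atol=1e-12)

    def test_zero_variance_target_is_nan_not_zero(self, rng):
        y = np.column_stack([np.full(5, 0.3), rng.uniform(size=5)])
        pred = rng.uniform(size=(5, 2))
        r2 = attribute_r2(pred, y)
        assert np.isnan(r2[0]) and np.isfinite(r2[1])
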