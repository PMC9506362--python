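"""Attribute schema, coalescing, augmentation-averaged prediction, pooling."""

import numpy as np
import pytest

from gaitformer.attribute_annotation import (AnnotationConfig, AttributeVector,
                                             N_ATTRIBUTES, SchemaError,
                                             aggregate_tracklet, annotate_tracklet,
                                             coalesce, load_schema, predict_crop,
                                             relative_areas, sample_crops)
from gaitformer.synthetic_data import render_tracklet, sample_walker


@pytest.fixture(scope="module")
def schema():
    return load_schema()


def zero_preds(schema):
    return {ds: np.zeros(len(labels)) for ds, labels in schema.source_labels.items()}


class TestSchema:
    def test_shipped_schema_is_complete(self, schema):
        """Exactly 42 targets in 8 non-empty groups; every source label in
        the three vocabularies is either mapped or explicitly dropped."""
        assert len(schema.names) == N_ATTRIBUTES
        assert len({schema.groups[n] for n in schema.names}) == 8
        assert set(schema.source_labels) == {"PA100k", "PETA", "RAP"}
        # loader enforces coverage; reaching here means no unmapped label

    def test_unmapped_label_is_load_time_error(self, tmp_path, schema):
        import yaml
        from importlib import resources

        raw = yaml.safe_load(
            (resources.files("gaitformer") / "data" / "attribute_schema.yaml").read_text())
        raw["drop"] = raw["drop"][:-1]   # orphan one label
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.dump(raw))
        with pytest.raises(SchemaError, match="neither mapped nor dropped"):
            load_schema(bad)


class TestCoalesce:
    def test_age_child_average(self, schema):
        """AgeLess18 = 0.8 and AgeLess16 = 0.6 average to AgeChild = 0.7."""
        preds = zero_preds(schema)
        preds["PA100k"][schema.source_labels["PA100k"].index("AgeLess18")] = 0.8
        preds["RAP"][schema.source_labels["RAP"].index("AgeLess16")] = 0.6
        out = coalesce(preds, schema)
        assert out.values[schema.index("AgeChild")] == pytest.approx(0.7)

    def test_single_source_passthrough(self, schema):
        preds = zero_preds(schema)
        preds["PA100k"][schema.source_labels["PA100k"].index("LongCoat")] = 0.37
        out = coalesce(preds, schema)
        assert out.values[schema.index("LongCoat")] == pytest.approx(0.37)

    def test_all_zero_sources(self, schema):
        out = coalesce(zero_preds(schema), schema)
        # PETA Male=0 inverts to Female evidence 1; everything else is 0
        expected_nonzero = {schema.index("Female")}
        assert set(np.flatnonzero(out.values)) == expected_nonzero

    def test_max_mode_uses_maximum(self, schema):
        preds = zero_preds(schema)
        for label, v in (("Formal lower", 0.2), ("Formal upper", 0.9)):
            preds["PETA"][schema.source_labels["PETA"].index(label)] = v
        preds["RAP"][schema.source_labels["RAP"].index("Suit-Up")] = 0.5
        out = coalesce(preds, schema)
        assert out.values[schema.index("FormalWear")] == pytest.approx(0.9)

    def test_output_in_unit_interval(self, schema, rng):
        preds = {ds: rng.uniform(0, 1, len(labels))
                 for ds, labels in schema.source_labels.items()}
        out = coalesce(preds, schema)
        assert np.all((out.values >= 0) & (out.values <= 1))


class TestPredictCrop:
    def test_constant_predictor(self):
        cfg = AnnotationConfig()
        out = predict_crop(lambda crop, desc: np.array([0.3, 0.7]), None, cfg)
        np.testing.assert_allclose(out, [0.3, 0.7])

    def test_mean_of_k_outputs(self):
        cfg = AnnotationConfig(k_augment=4)
        vals = iter([0.2, 0.4, 0.6, 0.8])
        out = predict_crop(lambda crop, desc: np.array([next(vals)]), None, cfg)
        assert out[0] == pytest.approx(0.5)

    def test_failures_skipped_all_fail_raises(self):
        cfg = AnnotationConfig(k_augment=4)
        calls = {"n": 0}

        def flaky(crop, desc):
            calls["n"] += 1
            if calls["n"] < 4:
                raise RuntimeError("boom")
            return np.array([1.0])

        assert predict_crop(flaky, None, cfg)[0] == 1.0

        def broken(crop, desc):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="every augmented copy"):
            predict_crop(broken, None, cfg)


class TestSampleCrops:
    @pytest.mark.parametrize("n,expected", [(100, [0, 48, 96]), (48, [0]),
                                            (200, [0, 48, 96, 144, 192])])
    def test_every_T_frames(self, n, expected):
        params, _ = sample_walker(5)
        track = render_tracklet(params, n, 24.0, np.random.default_rng(0))
        assert [t for t, _ in sample_crops(track, 48)] == expected

    def test_no_bboxes_is_error(self, rng):
        from gaitformer.skeleton_core import RawTracklet

        track = RawTracklet.from_arrays(rng.normal(size=(60, 18, 2)),
                                        np.full((60, 18), 0.9), fps=24.0)
        with pytest.raises(ValueError, match="bounding boxes"):
            sample_crops(track, 48)


class TestAggregate:
    def vec(self, x):
        return AttributeVector(np.full(N_ATTRIBUTES, x))

    def test_area_weighted_mean(self):
        """Areas (0.3, 0.1) weight predictions (0.8, 0.4) into 0.7."""
        out = aggregate_tracklet([self.vec(0.8), self.vec(0.4)], [0.3, 0.1])
        np.testing.assert_allclose(out.values, 0.7)

    def test_equal_areas_plain_mean(self):
        out = aggregate_tracklet([self.vec(0.2), self.vec(0.6)], [0.5, 0.5])
        np.testing.assert_allclose(out.values, 0.4)

    def test_single_crop_identity(self):
        out = aggregate_tracklet([self.vec(0.33)], [0.2])
        np.testing.assert_allclose(out.values, 0.33)

    def test_permutation_equivariance(self, rng):
        preds = [AttributeVector(rng.uniform(0, 1, N_ATTRIBUTES)) for _ in range(4)]
        areas = rng.uniform(0.1, 1.0, 4)
        a = aggregate_tracklet(preds, areas)
        perm = rng.permutation(4)
        b = aggregate_tracklet([preds[i] for i in perm], areas[perm])
        np.testing.assert_allclose(a.values, b.values)

    def test_growing_area_pulls_toward_that_crop(self):
        lo, hi = self.vec(0.1), self.vec(0.9)
        prev = aggregate_tracklet([lo, hi], [1.0, 0.5]).values[0]
        for area in (1.0, 2.0, 4.0):
            cur = aggregate_tracklet([lo, hi], [1.0, area]).values[0]
            assert cur >= prev
            prev = cur

    def test_all_zero_areas_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            aggregate_tracklet([self.vec(0.5)], [0.0])


class TestAnnotateTracklet:
    def test_end_to_end_with_mock_ensemble(self, schema):
        """Mock predictors at the vector level reproduce the analytic
        area-weighted coalesced value."""
        params, _ = sample_walker(9)
        track = render_tracklet(params, 100, 24.0, np.random.default_rng(1))
        constants = {"PA100k": 0.2, "PETA": 0.5, "RAP": 0.8}
        predictors = {
            ds: (lambda c, d, v=v, n=len(schema.source_labels[ds]): np.full(n, v))
            for ds, v in constants.items()}
        out = annotate_tracklet(track, predictors, schema, AnnotationConfig(seed=0))
        assert np.all((out.values >= 0) & (out.values <= 1))
        # constant predictions make area weighting irrelevant: the result is
        # the coalesced constant vector
        expected = coalesce({ds: np.full(len(schema.source_labels[ds]), v)
                             for ds, v in constants.items()}, schema)
        np.testing.assert_allclose(out.values, expected.values, atol=1e-12)

    def test_relative_areas_use_frame_size(self):
        params, _ = sample_walker(9)
        track = render_tracklet(params, 60, 24.0, np.random.default_rng(1))
        rel = relative_areas(track, [0, 48])
        assert np.all(rel > 0) and np.all(rel <= 1)
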