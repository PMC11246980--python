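"""Teacher-data buffering, pattern model, stabilization filter, hand mapping."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from myocomp.features import EmgStream, extract_feature_stream
from myocomp.intention import (
    PatternModel,
    RsfConfig,
    build_teacher_dataset,
    map_to_hand_command,
    predict_intention,
    stabilize_intentions,
    switch_count,
    train_pattern_model,
)
from myocomp.synthetic import LabelSchedule


def brute_force_stabilize(raw, window, tau, order, initial="rest"):
    """Independent re-statement of the modal-proportion rule."""
    out, prev = [], initial
    for i in range(len(raw)):
        win = raw[max(0, i - window + 1) : i + 1]
        best, best_count = None, -1
        for lab in sorted(set(win), key=order.index):
            c = win.count(lab)
            if c > best_count:
                best, best_count = lab, c
        if best_count / len(win) >= tau:
            prev = best
        out.append(prev)
    return out


class TestBuildTeacherDataset:
    def test_empty_schedule_rejected(self, rng):
        stream = EmgStream(2000.0, rng.standard_normal((1, 1024)))
        frames = extract_feature_stream(stream)
        with pytest.raises(ValueError, match="no teacher data"):
            build_teacher_dataset(frames, LabelSchedule())

    def test_buffer_window_frame_count(self, rng):
        # 2.0-s segment, skip 0.5 s, hop 128 at 2000 Hz (0.064 s per frame):
        # frame centres 0.064*(k+1) in [0.5, 2.0] -> floor(1.5/0.064)+1 = 24
        stream = EmgStream(2000.0, rng.standard_normal((1, 5000)))
        frames = extract_feature_stream(stream)
        ds = build_teacher_dataset(
            frames, LabelSchedule(((0.0, 2.0, "grip"),)), buffer_s=2.0, skip_s=0.5
        )
        assert ds.n_examples == 24

    def test_label_set_equals_taught_labels(self, rng):
        stream = EmgStream(2000.0, rng.standard_normal((1, 16000)))
        frames = extract_feature_stream(stream)
        schedule = LabelSchedule(((0, 2.5, "rest"), (2.5, 5, "grip"), (5, 7.5, "open")))
        ds = build_teacher_dataset(frames, schedule)
        assert set(ds.label_set) == {"rest", "grip", "open"}

    def test_invalid_buffer_rejected(self, rng):
        stream = EmgStream(2000.0, rng.standard_normal((1, 1024)))
        frames = extract_feature_stream(stream)
        with pytest.raises(ValueError, match="buffer"):
            build_teacher_dataset(frames, LabelSchedule(((0, 1, "grip"),)), buffer_s=0.5, skip_s=0.5)


class TestTrainPatternModel:
    def test_seeded_determinism(self, separable_dataset):
        ds, _ = separable_dataset
        a = train_pattern_model(ds, seed=42)
        b = train_pattern_model(ds, seed=42)
        for wa, wb in zip(a.coefs, b.coefs):
            np.testing.assert_array_equal(wa, wb)

    def test_separable_training_accuracy(self, separable_dataset):
        ds, centroids = separable_dataset
        # independence oracle: nearest-centroid is near-perfect on this data
        cents = np.vstack(list(centroids.values()))
        labs = list(centroids)
        nc = [labs[np.argmin(((c - cents) ** 2).sum(axis=1))] for c in ds.X]
        assert np.mean(np.array(nc) == ds.y) >= 0.99
        model = train_pattern_model(ds, seed=0)
        assert model.train_accuracy >= 0.99

    def test_class_list_matches_label_set(self, separable_dataset):
        ds, _ = separable_dataset
        model = train_pattern_model(ds, seed=0)
        assert set(model.classes) == set(ds.label_set)

    def test_single_class_rejected(self, rng):
        from myocomp.intention import TeacherDataset

        ds = TeacherDataset(rng.standard_normal((20, 4)), np.array(["grip"] * 20), ("grip",))
        with pytest.raises(ValueError, match="2 classes"):
            train_pattern_model(ds)

    def test_too_few_examples_per_class_rejected(self, rng):
        from myocomp.intention import TeacherDataset

        y = np.array(["grip"] * 20 + ["open"] * 3)
        ds = TeacherDataset(rng.standard_normal((23, 4)), y, ("grip", "open"))
        with pytest.raises(ValueError, match="examples"):
            train_pattern_model(ds)


class TestPredictIntention:
    def test_centroid_maps_to_its_class(self, separable_dataset):
        ds, centroids = separable_dataset
        model = train_pattern_model(ds, seed=0)
        for lab, c in centroids.items():
            assert predict_intention(c, model) == lab

    def test_heldout_accuracy_on_split(self, separable_dataset):
        from myocomp.intention import TeacherDataset

        ds, _ = separable_dataset
        idx = np.random.default_rng(1).permutation(ds.n_examples)
        half = ds.n_examples // 2
        tr = TeacherDataset(ds.X[idx[:half]], ds.y[idx[:half]], ds.label_set)
        model = train_pattern_model(tr, seed=0)
        acc = np.mean(model.predict_batch(ds.X[idx[half:]]) == ds.y[idx[half:]])
        assert acc >= 0.95

    def test_dimension_mismatch_rejected(self, separable_dataset):
        ds, _ = separable_dataset
        model = train_pattern_model(ds, seed=0)
        with pytest.raises(ValueError, match="dimension"):
            predict_intention(np.zeros(7), model)

    def test_json_roundtrip_preserves_predictions(self, separable_dataset, tmp_path):
        ds, _ = separable_dataset
        model = train_pattern_model(ds, seed=0)
        model.save(tmp_path / "model.json")
        clone = PatternModel.load(tmp_path / "model.json")
        np.testing.assert_array_equal(model.predict_batch(ds.X), clone.predict_batch(ds.X))


LABELS = ["rest", "grip", "open", "wrist_flex"]


class TestStabilizeIntentions:
    def test_constant_stream_passes_through(self):
        out = stabilize_intentions(["grip"] * 20, RsfConfig(10, 0.6))
        assert out == ["grip"] * 20

    def test_window_one_is_identity(self):
        raw = ["rest", "grip", "open", "grip", "rest"]
        assert stabilize_intentions(raw, RsfConfig(window=1, threshold=1.0)) == raw

    def test_single_frame_blips_removed(self):
        raw = ["grip"] * 30
        raw[10] = raw[20] = "open"
        out = stabilize_intentions(raw, RsfConfig(10, 0.6))
        assert out == ["grip"] * 30
        assert switch_count(out) <= switch_count(raw)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            raw = list(rng.choice(LABELS, size=60))
            cfg = RsfConfig(window=int(rng.integers(1, 12)), threshold=0.6)
            ours = stabilize_intentions(raw, cfg, label_order=LABELS)
            oracle = brute_force_stabilize(raw, cfg.window, cfg.threshold, LABELS)
            assert ours == oracle

    @given(st.lists(st.sampled_from(LABELS), min_size=1, max_size=80), st.integers(2, 15))
    def test_never_increases_switch_count(self, raw, window):
        out = stabilize_intentions(raw, RsfConfig(window=window, threshold=0.6))
        assert switch_count(out) <= switch_count(raw)

    @given(st.lists(st.sampled_from(LABELS), min_size=1, max_size=80))
    def test_never_invents_labels(self, raw):
        out = stabilize_intentions(raw, RsfConfig(10, 0.6))
        assert set(out) <= set(raw) | {"rest"}

    def test_longer_window_never_adds_single_frame_blips(self, rng):
        def blips(seq):
            return sum(
                1
                for i in range(1, len(seq) - 1)
                if seq[i] != seq[i - 1] and seq[i] != seq[i + 1]
            )

        for seed in range(5):
            raw = list(np.random.default_rng(seed).choice(LABELS, size=80))
            counts = [
                blips(stabilize_intentions(raw, RsfConfig(window=w, threshold=0.6)))
                for w in (2, 5, 10, 20)
            ]
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            stabilize_intentions([], RsfConfig())


class TestHandCommandMapping:
    @pytest.mark.parametrize(
        "label,command",
        [
            ("grip", "close"),
            ("open", "open"),
            ("rest", "hold"),
            ("wrist_flex", "hold"),
            ("wrist_extend", "hold"),
        ],
    )
    def test_mapping(self, label, command):
        assert map_to_hand_command(label) == command

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            map_to_hand_command("pinch")
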