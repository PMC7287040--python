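"""Label algebra, the rule-based scalogram reader, and the trainable net."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hfopipe.classifier import (
    CATEGORIES, EventLabel, ImageClassifierModel, ReferenceClassifier,
    SmallConvNet, classify_events, filter_qhfo, flags_to_category, is_qhfo,
    train_image_classifier,
)
from hfopipe.scalogram import EventImage


class TestLabelAlgebra:
    def test_total_and_surjective_onto_nine_categories(self):
        image = {flags_to_category(*c)
                 for c in itertools.product([False, True], repeat=4)}
        assert image == set(CATEGORIES)
        assert len(image) == 9

    @pytest.mark.parametrize("flags,expect", [
        ((False, True, True, False), "spike+R"),
        ((False, False, False, False), "other"),
        ((True, True, True, True), "artifact"),
        ((False, False, True, False), "R"),
        ((False, False, False, True), "FR"),
        ((False, False, True, True), "R+FR"),
        ((False, True, False, False), "spike"),
        ((False, True, False, True), "spike+FR"),
        ((False, True, True, True), "spike+R+FR"),
    ])
    def test_examples(self, flags, expect):
        assert flags_to_category(*flags) == expect

    def test_artifact_dominates_every_combination(self):
        for rest in itertools.product([False, True], repeat=3):
            assert flags_to_category(True, *rest) == "artifact"

    def test_event_label_short_circuits_on_artifact(self):
        lab = EventLabel(artifact=True, spike=True, ripple=True,
                         fast_ripple=True)
        assert lab.category == "artifact"
        assert not (lab.spike or lab.ripple or lab.fast_ripple)
        assert not lab.qhfo


class TestQhfo:
    def test_oscillation_required(self):
        assert is_qhfo("spike+R", ripple=True, fast_ripple=False)
        assert not is_qhfo("spike", ripple=False, fast_ripple=False)
        assert not is_qhfo("other", ripple=False, fast_ripple=False)
        assert not is_qhfo("artifact", ripple=False, fast_ripple=False)
        # configurable literal reading: any non-artifact/other event counts
        assert is_qhfo("spike", False, False, require_oscillation=False)

    def test_subsets(self):
        labels = [EventLabel(False, True, True, False),   # spike+R
                  EventLabel(False, False, False, True),  # FR
                  EventLabel(False, False, False, False),  # other
                  EventLabel(False, True, False, False),  # spike (not qHFO)
                  EventLabel(True, False, False, False)]  # artifact
        assert filter_qhfo(labels) == [0, 1]
        assert filter_qhfo(labels, "with_spike") == [0]
        assert filter_qhfo(labels, "without_spike") == [1]
        assert filter_qhfo(labels, "with_fr") == [1]
        assert filter_qhfo(labels, "without_fr") == [0]
        with pytest.raises(ValueError):
            filter_qhfo(labels, "nonsense")


@pytest.fixture(scope="module")
def labeled_corpus():
    """Small simulated corpus at high SNR with ground-truth flags."""
    from hfopipe.simulator import generate_training_corpus
    sgs, images, flags = generate_training_corpus(
        n_per_class=6, snr_db=15.0, seed=202, raster=(64, 64))
    return sgs, images, flags


class TestReferenceClassifier:
    def test_majority_correct_per_class(self, labeled_corpus):
        sgs, _, flags = labeled_corpus
        labels = classify_events(sgs, ReferenceClassifier())
        for cls, expect in [("R", "R"), ("FR", "FR"), ("spike", "spike"),
                            ("spike+R", "spike+R")]:
            idx = np.flatnonzero((flags["class"] == cls).to_numpy())
            cats = [labels[i].category for i in idx]
            assert cats.count(expect) >= len(idx) // 2 + 1, (cls, cats)

    def test_artifact_classes_read_as_artifact(self, labeled_corpus):
        sgs, _, flags = labeled_corpus
        labels = classify_events(sgs, ReferenceClassifier())
        idx = np.flatnonzero(
            flags["class"].isin(["emg_burst", "sharp_transient"]).to_numpy())
        cats = [labels[i].category for i in idx]
        assert cats.count("artifact") >= int(0.7 * len(idx)), cats

    def test_deterministic_and_order_equivariant(self, labeled_corpus):
        sgs, _, _ = labeled_corpus
        model = ReferenceClassifier()
        a = [l.category for l in classify_events(sgs, model)]
        b = [l.category for l in classify_events(sgs, model)]
        assert a == b
        perm = np.random.default_rng(3).permutation(len(sgs))
        c = [l.category for l in classify_events([sgs[i] for i in perm], model)]
        assert c == [a[i] for i in perm]

    def test_batch_size_and_order_preserved(self, labeled_corpus):
        sgs, _, _ = labeled_corpus
        labels = classify_events(sgs, ReferenceClassifier())
        assert len(labels) == len(sgs)


class TestTrainableNet:
    def test_trivially_separable_images(self):
        # bright top half vs bright bottom half: separable after the net's
        # per-image normalization
        rng = np.random.default_rng(0)
        top = 0.1 * rng.uniform(size=(40, 32, 32))
        top[:, :16, :] += 0.8
        bottom = 0.1 * rng.uniform(size=(40, 32, 32))
        bottom[:, 16:, :] += 0.8
        X = np.concatenate([top, bottom])
        y = np.array([False] * 40 + [True] * 40)
        model = train_image_classifier(X, y, flag="ripple", seed=0)
        assert model.validation_accuracy == 1.0

    def test_split_sizes(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(100, 16, 16))
        y = np.arange(100) % 2 == 0
        model = train_image_classifier(X, y, split=0.8, seed=0)
        assert model.n_train == 80 and model.n_val == 20

    def test_single_class_and_empty_rejected(self):
        X = np.zeros((10, 8, 8))
        with pytest.raises(ValueError, match="single class"):
            train_image_classifier(X, np.ones(10, bool))
        with pytest.raises(ValueError, match="empty"):
            train_image_classifier(np.zeros((0, 8, 8)), np.zeros(0, bool))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(60, 16, 16))
        X[30:] += 0.5
        y = np.array([False] * 30 + [True] * 30)
        m1 = train_image_classifier(X, y, seed=7)
        m2 = train_image_classifier(X, y, seed=7)
        assert m1.validation_accuracy == m2.validation_accuracy
        np.testing.assert_array_equal(m1.net.w, m2.net.w)

    def test_learns_ripple_flag_on_simulated_images(self, labeled_corpus):
        from hfopipe.simulator import balanced_flag_dataset
        _, images, flags = labeled_corpus
        n = min(int(flags["ripple"].sum()), int((~flags["ripple"]).sum()))
        X, y = balanced_flag_dataset(images, flags, "ripple", n, seed=1)
        model = train_image_classifier(X, y, flag="ripple", seed=0)
        assert model.validation_accuracy > 0.75

    def test_image_model_raster_mismatch(self, labeled_corpus):
        _, images, flags = labeled_corpus
        nets = {}
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(20, 32, 32))
        y = np.arange(20) % 2 == 0
        for f in ("artifact", "spike", "ripple", "fast_ripple"):
            nets[f] = train_image_classifier(X, y, flag=f, seed=0)
        model = ImageClassifierModel(models=nets)
        bad = EventImage(pixels=np.zeros((16, 16)))
        with pytest.raises(ValueError, match="raster"):
            model.predict_flags(None, bad)


class TestModelSerialization:
    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        X = rng.uniform(size=(40, 16, 16))
        X[20:] += 0.5
        y = np.array([False] * 20 + [True] * 20)
        nets = {f: train_image_classifier(X, y, flag=f, seed=0)
                for f in ("artifact", "spike", "ripple", "fast_ripple")}
        from hfopipe.classifier import load_model, save_model
        model = ImageClassifierModel(models=nets)
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        img = EventImage(pixels=X[0])
        assert back.predict_flags(None, img) == model.predict_flags(None, img)
        assert back.models["ripple"].validation_accuracy == pytest.approx(
            nets["ripple"].validation_accuracy)

    def test_labels_frame_layout(self):
        from hfopipe.classifier import labels_to_frame
        df = labels_to_frame([EventLabel(False, True, True, False),
                              EventLabel(True, False, False, False)])
        assert list(df["category"]) == ["spike+R", "artifact"]
        assert list(df["qhfo"]) == [True, False]
        assert set(df.columns) >= {"event_id", "artifact", "spike", "ripple",
                                   "fast_ripple"}
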