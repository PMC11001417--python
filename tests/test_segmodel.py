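"""Reference segmentation backend: protocols, augmentation, training, prediction."""

import numpy as np
import pytest

from cellcryst._geometry import mask_centroid, tight_bbox
from cellcryst.annotio import Instance
from cellcryst.metrics import evaluate_dataset
from cellcryst.segmodel import (
    InstancePrediction,
    TrainingProtocol,
    augment,
    init_model,
    load_model,
    predict,
    save_model,
    train,
)
from cellcryst.synthgen import generate_images


@pytest.fixture(scope="module")
def easy_data(easy_config):
    return generate_images(easy_config, 6, seed=31)


@pytest.fixture(scope="module")
def trained_state(easy_data):
    state = init_model("ref", {"crystal_G"}, seed=0)
    proto = TrainingProtocol.primary(seed=0)
    state, log = train(state, easy_data, proto)
    return state, log


def test_protocol_defaults_match_training_roles():
    primary = TrainingProtocol.primary()
    assert (primary.epochs, primary.learning_rate, primary.batch_size,
            primary.loss) == (40, 1e-3, 1, "BCE")
    secondary = TrainingProtocol.secondary()
    assert secondary.epochs == 10
    assert TrainingProtocol.secondary(learning_rate=1e-4).learning_rate == 1e-4
    assert TrainingProtocol.combined().epochs == 40
    with pytest.raises(ValueError, match="epochs"):
        TrainingProtocol(epochs=0)
    with pytest.raises(ValueError, match="learning_rate"):
        TrainingProtocol(learning_rate=0.0)


def test_init_model_deterministic_and_warm_start_lineage(easy_data):
    a = init_model("ref", {"crystal_G"}, seed=7)
    b = init_model("ref", {"crystal_G"}, seed=7)
    assert a.params == b.params
    assert a.lineage == []
    trained, _ = train(a, easy_data, TrainingProtocol.primary(epochs=1, seed=0))
    warm = init_model("ref", {"crystal_G"}, warm_start=trained, seed=1)
    assert warm.lineage == trained.lineage
    assert warm.params == trained.params


def test_warm_start_class_mismatch_reinitializes_head(easy_data, caplog):
    state = init_model("ref", {"crystal_G"}, seed=0)
    trained, _ = train(state, easy_data, TrainingProtocol.primary(epochs=1, seed=0))
    with caplog.at_level("WARNING"):
        warm = init_model("ref", {"crystal_G", "crystal_H"},
                          warm_start=trained, seed=5)
    assert "reinitialized" in caplog.text
    assert warm.params != trained.params
    assert warm.lineage == trained.lineage


def test_unknown_backend_error_lists_available():
    with pytest.raises(KeyError, match="ref"):
        init_model("nope", {"crystal_G"})


def _instances_with_blob(shape, r, c, size=4):
    m = np.zeros(shape, dtype=bool)
    m[r:r + size, c:c + size] = True
    return [Instance("crystal_G", mask=m)]


def test_double_horizontal_flip_is_identity():
    rng_img = np.random.default_rng(0)
    image = rng_img.random((16, 16))
    insts = _instances_with_blob((16, 16), 3, 5)
    proto = TrainingProtocol(augmentations=("hflip",), epochs=1)

    class AlwaysFlip:
        def random(self):
            return 0.0

    once_img, once = augment(image, insts, proto, AlwaysFlip())
    twice_img, twice = augment(once_img, once, proto, AlwaysFlip())
    np.testing.assert_array_equal(twice_img, image)
    np.testing.assert_array_equal(twice[0].mask, insts[0].mask)


def test_flip_reflects_mask_centroid():
    image = np.zeros((16, 16))
    insts = _instances_with_blob((16, 16), 2, 1)
    proto = TrainingProtocol(augmentations=("hflip",), epochs=1)
    cx0, cy0 = mask_centroid(insts[0].get_mask((16, 16)))

    class AlwaysFlip:
        def random(self):
            return 0.0

    _, flipped = augment(image, insts, proto, AlwaysFlip())
    cx1, cy1 = mask_centroid(flipped[0].mask)
    assert cx1 == pytest.approx(16 - cx0)
    assert cy1 == pytest.approx(cy0)


def test_crop_never_leaves_annotated_sample_empty():
    proto = TrainingProtocol(augmentations=("random_crop",), epochs=1)
    rng = np.random.default_rng(17)
    image = np.zeros((32, 32))
    insts = _instances_with_blob((32, 32), 0, 0, size=3)  # corner instance
    for _ in range(50):
        out_img, out = augment(image, insts, proto, rng)
        assert len(out) >= 1
        assert out[0].mask.any()
        assert out_img.size >= 0.5 * image.size - out_img.shape[0] - out_img.shape[1]


def test_training_reduces_loss_and_extends_lineage(trained_state):
    state, log = trained_state
    assert log.epoch_losses[-1] < log.epoch_losses[0]
    assert len(log.epoch_losses) == 40
    assert len(state.lineage) == 1
    assert state.lineage[0]["protocol"]["role"] == "primary"


def test_fixed_seed_reproduces_loss_trajectory(easy_data):
    runs = []
    for _ in range(2):
        state = init_model("ref", {"crystal_G"}, seed=3)
        _, log = train(state, easy_data,
                       TrainingProtocol.primary(epochs=3, seed=3))
        runs.append(log.epoch_losses)
    assert runs[0] == runs[1]


def test_secondary_training_appends_to_lineage(easy_data, trained_state):
    state, _ = trained_state
    warm = init_model("ref", {"crystal_G"}, warm_start=state, seed=0)
    tuned, _ = train(warm, easy_data, TrainingProtocol.secondary(seed=0))
    assert len(tuned.lineage) == 2
    assert tuned.lineage[1]["protocol"]["role"] == "secondary"


def test_warm_start_converges_faster_than_cold_start(easy_data, trained_state):
    state, _ = trained_state
    proto = TrainingProtocol.secondary(epochs=1, seed=9)
    warm = init_model("ref", {"crystal_G"}, warm_start=state, seed=9)
    _, warm_log = train(warm, easy_data, proto)
    cold = init_model("ref", {"crystal_G"}, seed=9)
    _, cold_log = train(cold, easy_data, proto)
    assert warm_log.epoch_losses[0] < cold_log.epoch_losses[0]


def test_train_rejects_empty_or_disjoint_datasets(easy_data):
    state = init_model("ref", {"crystal_G"}, seed=0)
    with pytest.raises(ValueError, match="empty"):
        train(state, [], TrainingProtocol.primary())
    wrong = init_model("ref", {"crystal_H"}, seed=0)
    with pytest.raises(ValueError, match="class set"):
        train(wrong, easy_data, TrainingProtocol.primary())


def test_predictions_sorted_with_tight_boxes_and_threshold_monotone(
        trained_state, easy_config):
    state, _ = trained_state
    test = generate_images(easy_config, 3, seed=77)
    for ann in test:
        preds = predict(state, ann.image, score_threshold=0.5)
        scores = [p.score for p in preds]
        assert scores == sorted(scores, reverse=True)
        for p in preds:
            assert p.box == tight_bbox(p.mask)
            assert 0.5 <= p.score <= 1.0
        counts = [len(predict(state, ann.image, score_threshold=t))
                  for t in (0.0, 0.5, 0.8, 0.95, 1.0)]
        assert counts == sorted(counts, reverse=True)


def test_blank_background_image_yields_no_predictions(trained_state):
    state, _ = trained_state
    rng = np.random.default_rng(0)
    blank = np.clip(rng.normal(200, 4, (128, 128)), 0, 255).astype(np.uint8)
    assert predict(state, blank, score_threshold=0.7) == []


def test_trained_model_segments_heldout_scenes(trained_state, easy_config):
    state, _ = trained_state
    test = generate_images(easy_config, 6, seed=55)
    preds = [predict(state, a.image, 0.7) for a in test]
    report = evaluate_dataset(preds, test, 0.7, gt_labels={"crystal_G"})
    assert report.mean_f >= 0.7


def test_checkpoint_round_trip_is_bit_identical(tmp_path, trained_state,
                                                easy_config):
    state, _ = trained_state
    path = tmp_path / "model.ckpt.json"
    save_model(state, path)
    loaded = load_model(path)
    assert loaded.params == state.params
    assert loaded.lineage == state.lineage
    img = generate_images(easy_config, 1, seed=91)[0].image
    a = predict(state, img, 0.5)
    b = predict(loaded, img, 0.5)
    assert len(a) == len(b)
    for pa, pb in zip(a, b):
        assert pa.score == pb.score
        np.testing.assert_array_equal(pa.mask, pb.mask)


def test_rgb_and_grayscale_inputs_predict_identically(trained_state,
                                                      easy_config):
    # datasets on disk are 8-bit RGB PNGs; in-memory renders are 2-D
    state, _ = trained_state
    gray = generate_images(easy_config, 1, seed=42)[0].image
    rgb = np.stack([gray] * 3, axis=-1)
    a = predict(state, gray, 0.5)
    b = predict(state, rgb, 0.5)
    assert len(a) == len(b) > 0
    for pa, pb in zip(a, b):
        assert pa.score == pb.score
        np.testing.assert_array_equal(pa.mask, pb.mask)


def test_instance_prediction_invariants():
    m = np.zeros((8, 8), dtype=bool)
    m[2:4, 3:6] = True
    p = InstancePrediction(mask=m, score=0.9, label="crystal")
    assert p.box == (3, 2, 5, 3)
    with pytest.raises(ValueError, match="nonempty"):
        InstancePrediction(mask=np.zeros((8, 8), bool), score=0.9, label="x")
    with pytest.raises(ValueError, match="score"):
        InstancePrediction(mask=m, score=1.5, label="x")
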