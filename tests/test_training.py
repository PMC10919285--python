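"""Training schedule, preprocessing geometry, split hygiene and the
experiment designs."""

import numpy as np
import pytest

from musclesegkit.core import LabelMap, Subject, Volume
from musclesegkit.networks import NetworkConfig, build_network
from musclesegkit.phantom import PhantomSpec, generate_cohort
from musclesegkit.training import (
    SliceDataset,
    TrainConfig,
    _crop_or_pad_width,
    _random_crops,
    default_batch_size,
    predict,
    preprocess,
    run_experiment,
    train,
)


@pytest.fixture(scope="module")
def tiny_train():
    """A 3-epoch training run on a tiny task, shared by schedule tests."""
    spec = PhantomSpec(grid_shape=(24, 24, 16), n_muscles=2, seed=2)
    cohort = generate_cohort(spec, 3, seed=2)
    cfg = TrainConfig(epochs=3, seed=0).scaled_for((24, 24, 16))
    net = build_network(NetworkConfig(arch="unet", n_classes=3, base_width=4,
                                      depth=4, seed=0))
    ds = SliceDataset.from_subjects(cohort, cfg)
    return train(net, ds, cfg), cfg, net, ds


# ---------------------------------------------------------------------------
# config + schedule


def test_learning_rate_schedule_closed_form(tiny_train):
    result, cfg, *_ = tiny_train
    for _, row in result.log.iterrows():
        expected = 0.01 * 0.9 ** int(row["epoch"])
        assert abs(row["lr"] - expected) < 1e-12
    assert abs(cfg.lr_at(1) - 0.009) < 1e-15


def test_best_checkpoint_is_max_over_epochs(tiny_train):
    result, *_ = tiny_train
    assert result.best_val_dsc == result.log["val_dsc"].max()


def test_batch_size_defaults_by_architecture():
    assert default_batch_size("unet") == 16
    assert default_batch_size("unetpp") == 16
    assert default_batch_size("ffu") == 10
    assert default_batch_size("affu") == 10


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        TrainConfig(lr_decay=0.0)
    with pytest.raises(ValueError):
        TrainConfig(crop_width_input=100, crop_width_random=125)


def test_scaled_config_preserves_crop_ratio():
    cfg = TrainConfig().scaled_for((48, 48, 96))
    assert cfg.crop_width_input == 48
    assert cfg.crop_width_random == round(48 * 125 / 256)


# ---------------------------------------------------------------------------
# preprocessing geometry


def test_wide_slice_center_cropped():
    arr = np.arange(300 * 4, dtype=np.float32).reshape(4, 300)
    out, off = _crop_or_pad_width(arr, 256)
    assert out.shape == (4, 256)
    assert off == 22
    assert np.array_equal(out, arr[:, 22:278])


def test_narrow_slice_zero_padded_symmetrically():
    arr = np.ones((4, 200), dtype=np.float32)
    out, off = _crop_or_pad_width(arr, 256)
    assert out.shape == (4, 256)
    assert off == -28
    assert out[:, :28].sum() == 0 and out[:, -28:].sum() == 0
    assert np.array_equal(out[:, 28:228], arr)


def test_label_histogram_preserved_inside_crop_window():
    spec = PhantomSpec(grid_shape=(24, 24, 16), n_muscles=2, seed=4)
    s = generate_cohort(spec, 1, seed=4)[0]
    cfg = TrainConfig().scaled_for((24, 24, 16))
    pairs = preprocess(s, cfg)
    for z, (_, lab) in enumerate(pairs):
        orig = s.labels.data[:, :, z]
        assert np.array_equal(
            np.bincount(lab.ravel(), minlength=3),
            np.bincount(orig.ravel(), minlength=3),
        )


def test_empty_label_subject_skipped_with_warning():
    vol = Volume(np.zeros((24, 24, 16)))
    lab = LabelMap(np.zeros((24, 24, 16), dtype=np.int32))
    s = Subject(id="empty", volume=vol, labels=lab)
    with pytest.warns(UserWarning, match="empty"):
        assert preprocess(s, TrainConfig()) == []


def test_random_crop_positions_cover_range_uniformly():
    """Chi-square sanity check over 10^4 crop draws."""
    from scipy import stats

    rng = np.random.default_rng(0)
    W, wr = 48, 23
    imgs = np.tile(np.arange(W, dtype=np.float32), (1, 1, 1, 1))
    positions = []
    for _ in range(10_000):
        out, _ = _random_crops(imgs, np.zeros((1, 1, W), np.int32), wr, rng)
        positions.append(int(out[0, 0, 0, 0]))
    n_pos = W - wr + 1
    counts = np.bincount(positions, minlength=n_pos)
    assert counts.min() > 0  # full valid range covered
    chi2 = ((counts - len(positions) / n_pos) ** 2 / (len(positions) / n_pos)).sum()
    p = stats.chi2.sf(chi2, df=n_pos - 1)
    assert p > 1e-3


# ---------------------------------------------------------------------------
# dataset split hygiene


def test_split_never_straddles_subjects(tiny_train):
    *_, ds = tiny_train
    subs = ds.subjects()
    tr, va = ds.split_by_subject([subs[-1]])
    assert set(tr.subject_ids).isdisjoint(set(va.subject_ids))
    assert set(tr.subject_ids) | set(va.subject_ids) == set(subs)


def test_degenerate_split_rejected(tiny_train):
    *_, ds = tiny_train
    with pytest.raises(ValueError):
        ds.split_by_subject(ds.subjects())


# ---------------------------------------------------------------------------
# training behaviour


def test_divergence_aborts_with_diagnostic():
    spec = PhantomSpec(grid_shape=(24, 24, 16), n_muscles=2, seed=2)
    cohort = generate_cohort(spec, 2, seed=2)
    cfg = TrainConfig(epochs=2, seed=0).scaled_for((24, 24, 16))
    net = build_network(NetworkConfig(arch="unet", n_classes=3, base_width=4,
                                      depth=4, seed=0))
    ds = SliceDataset.from_subjects(cohort, cfg)
    ds.images[0] = np.nan  # poisoned input makes the loss non-finite
    with pytest.raises(RuntimeError, match="diverged"):
        train(net, ds, cfg)


def test_prediction_labels_in_range_and_deterministic(tiny_train):
    _, cfg, net, _ = tiny_train
    spec = PhantomSpec(grid_shape=(24, 24, 16), n_muscles=2, seed=9)
    s = generate_cohort(spec, 1, seed=9)[0]
    a = predict(net, s.volume, cfg)
    b = predict(net, s.volume, cfg)
    assert np.array_equal(a.data, b.data)
    assert set(np.unique(a.data)) <= {0, 1, 2}
    assert a.shape == s.volume.shape


def test_predict_inverts_padding_for_narrow_volumes(tiny_train):
    _, _, net, _ = tiny_train
    cfg = TrainConfig(crop_width_input=32, crop_width_random=16)
    vol = Volume(np.random.default_rng(0).normal(size=(24, 24, 8)))
    out = predict(net, vol, cfg)
    assert out.shape == (24, 24, 8)


# ---------------------------------------------------------------------------
# experiment designs


def _stub(subject):
    return subject.labels


def test_leakage_guards():
    spec = PhantomSpec(grid_shape=(24, 24, 16), n_muscles=2, seed=6)
    cohort = generate_cohort(spec, 4, seed=6)
    cfg = TrainConfig(epochs=1).scaled_for((24, 24, 16))
    # overlap between train and test aborts
    with pytest.raises(ValueError, match="overlap"):
        run_experiment(
            "cross_cohort",
            {"train": cohort[:3], "test": cohort[2:]},
            cfg,
            predictor=_stub,
        )
    # augmented subject referencing a test subject aborts
    fake_aug = Subject(
        id="aug0",
        volume=cohort[0].volume,
        labels=cohort[0].labels,
        provenance="augmented",
        provenance_info={"reference_id": cohort[3].id},
    )
    with pytest.raises(ValueError, match="derives"):
        run_experiment(
            "augmented",
            {"train": cohort[:3] + [fake_aug], "test": cohort[3:]},
            cfg,
            predictor=_stub,
        )


def test_cross_validation_excludes_augmented_subjects():
    spec = PhantomSpec(grid_shape=(24, 24, 16), n_muscles=2, seed=6)
    cohort = generate_cohort(spec, 3, seed=6)
    aug = Subject(
        id="aug0",
        volume=cohort[0].volume,
        labels=cohort[0].labels,
        provenance="augmented",
        provenance_info={"reference_id": cohort[0].id},
    )
    cfg = TrainConfig(epochs=1).scaled_for((24, 24, 16))
    table = run_experiment(
        "cross_validation", {"train": cohort + [aug]}, cfg, predictor=_stub
    )
    assert set(table["subject_id"]) == {s.id for s in cohort}
    assert len(table) == 3 * 2  # 3 folds x 2 labels


def test_stub_predictor_scores_perfectly():
    spec = PhantomSpec(grid_shape=(24, 24, 16), n_muscles=2, seed=6)
    cohort = generate_cohort(spec, 3, seed=6)
    cfg = TrainConfig(epochs=1).scaled_for((24, 24, 16))
    table = run_experiment(
        "cross_cohort", {"train": cohort[:2], "test": cohort[2:]}, cfg,
        predictor=_stub,
    )
    assert (table["dsc"] == 1.0).all()
    assert (table["hd_mm"] == 0.0).all()
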