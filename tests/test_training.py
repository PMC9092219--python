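"""Dice loss analytics, gradient correctness, and the training contract."""

import numpy as np
import pytest

from la_recon.nn import NetworkConfig, build_network
from la_recon.training import (
    DatasetSplit,
    TrainConfig,
    cache_dataset,
    dice_coefficient,
    dice_loss,
    dice_loss_grad,
    load_cache,
    train,
)
from la_recon.types import LAGeometry, PartialShell

TINY = NetworkConfig(base_width=2, levels=2, kernel_size=3, dropout_rate=0.0, input_shape=(16, 16, 16))


def _tiny_pairs(n, seed=0, shape=(16, 16, 16)):
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        c = rng.uniform(5, np.array(shape) - 5)
        g = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij", sparse=True)
        ball = sum((gi - ci) ** 2 for gi, ci in zip(g, c)) <= rng.uniform(3, 5) ** 2
        shell = ball & ~np.roll(ball, 1, axis=0)
        pairs.append(
            (PartialShell(volume=shell, spacing_mm=1.0), LAGeometry(mask=ball, spacing_mm=1.0))
        )
    return pairs


# -- loss analytics ------------------------------------------------------------
def test_dice_loss_hand_values():
    truth = np.zeros((5, 5, 5))
    truth.ravel()[:10] = 1.0
    assert dice_loss(truth, truth) == 0.0  # identity: coefficient (2k+1)/(2k+1)
    assert dice_coefficient(np.zeros_like(truth), truth) == pytest.approx(1 / 11)
    assert dice_loss(np.zeros_like(truth), truth) == pytest.approx(10 / 11)
    pred = np.zeros((5, 5, 5))
    pred.ravel()[10:15] = 1.0
    truth2 = np.zeros((5, 5, 5))
    truth2.ravel()[:5] = 1.0
    assert dice_coefficient(pred, truth2) == pytest.approx(1 / 11)  # disjoint 5+5


def test_dice_loss_bounds_and_monotone_interpolation():
    rng = np.random.default_rng(0)
    truth = (rng.random((8, 8, 8)) < 0.3).astype(float)
    losses = [dice_loss(t * truth, truth) for t in np.linspace(0, 1, 11)]
    assert all(0 <= v < 1 for v in losses)
    assert all(a > b for a, b in zip(losses, losses[1:]))  # strictly decreasing
    with pytest.raises(ValueError, match="shape"):
        dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))


def test_dice_loss_grad_matches_finite_differences():
    rng = np.random.default_rng(1)
    pred = rng.random((6, 6, 6))
    truth = (rng.random((6, 6, 6)) < 0.4).astype(float)
    grad = dice_loss_grad(pred, truth)
    for _ in range(5):
        i = tuple(rng.integers(0, 6, size=3))
        eps = 1e-6
        up, down = pred.copy(), pred.copy()
        up[i] += eps
        down[i] -= eps
        fd = (dice_loss(up, truth) - dice_loss(down, truth)) / (2 * eps)
        assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-9)


# -- training contract ---------------------------------------------------------
def test_toy_training_contract():
    pairs = _tiny_pairs(4)
    split = DatasetSplit(train=pairs[:2], validation=pairs[2:])
    net = build_network(TINY, seed=0)
    res = train(split, net, TrainConfig(learning_rate=1e-3, max_epochs=3, patience=3, seed=0))
    assert len(res.history) <= 3
    assert res.best_val_dice == pytest.approx(res.history.val_dice.max())
    assert res.best_epoch == int(res.history.val_dice.idxmax())


def test_returned_weights_are_best_epoch_not_last():
    """After restoring the checkpoint, re-evaluating validation dice
    reproduces the recorded best value."""
    from la_recon.training import _validation_dice

    pairs = _tiny_pairs(6, seed=3)
    split = DatasetSplit(train=pairs[:4], validation=pairs[4:])
    net = build_network(TINY, seed=1)
    res = train(split, net, TrainConfig(learning_rate=3e-3, max_epochs=4, patience=4, seed=1))
    assert _validation_dice(res.network, split.validation) == pytest.approx(res.best_val_dice)


def test_patience_zero_stops_at_first_non_improvement():
    pairs = _tiny_pairs(4, seed=5)
    split = DatasetSplit(train=pairs[:2], validation=pairs[2:])
    net = build_network(TINY, seed=2)
    # a vanishing learning rate freezes validation dice, so epoch 1 cannot
    # improve on epoch 0 and patience 0 must stop right there
    res = train(split, net, TrainConfig(learning_rate=1e-16, max_epochs=50, patience=0, seed=2))
    dices = res.history.val_dice.to_numpy()
    assert len(dices) == 2
    assert dices[1] <= dices[0]


def test_training_learns_on_its_own_sample():
    """A few steps on one sample beat both the untrained network and the
    empty prediction on that same sample."""
    pairs = _tiny_pairs(2, seed=7)
    split = DatasetSplit(train=[pairs[0]], validation=[pairs[0]])
    net = build_network(TINY, seed=3)
    x = pairs[0][0].volume.astype(np.float32)[None]
    g = pairs[0][1].mask
    p0 = net.forward(x)
    dice_before = dice_coefficient(p0[1] > p0[0], g)
    res = train(split, net, TrainConfig(learning_rate=1e-2, max_epochs=15, patience=15, seed=3))
    p1 = res.network.forward(x)
    dice_after = dice_coefficient(p1[1] > p1[0], g)
    dice_empty = dice_coefficient(np.zeros_like(g, dtype=float), g)
    assert dice_after > dice_before
    assert dice_after > dice_empty


def test_epoch_zero_deterministic_given_seed():
    pairs = _tiny_pairs(4, seed=9)
    split = DatasetSplit(train=pairs[:2], validation=pairs[2:])
    losses = []
    for _ in range(2):
        net = build_network(TINY, seed=4)
        res = train(split, net, TrainConfig(max_epochs=1, patience=1, seed=4))
        losses.append(res.history.train_loss.iloc[0])
    assert losses[0] == losses[1]


def test_empty_split_rejected():
    with pytest.raises(ValueError, match="non-empty"):
        train(DatasetSplit(train=[], validation=[]), build_network(TINY, seed=0), TrainConfig())


# -- dataset cache -------------------------------------------------------------
def test_cache_round_trip_bit_exact(tmp_path):
    pairs = _tiny_pairs(3, seed=11)
    path = tmp_path / "cache.h5"
    cache_dataset(pairs, path)
    shells, labels, spacing = load_cache(path)
    assert shells.shape[0] == labels.shape[0] == 3
    assert spacing == 1.0
    for i, (shell, label) in enumerate(pairs):
        assert np.array_equal(shells[i] > 0, shell.volume)
        assert np.array_equal(labels[i] > 0, label.mask)


def test_cache_rejects_heterogeneous_shapes(tmp_path):
    pairs = _tiny_pairs(2) + _tiny_pairs(1, shape=(12, 12, 12))
    with pytest.raises(ValueError, match="cases \\[2\\]"):
        cache_dataset(pairs, tmp_path / "bad.h5")


def test_corrupt_cache_raises_descriptive_error(tmp_path):
    path = tmp_path / "corrupt.h5"
    path.write_bytes(b"this is not an hdf5 file")
    with pytest.raises(ValueError, match="cannot read dataset cache"):
        load_cache(path)


def test_config_validation():
    with pytest.raises(ValueError, match="beta"):
        TrainConfig(adam_beta1=0.999, adam_beta2=0.9)
    with pytest.raises(ValueError, match="patience"):
        TrainConfig(patience=10, max_epochs=5)
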