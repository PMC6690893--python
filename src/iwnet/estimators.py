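"""Scikit-learn style estimators wrapping the segmentation networks.

:class:`UNetSegmenter` trains the automatic block alone with the soft IoU
loss.  :class:`IWNetSegmenter` performs the full two-stage recipe: the
first block is trained with the IoU loss until validation stops improving,
its weights are frozen, and the correction block is then trained with the
combined IoU + attraction loss, pairing every nodule with each annotator's
mask and re-simulating the two-point user input every epoch.

Both estimators follow the scikit-learn contract (``get_params`` /
``set_params`` / fitted attributes with trailing underscores) so they
compose with ``sklearn.base.clone`` and model-selection utilities.  Inputs
``X`` are ``(n, nx, ny, nz)`` arrays of normalized intensity cubes.
"""

from __future__ import annotations

import copy
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .architecture import BlockSpec, IWNetModel, UNetBlock
from .field_map import WeightMap, weight_map
from .geometry import GridGeometry, PointPair
from .interaction import simulate_user_input
from .losses import (LossWeights, attraction_loss, attraction_loss_grad,
                     combined_loss, iou_loss, iou_loss_grad)

__all__ = ["UNetSegmenter", "IWNetSegmenter", "EarlyStopping"]


class EarlyStopping:
    """Stop when the validation loss fails to strictly improve.

    ``patience`` consecutive non-improving epochs end training; the best
    epoch's weights are kept for restoration.
    """

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = 0
        self.best_state = None
        self._since = 0
        self.epoch = 0

    def update(self, val_loss: float, state=None) -> bool:
        """Record one epoch; returns True when training should stop."""
        self.epoch += 1
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = self.epoch
            self.best_state = state
            self._since = 0
        else:
            self._since += 1
        return self._since >= self.patience


def _batches(n: int, batch_size: int, rng: Optional[np.random.Generator]):
    idx = np.arange(n)
    if rng is not None:
        rng.shuffle(idx)
    for start in range(0, n, batch_size):
        yield idx[start:start + batch_size]


def _val_split(n: int, val_fraction: float, rng: np.random.Generator):
    idx = np.arange(n)
    rng.shuffle(idx)
    n_val = max(1, int(round(val_fraction * n))) if n > 1 else 0
    return idx[n_val:], idx[:n_val]


def _block_state(block: UNetBlock):
    return [a.copy() for a in block.state_arrays()]


class UNetSegmenter(BaseEstimator):
    """Automatic nodule segmentation with a single encoder--decoder block.

    Parameters
    ----------
    filters : tuple of int
        Channel widths per resolution level (last entry: bottleneck).
    learning_rate, batch_size : Adam step size and mini-batch size.
    patience : epochs without validation improvement before stopping.
    max_epochs : hard cap on training epochs.
    val_fraction : fraction of samples held out for validation.
    threshold : binarization threshold of :meth:`predict`.
    seed : seeds weight initialization, the split and the shuffling.
    """

    def __init__(self, filters: Tuple[int, ...] = (12, 24, 68, 110),
                 n_bottleneck: int = 2, learning_rate: float = 1e-3,
                 batch_size: int = 8, patience: int = 3, max_epochs: int = 50,
                 val_fraction: float = 0.2, threshold: float = 0.5,
                 seed: int = 0):
        self.filters = filters
        self.n_bottleneck = n_bottleneck
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.patience = patience
        self.max_epochs = max_epochs
        self.val_fraction = val_fraction
        self.threshold = threshold
        self.seed = seed

    def _validate_xy(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4:
            raise ValueError("X must be (n_samples, nx, ny, nz)")
        if X.min() < 0 or X.max() > 1:
            raise ValueError("images must be normalized to [0, 1]")
        y = np.asarray(y).astype(bool)
        if y.shape != X.shape:
            raise ValueError("y must match X voxel-for-voxel")
        return X, y

    def fit(self, X, y, val_indices=None):
        X, y = self._validate_xy(X, y)
        if not y.any():
            raise ValueError("degenerate cohort: all masks are empty")
        rng = np.random.default_rng(self.seed)
        spec = BlockSpec(tuple(self.filters), input_channels=1,
                         n_bottleneck=self.n_bottleneck)
        block = UNetBlock(spec, rng)
        if val_indices is not None:
            val_idx = np.asarray(val_indices, dtype=int)
            train_idx = np.setdiff1d(np.arange(len(X)), val_idx)
        else:
            train_idx, val_idx = _val_split(len(X), self.val_fraction, rng)
        if len(val_idx) == 0:
            train_idx = val_idx = np.arange(len(X))
        opt = nn.Adam(block.layers(), lr=self.learning_rate)
        stopper = EarlyStopping(self.patience)
        self.history_ = []
        for epoch in range(self.max_epochs):
            tr_loss = _run_iou_epoch(block, opt, X[train_idx], y[train_idx],
                                     self.batch_size, rng)
            val_loss = _iou_val_loss(block, X[val_idx], y[val_idx],
                                     self.batch_size)
            self.history_.append({"epoch": epoch + 1, "train_loss": tr_loss,
                                  "val_loss": val_loss})
            if stopper.update(val_loss, _block_state(block)):
                break
        if stopper.best_state is not None:
            block.load_state_arrays(stopper.best_state)
        self.block_ = block
        self.best_epoch_ = stopper.best_epoch
        self.n_params_ = block.n_params()
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[None]
        out = np.empty(X.shape, dtype=np.float32)
        for sl in _batches(len(X), self.batch_size, None):
            out[sl] = self.block_.forward(X[sl][:, None], training=False)[:, 0]
        return out

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X) >= self.threshold


def _run_iou_epoch(block, opt, X, y, batch_size, rng) -> float:
    losses = []
    for sl in _batches(len(X), batch_size, rng):
        xb, yb = X[sl][:, None], y[sl]
        pred = block.forward(xb, training=True)
        opt.zero_grad()
        grad = np.empty_like(pred)
        for i in range(len(sl)):
            losses.append(iou_loss(yb[i], pred[i, 0]))
            grad[i, 0] = iou_loss_grad(yb[i], pred[i, 0]) / len(sl)
        block.backward(grad)
        opt.step()
    return float(np.mean(losses))


def _iou_val_loss(block, X, y, batch_size) -> float:
    losses = []
    for sl in _batches(len(X), batch_size, None):
        pred = block.forward(X[sl][:, None], training=False)
        for i in range(len(sl)):
            losses.append(iou_loss(y[sl][i], pred[i, 0]))
    return float(np.mean(losses))


class IWNetSegmenter(BaseEstimator):
    """Two-block interactive segmentation trained in two stages.

    ``fit`` expects ``X`` as ``(n, nx, ny, nz)`` images and ``y`` as a list
    of per-nodule lists of annotator masks; every (nodule, annotator) pair
    is one training sample.  ``gamma``, ``p`` and ``lambda1`` default to the
    values found by random search at full scale (0.59, 0.44, 0.68).
    """

    def __init__(self, filters: Tuple[int, ...] = (12, 24, 68, 110),
                 n_bottleneck: int = 2, learning_rate: float = 1e-3,
                 batch_size: int = 8, gamma: float = 0.59, p: float = 0.44,
                 lambda1: float = 0.68, stage1_patience: int = 3,
                 stage2_patience: int = 5, stage1_max_epochs: int = 50,
                 stage2_max_epochs: int = 50, val_fraction: float = 0.2,
                 threshold: float = 0.5, seed: int = 0):
        self.filters = filters
        self.n_bottleneck = n_bottleneck
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.gamma = gamma
        self.p = p
        self.lambda1 = lambda1
        self.stage1_patience = stage1_patience
        self.stage2_patience = stage2_patience
        self.stage1_max_epochs = stage1_max_epochs
        self.stage2_max_epochs = stage2_max_epochs
        self.val_fraction = val_fraction
        self.threshold = threshold
        self.seed = seed

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y, val_indices=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4:
            raise ValueError("X must be (n_samples, nx, ny, nz)")
        if len(y) != len(X):
            raise ValueError("y must hold one list of annotator masks per image")
        masks_per_nodule = [[np.asarray(m).astype(bool) for m in ms] for ms in y]
        if not any(m.any() for ms in masks_per_nodule for m in ms):
            raise ValueError("degenerate cohort: all masks are empty")
        rng = np.random.default_rng(self.seed)
        spec1 = BlockSpec(tuple(self.filters), input_channels=1,
                          n_bottleneck=self.n_bottleneck)
        spec2 = BlockSpec(tuple(self.filters), input_channels=3,
                          n_bottleneck=self.n_bottleneck)
        block1 = UNetBlock(spec1, rng)
        block2 = UNetBlock(spec2, rng)

        # expand (nodule, annotator) pairs; split at nodule level unless the
        # caller supplies explicit validation indices (e.g. held-out scans)
        if val_indices is not None:
            val_nod = np.asarray(val_indices, dtype=int)
            train_nod = np.setdiff1d(np.arange(len(X)), val_nod)
        else:
            train_nod, val_nod = _val_split(len(X), self.val_fraction, rng)
        if len(val_nod) == 0:
            train_nod = val_nod = np.arange(len(X))
        train_pairs = [(i, a) for i in train_nod
                       for a in range(len(masks_per_nodule[i]))]
        val_pairs = [(i, a) for i in val_nod
                     for a in range(len(masks_per_nodule[i]))]

        # ---- stage 1: automatic block alone, IoU loss
        opt1 = nn.Adam(block1.layers(), lr=self.learning_rate)
        stop1 = EarlyStopping(self.stage1_patience)
        self.history_ = []
        for epoch in range(self.stage1_max_epochs):
            tr = self._stage1_epoch(block1, opt1, X, masks_per_nodule,
                                    train_pairs, rng)
            vl = self._stage1_val(block1, X, masks_per_nodule, val_pairs)
            self.history_.append({"stage": 1, "epoch": epoch + 1,
                                  "train_loss": tr, "val_loss": vl})
            if stop1.update(vl, _block_state(block1)):
                break
        if stop1.best_state is not None:
            block1.load_state_arrays(stop1.best_state)
        block1.frozen = True  # weights frozen; stage 2 runs it in eval mode

        # ---- stage 2: full model, combined loss, block 2 only
        geometry = GridGeometry(X.shape[1:])
        weights = LossWeights(self.lambda1)
        val_maps = self._maps_for_pairs(X, masks_per_nodule, val_pairs,
                                        geometry, mode="eval")
        # block 1 is frozen and in inference mode: its outputs are fixed,
        # so compute them once for the whole cohort
        initial_cache = np.empty(X.shape, dtype=np.float32)
        for sl in _batches(len(X), self.batch_size, None):
            initial_cache[sl] = block1.forward(X[sl][:, None],
                                               training=False)[:, 0]
        opt2 = nn.Adam(block2.layers(), lr=self.learning_rate)
        stop2 = EarlyStopping(self.stage2_patience)
        train_maps = None
        for epoch in range(self.stage2_max_epochs):
            if train_maps is None:  # masks are fixed, so the simulated
                # input repeats across epochs; reuse the maps
                train_maps = self._maps_for_pairs(X, masks_per_nodule,
                                                  train_pairs, geometry,
                                                  mode="train")
            tr = self._stage2_epoch(block1, block2, opt2, X, masks_per_nodule,
                                    train_pairs, train_maps, weights, rng,
                                    initial_cache)
            vl = self._stage2_val(block1, block2, X, masks_per_nodule,
                                  val_pairs, val_maps, weights, initial_cache)
            self.history_.append({"stage": 2, "epoch": epoch + 1,
                                  "train_loss": tr, "val_loss": vl})
            if stop2.update(vl, _block_state(block2)):
                break
        if stop2.best_state is not None:
            block2.load_state_arrays(stop2.best_state)

        self.model_ = IWNetModel(block1, block2)
        self.n_params_ = self.model_.n_params()
        self.stage1_best_epoch_ = stop1.best_epoch
        self.stage2_best_epoch_ = stop2.best_epoch
        return self

    def _maps_for_pairs(self, X, masks, pairs, geometry, mode):
        """Weight map per (nodule, annotator) pair from simulated input.

        Pairs whose mask is too small to carry a diameter stroke fall back
        to the zero map (no guidance, no attraction penalty).
        """
        maps = {}
        for (i, a) in pairs:
            try:
                pts = simulate_user_input(masks[i][a], mode)
                maps[(i, a)] = weight_map(pts, self.p, geometry).values.astype(
                    np.float32)
            except ValueError:
                maps[(i, a)] = np.zeros(geometry.shape, dtype=np.float32)
        return maps

    def _stage1_epoch(self, block1, opt, X, masks, pairs, rng) -> float:
        losses = []
        for sl in _batches(len(pairs), self.batch_size, rng):
            batch = [pairs[j] for j in sl]
            xb = X[[i for i, _ in batch]][:, None]
            pred = block1.forward(xb, training=True)
            opt.zero_grad()
            grad = np.empty_like(pred)
            for bi, (i, a) in enumerate(batch):
                losses.append(iou_loss(masks[i][a], pred[bi, 0]))
                grad[bi, 0] = iou_loss_grad(masks[i][a], pred[bi, 0]) / len(batch)
            block1.backward(grad)
            opt.step()
        return float(np.mean(losses))

    def _stage1_val(self, block1, X, masks, pairs) -> float:
        losses = []
        for sl in _batches(len(pairs), self.batch_size, None):
            batch = [pairs[j] for j in sl]
            pred = block1.forward(X[[i for i, _ in batch]][:, None],
                                  training=False)
            for bi, (i, a) in enumerate(batch):
                losses.append(iou_loss(masks[i][a], pred[bi, 0]))
        return float(np.mean(losses))

    def _stage2_forward(self, block1, block2, X, batch, maps, training,
                        initial_cache=None):
        xb = X[[i for i, _ in batch]][:, None]
        if initial_cache is not None:
            initial = initial_cache[[i for i, _ in batch]][:, None]
        else:
            initial = block1.forward(xb, training=False)
        mb = np.stack([maps[key] for key in batch])[:, None]
        x2 = np.concatenate([xb, initial, mb], axis=1)
        corrected = block2.forward(x2, training=training)
        return corrected

    def _pair_loss_grad(self, truth, m_map, pred, weights):
        wm = WeightMap(np.asarray(m_map, dtype=np.float64), normalized=True)
        loss = combined_loss(truth, pred, wm, self.gamma, weights)
        grad = (weights.lambda1 * iou_loss_grad(truth, pred)
                + (1.0 - weights.lambda1)
                * attraction_loss_grad(wm, self.gamma, pred))
        return loss, grad

    def _stage2_epoch(self, block1, block2, opt, X, masks, pairs, maps,
                      weights, rng, initial_cache=None) -> float:
        losses = []
        for sl in _batches(len(pairs), self.batch_size, rng):
            batch = [pairs[j] for j in sl]
            corrected = self._stage2_forward(block1, block2, X, batch, maps,
                                             training=True,
                                             initial_cache=initial_cache)
            opt.zero_grad()
            grad = np.empty_like(corrected)
            for bi, (i, a) in enumerate(batch):
                loss, g = self._pair_loss_grad(masks[i][a], maps[(i, a)],
                                               corrected[bi, 0], weights)
                losses.append(loss)
                grad[bi, 0] = g / len(batch)
            block2.backward(grad)
            opt.step()
        return float(np.mean(losses))

    def _stage2_val(self, block1, block2, X, masks, pairs, maps, weights,
                    initial_cache=None) -> float:
        losses = []
        for sl in _batches(len(pairs), self.batch_size, None):
            batch = [pairs[j] for j in sl]
            corrected = self._stage2_forward(block1, block2, X, batch, maps,
                                             training=False,
                                             initial_cache=initial_cache)
            for bi, (i, a) in enumerate(batch):
                loss, _ = self._pair_loss_grad(masks[i][a], maps[(i, a)],
                                               corrected[bi, 0], weights)
                losses.append(loss)
        return float(np.mean(losses))

    # -- prediction ---------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        """Automatic (first-block) soft prediction."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[None]
        out = np.empty(X.shape, dtype=np.float32)
        for sl in _batches(len(X), self.batch_size, None):
            out[sl] = self.model_.block1.forward(X[sl][:, None],
                                                 training=False)[:, 0]
        return out

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X) >= self.threshold

    def predict_guided(self, X, points: Sequence[Optional[PointPair]]):
        """Initial and corrected soft predictions for per-sample point pairs."""
        X = np.asarray(X, dtype=np.float32)
        squeeze = X.ndim == 3
        if squeeze:
            X = X[None]
            points = [points] if isinstance(points, (PointPair, type(None))) \
                else points
        if len(points) != len(X):
            raise ValueError("need one PointPair (or None) per sample")
        geometry = GridGeometry(X.shape[1:])
        maps = np.empty(X.shape, dtype=np.float32)
        for i, pts in enumerate(points):
            maps[i] = weight_map(pts, self.p, geometry).values
        init = np.empty(X.shape, dtype=np.float32)
        corr = np.empty(X.shape, dtype=np.float32)
        for sl in _batches(len(X), self.batch_size, None):
            a, b = self.model_.forward_guided(X[sl][:, None],
                                              maps[sl][:, None],
                                              training=False)
            init[sl], corr[sl] = a[:, 0], b[:, 0]
        if squeeze:
            return init[0], corr[0]
        return init, corr
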