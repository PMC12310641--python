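"""Scikit-learn style estimator facade for the segmentation stage.

`AtDUNetSegmenter` wraps network construction, the training loop and
mask inference behind the familiar ``fit`` / ``predict`` /
``get_params`` / ``set_params`` surface, so the segmenter composes with
sklearn model-selection utilities.  The geometric measurement stage has
no learned state and stays functional (:func:`lidcurve.measure.measure_eye`).
"""
from __future__ import annotations

import numpy as np

from .network import NetConfig, build_network
from .training import TrainConfig, fit_network, infer_masks, prepare_sample


class AtDUNetSegmenter:
    """Dual-head eyelid/cornea segmenter with an sklearn-like interface.

    Parameters mirror :class:`NetConfig` and :class:`TrainConfig`.
    Fitted attributes: ``network_`` (trained AtDU-Net), ``history_``
    (per-epoch log), ``best_dice_`` (best held-out mean Dice).

    ``fit(X, y)`` takes ``X`` as an array/list of RGB images (H, W, 3)
    and ``y`` as paired boolean masks of shape (N, H, W, 2) ordered
    (fissure, cornea).  ``predict(X)`` returns masks in that layout.
    """

    def __init__(self, *, base_channels: int = 8, depth: int = 3,
                 use_has: bool = True, use_sad: bool = True,
                 dual_decoder: bool = True,
                 heads_enabled: tuple[str, ...] = ("fissure", "cornea"),
                 input_size: tuple[int, int] = (96, 144),
                 epochs: int = 30, batch_size: int = 2,
                 learning_rate: float = 1e-3, threshold: float = 0.5,
                 augment: bool = True, crop_fraction: float = 0.85,
                 holdout_fraction: float = 30.0 / 130.0,
                 random_state: int = 0):
        self.base_channels = base_channels
        self.depth = depth
        self.use_has = use_has
        self.use_sad = use_sad
        self.dual_decoder = dual_decoder
        self.heads_enabled = heads_enabled
        self.input_size = input_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.threshold = threshold
        self.augment = augment
        self.crop_fraction = crop_fraction
        self.holdout_fraction = holdout_fraction
        self.random_state = random_state

    # -- sklearn plumbing ---------------------------------------------
    _param_names = ("base_channels", "depth", "use_has", "use_sad",
                    "dual_decoder", "heads_enabled", "input_size", "epochs",
                    "batch_size", "learning_rate", "threshold", "augment",
                    "crop_fraction", "holdout_fraction", "random_state")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "AtDUNetSegmenter":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _net_config(self) -> NetConfig:
        cfg = NetConfig(base_channels=self.base_channels, depth=self.depth,
                        use_has=self.use_has, use_sad=self.use_sad,
                        dual_decoder=self.dual_decoder,
                        heads_enabled=tuple(self.heads_enabled),
                        input_size=tuple(self.input_size))
        cfg.validate()
        return cfg

    def _train_config(self) -> TrainConfig:
        tc = TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                         learning_rate=self.learning_rate,
                         seed=self.random_state,
                         augment_crop=self.augment, augment_hflip=self.augment,
                         augment_vflip=self.augment,
                         crop_fraction=self.crop_fraction,
                         threshold=self.threshold)
        tc.validate()
        return tc

    # -- estimator API -------------------------------------------------
    def fit(self, X, y) -> "AtDUNetSegmenter":
        X = list(X)
        y = np.asarray(y)
        if len(X) != len(y) or y.ndim != 4 or y.shape[3] != 2:
            raise ValueError("y must be (n_samples, H, W, 2) masks paired with X")
        samples = []
        for i, (img, masks) in enumerate(zip(X, y)):
            im, fis, cor = prepare_sample(np.asarray(img), masks[..., 0].astype(bool),
                                          masks[..., 1].astype(bool),
                                          tuple(self.input_size))
            samples.append({"id": f"s{i:04d}", "image": im,
                            "fissure": fis, "cornea": cor})
        n_test = max(int(round(len(samples) * self.holdout_fraction)), 1)
        if len(samples) - n_test < 1:
            raise ValueError("need at least 1 training sample after holdout")
        manifest = {"train": [s["id"] for s in samples[:-n_test]],
                    "test": [s["id"] for s in samples[-n_test:]]}
        by_id = {s["id"]: s for s in samples}

        # fit_network loads from a manifest; feed it preloaded samples
        net = build_network(self._net_config(), seed=self.random_state)
        tc = self._train_config()
        net, log = fit_network(net, manifest, tc, preloaded=by_id)
        self.network_ = net
        self.history_ = log
        self.best_dice_ = max(l["test_mean_dice"] for l in log) if log else float("nan")
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        h, w = self.input_size
        out = np.zeros((len(X), h, w, 2), dtype=bool)
        for i, img in enumerate(X):
            im, _, _ = prepare_sample(np.asarray(img),
                                      np.zeros(np.asarray(img).shape[:2], bool),
                                      np.zeros(np.asarray(img).shape[:2], bool),
                                      (h, w))
            masks = infer_masks(self.network_, im, self.threshold)
            out[i, ..., 0] = masks.get("fissure", False)
            out[i, ..., 1] = masks.get("cornea", False)
        return out

    def score(self, X, y) -> float:
        """Mean Dice over heads and samples (higher is better)."""
        from .metrics import overlap_scores
        pred = self.predict(X)
        y = np.asarray(y)
        # resize targets to the working resolution, then Dice
        dices = []
        for i in range(len(pred)):
            _, fis, cor = prepare_sample(np.asarray(X[i]),
                                         y[i, ..., 0].astype(bool),
                                         y[i, ..., 1].astype(bool),
                                         tuple(self.input_size))
            dices.append(overlap_scores(pred[i, ..., 0], fis)[1])
            dices.append(overlap_scores(pred[i, ..., 1], cor)[1])
        return float(np.mean(dices))

    def _check_fitted(self) -> None:
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
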