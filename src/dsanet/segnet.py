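"""Multi-task segmentation network (Model 1).

Variants
--------
``baseline``      U-Net on the key frame alone
``baseline_tdl``  adds a temporal-difference encoder on the 10-frame window,
                  supervised with an L1 loss against the frame-difference
                  target; its output map joins the segmentation input
``baseline_lrs``  adds a liver-region U-Net supervised with BCE+Dice; its
                  probability map joins the segmentation input
``ffs``           the fusion variant: key frame + learned temporal
                  difference + liver probability, all subnets co-trained
                  under the composite loss λ0·L_ltd + λ1·L_lrs + L_seg

The composite-loss hyperparameters default to a=0.5, λ0=0.1, λ1=1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import Adam, Conv2d, Param, ReLU, Sequential, UNet, sigmoid
from .preprocess import KeyFrameBundle

EPS = 1e-7
VARIANTS = ("baseline", "baseline_tdl", "baseline_lrs", "ffs")


@dataclass
class SegLossWeights:
    a: float = 0.5
    lambda0: float = 0.1
    lambda1: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("a must be in [0, 1]")
        if self.lambda0 < 0 or self.lambda1 < 0:
            raise ValueError("lambda weights must be nonnegative")


@dataclass
class SegOutput:
    tumor_prob: np.ndarray
    liver_prob: np.ndarray | None
    ltd_map: np.ndarray | None
    tumor_mask: np.ndarray = field(init=False)
    liver_mask: np.ndarray | None = field(init=False)

    def __post_init__(self):
        self.tumor_mask = (self.tumor_prob >= 0.5).astype(np.uint8)
        self.liver_mask = (None if self.liver_prob is None
                           else (self.liver_prob >= 0.5).astype(np.uint8))


@dataclass
class SegModelConfig:
    variant: str = "ffs"
    unet_depth: int = 4
    base_channels: int = 16
    tdl_frames: int = 10
    tdl_channels: int = 8
    image_size: int = 64
    epochs: int = 8
    #: epochs spent training only the TDL/LRS subnets on their own losses
    #: before co-training starts (no-op for the plain baseline)
    warmup_epochs: int = 1
    batch_size: int = 4
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"choose from {VARIANTS}")
        if self.tdl_frames < 2:
            raise ValueError("tdl_frames must be >= 2")


# ---------------------------------------------------------------------------
# loss functions


def loss_ltd(ltd_map: np.ndarray, fd_map: np.ndarray) -> float:
    """Mean absolute difference between the learned and observed
    frame-difference maps (pixel-mean L1)."""
    ltd_map, fd_map = np.asarray(ltd_map), np.asarray(fd_map)
    if ltd_map.shape != fd_map.shape:
        raise ValueError(f"shape mismatch: {ltd_map.shape} vs {fd_map.shape}")
    return float(np.abs(ltd_map - fd_map).mean())


def combined_bce_dice(pred_prob: np.ndarray, target_mask: np.ndarray,
                      a: float = 0.5, smooth: float = 1.0) -> float:
    """a·BCE + (1−a)·(1 − soft Dice) with probability clamping at 1e−7."""
    p = np.asarray(pred_prob, dtype=np.float64)
    g = np.asarray(target_mask)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    if not np.isin(g, (0, 1)).all():
        raise ValueError("target mask must be binary")
    g = g.astype(np.float64)
    p = np.clip(p, EPS, 1.0 - EPS)
    bce = float(-(g * np.log(p) + (1.0 - g) * np.log(1.0 - p)).mean())
    dice = (2.0 * (p * g).sum() + smooth) / (p.sum() + g.sum() + smooth)
    return a * bce + (1.0 - a) * (1.0 - float(dice))


def loss_total(l_ltd: float, l_lrs: float, l_seg: float,
               w: SegLossWeights | None = None) -> float:
    """λ0·L_ltd + λ1·L_lrs + L_seg."""
    w = w or SegLossWeights()
    return w.lambda0 * l_ltd + w.lambda1 * l_lrs + l_seg


def _bce_dice_grad(p: np.ndarray, g: np.ndarray, a: float,
                   smooth: float = 1.0) -> np.ndarray:
    """dL/dp for combined_bce_dice on one image (clamped region has zero
    BCE gradient contribution outside the clamp)."""
    p = np.clip(p.astype(np.float64), EPS, 1.0 - EPS)
    g = g.astype(np.float64)
    n = p.size
    gbce = (p - g) / (p * (1.0 - p)) / n
    inter = (p * g).sum()
    denom = p.sum() + g.sum() + smooth
    gdice = -(2.0 * g * denom - (2.0 * inter + smooth)) / denom ** 2
    return (a * gbce + (1.0 - a) * gdice).astype(np.float32)


# ---------------------------------------------------------------------------
# model


class TDLNet(Sequential):
    """Shallow stride-1 encoder mapping the 10-frame stack to one map."""

    def __init__(self, in_frames: int, ch: int, rng: np.random.Generator):
        super().__init__(
            Conv2d(in_frames, ch, rng=rng), ReLU(),
            Conv2d(ch, ch, rng=rng), ReLU(),
            Conv2d(ch, 1, rng=rng),
        )


class SegModel:
    """One of the four segmentation variants with co-trained subnets."""

    def __init__(self, cfg: SegModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.tdl_net = None
        self.liver_net = None
        in_ch = 1
        if cfg.variant in ("baseline_tdl", "ffs"):
            self.tdl_net = TDLNet(cfg.tdl_frames, cfg.tdl_channels, rng)
            in_ch += 1
        if cfg.variant in ("baseline_lrs", "ffs"):
            self.liver_net = UNet(1, base=cfg.base_channels,
                                  depth=cfg.unet_depth, rng=rng)
            in_ch += 1
        self.seg_net = UNet(in_ch, base=cfg.base_channels,
                            depth=cfg.unet_depth, rng=rng)
        self.trained = False

    def params(self) -> list[Param]:
        ps: list[Param] = []
        for net in (self.tdl_net, self.liver_net, self.seg_net):
            if net is not None:
                ps.extend(net.params())
        return ps

    def _seg_input(self, kf, ltd, liver_prob):
        chans = [kf]
        if self.tdl_net is not None:
            chans.append(ltd)
        if self.liver_net is not None:
            chans.append(liver_prob)
        return np.concatenate(chans, axis=1)

    def forward(self, key_frames: np.ndarray,
                tdl_windows: np.ndarray | None = None) -> dict:
        """``key_frames`` (N,1,S,S); ``tdl_windows`` (N,F,S,S) when the
        variant uses the temporal encoder."""
        ltd = liver_prob = liver_logits = None
        if self.tdl_net is not None:
            if tdl_windows is None:
                raise ValueError("variant requires tdl_windows")
            ltd = self.tdl_net.forward(tdl_windows.astype(np.float32))
        if self.liver_net is not None:
            liver_logits = self.liver_net.forward(key_frames.astype(np.float32))
            liver_prob = sigmoid(liver_logits)
        x = self._seg_input(key_frames.astype(np.float32), ltd, liver_prob)
        seg_logits = self.seg_net.forward(x)
        return {
            "seg_logits": seg_logits,
            "seg_prob": sigmoid(seg_logits),
            "liver_prob": liver_prob,
            "ltd_map": ltd,
        }

    def train_step_aux(self, batch: dict, opt: Adam, w: SegLossWeights) -> dict:
        """Warm-up step: fit only the auxiliary subnets on their own losses
        so the fusion network starts from informative input channels."""
        losses = {"l_ltd": 0.0, "l_lrs": 0.0}
        opt.zero_grad()
        if self.tdl_net is not None:
            ltd = self.tdl_net.forward(batch["tdl_windows"].astype(np.float32))
            fd = batch["fd_maps"].astype(np.float32)
            losses["l_ltd"] = float(np.abs(ltd - fd).mean())
            self.tdl_net.backward(
                (np.sign(ltd - fd) / ltd.size).astype(np.float32))
        if self.liver_net is not None:
            logits = self.liver_net.forward(batch["key_frames"].astype(np.float32))
            lp = sigmoid(logits)
            lgt = batch["liver_masks"].astype(np.float32)
            N = lp.shape[0]
            losses["l_lrs"] = float(np.mean([
                combined_bce_dice(lp[i, 0], lgt[i, 0], w.a) for i in range(N)]))
            g_lp = np.stack([_bce_dice_grad(lp[i, 0], lgt[i, 0], w.a)
                             for i in range(N)])[:, None] / N
            self.liver_net.backward((g_lp * lp * (1 - lp)).astype(np.float32))
        opt.step()
        return losses

    def train_step(self, batch: dict, opt: Adam, w: SegLossWeights) -> dict:
        kf = batch["key_frames"]
        out = self.forward(kf, batch.get("tdl_windows"))
        N = kf.shape[0]
        p = out["seg_prob"]
        gt = batch["tumor_masks"].astype(np.float32)

        l_seg = float(np.mean([
            combined_bce_dice(p[i, 0], gt[i, 0], w.a) for i in range(N)]))
        g_seg_prob = np.stack([
            _bce_dice_grad(p[i, 0], gt[i, 0], w.a) for i in range(N)])[:, None] / N

        l_lrs = 0.0
        g_liver_prob = None
        if self.liver_net is not None:
            lp = out["liver_prob"]
            lgt = batch["liver_masks"].astype(np.float32)
            l_lrs = float(np.mean([
                combined_bce_dice(lp[i, 0], lgt[i, 0], w.a) for i in range(N)]))
            g_liver_prob = np.stack([
                _bce_dice_grad(lp[i, 0], lgt[i, 0], w.a)
                for i in range(N)])[:, None] / N

        l_ltd = 0.0
        g_ltd = None
        if self.tdl_net is not None:
            ltd = out["ltd_map"]
            fd = batch["fd_maps"].astype(np.float32)
            l_ltd = float(np.abs(ltd - fd).mean())
            g_ltd = np.sign(ltd - fd).astype(np.float32) / ltd.size

        opt.zero_grad()
        # seg branch: chain through the output sigmoid.  The auxiliary maps
        # are fed to the fusion net as stop-gradient inputs: each subnet is
        # optimized by its own supervised loss term of the composite
        # objective, which keeps co-training stable at small batch sizes.
        g_logits = g_seg_prob * p * (1.0 - p)
        self.seg_net.backward(g_logits.astype(np.float32))
        if self.tdl_net is not None:
            self.tdl_net.backward((w.lambda0 * g_ltd).astype(np.float32))
        if self.liver_net is not None:
            lp = out["liver_prob"]
            g_llogits = w.lambda1 * g_liver_prob * lp * (1.0 - lp)
            self.liver_net.backward(g_llogits.astype(np.float32))
        opt.step()
        return {"l_seg": l_seg, "l_lrs": l_lrs, "l_ltd": l_ltd,
                "l_total": loss_total(l_ltd, l_lrs, l_seg, w)}

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p.v for i, p in enumerate(self.params())}
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {"config": asdict(self.cfg), "trained": self.trained}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "SegModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model = cls(SegModelConfig(**sidecar["config"]))
        data = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(model.params()):
            p.v[...] = data[f"p{i}"]
        model.trained = sidecar["trained"]
        return model


def build_model(cfg: SegModelConfig) -> SegModel:
    return SegModel(cfg)


def predict_segmentation(model: SegModel, bundle: KeyFrameBundle) -> SegOutput:
    """Deterministic inference on one preprocessed bundle."""
    if not model.trained:
        raise RuntimeError("model is not trained")
    s = model.cfg.image_size
    if bundle.key_frame.shape != (s, s):
        raise ValueError(
            f"bundle size {bundle.key_frame.shape} does not match model "
            f"input {(s, s)}")
    kf = bundle.key_frame[None, None]
    windows = None
    if model.tdl_net is not None:
        windows = bundle.tdl_window[None]
    out = model.forward(kf, windows)
    return SegOutput(
        tumor_prob=out["seg_prob"][0, 0],
        liver_prob=None if out["liver_prob"] is None else out["liver_prob"][0, 0],
        ltd_map=None if out["ltd_map"] is None else out["ltd_map"][0, 0],
    )


# ---------------------------------------------------------------------------
# training with patient-level cross-validation


def _patient_samples(entry: dict, use_augmentation: bool = True) -> list[dict]:
    """Training samples for one patient: the key frame and, optionally, the
    ±1 augmentation frames, each paired with the key frame's masks and
    temporal window."""
    b: KeyFrameBundle = entry["bundle"]
    frames = [b.key_frame]
    if use_augmentation:
        frames += list(b.aug_frames)
    return [{
        "key_frame": f,
        "tdl_window": b.tdl_window,
        "fd_map": b.fd_map,
        "tumor_mask": entry["tumor_mask"],
        "liver_mask": entry["liver_mask"],
    } for f in frames]


def make_folds(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Disjoint, exhaustive patient-level folds."""
    if n < folds:
        raise ValueError(f"need at least {folds} patients, got {n}")
    rng = np.random.default_rng(seed)
    return [np.sort(a) for a in np.array_split(rng.permutation(n), folds)]


def _fit(model: SegModel, samples: list[dict], cfg: SegModelConfig,
         w: SegLossWeights, rng: np.random.Generator) -> list[float]:
    opt = Adam(model.params(), lr=cfg.learning_rate)
    has_aux = model.tdl_net is not None or model.liver_net is not None

    def batches():
        order = rng.permutation(len(samples))
        for b0 in range(0, len(samples), cfg.batch_size):
            rows = [samples[i] for i in order[b0 : b0 + cfg.batch_size]]
            yield {
                "key_frames": np.stack([r["key_frame"] for r in rows])[:, None],
                "tumor_masks": np.stack([r["tumor_mask"] for r in rows])[:, None],
                "liver_masks": np.stack([r["liver_mask"] for r in rows])[:, None],
                "fd_maps": np.stack([r["fd_map"] for r in rows])[:, None],
                "tdl_windows": np.stack([r["tdl_window"] for r in rows]),
            }

    if has_aux:
        for _ in range(cfg.warmup_epochs):
            for batch in batches():
                model.train_step_aux(batch, opt, w)
    epoch_losses = []
    for _ in range(cfg.epochs):
        losses = [model.train_step(batch, opt, w)["l_total"]
                  for batch in batches()]
        epoch_losses.append(float(np.mean(losses)))
    model.trained = True
    return epoch_losses


def train_segmentation(dataset: list[dict], cfg: SegModelConfig,
                       folds: int = 5, weights: SegLossWeights | None = None,
                       use_augmentation: bool = True
                       ) -> tuple[list[SegModel], pd.DataFrame]:
    """Five-fold patient-level cross-validation.

    ``dataset``: one dict per patient with ``patient_id``, ``bundle``,
    ``tumor_mask``, ``liver_mask`` (2-D arrays at ``cfg.image_size``).
    Returns the per-fold models and the out-of-fold Dice table.
    """
    from .evalstats import dice_coefficient

    w = weights or SegLossWeights()
    fold_idx = make_folds(len(dataset), folds, cfg.seed)
    models, rows = [], []
    for k, val_idx in enumerate(fold_idx):
        val_set = set(int(i) for i in val_idx)
        train_entries = [d for i, d in enumerate(dataset) if i not in val_set]
        samples = [s for e in train_entries
                   for s in _patient_samples(e, use_augmentation)]
        model = SegModel(SegModelConfig(**{**asdict(cfg), "seed": cfg.seed + k}))
        rng = np.random.default_rng(cfg.seed * 7919 + k)
        epoch_losses = _fit(model, samples, cfg, w, rng)
        for i in val_idx:
            entry = dataset[int(i)]
            out = predict_segmentation(model, entry["bundle"])
            rows.append({
                "patient_id": entry["patient_id"],
                "fold": k,
                "dice": dice_coefficient(out.tumor_mask, entry["tumor_mask"]),
                "first_epoch_loss": epoch_losses[0],
                "final_epoch_loss": epoch_losses[-1],
            })
        models.append(model)
    return models, pd.DataFrame(rows)
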