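"""Treatment-response classifier: image branch on the key frame (optionally
with a segmentation mask), tabular branch on clinical covariates, fused
linear head.

Input variants
--------------
``KF``                one-channel key frame, image branch only
``clinical``          tabular branch only
``KF_mask``           three channels: key frame, key-frame×mask, mask
``KF_mask_clinical``  three-channel image plus tabular branch

``mask_source`` chooses predicted masks or ground truth (the upper-bound
arm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn import (
    Adam, Conv2d, GlobalAvgPool, Linear, Module, Param, ReLU, Sequential,
    sigmoid,
)

VARIANTS = ("KF", "clinical", "KF_mask", "KF_mask_clinical")

BINARY_FIELDS = {
    "sex": ("female", "male"),
    "hbv": ("neg", "pos"),
    "ascites": ("no", "yes"),
    "ast_ge40": ("no", "yes"),
    "alt_ge40": ("no", "yes"),
    "crp_ge1": ("no", "yes"),
    "afp_ge200": ("no", "yes"),
}
CONTINUOUS_FIELDS = ("age", "pt", "tbil", "alb")
ORDINAL_FIELDS = ("child_pugh",)
FEATURE_ORDER = ("age", "sex", "hbv", "child_pugh", "ascites", "pt", "tbil",
                 "alb", "ast_ge40", "alt_ge40", "crp_ge1", "afp_ge200")


@dataclass
class ClinicalRecord:
    """Pre-treatment covariates; ``None`` marks a missing value."""

    age: float | None
    sex: str | None
    hbv: str | None
    child_pugh: int | None
    ascites: str | None
    pt: float | None
    tbil: float | None
    alb: float | None
    ast_ge40: str | None
    alt_ge40: str | None
    crp_ge1: str | None
    afp_ge200: str | None

    def __post_init__(self):
        if self.age is not None and self.age <= 0:
            raise ValueError("age must be positive")
        if self.child_pugh is not None and not 5 <= self.child_pugh <= 9:
            raise ValueError("child_pugh must be in [5, 9]")
        for name, (lo, hi) in BINARY_FIELDS.items():
            v = getattr(self, name)
            if v is not None and v not in (lo, hi):
                raise ValueError(f"{name} must be one of {(lo, hi)}, got {v!r}")


@dataclass
class ResponseLabel:
    label: str  # "responder" | "non_responder"

    def __post_init__(self):
        if self.label not in ("responder", "non_responder"):
            raise ValueError(f"invalid label {self.label!r}")

    @property
    def binary(self) -> int:
        return 1 if self.label == "responder" else 0


class TabularTransform:
    """Z-score continuous covariates, binarize categoricals, keep the
    Child–Pugh score ordinal; impute missing values with the training
    median (continuous) or mode (categorical).  Fit once on training data,
    reapply unchanged elsewhere."""

    def __init__(self):
        self.stats_: dict | None = None

    def fit(self, records: list[ClinicalRecord]) -> "TabularTransform":
        if not records:
            raise ValueError("cannot fit on an empty record list")
        stats = {}
        for name in CONTINUOUS_FIELDS:
            vals = [getattr(r, name) for r in records if getattr(r, name) is not None]
            if not vals:
                raise ValueError(f"column {name!r} is entirely missing")
            med = float(np.median(vals))
            mean = float(np.mean(vals))
            sd = float(np.std(vals))
            stats[name] = {"median": med, "mean": mean, "sd": sd if sd > 0 else 1.0}
        for name in (*BINARY_FIELDS, *ORDINAL_FIELDS):
            vals = [getattr(r, name) for r in records if getattr(r, name) is not None]
            if not vals:
                raise ValueError(f"column {name!r} is entirely missing")
            uniq, counts = np.unique(vals, return_counts=True)
            stats[name] = {"mode": uniq[np.argmax(counts)].item()}
        self.stats_ = stats
        return self

    def transform(self, records: list[ClinicalRecord]) -> np.ndarray:
        if self.stats_ is None:
            raise RuntimeError("transform is not fitted")
        rows = []
        for r in records:
            row = []
            for name in FEATURE_ORDER:
                v = getattr(r, name)
                if name in CONTINUOUS_FIELDS:
                    s = self.stats_[name]
                    x = s["median"] if v is None else float(v)
                    row.append((x - s["mean"]) / s["sd"])
                elif name in ORDINAL_FIELDS:
                    x = self.stats_[name]["mode"] if v is None else v
                    row.append(float(x))
                else:
                    x = self.stats_[name]["mode"] if v is None else v
                    row.append(1.0 if x == BINARY_FIELDS[name][1] else 0.0)
            rows.append(row)
        return np.asarray(rows, dtype=np.float32)

    def fit_transform(self, records):
        return self.fit(records).transform(records)

    def to_dict(self) -> dict:
        return {"stats": self.stats_}

    @classmethod
    def from_dict(cls, d: dict) -> "TabularTransform":
        t = cls()
        t.stats_ = d["stats"]
        return t


def preprocess_tabular(records: list[ClinicalRecord]
                       ) -> tuple[np.ndarray, TabularTransform]:
    """Fit the transform on ``records`` and return (matrix, fitted transform)."""
    t = TabularTransform()
    return t.fit_transform(records), t


def compose_image_input(key_frame: np.ndarray | None,
                        mask: np.ndarray | None, variant: str) -> np.ndarray | None:
    """Stack the image channels for ``variant`` (None for clinical-only)."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "clinical":
        return None
    if key_frame is None:
        raise ValueError(f"variant {variant!r} requires a key frame")
    kf = np.asarray(key_frame, dtype=np.float32)
    if variant == "KF":
        return kf[None]
    if mask is None:
        raise ValueError(f"variant {variant!r} requires a mask")
    m = np.asarray(mask, dtype=np.float32)
    if m.shape != kf.shape:
        raise ValueError("key frame and mask shapes differ")
    return np.stack([kf, kf * m, m])


def image_channels(variant: str) -> int:
    return {"KF": 1, "KF_mask": 3, "KF_mask_clinical": 3, "clinical": 0}[variant]


@dataclass
class RespModelConfig:
    input_variant: str = "KF_mask_clinical"
    mask_source: str = "pred"  # "pred" | "gt"
    image_backbone_width: int = 8
    mlp_hidden: tuple[int, ...] = (32, 16)
    fusion_hidden: int = 32
    n_tabular: int = len(FEATURE_ORDER)
    image_size: int = 64
    epochs: int = 12
    batch_size: int = 8
    learning_rate: float = 1e-3
    val_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.input_variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.input_variant!r}")
        if self.mask_source not in ("pred", "gt"):
            raise ValueError(f"unknown mask_source {self.mask_source!r}")


class ResBlock(Module):
    """Two 3×3 convs with an identity skip; ReLU after the addition."""

    def __init__(self, ch: int, rng: np.random.Generator):
        self.conv1, self.r1 = Conv2d(ch, ch, rng=rng), ReLU()
        self.conv2 = Conv2d(ch, ch, rng=rng)
        self.rout = ReLU()

    def params(self):
        return [*self.conv1.params(), *self.conv2.params()]

    def forward(self, x):
        h = self.conv2.forward(self.r1.forward(self.conv1.forward(x)))
        return self.rout.forward(h + x)

    def backward(self, gout):
        g = self.rout.backward(gout)
        gb = self.conv1.backward(self.r1.backward(self.conv2.backward(g)))
        return g + gb


class ResponseModel:
    """Two-branch classifier ending in a single response probability."""

    def __init__(self, cfg: RespModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        w = cfg.image_backbone_width
        cin = image_channels(cfg.input_variant)
        self.image_net = None
        img_feat = 0
        if cin:
            self.image_net = Sequential(
                Conv2d(cin, w, stride=2, rng=rng), ReLU(),
                ResBlock(w, rng),
                Conv2d(w, 2 * w, stride=2, rng=rng), ReLU(),
                ResBlock(2 * w, rng),
                Conv2d(2 * w, 4 * w, stride=2, rng=rng), ReLU(),
                ResBlock(4 * w, rng),
                GlobalAvgPool(),
            )
            img_feat = 4 * w
        self.tab_net = None
        tab_feat = 0
        if cfg.input_variant in ("clinical", "KF_mask_clinical"):
            layers: list[Module] = []
            fin = cfg.n_tabular
            for h in cfg.mlp_hidden:
                layers += [Linear(fin, h, rng=rng), ReLU()]
                fin = h
            self.tab_net = Sequential(*layers)
            tab_feat = fin
        self.head = Sequential(
            Linear(img_feat + tab_feat, cfg.fusion_hidden, rng=rng), ReLU(),
            Linear(cfg.fusion_hidden, 1, rng=rng),
        )
        self._img_feat, self._tab_feat = img_feat, tab_feat

    def params(self) -> list[Param]:
        ps = []
        for net in (self.image_net, self.tab_net, self.head):
            if net is not None:
                ps.extend(net.params())
        return ps

    def forward(self, images: np.ndarray | None,
                tabular: np.ndarray | None) -> np.ndarray:
        feats = []
        if self.image_net is not None:
            if images is None:
                raise ValueError("model variant requires image input")
            feats.append(self.image_net.forward(images.astype(np.float32)))
        if self.tab_net is not None:
            if tabular is None:
                raise ValueError("model variant requires tabular input")
            feats.append(self.tab_net.forward(tabular.astype(np.float32)))
        h = np.concatenate(feats, axis=1) if len(feats) > 1 else feats[0]
        return self.head.forward(h)[:, 0]  # logits

    def backward(self, glogits: np.ndarray) -> None:
        g = self.head.backward(glogits[:, None].astype(np.float32))
        if self.image_net is not None and self.tab_net is not None:
            gi, gt = g[:, : self._img_feat], g[:, self._img_feat:]
            self.image_net.backward(gi)
            self.tab_net.backward(gt)
        elif self.image_net is not None:
            self.image_net.backward(g)
        else:
            self.tab_net.backward(g)

    def predict_proba(self, images, tabular) -> np.ndarray:
        return sigmoid(self.forward(images, tabular))


def build_response_model(cfg: RespModelConfig) -> ResponseModel:
    return ResponseModel(cfg)


def predict_response(model: ResponseModel, images, tabular
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and binary calls (probability ≥ 0.5 → responder)."""
    p = model.predict_proba(images, tabular)
    return p, (p >= 0.5).astype(int)


def _compose_batch(rows: list[dict], variant: str) -> np.ndarray | None:
    if variant == "clinical":
        return None
    return np.stack([
        compose_image_input(r["key_frame"], r.get("mask"), variant)
        for r in rows
    ])


def train_response(dataset: list[dict], cfg: RespModelConfig
                   ) -> tuple[ResponseModel, pd.DataFrame, TabularTransform | None]:
    """Train on a patient-level split; return the model, a table of held-out
    predictions, and the fitted tabular transform (fitted on training rows
    only).

    Each dataset row: ``patient_id``, ``key_frame``, ``mask`` (per
    ``cfg.mask_source``), ``clinical`` (:class:`ClinicalRecord`),
    ``label`` (:class:`ResponseLabel`).
    """
    labels = np.array([r["label"].binary for r in dataset])
    if labels.min() == labels.max():
        raise ValueError("training labels contain a single class")

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(dataset))
    n_val = max(1, int(round(cfg.val_fraction * len(dataset))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if labels[train_idx].min() == labels[train_idx].max():
        raise ValueError("training split contains a single class")

    transform = None
    Xtab_train = Xtab_val = None
    if cfg.input_variant in ("clinical", "KF_mask_clinical"):
        transform = TabularTransform().fit(
            [dataset[i]["clinical"] for i in train_idx])
        Xtab_train = transform.transform([dataset[i]["clinical"] for i in train_idx])
        Xtab_val = transform.transform([dataset[i]["clinical"] for i in val_idx])

    train_rows = [dataset[i] for i in train_idx]
    val_rows = [dataset[i] for i in val_idx]
    Ximg_train = _compose_batch(train_rows, cfg.input_variant)
    Ximg_val = _compose_batch(val_rows, cfg.input_variant)
    y_train = labels[train_idx].astype(np.float32)

    # inverse-frequency class weights guard against degenerate majority calls
    n1 = float(y_train.sum())
    n0 = float(len(y_train) - n1)
    w1, w0 = len(y_train) / (2.0 * n1), len(y_train) / (2.0 * n0)

    model = ResponseModel(cfg)
    opt = Adam(model.params(), lr=cfg.learning_rate)
    n = len(train_rows)
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        for b0 in range(0, n, cfg.batch_size):
            bi = perm[b0 : b0 + cfg.batch_size]
            xb_img = Ximg_train[bi] if Ximg_train is not None else None
            xb_tab = Xtab_train[bi] if Xtab_train is not None else None
            yb = y_train[bi]
            logits = model.forward(xb_img, xb_tab)
            p = sigmoid(logits)
            wts = np.where(yb == 1, w1, w0).astype(np.float32)
            glog = wts * (p - yb) / len(yb)
            opt.zero_grad()
            model.backward(glog)
            opt.step()

    probs = model.predict_proba(Ximg_val, Xtab_val)
    preds = pd.DataFrame({
        "patient_id": [r["patient_id"] for r in val_rows],
        "probability": probs,
        "call": (probs >= 0.5).astype(int),
        "label": labels[val_idx],
    })
    return model, preds, transform
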