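"""Run configuration: one YAML file drives the whole pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .respnet import RespModelConfig
from .segnet import SegModelConfig
from .synthetic import CohortConfig, PhantomConfig


@dataclass
class EvalConfig:
    bootstrap_reps: int = 200
    lesion_match_frac: float = 0.10
    size_bins: tuple[float, float] = (3.0, 5.0)


@dataclass
class RunConfig:
    out_dir: str = "runs/run"
    seed: int = 0
    deterministic: bool = True
    easy_cohort: bool = True
    folds: int = 5
    cohort: CohortConfig = field(default_factory=CohortConfig)
    seg: SegModelConfig = field(default_factory=SegModelConfig)
    clf: RespModelConfig = field(default_factory=RespModelConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)


class ConfigError(ValueError):
    pass


def load_config(path) -> RunConfig:
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as e:
        mark = getattr(e, "problem_mark", None)
        loc = f" (line {mark.line + 1})" if mark else ""
        raise ConfigError(f"cannot parse {path}{loc}: {e}") from e
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    try:
        phantom = PhantomConfig(**raw.get("phantom", {}))
        cohort_kwargs = dict(raw.get("cohort", {}))
        cohort = CohortConfig(phantom=phantom, **cohort_kwargs)
        seg = SegModelConfig(**raw.get("seg", {}))
        clf_kwargs = dict(raw.get("clf", {}))
        if "mlp_hidden" in clf_kwargs:
            clf_kwargs["mlp_hidden"] = tuple(clf_kwargs["mlp_hidden"])
        clf = RespModelConfig(**clf_kwargs)
        ev_kwargs = dict(raw.get("eval", {}))
        if "size_bins" in ev_kwargs:
            ev_kwargs["size_bins"] = tuple(ev_kwargs["size_bins"])
        ev = EvalConfig(**ev_kwargs)
        cfg = RunConfig(
            out_dir=raw.get("out_dir", "runs/run"),
            seed=int(raw.get("seed", 0)),
            deterministic=bool(raw.get("deterministic", True)),
            easy_cohort=bool(raw.get("easy_cohort", True)),
            folds=int(raw.get("folds", 5)),
            cohort=cohort, seg=seg, clf=clf, eval=ev,
        )
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid configuration: {e}") from e
    # one global seed propagates everywhere unless overridden per stage
    if "seed" in raw:
        if "seed" not in raw.get("cohort", {}):
            cfg.cohort.seed = cfg.seed
        if "seed" not in raw.get("seg", {}):
            cfg.seg.seed = cfg.seed
        if "seed" not in raw.get("clf", {}):
            cfg.clf.seed = cfg.seed
    return cfg


DESK_CONFIG = {
    "out_dir": "runs/desk",
    "seed": 1,
    "easy_cohort": True,
    "folds": 5,
    "cohort": {"n_patients": 40},
    "phantom": {"height": 64, "width": 64},
    "seg": {"variant": "ffs", "base_channels": 8, "unet_depth": 3,
            "epochs": 6, "image_size": 64},
    "clf": {"input_variant": "KF_mask_clinical", "mask_source": "pred",
            "image_size": 64, "epochs": 10},
    "eval": {"bootstrap_reps": 200},
}
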