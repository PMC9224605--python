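"""Model checkpointing: npz weights plus a JSON sidecar with the config echo."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .errors import InvalidInputError
from .evaluator import EvalConfig, EvaluatorModel, build_evaluator
from .segmentation import SegConfig, SegModel, build_seg_model

__all__ = ["save_seg_model", "load_seg_model", "save_eval_model", "load_eval_model",
           "save_encoder_state", "load_encoder_state"]


def _jsonable(cfg) -> dict:
    out = {}
    for k, v in asdict(cfg).items():
        out[k] = list(v) if isinstance(v, tuple) else v
    return out


def _write(path: Path, state: dict, meta: dict) -> None:
    path = Path(path)
    np.savez(path, **state)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _read(path: Path) -> tuple[dict, dict]:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise InvalidInputError(f"missing sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    with np.load(path) as npz:
        state = {k: npz[k] for k in npz.files}
    return state, meta


def save_seg_model(path, model: SegModel, extra: dict | None = None) -> None:
    meta = {"kind": "segmentation", "config": _jsonable(model.cfg)}
    meta.update(extra or {})
    _write(Path(path), model.state_dict(), meta)


def load_seg_model(path) -> SegModel:
    state, meta = _read(Path(path))
    if meta.get("kind") != "segmentation":
        raise InvalidInputError(f"{path} is not a segmentation checkpoint")
    cfg_d = meta["config"]
    cfg_d["tap_layers"] = tuple(cfg_d["tap_layers"])
    cfg = SegConfig(**cfg_d)
    model = build_seg_model(cfg)
    model.load_state_dict(state)
    return model


def save_eval_model(path, model: EvaluatorModel, extra: dict | None = None) -> None:
    meta = {"kind": "evaluator", "config": _jsonable(model.cfg),
            "intensity_dim": model.intensity_dim}
    meta.update(extra or {})
    _write(Path(path), model.state_dict(), meta)


def load_eval_model(path) -> EvaluatorModel:
    state, meta = _read(Path(path))
    if meta.get("kind") != "evaluator":
        raise InvalidInputError(f"{path} is not an evaluator checkpoint")
    cfg_d = meta["config"]
    cfg_d["lr_milestones"] = tuple(cfg_d["lr_milestones"])
    cfg = EvalConfig(**cfg_d)
    model = build_evaluator(cfg, int(meta["intensity_dim"]))
    model.load_state_dict(state)
    return model


def save_encoder_state(path, state: dict, cfg: SegConfig, extra: dict | None = None) -> None:
    meta = {"kind": "mae-encoder", "config": _jsonable(cfg)}
    meta.update(extra or {})
    _write(Path(path), state, meta)


def load_encoder_state(path) -> tuple[dict, SegConfig]:
    state, meta = _read(Path(path))
    if meta.get("kind") != "mae-encoder":
        raise InvalidInputError(f"{path} is not a pretrained-encoder checkpoint")
    cfg_d = meta["config"]
    cfg_d["tap_layers"] = tuple(cfg_d["tap_layers"])
    return state, SegConfig(**cfg_d)
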