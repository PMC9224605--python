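"""Growth-state prediction from masked perfusion fused with intensity features.

The evaluation stage reads the blood-perfusion image masked by the
segmentation, resizes it to the working resolution, patchifies it, and
keeps only patches that actually carry perfusion — on typical lesions
this discards ~90% of tokens. The retained patches are encoded by a
perfusion transformer; each token is then concatenated channel-wise with
the frozen intensity encoder's token at the same grid position (the
cascade), and a transformer decoder reads a fused global token to emit
three class probabilities: regressive, stable, progressive.

Training follows the reference recipe (lr 0.001 halved at 50/100/200
epochs, 400 epochs, random erasing of 25% of pixels); the tiny profile
scales the schedule proportionally so 5-fold cross-validation runs on one
CPU in minutes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from skimage.transform import resize as sk_resize

from .errors import EmptyRegionError, EmptySelectionError, InvalidInputError
from .metrics import CLASS_ORDER, FoldSplit, aggregate_folds, metrics_report
from .nn import SGD, Linear, Module, Tensor, TransformerBlock, ViTEncoder, cat, clip_grad_norm, softmax_cross_entropy
from .segmentation import PatchGrid, SegModel, patchify, resize_image

__all__ = [
    "EvalConfig",
    "SelectedPatches",
    "StagePrediction",
    "PU_SCALE",
    "mask_and_resize",
    "select_perfusion_patches",
    "random_erase",
    "EvaluatorModel",
    "build_evaluator",
    "intensity_tokens",
    "encode_perfusion",
    "fuse_features",
    "predict_stage",
    "train_evaluator",
    "EvalCVResult",
    "best_threshold_classifier",
]

# PU values are divided by this before entering the network; ~1.5× the
# cohort mean keeps inputs O(1).
PU_SCALE = 200.0


@dataclass(frozen=True)
class EvalConfig:
    """Evaluator configuration (defaults = reference recipe)."""

    image_size: int = 512
    patch_size: int = 16
    perf_dim: int = 192
    perf_depth: int = 4
    decoder_depth: int = 4
    n_heads: int = 4
    mlp_ratio: float = 2.0
    classes: int = 3
    epochs: int = 400
    lr_initial: float = 0.001
    lr_milestones: tuple[int, ...] = (50, 100, 200)
    lr_factor: float = 0.5
    momentum: float = 0.9
    grad_clip: float = 1.0
    weight_decay: float = 0.0
    random_erase_fraction: float = 0.25
    translate_augment: bool = True  # random whole-lesion shifts during training
    selection_threshold: float = 0.0  # τ, in PU
    seed: int = 0
    tiny_profile: bool = False

    def __post_init__(self):
        if not 0.0 <= self.random_erase_fraction < 1.0:
            raise InvalidInputError("random_erase_fraction must be in [0, 1)")
        if list(self.lr_milestones) != sorted(set(self.lr_milestones)):
            raise InvalidInputError("lr_milestones must be strictly increasing")

    @classmethod
    def tiny(cls, seed: int = 0, **overrides) -> "EvalConfig":
        """Desk-scale profile; the LR milestones keep their 400-epoch fractions."""
        epochs = overrides.pop("epochs", 60)
        milestones = tuple(max(1, round(epochs * m / 400)) for m in (50, 100, 200))
        params = dict(
            image_size=64, patch_size=8, perf_dim=32, perf_depth=2, decoder_depth=2,
            n_heads=4, epochs=epochs, lr_milestones=milestones, lr_initial=0.01,
            weight_decay=1e-3, random_erase_fraction=0.0, seed=seed, tiny_profile=True,
        )
        params.update(overrides)
        return cls(**params)

    @property
    def grid(self) -> PatchGrid:
        return PatchGrid(self.image_size, self.patch_size)


@dataclass(frozen=True)
class SelectedPatches:
    """Patch-grid indices that carry perfusion, with their pixel contents."""

    indices: np.ndarray  # strictly increasing, within [0, n_patches)
    contents: np.ndarray  # (k, patch_size²)
    grid: PatchGrid


@dataclass(frozen=True)
class StagePrediction:
    """Softmax probabilities over (regressive, stable, progressive)."""

    probabilities: np.ndarray
    label: str

    @property
    def label_index(self) -> int:
        return CLASS_ORDER.index(self.label)


def mask_and_resize(field: np.ndarray, mask: np.ndarray, size: int) -> np.ndarray:
    """Zero non-keloid perfusion, then resize to (size, size) bilinearly."""
    field = np.asarray(field, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if field.shape != mask.shape:
        raise InvalidInputError(f"field shape {field.shape} != mask shape {mask.shape}")
    if not mask.any():
        raise EmptyRegionError("segmentation mask is empty")
    masked = np.where(mask, field, 0.0)
    if masked.shape == (size, size):
        return masked
    return sk_resize(masked, (size, size), order=1, anti_aliasing=True, preserve_range=True)


def select_perfusion_patches(masked_image: np.ndarray, patch_size: int,
                             tau: float = 0.0) -> SelectedPatches:
    """Keep patches containing at least one pixel with PU > τ."""
    grid, patches = patchify(masked_image, patch_size)
    keep = np.nonzero((patches > tau).any(axis=1))[0]
    if keep.size == 0:
        raise EmptySelectionError("no patch carries perfusion above threshold")
    return SelectedPatches(indices=keep, contents=patches[keep], grid=grid)


def random_erase(image: np.ndarray, fraction: float, rng: np.random.Generator | int) -> np.ndarray:
    """Set exactly ``round(fraction × n_pixels)`` uniform random pixels to 0."""
    if not 0.0 <= fraction < 1.0:
        raise InvalidInputError("erase fraction must be in [0, 1)")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    img = np.asarray(image, dtype=float).copy()
    n = img.size
    n_erase = int(round(fraction * n))
    if n_erase:
        flat = img.reshape(-1)
        flat[rng.choice(n, size=n_erase, replace=False)] = 0.0
    return img


class EvaluatorModel(Module):
    """Perfusion encoder + channel-wise fusion + transformer prediction decoder."""

    def __init__(self, cfg: EvalConfig, intensity_dim: int, rng: np.random.Generator):
        self.cfg = cfg
        grid = cfg.grid
        self.perf_encoder = ViTEncoder(
            grid.n_patches, cfg.patch_size**2, cfg.perf_dim, cfg.perf_depth,
            cfg.n_heads, rng, mlp_ratio=cfg.mlp_ratio,
        )
        self.intensity_dim = intensity_dim
        dec_dim = cfg.perf_dim
        self.fuse_proj = Linear(cfg.perf_dim + intensity_dim, dec_dim, rng)
        self.decoder = [TransformerBlock(dec_dim, cfg.n_heads, cfg.mlp_ratio, rng)
                        for _ in range(cfg.decoder_depth)]
        self.head = Linear(dec_dim, cfg.classes, rng, scale=0.02)

    def forward(self, selected: SelectedPatches, int_tokens: np.ndarray,
                int_global: np.ndarray) -> Tensor:
        """Class logits for one case.

        ``int_tokens`` are the frozen intensity-encoder tokens at the
        selected grid positions, ``int_global`` their image-wide mean.
        """
        perf = encode_perfusion(selected, self.perf_encoder)  # (1, k+1, dp)
        k = len(selected.indices)
        if int_tokens.shape[0] != k:
            raise InvalidInputError("intensity tokens do not align with the selected patch grid")
        ints = np.concatenate([int_global[None, :], int_tokens], axis=0)[None]  # (1, k+1, di)
        fused = fuse_features(perf, Tensor(ints))
        seq = self.fuse_proj(fused)
        for blk in self.decoder:
            seq = blk(seq)
        summary = seq.gather_rows(np.array([0]), axis=1).reshape(1, seq.shape[-1])
        return self.head(summary).reshape(self.cfg.classes)

    __call__ = forward


def encode_perfusion(selected: SelectedPatches, encoder: ViTEncoder) -> Tensor:
    """Per-patch perfusion tokens plus a leading global summary (mean) token.

    The encoder's final layer norm is skipped here: normalizing each token
    to unit scale would suppress the absolute perfusion level, which is
    exactly the signal the growth state rides on; the pre-norm residual
    stream keeps it.
    """
    if len(selected.indices) == 0:
        raise EmptySelectionError("cannot encode an empty patch selection")
    tokens = encoder(selected.contents[None], indices=selected.indices,
                     final_norm=False)  # (1, k, d)
    summary = tokens.mean(axis=1, keepdims=True)
    return cat([summary, tokens], axis=1)


def fuse_features(perf_tokens: Tensor, intensity_tokens: Tensor) -> Tensor:
    """Concatenate perfusion and intensity tokens channel-wise per position."""
    if perf_tokens.shape[:2] != intensity_tokens.shape[:2]:
        raise InvalidInputError(
            f"token grids disagree: {perf_tokens.shape[:2]} vs {intensity_tokens.shape[:2]}"
        )
    return cat([perf_tokens, intensity_tokens], axis=-1)


def build_evaluator(cfg: EvalConfig, intensity_dim: int, seed_offset: int = 0) -> EvaluatorModel:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 41, seed_offset]))
    return EvaluatorModel(cfg, intensity_dim, rng)


def intensity_tokens(seg_model: SegModel, image: np.ndarray, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Frozen final-layer intensity tokens for one image, plus their mean.

    The segmentation encoder is applied without gradient tracking; the
    cascade never fine-tunes it.
    """
    cfg = seg_model.cfg
    img = resize_image(image, cfg.image_size) / 255.0 - 0.5
    _, patches = patchify(img, cfg.patch_size)
    toks = seg_model.encoder(patches[None]).data[0]  # (N, D)
    return toks, toks.mean(axis=0)


def predict_stage(model: EvaluatorModel, selected: SelectedPatches,
                  int_tokens: np.ndarray, int_global: np.ndarray) -> StagePrediction:
    """Softmax class probabilities; argmax label, ties to the lowest index."""
    logits = model(selected, int_tokens, int_global).data
    z = logits - logits.max()
    probs = np.exp(z) / np.exp(z).sum()
    return StagePrediction(probabilities=probs, label=CLASS_ORDER[int(np.argmax(probs))])


@dataclass
class EvalCVResult:
    models: list
    pooled_report: dict
    fold_accuracy: list[float]
    summary: dict
    pooled_true: list[int] = dc_field(default_factory=list)
    pooled_pred: list[int] = dc_field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return self.pooled_report["overall_accuracy"]


def _prepare_eval(samples, cfg: EvalConfig, seg_model: SegModel, masks=None):
    """Cache per-case masked perfusion, patch selection and intensity tokens."""
    prepped = []
    for i, rec in enumerate(samples):
        mask = rec.mask if masks is None else masks[i]
        masked = mask_and_resize(rec.field, mask, cfg.image_size) / PU_SCALE
        sel = select_perfusion_patches(masked, cfg.patch_size, cfg.selection_threshold / PU_SCALE)
        toks, glob = intensity_tokens(seg_model, rec.intensity, cfg.image_size)
        label = CLASS_ORDER.index(rec.stage)
        prepped.append((masked, sel, toks, glob, label))
    return prepped


def _with_tokens(prepped_base, samples, seg_model: SegModel, cfg: EvalConfig):
    """Swap in intensity tokens from a specific (per-fold) encoder."""
    out = []
    for (masked, sel, _t, _g, label), rec in zip(prepped_base, samples):
        toks, glob = intensity_tokens(seg_model, rec.intensity, cfg.image_size)
        out.append((masked, sel, toks, glob, label))
    return out


def train_evaluator(samples, cfg: EvalConfig, seg_model, folds: FoldSplit,
                    masks=None) -> EvalCVResult:
    """Cross-validated training of the growth-state classifier.

    ``seg_model`` supplies the frozen intensity encoder — either one
    model, or a list with one per fold (no validation case then meets an
    encoder trained on it). ``masks`` defaults to each record's
    ground-truth mask; pass predicted masks to evaluate the full cascade.
    Reports pooled validation metrics across folds (headline) and the
    per-fold accuracy vector.
    """
    if len(samples) != len(folds.assignments):
        raise InvalidInputError("fold assignments do not match the dataset")
    per_fold_seg = isinstance(seg_model, (list, tuple))
    if per_fold_seg and len(seg_model) != folds.k:
        raise InvalidInputError("need one segmentation model per fold")
    seg0 = seg_model[0] if per_fold_seg else seg_model
    prepped = _prepare_eval(samples, cfg, seg0, masks)
    labels = np.array([p[4] for p in prepped])
    models = []
    fold_acc = []
    pooled_true: list[int] = []
    pooled_pred: list[int] = []
    for fold in range(folds.k):
        train_idx, val_idx = folds.train_val(fold)
        if folds.k == 1:
            val_idx = train_idx
        if len(np.unique(labels[train_idx])) < cfg.classes:
            warnings.warn(f"fold {fold}: training split is missing a class (degenerate fold)")
        fold_seg = seg_model[fold] if per_fold_seg else seg_model
        if per_fold_seg and fold > 0:
            prepped = _with_tokens(prepped, samples, fold_seg, cfg)
        model = _train_one_eval(prepped, train_idx, cfg, fold_seg, fold)
        correct = 0
        for i in val_idx:
            _, sel, toks, glob, label = prepped[i]
            pred = predict_stage(model, sel, toks[sel.indices], glob)
            pooled_true.append(label)
            pooled_pred.append(pred.label_index)
            correct += int(pred.label_index == label)
        fold_acc.append(correct / len(val_idx))
        models.append(model)
    report = metrics_report(pooled_true, pooled_pred)
    return EvalCVResult(models=models, pooled_report=report, fold_accuracy=fold_acc,
                        summary=aggregate_folds(fold_acc), pooled_true=pooled_true,
                        pooled_pred=pooled_pred)


def _translate(masked: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shift the lesion to a uniform random position that keeps it in frame.

    Breaks the association between grid position and case identity so the
    classifier must read patch content, not location.
    """
    nz = np.nonzero(masked > 0)
    if nz[0].size == 0:
        return masked
    H, W = masked.shape
    r0, r1 = int(nz[0].min()), int(nz[0].max())
    c0, c1 = int(nz[1].min()), int(nz[1].max())
    dr = int(rng.integers(-r0, H - 1 - r1, endpoint=True))
    dc = int(rng.integers(-c0, W - 1 - c1, endpoint=True))
    return np.roll(masked, (dr, dc), axis=(0, 1))


def _train_one_eval(prepped, train_idx, cfg: EvalConfig, seg_model: SegModel,
                    fold_id: int) -> EvaluatorModel:
    int_dim = seg_model.cfg.embed_dim
    model = build_evaluator(cfg, int_dim, seed_offset=fold_id)
    params = model.parameters()
    opt = SGD(params, lr=cfg.lr_initial, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 43, fold_id]))
    for epoch in range(cfg.epochs):
        halvings = sum(epoch >= m for m in cfg.lr_milestones)
        opt.lr = cfg.lr_initial * cfg.lr_factor**halvings
        for i in rng.permutation(train_idx):
            masked, sel, toks, glob, label = prepped[i]
            img = masked
            if cfg.translate_augment:
                img = _translate(img, rng)
            if cfg.random_erase_fraction > 0:
                img = random_erase(img, cfg.random_erase_fraction, rng)
            if cfg.translate_augment or cfg.random_erase_fraction > 0:
                try:
                    sel_aug = select_perfusion_patches(
                        img, cfg.patch_size, cfg.selection_threshold / PU_SCALE)
                except EmptySelectionError:
                    sel_aug = sel
            else:
                sel_aug = sel
            logits = model(sel_aug, toks[sel_aug.indices], glob)
            loss = softmax_cross_entropy(logits.reshape(1, cfg.classes), np.array([label]))
            opt.zero_grad()
            loss.backward()
            clip_grad_norm(params, cfg.grad_clip)
            opt.step()
    return model


def best_threshold_classifier(train_values, train_labels, val_values) -> np.ndarray:
    """Best two-threshold classifier on a scalar feature (mean PU baseline).

    Exhausts ordered threshold pairs over training midpoints, assigning
    (regressive, stable, progressive) to increasing value bands, and
    returns predictions for ``val_values``. The trained evaluator should
    beat or match this baseline — it can exploit heterogeneity, the
    baseline cannot.
    """
    tv = np.asarray(train_values, dtype=float)
    tl = np.asarray(train_labels)
    cuts = np.unique(tv)
    mids = np.concatenate([[-np.inf], (cuts[1:] + cuts[:-1]) / 2.0, [np.inf]])
    best = (-1.0, (-np.inf, np.inf))
    for i, t1 in enumerate(mids):
        for t2 in mids[i:]:
            pred = np.digitize(tv, [t1, t2])
            acc = float((pred == tl).mean())
            if acc > best[0]:
                best = (acc, (t1, t2))
    t1, t2 = best[1]
    return np.digitize(np.asarray(val_values, dtype=float), [t1, t2])
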