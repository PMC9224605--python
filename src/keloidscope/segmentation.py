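"""Keloid segmentation: ViT encoder + pyramid head, MAE pretraining, DICE.

The intensity image is resized to a square, tiled into non-overlapping
patches (512/16 → 1024 tokens at full scale), encoded by a transformer,
and decoded to per-pixel keloid/background scores by a pyramid-style head
that taps several encoder depths (the UPerNet pattern, reduced to linear
lateral projections here). Because 150 cases are far too few to train a
ViT from scratch, the encoder can first be pretrained as a masked
autoencoder: 75% of patches are hidden and the network reconstructs the
missing pixels.

A ``tiny_profile`` configuration (64-px images, 2-layer encoder) makes
the full train/evaluate loop run on one CPU in seconds per fold; the
default profile mirrors the reference training recipe (512 px, 12 layers,
SGD from lr 0.02 with exponential decay, 100 epochs, flip + ≤15°
rotation augmentation).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy.ndimage import rotate as nd_rotate
from skimage.transform import resize as sk_resize

from .errors import InvalidInputError, InvalidShapeError
from .metrics import FoldSplit, aggregate_folds
from .nn import SGD, Linear, Module, Tensor, ViTEncoder, MAEDecoder, clip_grad_norm, mae_loss, softmax_cross_entropy

__all__ = [
    "PatchGrid",
    "SegConfig",
    "MAEConfig",
    "patchify",
    "unpatchify",
    "mae_mask_select",
    "augment_pair",
    "dice",
    "SegModel",
    "build_seg_model",
    "pretrain_mae",
    "train_segmentation",
    "predict_mask",
    "SegCVResult",
]


@dataclass(frozen=True)
class PatchGrid:
    """Row-major tiling of a square image into square patches."""

    image_size: int
    patch_size: int

    def __post_init__(self):
        if self.image_size % self.patch_size != 0:
            raise InvalidShapeError(
                f"image size {self.image_size} not divisible by patch size {self.patch_size}"
            )

    @property
    def side(self) -> int:
        return self.image_size // self.patch_size

    @property
    def n_patches(self) -> int:
        return self.side**2

    def index_to_rc(self, index: int) -> tuple[int, int]:
        return divmod(int(index), self.side)

    def rc_to_index(self, row: int, col: int) -> int:
        return int(row) * self.side + int(col)


@dataclass(frozen=True)
class SegConfig:
    """Segmentation training configuration (defaults = reference recipe)."""

    image_size: int = 512
    patch_size: int = 16
    encoder_depth: int = 12
    embed_dim: int = 768
    n_heads: int = 12
    mlp_ratio: float = 4.0
    tap_layers: tuple[int, ...] = (2, 5, 8, 11)
    epochs: int = 100
    batch_size: int = 8
    lr_initial: float = 0.02
    lr_gamma: float = 0.95  # per-epoch exponential decay factor
    momentum: float = 0.9
    grad_clip: float = 1.0
    augment: bool = True
    max_rotation_deg: float = 15.0
    seed: int = 0
    tiny_profile: bool = False

    @classmethod
    def tiny(cls, seed: int = 0, **overrides) -> "SegConfig":
        """Desk-scale profile: 64-px images, 2-layer, 32-dim encoder."""
        params = dict(
            image_size=64, patch_size=8, encoder_depth=2, embed_dim=32, n_heads=4,
            mlp_ratio=2.0, tap_layers=(0, 1), epochs=40, batch_size=8,
            lr_initial=0.05, lr_gamma=0.98,
            seed=seed, tiny_profile=True,
        )
        params.update(overrides)
        return cls(**params)

    @property
    def grid(self) -> PatchGrid:
        return PatchGrid(self.image_size, self.patch_size)


@dataclass(frozen=True)
class MAEConfig:
    """Masked-autoencoder pretraining configuration."""

    mask_ratio: float = 0.75
    pretrain_epochs: int = 1600
    decoder_dim: int = 64
    decoder_depth: int = 2
    decoder_heads: int = 4
    lr: float = 0.05
    batch_size: int = 16

    def __post_init__(self):
        if not 0.0 <= self.mask_ratio < 1.0:
            raise InvalidInputError("mask_ratio must be in [0, 1)")

    @classmethod
    def tiny(cls, **overrides) -> "MAEConfig":
        params = dict(pretrain_epochs=25, decoder_dim=24, decoder_depth=1, decoder_heads=2)
        params.update(overrides)
        return cls(**params)


# -- patch plumbing -------------------------------------------------------

def patchify(image: np.ndarray, patch_size: int) -> tuple[PatchGrid, np.ndarray]:
    """Tile a square (H, H[, C]) image into row-major flattened patches.

    Returns the grid plus an (n_patches, patch_size²·C) array; inverse of
    :func:`unpatchify` bit-for-bit.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        image = image[:, :, None]
    if image.ndim != 3 or image.shape[0] != image.shape[1]:
        raise InvalidShapeError(f"expected a square image, got shape {image.shape}")
    size = image.shape[0]
    grid = PatchGrid(size, patch_size)
    s, p, c = grid.side, patch_size, image.shape[2]
    patches = (
        image.reshape(s, p, s, p, c).transpose(0, 2, 1, 3, 4).reshape(grid.n_patches, p * p * c)
    )
    return grid, patches


def unpatchify(patches: np.ndarray, grid: PatchGrid, channels: int = 1) -> np.ndarray:
    """Reassemble :func:`patchify` output into the original image."""
    s, p = grid.side, grid.patch_size
    patches = np.asarray(patches)
    if patches.shape != (grid.n_patches, p * p * channels):
        raise InvalidShapeError(f"patch array shape {patches.shape} does not match grid")
    img = patches.reshape(s, s, p, p, channels).transpose(0, 2, 1, 3, 4)
    img = img.reshape(grid.image_size, grid.image_size, channels)
    return img[:, :, 0] if channels == 1 else img


def mae_mask_select(grid: PatchGrid | int, mask_ratio: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly partition patch indices into (visible, masked) sets.

    ``round(mask_ratio × n_patches)`` indices are masked, drawn without
    replacement; both outputs are sorted. Deterministic given ``seed``.
    """
    if not 0.0 <= mask_ratio < 1.0:
        raise InvalidInputError("mask_ratio must be in [0, 1)")
    n = grid.n_patches if isinstance(grid, PatchGrid) else int(grid)
    n_masked = int(round(mask_ratio * n))
    rng = np.random.default_rng(seed)
    masked = np.sort(rng.choice(n, size=n_masked, replace=False))
    visible = np.setdiff1d(np.arange(n), masked)
    return visible, masked


# -- geometry and metrics -------------------------------------------------

def augment_pair(image: np.ndarray, mask: np.ndarray, cfg: SegConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random flip/flip/rotation triple to an (image, mask) pair.

    The same geometric transform hits both; the mask is resampled
    nearest-neighbor so it stays binary. Rotation is rigid, uniform in
    [−max_rotation_deg, +max_rotation_deg] about the center.
    """
    img = np.asarray(image, dtype=float)
    msk = np.asarray(mask, dtype=bool)
    if img.shape[:2] != msk.shape:
        raise InvalidInputError("image and mask shapes differ")
    if rng.random() < 0.5:
        img, msk = img[:, ::-1].copy(), msk[:, ::-1].copy()
    if rng.random() < 0.5:
        img, msk = img[::-1, :].copy(), msk[::-1, :].copy()
    angle = rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg)
    img = nd_rotate(img, angle, reshape=False, order=1, mode="nearest")
    msk = nd_rotate(msk.astype(np.uint8), angle, reshape=False, order=0, mode="constant") > 0
    return img, msk


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Overlap 2|A∩B| / (|A|+|B|); two empty masks count as perfect (1.0)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise InvalidInputError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


# -- models ---------------------------------------------------------------

class SegModel(Module):
    """ViT encoder + multi-depth pyramid head predicting 2-class pixel scores."""

    def __init__(self, cfg: SegConfig, rng: np.random.Generator):
        self.cfg = cfg
        grid = cfg.grid
        self.encoder = ViTEncoder(
            grid.n_patches, cfg.patch_size**2, cfg.embed_dim, cfg.encoder_depth,
            cfg.n_heads, rng, mlp_ratio=cfg.mlp_ratio,
        )
        self.laterals = [Linear(cfg.embed_dim, cfg.embed_dim, rng) for _ in cfg.tap_layers]
        # raw patch pixels skip into the head so boundaries are not limited
        # by the token bottleneck
        self.head = Linear(cfg.embed_dim + cfg.patch_size**2, cfg.patch_size**2 * 2, rng, scale=0.02)

    def forward(self, images: np.ndarray) -> Tensor:
        """Normalized (B, S, S) images → (B, S, S, 2) pixel logits."""
        cfg = self.cfg
        grid = cfg.grid
        B = images.shape[0]
        s, p = grid.side, cfg.patch_size
        patches = images.reshape(B, s, p, s, p).transpose(0, 1, 3, 2, 4).reshape(B, grid.n_patches, p * p)
        layers = self.encoder(patches, return_layers=True)
        feat = None
        for lat, tap in zip(self.laterals, cfg.tap_layers):
            term = lat(layers[tap])
            feat = term if feat is None else feat + term
        from .nn import cat as _cat

        head_in = _cat([feat.gelu(), Tensor(patches)], axis=-1)
        logits = self.head(head_in)  # (B, N, p²·2)
        logits = logits.reshape(B, s, s, p, p, 2).transpose(0, 1, 3, 2, 4, 5)
        return logits.reshape(B, cfg.image_size, cfg.image_size, 2)

    __call__ = forward


def build_seg_model(cfg: SegConfig, seed_offset: int = 0) -> SegModel:
    return SegModel(cfg, np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 17, seed_offset])))


# -- data preparation -----------------------------------------------------

def _normalize_image(image: np.ndarray) -> np.ndarray:
    return np.asarray(image, dtype=float) / 255.0 - 0.5


def resize_image(image: np.ndarray, size: int) -> np.ndarray:
    """Bilinear (anti-aliased) resize of a grayscale image to (size, size)."""
    img = np.asarray(image, dtype=float)
    if img.shape[:2] == (size, size):
        return img
    return sk_resize(img, (size, size), order=1, anti_aliasing=True, preserve_range=True)


def resize_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resize keeping the mask binary."""
    msk = np.asarray(mask)
    if msk.shape == shape:
        return msk.astype(bool)
    return sk_resize(msk.astype(float), shape, order=0, anti_aliasing=False, preserve_range=True) > 0.5


def _prepare(samples, cfg: SegConfig) -> tuple[np.ndarray, np.ndarray]:
    """Resize + normalize all samples once: (n, S, S) images, (n, S, S) masks."""
    imgs, masks = [], []
    for rec in samples:
        image, mask = (rec.intensity, rec.mask) if hasattr(rec, "intensity") else rec
        imgs.append(_normalize_image(resize_image(image, cfg.image_size)))
        masks.append(resize_mask(mask, (cfg.image_size, cfg.image_size)))
    return np.stack(imgs), np.stack(masks)


# -- training -------------------------------------------------------------

def pretrain_mae(images, cfg: SegConfig, mae_cfg: MAEConfig | None = None,
                 val_fraction: float = 0.2) -> tuple[dict, dict]:
    """Masked-autoencoder pretraining of the segmentation encoder.

    ``images`` is a list of grayscale arrays (or SampleRecords). Returns
    ``(encoder_state, history)`` where history holds the per-epoch
    training loss and the held-out masked-reconstruction error before and
    after training.
    """
    if len(images) == 0:
        raise InvalidInputError("cannot pretrain on an empty dataset")
    mae_cfg = mae_cfg or (MAEConfig.tiny() if cfg.tiny_profile else MAEConfig())
    arrs = [rec.intensity if hasattr(rec, "intensity") else rec for rec in images]
    data = np.stack([_normalize_image(resize_image(a, cfg.image_size)) for a in arrs])
    grid = cfg.grid
    s, p = grid.side, cfg.patch_size
    patches = data.reshape(len(data), s, p, s, p).transpose(0, 1, 3, 2, 4).reshape(len(data), grid.n_patches, p * p)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 29]))
    n_val = max(1, int(round(val_fraction * len(data)))) if len(data) > 1 else 0
    order = rng.permutation(len(data))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        train_idx = val_idx

    model = build_seg_model(cfg)
    decoder = MAEDecoder(cfg.embed_dim, grid.n_patches, p * p, mae_cfg.decoder_dim,
                         mae_cfg.decoder_depth, mae_cfg.decoder_heads, rng)

    def held_out_error(enc: ViTEncoder) -> float:
        vis, masked = mae_mask_select(grid, mae_cfg.mask_ratio, seed=cfg.seed + 7919)
        if len(val_idx) == 0:
            return float("nan")
        batch = patches[val_idx]
        tok = enc(batch[:, vis, :], indices=vis)
        recon = decoder(tok, vis)
        err = recon.data[:, masked, :] - batch[:, masked, :]
        return float((err * err).mean())

    initial_err = held_out_error(model.encoder)
    params = model.encoder.parameters() + decoder.parameters()
    opt = SGD(params, lr=mae_cfg.lr, momentum=0.9)
    losses = []
    step = 0
    for _epoch in range(mae_cfg.pretrain_epochs):
        perm = rng.permutation(train_idx)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(perm), mae_cfg.batch_size):
            batch = patches[perm[start:start + mae_cfg.batch_size]]
            vis, masked = mae_mask_select(grid, mae_cfg.mask_ratio, seed=cfg.seed * 100003 + step)
            step += 1
            if mae_cfg.mask_ratio == 0.0:
                vis, masked = np.arange(grid.n_patches), np.arange(grid.n_patches)
            tok = model.encoder(batch[:, vis, :], indices=vis)
            recon = decoder(tok, vis)
            loss = mae_loss(recon, batch, masked)
            opt.zero_grad()
            loss.backward()
            clip_grad_norm(params, cfg.grad_clip)
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        losses.append(epoch_loss / max(n_batches, 1))
    final_err = held_out_error(model.encoder)
    history = {"train_loss": losses, "val_error_initial": initial_err, "val_error_final": final_err}
    return model.encoder.state_dict(), history


def _train_one_seg(train_imgs, train_masks, cfg: SegConfig, pretrained: dict | None,
                   fold_id: int) -> SegModel:
    model = build_seg_model(cfg, seed_offset=fold_id)
    if pretrained is not None:
        model.encoder.load_state_dict(pretrained)
    params = model.parameters()
    opt = SGD(params, lr=cfg.lr_initial, momentum=cfg.momentum)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 31, fold_id]))
    n = len(train_imgs)
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr_initial * cfg.lr_gamma**epoch
        perm = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            if cfg.augment:
                pairs = [augment_pair(train_imgs[i], train_masks[i], cfg, rng) for i in idx]
                imgs = np.stack([p[0] for p in pairs])
                masks = np.stack([p[1] for p in pairs])
            else:
                imgs, masks = train_imgs[idx], train_masks[idx]
            logits = model(imgs)
            loss = softmax_cross_entropy(logits, masks.astype(np.intp))
            opt.zero_grad()
            loss.backward()
            clip_grad_norm(params, cfg.grad_clip)
            opt.step()
    return model


@dataclass
class SegCVResult:
    models: list
    fold_dice: list[float]
    summary: dict
    per_image_dice: list[list[float]] = dc_field(default_factory=list)

    @property
    def mean_dice(self) -> float:
        return self.summary["mean"]


def train_segmentation(samples, cfg: SegConfig, folds: FoldSplit,
                       pretrained: dict | None = None) -> SegCVResult:
    """Train one model per fold; report per-image validation DICE per fold.

    DICE is computed per validation image at model resolution, averaged
    within a fold, then across folds (unweighted).
    """
    if len(samples) != len(folds.assignments):
        raise InvalidInputError("fold assignments do not match the dataset")
    imgs, masks = _prepare(samples, cfg)
    models, fold_dice, per_image = [], [], []
    for fold in range(folds.k):
        train_idx, val_idx = folds.train_val(fold)
        if folds.k == 1:
            val_idx = train_idx
        if masks[train_idx].all() or not masks[train_idx].any():
            import warnings

            warnings.warn(f"fold {fold}: training pixels are single-class (degenerate fold)")
        model = _train_one_seg(imgs[train_idx], masks[train_idx], cfg, pretrained, fold)
        scores = []
        for i in val_idx:
            logits = model(imgs[i:i + 1]).data
            pred = np.argmax(logits[0], axis=-1) > 0
            scores.append(dice(pred, masks[i]))
        models.append(model)
        per_image.append(scores)
        fold_dice.append(float(np.mean(scores)))
    return SegCVResult(models=models, fold_dice=fold_dice,
                       summary=aggregate_folds(fold_dice), per_image_dice=per_image)


def predict_mask(model: SegModel, image: np.ndarray) -> np.ndarray:
    """Segment one grayscale image; returns a binary mask at input resolution."""
    cfg = model.cfg
    native_shape = np.asarray(image).shape[:2]
    img = _normalize_image(resize_image(image, cfg.image_size))
    logits = model(img[None]).data[0]
    pred = np.argmax(logits, axis=-1) > 0
    return resize_mask(pred, native_shape)
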