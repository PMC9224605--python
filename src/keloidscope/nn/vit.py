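"""Vision-transformer encoder and masked-autoencoder head on the autograd core.

The encoder operates on a row-major grid of non-overlapping square patches.
It can run on an arbitrary subset of patch positions (visible patches during
masked-autoencoder pretraining, perfusion-bearing patches in the cascade
evaluator); positional embeddings are gathered by grid index so tokens keep
their spatial identity.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor, cat, mse_masked
from .layers import LayerNorm, Linear, Module, TransformerBlock

__all__ = ["ViTEncoder", "MAEDecoder", "mae_loss"]


class ViTEncoder(Module):
    """Patch-token transformer encoder.

    Parameters
    ----------
    n_patches:
        Number of grid cells (side² for a square image).
    patch_dim:
        Flattened pixel dimension of one patch (patch_size² × channels).
    dim, depth, n_heads, mlp_ratio:
        Usual transformer hyperparameters.
    """

    def __init__(self, n_patches: int, patch_dim: int, dim: int, depth: int,
                 n_heads: int, rng: np.random.Generator, mlp_ratio: float = 2.0):
        self.n_patches = n_patches
        self.patch_dim = patch_dim
        self.dim = dim
        self.depth = depth
        self.embed = Linear(patch_dim, dim, rng)
        self.pos = Parameter(rng.normal(0.0, 0.02, size=(n_patches, dim)))
        self.blocks = [TransformerBlock(dim, n_heads, mlp_ratio, rng) for _ in range(depth)]
        self.norm = LayerNorm(dim)

    def __call__(self, patches: np.ndarray | Tensor,
                 indices: np.ndarray | None = None,
                 return_layers: bool = False,
                 final_norm: bool = True):
        """Encode patch pixel contents.

        ``patches`` is (B, n, patch_dim); if ``indices`` (length n) is given,
        the n tokens sit at those grid positions, otherwise n must equal
        ``n_patches``. Returns the final normalized tokens, or a list of
        per-block outputs (post-norm applied only to the last) when
        ``return_layers`` is set.
        """
        x = patches if isinstance(patches, Tensor) else Tensor(patches)
        tok = self.embed(x)
        if indices is None:
            tok = tok + self.pos
        else:
            tok = tok + self.pos.gather_rows(np.asarray(indices), axis=0)
        layers = []
        for blk in self.blocks:
            tok = blk(tok)
            if return_layers:
                layers.append(tok)
        if final_norm:
            tok = self.norm(tok)
        if return_layers:
            layers[-1] = tok
            return layers
        return tok


class MAEDecoder(Module):
    """Lightweight decoder reconstructing pixel patches from visible tokens.

    Visible encoder tokens are projected to the decoder width, merged with a
    shared learnable mask token at the masked positions, run through a small
    transformer, and mapped back to patch pixels.
    """

    def __init__(self, encoder_dim: int, n_patches: int, patch_dim: int,
                 dim: int, depth: int, n_heads: int, rng: np.random.Generator):
        self.n_patches = n_patches
        self.proj = Linear(encoder_dim, dim, rng)
        self.mask_token = Parameter(rng.normal(0.0, 0.02, size=(dim,)))
        self.pos = Parameter(rng.normal(0.0, 0.02, size=(n_patches, dim)))
        self.blocks = [TransformerBlock(dim, n_heads, 2.0, rng) for _ in range(depth)]
        self.norm = LayerNorm(dim)
        self.head = Linear(dim, patch_dim, rng)

    def __call__(self, visible_tokens: Tensor, visible_idx: np.ndarray) -> Tensor:
        B = visible_tokens.shape[0]
        vis = self.proj(visible_tokens)  # (B, n_vis, dim)
        dim = self.mask_token.shape[0]
        # full sequence: mask token everywhere, then overwrite visible slots.
        # Build by concatenating along tokens then scattering via gather is
        # awkward in reverse; instead assemble per-position with a permutation.
        n = self.n_patches
        visible_idx = np.asarray(visible_idx, dtype=np.intp)
        masked_idx = np.setdiff1d(np.arange(n), visible_idx)
        n_mask = masked_idx.size
        mask_tok = self.mask_token.reshape(1, 1, dim)
        ones = Tensor(np.ones((B, n_mask, 1)))
        mask_block = ones.matmul(mask_tok.reshape(1, dim))  # (B, n_mask, dim)
        seq = cat([vis, mask_block], axis=1)  # (B, n, dim) in permuted order
        order = np.concatenate([visible_idx, masked_idx])
        inv = np.argsort(order)
        seq = seq.gather_rows(inv, axis=1)  # back to grid order
        seq = seq + self.pos
        for blk in self.blocks:
            seq = blk(seq)
        return self.head(self.norm(seq))  # (B, n_patches, patch_dim)


def mae_loss(recon: Tensor, target: np.ndarray, masked_idx: np.ndarray) -> Tensor:
    """MSE restricted to the masked patches (the reconstruction objective)."""
    weight = np.zeros(recon.shape[:2] + (1,))
    weight[:, np.asarray(masked_idx, dtype=np.intp), :] = 1.0
    return mse_masked(recon, target, np.broadcast_to(weight, recon.shape))
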