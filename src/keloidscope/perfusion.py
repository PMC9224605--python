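"""Blood-perfusion recovery from rendered heatmaps.

LSCI devices export the perfusion map as a rendered blue-to-red heatmap
rather than raw perfusion units (PU, mL/100 g/min). Given a colorbar
lookup table (LUT) that pairs colors with PU values, the per-pixel PU is
recovered by nearest-color matching, restricted to the segmented keloid,
and summarized as a mean with the associated absolute/relative error
statistics against the device-reported value.

The device vendor's exact colormap is not public, so the LUT is always an
explicit input: either an anchor table (TSV) or a colorbar strip image
with its endpoint PU values. A packaged blue→cyan→green→yellow→red ramp
(:func:`default_lut`) is what the synthetic generator renders with.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    AmbiguousLUTError,
    EmptyRegionError,
    InvalidInputError,
    InvalidLUTError,
)

__all__ = [
    "ColorbarLUT",
    "PerfusionStats",
    "PerfusionError",
    "build_lut",
    "default_lut",
    "lut_from_colorbar_image",
    "rgb_to_pu",
    "crop_and_mask",
    "mean_perfusion",
    "perfusion_error",
    "mask_bbox",
]


@dataclass(frozen=True)
class ColorbarLUT:
    """Ordered color→PU anchors; PU strictly increasing along the table."""

    colors: np.ndarray  # (n, 3) uint8
    pu: np.ndarray  # (n,) float64, strictly increasing

    @property
    def n_anchors(self) -> int:
        return len(self.pu)

    @property
    def pu_min(self) -> float:
        return float(self.pu[0])

    @property
    def pu_max(self) -> float:
        return float(self.pu[-1])

    @property
    def quantization_step(self) -> float:
        """Largest PU gap between consecutive anchors."""
        return float(np.max(np.diff(self.pu)))

    def anchors(self) -> list[tuple[tuple[int, int, int], float]]:
        return [(tuple(int(c) for c in col), float(p)) for col, p in zip(self.colors, self.pu)]


@dataclass(frozen=True)
class PerfusionStats:
    """Mean PU over a region of interest."""

    mean_pu: float
    n_pixels: int
    bounding_box: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open


@dataclass(frozen=True)
class PerfusionError:
    """Absolute (PU) and relative (%) disagreement between two mean-PU readings."""

    abs_error: float
    rel_error: float


def build_lut(anchor_table, densify: int | None = None) -> ColorbarLUT:
    """Validate (and optionally densify) a color→PU anchor table.

    Raises :class:`InvalidLUTError` for fewer than two anchors or
    non-increasing PU, and :class:`AmbiguousLUTError` when the same color
    is paired with two different PU values. ``densify`` resamples the
    table to that many anchors by piecewise-linear interpolation in both
    RGB and PU.
    """
    if len(anchor_table) < 2:
        raise InvalidLUTError("a colorbar LUT needs at least 2 anchors")
    colors = np.asarray([c for c, _ in anchor_table], dtype=float)
    pu = np.asarray([p for _, p in anchor_table], dtype=np.float64)
    if colors.shape[1] != 3:
        raise InvalidLUTError("anchor colors must be RGB triples")
    if np.any(colors < 0) or np.any(colors > 255):
        raise InvalidLUTError("anchor colors must lie in 0..255")
    if not np.all(np.diff(pu) > 0):
        raise InvalidLUTError("anchor PU values must be strictly increasing")
    rounded = np.round(colors).astype(np.uint8)
    _, first_idx, inverse = np.unique(rounded, axis=0, return_index=True, return_inverse=True)
    if len(first_idx) != len(rounded):
        # duplicate colors are only tolerable if they carry identical PU
        for group in range(len(first_idx)):
            members = np.nonzero(inverse == group)[0]
            if len(members) > 1 and not np.allclose(pu[members], pu[members[0]]):
                raise AmbiguousLUTError(
                    f"color {tuple(rounded[members[0]])} maps to conflicting PU values"
                )
        raise AmbiguousLUTError("duplicate anchor colors in LUT")
    if densify is not None:
        if densify < 2:
            raise InvalidLUTError("densified LUT needs at least 2 anchors")
        t_old = np.linspace(0.0, 1.0, len(pu))
        t_new = np.linspace(0.0, 1.0, densify)
        pu = np.interp(t_new, t_old, pu)
        colors = np.stack([np.interp(t_new, t_old, colors[:, ch]) for ch in range(3)], axis=1)
        rounded = np.round(colors).astype(np.uint8)
        if len(np.unique(rounded, axis=0)) != len(rounded):
            raise AmbiguousLUTError("densification produced duplicate colors; use fewer anchors")
    return ColorbarLUT(colors=rounded, pu=np.asarray(pu, dtype=np.float64))


# Five-point blue→cyan→green→yellow→red ramp; linear interpolation between
# stops changes exactly one channel at a time, so a ≤256-entry table has
# strictly distinct colors.
_RAMP_STOPS = np.array(
    [[0, 0, 255], [0, 255, 255], [0, 255, 0], [255, 255, 0], [255, 0, 0]], dtype=float
)


def default_lut(n_entries: int = 256, pu_min: float = 0.0, pu_max: float = 300.0) -> ColorbarLUT:
    """The packaged blue→red ramp used by the synthetic renderer.

    The default PU range 0–300 covers resting skin (~30 PU) through the
    most perfused keloids in the study population (face ≈ 183 PU mean
    plus within-lesion heterogeneity).
    """
    if not 2 <= n_entries <= 256:
        raise InvalidLUTError("default ramp supports 2..256 entries")
    if not pu_min < pu_max:
        raise InvalidLUTError("pu_min must be < pu_max")
    t = np.linspace(0.0, 4.0, n_entries)
    seg = np.minimum(t.astype(int), 3)
    frac = t - seg
    colors = _RAMP_STOPS[seg] * (1 - frac[:, None]) + _RAMP_STOPS[seg + 1] * frac[:, None]
    pu = np.linspace(pu_min, pu_max, n_entries)
    return build_lut(list(zip(np.round(colors).astype(int).tolist(), pu)))


def lut_from_colorbar_image(strip: np.ndarray, pu_min: float, pu_max: float,
                            axis: str = "column") -> ColorbarLUT:
    """Read a LUT off a rendered colorbar strip.

    One anchor per pixel position along ``axis`` (``"row"`` = PU varies
    across rows, ``"column"`` = across columns), colors averaged across
    the perpendicular direction, PU linearly spaced from ``pu_min`` at
    the first position to ``pu_max`` at the last. Consecutive duplicate
    colors (saturated colorbar ends) are collapsed onto their first
    position before validation.
    """
    if pu_min >= pu_max:
        raise InvalidInputError("pu_min must be strictly less than pu_max")
    strip = np.asarray(strip, dtype=float)
    if strip.ndim == 2:
        strip = np.repeat(strip[:, :, None], 3, axis=2)
    if strip.ndim != 3 or strip.shape[2] != 3:
        raise InvalidInputError("colorbar strip must be an RGB (or grayscale) image")
    if axis == "row":
        profile = strip.mean(axis=1)  # (H, 3)
    elif axis == "column":
        profile = strip.mean(axis=0)  # (W, 3)
    else:
        raise InvalidInputError("axis must be 'row' or 'column'")
    if len(profile) < 2:
        raise InvalidInputError("colorbar strip needs at least 2 pixels along its axis")
    colors = np.round(profile).astype(int)
    pu = np.linspace(pu_min, pu_max, len(colors))
    keep = np.ones(len(colors), dtype=bool)
    keep[1:] = np.any(colors[1:] != colors[:-1], axis=1)
    anchors = [(tuple(c), float(p)) for c, p in zip(colors[keep], pu[keep])]
    return build_lut(anchors)


def rgb_to_pu(heatmap: np.ndarray, lut: ColorbarLUT) -> tuple[np.ndarray, np.ndarray]:
    """Invert a rendered heatmap to per-pixel PU by nearest-color matching.

    Returns ``(field, distance)`` where ``distance`` is the Euclidean RGB
    distance to the matched anchor — large distances flag off-palette
    pixels such as annotation overlays. Ties in color distance resolve to
    the lower PU anchor. Never raises on pixel content.
    """
    heatmap = np.asarray(heatmap)
    if heatmap.ndim != 3 or heatmap.shape[2] != 3:
        raise InvalidInputError("heatmap must be an (H, W, 3) RGB image")
    h, w, _ = heatmap.shape
    px = heatmap.reshape(-1, 3).astype(np.int64)
    anchors = lut.colors.astype(np.int64)
    # squared distances in exact integer arithmetic so ties are exact;
    # argmin picks the first (= lowest-PU) anchor on ties.
    d2 = (
        (px * px).sum(axis=1, keepdims=True)
        - 2 * px @ anchors.T
        + (anchors * anchors).sum(axis=1)
    )
    nearest = np.argmin(d2, axis=1)
    field = lut.pu[nearest].reshape(h, w)
    dist = np.sqrt(d2[np.arange(len(px)), nearest].astype(float)).reshape(h, w)
    return field, dist


def mask_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Tight half-open bounding box (row0, col0, row1, col1) of a mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError("mask is empty")
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    return int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1


def crop_and_mask(field: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Zero the field outside the keloid and return its bounding-box crop.

    Cropping to the lesion removes pigmentation-contaminated background
    perfusion before any summary statistic is taken.
    """
    field = np.asarray(field, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if field.shape != mask.shape:
        raise InvalidInputError(f"field shape {field.shape} != mask shape {mask.shape}")
    bbox = mask_bbox(mask)
    masked = np.where(mask, field, 0.0)
    return masked, bbox


def mean_perfusion(field: np.ndarray, mask: np.ndarray) -> PerfusionStats:
    """Mean PU over mask-positive pixels."""
    field = np.asarray(field, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if field.shape != mask.shape:
        raise InvalidInputError(f"field shape {field.shape} != mask shape {mask.shape}")
    bbox = mask_bbox(mask)  # raises EmptyRegionError on empty mask
    vals = field[mask]
    return PerfusionStats(mean_pu=float(vals.mean()), n_pixels=int(mask.sum()), bounding_box=bbox)


def perfusion_error(a: float, b: float) -> PerfusionError:
    """Absolute |A−B| and relative |A−B|/max(|A|,|B|)×100 disagreement.

    A is conventionally the device-reported mean PU and B the recovered
    one; the formula is symmetric. The degenerate case A = B = 0 is
    defined as 0% relative error.
    """
    if a < 0 or b < 0:
        raise InvalidInputError("perfusion values must be nonnegative")
    abs_err = abs(a - b)
    denom = max(abs(a), abs(b))
    rel = 0.0 if denom == 0 else abs_err / denom * 100.0
    return PerfusionError(abs_error=float(abs_err), rel_error=float(rel))
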