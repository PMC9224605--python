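"""Synthetic LSCI case generator.

Clinical LSCI exports are private, so every downstream stage is exercised
on generated cases that reproduce the statistical structure the workflow
relies on: irregular keloid-shaped regions, spatially correlated
within-lesion perfusion whose level depends on growth state, a rendered
blue→red heatmap, a grayscale intensity image with pigmentation-like
distractors outside the lesion, and the 49/37/64 regressive/stable/
progressive mix over 150 cases observed in the study population.

The generative choices (documented in the methods note):

* Growth state scales the site-level mean perfusion multiplicatively
  (regressive ×0.8, stable ×1.0, progressive ×1.25) and sets the
  within-lesion heterogeneity (CV 0.10/0.15/0.25) — level plus
  unevenness is the learnable signal.
* Lesion shapes are thresholded low-pass random fields, falling back to
  randomly perturbed ellipses when the component count comes out wrong.
* Background skin perfusion is normal with 10% CV, clipped at zero.

Everything is a pure function of ``(spec, seed)``: repeat calls are
byte-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter, label as cc_label
from skimage.draw import polygon as draw_polygon

from .errors import EmptyRegionError, InsufficientNError, InvalidSpecError
from .perfusion import ColorbarLUT, default_lut

__all__ = [
    "STAGES",
    "STAGE_SCALE",
    "STAGE_HETERO_CV",
    "COHORT_SITE_PROFILES",
    "OVERALL_MEAN_PU",
    "DEFAULT_STAGE_MIX",
    "SceneSpec",
    "SampleRecord",
    "make_keloid_mask",
    "make_perfusion_field",
    "make_intensity_image",
    "render_heatmap",
    "generate_dataset",
    "write_dataset",
    "load_dataset",
    "largest_remainder_counts",
    "expected_dataset_mean_pu",
]

STAGES = ("regressive", "stable", "progressive")

# growth state → multiplicative scale on the site mean and within-lesion CV
STAGE_SCALE = {"regressive": 0.80, "stable": 1.00, "progressive": 1.25}
STAGE_HETERO_CV = {"regressive": 0.10, "stable": 0.15, "progressive": 0.25}

# body-site perfusion profiles: (name, mean PU, cohort weight)
COHORT_SITE_PROFILES: tuple[tuple[str, float, float], ...] = (
    ("back", 127.6, 34 / 150),
    ("chest", 135.8, 63 / 150),
    ("ear", 157.8, 8 / 150),
    ("face", 182.8, 6 / 150),
    ("hip", 103.0, 9 / 150),
    ("limb", 105.2, 18 / 150),
    ("abdomen", 118.5, 12 / 150),
)
OVERALL_MEAN_PU = 129.9

DEFAULT_STAGE_MIX = (49 / 150, 37 / 150, 64 / 150)

# per-sample lognormal jitter of the target mean (CV ≈ 8%): individual
# lesions of the same site and stage do not share one exact perfusion level
TARGET_JITTER_CV = 0.08


def _rng(seed: int, *salts: str) -> np.random.Generator:
    """Independent generator for one (seed, operation) pair."""
    entropy = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(s.encode()) for s in salts]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic case."""

    image_height: int = 256
    image_width: int = 256
    n_keloids: int = 1
    area_fraction_range: tuple[float, float] = (0.05, 0.25)
    stage: str = "stable"
    target_mean_pu: float = OVERALL_MEAN_PU
    background_mean_pu: float = 35.0
    heterogeneity_scale: float = 12.0
    pigmentation_distractors: int = 2
    seed: int = 0

    def validate(self) -> "SceneSpec":
        low, high = self.area_fraction_range
        if not (0.0 < low < high < 1.0):
            raise InvalidSpecError(f"area_fraction_range must satisfy 0 < low < high < 1, got {self.area_fraction_range}")
        if self.n_keloids < 1:
            raise InvalidSpecError("n_keloids must be >= 1")
        if self.stage not in STAGES:
            raise InvalidSpecError(f"stage must be one of {STAGES}")
        if self.target_mean_pu <= 0 or self.background_mean_pu < 0:
            raise InvalidSpecError("perfusion means must be positive")
        if self.stage == "progressive" and self.target_mean_pu <= self.background_mean_pu:
            raise InvalidSpecError("a progressive keloid must out-perfuse the background")
        if self.heterogeneity_scale <= 0:
            raise InvalidSpecError("heterogeneity_scale must be positive")
        if self.pigmentation_distractors < 0:
            raise InvalidSpecError("pigmentation_distractors must be >= 0")
        if min(self.image_height, self.image_width) < 32:
            raise InvalidSpecError("images smaller than 32 px are not supported")
        return self


@dataclass
class SampleRecord:
    """One synthetic case: intensity image, heatmap, truth field/mask, label."""

    intensity: np.ndarray  # (H, W) uint8
    heatmap: np.ndarray  # (H, W, 3) uint8
    field: np.ndarray  # (H, W) float64, PU
    mask: np.ndarray  # (H, W) bool
    stage: str
    meta: dict = dc_field(default_factory=dict)


def _smooth_unit_noise(shape, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian-smoothed white noise, standardized to zero mean, unit SD."""
    noise = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = noise.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return (noise - noise.mean()) / sd


def _star_blob(center, area_px: float, rng: np.random.Generator, shape) -> np.ndarray:
    """Rasterize an irregular star-shaped blob of approximately ``area_px``."""
    amps = rng.uniform(0.03, 0.12, size=4)
    phases = rng.uniform(0, 2 * np.pi, size=4)
    theta = np.linspace(0, 2 * np.pi, 180, endpoint=False)
    wobble = 1.0 + sum(a * np.cos((k + 2) * theta + p) for k, (a, p) in enumerate(zip(amps, phases)))
    r0 = np.sqrt(area_px / (np.pi * float(np.mean(wobble**2))))
    out = np.zeros(shape, dtype=bool)
    for _ in range(3):  # one-shot area correction, then accept
        rr = r0 * wobble
        rows = center[0] + rr * np.sin(theta)
        cols = center[1] + rr * np.cos(theta)
        pr, pc = draw_polygon(rows, cols, shape=shape)
        out = np.zeros(shape, dtype=bool)
        out[pr, pc] = True
        got = out.sum()
        if got == 0:
            r0 *= 1.5
            continue
        ratio = np.sqrt(area_px / got)
        if abs(ratio - 1.0) < 0.02:
            break
        r0 *= ratio
    return out


def _ellipse_fallback(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Place ``n_keloids`` disjoint perturbed-ellipse blobs with areas in range."""
    H, W = spec.image_height, spec.image_width
    low, high = spec.area_fraction_range
    span = high - low
    mask = np.zeros((H, W), dtype=bool)
    placed = 0
    for _ in range(200):
        if placed == spec.n_keloids:
            break
        frac = rng.uniform(low + 0.15 * span, high - 0.15 * span)
        area_px = frac * H * W
        r_est = np.sqrt(area_px / np.pi) * 1.2
        if 2 * r_est >= min(H, W):
            frac = low + 0.15 * span
            area_px = frac * H * W
            r_est = np.sqrt(area_px / np.pi) * 1.2
        center = (rng.uniform(r_est, H - r_est), rng.uniform(r_est, W - r_est))
        blob = _star_blob(center, area_px, rng, (H, W))
        got = blob.sum() / (H * W)
        if not (low < got < high):
            continue
        if (blob & binary_dilation(mask, iterations=3)).any():
            continue
        if cc_label(blob)[1] != 1:
            continue
        mask |= blob
        placed += 1
    if placed != spec.n_keloids:
        raise InvalidSpecError(
            f"could not place {spec.n_keloids} keloids with area range {spec.area_fraction_range}"
        )
    return mask


def make_keloid_mask(spec: SceneSpec) -> np.ndarray:
    """Generate a binary mask with ``n_keloids`` irregular smooth-bordered blobs.

    Primary model: a Gaussian-smoothed uniform random field thresholded at
    the quantile that yields the target total area. If the connected
    component count or the per-component areas are wrong after 10 retries,
    falls back to perturbed ellipses (which control count and area
    directly).
    """
    spec.validate()
    H, W = spec.image_height, spec.image_width
    low, high = spec.area_fraction_range
    base = _rng(spec.seed, "mask")
    for _ in range(10):
        fracs = base.uniform(low + 0.1 * (high - low), high - 0.1 * (high - low), size=spec.n_keloids)
        total = min(float(fracs.sum()), 0.6)
        sigma = max(4.0, 0.5 * np.sqrt(total / spec.n_keloids * H * W / np.pi))
        field = gaussian_filter(base.uniform(size=(H, W)), sigma, mode="reflect")
        thresh = np.quantile(field, 1.0 - total)
        mask = field > thresh
        labels, n_cc = cc_label(mask)
        if n_cc != spec.n_keloids:
            continue
        areas = np.bincount(labels.ravel())[1:] / (H * W)
        if np.all((areas > low) & (areas < high)):
            return mask
    return _ellipse_fallback(spec, _rng(spec.seed, "mask-fallback"))


def make_perfusion_field(mask: np.ndarray, spec: SceneSpec) -> np.ndarray:
    """Per-pixel PU: correlated heterogeneous flow inside, skin baseline outside.

    Inside the lesion the field is ``target × (1 + cv·g)`` with ``g`` a
    smoothed standardized noise field (correlation length
    ``heterogeneity_scale``) and ``cv`` set by the growth state, so the
    empirical inside mean equals the target before clipping. The
    background is N(background_mean_pu, 10% CV). Everything is clipped
    at 0 (physical perfusion is nonnegative).
    """
    spec.validate()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError("cannot synthesize perfusion for an empty keloid mask")
    H, W = mask.shape
    rng = _rng(spec.seed, "field")
    cv = STAGE_HETERO_CV[spec.stage]
    out = rng.normal(spec.background_mean_pu, 0.10 * spec.background_mean_pu, size=(H, W))
    if np.isinf(spec.heterogeneity_scale):
        inside = np.full((H, W), spec.target_mean_pu)
    else:
        g = _smooth_unit_noise((H, W), spec.heterogeneity_scale, rng)
        gv = g[mask]
        sd = gv.std()
        g_inside = np.zeros((H, W)) if sd < 1e-12 else (g - gv.mean()) / sd
        inside = spec.target_mean_pu * (1.0 + cv * g_inside)
    out = np.where(mask, inside, out)
    return np.clip(out, 0.0, None)


def render_heatmap(field: np.ndarray, lut: ColorbarLUT | None = None) -> np.ndarray:
    """Render a PU field to RGB the way the device draws its heatmap.

    Each pixel takes the color of the LUT anchor whose PU is nearest;
    values outside the LUT range clip to the end anchors. Ties resolve to
    the lower-PU anchor, matching the inversion's tie rule.
    """
    if lut is None:
        lut = default_lut()
    field = np.asarray(field, dtype=float)
    if not np.all(np.isfinite(field)):
        raise InvalidSpecError("perfusion field must be finite")
    midpoints = (lut.pu[1:] + lut.pu[:-1]) / 2.0
    idx = np.searchsorted(midpoints, field, side="left")
    return lut.colors[idx]


def make_intensity_image(mask: np.ndarray, spec: SceneSpec) -> np.ndarray:
    """Grayscale intensity image: lesion vs skin texture plus dark distractors.

    The keloid region is brighter with finer-grained texture; the
    requested number of pigmentation-like distractor patches (darker,
    smooth) are placed strictly outside the mask so segmentation cannot
    rely on brightness alone being informative everywhere.
    """
    spec.validate()
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    rng = _rng(spec.seed, "intensity")
    img = 90.0 + 8.0 * _smooth_unit_noise((H, W), 8.0, rng)
    keloid_tex = 150.0 + 12.0 * _smooth_unit_noise((H, W), 2.0, rng)
    img = np.where(mask, keloid_tex, img)

    if spec.pigmentation_distractors > 0:
        forbidden = binary_dilation(mask, iterations=4)
        placed = 0
        for _ in range(100 * spec.pigmentation_distractors):
            if placed == spec.pigmentation_distractors:
                break
            frac = rng.uniform(0.002, 0.01)
            r_est = np.sqrt(frac * H * W / np.pi) * 1.3
            center = (rng.uniform(r_est, H - r_est), rng.uniform(r_est, W - r_est))
            blob = _star_blob(center, frac * H * W, rng, (H, W))
            blob &= ~forbidden  # distractors never touch the lesion
            if blob.sum() < 0.5 * frac * H * W:
                continue
            img = np.where(blob, 55.0 + 6.0 * _smooth_unit_noise((H, W), 3.0, rng), img)
            placed += 1

    img = img + rng.normal(0.0, 3.0, size=(H, W))  # sensor noise
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def largest_remainder_counts(n: int, proportions: Sequence[float]) -> list[int]:
    """Integer class counts by largest-remainder rounding of ``n × p``."""
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=0.01):
        raise InvalidSpecError("stage proportions must be nonnegative and sum to 1")
    p = p / p.sum()
    exact = n * p
    counts = np.floor(exact).astype(int)
    short = n - counts.sum()
    order = np.lexsort((np.arange(len(p)), -(exact - counts)))
    for i in range(short):
        counts[order[i]] += 1
    return counts.tolist()


def _make_case(spec: SceneSpec, lut: ColorbarLUT) -> SampleRecord:
    mask = make_keloid_mask(spec)
    field = make_perfusion_field(mask, spec)
    heatmap = render_heatmap(field, lut)
    intensity = make_intensity_image(mask, spec)
    return SampleRecord(
        intensity=intensity,
        heatmap=heatmap,
        field=field,
        mask=mask,
        stage=spec.stage,
        meta={"seed": spec.seed, "spec": spec, "mean_pu_inside": float(field[mask].mean())},
    )


def generate_dataset(
    n: int,
    stage_mix: Sequence[float] = DEFAULT_STAGE_MIX,
    site_profiles: Sequence[tuple[str, float, float]] = COHORT_SITE_PROFILES,
    seed: int = 0,
    base_spec: SceneSpec | None = None,
    lut: ColorbarLUT | None = None,
) -> tuple[list[SampleRecord], list[dict]]:
    """Generate ``n`` cases with the requested stage mix and site profiles.

    Per-stage counts follow largest-remainder rounding of ``n × stage_mix``;
    each case draws a body-site profile by cohort weight, scales it by the
    stage multiplier and an 8%-CV lognormal per-lesion jitter, and renders
    the full image quadruple. Returns the records and a manifest (one dict
    per case: file names, stage, site, true inside-mask mean PU, seed).
    """
    if n < 3:
        raise InsufficientNError("need at least 3 cases to cover three growth states")
    counts = largest_remainder_counts(n, stage_mix)
    if lut is None:
        lut = default_lut()
    base = base_spec if base_spec is not None else SceneSpec(seed=seed)
    rng = _rng(seed, "dataset")
    stages = np.repeat(np.arange(3), counts)
    rng.shuffle(stages)
    site_names = [s[0] for s in site_profiles]
    site_means = np.array([s[1] for s in site_profiles])
    site_w = np.array([s[2] for s in site_profiles], dtype=float)
    site_w = site_w / site_w.sum()
    sigma = np.sqrt(np.log(1.0 + TARGET_JITTER_CV**2))
    records: list[SampleRecord] = []
    manifest: list[dict] = []
    for i, stage_idx in enumerate(stages):
        stage = STAGES[stage_idx]
        site_i = rng.choice(len(site_names), p=site_w)
        jitter = float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
        target = float(site_means[site_i]) * STAGE_SCALE[stage] * jitter
        case_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(base, stage=stage, target_mean_pu=target, seed=case_seed)
        rec = _make_case(spec, lut)
        rec.meta.update(case_id=f"case_{i:04d}", site=site_names[site_i])
        records.append(rec)
        manifest.append(
            {
                "case_id": rec.meta["case_id"],
                "intensity": f"case_{i:04d}_intensity.png",
                "heatmap": f"case_{i:04d}_heatmap.png",
                "field": f"case_{i:04d}_field.tsv",
                "mask": f"case_{i:04d}_mask.png",
                "stage": stage,
                "site": site_names[site_i],
                "mean_pu": f"{rec.meta['mean_pu_inside']:.4f}",
                "seed": str(case_seed),
            }
        )
    return records, manifest


def expected_dataset_mean_pu(
    stage_mix: Sequence[float] = DEFAULT_STAGE_MIX,
    site_profiles: Sequence[tuple[str, float, float]] = COHORT_SITE_PROFILES,
) -> float:
    """Analytic expectation of the dataset-level inside-mask mean PU."""
    p = np.asarray(stage_mix, dtype=float)
    p = p / p.sum()
    scale = float(sum(p[i] * STAGE_SCALE[s] for i, s in enumerate(STAGES)))
    w = np.asarray([s[2] for s in site_profiles], dtype=float)
    w = w / w.sum()
    site_mean = float(sum(wi * s[1] for wi, s in zip(w, site_profiles)))
    return site_mean * scale


def write_dataset(records: list[SampleRecord], manifest: list[dict], out_dir) -> None:
    """Write PNGs, field TSVs, the manifest TSV, and a spec echo JSON."""
    from pathlib import Path

    from . import io as kio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec, row in zip(records, manifest):
        kio.write_image(out / row["intensity"], rec.intensity)
        kio.write_image(out / row["heatmap"], rec.heatmap)
        kio.write_field_tsv(out / row["field"], rec.field)
        kio.write_mask(out / row["mask"], rec.mask)
    kio.write_manifest(out / "manifest.tsv", manifest)
    spec0 = records[0].meta["spec"]
    echo = {k: v for k, v in vars(spec0).items() if k not in ("seed", "stage", "target_mean_pu")}
    kio.write_json(out / "spec.json", {"n": len(records), "base_spec": echo})


def load_dataset(data_dir) -> tuple[list[SampleRecord], list[dict]]:
    """Load a dataset previously written by :func:`write_dataset`."""
    from pathlib import Path

    from . import io as kio

    data = Path(data_dir)
    manifest = kio.read_manifest(data / "manifest.tsv")
    records = []
    for row in manifest:
        records.append(
            SampleRecord(
                intensity=kio.read_image(data / row["intensity"]),
                heatmap=kio.read_image(data / row["heatmap"]),
                field=kio.read_field_tsv(data / row["field"]),
                mask=kio.read_mask(data / row["mask"]),
                stage=row["stage"],
                meta={"case_id": row["case_id"], "site": row.get("site", ""),
                      "seed": int(row["seed"]), "mean_pu_inside": float(row["mean_pu"])},
            )
        )
    return records, manifest
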