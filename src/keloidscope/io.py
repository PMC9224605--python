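"""File I/O: PNG images, TSV perfusion fields and LUTs, manifests, JSON reports.

All on-disk formats are plain text or PNG so datasets stay portable:
masks are 0/255 single-channel PNGs, perfusion fields are row-major
tab-separated float matrices, LUTs are 4-column TSVs (r, g, b, pu).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import InvalidInputError

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_field_tsv",
    "write_field_tsv",
    "read_lut_tsv",
    "write_lut_tsv",
    "read_manifest",
    "write_manifest",
    "write_json",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG as uint8; RGB kept as (H, W, 3), grayscale as (H, W)."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return np.asarray(arr, dtype=np.uint8)


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 PNG mask into a boolean array."""
    arr = read_image(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return arr > 127


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    write_image(path, np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8))


def read_field_tsv(path: str | Path) -> np.ndarray:
    field = np.loadtxt(path, delimiter="\t", ndmin=2)
    if not np.all(np.isfinite(field)):
        raise InvalidInputError(f"non-finite values in perfusion field {path}")
    return field


def write_field_tsv(path: str | Path, field: np.ndarray) -> None:
    np.savetxt(path, np.asarray(field, dtype=float), delimiter="\t", fmt="%.4f")


def read_lut_tsv(path: str | Path) -> list[tuple[tuple[int, int, int], float]]:
    """Read LUT anchors from a TSV with header columns r, g, b, pu."""
    anchors = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"r", "g", "b", "pu"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise InvalidInputError(f"LUT file {path} must have header columns r, g, b, pu")
        for row in reader:
            anchors.append(
                ((int(row["r"]), int(row["g"]), int(row["b"])), float(row["pu"]))
            )
    return anchors


def write_lut_tsv(path: str | Path, anchors) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["r", "g", "b", "pu"])
        for (r, g, b), pu in anchors:
            writer.writerow([int(r), int(g), int(b), repr(float(pu))])


def read_manifest(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def write_manifest(path: str | Path, rows: list[dict]) -> None:
    if not rows:
        raise InvalidInputError("empty manifest")
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()), delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


def write_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
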