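"""Image and temperature-field input, RGB decomposition, and ROI handling.

A thermal camera exports a pseudo-color image in which a palette maps surface
temperature to RGB.  Texture analysis operates on the three color component
planes separately, each treated as an 8-bit grayscale image; the conventional
thermal features (Taver/Tmax/Tmin, degC) are computed from a radiometric
temperature matrix, never inferred back from palette colors.

Coordinate convention: row-major, 0-based ``(row, col)``.  ROI masks are
binary rasters aligned with the image; rectangle and polygon geometries are
rasterized by pixel-center inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib.path import Path as MplPath
from PIL import Image

__all__ = [
    "RoiMask",
    "ConventionalFeatures",
    "ROI_NAMES",
    "read_image",
    "read_temperature_field",
    "decompose_components",
    "extract_roi_pixels",
    "conventional_features",
]

#: Anatomical names of the four regions of interest on the thoracolumbar view.
ROI_NAMES = {
    1: "withers",
    2: "thoracic spine",
    3: "left back musculature",
    4: "right back musculature",
}

COMPONENTS = ("R", "G", "B")


@dataclass(frozen=True)
class RoiMask:
    """A labelled region of interest as a binary raster."""

    label: int
    membership: np.ndarray  # bool, image-shaped
    name: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.membership, dtype=bool)
        object.__setattr__(self, "membership", m)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not m.any():
            raise ValueError(f"ROI {self.label}: mask has no member pixels")

    @property
    def n_pixels(self) -> int:
        return int(self.membership.sum())

    @classmethod
    def from_rectangle(
        cls, label: int, shape: tuple[int, int], top: int, left: int,
        height: int, width: int, name: str = "",
    ) -> "RoiMask":
        m = np.zeros(shape, dtype=bool)
        m[top : top + height, left : left + width] = True
        return cls(label, m, name)

    @classmethod
    def from_polygon(
        cls, label: int, shape: tuple[int, int],
        vertices: list[tuple[float, float]], name: str = "",
    ) -> "RoiMask":
        """Rasterize a polygon given as (row, col) vertices by pixel-center
        inclusion: pixel (r, c) belongs to the ROI iff its center lies inside
        the polygon."""
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        centers = np.column_stack([rows.ravel(), cols.ravel()])
        path = MplPath(np.asarray(vertices, dtype=float))
        inside = path.contains_points(centers).reshape(shape)
        return cls(label, inside, name)


@dataclass(frozen=True)
class ConventionalFeatures:
    """Taver/Tmax/Tmin (degC) of one ROI."""

    taver: float
    tmax: float
    tmin: float

    def __post_init__(self) -> None:
        if not self.tmin <= self.taver <= self.tmax:
            raise ValueError("requires tmin <= taver <= tmax")


def read_image(path: str | Path) -> np.ndarray:
    """Read a BMP/PNG/JPEG as an (H, W, 3) uint8 RGB array; alpha discarded."""
    try:
        with Image.open(path) as img:
            return np.asarray(img.convert("RGB"), dtype=np.uint8)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc


def write_image(pixels: np.ndarray, path: str | Path) -> None:
    """Write an (H, W, 3) uint8 RGB array losslessly (use PNG or BMP)."""
    Image.fromarray(np.asarray(pixels, dtype=np.uint8), mode="RGB").save(path)


def read_temperature_field(path: str | Path) -> np.ndarray:
    """Read a plain-text/CSV matrix of temperatures (degC) as a float array."""
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = line.replace(",", " ").split()
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric cell on row {lineno}") from exc
    if not rows:
        raise ValueError(f"{path}: empty temperature matrix")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        bad = next(i for i, r in enumerate(rows, start=1) if len(r) != len(rows[0]))
        raise ValueError(f"{path}: ragged row {bad}")
    return np.asarray(rows, dtype=float)


def write_temperature_field(field: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(field, dtype=float), fmt="%.4f", delimiter=",")


def decompose_components(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split an RGB image into its R, G, B component planes (in that order).

    Each plane is the raw 8-bit channel, i.e. the image "transformed to
    grayscale" by keeping one color component.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    return image[:, :, 0].copy(), image[:, :, 1].copy(), image[:, :, 2].copy()


def extract_roi_pixels(
    plane_or_field: np.ndarray, mask: RoiMask
) -> tuple[np.ndarray, np.ma.MaskedArray]:
    """Member-pixel values of an ROI plus a masked 2-D view.

    The masked view marks non-member pixels as invalid (masked), so that
    fill values can never leak into downstream statistics.
    """
    arr = np.asarray(plane_or_field)
    if arr.shape != mask.membership.shape:
        raise ValueError(
            f"shape mismatch: data {arr.shape} vs mask {mask.membership.shape}"
        )
    values = arr[mask.membership]
    view = np.ma.masked_array(arr, mask=~mask.membership)
    return values, view


def conventional_features(field: np.ndarray, mask: RoiMask) -> ConventionalFeatures:
    """Mean, max and min temperature over the ROI's member pixels."""
    values, _ = extract_roi_pixels(field, mask)
    if values.size == 0:
        raise ValueError("empty ROI")
    return ConventionalFeatures(
        taver=float(values.mean()), tmax=float(values.max()), tmin=float(values.min())
    )
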