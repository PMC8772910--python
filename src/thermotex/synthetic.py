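"""Synthetic thermography study generator.

Real radiometric images of the study design are not publicly deposited, so
this module generates a full synthetic study with the statistical structure
the analysis assumes: a cohort of 12 horses and 6 riders (2 per weight
group), a pre- and post-exercise temperature field per rider x horse
combination (72 x 2 = 144 images), pseudo-color renderings through a
monotone iron-like palette, and the four default ROI masks.

The physical model is deliberately simple and injected in *temperature*
space so both the conventional and the texture pipelines see a coherent
signal:

* a smooth spatially-correlated baseline field (low-pass-filtered Gaussian
  noise) around ``baseline_temp``, plus white per-pixel sensor noise;
* post-exercise, a uniform warming of ``exercise_warming`` degC everywhere;
* post-exercise, extra high-frequency heterogeneity (white noise of sd
  ``heterogeneity_sd[group]``) confined to the muscle-rich ROIs 1, 3 and 4 —
  the thoracic-spine strip (ROI 2) warms but gains no group-dependent
  texture.

Because the palette's red channel rises monotonically through the working
temperature range, group-dependent temperature heterogeneity surfaces as
red-component texture heterogeneity, which is exactly the contrast the
screening pipeline is meant to detect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import ROI_NAMES, RoiMask, write_image, write_temperature_field
from .study_design import (
    CombinationRecord,
    HorseRecord,
    RiderRecord,
    assign_weight_group,
    build_combination_table,
)

__all__ = [
    "PaletteSpec",
    "IRON_PALETTE",
    "SimulationConfig",
    "SyntheticStudy",
    "generate_cohort",
    "generate_temperature_field",
    "render_pseudocolor",
    "default_roi_masks",
    "generate_study",
]

MUSCLE_RICH_ROIS = (1, 3, 4)


@dataclass(frozen=True)
class PaletteSpec:
    """Piecewise-linear temperature -> RGB palette, monotone in temperature."""

    temperatures: tuple[float, ...]  # degC, strictly increasing control points
    colors: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        c = np.asarray(self.colors, dtype=float)
        if t.size != c.shape[0] or t.size < 2:
            raise ValueError("palette needs matching temperatures and colors")
        if np.any(np.diff(t) <= 0):
            raise ValueError("palette temperatures must be strictly increasing")
        if np.any(np.diff(c[:, 0]) < 0):
            raise ValueError("red channel must be non-decreasing with temperature")

    @property
    def t_min(self) -> float:
        return self.temperatures[0]

    @property
    def t_max(self) -> float:
        return self.temperatures[-1]


#: Iron-like palette spanning the camera's 10-50 degC working range; the red
#: channel rises steeply through the physiological 25-40 degC window.
IRON_PALETTE = PaletteSpec(
    temperatures=(10.0, 18.0, 26.0, 34.0, 42.0, 50.0),
    colors=(
        (0, 0, 0),
        (60, 0, 90),
        (140, 20, 120),
        (220, 80, 40),
        (255, 180, 30),
        (255, 255, 220),
    ),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    n_horses: int = 12
    riders_per_group: int = 2
    seed: int = 0
    image_size: tuple[int, int] = (120, 160)  # (rows, cols)
    baseline_temp: float = 30.0  # degC
    smooth_sd: float = 0.8  # degC, sd of the correlated baseline pattern
    correlation_length: float = 8.0  # pixels
    pixel_noise_sd: float = 0.5  # degC, white sensor noise
    exercise_warming: float = 1.5  # degC added everywhere post-exercise
    heterogeneity_sd: dict[str, float] = field(
        default_factory=lambda: {"L": 0.3, "M": 0.6, "H": 0.9}
    )  # degC, post-exercise texture noise in muscle-rich ROIs
    palette: PaletteSpec = IRON_PALETTE

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.heterogeneity_sd.values()):
            raise ValueError("heterogeneity multipliers must be non-negative")
        if self.n_horses < 1 or self.riders_per_group < 1:
            raise ValueError("cohort sizes must be positive")


# Cohort population moments of the emulated study: horse bodyweight
# 566.7 +/- 13.7 kg, withers height 160.3 +/- 3.9 cm, saddles 4.1-4.5 kg,
# rider group bodyweights around 59 / 76 / 91.5 kg with group BMIs around
# 23.2 / 27.0 / 30.6 kg/m^2.
HORSE_BW_MEAN, HORSE_BW_SD = 566.7, 13.7
HORSE_HEIGHT_MEAN, HORSE_HEIGHT_SD = 160.3, 3.9
SADDLE_RANGE = (4.1, 4.5)
RIDER_BW_MEANS = {"L": 59.0, "M": 76.0, "H": 91.5}
RIDER_BW_SD = 1.0
RIDER_BMI_MEANS = {"L": 23.2, "M": 27.0, "H": 30.6}


def _child_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Independent generator per (combination, timepoint), stable in the key."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(key))
    )


def generate_cohort(config: SimulationConfig) -> tuple[list[RiderRecord], list[HorseRecord]]:
    """Draw a cohort with the emulated study's population moments."""
    rng = _child_rng(config.seed, 0)
    horses = []
    for i in range(config.n_horses):
        horses.append(
            HorseRecord(
                id=str(i + 1),
                bodyweight=float(rng.normal(HORSE_BW_MEAN, HORSE_BW_SD)),
                height_withers=float(rng.normal(HORSE_HEIGHT_MEAN, HORSE_HEIGHT_SD)),
                saddle_weight=float(rng.uniform(*SADDLE_RANGE)),
            )
        )
    riders = []
    labels = iter("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    for group in ("L", "M", "H"):
        for _ in range(config.riders_per_group):
            bw = float(rng.normal(RIDER_BW_MEANS[group], RIDER_BW_SD))
            # height chosen so the rider's BMI lands near the group mean
            height = float(100.0 * np.sqrt(bw / rng.normal(RIDER_BMI_MEANS[group], 0.5)))
            riders.append(RiderRecord(next(labels), bw, height, group))
    return riders, horses


def default_roi_masks(shape: tuple[int, int]) -> list[RoiMask]:
    """Four non-overlapping ROIs in a fixed geometry on the dorsal view:
    a cranial withers patch (1), a narrow midline spine strip (2) and left /
    right lateral muscle patches (3, 4).  Fractional placement scales with
    the image size."""
    h, w = shape

    def rect(label, top, left, height, width):
        return RoiMask.from_rectangle(
            label, shape, int(top * h), int(left * w), int(height * h), int(width * w),
            name=ROI_NAMES[label],
        )

    return [
        rect(1, 0.05, 0.35, 0.33, 0.30),
        rect(2, 0.45, 0.45, 0.48, 0.10),
        rect(3, 0.45, 0.08, 0.48, 0.30),
        rect(4, 0.45, 0.62, 0.48, 0.30),
    ]


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sd: float, corr_length: float) -> np.ndarray:
    """Zero-mean correlated Gaussian field with pointwise sd ``sd``."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=corr_length, mode="reflect")
    std = smooth.std()
    if std == 0:
        return np.zeros(shape)
    return smooth * (sd / std)


def generate_temperature_field(
    combination_index: int,
    timepoint: str,
    group: str,
    config: SimulationConfig,
    masks: list[RoiMask] | None = None,
) -> np.ndarray:
    """One surface-temperature field (degC) for a combination and timepoint.

    Pre-exercise fields are the baseline model; post-exercise fields add the
    uniform warming plus group-dependent heterogeneity in ROIs 1, 3, 4.
    """
    if timepoint not in ("pre", "post"):
        raise ValueError("timepoint must be 'pre' or 'post'")
    masks = masks if masks is not None else default_roi_masks(config.image_size)
    t_index = 0 if timepoint == "pre" else 1
    rng = _child_rng(config.seed, 1, combination_index, t_index)
    field_ = config.baseline_temp + _smooth_field(
        rng, config.image_size, config.smooth_sd, config.correlation_length
    )
    field_ = field_ + rng.normal(0.0, config.pixel_noise_sd, config.image_size)
    if timepoint == "post":
        field_ = field_ + config.exercise_warming
        het = config.heterogeneity_sd.get(group, 0.0)
        if het > 0:
            noise = rng.normal(0.0, het, config.image_size)
            muscle = np.zeros(config.image_size, dtype=bool)
            for roi in masks:
                if roi.label in MUSCLE_RICH_ROIS:
                    muscle |= roi.membership
            field_ = field_ + noise * muscle
    return field_


def render_pseudocolor(field: np.ndarray, palette: PaletteSpec = IRON_PALETTE) -> np.ndarray:
    """Render a temperature field through the palette to an RGB uint8 image.

    Temperatures outside the palette range are clamped (with a warning), as
    a real camera would saturate.
    """
    field = np.asarray(field, dtype=float)
    if field.min() < palette.t_min or field.max() > palette.t_max:
        warnings.warn("temperatures outside palette range were clamped")
        field = np.clip(field, palette.t_min, palette.t_max)
    t = np.asarray(palette.temperatures, dtype=float)
    c = np.asarray(palette.colors, dtype=float)
    channels = [
        np.rint(np.interp(field, t, c[:, ch])).astype(np.uint8) for ch in range(3)
    ]
    return np.stack(channels, axis=-1)


@dataclass
class SyntheticStudy:
    """A generated study: metadata, fields, rendered images and masks."""

    config: SimulationConfig
    riders: list[RiderRecord]
    horses: list[HorseRecord]
    combinations: list[CombinationRecord]
    masks: list[RoiMask]
    fields: dict[tuple[str, str, str], np.ndarray]
    images: dict[tuple[str, str, str], np.ndarray]

    @property
    def metadata(self) -> pd.DataFrame:
        rows = [
            {
                "rider_id": rid,
                "horse_id": hid,
                "timepoint": tp,
                "group": self._group_of[rid, hid],
            }
            for (rid, hid, tp) in self.images
        ]
        return pd.DataFrame(rows)

    @property
    def _group_of(self) -> dict[tuple[str, str], str]:
        return {(c.rider_id, c.horse_id): c.group for c in self.combinations}

    def write(self, outdir: str | Path) -> None:
        """Materialize the study on disk: PNG images, CSV fields, mask
        geometry JSON and a metadata CSV."""
        outdir = Path(outdir)
        (outdir / "images").mkdir(parents=True, exist_ok=True)
        (outdir / "fields").mkdir(parents=True, exist_ok=True)
        for (rid, hid, tp), image in self.images.items():
            write_image(image, outdir / "images" / f"{rid}_{hid}_{tp}.png")
        for (rid, hid, tp), field_ in self.fields.items():
            write_temperature_field(field_, outdir / "fields" / f"{rid}_{hid}_{tp}.csv")
        import json

        geometry = []
        for roi in self.masks:
            rows, cols = np.nonzero(roi.membership)
            geometry.append(
                {
                    "label": roi.label,
                    "name": roi.name,
                    "shape": "rectangle",
                    "top": int(rows.min()),
                    "left": int(cols.min()),
                    "height": int(rows.max() - rows.min() + 1),
                    "width": int(cols.max() - cols.min() + 1),
                }
            )
        with open(outdir / "masks.json", "w") as fh:
            json.dump({"image_size": list(self.config.image_size), "rois": geometry}, fh, indent=1)
        self.metadata.to_csv(outdir / "metadata.csv", index=False)


def generate_study(config: SimulationConfig | None = None) -> SyntheticStudy:
    """Generate the full synthetic study (144 images under the defaults)."""
    config = config or SimulationConfig()
    riders, horses = generate_cohort(config)
    combinations = build_combination_table(riders, horses)
    masks = default_roi_masks(config.image_size)
    fields: dict[tuple[str, str, str], np.ndarray] = {}
    images: dict[tuple[str, str, str], np.ndarray] = {}
    for idx, comb in enumerate(combinations):
        for tp in ("pre", "post"):
            field_ = generate_temperature_field(idx, tp, comb.group, config, masks)
            key = (comb.rider_id, comb.horse_id, tp)
            fields[key] = field_
            images[key] = render_pseudocolor(field_, config.palette)
    return SyntheticStudy(config, riders, horses, combinations, masks, fields, images)
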