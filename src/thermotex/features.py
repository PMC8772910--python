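"""Texture features of grayscale component planes.

Three families, 31 features in total, computed per (ROI, color component):

* **Histogram statistics (HS, 13)** — first-order features of the normalized
  gray-level histogram H(k), k = 0..K-1 with K = 2^n gray levels: Mean,
  Variance, Skewness, Kurtosis, the 1/10/50/90/99th percentiles, two
  "dominant" gray levels (argmax of H and of its r-bin moving sum) and two
  "maximum of moments" (max of H and of the moving sum).
* **Gray-level run-length matrix (GLRLM, 7)** — counts p(i, j) of maximal
  runs of gray level i and length j along one scan direction: GLN, RLN, LRE,
  SRE, Fraction, MRLN, MGLN.
* **Gray-level co-occurrence matrix (GLCM, 11)** — the symmetric, normalized
  joint distribution p(i, j) of gray-level pairs at offset (d, direction);
  the classic Haralick set AngScMom, Contrast, Correlat, SumOfSqs,
  InvDefMom, SumAverg, SumVarnc, SumEntrp, Entropy, DifVarnc, DifEntrp.

Conventions (all configurable): 8-bit gray levels; GLCM distance d = 1 with
features averaged over the four canonical directions; GLRLM along the
horizontal direction; entropies in bits (log base 2) with 0*log 0 = 0;
zero-variance planes yield Skewness = Kurtosis = Correlat = 0 instead of NaN.
Only pixels inside the ROI mask contribute; mask gaps break runs and pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .imaging import COMPONENTS, RoiMask, conventional_features, decompose_components

__all__ = [
    "HS_FEATURES",
    "GLRLM_FEATURES",
    "GLCM_FEATURES",
    "TEXTURE_FEATURES",
    "DIRECTIONS",
    "NormalizedHistogram",
    "RunLengthMatrix",
    "CooccurrenceMatrix",
    "compute_histogram",
    "hs_features",
    "build_glrlm",
    "glrlm_features",
    "build_glcm",
    "glcm_features",
    "texture_feature_vector",
    "TextureFeatureExtractor",
    "extract_all_features",
]

HS_FEATURES = (
    "Mean", "Variance", "Skewness", "Kurtosis",
    "Perc01", "Perc10", "Perc50", "Perc90", "Perc99",
    "Domn01", "Domn10", "Maxm01", "Maxm10",
)
GLRLM_FEATURES = ("GLN", "RLN", "LRE", "SRE", "Fraction", "MRLN", "MGLN")
GLCM_FEATURES = (
    "AngScMom", "Contrast", "Correlat", "SumOfSqs", "InvDefMom",
    "SumAverg", "SumVarnc", "SumEntrp", "Entropy", "DifVarnc", "DifEntrp",
)
TEXTURE_FEATURES = HS_FEATURES + GLRLM_FEATURES + GLCM_FEATURES

#: Canonical scan/offset directions in degrees and their (drow, dcol) steps.
DIRECTIONS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def _as_plane(plane: np.ndarray, bits: int) -> np.ndarray:
    plane = np.asarray(plane)
    if plane.ndim != 2:
        raise ValueError("component plane must be 2-D")
    k = 1 << bits
    if plane.min() < 0 or plane.max() >= k:
        raise ValueError(f"gray levels must lie in 0..{k - 1} for {bits}-bit data")
    return plane.astype(np.int64)


def _full_mask(plane: np.ndarray, mask: RoiMask | np.ndarray | None) -> np.ndarray:
    if mask is None:
        return np.ones(plane.shape, dtype=bool)
    m = mask.membership if isinstance(mask, RoiMask) else np.asarray(mask, dtype=bool)
    if m.shape != plane.shape:
        raise ValueError("mask shape does not match plane shape")
    return m


# --------------------------------------------------------------------------
# Histogram statistics


@dataclass(frozen=True)
class NormalizedHistogram:
    """Normalized gray-level histogram H(k) of the ROI's member pixels."""

    bins: np.ndarray  # H(k), k = 0..K-1, sums to 1
    pixel_count: int
    bits: int = 8

    def __post_init__(self) -> None:
        bins = np.asarray(self.bins, dtype=float)
        object.__setattr__(self, "bins", bins)
        if bins.size != 1 << self.bits:
            raise ValueError("histogram length must be 2^bits")
        if bins.min() < 0 or abs(bins.sum() - 1.0) > 1e-9:
            raise ValueError("histogram must be a probability vector")


def compute_histogram(values: np.ndarray, bits: int = 8) -> NormalizedHistogram:
    """Normalized histogram of ROI member pixels: H(k) = count(k) / NM."""
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise ValueError("cannot histogram an empty pixel set")
    k = 1 << bits
    if values.min() < 0 or values.max() >= k:
        raise ValueError(f"values must lie in 0..{k - 1}")
    counts = np.bincount(values.astype(np.int64), minlength=k)
    return NormalizedHistogram(counts / values.size, int(values.size), bits)


def hs_features(hist: NormalizedHistogram, window: int = 10) -> dict[str, float]:
    """The 13 first-order features of a normalized histogram.

    ``window`` is the bin width r of the moving sum behind Domn10/Maxm10;
    ties in argmax positions break toward the smallest gray level.
    """
    h = hist.bins
    k = np.arange(h.size, dtype=float)
    mean = float(k @ h)
    centered = k - mean
    variance = float((centered**2) @ h)
    if variance > 0:
        skewness = float((centered**3) @ h) / variance**1.5
        kurtosis = float((centered**4) @ h) / variance**2 - 3.0
    else:
        skewness = kurtosis = 0.0
    cdf = np.cumsum(h)
    percentiles = {
        f"Perc{q:02d}": float(np.searchsorted(cdf, q / 100.0, side="left"))
        for q in (1, 10, 50, 90, 99)
    }
    moving = np.convolve(h, np.ones(window), mode="valid")  # r-bin moving sum
    return {
        "Mean": mean,
        "Variance": variance,
        "Skewness": skewness,
        "Kurtosis": kurtosis,
        **percentiles,
        "Domn01": float(np.argmax(h)),
        "Domn10": float(np.argmax(moving)),
        "Maxm01": float(h.max()),
        "Maxm10": float(moving.max()),
    }


# --------------------------------------------------------------------------
# Gray-level run-length matrix


@dataclass(frozen=True)
class RunLengthMatrix:
    """Run counts p(i, j): gray level i (rows) x run length j = 1..L (cols)."""

    counts: np.ndarray  # shape (K, L); column j-1 holds runs of length j
    direction: int
    bits: int = 8

    @property
    def n_runs(self) -> int:
        return int(self.counts.sum())

    @property
    def n_pixels(self) -> int:
        j = np.arange(1, self.counts.shape[1] + 1)
        return int((self.counts * j).sum())


def _scan_lines(plane: np.ndarray, mask: np.ndarray, direction: int):
    """Yield (values, member_flags) along each scan line of a direction."""
    if direction == 0:
        for r in range(plane.shape[0]):
            yield plane[r], mask[r]
    elif direction == 90:
        for c in range(plane.shape[1]):
            yield plane[:, c], mask[:, c]
    elif direction == 135:
        h, w = plane.shape
        for k in range(-(h - 1), w):
            yield plane.diagonal(k), mask.diagonal(k)
    elif direction == 45:
        fp, fm = np.fliplr(plane), np.fliplr(mask)
        h, w = plane.shape
        for k in range(-(h - 1), w):
            yield fp.diagonal(k), fm.diagonal(k)
    else:
        raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}, got {direction}")


def build_glrlm(
    plane: np.ndarray,
    mask: RoiMask | np.ndarray | None = None,
    direction: int = 0,
    bits: int = 8,
) -> RunLengthMatrix:
    """Run-length matrix of the masked plane along one direction.

    A run is a maximal stretch of equal gray level inside a contiguous
    masked segment of a scan line; mask gaps terminate runs.
    """
    plane = _as_plane(plane, bits)
    m = _full_mask(plane, mask)
    max_len = max(plane.shape[0], plane.shape[1])
    counts = np.zeros((1 << bits, max_len), dtype=np.int64)
    for values, member in _scan_lines(plane, m, direction):
        idx = np.flatnonzero(member)
        if idx.size == 0:
            continue
        # split member indices into contiguous segments (mask gaps break runs)
        breaks = np.flatnonzero(np.diff(idx) > 1) + 1
        for seg in np.split(idx, breaks):
            vals = values[seg]
            # run-length encode the segment
            change = np.flatnonzero(np.diff(vals) != 0) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [vals.size]))
            lengths = ends - starts
            np.add.at(counts, (vals[starts], lengths - 1), 1)
    return RunLengthMatrix(counts, direction, bits)


def glrlm_features(m: RunLengthMatrix) -> dict[str, float]:
    """The 7 run-length features of a run-length matrix."""
    p = m.counts.astype(float)
    n_runs = p.sum()
    if n_runs < 1:
        raise ValueError("run-length matrix is empty")
    j = np.arange(1, p.shape[1] + 1, dtype=float)
    by_level = p.sum(axis=1)  # sum over run lengths, per gray level
    by_length = p.sum(axis=0)  # sum over gray levels, per run length
    return {
        "GLN": float((by_level**2).sum() / n_runs),
        "RLN": float((by_length**2).sum() / n_runs),
        "LRE": float((p * j**2).sum() / n_runs),
        "SRE": float((p / j**2).sum() / n_runs),
        "Fraction": float(n_runs / (p * j).sum()),
        "MRLN": float((by_length**2).sum() / n_runs**2),
        "MGLN": float((by_level**2).sum() / n_runs**2),
    }


# --------------------------------------------------------------------------
# Gray-level co-occurrence matrix


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Symmetric gray-level co-occurrence matrix at offset (distance, direction)."""

    entries: np.ndarray  # (K, K)
    distance: int
    direction: int
    bits: int = 8
    normalized: bool = True

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", e)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError("co-occurrence matrix must be square")
        if self.normalized and abs(e.sum() - 1.0) > 1e-9:
            raise ValueError("normalized matrix must sum to 1")


def build_glcm(
    plane: np.ndarray,
    mask: RoiMask | np.ndarray | None = None,
    distance: int = 1,
    direction: int = 0,
    bits: int = 8,
    normalize: bool = True,
) -> CooccurrenceMatrix:
    """Symmetric co-occurrence matrix of the masked plane.

    Every pixel pair offset by (distance, direction) with both ends inside
    the mask increments both p(a, b) and p(b, a).
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}, got {direction}")
    plane = _as_plane(plane, bits)
    m = _full_mask(plane, mask)
    dr, dc = DIRECTIONS[direction]
    dr, dc = dr * distance, dc * distance
    h, w = plane.shape
    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    a = plane[r0s:r0e, c0s:c0e]
    b = plane[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    valid = m[r0s:r0e, c0s:c0e] & m[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    if not valid.any():
        raise ValueError("no valid pixel pair inside the ROI at this offset")
    k = 1 << bits
    counts = np.zeros((k, k), dtype=np.int64)
    av, bv = a[valid], b[valid]
    np.add.at(counts, (av, bv), 1)
    np.add.at(counts, (bv, av), 1)
    entries = counts / counts.sum() if normalize else counts.astype(float)
    return CooccurrenceMatrix(entries, distance, direction, bits, normalize)


@lru_cache(maxsize=8)
def _glcm_index_arrays(k: int):
    i = np.arange(k, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    return i, (ii - jj) ** 2, ii * jj, (ii + jj).astype(np.int64).ravel(), np.abs(
        ii - jj
    ).astype(np.int64).ravel()


def _entropy(p: np.ndarray, log_base: float) -> float:
    nz = p[p > 0]
    return float(-(nz * (np.log(nz) / math.log(log_base))).sum())


def glcm_features(m: CooccurrenceMatrix, log_base: float = 2.0) -> dict[str, float]:
    """The 11 Haralick features of a normalized co-occurrence matrix.

    Entropies use ``log_base`` (bits by default) with the 0*log 0 = 0
    convention; Correlat is 0 for a zero-variance marginal.
    """
    if not m.normalized:
        raise ValueError("features require a normalized co-occurrence matrix")
    p = m.entries
    k = p.shape[0]
    levels, sqdiff, prod, sum_idx, diff_idx = _glcm_index_arrays(k)
    px = p.sum(axis=1)  # == p.sum(axis=0) for a symmetric matrix
    py = p.sum(axis=0)
    mu_x = float(levels @ px)
    mu_y = float(levels @ py)
    var_x = float(((levels - mu_x) ** 2) @ px)
    var_y = float(((levels - mu_y) ** 2) @ py)
    sd_x, sd_y = math.sqrt(var_x), math.sqrt(var_y)
    p_sum = np.bincount(sum_idx, weights=p.ravel(), minlength=2 * k - 1)
    p_diff = np.bincount(diff_idx, weights=p.ravel(), minlength=k)
    ks = np.arange(p_sum.size, dtype=float)
    kd = np.arange(p_diff.size, dtype=float)
    mu_sum = float(ks @ p_sum)
    mu_diff = float(kd @ p_diff)
    if sd_x > 0 and sd_y > 0:
        correlat = (float((prod * p).sum()) - mu_x * mu_y) / (sd_x * sd_y)
    else:
        correlat = 0.0
    return {
        "AngScMom": float((p**2).sum()),
        "Contrast": float((sqdiff * p).sum()),
        "Correlat": correlat,
        "SumOfSqs": var_x,
        "InvDefMom": float((p / (1.0 + sqdiff)).sum()),
        "SumAverg": mu_sum,
        "SumVarnc": float(((ks - mu_sum) ** 2) @ p_sum),
        "SumEntrp": _entropy(p_sum, log_base),
        "Entropy": _entropy(p.ravel(), log_base),
        "DifVarnc": float(((kd - mu_diff) ** 2) @ p_diff),
        "DifEntrp": _entropy(p_diff, log_base),
    }


# --------------------------------------------------------------------------
# Full per-(ROI, component) extraction


def texture_feature_vector(
    plane: np.ndarray,
    mask: RoiMask | np.ndarray | None = None,
    *,
    bits: int = 8,
    distance: int = 1,
    glcm_directions: Sequence[int] = (0, 45, 90, 135),
    glrlm_direction: int = 0,
    average_directions: bool = True,
    log_base: float = 2.0,
    window: int = 10,
) -> dict[str, float]:
    """All 31 texture features of one masked component plane.

    GLCM features are computed per direction and averaged (the default) or
    returned per direction with ``<name>@<angle>`` keys.
    """
    plane = _as_plane(plane, bits)
    m = _full_mask(plane, mask)
    out: dict[str, float] = {}
    out.update(hs_features(compute_histogram(plane[m], bits), window))
    out.update(glrlm_features(build_glrlm(plane, m, glrlm_direction, bits)))
    per_dir = [
        glcm_features(build_glcm(plane, m, distance, d, bits), log_base)
        for d in glcm_directions
    ]
    if average_directions:
        for name in GLCM_FEATURES:
            out[name] = float(np.mean([d[name] for d in per_dir]))
    else:
        for angle, feats in zip(glcm_directions, per_dir):
            for name in GLCM_FEATURES:
                out[f"{name}@{angle}"] = feats[name]
    return out


class TextureFeatureExtractor(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer mapping masked planes to 31 features.

    ``transform`` accepts a sequence of samples, each either a 2-D plane or a
    ``(plane, mask)`` pair, and returns an ``(n_samples, 31)`` array in the
    order of :data:`TEXTURE_FEATURES`.

    Parameters
    ----------
    bits : gray-level depth n; K = 2^n levels.
    distance : GLCM pixel offset d.
    glcm_directions : angles over which GLCM features are averaged.
    glrlm_direction : scan angle of the run-length matrix.
    log_base : logarithm base of the entropy features (2 = bits).
    window : moving-sum width r of Domn10/Maxm10.
    """

    def __init__(
        self,
        bits: int = 8,
        distance: int = 1,
        glcm_directions: tuple[int, ...] = (0, 45, 90, 135),
        glrlm_direction: int = 0,
        log_base: float = 2.0,
        window: int = 10,
    ):
        self.bits = bits
        self.distance = distance
        self.glcm_directions = glcm_directions
        self.glrlm_direction = glrlm_direction
        self.log_base = log_base
        self.window = window

    def fit(self, X, y=None):
        self.n_features_out_ = len(TEXTURE_FEATURES)
        return self

    def transform(self, X) -> np.ndarray:
        rows = []
        for sample in X:
            plane, mask = sample if isinstance(sample, tuple) else (sample, None)
            feats = texture_feature_vector(
                plane,
                mask,
                bits=self.bits,
                distance=self.distance,
                glcm_directions=self.glcm_directions,
                glrlm_direction=self.glrlm_direction,
                log_base=self.log_base,
                window=self.window,
            )
            rows.append([feats[name] for name in TEXTURE_FEATURES])
        return np.asarray(rows, dtype=float)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(TEXTURE_FEATURES, dtype=object)


def extract_all_features(
    images: Mapping[tuple[str, str, str], np.ndarray],
    masks: Sequence[RoiMask],
    fields: Mapping[tuple[str, str, str], np.ndarray] | None = None,
    extractor: TextureFeatureExtractor | None = None,
    errors: list | None = None,
) -> pd.DataFrame:
    """Wide feature table over a study's images.

    Parameters
    ----------
    images : mapping (rider_id, horse_id, timepoint) -> RGB image.
    masks : the four ROI masks shared by all images.
    fields : optional matching temperature fields; when present the three
        conventional features are added per ROI.
    errors : optional list collecting (key, exception) for skipped images;
        a failing image never aborts the run.

    Returns a DataFrame with one row per image, indexed by the image key,
    and one column per ``ROI{label}_{component}_{feature}`` combination
    (4 ROIs x 3 components x 31 features = 372 texture columns), plus
    ``ROI{label}_T{aver,max,min}`` columns when fields are given.
    """
    extractor = extractor or TextureFeatureExtractor()
    rows = {}
    for key, image in images.items():
        try:
            planes = dict(zip(COMPONENTS, decompose_components(image)))
            row: dict[str, float] = {}
            for roi in masks:
                for comp, plane in planes.items():
                    vec = texture_feature_vector(
                        plane,
                        roi,
                        bits=extractor.bits,
                        distance=extractor.distance,
                        glcm_directions=extractor.glcm_directions,
                        glrlm_direction=extractor.glrlm_direction,
                        log_base=extractor.log_base,
                        window=extractor.window,
                    )
                    for name, value in vec.items():
                        row[f"ROI{roi.label}_{comp}_{name}"] = value
                if fields is not None and key in fields:
                    conv = conventional_features(fields[key], roi)
                    row[f"ROI{roi.label}_Taver"] = conv.taver
                    row[f"ROI{roi.label}_Tmax"] = conv.tmax
                    row[f"ROI{roi.label}_Tmin"] = conv.tmin
            rows[key] = row
        except Exception as exc:  # record and continue with the other images
            if errors is not None:
                errors.append((key, exc))
    table = pd.DataFrame.from_dict(rows, orient="index")
    if rows:
        table.index = pd.MultiIndex.from_tuples(
            table.index, names=["rider_id", "horse_id", "timepoint"]
        )
    return table
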