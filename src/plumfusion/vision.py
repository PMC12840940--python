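"""16-dimensional colour + texture signature of a fruit image.

The vector concatenates, in frozen order: mean and population SD of the
three RGB channels, mean and population SD of the CIELAB L*, a*, b*
channels (sRGB, D65/2 degree observer), and four gray-level co-occurrence
matrix (GLCM) texture properties — contrast, dissimilarity, energy
(angular second moment, sum of squared P) and homogeneity — computed on
BT.601 luminance quantized to 32 gray levels, at offsets of one pixel in
the 0/45/90/135 degree orientations, each averaged over the four angles.
Downstream models depend on this order; it is versioned by
:data:`FEATURE_NAMES`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.color import rgb2lab
from skimage.feature import graycomatrix, graycoprops
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FEATURE_NAMES",
    "rgb_to_lab",
    "color_statistics",
    "glcm_features",
    "extract_visual_features",
    "VisualFeatureExtractor",
    "load_image",
    "extract_features_table",
]

FEATURE_NAMES = (
    "mean_R", "sd_R", "mean_G", "sd_G", "mean_B", "sd_B",
    "mean_L", "sd_L", "mean_a", "sd_a", "mean_b", "sd_b",
    "glcm_contrast", "glcm_dissimilarity", "glcm_energy", "glcm_homogeneity",
)

GLCM_ANGLES_DEG = (0.0, 45.0, 90.0, 135.0)
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])  # ITU-R BT.601


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if image.shape[0] < 2 or image.shape[1] < 2:
        raise ValueError("image must be at least 2x2 pixels")
    return image


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """Per-pixel sRGB -> CIELAB (D65/2deg), L* in [0, 100]."""
    image = _validate_image(image)
    return rgb2lab(np.asarray(image, dtype=np.uint8))


def color_statistics(image: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Mean and population SD per RGB and Lab channel (12 values).

    Pixels are the full population of the imaged region, hence ddof=0.
    """
    image = _validate_image(image)
    lab = rgb_to_lab(image)
    if mask is not None:
        mask = np.asarray(mask, bool)
        if mask.shape != image.shape[:2]:
            raise ValueError("mask shape must match the image")
        if not mask.any():
            raise ValueError("mask selects no pixels")
    out = []
    for stack in (image.astype(float), lab):
        for ch in range(3):
            plane = stack[:, :, ch]
            vals = plane[mask] if mask is not None else plane.ravel()
            out.extend([vals.mean(), vals.std(ddof=0)])
    return np.array(out)


def _quantize_luminance(image: np.ndarray, levels: int) -> np.ndarray:
    lum = image.astype(float) @ _LUMA_WEIGHTS
    return np.clip((lum * levels / 256.0).astype(int), 0, levels - 1)


def glcm_features(
    image: np.ndarray,
    levels: int = 32,
    distance: int = 1,
    angles_deg: tuple[float, ...] = GLCM_ANGLES_DEG,
) -> np.ndarray:
    """Angle-averaged contrast, dissimilarity, energy (ASM), homogeneity.

    Co-occurrence matrices are made symmetric and normalized before the
    property sums (the standard Haralick convention).  Energy here is the
    angular second moment sum(P^2) itself, not its square root.
    """
    image = _validate_image(image)
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if image.shape[0] < distance + 1 and image.shape[1] < distance + 1:
        raise ValueError("image smaller than the co-occurrence offset")
    quant = _quantize_luminance(image, levels).astype(np.uint8)
    glcm = graycomatrix(
        quant,
        distances=[distance],
        angles=[np.deg2rad(a) for a in angles_deg],
        levels=levels,
        symmetric=True,
        normed=True,
    )
    contrast = graycoprops(glcm, "contrast")[0]
    dissim = graycoprops(glcm, "dissimilarity")[0]
    asm = graycoprops(glcm, "ASM")[0]
    homog = graycoprops(glcm, "homogeneity")[0]
    return np.array([contrast.mean(), dissim.mean(), asm.mean(), homog.mean()])


def extract_visual_features(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    levels: int = 32,
    distance: int = 1,
) -> np.ndarray:
    """The frozen 16-vector: 12 colour statistics followed by 4 GLCM textures.

    An optional fruit mask restricts the colour statistics; the GLCM is
    computed on the bounding box of the mask (texture needs a dense grid).
    Masking is off by default.
    """
    image = _validate_image(image)
    if mask is not None:
        mask = np.asarray(mask, bool)
        rows, cols = np.nonzero(mask)
        box = image[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
    else:
        box = image
    return np.concatenate(
        [color_statistics(image, mask), glcm_features(box, levels, distance)]
    )


def load_image(path) -> np.ndarray:
    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"))


class VisualFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer mapping a sequence of RGB images (or paths) to
    the (n, 16) visual feature matrix in :data:`FEATURE_NAMES` order."""

    def __init__(self, levels: int = 32, distance: int = 1):
        self.levels = levels
        self.distance = distance

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        rows = []
        for item in X:
            img = load_image(item) if isinstance(item, (str, Path)) else item
            rows.append(extract_visual_features(img, levels=self.levels, distance=self.distance))
        return np.vstack(rows) if rows else np.empty((0, len(FEATURE_NAMES)))

    def get_feature_names_out(self, input_features=None):
        return np.array(FEATURE_NAMES)


def extract_features_table(image_dir, sample_ids: list[str], **kwargs) -> pd.DataFrame:
    """Features CSV contract: sample_id + the 16 named columns in frozen order."""
    ext = VisualFeatureExtractor(**kwargs)
    paths = [Path(image_dir) / f"{sid}.png" for sid in sample_ids]
    mat = ext.transform(paths)
    df = pd.DataFrame(mat, columns=list(FEATURE_NAMES))
    df.insert(0, "sample_id", sample_ids)
    return df
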