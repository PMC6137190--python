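"""Texture and shape descriptors for candidate-fish regions.

The recogniser never sees pixels directly: each RoI is summarised by a
fixed-length vector of 23 named features — 9 texture statistics computed on
the grayscale patch (first-order intensity statistics plus four gray-level
co-occurrence properties) and 14 shape statistics computed on the convex
hull and the component mask (hull geometry, solidity/extent, best-fit
ellipse eccentricity, and the seven log-scaled Hu moment invariants).

The schema is a pluggable registry: a different feature list can be swapped
in without touching the learner, which performs its own feature selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import regionprops

from .segmentation import RoI

GLCM_LEVELS = 32
GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)

TEXTURE_NAMES = [
    "intensity_mean",
    "intensity_std",
    "intensity_skewness",
    "intensity_kurtosis",
    "intensity_entropy",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_energy",
    "glcm_homogeneity",
]

SHAPE_NAMES = [
    "hull_area",
    "hull_perimeter",
    "circularity",
    "bbox_aspect_ratio",
    "solidity",
    "extent",
    "eccentricity",
    "hu_1",
    "hu_2",
    "hu_3",
    "hu_4",
    "hu_5",
    "hu_6",
    "hu_7",
]

FEATURE_NAMES = TEXTURE_NAMES + SHAPE_NAMES


def texture_features(patch: np.ndarray) -> np.ndarray:
    """First-order and co-occurrence texture statistics of a gray patch.

    Co-occurrence matrices are computed at distance 1 over four offsets
    (0, 45, 90, 135 degrees) on the patch quantised to 32 gray levels and
    averaged.  Degenerate (constant) patches yield entropy 0, energy 1 and
    correlation defined as 0.
    """
    if patch.size == 0:
        raise ValueError("empty patch")
    x = patch.astype(np.float64).ravel()
    mean = float(x.mean())
    std = float(x.std())
    if std == 0.0:
        skew = 0.0
        kurt = 0.0
    else:
        skew = float(sps.skew(x))
        kurt = float(sps.kurtosis(x))
    counts = np.bincount(patch.astype(np.uint8).ravel(), minlength=256)
    p = counts[counts > 0] / x.size
    entropy = float(-(p * np.log2(p)).sum())

    if patch.shape[0] < 2 or patch.shape[1] < 2:
        contrast, correlation, energy, homogeneity = 0.0, 0.0, 1.0, 1.0
    else:
        q = (patch.astype(np.uint16) * GLCM_LEVELS // 256).astype(np.uint8)
        glcm = graycomatrix(
            q, distances=[1], angles=GLCM_ANGLES, levels=GLCM_LEVELS,
            symmetric=True, normed=True,
        )
        contrast = float(graycoprops(glcm, "contrast").mean())
        energy = float(graycoprops(glcm, "energy").mean())
        homogeneity = float(graycoprops(glcm, "homogeneity").mean())
        if q.min() == q.max():  # degenerate texture: correlation undefined -> 0
            correlation = 0.0
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = graycoprops(glcm, "correlation")
            corr = np.where(np.isfinite(corr), corr, 0.0)
            correlation = float(corr.mean())
    return np.array(
        [mean, std, skew, kurt, entropy, contrast, correlation, energy, homogeneity]
    )


def _polygon_area_perimeter(verts: np.ndarray) -> tuple[float, float]:
    """Shoelace area and edge-length perimeter of a closed polygon."""
    v = np.asarray(verts, dtype=np.float64)
    r, c = v[:, 0], v[:, 1]
    area = 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))
    perim = float(np.sqrt(((v - np.roll(v, -1, axis=0)) ** 2).sum(axis=1)).sum())
    return float(area), perim


def shape_features(roi: RoI) -> np.ndarray:
    """Hull geometry, region shape ratios and Hu moment invariants.

    Circularity is 4*pi*A/P^2 on the hull polygon; solidity and extent come
    from the rasterised component mask; Hu moments are log-scaled as
    -sign(h)*log10(|h|) so their dynamic range suits the learner.
    """
    if roi.hull.shape[0] < 3:
        raise ValueError("degenerate hull: fewer than 3 vertices")
    hull_area, hull_perim = _polygon_area_perimeter(roi.hull)
    if hull_area <= 0:
        raise ValueError("degenerate (collinear) hull")
    circularity = 4.0 * np.pi * hull_area / hull_perim**2
    rmin, cmin, rmax, cmax = roi.bbox
    height, width = rmax - rmin, cmax - cmin
    aspect = height / width if width > 0 else 0.0

    props = regionprops(roi.mask.astype(np.uint8))[0]
    solidity = float(props.solidity)
    extent = float(props.extent)
    eccentricity = float(props.eccentricity)
    hu = props.moments_hu
    log_hu = [
        0.0 if abs(h) < 1e-30 else float(-np.sign(h) * np.log10(abs(h))) for h in hu
    ]
    return np.array(
        [hull_area, hull_perim, circularity, aspect, solidity, extent, eccentricity]
        + log_hu
    )


def extract_features(roi: RoI) -> np.ndarray:
    """Full feature vector (texture block then shape block)."""
    vec = np.concatenate([texture_features(roi.patch), shape_features(roi)])
    if not np.all(np.isfinite(vec)):
        bad = [FEATURE_NAMES[i] for i in np.flatnonzero(~np.isfinite(vec))]
        raise ValueError(f"non-finite features: {bad}")
    return vec


def feature_matrix(rois: Sequence[RoI]) -> np.ndarray:
    """Stack feature vectors for a list of RoIs into an (n, n_features) matrix."""
    if not rois:
        return np.empty((0, len(FEATURE_NAMES)))
    return np.vstack([extract_features(r) for r in rois])


@dataclass
class MinMaxNormalizer:
    """Min-max scaling to [0, 1] using ranges learned on the training pool.

    Test-time values outside the training range are clipped; a feature that
    was constant in training maps to 0.
    """

    minima: np.ndarray = None
    maxima: np.ndarray = None

    def fit(self, X: np.ndarray) -> "MinMaxNormalizer":
        self.minima = X.min(axis=0)
        self.maxima = X.max(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = self.maxima - self.minima
        span = np.where(span == 0, 1.0, span)
        return np.clip((X - self.minima) / span, 0.0, 1.0)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


# --- pluggable schema registry -------------------------------------------

_SCHEMAS: dict[str, tuple[list[str], Callable[[RoI], np.ndarray]]] = {
    "default": (FEATURE_NAMES, extract_features),
}


def register_schema(
    name: str, feature_names: Sequence[str], extractor: Callable[[RoI], np.ndarray]
) -> None:
    """Register an alternative feature schema under ``name``."""
    _SCHEMAS[name] = (list(feature_names), extractor)


def get_schema(name: str = "default") -> tuple[list[str], Callable[[RoI], np.ndarray]]:
    if name not in _SCHEMAS:
        raise KeyError(f"unknown feature schema {name!r}")
    return _SCHEMAS[name]
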