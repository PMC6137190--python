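"""Candidate-fish region extraction by consecutive-frame differencing.

The core assumption is temporal: fish move between two consecutive frames
while background, illumination field and lens bio-fouling are (almost)
static, so the absolute difference of consecutive grayscale frames
suppresses everything but the moving subjects.  The difference image is
blurred, thresholded against a local Gaussian-weighted mean, cleaned with
morphological opening/closing, and each remaining connected component is
characterised by the convex hull of its pixels.  The hull's bounding box,
mapped back onto the *original* frame, is the region of interest (RoI)
handed to feature extraction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.filters import threshold_local
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import closing, opening

from .io import FrameRecord, FrameSequence


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the differencing pipeline (pixel units).

    k_blur/sigma_blur: Gaussian pre-blur of the difference image.
    block_size/offset: local adaptive threshold — a pixel is foreground iff
    its blurred difference exceeds the Gaussian-weighted local mean over a
    ``block_size`` neighbourhood by more than ``offset`` gray levels.
    k_morph: diameter of the elliptical structuring element used for the
    opening-then-closing cleanup.  min_blob_area: smallest component kept.
    """

    k_blur: int = 5
    sigma_blur: float = 1.5
    block_size: int = 51
    offset: float = 7.0
    k_morph: int = 5
    min_blob_area: int = 100

    def __post_init__(self) -> None:
        if self.block_size % 2 == 0 or self.block_size < 3:
            raise ValueError("block_size must be odd and >= 3")
        if self.k_blur <= 0 or self.k_morph <= 0:
            raise ValueError("kernel sizes must be positive")
        if self.sigma_blur <= 0:
            raise ValueError("sigma_blur must be positive")
        if self.min_blob_area < 1:
            raise ValueError("min_blob_area must be >= 1")


@dataclass
class RoI:
    """A convex-hull-bounded candidate fish region on one frame.

    ``hull`` holds the (row, col) hull vertices in counter-clockwise order;
    ``bbox`` is the minimal half-open axis-aligned box containing the hull;
    ``patch`` is the grayscale crop of the *original* frame at ``bbox`` and
    ``mask`` the component's binary support within the same box.
    """

    frame_id: str
    hull: np.ndarray
    bbox: tuple[int, int, int, int]
    area_px: int
    patch: np.ndarray
    mask: np.ndarray = field(repr=False, default=None)


def elliptical_footprint(k: int) -> np.ndarray:
    """k x k elliptical structuring element (inscribed ellipse, corners cut)."""
    r = k // 2
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy / (r + 0.5)) ** 2 + (xx / (r + 0.5)) ** 2 <= 1.0


def difference_image(current: FrameRecord, previous: FrameRecord) -> np.ndarray:
    """Per-pixel absolute grayscale difference of two frames."""
    a = current.pixels.astype(np.float64)
    b = previous.pixels.astype(np.float64)
    if a.shape != b.shape:
        raise ValueError(f"frame shape mismatch: {a.shape} vs {b.shape}")
    return np.abs(a - b)


def threshold_and_clean(diff: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Blur, locally threshold and morphologically clean a difference image.

    Returns a boolean mask of the same shape.  The Gaussian pre-blur kernel
    radius is tied to ``k_blur`` via the truncation of the Gaussian; the
    adaptive threshold is the local Gaussian-weighted mean plus ``offset``.
    """
    if np.any(diff < 0):
        raise ValueError("difference image must be non-negative")
    radius = params.k_blur // 2
    blurred = ndimage.gaussian_filter(
        diff.astype(np.float64),
        sigma=params.sigma_blur,
        truncate=max(radius / params.sigma_blur, 1e-6),
    )
    # skimage subtracts its offset from the local mean, so pass the negative
    # to demand blurred > local_mean + offset.
    thresh = threshold_local(
        blurred, block_size=params.block_size, method="gaussian", offset=-params.offset
    )
    mask = blurred > thresh
    footprint = elliptical_footprint(params.k_morph)
    mask = opening(mask, footprint)
    mask = closing(mask, footprint)
    return mask


def extract_rois(
    mask: np.ndarray, original: FrameRecord, min_blob_area: int = 100
) -> list[RoI]:
    """One RoI per connected component of ``mask`` with enough area.

    The hull is the convex hull of the component's pixel centres; the patch
    is cropped from the original frame at the hull's bounding box.
    Components touching the image border are kept (partial fish at the frame
    edge are legitimate detections); components whose pixels are collinear
    cannot form a convex polygon and are skipped.
    """
    pixels = original.pixels
    if mask.shape != pixels.shape:
        raise ValueError("mask and frame shapes differ")
    labelled = cc_label(mask, connectivity=2)
    rois: list[RoI] = []
    for region in regionprops(labelled):
        if region.area < min_blob_area:
            continue
        coords = region.coords  # (n, 2) row, col
        try:
            hull = ConvexHull(coords.astype(np.float64))
        except QhullError:
            continue
        verts = coords[hull.vertices]
        rmin, cmin, rmax, cmax = region.bbox  # already half-open
        patch = pixels[rmin:rmax, cmin:cmax].copy()
        local_mask = labelled[rmin:rmax, cmin:cmax] == region.label
        rois.append(
            RoI(
                frame_id=original.frame_id,
                hull=verts.astype(np.int64),
                bbox=(rmin, cmin, rmax, cmax),
                area_px=int(region.area),
                patch=patch,
                mask=local_mask,
            )
        )
    return rois


def segment_frame(
    seq: FrameSequence, index: int, params: SegmentationParams | None = None
) -> list[RoI]:
    """Segment frame ``index`` against its predecessor.

    Composition of :func:`difference_image`, :func:`threshold_and_clean`
    and :func:`extract_rois`; the RoIs are attributed to the current frame.
    The first frame of a sequence has no predecessor and cannot be
    segmented.
    """
    if index < 1:
        raise ValueError("segment_frame needs a predecessor frame (index >= 1)")
    params = params or SegmentationParams()
    diff = difference_image(seq[index], seq[index - 1])
    mask = threshold_and_clean(diff, params)
    return extract_rois(mask, seq[index], params.min_blob_area)


def write_rois_csv(rois: Sequence[RoI], path: Path | str) -> None:
    """Dump RoIs to CSV: one row per RoI, hull as semicolon-separated pairs."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["frame_id", "row_min", "col_min", "row_max", "col_max", "area_px", "hull"]
        )
        for roi in rois:
            hull_str = ";".join(f"{r},{c}" for r, c in roi.hull)
            writer.writerow([roi.frame_id, *roi.bbox, roi.area_px, hull_str])
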