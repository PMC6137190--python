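"""Ground-truthed synthetic underwater image sequences and feature datasets.

The generator emulates the acquisition conditions of a fixed seafloor
camera imaging every 30 minutes, day and night: a static background with
low-amplitude sensor noise, fish-shaped moving ellipses whose per-frame
abundance follows separate day and night Poisson laws, occasional schools
of overlapping bodies, slowly growing dark bio-fouling patches that occlude
the scene near the lens, turbidity as whole-frame blur plus contrast
compression, a radial vignette under night-time artificial light, and rare
corrupted or wrong-view frames.  Every frame carries exact ground truth
(fish placements, fouling mask, flags), so the whole pipeline can be tested
without any real imagery.

Fish are intensity-contrasted ellipses with mild texture noise rather than
realistic renders: the pipeline's operators (differencing, hulls,
texture/shape statistics, the evolved classifier) are exercised
identically, and the ground truth stays exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from .io import AnnotationRecord, FrameRecord, FrameSequence, MANIFEST_COLUMNS

#: turbidity score -> (Gaussian blur sigma, contrast scale)
TURBIDITY_BLUR_SIGMA = 1.0
TURBIDITY_CONTRAST_LOSS = 0.15


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions of one synthetic sequence (all rates per frame)."""

    frame_shape: tuple[int, int] = (240, 320)
    n_frames: int = 300
    day_fish_mean: float = 3.0
    night_fish_mean: float = 1.0
    fish_semi_major: tuple[float, float] = (9.0, 16.0)
    fish_semi_minor: tuple[float, float] = (5.0, 8.0)
    fish_contrast: tuple[float, float] = (40.0, 90.0)
    turbidity: int = 0
    fouling: int = 0
    fouling_growth_every: int = 50
    fouling_growth_px: float = 1.0
    school_probability: float = 0.05
    school_size_mean: float = 5.0
    error_frame_probability: float = 0.02
    ptz_wrong_probability: float = 0.01
    background_level: float = 120.0
    noise_sigma: float = 2.0
    vignette_strength: float = 0.6
    start_time: datetime = datetime(2013, 1, 1, 0, 0)
    interval: timedelta = timedelta(minutes=30)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.turbidity not in (0, 1, 2, 3) or self.fouling not in (0, 1, 2, 3):
            raise ValueError("turbidity and fouling scores must be in 0..3")
        if self.day_fish_mean < 0 or self.night_fish_mean < 0:
            raise ValueError("fish means must be >= 0")
        h, w = self.frame_shape
        if 2 * self.fish_semi_major[1] >= min(h, w):
            raise ValueError("fish larger than frame")


@dataclass
class GroundTruth:
    """Exact per-frame truth of a generated sequence."""

    frame_shape: tuple[int, int]
    counts: list[int]
    fish: list[list[tuple]]  # per frame: (cy, cx, a, b, angle)
    error_frames: list[bool]
    ptz_ok: list[bool]
    fouling_patches: list[tuple]  # (cy, cx, r0)
    fouling_growth_every: int
    fouling_growth_px: float

    def fish_masks(self, index: int) -> list[np.ndarray]:
        masks = []
        for cy, cx, a, b, angle in self.fish[index]:
            m = np.zeros(self.frame_shape, dtype=bool)
            rr, cc = draw_ellipse(cy, cx, a, b, shape=self.frame_shape, rotation=angle)
            m[rr, cc] = True
            masks.append(m)
        return masks

    def fouling_mask(self, index: int) -> np.ndarray:
        m = np.zeros(self.frame_shape, dtype=bool)
        if not self.fouling_patches:
            return m
        growth = (index // self.fouling_growth_every) * self.fouling_growth_px
        for cy, cx, r0 in self.fouling_patches:
            rr, cc = draw_ellipse(cy, cx, r0 + growth, r0 + growth, shape=self.frame_shape)
            m[rr, cc] = True
        return m


def _irradiance(t: datetime) -> float:
    """Diurnal solar irradiance proxy (W m^-2): sinusoid, zero at night."""
    hour = t.hour + t.minute / 60.0
    return max(0.0, 800.0 * np.sin(np.pi * (hour - 6.0) / 12.0))


def _smooth_field(shape, rng, sigma=15.0, amplitude=8.0) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.normal(0.0, 1.0, shape), sigma)
    s = f.std()
    return f / s * amplitude if s > 0 else f


def _vignette(shape, strength: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - h / 2) / (h / 2)) ** 2 + ((xx - w / 2) / (w / 2)) ** 2
    return 1.0 - strength * np.clip(r2 / 2.0, 0.0, 1.0)


def _place_fish(
    rng: np.random.Generator,
    config: SceneConfig,
    n: int,
    prev_centers: list[tuple],
    school: bool,
) -> list[tuple]:
    """Fish placements keeping each new fish >= one body length away from
    every fish of the previous frame, so differencing sees clean motion."""
    h, w = config.frame_shape
    a_lo, a_hi = config.fish_semi_major
    b_lo, b_hi = config.fish_semi_minor
    placements = []
    school_center = (rng.uniform(a_hi, h - a_hi), rng.uniform(a_hi, w - a_hi))
    for _ in range(n):
        a = rng.uniform(a_lo, a_hi)
        b = rng.uniform(b_lo, b_hi)
        angle = rng.uniform(0, np.pi)
        for _attempt in range(20):
            if school:
                cy = np.clip(school_center[0] + rng.normal(0, 2.5 * a), a, h - a)
                cx = np.clip(school_center[1] + rng.normal(0, 2.5 * a), a, w - a)
            else:
                cy = rng.uniform(a, h - a)
                cx = rng.uniform(a, w - a)
            far = all(
                (cy - pcy) ** 2 + (cx - pcx) ** 2 >= (2.0 * max(a, pa)) ** 2
                for pcy, pcx, pa in prev_centers
            )
            if far:
                break
        placements.append((float(cy), float(cx), float(a), float(b), float(angle)))
    return placements


def generate_sequence(
    config: SceneConfig,
) -> tuple[FrameSequence, list[AnnotationRecord], GroundTruth]:
    """Render a fully seeded synthetic sequence with exact ground truth.

    The background (and the fouling texture) is static up to sensor noise,
    fouling patches change only at growth steps, and fish are re-placed
    every frame at least one body length away from their previous-frame
    positions — so consecutive-frame differencing isolates the fish.
    """
    rng = np.random.default_rng(config.rng_seed)
    h, w = config.frame_shape
    background = config.background_level + _smooth_field((h, w), rng)
    wrong_view = config.background_level + _smooth_field((h, w), rng, sigma=8.0, amplitude=20.0)
    fouling_tex = 18.0 + _smooth_field((h, w), rng, sigma=5.0, amplitude=4.0)
    vignette = _vignette((h, w), config.vignette_strength)

    # fouling patches: `2*score` dark occluders whose radius scales with score
    patches = []
    for _ in range(2 * config.fouling):
        cy = rng.uniform(0.1 * h, 0.9 * h)
        cx = rng.uniform(0.1 * w, 0.9 * w)
        r0 = rng.uniform(10.0 + 5.0 * config.fouling, 16.0 + 7.0 * config.fouling)
        patches.append((float(cy), float(cx), float(r0)))

    truth = GroundTruth(
        frame_shape=(h, w),
        counts=[],
        fish=[],
        error_frames=[],
        ptz_ok=[],
        fouling_patches=patches,
        fouling_growth_every=config.fouling_growth_every,
        fouling_growth_px=config.fouling_growth_px,
    )
    frames: list[FrameRecord] = []
    annotations: list[AnnotationRecord] = []
    prev_centers: list[tuple] = []
    blur_sigma = TURBIDITY_BLUR_SIGMA * config.turbidity
    contrast = 1.0 - TURBIDITY_CONTRAST_LOSS * config.turbidity

    for i in range(config.n_frames):
        t = config.start_time + i * config.interval
        irr = _irradiance(t)
        is_day = irr > 5.0
        frame_id = f"frame_{i:05d}"

        u = rng.random()
        error = u < config.error_frame_probability
        ptz_wrong = (not error) and u < config.error_frame_probability + config.ptz_wrong_probability

        if error:
            img = rng.uniform(0, 255, (h, w))
            placements = []
            prev_centers = []
        elif ptz_wrong:
            img = wrong_view + rng.normal(0, config.noise_sigma, (h, w))
            placements = []
            prev_centers = []
        else:
            img = background + rng.normal(0, config.noise_sigma, (h, w))
            mean = config.day_fish_mean if is_day else config.night_fish_mean
            n_fish = int(rng.poisson(mean))
            school = rng.random() < config.school_probability
            if school and n_fish > 0:
                n_fish += int(rng.poisson(config.school_size_mean))
            placements = _place_fish(rng, config, n_fish, prev_centers, school)
            for cy, cx, a, b, angle in placements:
                rr, cc = draw_ellipse(cy, cx, a, b, shape=(h, w), rotation=angle)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                delta = sign * rng.uniform(*config.fish_contrast)
                img[rr, cc] += delta + rng.normal(0, 5.0, rr.size)
            prev_centers = [(p[0], p[1], p[2]) for p in placements]
            if not is_day:
                img = img * vignette
            if config.turbidity > 0:
                img = ndimage.gaussian_filter(img, blur_sigma)
                img = img.mean() + (img - img.mean()) * contrast
            fmask = truth.fouling_mask(i)
            img = np.where(fmask, fouling_tex, img)

        count = len(placements)
        truth.counts.append(count)
        truth.fish.append(placements)
        truth.error_frames.append(bool(error))
        truth.ptz_ok.append(not ptz_wrong)
        frames.append(
            FrameRecord(
                frame_id=frame_id,
                timestamp=t,
                _pixels=np.clip(img, 0, 255).astype(np.uint8),
            )
        )
        annotations.append(
            AnnotationRecord(
                frame_id=frame_id,
                observed_count=count,
                turbidity=config.turbidity,
                fouling=config.fouling,
                irradiance=irr,
                photoperiod="day" if is_day else "night",
                ptz_ok=not ptz_wrong,
                error_frame=bool(error),
            )
        )

    return FrameSequence(frames=frames, nominal_interval=config.interval), annotations, truth


def write_dataset(
    seq: FrameSequence,
    annotations: list[AnnotationRecord],
    truth: Optional[GroundTruth],
    out_dir: Path | str,
) -> None:
    """Write PNG frames + manifest CSV (+ truth JSON) loadable by dataset IO."""
    import json

    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for frame, ann in zip(seq.frames, annotations):
        Image.fromarray(frame.pixels).save(img_dir / f"{frame.frame_id}.png")
        rows.append(
            {
                "frame_id": frame.frame_id,
                "timestamp_iso8601": frame.timestamp.isoformat(),
                "observed_count": ann.observed_count,
                "turbidity": ann.turbidity,
                "fouling": ann.fouling,
                "irradiance": ann.irradiance,
                "photoperiod": ann.photoperiod,
                "ptz_ok": ann.ptz_ok,
                "error_frame": ann.error_frame,
            }
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(out_dir / "manifest.csv", index=False)
    if truth is not None:
        payload = {
            "frame_shape": list(truth.frame_shape),
            "counts": truth.counts,
            "fish": [[list(p) for p in fr] for fr in truth.fish],
            "error_frames": truth.error_frames,
            "ptz_ok": truth.ptz_ok,
            "fouling_patches": [list(p) for p in truth.fouling_patches],
            "fouling_growth_every": truth.fouling_growth_every,
            "fouling_growth_px": truth.fouling_growth_px,
        }
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(payload, fh)


def load_ground_truth(path: Path | str) -> GroundTruth:
    import json

    with open(path) as fh:
        p = json.load(fh)
    return GroundTruth(
        frame_shape=tuple(p["frame_shape"]),
        counts=p["counts"],
        fish=[[tuple(f) for f in fr] for fr in p["fish"]],
        error_frames=p["error_frames"],
        ptz_ok=p["ptz_ok"],
        fouling_patches=[tuple(q) for q in p["fouling_patches"]],
        fouling_growth_every=p["fouling_growth_every"],
        fouling_growth_px=p["fouling_growth_px"],
    )


def generate_feature_dataset(
    n_pos: int,
    n_neg: int,
    separation: float,
    rng_seed: int = 0,
    n_features: int | None = None,
    n_informative: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-Gaussian labeled feature pool for testing the learner alone.

    Both classes are unit-variance Gaussians in ``n_features`` dimensions;
    on a random subset of ``n_informative`` features the positive class
    mean is shifted by ``separation`` pooled standard deviations.  Returns
    (X, y) with exactly ``n_pos`` positives followed by ``n_neg`` negatives.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one example per class")
    if n_features is None:
        from .features import FEATURE_NAMES

        n_features = len(FEATURE_NAMES)
    rng = np.random.default_rng(rng_seed)
    informative = rng.choice(n_features, size=n_informative, replace=False)
    X = rng.normal(0.0, 1.0, (n_pos + n_neg, n_features))
    X[:n_pos, informative] += separation
    y = np.concatenate([np.ones(n_pos, dtype=np.int64), np.zeros(n_neg, dtype=np.int64)])
    return X, y
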