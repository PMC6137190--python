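"""Loading, validation and stratification of time-lapse image datasets.

A dataset is a directory of still images plus a CSV manifest carrying, per
frame: an identifier, an ISO-8601 timestamp, the manually observed fish
count, turbidity and bio-fouling scores (0-3), solar irradiance, an optional
day/night label, and flags for wrong camera position and transmission
errors.  Frames are always handled as a time-sorted sequence because the
segmentation stage differences consecutive frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

MANIFEST_COLUMNS = [
    "frame_id",
    "timestamp_iso8601",
    "observed_count",
    "turbidity",
    "fouling",
    "irradiance",
    "photoperiod",
    "ptz_ok",
    "error_frame",
]

#: Default irradiance (W m^-2) above which a frame counts as daylight.
DAY_IRRADIANCE_THRESHOLD = 5.0


@dataclass
class FrameRecord:
    """One still image with its acquisition timestamp.

    Pixels are lazily loaded from ``image_path`` on first access and
    converted to 8-bit grayscale with the standard luma weighting; synthetic
    frames may carry their pixel grid directly.
    """

    frame_id: str
    timestamp: datetime
    image_path: Optional[Path] = None
    _pixels: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def pixels(self) -> np.ndarray:
        if self._pixels is None:
            if self.image_path is None:
                raise ValueError(f"frame {self.frame_id}: no pixels and no image path")
            with Image.open(self.image_path) as img:
                self._pixels = np.asarray(img.convert("L"), dtype=np.uint8)
        return self._pixels

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class FrameSequence:
    """Time-ordered frames; timestamps must be strictly increasing."""

    frames: list[FrameRecord]
    nominal_interval: timedelta = timedelta(minutes=30)

    def __post_init__(self) -> None:
        ts = [f.timestamp for f in self.frames]
        for a, b in zip(ts, ts[1:]):
            if b <= a:
                raise ValueError(f"timestamps not strictly increasing at {b}")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> FrameRecord:
        return self.frames[i]


@dataclass
class AnnotationRecord:
    """Manual annotation attached to one frame."""

    frame_id: str
    observed_count: Optional[int] = None
    turbidity: Optional[int] = None
    fouling: Optional[int] = None
    irradiance: Optional[float] = None
    photoperiod: Optional[str] = None
    ptz_ok: bool = True
    error_frame: bool = False

    def __post_init__(self) -> None:
        if self.observed_count is not None and self.observed_count < 0:
            raise ValueError(f"frame {self.frame_id}: negative observed_count")
        for name in ("turbidity", "fouling"):
            v = getattr(self, name)
            if v is not None and v not in (0, 1, 2, 3):
                raise ValueError(f"frame {self.frame_id}: {name} score {v} not in 0..3")
        if self.photoperiod is not None and self.photoperiod not in ("day", "night"):
            raise ValueError(f"frame {self.frame_id}: bad photoperiod {self.photoperiod!r}")


def _parse_optional_int(value, frame_id: str, column: str) -> Optional[int]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        return int(value)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"frame {frame_id}: unparseable {column} {value!r}") from exc


def _parse_bool(value, default: bool) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return default
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no"):
        return False
    raise ValueError(f"unparseable boolean {value!r}")


def load_sequence(
    image_dir: Path | str, manifest: Path | str
) -> tuple[FrameSequence, list[AnnotationRecord]]:
    """Load a manifest and its images into a time-sorted sequence.

    Every image referenced by the manifest must exist; missing files,
    duplicate timestamps and malformed scores are hard errors that name the
    offending frame.  Annotations are returned in the same (sorted) order as
    the frames.
    """
    image_dir = Path(image_dir)
    df = pd.read_csv(manifest, dtype={"frame_id": str})
    missing_cols = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"manifest missing columns: {sorted(missing_cols)}")

    frames: list[FrameRecord] = []
    annotations: list[AnnotationRecord] = []
    for row in df.itertuples(index=False):
        fid = str(row.frame_id)
        ts = datetime.fromisoformat(str(row.timestamp_iso8601))
        path = image_dir / f"{fid}.png"
        if not path.exists():
            alt = image_dir / f"{fid}.jpg"
            if alt.exists():
                path = alt
            else:
                raise FileNotFoundError(f"frame {fid}: image file {path} not found")
        irr = row.irradiance
        if irr is not None and isinstance(irr, float) and math.isnan(irr):
            irr = None
        photo = row.photoperiod
        if photo is None or (isinstance(photo, float) and math.isnan(photo)) or photo == "":
            photo = None
        frames.append(FrameRecord(frame_id=fid, timestamp=ts, image_path=path))
        annotations.append(
            AnnotationRecord(
                frame_id=fid,
                observed_count=_parse_optional_int(row.observed_count, fid, "observed_count"),
                turbidity=_parse_optional_int(row.turbidity, fid, "turbidity"),
                fouling=_parse_optional_int(row.fouling, fid, "fouling"),
                irradiance=None if irr is None else float(irr),
                photoperiod=photo,
                ptz_ok=_parse_bool(row.ptz_ok, True),
                error_frame=_parse_bool(row.error_frame, False),
            )
        )

    order = sorted(range(len(frames)), key=lambda i: frames[i].timestamp)
    frames = [frames[i] for i in order]
    annotations = [annotations[i] for i in order]
    seen: set[datetime] = set()
    for f in frames:
        if f.timestamp in seen:
            raise ValueError(f"duplicate timestamp {f.timestamp} (frame {f.frame_id})")
        seen.add(f.timestamp)
    return FrameSequence(frames=frames), annotations


def classify_photoperiod(
    record: AnnotationRecord, threshold: float = DAY_IRRADIANCE_THRESHOLD
) -> str:
    """Assign day/night: day iff irradiance exceeds ``threshold``.

    A pre-set photoperiod label passes through unchanged; lacking both a
    label and an irradiance reading is an error.
    """
    if record.photoperiod is not None:
        return record.photoperiod
    if record.irradiance is None:
        raise ValueError(f"frame {record.frame_id}: no irradiance and no photoperiod label")
    return "day" if record.irradiance > threshold else "night"


def sample_training_frames(
    seq: FrameSequence,
    annotations: Sequence[AnnotationRecord],
    fraction: float,
    rng_seed: int,
    threshold: float = DAY_IRRADIANCE_THRESHOLD,
) -> list[str]:
    """Uniform per-photoperiod subsample of frame ids for training.

    Within each of the day and night strata, ``floor(fraction * stratum
    size)`` frames are drawn uniformly without replacement.  Reproducible
    given the seed; an empty stratum is skipped with a warning.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return [f.frame_id for f in seq.frames]
    strata: dict[str, list[str]] = {"day": [], "night": []}
    for ann in annotations:
        strata[classify_photoperiod(ann, threshold)].append(ann.frame_id)
    rng = np.random.default_rng(rng_seed)
    chosen: list[str] = []
    for label in ("day", "night"):
        ids = strata[label]
        if not ids:
            import warnings

            warnings.warn(f"photoperiod stratum {label!r} is empty; skipped", stacklevel=2)
            continue
        n = int(math.floor(fraction * len(ids)))
        picked = rng.choice(len(ids), size=n, replace=False)
        chosen.extend(ids[i] for i in sorted(picked))
    return chosen
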