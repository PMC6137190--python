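"""Observed vs recognized abundance series: pairing, stratification,
multi-scale aggregation and correlation.

The unit of evaluation is a pair of timestamp-aligned count series — the
manual (observed) counts and the counts produced by the classifier — which
can be restricted to the "reduced" dataset (wrong-camera-position and
transmission-error frames removed), stratified by turbidity and bio-fouling
score, aggregated to day/night or monthly means, and compared by Pearson
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gp import GPClassifierEnsemble, predict_count
from .io import AnnotationRecord, FrameSequence, classify_photoperiod
from .segmentation import SegmentationParams, segment_frame

STRATA_COLUMNS = ["turbidity", "fouling", "photoperiod", "ptz_ok", "error_frame"]


@dataclass
class CountSeries:
    """Ordered (timestamp, count) entries with per-entry annotation strata."""

    df: pd.DataFrame  # columns: timestamp, count + STRATA_COLUMNS
    source: str  # "observed" | "recognized"

    def __post_init__(self) -> None:
        ts = self.df["timestamp"].to_numpy()
        if len(ts) > 1 and not (ts[1:] > ts[:-1]).all():
            raise ValueError("timestamps must be strictly increasing")
        if (self.df["count"] < 0).any():
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def counts(self) -> np.ndarray:
        return self.df["count"].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, source: str) -> "CountSeries":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        return cls(df=df, source=source)


@dataclass
class CorrelationResult:
    """Pearson r with its two-sided p-value and the paired sample size."""

    r: float
    p: float
    n: int
    defined: bool = True


Counter = Union[GPClassifierEnsemble, Callable[[int, list], int]]


def build_series(
    seq: FrameSequence,
    annotations: Sequence[AnnotationRecord],
    counter: Counter,
    seg_params: Optional[SegmentationParams] = None,
) -> tuple[CountSeries, CountSeries]:
    """Segment and count every evaluable frame; return paired series.

    A frame is evaluable when it has an observed count and a usable
    predecessor: the first frame has no difference image, and a frame whose
    predecessor is a corrupted or wrong-view frame has no valid difference
    either, so both are excluded.  ``counter`` is either a trained ensemble
    or any callable ``(frame_index, rois) -> count`` (e.g. an oracle stub).
    """
    seg_params = seg_params or SegmentationParams()
    obs_rows, rec_rows = [], []
    for i in range(1, len(seq)):
        ann = annotations[i]
        if ann.observed_count is None:
            continue
        prev = annotations[i - 1]
        if prev.error_frame or not prev.ptz_ok:
            continue
        rois = segment_frame(seq, i, seg_params)
        if isinstance(counter, GPClassifierEnsemble):
            rec = predict_count(counter, rois)
        else:
            rec = int(counter(i, rois))
        try:
            photo = classify_photoperiod(ann)
        except ValueError:
            photo = None
        strata = dict(
            turbidity=ann.turbidity,
            fouling=ann.fouling,
            photoperiod=photo,
            ptz_ok=ann.ptz_ok,
            error_frame=ann.error_frame,
        )
        ts = seq[i].timestamp
        obs_rows.append(dict(timestamp=ts, count=ann.observed_count, **strata))
        rec_rows.append(dict(timestamp=ts, count=rec, **strata))
    if not obs_rows:
        raise ValueError("no evaluable frames (no observed counts with predecessors)")
    cols = ["timestamp", "count"] + STRATA_COLUMNS
    return (
        CountSeries(pd.DataFrame(obs_rows, columns=cols), source="observed"),
        CountSeries(pd.DataFrame(rec_rows, columns=cols), source="recognized"),
    )


def _apply_mask(
    observed: CountSeries, recognized: CountSeries, mask: np.ndarray
) -> tuple[CountSeries, CountSeries]:
    return (
        replace(observed, df=observed.df.loc[mask].reset_index(drop=True)),
        replace(recognized, df=recognized.df.loc[mask].reset_index(drop=True)),
    )


def _check_paired(observed: CountSeries, recognized: CountSeries) -> None:
    if len(observed) != len(recognized) or not (
        observed.df["timestamp"].to_numpy() == recognized.df["timestamp"].to_numpy()
    ).all():
        raise ValueError("series are not timestamp-aligned")


def filter_reduced(
    observed: CountSeries,
    recognized: CountSeries,
    max_count: Optional[int] = None,
) -> tuple[CountSeries, CountSeries]:
    """Reduced dataset: drop wrong-PTZ and error frames (paired).

    ``max_count`` optionally also drops very crowded frames (observed count
    above the cutoff); disabled by default.
    """
    _check_paired(observed, recognized)
    df = observed.df
    mask = df["ptz_ok"].astype(bool).to_numpy() & ~df["error_frame"].astype(bool).to_numpy()
    if max_count is not None:
        mask &= df["count"].to_numpy() <= max_count
    return _apply_mask(observed, recognized, mask)


def stratify(
    observed: CountSeries,
    recognized: CountSeries,
    turbidity: Optional[set[int]] = None,
    fouling: Optional[set[int]] = None,
) -> tuple[CountSeries, CountSeries]:
    """Keep entries whose turbidity/fouling scores fall in the given sets."""
    _check_paired(observed, recognized)
    mask = np.ones(len(observed), dtype=bool)
    if turbidity is not None:
        mask &= observed.df["turbidity"].isin(list(turbidity)).to_numpy()
    if fouling is not None:
        mask &= observed.df["fouling"].isin(list(fouling)).to_numpy()
    return _apply_mask(observed, recognized, mask)


def aggregate(series: CountSeries, scale: str) -> CountSeries:
    """Aggregate counts to 30-min (identity), day/night or monthly means.

    day_night: one mean per (calendar day, photoperiod); monthly: one mean
    per calendar month.  The aggregate entry keeps the group's first
    timestamp so chronological order is preserved.
    """
    if scale == "raw_30min":
        return replace(series, df=series.df.copy())
    df = series.df
    if scale == "day_night":
        if df["photoperiod"].isna().any():
            raise ValueError("day_night aggregation needs photoperiod labels")
        keys = [df["timestamp"].dt.date, df["photoperiod"]]
    elif scale == "monthly":
        keys = [df["timestamp"].dt.to_period("M")]
    else:
        raise ValueError(f"unknown scale {scale!r}")
    grouped = (
        df.groupby(keys, sort=False, observed=True)
        .agg(timestamp=("timestamp", "first"), count=("count", "mean"))
        .reset_index(drop=True)
    )
    if scale == "day_night":
        photo = df.groupby(keys, sort=False, observed=True)["photoperiod"].first().to_numpy()
        grouped["photoperiod"] = photo
    else:
        grouped["photoperiod"] = None
    for col in ("turbidity", "fouling", "ptz_ok", "error_frame"):
        grouped[col] = None
    grouped = grouped.sort_values("timestamp").reset_index(drop=True)
    cols = ["timestamp", "count"] + STRATA_COLUMNS
    return replace(series, df=grouped[cols])


def pearson(a: CountSeries, b: CountSeries) -> CorrelationResult:
    """Product-moment correlation of two aligned series.

    Undefined (flagged, NaN) when either series is constant; the p-value is
    the standard two-sided t-transform with n-2 degrees of freedom.
    """
    _check_paired(a, b)
    n = len(a)
    if n < 3:
        return CorrelationResult(r=np.nan, p=np.nan, n=n, defined=False)
    x, y = a.counts, b.counts
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(r=np.nan, p=np.nan, n=n, defined=False)
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=n)


def score_correlation_table(
    observed: CountSeries, recognized: CountSeries, scale: str = "raw_30min"
) -> pd.DataFrame:
    """4x4 turbidity-by-fouling grid of Pearson r (long format).

    One row per (fouling, turbidity) score pair with r, p and n; cells with
    fewer than 3 paired entries or a constant series are reported missing.
    """
    rows = []
    for f in range(4):
        for t in range(4):
            o, r = stratify(observed, recognized, turbidity={t}, fouling={f})
            if len(o) >= 3:
                o2, r2 = aggregate(o, scale), aggregate(r, scale)
                res = pearson(o2, r2)
            else:
                res = CorrelationResult(np.nan, np.nan, len(o), defined=False)
            rows.append(
                dict(fouling=f, turbidity=t, r=res.r, p=res.p, n=res.n, defined=res.defined)
            )
    return pd.DataFrame(rows)
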