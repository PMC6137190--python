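"""Paired count series: building, filtering, aggregation, correlation."""

from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from fincount.synthetic import SceneConfig, generate_sequence
from fincount.timeseries import (
    STRATA_COLUMNS,
    CountSeries,
    aggregate,
    build_series,
    filter_reduced,
    pearson,
    score_correlation_table,
    stratify,
)


def series_from(counts, start=datetime(2013, 3, 1), step=timedelta(minutes=30),
                source="observed", **strata):
    rows = []
    for i, c in enumerate(counts):
        row = dict(timestamp=start + i * step, count=c)
        for col in STRATA_COLUMNS:
            v = strata.get(col)
            row[col] = v[i] if isinstance(v, (list, np.ndarray)) else (
                v if v is not None else {"ptz_ok": True, "error_frame": False}.get(col, 0)
            )
        if "photoperiod" not in strata:
            row["photoperiod"] = "day"
        rows.append(row)
    return CountSeries(pd.DataFrame(rows), source=source)


@pytest.fixture(scope="module")
def oracle_pair():
    """Series built with a perfect counter: recognized == observed."""
    cfg = SceneConfig(n_frames=150, error_frame_probability=0.0,
                      ptz_wrong_probability=0.0, rng_seed=21)
    seq, anns, truth = generate_sequence(cfg)
    oracle = lambda i, rois: truth.counts[i]
    return build_series(seq, anns, oracle)


def test_build_series_pairing_and_first_frame_excluded(oracle_pair):
    obs, rec = oracle_pair
    assert len(obs) == len(rec) == 149  # first frame has no difference image
    assert (obs.df["timestamp"].to_numpy() == rec.df["timestamp"].to_numpy()).all()
    np.testing.assert_array_equal(obs.counts, rec.counts)


def test_recognized_counts_have_no_label_leakage():
    """Permuting the observed annotations must not change recognized counts."""
    cfg = SceneConfig(n_frames=20, error_frame_probability=0.0,
                      ptz_wrong_probability=0.0, rng_seed=22)
    seq, anns, _ = generate_sequence(cfg)
    counter = lambda i, rois: len(rois)
    _, rec1 = build_series(seq, anns, counter)
    rng = np.random.default_rng(0)
    shuffled_counts = rng.permutation([a.observed_count for a in anns])
    for a, c in zip(anns, shuffled_counts):
        a.observed_count = int(c)
    _, rec2 = build_series(seq, anns, counter)
    np.testing.assert_array_equal(rec1.counts, rec2.counts)


def test_frames_after_corrupted_predecessor_are_excluded():
    cfg = SceneConfig(n_frames=60, error_frame_probability=0.15,
                      ptz_wrong_probability=0.0, rng_seed=23)
    seq, anns, truth = generate_sequence(cfg)
    obs, _ = build_series(seq, anns, lambda i, rois: 0)
    bad_pred = {seq[i].timestamp for i in range(1, 60) if anns[i - 1].error_frame}
    assert bad_pred  # the draw contains at least one error frame
    assert not bad_pred & set(obs.df["timestamp"])


def test_filter_reduced_identity_when_clean():
    obs = series_from([1, 2, 3, 4])
    rec = series_from([1, 1, 3, 3], source="recognized")
    o2, r2 = filter_reduced(obs, rec)
    assert o2.df.equals(obs.df) and r2.df.equals(rec.df)


def test_filter_reduced_drops_flagged_pairs():
    flags = [False, True, False, True, True, False, False, False, False, False]
    obs = series_from(list(range(10)), error_frame=flags)
    rec = series_from(list(range(10)), source="recognized", error_frame=flags)
    o2, r2 = filter_reduced(obs, rec)
    assert len(o2) == len(r2) == 7
    assert (o2.df["timestamp"].to_numpy() == r2.df["timestamp"].to_numpy()).all()


def test_crowding_cutoff_optional():
    obs = series_from([1, 50, 2, 3])
    rec = series_from([1, 10, 2, 3], source="recognized")
    o2, _ = filter_reduced(obs, rec, max_count=10)
    assert len(o2) == 3


def test_stratify_and_filter_commute():
    turb = [0, 1, 2, 3, 0, 1, 2, 3]
    flags = [False, False, True, False, True, False, False, False]
    obs = series_from([1] * 8, turbidity=turb, error_frame=flags)
    rec = series_from([2] * 8, source="recognized", turbidity=turb, error_frame=flags)
    a = stratify(*filter_reduced(obs, rec), turbidity={0, 1})
    b = filter_reduced(*stratify(obs, rec, turbidity={0, 1}))
    assert a[0].df.equals(b[0].df) and a[1].df.equals(b[1].df)


def test_aggregate_constant_is_constant():
    ts = [datetime(2013, 1, 1) + i * timedelta(hours=6) for i in range(40)]
    photo = ["night", "day", "day", "night"] * 10
    df = pd.DataFrame(
        dict(timestamp=ts, count=4.0, turbidity=0, fouling=0,
             photoperiod=photo, ptz_ok=True, error_frame=False)
    )
    s = CountSeries(df, source="observed")
    for scale in ("raw_30min", "day_night", "monthly"):
        agg = aggregate(s, scale)
        assert (agg.counts == 4.0).all()
        ts_out = agg.df["timestamp"].to_numpy()
        assert (ts_out[1:] > ts_out[:-1]).all()


def test_day_night_aggregation_means():
    base = datetime(2013, 7, 1)
    rows = [
        (base.replace(hour=2), 0, "night"),
        (base.replace(hour=3), 0, "night"),
        (base.replace(hour=10), 2, "day"),
        (base.replace(hour=14), 4, "day"),
    ]
    df = pd.DataFrame(
        [dict(timestamp=t, count=c, turbidity=0, fouling=0, photoperiod=p,
              ptz_ok=True, error_frame=False) for t, c, p in rows]
    )
    agg = aggregate(CountSeries(df, source="observed"), "day_night")
    by_photo = dict(zip(agg.df["photoperiod"], agg.counts))
    assert by_photo == {"night": 0.0, "day": 3.0}


def test_monthly_aggregation():
    ts = [datetime(2013, 1, 5), datetime(2013, 1, 20), datetime(2013, 2, 2)]
    df = pd.DataFrame(
        dict(timestamp=ts, count=[2, 4, 10], turbidity=0, fouling=0,
             photoperiod="day", ptz_ok=True, error_frame=False)
    )
    agg = aggregate(CountSeries(df, source="observed"), "monthly")
    np.testing.assert_allclose(agg.counts, [3.0, 10.0])


def test_pearson_trivial_and_degenerate():
    a = series_from([1, 2, 3, 4, 5])
    b = series_from([2, 4, 6, 8, 10], source="recognized")
    assert pearson(a, b).r == pytest.approx(1.0)
    neg = series_from([5, 4, 3, 2, 1], source="recognized")
    assert pearson(a, neg).r == pytest.approx(-1.0)
    const = series_from([3, 3, 3, 3, 3], source="recognized")
    assert not pearson(a, const).defined


def test_pearson_misaligned_rejected():
    a = series_from([1, 2, 3])
    b = series_from([1, 2, 3], start=datetime(2013, 3, 1, 0, 15), source="recognized")
    with pytest.raises(ValueError):
        pearson(a, b)


def test_pearson_recovers_constructed_population_correlation():
    """b = 0.8 a + noise with sigma set for population r = 0.9; the sample r
    must fall inside the Fisher-z 99.9% interval around atanh(0.9)."""
    rng = np.random.default_rng(12)
    n = 50
    x = rng.normal(10, 2, n)
    rho = 0.9
    slope = 0.8
    sigma = slope * 2.0 * np.sqrt(1 / rho**2 - 1)
    yv = slope * x + rng.normal(0, sigma, n)
    ts = [datetime(2013, 1, 1) + i * timedelta(minutes=30) for i in range(n)]
    mk = lambda vals, src: CountSeries(
        pd.DataFrame(dict(timestamp=ts, count=np.abs(vals), turbidity=0, fouling=0,
                          photoperiod="day", ptz_ok=True, error_frame=False)), src)
    r = pearson(mk(x, "observed"), mk(yv, "recognized")).r
    z, z0 = np.arctanh(r), np.arctanh(rho)
    assert abs(z - z0) <= 3.29 / np.sqrt(n - 3)


def test_oracle_closure_all_scales_and_strata(oracle_pair):
    """With a perfect counter every defined correlation is exactly 1."""
    obs, rec = oracle_pair
    for scale in ("raw_30min", "day_night", "monthly"):
        o2, r2 = aggregate(obs, scale), aggregate(rec, scale)
        res = pearson(o2, r2)
        if res.defined:
            assert res.r == pytest.approx(1.0)
    table = score_correlation_table(obs, rec)
    assert len(table) == 16
    defined = table[table["defined"]]
    np.testing.assert_allclose(defined["r"].to_numpy(), 1.0)


def test_score_table_flags_sparse_cells(oracle_pair):
    obs, rec = oracle_pair
    table = score_correlation_table(obs, rec)
    # the generated scene is all turbidity 0 / fouling 0: other cells missing
    sparse = table[(table["turbidity"] > 0) | (table["fouling"] > 0)]
    assert not sparse["defined"].any()
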