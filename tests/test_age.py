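"""BSI computation, cloud masking, 12-month median smoothing, threshold
calibration, the backward detection scan and the year encoding."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from palmage.age import (AgeModelParams, BsiAgeModel, BsiSeries,
                         SmoothedBsiSeries, build_bsi_series,
                         calibrate_threshold, compute_bsi, decode_year,
                         detect_year, encode_year, mask_clouds,
                         smooth_median_12mo)
from palmage.synthetic import (ConfigurationError, OpticalObservation,
                               ScenarioConfig, generate_landscape,
                               simulate_optical_series)


# ------------------------------------------------------------------------- BSI

@pytest.mark.parametrize("b, r, n, s, expected", [
    (0.2, 0.2, 0.2, 0.2, 0.0),
    (0.0, 0.3, 0.0, 0.2, 1.0),
    (0.05, 0.10, 0.40, 0.20, -0.2),
])
def test_bsi_values(b, r, n, s, expected):
    bsi, ok = compute_bsi(b, r, n, s)
    assert ok and bsi == pytest.approx(expected)


def test_bsi_zero_denominator_masked():
    bsi, ok = compute_bsi(0.0, 0.0, 0.0, 0.0)
    assert not ok and np.isnan(bsi)


# ---------------------------------------------------------------- cloud masking

def _obs(cloud_fraction, seed=0):
    rng = np.random.default_rng(seed)
    cloud = rng.random((4, 4)) < cloud_fraction
    z = np.full((4, 4), 0.2)
    return OpticalObservation(np.datetime64("2000-01-01"), 2000.0,
                              z, z, z, z, cloud)


def test_mask_clouds_drops_fully_flagged_scenes():
    clear = _obs(0.0)
    overcast = _obs(1.1)
    assert mask_clouds([clear, overcast, clear]) == [clear, clear]
    assert mask_clouds([overcast, overcast]) == []


def test_cloud_flags_become_nans_in_series(small_config, small_truth):
    series = build_bsi_series(simulate_optical_series(small_truth, small_config))
    opt = simulate_optical_series(small_truth, small_config)
    i = 40
    obs = opt.observation(i)
    nan_count = np.isnan(series.values[i]).sum()
    assert nan_count == obs.cloud.sum()


# ------------------------------------------------------------------- smoothing

def _series(month_values: dict, archive_start=1984, map_year=2017):
    """BsiSeries with one pixel; month_values maps absolute month index ->
    list of BSI observations in that month."""
    months, vals = [], []
    for m in sorted(month_values):
        for v in month_values[m]:
            months.append(m)
            vals.append(v)
    months = np.asarray(months)
    times = archive_start + months / 12.0 + 0.01
    return BsiSeries(months, times, np.asarray(vals, np.float32)[:, None],
                     archive_start, map_year)


def test_smoothing_omits_windows_with_too_few_observations():
    sm = smooth_median_12mo(_series({13: [0.1, 0.3]}), min_obs=3)
    w = np.flatnonzero(sm.window_month == 24)[0]   # window covering month 13
    assert not sm.valid[w, 0]
    assert np.isnan(sm.values[w, 0])


def test_smoothing_median_of_three():
    sm = smooth_median_12mo(_series({13: [0.1], 14: [0.3], 15: [0.2]}), 3)
    w = np.flatnonzero(sm.window_month == 15)[0]
    assert sm.valid[w, 0]
    assert sm.values[w, 0] == pytest.approx(0.2)


def test_smoothing_constant_full_cadence():
    sm = smooth_median_12mo(
        _series({m: [0.4, 0.4] for m in range(408)}), 3)
    assert sm.valid.all()
    assert np.allclose(sm.values, 0.4)
    # windows step monthly from one year after archive start to map-year end
    assert sm.window_month[0] == 12 and sm.window_month[-1] == 407


def test_smoothing_window_excludes_month_13_back():
    # Window ending at month 24 spans months 13..24; an observation in
    # month 12 must not contribute.
    sm = smooth_median_12mo(_series({12: [9.0], 20: [0.1, 0.1, 0.1]}), 3)
    w = np.flatnonzero(sm.window_month == 24)[0]
    assert sm.values[w, 0] == pytest.approx(0.1)


# ----------------------------------------------------------------- calibration

def test_threshold_matches_sorting_oracle():
    vals = np.linspace(-1, 1, 100)  # 100 palm pixels
    sm = SmoothedBsiSeries(np.array([407]), np.array([2017]),
                           vals[None, :].astype(np.float32),
                           np.full((1, 100), 5, np.int16), 3, 1984, 2017)
    params = calibrate_threshold(sm, np.ones(100, bool), percentile=95.0)
    srt = np.sort(vals)
    rank = 0.95 * 99
    lo, hi = int(np.floor(rank)), int(np.ceil(rank))
    oracle = srt[lo] + (rank - lo) * (srt[hi] - srt[lo])
    assert params.threshold == pytest.approx(oracle)


def test_threshold_constant_values():
    sm = SmoothedBsiSeries(np.array([407]), np.array([2017]),
                           np.full((1, 120), 0.25, np.float32),
                           np.full((1, 120), 5, np.int16), 3, 1984, 2017)
    assert calibrate_threshold(sm, np.ones(120, bool)).threshold == pytest.approx(0.25)


def test_threshold_needs_enough_palm_pixels():
    sm = SmoothedBsiSeries(np.array([407]), np.array([2017]),
                           np.zeros((1, 50), np.float32),
                           np.full((1, 50), 5, np.int16), 3, 1984, 2017)
    with pytest.raises(ConfigurationError):
        calibrate_threshold(sm, np.ones(50, bool))


def test_threshold_separates_bare_from_closed_five_percent_construction():
    # Exactly 5% of palm pixels still bare (high BSI) in the map year:
    # the 95th percentile must fall between the two groups.
    vals = np.r_[np.full(950, -0.34), np.full(50, 0.21)].astype(np.float32)
    sm = SmoothedBsiSeries(np.array([407]), np.array([2017]), vals[None, :],
                           np.full((1, 1000), 5, np.int16), 3, 1984, 2017)
    tau = calibrate_threshold(sm, np.ones(1000, bool)).threshold
    assert -0.34 < tau <= 0.21


# ------------------------------------------------------------------- detection

def _smoothed_single(medians_by_year: dict, map_year=2017):
    """One-pixel smoothed series with a constant median per calendar year."""
    months = np.arange(12, (map_year - 1984 + 1) * 12)
    years = 1984 + months // 12
    vals = np.array([medians_by_year.get(y, np.nan) for y in years],
                    np.float32)[:, None]
    n_obs = np.where(np.isnan(vals), 0, 5).astype(np.int16)
    return SmoothedBsiSeries(months, years, vals, n_obs, 3, 1984, map_year)


PARAMS = AgeModelParams(threshold=0.0, map_year=2017, archive_start=1984)


def test_detection_year_is_first_window_below_threshold():
    # Bare (>= tau) through 2013, below from January 2014 -> 2014 -> code 34.
    med = {y: 0.3 for y in range(1985, 2014)}
    med.update({y: -0.3 for y in range(2014, 2018)})
    codes = detect_year(_smoothed_single(med), PARAMS, np.array([True]))
    assert codes[0] == 34


def test_never_bare_pixel_is_left_censored_to_code_4():
    med = {y: -0.3 for y in range(1985, 2018)}
    assert detect_year(_smoothed_single(med), PARAMS, np.array([True]))[0] == 4


def test_non_palm_pixel_is_nodata():
    med = {y: 0.3 for y in range(1985, 2018)}
    assert detect_year(_smoothed_single(med), PARAMS, np.array([False]))[0] == 0


def test_still_bare_in_map_year_gets_map_year_code():
    med = {y: -0.3 for y in range(1985, 2015)}
    med.update({y: 0.4 for y in range(2015, 2018)})
    assert detect_year(_smoothed_single(med), PARAMS, np.array([True]))[0] == 37


def test_all_invalid_palm_series_is_censored():
    assert detect_year(_smoothed_single({}), PARAMS, np.array([True]))[0] == 4


def test_bare_with_no_valid_follow_up_uses_last_bare_year():
    med = {y: 0.3 for y in range(1985, 2011)}   # nothing after 2010
    assert detect_year(_smoothed_single(med), PARAMS, np.array([True]))[0] == \
        encode_year(2010)


def test_codes_never_in_forbidden_range(small_config, small_truth):
    cfg, truth = small_config, small_truth
    palm = truth.palm_mask
    sm = smooth_median_12mo(
        build_bsi_series(simulate_optical_series(truth, cfg), palm), 3)
    model = BsiAgeModel().fit(sm, np.ones(int(palm.sum()), bool))
    codes = model.predict(sm, np.ones(int(palm.sum()), bool))
    assert not np.isin(codes, [1, 2, 3]).any()
    assert codes.max() <= cfg.map_year - 1980


def test_later_archive_start_never_moves_detection_earlier(small_config,
                                                           small_truth):
    cfg, truth = small_config, small_truth
    palm = truth.palm_mask
    series = build_bsi_series(simulate_optical_series(truth, cfg), palm)
    sm_full = smooth_median_12mo(series, 3)
    params = calibrate_threshold(sm_full, np.ones(series.values.shape[1], bool))
    full = detect_year(sm_full, params, np.ones(series.values.shape[1], bool))

    cut = 1995
    keep = series.times >= cut
    truncated = BsiSeries(series.month_index[keep] - (cut - 1984) * 12,
                          series.times[keep], series.values[keep],
                          cut, series.map_year)
    sm_cut = smooth_median_12mo(truncated, 3)
    params_cut = AgeModelParams(params.threshold, archive_start=cut,
                                map_year=series.map_year)
    late = detect_year(sm_cut, params_cut, np.ones(series.values.shape[1], bool))
    years_full = full.astype(int) + 1980
    years_late = np.where(late == 4, cut, late.astype(int) + (cut - 4))
    censored = late == 4
    assert (years_late[~censored] >= years_full[~censored] - 0).all()
    # censored pixels were detected at or before the new archive start + 1
    assert (years_full[censored] <= cut + 1).all()


# -------------------------------------------------------------------- encoding

def test_encoding_endpoints():
    assert encode_year(1984) == 4
    assert encode_year(2017) == 37


@given(st.integers(1984, 2017))
def test_encode_decode_roundtrip(year):
    assert decode_year(encode_year(year)) == year


def test_encoding_errors():
    with pytest.raises(ValueError):
        encode_year(1983)
    with pytest.raises(ValueError):
        encode_year(2018)
    for bad in (1, 2, 3):
        with pytest.raises(ValueError):
            decode_year(bad)
    assert decode_year(0) is None
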