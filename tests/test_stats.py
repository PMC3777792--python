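"""Group statistics, LDV, regressions, ROI analysis and Fugl-Meyer
bookkeeping, including calibration and power properties."""

import numpy as np
import pytest
import scipy.stats as sps

from visconn import (
    ViscParams,
    difference_volume,
    fa_threshold_sweep,
    fm_domain_totals,
    fm_totals,
    ldv,
    metric_fa_correlation,
    multiple_regression,
    roi_analysis,
    simple_regression,
    voxelwise_ttest,
)
from visconn.stats import (
    FM_DOMAIN_MAXIMA,
    FM_LEAF_MAXIMA,
    fa_correlation_reference_table,
    stroke_cohort_fm_table,
)


# ---------------------------------------------------------------------------
# Fugl-Meyer bookkeeping


def test_fm_maxima_sums():
    full = fm_totals({k: v for k, v in FM_LEAF_MAXIMA.items()})
    assert full.ue_total == 130
    assert full.le_total == 96
    assert full.grand_total == 226
    assert sum(FM_DOMAIN_MAXIMA.values()) == 226
    for name, mx in FM_DOMAIN_MAXIMA.items():
        assert full.domain_total(name) == mx


def test_fm_validation_names_offender():
    with pytest.raises(ValueError, match="ue_synergy"):
        fm_totals({"ue_synergy": 31})
    with pytest.raises(ValueError, match="unknown"):
        fm_totals({"tail_wagging": 1})
    with pytest.raises(ValueError, match="balance"):
        fm_domain_totals(motor=50, balance=15, sensation=0, rom=0, pain=0)
    assert fm_domain_totals(100, 14, 24, 44, 44) == 226


def test_reference_cohort_internally_consistent():
    table = stroke_cohort_fm_table()
    domains = table[["motor", "balance", "sensation", "rom", "pain"]].sum(axis=1)
    np.testing.assert_array_equal(domains, table["total"])
    np.testing.assert_array_equal(
        table["ue_total"] + table["le_total"], table["total"]
    )
    s01 = table.loc["S01"]
    assert s01["total"] == 170
    assert s01["ue_total"] == 93 and s01["le_total"] == 77


def test_fa_reference_table_summary():
    table = fa_correlation_reference_table()
    assert len(table) == 18
    visc = table["visc"]
    assert round(float(visc.mean()), 3) == 0.184
    assert round(float(visc.std(ddof=1)), 3) == 0.033


# ---------------------------------------------------------------------------
# voxelwise t-test


def test_ttest_closed_form():
    res = voxelwise_ttest(
        np.zeros((1, 1, 1)),
        [np.full((1, 1, 1), v) for v in (1.0, 2.0, 3.0)],
    )
    assert res.df == 2
    assert res.t[0, 0, 0] == pytest.approx(2.0 * np.sqrt(3.0))
    assert res.p[0, 0, 0] == pytest.approx(
        sps.t.sf(2.0 * np.sqrt(3.0), 2)
    )


def test_ttest_zero_variance_convention():
    res = voxelwise_ttest(
        np.ones((1, 1, 1)), [np.full((1, 1, 1), 2.0)] * 4
    )
    assert np.isinf(res.t[0, 0, 0]) and res.t[0, 0, 0] > 0
    assert res.significant[0, 0, 0]
    res0 = voxelwise_ttest(np.ones((1, 1, 1)), [np.ones((1, 1, 1))] * 4)
    assert res0.t[0, 0, 0] == 0.0
    assert not res0.significant[0, 0, 0]


def test_ttest_tails_and_errors():
    subject = np.full((1, 1, 1), 10.0)
    controls = [np.full((1, 1, 1), v) for v in (1.0, 2.0, 3.0)]
    lo = voxelwise_ttest(subject, controls, tail="controls_greater")
    hi = voxelwise_ttest(subject, controls, tail="subject_greater")
    assert not lo.significant.any()
    assert hi.significant.all()
    with pytest.raises(ValueError, match="tail"):
        voxelwise_ttest(subject, controls, tail="two_sided")
    with pytest.raises(ValueError):
        voxelwise_ttest(subject, controls[:1])
    with pytest.raises(ValueError):
        voxelwise_ttest(np.zeros((2, 1, 1)), controls)


def test_difference_volume_and_ldv():
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[:2] = True
    region = np.zeros_like(mask)
    region[0] = True
    assert difference_volume(mask) == 32
    assert difference_volume(mask, region) == 16
    assert ldv(32) == pytest.approx(np.log(32))
    assert np.isnan(ldv(0))
    with pytest.raises(ValueError):
        ldv(-1)


def test_type_one_rate_with_fixed_pseudo_subject():
    """The prescribed statistic is exactly t_{n-1} when the subject map is
    the fixed null mean; the empirical rate must sit in the binomial 99% CI."""
    rng = np.random.default_rng(2024)
    shape = (16, 16, 16)
    controls = [rng.normal(0.0, 1.0, shape) for _ in range(9)]
    res = voxelwise_ttest(np.zeros(shape), controls, tail="controls_greater")
    rate = res.significant.mean()
    n = np.prod(shape)
    half = 2.576 * np.sqrt(0.05 * 0.95 / n)
    assert 0.05 - half < rate < 0.05 + half


def test_drawn_subject_is_anticonservative():
    """With the subject itself a draw from the control distribution the
    prescribed statistic is sqrt(n+1) times t_{n-1}: the type-I rate is far
    above alpha.  Documented behaviour, not a bug in this implementation."""
    rng = np.random.default_rng(7)
    shape = (16, 16, 16)
    controls = [rng.normal(0.0, 1.0, shape) for _ in range(9)]
    subject = rng.normal(0.0, 1.0, shape)
    rate = voxelwise_ttest(subject, controls).significant.mean()
    assert rate > 0.15


# ---------------------------------------------------------------------------
# regressions


def test_simple_regression_perfect_line():
    x = np.array([1.0, 2, 3, 4, 5])
    reg = simple_regression(x, 2.0 * x + 1.0)
    assert reg.r_squared == pytest.approx(1.0)
    assert reg.coef[1] == pytest.approx(2.0)
    assert reg.coef[0] == pytest.approx(1.0)
    assert reg.n == 5


def test_simple_regression_drops_nan():
    x = np.array([1.0, 2, np.nan, 4, 5])
    y = np.array([1.0, 2, 3, 4, np.nan])
    reg = simple_regression(x, y)
    assert reg.n == 3
    with pytest.raises(ValueError):
        simple_regression([1.0, np.nan, np.nan, 2.0], [1.0, 2, 3, 4])
    with pytest.raises(ValueError, match="constant"):
        simple_regression([2.0, 2.0, 2.0, 2.0], [1.0, 2, 3, 4])


def test_multiple_regression_bonferroni_flags():
    rng = np.random.default_rng(1)
    n = 40
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    y = 3.0 * x1 + rng.normal(scale=0.5, size=n)  # x2 irrelevant
    reg = multiple_regression(np.column_stack([x1, x2]), y)
    assert reg.corrected_alpha == pytest.approx(0.05 / 3)
    assert reg.significant["x0"] is True
    assert reg.significant["x1"] is False
    assert reg.coef_pvalues.shape == (3,)
    with pytest.raises(ValueError):
        multiple_regression(np.ones((5, 1)), np.arange(5.0))


def test_regression_f_test_calibrated():
    """Null F-test at n = 10: rejection rate ~ 0.05 over 1000 replicates."""
    rng = np.random.default_rng(99)
    hits = 0
    reps = 1000
    for _ in range(reps):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        if simple_regression(x, y).p_value < 0.05:
            hits += 1
    half = 2.576 * np.sqrt(0.05 * 0.95 / reps)
    assert 0.05 - half < hits / reps < 0.05 + half


def test_lesion_severity_power():
    """Constructed lesion-severity cohorts at n = 10: LDV grows as the FM
    score falls, so the LDV-FM regression must come out significant with a
    negative slope (the synthetic stand-in for the real-brain finding)."""
    shape = (12, 12, 12)
    fm = np.linspace(220, 120, 10)
    for seed in range(5):
        rng = np.random.default_rng(seed)
        controls = [rng.normal(0.0, 0.1, shape) for _ in range(9)]
        ldvs = []
        for score in fm:
            n_lesion = int(5 + (226 - score))  # more impaired -> larger lesion
            subject = rng.normal(0.0, 0.1, shape)
            flat = subject.reshape(-1)
            flat[:n_lesion] -= 1.0  # suppressed metric inside the lesion
            res = voxelwise_ttest(subject, controls, tail="controls_greater")
            ldvs.append(ldv(difference_volume(res.significant)))
        reg = simple_regression(np.array(ldvs), fm)
        assert reg.p_value < 0.05
        assert reg.coef[1] < 0  # higher LDV, lower FM score


# ---------------------------------------------------------------------------
# ROI analysis and FA relations


def test_roi_analysis_table():
    rng = np.random.default_rng(3)
    shape = (8, 8, 8)
    labels = np.zeros(shape, dtype=int)
    labels[:4] = 1
    labels[4:] = 2
    fm = np.array([100.0, 140, 180, 220])
    maps = {"VISC": [], "FA": []}
    masks = {"VISC": [], "FA": []}
    for score in fm:
        base = rng.normal(1.0, 0.05, shape) * (score / 226.0)
        maps["VISC"].append(base)
        maps["FA"].append(base * 0.5)
        sig = rng.random(shape) < 0.2
        masks["VISC"].append(sig)
        masks["FA"].append(sig)
    table = roi_analysis(maps, masks, labels, fm)
    assert len(table) == 4  # 2 ROIs x 2 metrics
    assert set(table["roi"]) == {1, 2}
    assert {"ldv_r2", "mean_all_r2", "star_metrics"} <= set(table.columns)
    # regional means scale with the score: near-perfect regression
    assert (table["mean_all_r2"] > 0.9).all()


def test_metric_fa_correlation():
    rng = np.random.default_rng(4)
    fa = rng.uniform(0.0, 0.8, (10, 10, 10))
    metric = 2.0 * fa + rng.normal(0, 0.05, fa.shape)
    r2 = metric_fa_correlation(metric, fa, fa_floor=0.15)
    assert 0.9 < r2 <= 1.0
    with pytest.raises(ValueError):
        metric_fa_correlation(metric, np.zeros_like(fa))
    with pytest.raises(ValueError):
        metric_fa_correlation(metric[:5], fa)


# ---------------------------------------------------------------------------
# FA threshold sweep


def test_fa_threshold_sweep_on_fan(fan_field):
    roi = np.ones(fan_field.shape, dtype=bool)
    table, fit = fa_threshold_sweep(fan_field, roi,
                                    visc_params=ViscParams(alpha=1.0))
    assert len(table) == 7
    np.testing.assert_allclose(
        table["fa_threshold"], np.arange(0.10, 0.401, 0.05), atol=1e-9
    )
    assert (table["mean_visc"] > 0).all()
    # connectivity falls as the stopping threshold rises
    assert fit["slope"] < 0
    assert fit["r"] < -0.9


def test_fa_threshold_sweep_validation(fan_field):
    roi = np.ones(fan_field.shape, dtype=bool)
    with pytest.raises(ValueError, match="ascending"):
        fa_threshold_sweep(fan_field, roi, thresholds=[0.3, 0.2])
    with pytest.raises(ValueError, match="ROI"):
        fa_threshold_sweep(fan_field, np.zeros(fan_field.shape, dtype=bool))
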