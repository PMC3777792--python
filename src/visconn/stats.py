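"""Voxel-based group statistics, difference volumes, regressions, ROI
summaries, and Fugl-Meyer score bookkeeping.

The group comparison is a per-voxel one-tailed paired-style t-test on the
differences between each of n control maps and a single subject map (zero
mean-difference null, df = n - 1).  The count of significant voxels — the
difference volume — enters regressions as its natural logarithm, the
logarithmic difference volume (LDV).  Simple and multiple OLS regressions
relate LDV (or regional means) to Fugl-Meyer sensorimotor scores, with
slope significance by F-test and Bonferroni correction over the number of
metrics (3 by default) for the multiple regressions.

Fugl-Meyer bookkeeping follows the standard impairment scale: a grand total
of 226 split into an upper-extremity (UE, max 130) and lower-extremity
(LE, max 96) total, and cross-cutting domains motor (100), balance (14),
sensation (24), range of motion (44) and pain (44).  Lower scores mean
greater impairment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .connectivity import ViscParams, build_direct, compute_visc
from .dti import ScalarMap, TensorField, compute_fa
from .tractography import TrackingParams, filter_fibers, generate_seeds, track_all

__all__ = [
    "FM_LEAF_MAXIMA",
    "FM_DOMAIN_MAXIMA",
    "FMScore",
    "fm_totals",
    "fm_domain_totals",
    "stroke_cohort_fm_table",
    "fa_correlation_reference_table",
    "VoxelTestResult",
    "voxelwise_ttest",
    "difference_volume",
    "ldv",
    "RegressionResult",
    "simple_regression",
    "multiple_regression",
    "roi_analysis",
    "metric_fa_correlation",
    "fa_threshold_sweep",
]


# ---------------------------------------------------------------------------
# Fugl-Meyer bookkeeping

#: Maximum per leaf sub-score of the (slightly extended) Fugl-Meyer scale.
FM_LEAF_MAXIMA: dict[str, int] = {
    # upper extremity
    "ue_reflexes": 6,
    "ue_synergy": 30,
    "wrist_hand": 24,
    "ue_coordination": 6,
    "parachute": 4,
    "ue_light_touch": 4,
    "ue_proprioception": 8,
    "ue_rom": 24,
    "ue_pain": 24,
    # lower extremity
    "le_reflexes": 6,
    "le_synergy": 22,
    "le_coordination": 6,
    "standing_balance": 8,
    "sit_without_support": 2,
    "le_light_touch": 4,
    "le_proprioception": 8,
    "le_rom": 20,
    "le_pain": 20,
}

_UE_LEAVES = (
    "ue_reflexes",
    "ue_synergy",
    "wrist_hand",
    "ue_coordination",
    "parachute",
    "ue_light_touch",
    "ue_proprioception",
    "ue_rom",
    "ue_pain",
)
_LE_LEAVES = (
    "le_reflexes",
    "le_synergy",
    "le_coordination",
    "standing_balance",
    "sit_without_support",
    "le_light_touch",
    "le_proprioception",
    "le_rom",
    "le_pain",
)
_UE_MOTOR = ("ue_reflexes", "ue_synergy", "wrist_hand", "ue_coordination")
_LE_MOTOR = ("le_reflexes", "le_synergy", "le_coordination")

#: Cross-cutting domain maxima (UE + LE combined).
FM_DOMAIN_MAXIMA: dict[str, int] = {
    "motor": 100,
    "balance": 14,
    "sensation": 24,
    "rom": 44,
    "pain": 44,
}

_DOMAIN_LEAVES: dict[str, tuple[str, ...]] = {
    "motor": _UE_MOTOR + _LE_MOTOR,
    "balance": ("parachute", "standing_balance", "sit_without_support"),
    "sensation": (
        "ue_light_touch",
        "ue_proprioception",
        "le_light_touch",
        "le_proprioception",
    ),
    "rom": ("ue_rom", "le_rom"),
    "pain": ("ue_pain", "le_pain"),
}


@dataclass
class FMScore:
    """Validated Fugl-Meyer leaf sub-scores with derived totals."""

    subscores: dict[str, float]

    def _sum(self, leaves) -> float:
        return float(sum(self.subscores[k] for k in leaves))

    @property
    def ue_total(self) -> float:
        return self._sum(_UE_LEAVES)

    @property
    def le_total(self) -> float:
        return self._sum(_LE_LEAVES)

    @property
    def ue_motor(self) -> float:
        return self._sum(_UE_MOTOR)

    @property
    def le_motor(self) -> float:
        return self._sum(_LE_MOTOR)

    @property
    def grand_total(self) -> float:
        return self.ue_total + self.le_total

    def domain_total(self, domain: str) -> float:
        return self._sum(_DOMAIN_LEAVES[domain])


def fm_totals(subscores: dict[str, float]) -> FMScore:
    """Validate leaf sub-scores and compute totals.

    Missing leaves default to 0.  A sub-score above its maximum (or below 0,
    or an unknown name) raises a ValueError naming the offending domain.
    """
    clean: dict[str, float] = {k: 0.0 for k in FM_LEAF_MAXIMA}
    for name, value in subscores.items():
        if name not in FM_LEAF_MAXIMA:
            raise ValueError(f"unknown Fugl-Meyer sub-score: {name!r}")
        if not 0 <= value <= FM_LEAF_MAXIMA[name]:
            raise ValueError(
                f"sub-score {name!r} = {value} outside [0, {FM_LEAF_MAXIMA[name]}]"
            )
        clean[name] = float(value)
    return FMScore(subscores=clean)


def fm_domain_totals(
    motor: float, balance: float, sensation: float, rom: float, pain: float
) -> float:
    """Grand total from the five cross-cutting domain scores, validating each
    against its maximum."""
    values = {"motor": motor, "balance": balance, "sensation": sensation,
              "rom": rom, "pain": pain}
    for name, v in values.items():
        if not 0 <= v <= FM_DOMAIN_MAXIMA[name]:
            raise ValueError(
                f"domain {name!r} = {v} outside [0, {FM_DOMAIN_MAXIMA[name]}]"
            )
    return float(sum(values.values()))


def stroke_cohort_fm_table() -> pd.DataFrame:
    """Bundled Fugl-Meyer scores of a reference chronic-stroke cohort
    (per-subject domain scores and UE/LE totals; lower = more impaired)."""
    rows = [
        # subject, total, motor, balance, sensation, rom, pain, ue, ue_motor, le, le_motor
        ("S01", 170, 75, 11, 3, 37, 44, 93, 45, 77, 30),
        ("S02", 143, 51, 10, 7, 31, 44, 70, 26, 73, 25),
        ("S04", 207, 87, 10, 23, 43, 44, 130, 66, 77, 21),
        ("S10", 169, 71, 10, 22, 30, 36, 90, 47, 79, 24),
        ("S11", 218, 92, 14, 24, 44, 44, 127, 61, 91, 31),
        ("S13", 169, 58, 10, 24, 33, 44, 99, 39, 70, 19),
        ("S14", 152, 49, 8, 24, 37, 34, 68, 22, 84, 27),
        ("S15", 144, 35, 10, 22, 33, 44, 71, 18, 73, 17),
        ("S17", 124, 32, 8, 4, 36, 44, 58, 14, 66, 18),
        ("S19", 194, 74, 12, 24, 40, 44, 101, 42, 93, 32),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "subject", "total", "motor", "balance", "sensation", "rom",
            "pain", "ue_total", "ue_motor", "le_total", "le_motor",
        ],
    ).set_index("subject")


def fa_correlation_reference_table() -> pd.DataFrame:
    """Bundled per-subject R^2 of three tractography-derived metrics against
    FA (voxels with FA > 0.15) in a reference cohort of 18 subjects."""
    rows = [
        ("C13", 0.131, 0.200, 0.195),
        ("C17", 0.174, 0.217, 0.192),
        ("C18", 0.176, 0.220, 0.204),
        ("C19", 0.134, 0.220, 0.204),
        ("C20", 0.075, 0.166, 0.192),
        ("C21", 0.175, 0.211, 0.201),
        ("C23", 0.120, 0.171, 0.154),
        ("C26", 0.139, 0.225, 0.179),
        ("S01", 0.168, 0.248, 0.206),
        ("S02", 0.208, 0.256, 0.249),
        ("S04", 0.125, 0.199, 0.174),
        ("S10", 0.143, 0.207, 0.186),
        ("S11", 0.166, 0.203, 0.176),
        ("S13", 0.150, 0.222, 0.192),
        ("S14", 0.154, 0.206, 0.193),
        ("S15", 0.142, 0.175, 0.170),
        ("S17", 0.026, 0.072, 0.084),
        ("S19", 0.118, 0.153, 0.158),
    ]
    return pd.DataFrame(
        rows, columns=["subject", "fiber_count", "mean_fiber_length", "visc"]
    ).set_index("subject")


# ---------------------------------------------------------------------------
# voxel-wise group comparison


@dataclass
class VoxelTestResult:
    """Per-voxel t statistics, one-tailed p values and significance mask."""

    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    tail: str
    df: int
    alpha: float


def _as_array(m) -> np.ndarray:
    return m.values if isinstance(m, ScalarMap) else np.asarray(m, dtype=float)


def voxelwise_ttest(
    subject_map,
    control_maps,
    tail: str = "controls_greater",
    alpha: float = 0.05,
    valid_mask: np.ndarray | None = None,
) -> VoxelTestResult:
    """One-tailed t-test per voxel on d_c = control_c - subject.

    ``tail='controls_greater'`` tests H1: mean d > 0 (metric reduced in the
    subject, the expectation for FA and VISC around a lesion);
    ``tail='subject_greater'`` tests H1: mean d < 0 (elevated in the subject,
    the expectation for MD).  df = n_controls - 1.  Zero-variance voxels get
    t = +/-inf by the sign of the mean difference (t = 0 when the mean is
    also zero).  No voxel-level multiple-comparison correction is applied;
    ``alpha`` (default 0.05, uncorrected) sets the significance mask.
    """
    if tail not in ("controls_greater", "subject_greater"):
        raise ValueError(f"unknown tail: {tail!r}")
    subject = _as_array(subject_map)
    controls = np.stack([_as_array(c) for c in control_maps])
    n = controls.shape[0]
    if n < 2:
        raise ValueError("need >= 2 control maps")
    if controls.shape[1:] != subject.shape:
        raise ValueError("subject and control maps must share a grid")

    d = controls - subject[None]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    df = n - 1

    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    t = np.where(zero_var, np.where(mean > 0, np.inf, np.where(mean < 0, -np.inf, 0.0)), t)

    if tail == "controls_greater":
        p = sps.t.sf(t, df)
    else:
        p = sps.t.cdf(t, df)
    sig = p < alpha
    if valid_mask is not None:
        sig &= valid_mask
    return VoxelTestResult(t=t, p=p, significant=sig, tail=tail, df=df, alpha=alpha)


def difference_volume(sig_mask: np.ndarray, region: np.ndarray | None = None) -> int:
    """Count of significant voxels, optionally restricted to a region."""
    m = np.asarray(sig_mask, dtype=bool)
    if region is not None:
        m = m & np.asarray(region, dtype=bool)
    return int(np.count_nonzero(m))


def ldv(count: int) -> float:
    """Logarithmic difference volume: ln(count).

    A zero count propagates as NaN (missing — excluded from regressions),
    never -inf.
    """
    if count < 0:
        raise ValueError("difference volume cannot be negative")
    if count == 0:
        return float("nan")
    return float(np.log(count))


# ---------------------------------------------------------------------------
# regressions


@dataclass
class RegressionResult:
    """OLS fit summary.  ``coef`` includes the intercept first."""

    coef: np.ndarray
    r_squared: float
    f_stat: float
    p_value: float
    n: int
    predictor_names: tuple[str, ...]
    coef_pvalues: np.ndarray = field(default=None)  # type: ignore[assignment]
    significant: dict | None = None
    corrected_alpha: float | None = None


def _drop_missing(x: np.ndarray, y: np.ndarray):
    keep = np.all(np.isfinite(x), axis=1) & np.isfinite(y)
    return x[keep], y[keep]


def simple_regression(x, y) -> RegressionResult:
    """OLS of y on a single predictor; slope significance by F-test.

    NaN rows (missing LDVs) are dropped.  A constant predictor raises.
    """
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    y = np.asarray(y, dtype=float).ravel()
    x, y = _drop_missing(x, y)
    if x.shape[0] < 3:
        raise ValueError("simple regression needs >= 3 complete observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        coef=np.asarray(model.params),
        r_squared=float(model.rsquared),
        f_stat=float(model.fvalue),
        p_value=float(model.f_pvalue),
        n=int(model.nobs),
        predictor_names=("x",),
        coef_pvalues=np.asarray(model.pvalues),
    )


def multiple_regression(
    predictors, y, m_corrections: int = 3, alpha: float = 0.05
) -> RegressionResult:
    """OLS of y on several predictors with Bonferroni-corrected per-coefficient
    significance at ``alpha / m_corrections`` (m defaults to the number of
    DTI metrics, 3)."""
    if isinstance(predictors, pd.DataFrame):
        names = tuple(str(c) for c in predictors.columns)
        x = predictors.to_numpy(dtype=float)
    else:
        x = np.asarray(predictors, dtype=float)
        if x.ndim == 1:
            x = x.reshape(-1, 1)
        names = tuple(f"x{i}" for i in range(x.shape[1]))
    y = np.asarray(y, dtype=float).ravel()
    x, y = _drop_missing(x, y)
    if x.shape[0] <= x.shape[1] + 1:
        raise ValueError("not enough observations for the number of predictors")
    for j in range(x.shape[1]):
        if np.ptp(x[:, j]) == 0:
            raise ValueError(f"constant predictor: {names[j]!r}")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    corrected = alpha / m_corrections
    pvals = np.asarray(model.pvalues)
    sig = {names[j]: bool(pvals[j + 1] < corrected) for j in range(x.shape[1])}
    return RegressionResult(
        coef=np.asarray(model.params),
        r_squared=float(model.rsquared),
        f_stat=float(model.fvalue),
        p_value=float(model.f_pvalue),
        n=int(model.nobs),
        predictor_names=names,
        coef_pvalues=pvals,
        significant=sig,
        corrected_alpha=corrected,
    )


# ---------------------------------------------------------------------------
# ROI analysis


def _stars(p: float, m: int) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01 / m:
        return "**"
    if p < 0.05 / m:
        return "*"
    return ""


def roi_analysis(
    metric_maps: dict,
    sig_masks: dict,
    label_image: np.ndarray,
    fm_scores,
    nonzero_masks: list | None = None,
    m_corrections: int = 3,
) -> pd.DataFrame:
    """Per-ROI regressions of LDV and regional means against FM scores.

    Parameters
    ----------
    metric_maps:
        ``{metric_name: [3D array per subject]}`` metric maps in the common
        analysis space.
    sig_masks:
        ``{metric_name: [3D bool array per subject]}`` per-subject
        significance masks from the voxel-wise group tests.
    label_image:
        Integer-coded ROI labels on the analysis grid (0 = outside).
    fm_scores:
        Per-subject Fugl-Meyer totals (same order as the map lists).
    nonzero_masks:
        Optional per-subject masks restricting the "nonzero" regional mean
        (the mean is always also computed over all ROI voxels).

    Returns one row per (ROI label, metric) with the significant-voxel count
    and LDV per subject summarised through their regression on FM, regional
    means regressed on FM, and star flags at the two corrected significance
    levels (p < 0.05/m and p < 0.01/m; a second pair additionally corrects
    for the number of ROIs).  Empty ROIs yield rows of missing values.
    """
    labels = np.asarray(label_image)
    fm = np.asarray(fm_scores, dtype=float)
    rois = sorted(int(v) for v in np.unique(labels) if v != 0)
    n_rois = max(len(rois), 1)
    records = []
    for roi in rois:
        region = labels == roi
        empty = not np.any(region)
        for metric, maps in metric_maps.items():
            row: dict = {"roi": roi, "metric": metric, "n_voxels": int(region.sum())}
            if empty:
                records.append(row)
                continue
            counts = [difference_volume(m_, region) for m_ in sig_masks[metric]]
            ldvs = np.array([ldv(c) for c in counts])
            row["mean_count"] = float(np.mean(counts))
            try:
                reg = simple_regression(ldvs, fm)
                row["ldv_r2"], row["ldv_p"] = reg.r_squared, reg.p_value
            except ValueError:
                row["ldv_r2"], row["ldv_p"] = np.nan, np.nan

            means_all = np.array([m_[region].mean() for m_ in maps])
            if nonzero_masks is not None:
                means_nz = np.array(
                    [
                        m_[region & nz].mean() if np.any(region & nz) else np.nan
                        for m_, nz in zip(maps, nonzero_masks)
                    ]
                )
            else:
                means_nz = np.array(
                    [
                        m_[region & (m_ != 0)].mean()
                        if np.any(region & (m_ != 0))
                        else np.nan
                        for m_ in maps
                    ]
                )
            for tag, means in (("mean_all", means_all), ("mean_nonzero", means_nz)):
                try:
                    reg = simple_regression(means, fm)
                    row[f"{tag}_r2"], row[f"{tag}_p"] = reg.r_squared, reg.p_value
                except ValueError:
                    row[f"{tag}_r2"], row[f"{tag}_p"] = np.nan, np.nan

            p = row.get("mean_all_p", np.nan)
            row["star_metrics"] = _stars(p, m_corrections)
            row["star_metrics_rois"] = _stars(p, m_corrections * n_rois)
            records.append(row)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# FA correlation and threshold sweep


def metric_fa_correlation(metric_map, fa_map, fa_floor: float = 0.15) -> float:
    """R^2 of the OLS between a metric and FA over voxels with FA > floor."""
    metric = _as_array(metric_map).ravel()
    fa = _as_array(fa_map).ravel()
    if metric.shape != fa.shape:
        raise ValueError("metric and FA maps must share a grid")
    keep = fa > fa_floor
    if np.count_nonzero(keep) < 3:
        raise ValueError("fewer than 3 voxels above the FA floor")
    return simple_regression(fa[keep], metric[keep]).r_squared


def fa_threshold_sweep(
    tensor_field: TensorField,
    roi_mask: np.ndarray,
    thresholds=None,
    params: TrackingParams = TrackingParams(),
    visc_params: ViscParams = ViscParams(),
) -> tuple[pd.DataFrame, dict]:
    """Mean VISC of an ROI across tractography FA stopping thresholds.

    Runs seeding, tracking, length filtering and connectivity per threshold
    (default 0.10 ... 0.40 in 0.05 steps) and reports the ROI mean VISC, its
    natural log, and the log-linear fit (correlation R of log mean VISC with
    threshold).  Rows with zero mean VISC are excluded from the log fit.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.10, 0.401, 0.05), 10)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly ascending")
    roi = np.asarray(roi_mask, dtype=bool)
    if not np.any(roi):
        raise ValueError("empty ROI")

    from .connectivity import VoxelGrid

    grid = VoxelGrid(tensor_field.shape, tensor_field.voxel_size)
    fa_map = compute_fa(tensor_field)
    rows = []
    for thr in thresholds:
        p = _dc_replace(params, fa_stop=float(thr))
        seeds = generate_seeds(fa_map, p)
        if seeds.shape[0] == 0:
            mean_visc = 0.0
        else:
            fibers = filter_fibers(track_all(seeds, tensor_field, fa_map, p), p)
            graph = build_direct(fibers, grid)
            visc = compute_visc(graph, visc_params)
            mean_visc = float(visc.values[roi].mean())
        rows.append(
            {
                "fa_threshold": float(thr),
                "mean_visc": mean_visc,
                "log_mean_visc": float(np.log(mean_visc)) if mean_visc > 0 else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    fit: dict = {"r": np.nan, "slope": np.nan, "intercept": np.nan}
    ok = np.isfinite(table["log_mean_visc"])
    if ok.sum() >= 3 and table.loc[ok, "log_mean_visc"].nunique() > 1:
        x = table.loc[ok, "fa_threshold"].to_numpy()
        yv = table.loc[ok, "log_mean_visc"].to_numpy()
        slope, intercept = np.polyfit(x, yv, 1)
        r = float(np.corrcoef(x, yv)[0, 1])
        fit = {"r": r, "slope": float(slope), "intercept": float(intercept)}
    elif ok.sum() < 3:
        warnings.warn("too few nonzero sweep rows for a log-linear fit", stacklevel=2)
    return table, fit
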