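"""Agreement metrics, clinical classification and nonparametric tests.

Per aligned sample the absolute error is EA = |θ_sensor − θ_gold| and a
movement's dispersion is summarized by the root mean square of the
absolute error, RMSAE = sqrt((x₁² + ... + xₙ²)/n).

Accuracy is banded against the clinical reference (CR) — the published
human goniometry error of 12.78 ± 7.44° — using a movement's median
absolute error m and its standard deviation s:

* excellent  if m + s < CR,
* good       if m < CR,
* moderate   if m exceeds CR by at most 5°,
* poor       otherwise.

Correlation strength uses the Portney–Watkins Pearson bands
(poor < 0.5 ≤ moderate < 0.75 ≤ good < 0.9 ≤ excellent).  Because the
error data are not normally distributed, sensors are compared with
Friedman's rank sum across paired executions and pairwise Wilcoxon
signed-rank tests, reported with the usual significance tiers
("*" for p < 0.05, "**" for p < 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

from .errors import UndefinedCorrelationError
from .series import AngleSeries


@dataclass
class ErrorSeries:
    """Per-sample absolute error (degrees) for one sensor vs the gold stream."""

    values: np.ndarray
    movement_code: str | None = None
    sensor: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("absolute errors cannot be negative")

    def __len__(self) -> int:
        return self.values.size

    @property
    def median(self) -> float:
        return float(np.median(self.values))


@dataclass(frozen=True)
class ClinicalReference:
    """Human measurement error in the clinical environment, degrees."""

    mean: float = 12.78
    sd: float = 7.44
    moderate_margin: float = 5.0


CLINICAL_REFERENCE = ClinicalReference()


def absolute_error(sensor: AngleSeries, gold: AngleSeries) -> ErrorSeries:
    """Elementwise |θ_sensor − θ_gold|; the series must be aligned."""
    if len(sensor) != len(gold):
        raise ValueError(
            f"series lengths differ ({len(sensor)} vs {len(gold)}): not aligned"
        )
    return ErrorSeries(
        values=np.abs(sensor.values - gold.values),
        movement_code=sensor.movement_code or gold.movement_code,
        sensor=sensor.source,
    )


def rms_error(errors: ErrorSeries | np.ndarray) -> float:
    """Root mean square of the absolute error: sqrt(sum(x_i^2)/n)."""
    x = errors.values if isinstance(errors, ErrorSeries) else np.asarray(errors, float)
    if x.size == 0:
        raise ValueError("cannot take the RMS of an empty error series")
    return float(np.sqrt(np.mean(np.square(x))))


def classify_error(
    median: float, sd: float, ref: ClinicalReference = CLINICAL_REFERENCE
) -> str:
    """Band a median ± SD absolute error against the clinical reference.

    Only the median (not median + SD) is compared for the good/moderate
    boundary; the SD enters solely the excellent criterion.
    """
    if median < 0 or sd < 0:
        raise ValueError("median and SD must be non-negative")
    if median + sd < ref.mean:
        return "excellent"
    if median < ref.mean:
        return "good"
    if median <= ref.mean + ref.moderate_margin:
        return "moderate"
    return "poor"


PEARSON_BANDS = (
    (0.9, "excellent"),
    (0.75, "good"),
    (0.5, "moderate"),
    (float("-inf"), "poor"),
)


def pearson_band(sensor: AngleSeries | np.ndarray, gold: AngleSeries | np.ndarray):
    """Pearson r between aligned angle series plus its Portney–Watkins band."""
    x = sensor.values if isinstance(sensor, AngleSeries) else np.asarray(sensor, float)
    y = gold.values if isinstance(gold, AngleSeries) else np.asarray(gold, float)
    if x.size != y.size:
        raise ValueError("series must be aligned (equal lengths)")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero-variance series: correlation undefined")
    r = float(sst.pearsonr(x, y).statistic)
    return r, band_for_r(r)


def band_for_r(r: float) -> str:
    for cut, label in PEARSON_BANDS:
        if r >= cut:
            return label
    raise AssertionError("unreachable")


def significance_tier(p: float) -> str:
    """Printed significance tier: '**' for p < 0.001, '*' for p < 0.05."""
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class RankTestResult:
    friedman_statistic: float
    friedman_p: float
    friedman_tier: str
    wilcoxon: pd.DataFrame  # columns: sensor_a, sensor_b, statistic, p, tier


def rank_tests(errors_by_sensor: dict[str, np.ndarray]) -> RankTestResult:
    """Friedman rank sum across sensors plus pairwise Wilcoxon post hoc.

    ``errors_by_sensor`` maps sensor name → per-execution error summary
    (one value per execution, paired across sensors), so the blocking
    unit is the movement execution.  Requires at least three sensors and
    equal group sizes.
    """
    names = list(errors_by_sensor)
    groups = [np.asarray(errors_by_sensor[n], float) for n in names]
    if len(groups) < 3:
        raise ValueError("Friedman's test needs at least three paired groups")
    sizes = {g.size for g in groups}
    if len(sizes) != 1:
        raise ValueError(f"groups must be equally sized, got sizes {sorted(sizes)}")
    if groups[0].size < 2:
        raise ValueError("need at least two paired executions")

    if all(np.array_equal(groups[0], g) for g in groups[1:]):
        # identical groups carry no rank information; scipy rejects them
        stat, p = 0.0, 1.0
    else:
        stat, p = sst.friedmanchisquare(*groups)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = groups[i], groups[j]
            if np.array_equal(a, b):
                w, pw = 0.0, 1.0
            else:
                w, pw = sst.wilcoxon(a, b)
            rows.append(
                {
                    "sensor_a": names[i],
                    "sensor_b": names[j],
                    "statistic": float(w),
                    "p": float(pw),
                    "tier": significance_tier(float(pw)),
                }
            )
    return RankTestResult(
        friedman_statistic=float(stat),
        friedman_p=float(p),
        friedman_tier=significance_tier(float(p)),
        wilcoxon=pd.DataFrame(rows),
    )


def normality_p(values: np.ndarray) -> float:
    """Shapiro–Wilk p-value, the pre-check that routes to rank tests."""
    return float(sst.shapiro(np.asarray(values, float)).pvalue)


def mean_of_medians(per_movement: pd.Series | np.ndarray) -> tuple[float, float]:
    """Arithmetic mean ± sample (n−1) SD of per-movement summary values.

    This is the aggregation convention of the study's summary rows: each
    movement contributes its median (or RMS, or r) once, and the group
    row is the mean of those values with the sample standard deviation.
    A single-movement group has no dispersion and returns SD = NaN.
    """
    x = np.asarray(per_movement, float)
    if x.size == 0:
        raise ValueError("empty group")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else float("nan")
    return float(np.mean(x)), sd


@dataclass
class ValidationReport:
    """Full paired comparison of every sensor against the gold stream."""

    per_movement: pd.DataFrame  # movement, limb_group, sensor, median_ae, rmsae, r, ...
    group_summary: pd.DataFrame  # sensor, group, mean/sd of medians, rms, r, label
    rank_tests: dict[str, RankTestResult] = field(default_factory=dict)
    normality_p_value: float | None = None
    meta: dict = field(default_factory=dict)


def summarize_movements(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Per movement × sensor summaries from tidy per-sample errors.

    ``per_sample`` needs columns movement, limb_group, sensor,
    error_deg, and (for correlations) sensor_angle and gold_angle.
    """
    def _one(g: pd.DataFrame) -> pd.Series:
        out = {
            "median_ae": float(np.median(g["error_deg"])),
            "sd_ae": float(np.std(g["error_deg"], ddof=1)) if len(g) > 1 else np.nan,
            "rmsae": rms_error(g["error_deg"].to_numpy()),
            "n_samples": int(len(g)),
        }
        if {"sensor_angle", "gold_angle"} <= set(g.columns):
            r, band = pearson_band(
                g["sensor_angle"].to_numpy(), g["gold_angle"].to_numpy()
            )
            out["pearson_r"] = r
            out["pearson_band"] = band
        return pd.Series(out)

    return (
        per_sample.groupby(["movement", "limb_group", "sensor"], sort=True)
        .apply(_one, include_groups=False)
        .reset_index()
    )


def aggregate_report(
    per_sample: pd.DataFrame,
    ref: ClinicalReference = CLINICAL_REFERENCE,
    execution_column: str = "execution",
) -> ValidationReport:
    """Build the full validation report from tidy per-sample errors.

    Group rows follow the study's convention: for each limb group the
    arithmetic mean ± sample SD of the per-movement median errors (and
    RMS, and r); the all-data row pools the upper- and lower-limb
    per-movement values.  The classification label is computed from each
    group's mean-of-medians and its SD against the clinical reference.
    """
    per_movement = summarize_movements(per_sample)

    rows = []
    for sensor, sg in per_movement.groupby("sensor"):
        groups = {"all data": sg}
        for limb, lg in sg.groupby("limb_group"):
            groups[f"{limb} limbs"] = lg
        for group_name, g in groups.items():
            mean_med, sd_med = mean_of_medians(g["median_ae"])
            row = {
                "sensor": sensor,
                "group": group_name,
                "n_movements": int(len(g)),
                "median_ae_mean": mean_med,
                "median_ae_sd": sd_med,
                "classification": classify_error(
                    mean_med, 0.0 if np.isnan(sd_med) else sd_med, ref
                ),
            }
            row["rmsae_mean"], row["rmsae_sd"] = mean_of_medians(g["rmsae"])
            if "pearson_r" in g.columns:
                row["pearson_r_mean"], row["pearson_r_sd"] = mean_of_medians(
                    g["pearson_r"]
                )
                row["pearson_band"] = band_for_r(row["pearson_r_mean"])
            rows.append(row)
    group_summary = pd.DataFrame(rows)

    tests: dict[str, RankTestResult] = {}
    if execution_column in per_sample.columns and per_sample["sensor"].nunique() >= 3:
        per_exec = (
            per_sample.groupby(["movement", execution_column, "sensor"])["error_deg"]
            .median()
            .unstack("sensor")
            .dropna()
        )
        if len(per_exec) >= 2:
            tests["all data"] = rank_tests(
                {s: per_exec[s].to_numpy() for s in per_exec.columns}
            )
    return ValidationReport(
        per_movement=per_movement,
        group_summary=group_summary,
        rank_tests=tests,
        normality_p_value=(
            normality_p(per_sample["error_deg"].to_numpy()[:5000])
            if len(per_sample) >= 3
            else None
        ),
    )
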