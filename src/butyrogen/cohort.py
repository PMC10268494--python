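"""Breath-gas and fecal-metabolite cohort pipeline.

The pipeline mirrors a supplement-intervention breath study: CO2-normalize
breath gases, drop gross outliers with Tukey's fences (k = 3 interquartile
ranges), classify each subject-period as methanogenic (MG) from corrected
breath CH4, average each metric per subject within the before/during
periods, and compare MG vs non-MG subject means with two-sided two-sample
t-tests.

Input tables
------------
breath : DataFrame with columns ``subject, semester, period, h2_ppm,
    ch4_ppm, co2_pct`` (one row per breath sample; period is ``before`` or
    ``during``).
fecal : DataFrame with columns ``subject, period, analyte, value`` (long
    form; values normalized to wet weight upstream).

Columns whose names start with ``_`` (e.g. simulation truth columns) are
carried through untouched and never analyzed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .accounting import significance_stars, two_sample_t

NOMINAL_CO2_PCT = 3.5
PERIODS = ("before", "during")


# ---------------------------------------------------------------------------
# Breath normalization
# ---------------------------------------------------------------------------

def normalize_breath(breath: pd.DataFrame, nominal_co2_pct: float = NOMINAL_CO2_PCT
                     ) -> pd.DataFrame:
    """Normalize breath H2 and CH4 to a nominal CO2 percentage.

    Each gas is scaled by ``nominal / co2_pct`` — an alveolar-air correction
    that compensates for dilution of the breath sample.  Adds
    ``h2_norm_ppm`` and ``ch4_norm_ppm`` columns; CO2 <= 0 is an error.
    """
    if (breath["co2_pct"] <= 0).any():
        bad = breath.loc[breath["co2_pct"] <= 0, "subject"].tolist()
        raise ValueError(f"non-positive CO2 percent for subject(s) {bad}: cannot normalize")
    out = breath.copy()
    factor = nominal_co2_pct / out["co2_pct"]
    out["h2_norm_ppm"] = out["h2_ppm"] * factor
    out["ch4_norm_ppm"] = out["ch4_ppm"] * factor
    return out


# ---------------------------------------------------------------------------
# Outlier exclusion
# ---------------------------------------------------------------------------

@dataclass
class TukeyResult:
    values: np.ndarray
    excluded: np.ndarray  # boolean mask, True = excluded
    q1: float
    q3: float
    lower_fence: float
    upper_fence: float

    @property
    def kept(self) -> np.ndarray:
        return self.values[~self.excluded]


def tukey_exclude(values: Sequence[float], k: float = 3.0,
                  quartile_method: str = "linear") -> TukeyResult:
    """Flag values beyond k interquartile ranges outside the quartiles.

    Quartiles use linear interpolation by default (configurable through any
    numpy quantile ``method``).  Fewer than 4 values makes the IQR weakly
    defined; a warning is raised but the fences are still applied.
    """
    arr = np.asarray(values, float)
    if arr.size == 0:
        raise ValueError("tukey_exclude needs at least one value")
    if arr.size < 4:
        warnings.warn(f"only {arr.size} values: interquartile range is weakly defined",
                      stacklevel=2)
    q1, q3 = np.quantile(arr, [0.25, 0.75], method=quartile_method)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    excluded = (arr < lo) | (arr > hi)
    return TukeyResult(values=arr, excluded=excluded, q1=float(q1), q3=float(q3),
                       lower_fence=float(lo), upper_fence=float(hi))


# ---------------------------------------------------------------------------
# Methanogen classification
# ---------------------------------------------------------------------------

@dataclass
class MethanogenStatus:
    subject: str
    period: str
    status: str  # "MG" | "non-MG"
    max_corrected_ch4_ppm: float
    baseline_applied_ppm: float


def classify_methanogenic(breath: pd.DataFrame, threshold_ppm: float = 4.0,
                          baseline_ppm: float = 1.0,
                          baseline_semesters: Iterable[str] = ()) -> pd.DataFrame:
    """Classify each subject-period as methanogenic from corrected breath CH4.

    The semester baseline (an instrument-calibration offset) is subtracted
    from every normalized CH4 value in the listed semesters and floored at
    zero; a subject-period is MG iff any corrected sample is strictly over
    the threshold (default 4 ppm).  Classification is separate for the
    before and during periods.

    Returns a DataFrame ``subject, period, status, max_corrected_ch4_ppm,
    baseline_applied_ppm``.
    """
    if "ch4_norm_ppm" not in breath.columns:
        breath = normalize_breath(breath)
    baseline_semesters = set(baseline_semesters)
    rows = []
    for (subject, period), grp in breath.groupby(["subject", "period"], sort=True):
        if len(grp) == 0:
            continue
        if "semester" in grp.columns:
            applied = grp["semester"].isin(baseline_semesters).map(
                {True: baseline_ppm, False: 0.0})
        else:
            applied = pd.Series(0.0, index=grp.index)
        corrected = (grp["ch4_norm_ppm"] - applied).clip(lower=0.0)
        max_corr = float(corrected.max())
        rows.append({
            "subject": subject,
            "period": period,
            "status": "MG" if max_corr > threshold_ppm else "non-MG",
            "max_corrected_ch4_ppm": max_corr,
            "baseline_applied_ppm": float(applied.max()),
        })
    if not rows:
        raise ValueError("no breath samples to classify")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Subject-period averaging and group comparison
# ---------------------------------------------------------------------------

def subject_period_means(samples: pd.DataFrame, value_col: str, k: float = 3.0,
                         quartile_method: str = "linear") -> pd.DataFrame:
    """Per-subject arithmetic mean per period, after metric-wide outlier removal.

    Tukey's fences are applied once across *all* samples of the metric (not
    per subject), then means are taken per subject-period.  Subjects whose
    samples were all excluded in a period are dropped with a warning.
    """
    df = samples.dropna(subset=[value_col])
    res = tukey_exclude(df[value_col].to_numpy(), k=k, quartile_method=quartile_method)
    kept = df.loc[~res.excluded]
    dropped = set(map(tuple, df[["subject", "period"]].drop_duplicates().to_numpy())) - \
        set(map(tuple, kept[["subject", "period"]].drop_duplicates().to_numpy()))
    if dropped:
        warnings.warn(f"all samples excluded for subject-period(s) {sorted(dropped)}",
                      stacklevel=2)
    out = (kept.groupby(["subject", "period"], sort=True)[value_col]
           .mean().rename("mean").reset_index())
    return out


@dataclass
class GroupComparison:
    """MG vs non-MG comparison of subject-period means for one metric."""

    metric: str
    period: str
    mg: np.ndarray
    non_mg: np.ndarray
    t: float
    p: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p)

    def row(self) -> dict:
        return {
            "metric": self.metric, "period": self.period,
            "n_MG": len(self.mg), "n_nonMG": len(self.non_mg),
            "mean_MG": self.mg.mean(),
            "sem_MG": self.mg.std(ddof=1) / np.sqrt(len(self.mg)),
            "mean_nonMG": self.non_mg.mean(),
            "sem_nonMG": self.non_mg.std(ddof=1) / np.sqrt(len(self.non_mg)),
            "t": self.t, "p": self.p, "stars": self.stars,
        }

    def summary(self) -> str:
        r = self.row()
        return (f"{self.metric} ({self.period}): "
                f"MG {r['mean_MG']:.3g} +/- {r['sem_MG']:.2g} (n={r['n_MG']}) vs "
                f"non-MG {r['mean_nonMG']:.3g} +/- {r['sem_nonMG']:.2g} (n={r['n_nonMG']}); "
                f"t={self.t:.3f}, p={self.p:.4g} {self.stars}")


def compare_mg_groups(means: pd.DataFrame, status: pd.DataFrame, metric: str,
                      period: str, exclude_subjects: Iterable[str] = ()) -> GroupComparison:
    """Two-sided t-test of MG vs non-MG subject means for one period.

    ``means`` comes from `subject_period_means`; ``status`` from
    `classify_methanogenic` (matched on subject within the same period).
    ``exclude_subjects`` supports explicit removal of flagged observations.
    """
    st = status.loc[status["period"] == period, ["subject", "status"]]
    m = means.loc[means["period"] == period].merge(st, on="subject", how="inner")
    m = m.loc[~m["subject"].isin(set(exclude_subjects))]
    mg = m.loc[m["status"] == "MG", "mean"].to_numpy()
    non_mg = m.loc[m["status"] == "non-MG", "mean"].to_numpy()
    if len(mg) < 2 or len(non_mg) < 2:
        raise ValueError(
            f"degenerate groups for {metric!r} in period {period!r}: "
            f"MG n={len(mg)}, non-MG n={len(non_mg)}"
        )
    t, p = two_sample_t(mg, non_mg)
    return GroupComparison(metric=metric, period=period, mg=mg, non_mg=non_mg, t=t, p=p)


def period_contrast(means: pd.DataFrame, paired: bool = True) -> tuple[float, float]:
    """During vs before contrast of subject means for one metric.

    Exposed in both paired (per-subject differences) and unpaired flavors,
    since a before/during design supports either reading.  Returns (t, p).
    """
    from scipy import stats

    wide = means.pivot(index="subject", columns="period", values="mean")
    if paired:
        both = wide.dropna(subset=["before", "during"])
        if len(both) < 2:
            raise ValueError("paired contrast needs >= 2 subjects with both periods")
        t, p = stats.ttest_rel(both["during"], both["before"])
        return float(t), float(p)
    return two_sample_t(wide["during"].dropna(), wide["before"].dropna())


def analyze_cohort(breath: pd.DataFrame, fecal: pd.DataFrame | None = None,
                   threshold_ppm: float = 4.0, baseline_ppm: float = 1.0,
                   baseline_semesters: Iterable[str] = (), k: float = 3.0,
                   exclude_subjects: Iterable[str] = ()) -> pd.DataFrame:
    """End-to-end cohort pipeline; returns a tidy MG vs non-MG comparison table.

    Steps: normalize breath gases, classify methanogenesis per period,
    Tukey-exclude per metric, average per subject-period, and run the MG vs
    non-MG t-test for every metric in both periods.  Metrics are breath H2
    and CH4 plus every fecal analyte present.
    """
    breath = normalize_breath(breath)
    status = classify_methanogenic(breath, threshold_ppm=threshold_ppm,
                                   baseline_ppm=baseline_ppm,
                                   baseline_semesters=baseline_semesters)
    metrics: list[tuple[str, pd.DataFrame, str]] = [
        ("breath_h2_ppm", breath, "h2_norm_ppm"),
        ("breath_ch4_ppm", breath, "ch4_norm_ppm"),
    ]
    if fecal is not None and len(fecal):
        for analyte, grp in fecal.groupby("analyte"):
            metrics.append((f"fecal_{analyte}", grp.rename(columns={"value": analyte}), analyte))

    rows = []
    for name, table, col in metrics:
        means = subject_period_means(table, col, k=k)
        for period in PERIODS:
            if period not in set(means["period"]):
                continue
            try:
                cmp_ = compare_mg_groups(means, status, name, period,
                                         exclude_subjects=exclude_subjects)
            except ValueError:
                continue  # degenerate group in this period; skip the row
            rows.append(cmp_.row())
    return pd.DataFrame(rows)
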