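"""Nonparametric comparison battery for cohort feature tables.

Three families of analyses compare the nine per-channel features:

* **transducer contrasts** — 16 Wilcoxon signed-rank tests on per-swallow
  paired differences (8 features x {AP vs SOUND, SI vs SOUND}); duration is
  excluded because the segmentation, and hence the duration, is shared by
  construction.  Family-wise Bonferroni threshold 0.05/16, reported to three
  decimals as 0.003.
* **sex contrasts** — 25 Wilcoxon rank-sum tests (8 features x 3 channels
  plus duration), male vs female, at the Bonferroni threshold 0.05/25 =
  0.002.  By default swallows are aggregated to per-subject medians first so
  subjects, not swallows, are the independent units.
* **age regressions** — ordinary least squares of each feature on age,
  stratified by sex; only the variance explained (r^2) is reported, with no
  significance claim, since small cohorts lack the power to grade such small
  effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .errors import ConfigurationError, PairingError, ParameterError
from .features import PER_CHANNEL_FEATURES

__all__ = [
    "StatTestResult",
    "RegressionResult",
    "bonferroni_alpha",
    "transducer_tests",
    "sex_tests",
    "age_regressions",
    "summarize",
    "wavelet_energy_profile",
]

ACCEL_CHANNELS = ("AP", "SI")
ALL_CHANNELS = ("AP", "SI", "SOUND")


@dataclass(frozen=True)
class StatTestResult:
    """Outcome of one hypothesis test in a corrected family."""

    test_id: str
    family: str  # "transducer" | "sex"
    feature: str
    channels: tuple[str, ...]
    statistic: float
    p_value: float
    alpha_corrected: float
    significant: bool
    n: int


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of one feature against age within one sex stratum."""

    feature: str
    channel: str
    slope: float
    intercept: float
    r_squared: float
    sex_stratum: str
    n: int


def bonferroni_alpha(
    family_alpha: float, n_tests: int, decimals: int | None = None
) -> float:
    """Bonferroni-corrected per-test threshold ``family_alpha / n_tests``.

    ``decimals`` optionally rounds the threshold as it would be quoted in a
    report (0.05/16 = 0.003125 -> 0.003).
    """
    if n_tests < 1:
        raise ParameterError(f"n_tests must be >= 1, got {n_tests}")
    alpha = family_alpha / n_tests
    if decimals is not None:
        alpha = round(alpha, decimals)
    return alpha


def _results_to_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "test_id": r.test_id,
                "family": r.family,
                "feature": r.feature,
                "channels": "+".join(r.channels),
                "statistic": r.statistic,
                "p_value": r.p_value,
                "alpha_corrected": r.alpha_corrected,
                "significant": r.significant,
                "n": r.n,
            }
        )
    return pd.DataFrame(rows)


def results_table(results) -> pd.DataFrame:
    """Flatten a list of :class:`StatTestResult` into a DataFrame."""
    return _results_to_frame(results)


def _pivot(table: pd.DataFrame) -> pd.DataFrame:
    """Wide per-swallow view: rows (subject, swallow), columns (channel, feature)."""
    return table.pivot_table(
        index=["subject_id", "swallow_idx"],
        columns=["channel", "feature"],
        values="value",
        aggfunc="first",
    )


def _wilcoxon_paired(diff: np.ndarray) -> tuple[float, float]:
    """Signed-rank test on paired differences, zero-discard convention.

    All-zero differences carry no evidence against the null and report p=1.
    Exact p-values for 25 or fewer nonzero pairs, normal approximation with
    continuity correction above that.
    """
    nz = diff[diff != 0.0]
    if len(nz) == 0:
        return 0.0, 1.0
    method = "exact" if len(nz) <= 25 else "approx"
    try:
        res = spstats.wilcoxon(
            nz, zero_method="wilcox", correction=True, method=method
        )
    except ValueError:
        return 0.0, 1.0
    return float(res.statistic), float(res.pvalue)


def transducer_tests(
    table: pd.DataFrame, family_alpha: float = 0.05
) -> list[StatTestResult]:
    """Paired accelerometer-vs-sound contrasts: 16 Wilcoxon signed-rank tests.

    Each of the 8 per-channel features is compared between each accelerometer
    axis and the sound channel on per-swallow pairs.  Rows missing either
    side of a pair raise :class:`PairingError`.
    """
    wide = _pivot(table.dropna(subset=["value"]))
    present = set(wide.columns.get_level_values(0))
    if "SOUND" not in present:
        raise ConfigurationError("transducer tests need a SOUND channel")
    axes = [a for a in ACCEL_CHANNELS if a in present]
    if not axes:
        raise ConfigurationError("transducer tests need an accelerometer channel")
    n_tests = len(PER_CHANNEL_FEATURES) * len(ACCEL_CHANNELS)  # 16 by design
    alpha = bonferroni_alpha(family_alpha, n_tests, decimals=3)
    results = []
    for axis in axes:
        for feature in PER_CHANNEL_FEATURES:
            try:
                a = wide[(axis, feature)]
                b = wide[("SOUND", feature)]
            except KeyError as exc:
                raise PairingError(
                    f"feature {feature!r} missing for {axis} or SOUND"
                ) from exc
            pair = pd.concat([a, b], axis=1).dropna()
            if pair.empty:
                raise PairingError(f"no complete pairs for {axis} vs SOUND {feature}")
            diff = pair.iloc[:, 0].to_numpy() - pair.iloc[:, 1].to_numpy()
            stat, p = _wilcoxon_paired(diff)
            results.append(
                StatTestResult(
                    test_id=f"transducer:{axis}-SOUND:{feature}",
                    family="transducer",
                    feature=feature,
                    channels=(axis, "SOUND"),
                    statistic=stat,
                    p_value=p,
                    alpha_corrected=alpha,
                    significant=p < alpha,
                    n=len(pair),
                )
            )
    return results


def _subject_medians(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse swallows to per-subject medians, keeping sex and age."""
    return (
        table.groupby(["subject_id", "sex", "age", "channel", "feature"], sort=True)[
            "value"
        ]
        .median()
        .reset_index()
    )


def _ranksum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    method = "exact" if max(len(x), len(y)) <= 25 else "asymptotic"
    try:
        res = spstats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:  # e.g. ties with exact method
        res = spstats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def sex_tests(
    table: pd.DataFrame,
    family_alpha: float = 0.05,
    per_subject: bool = True,
) -> list[StatTestResult]:
    """Male-vs-female contrasts: 25 Wilcoxon rank-sum tests.

    8 features x 3 channels plus one duration test, at the Bonferroni
    threshold ``family_alpha / 25``.  With ``per_subject`` (default) the unit
    of analysis is the subject via median aggregation; ``per_subject=False``
    pools swallows for sensitivity analysis.
    """
    data = table.dropna(subset=["value"])
    sexes = set(data["sex"].unique())
    if not {"male", "female"} <= sexes:
        raise ConfigurationError("sex tests require both male and female subjects")
    if per_subject:
        data = _subject_medians(data)
    n_tests = len(PER_CHANNEL_FEATURES) * len(ALL_CHANNELS) + 1  # 25 by design
    alpha = bonferroni_alpha(family_alpha, n_tests, decimals=3)
    contrasts = [("ALL", "duration_s")] + [
        (ch, f) for ch in ALL_CHANNELS for f in PER_CHANNEL_FEATURES
    ]
    results = []
    for channel, feature in contrasts:
        sub = data[(data["channel"] == channel) & (data["feature"] == feature)]
        x = sub.loc[sub["sex"] == "male", "value"].to_numpy()
        y = sub.loc[sub["sex"] == "female", "value"].to_numpy()
        if len(x) == 0 or len(y) == 0:
            raise ConfigurationError(f"no data for sex contrast {channel}:{feature}")
        stat, p = _ranksum(x, y)
        results.append(
            StatTestResult(
                test_id=f"sex:{channel}:{feature}",
                family="sex",
                feature=feature,
                channels=(channel,),
                statistic=stat,
                p_value=p,
                alpha_corrected=alpha,
                significant=p < alpha,
                n=len(x) + len(y),
            )
        )
    return results


def age_regressions(
    table: pd.DataFrame, per_subject: bool = True
) -> list[RegressionResult]:
    """OLS of each feature on age, stratified by sex.

    Returns slope, intercept and r^2 per feature x channel x sex stratum.
    Constant features regress to slope 0 with r^2 = 0; a stratum with fewer
    than three distinct ages is an error.
    """
    data = table.dropna(subset=["value"])
    if per_subject:
        data = _subject_medians(data)
    contrasts = [("ALL", "duration_s")] + [
        (ch, f) for ch in ALL_CHANNELS for f in PER_CHANNEL_FEATURES
    ]
    results = []
    for sex in ("male", "female"):
        stratum = data[data["sex"] == sex]
        if stratum.empty:
            continue
        if stratum["age"].nunique() < 3:
            raise ParameterError(f"stratum {sex!r} has fewer than 3 distinct ages")
        for channel, feature in contrasts:
            sub = stratum[
                (stratum["channel"] == channel) & (stratum["feature"] == feature)
            ]
            if sub.empty:
                continue
            age = sub["age"].to_numpy(dtype=float)
            val = sub["value"].to_numpy(dtype=float)
            if np.ptp(age) == 0:
                raise ParameterError("constant age within stratum")
            if np.ptp(val) == 0:
                slope, intercept, r2 = 0.0, float(val[0]), 0.0
            else:
                fit = spstats.linregress(age, val)
                slope, intercept = float(fit.slope), float(fit.intercept)
                r2 = float(fit.rvalue**2)
            results.append(
                RegressionResult(
                    feature=feature,
                    channel=channel,
                    slope=slope,
                    intercept=intercept,
                    r_squared=r2,
                    sex_stratum=sex,
                    n=len(sub),
                )
            )
    return results


def regressions_table(results) -> pd.DataFrame:
    """Flatten a list of :class:`RegressionResult` into a DataFrame."""
    return pd.DataFrame(
        [
            {
                "sex_stratum": r.sex_stratum,
                "channel": r.channel,
                "feature": r.feature,
                "slope": r.slope,
                "intercept": r.intercept,
                "r_squared": r.r_squared,
                "n": r.n,
            }
            for r in results
        ]
    )


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD per feature x channel x sex, report-table style.

    Returns a long frame with columns (sex, feature, channel, mean, sd, n);
    duration appears under channel ``ALL``.
    """
    data = table.dropna(subset=["value"])
    if data.empty:
        raise ParameterError("cannot summarise an empty table")
    g = data.groupby(["sex", "feature", "channel"])["value"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)  # single-value cells
    return out


def wavelet_energy_profile(
    level_energy_table: pd.DataFrame,
) -> pd.DataFrame:
    """Mean and SD of relative wavelet energies per level per channel.

    Expects a long frame with columns (channel, level, rel_energy) where
    ``level`` labels the decomposition bands (a_L, d_L..d_1); yields the
    energy-profile summary used for decomposition bar plots.
    """
    g = level_energy_table.groupby(["channel", "level"])["rel_energy"]
    return g.agg(mean="mean", sd="std").reset_index()
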