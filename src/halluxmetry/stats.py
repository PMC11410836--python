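"""Validation statistics for automatic vs manual angle measurements.

Implements the full agreement analysis used to validate the automatic
goniometer: per-parameter mean absolute error (MAE) of the automatic
measurement against the median of three human raters, a one-sample
one-tailed t-test of MAE against the 3-degree acceptability margin, error
bands (<3, 3-5, >5 degrees), the pairwise inter-rater absolute differences
Diff_12 / Diff_23 / Diff_31 and their per-case mean Diff_123, a two-tailed
paired t-test of MAE against Diff_123, and the noncentral-t power analysis
that sizes a validation cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError
from .geometry import AngleSet

#: Table-style parameter order: derived angles first, then per-bone inclinations
PARAMETERS: Tuple[str, ...] = ("HVA", "IMA", "PH1a", "MT1a", "MT2a", "MT3a",
                               "MT4a", "MT5a")

#: acceptability margin for angle errors, degrees
DEFAULT_BOUND_DEG = 3.0


@dataclass(frozen=True)
class CaseMeasurements:
    """One case: the automatic angle set plus the raters' angle sets."""

    case_id: str
    auto: AngleSet
    raters: Tuple[AngleSet, ...]

    def __post_init__(self) -> None:
        if len(self.raters) < 1:
            raise ValueError("at least one rater measurement is required")
        object.__setattr__(self, "raters", tuple(self.raters))


def rater_median(raters: Sequence[AngleSet]) -> AngleSet:
    """Per-parameter median across raters (even counts average the middle two).

    The result is a per-parameter summary: its HVA/IMA fields are medians of
    the raters' HVA/IMA and need not equal differences of the median
    inclinations.
    """
    if len(raters) < 1:
        raise ValueError("at least one rater is required")
    values = {p: float(np.median([r.as_dict()[p] for r in raters]))
              for p in ("PH1a", "MT1a", "MT2a", "MT3a", "MT4a", "MT5a",
                        "HVA", "IMA")}
    return AngleSet(**values)


@dataclass(frozen=True)
class MAETestResult:
    mae: float
    ci95_upper: float
    p_value: float
    n: int


def mae_test(auto: Sequence[float], reference: Sequence[float],
             bound: float = DEFAULT_BOUND_DEG) -> MAETestResult:
    """MAE with one-sided test of H1: mean absolute error < ``bound``.

    ``ci95_upper`` is the one-sided 95% upper confidence bound of the mean
    absolute error, consistent with the one-tailed test.  A zero-variance
    error vector is handled as p = 0 when the MAE is below the bound and
    p = 1 otherwise.
    """
    a = np.asarray(auto, dtype=np.float64)
    r = np.asarray(reference, dtype=np.float64)
    if a.shape != r.shape:
        raise ValueError("auto and reference must be paired by case")
    n = a.size
    if n < 2:
        raise ValueError("at least two cases are required")
    ae = np.abs(a - r)
    mae = float(ae.mean())
    sd = float(ae.std(ddof=1))
    if sd == 0.0:
        p = 0.0 if mae < bound else 1.0
        return MAETestResult(mae=mae, ci95_upper=mae, p_value=p, n=n)
    t_res = sps.ttest_1samp(ae, popmean=bound, alternative="less")
    ci = mae + sps.t.ppf(0.95, n - 1) * sd / np.sqrt(n)
    return MAETestResult(mae=mae, ci95_upper=float(ci),
                         p_value=float(t_res.pvalue), n=n)


def error_bands(ae: Sequence[float]) -> Tuple[int, int, int]:
    """Counts of cases with absolute error in [0, 3), [3, 5] and (5, inf)."""
    x = np.asarray(ae, dtype=np.float64)
    if x.size and x.min() < 0:
        raise ValueError("absolute errors must be non-negative")
    lt3 = int((x < 3.0).sum())
    mid = int(((x >= 3.0) & (x <= 5.0)).sum())
    gt5 = int((x > 5.0).sum())
    return (lt3, mid, gt5)


def interrater_diffs(rater_values: np.ndarray) -> pd.DataFrame:
    """Pairwise absolute rater differences and their per-case mean.

    ``rater_values`` has shape (n_cases, 3), one column per rater.  Returns
    a DataFrame with columns Diff_12, Diff_23, Diff_31, Diff_123.
    """
    v = np.asarray(rater_values, dtype=np.float64)
    if v.ndim != 2 or v.shape[1] != 3:
        raise ValueError("exactly three raters are required")
    d12 = np.abs(v[:, 0] - v[:, 1])
    d23 = np.abs(v[:, 1] - v[:, 2])
    d31 = np.abs(v[:, 2] - v[:, 0])
    return pd.DataFrame({
        "Diff_12": d12, "Diff_23": d23, "Diff_31": d31,
        "Diff_123": (d12 + d23 + d31) / 3.0,
    })


def compare_mae_vs_diff123(ae: Sequence[float], diff123: Sequence[float]) -> float:
    """Two-tailed paired t-test of per-case AE against per-case Diff_123."""
    a = np.asarray(ae, dtype=np.float64)
    d = np.asarray(diff123, dtype=np.float64)
    if a.shape != d.shape:
        raise ValueError("AE and Diff_123 must be paired by case")
    if a.size < 2:
        raise ValueError("at least two cases are required")
    delta = a - d
    if np.all(delta == delta[0]):
        if delta[0] == 0.0:
            return 1.0
        return 0.0
    return float(sps.ttest_rel(a, d).pvalue)


def power_one_sided(n: int, assumed_mae: float, sd: float, bound: float,
                    alpha: float) -> float:
    """Power of the one-sided one-sample t-test of H0: mean >= bound."""
    df = n - 1
    ncp = (assumed_mae - bound) / (sd / np.sqrt(n))
    t_crit = sps.t.ppf(alpha, df)
    return float(sps.nct.cdf(t_crit, df, ncp))


def required_sample_size(assumed_mae: float = 1.5, sd: float = 3.58,
                         bound: float = DEFAULT_BOUND_DEG, power: float = 0.99,
                         alpha: float = 0.05, n_max: int = 1_000_000) -> int:
    """Smallest n at which the one-sided t-test reaches the requested power.

    Iterates the noncentral-t power formula over n.  With the default
    arguments (true MAE 1.5 deg, error SD 3.58 deg, 3-degree margin,
    power 0.99, one-sided alpha 0.05) the answer is 92.
    """
    if not 0.0 < power < 1.0:
        raise ConfigurationError("power must lie in (0, 1)")
    if sd <= 0:
        raise ConfigurationError("sd must be positive")
    if assumed_mae >= bound:
        raise ConfigurationError("assumed_mae must be below the bound (nonzero effect)")
    for n in range(2, n_max + 1):
        if power_one_sided(n, assumed_mae, sd, bound, alpha) >= power:
            return n
    raise ConfigurationError(f"no n <= {n_max} reaches the requested power")


@dataclass(frozen=True)
class ValidationReport:
    """Per-parameter agreement table plus run metadata.

    ``table`` rows follow :data:`PARAMETERS`; columns: MAE, CI95_upper,
    p_vs_bound, n_lt3, n_3to5, n_gt5, Diff_12_mean, Diff_23_mean,
    Diff_31_mean, Diff_123_mean, Diff_123_sd_cases, Diff_123_sd_pairs,
    p_MAE_vs_Diff123.
    """

    table: pd.DataFrame
    n_cases: int
    bound: float


def validation_report(cases: Sequence[CaseMeasurements],
                      bound: float = DEFAULT_BOUND_DEG) -> ValidationReport:
    """Full agreement analysis of automatic vs three-rater manual measurements.

    For each parameter, the automatic value is compared with the per-case
    median of the three raters (MAE, one-tailed t-test against ``bound``,
    error bands) and with the inter-rater spread (Diff statistics, paired
    two-tailed t-test of AE against Diff_123).  Diff_123 dispersion is
    summarized two ways: the SD across cases of per-case Diff_123, and the
    SD across the three pairwise case-averaged differences.
    """
    if len(cases) < 2:
        raise ValueError("at least two cases are required")
    if any(len(c.raters) != 3 for c in cases):
        raise ValueError("the Diff statistics require exactly three raters per case")
    rows = []
    for param in PARAMETERS:
        auto = np.array([c.auto.as_dict()[param] for c in cases])
        rater_vals = np.array([[r.as_dict()[param] for r in c.raters]
                               for c in cases])
        ref = np.median(rater_vals, axis=1)
        res = mae_test(auto, ref, bound=bound)
        ae = np.abs(auto - ref)
        bands = error_bands(ae)
        diffs = interrater_diffs(rater_vals)
        pair_means = diffs[["Diff_12", "Diff_23", "Diff_31"]].mean()
        rows.append({
            "parameter": param,
            "MAE": res.mae,
            "CI95_upper": res.ci95_upper,
            "p_vs_bound": res.p_value,
            "n_lt3": bands[0], "n_3to5": bands[1], "n_gt5": bands[2],
            "Diff_12_mean": float(pair_means["Diff_12"]),
            "Diff_23_mean": float(pair_means["Diff_23"]),
            "Diff_31_mean": float(pair_means["Diff_31"]),
            "Diff_123_mean": float(diffs["Diff_123"].mean()),
            "Diff_123_sd_cases": float(diffs["Diff_123"].std(ddof=1)),
            "Diff_123_sd_pairs": float(pair_means.std(ddof=1)),
            "p_MAE_vs_Diff123": compare_mae_vs_diff123(ae, diffs["Diff_123"]),
        })
    table = pd.DataFrame(rows).set_index("parameter")
    return ValidationReport(table=table, n_cases=len(cases), bound=bound)
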