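"""Pre-clustering statistics on biological read-outs.

Replicate groups are screened for a single outlier with a two-sided Grubbs
test before averaging; assay values measured against a plate/run control
are expressed relative to that control; and each protein source is compared
to the benchmark source per variable with a two-sample t-test (Welch by
default) plus a one-way ANOVA across all sources.

Note on power: with triplicates (n = 3) the Grubbs statistic is bounded by
(n−1)/√n ≈ 1.1547 while the α = 0.05 critical value is ≈ 1.1543, so the
test can only ever flag an outlier when the two remaining values are almost
identical. Screening triplicates is therefore close to a no-op; it gains
real power from n ≥ 4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ion_io import BioReadoutTable


@dataclass(frozen=True)
class GrubbsResult:
    """Outcome of a single two-sided Grubbs test on one replicate group."""

    g_statistic: float
    critical_value: float
    outlier_index: int | None
    alpha: float


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided single-outlier critical value.

    G_crit = ((n−1)/√n) · sqrt(t² / (n−2+t²)) with t the upper α/(2n)
    quantile of Student's t at n−2 degrees of freedom.
    """
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_test(values, alpha: float = 0.05) -> GrubbsResult:
    """Two-sided single-outlier Grubbs test: G = max|x_i − mean| / sd.

    At most one observation is flagged per call; a zero-variance group has
    G defined as 0 and no outlier. Requires n >= 3 finite values.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("Grubbs test needs a 1-D sample with n >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("Grubbs test needs finite values")
    n = len(x)
    sd = x.std(ddof=1)
    crit = float(grubbs_critical_value(n, alpha))
    if sd == 0:
        return GrubbsResult(0.0, crit, None, alpha)
    deviations = np.abs(x - x.mean())
    idx = int(deviations.argmax())
    g = float(deviations[idx] / sd)
    return GrubbsResult(g, crit, idx if g > crit else None, alpha)


def screen_outliers(
    bio: BioReadoutTable, alpha: float = 0.05
) -> tuple[BioReadoutTable, pd.DataFrame]:
    """Apply the Grubbs test once per (source, variable) group.

    Flagged values are removed from the returned table; a flags frame lists
    every removed cell with its statistic and critical value. Groups with
    fewer than 3 replicates are left untouched.
    """
    frame = bio.data
    drop_rows = []
    flags = []
    for (src, var), group in frame.groupby(["source_id", "variable"], sort=False):
        if len(group) < 3:
            continue
        result = grubbs_test(group["value"].to_numpy(), alpha=alpha)
        if result.outlier_index is not None:
            row = group.iloc[result.outlier_index]
            drop_rows.append(row.name)
            flags.append({
                "source_id": src,
                "variable": var,
                "replicate_id": row["replicate_id"],
                "value": row["value"],
                "g_statistic": result.g_statistic,
                "critical_value": result.critical_value,
            })
    cleaned = BioReadoutTable(frame.drop(index=drop_rows))
    columns = ["source_id", "variable", "replicate_id", "value", "g_statistic", "critical_value"]
    return cleaned, pd.DataFrame(flags, columns=columns)


def normalize_to_control(values, control, scale: float = 1.0) -> np.ndarray:
    """Divide each value by the mean of its run's control measurements.

    ``scale`` rescales the ratio (e.g. 100 for percent-viability). The
    control mean must be positive. Scale-equivariant: multiplying values and
    control by the same factor leaves the output unchanged.
    """
    control = np.asarray(control, dtype=float)
    mean = control.mean()
    if not mean > 0:
        raise ValueError(f"control mean must be > 0, got {mean}")
    return np.asarray(values, dtype=float) / mean * scale


@dataclass
class BenchmarkComparison:
    """t-test table (per source vs benchmark, per variable) and per-variable ANOVA."""

    t_tests: pd.DataFrame
    anova: pd.DataFrame


def compare_to_benchmark(
    bio: BioReadoutTable,
    benchmark: str,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> BenchmarkComparison:
    """Test each source against the benchmark per variable; ANOVA across sources.

    ``equal_var=False`` gives Welch's t-test (default); significance is an
    uncorrected p < alpha call. Cells with fewer than 2 replicates after
    outlier screening are marked untestable (NaN statistics).
    """
    if benchmark not in bio.sources:
        raise ValueError(f"benchmark source {benchmark!r} not present in bio table")
    t_rows = []
    a_rows = []
    for var in bio.variables:
        bench_values = bio.values_for(benchmark, var)
        groups = []
        for src in bio.sources:
            values = bio.values_for(src, var)
            if len(values) >= 2:
                groups.append(values)
            if src == benchmark:
                continue
            if len(values) < 2 or len(bench_values) < 2:
                t_rows.append({
                    "source_id": src, "variable": var,
                    "n_source": len(values), "n_benchmark": len(bench_values),
                    "statistic": np.nan, "p_value": np.nan,
                    "significant": False, "testable": False,
                })
                continue
            t_stat, p = stats.ttest_ind(values, bench_values, equal_var=equal_var)
            t_rows.append({
                "source_id": src, "variable": var,
                "n_source": len(values), "n_benchmark": len(bench_values),
                "statistic": float(t_stat), "p_value": float(p),
                "significant": bool(p < alpha), "testable": True,
            })
        if len(groups) >= 2:
            f_stat, p = stats.f_oneway(*groups)
            a_rows.append({
                "variable": var, "n_groups": len(groups),
                "f_statistic": float(f_stat), "p_value": float(p),
                "significant": bool(p < alpha),
            })
        else:
            a_rows.append({
                "variable": var, "n_groups": len(groups),
                "f_statistic": np.nan, "p_value": np.nan, "significant": False,
            })
    return BenchmarkComparison(t_tests=pd.DataFrame(t_rows), anova=pd.DataFrame(a_rows))
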