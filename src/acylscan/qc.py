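"""Replicate outlier screening with the Grubbs test.

Each condition's biological replicates are summarised to one scalar per
replicate (median log2 intensity over detected proteins) and screened with a
single-pass, two-sided Grubbs test at alpha = 0.05. At most one replicate
per condition is removed — matching the convention of discarding a single
aberrant run and proceeding with the remaining three.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import LFQMatrix


class DegenerateSampleError(ValueError):
    """Raised when the Grubbs statistic is undefined (n < 3 or zero spread)."""


@dataclass(frozen=True)
class GrubbsResult:
    statistic_G: float
    critical_value: float
    alpha: float
    outlier_index: int | None
    n: int

    def __post_init__(self) -> None:
        flagged = self.statistic_G > self.critical_value
        if flagged != (self.outlier_index is not None):
            raise ValueError("outlier_index must be set iff G exceeds the critical value")


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value: ((n-1)/sqrt(n)) * sqrt(t^2/(n-2+t^2))
    with t the upper alpha/(2n) Student-t quantile at n-2 degrees of freedom."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_test(values, alpha: float = 0.05) -> GrubbsResult:
    """Single-outlier two-sided Grubbs test.

    G = max_i |x_i - mean| / sd (sample sd). The most extreme point is
    flagged iff G exceeds the critical value at ``alpha``.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise DegenerateSampleError(f"Grubbs test needs n >= 3, got {n}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateSampleError("degenerate sample: zero standard deviation")
    deviations = np.abs(x - x.mean())
    idx = int(np.argmax(deviations))
    g = float(deviations[idx] / sd)
    crit = float(grubbs_critical_value(n, alpha))
    return GrubbsResult(
        statistic_G=g,
        critical_value=crit,
        alpha=alpha,
        outlier_index=idx if g > crit else None,
        n=n,
    )


def replicate_summary(matrix: LFQMatrix, condition: str) -> pd.Series:
    """One scalar per replicate: median log2 intensity over detected proteins.

    A robust global-scale summary — a replicate whose intensities are
    systematically shifted (e.g. a failed injection) moves its median while
    protein reordering or a handful of aberrant proteins do not.
    """
    block = matrix.condition_values(condition)
    if block.shape[1] < 3:
        raise DegenerateSampleError(
            f"condition {condition!r} has {block.shape[1]} replicates; Grubbs needs >= 3"
        )
    out = {}
    for sample_id in block.columns:
        col = block[sample_id].to_numpy(dtype=float)
        detected = col[col > 0]
        if detected.size == 0:
            raise DegenerateSampleError(
                f"replicate {sample_id!r} detected no proteins; cannot summarise"
            )
        out[sample_id] = float(np.median(np.log2(detected)))
    return pd.Series(out, name=condition)


def drop_outlier_replicates(
    matrix: LFQMatrix, alpha: float = 0.05
) -> tuple[LFQMatrix, pd.DataFrame]:
    """Screen every condition once and drop at most one replicate per condition.

    Returns the cleaned matrix and a report with one row per condition
    (summary values, G, critical value, dropped sample id or None). A drop
    that would leave fewer than 2 replicates raises instead.
    """
    to_drop: list[str] = []
    report_rows = []
    for condition in matrix.conditions:
        summary = replicate_summary(matrix, condition)
        result = grubbs_test(summary.to_numpy(), alpha=alpha)
        dropped = None
        if result.outlier_index is not None:
            dropped = summary.index[result.outlier_index]
            if len(summary) - 1 < 2:
                raise DegenerateSampleError(
                    f"dropping {dropped!r} would leave condition {condition!r} "
                    "with fewer than 2 replicates"
                )
            to_drop.append(dropped)
        report_rows.append(
            {
                "condition": condition,
                "n_replicates": result.n,
                "statistic_G": result.statistic_G,
                "critical_value": result.critical_value,
                "alpha": alpha,
                "dropped_sample": dropped,
            }
        )
    report = pd.DataFrame(report_rows)
    cleaned = matrix.drop_samples(to_drop) if to_drop else matrix.copy()
    return cleaned, report
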