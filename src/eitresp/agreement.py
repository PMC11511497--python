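"""Nonparametric Bland-Altman agreement and comparison summary tables.

Differences are summarized by their median and the reproducibility
coefficient RPC = 1.45 * IQR, whose limits ``median +/- RPC`` approximate
the usual 1.96-sigma limits for Gaussian differences without assuming
normality.  Quantiles are linearly interpolated between order statistics.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = ["AgreementError", "AgreementReport", "bland_altman_np", "comparison_summary"]

RPC_FACTOR = 1.45


class AgreementError(ValueError):
    pass


@dataclass(frozen=True)
class AgreementReport:
    """Comparison-table record (correlation block + Bland-Altman block)."""

    n: int
    slope: float
    intercept: float
    pearson_r: float
    spearman_rho: float
    rmse: float
    diff_std: float
    diff_median: float
    diff_iqr: float
    rpc: float
    limit_low: float
    limit_high: float
    pct_within_limits: float
    skewness: float
    kurtosis: float
    means: np.ndarray = None
    diffs: np.ndarray = None

    def to_series(self) -> pd.Series:
        d = asdict(self)
        d.pop("means")
        d.pop("diffs")
        return pd.Series(d)


def bland_altman_np(x, y) -> AgreementReport:
    """Nonparametric Bland-Altman analysis of test ``y`` against reference ``x``.

    Differences are ``y - x`` plotted against the pairwise means.  Kurtosis
    is moment-based and non-excess; the standard deviation uses the n-1
    denominator.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise AgreementError(
            f"length mismatch {x.shape} vs {y.shape}: truncate the pair first"
        )
    n = x.shape[0]
    if n < 4:
        raise AgreementError(f"need at least 4 paired values, got {n}")
    d = y - x
    means = (x + y) / 2.0
    q25, q75 = np.percentile(d, [25, 75], method="linear")
    iqr = q75 - q25
    median = float(np.median(d))
    rpc = RPC_FACTOR * iqr
    within = float(np.mean(np.abs(d - median) <= rpc) * 100.0)
    # regression of y on x for the summary block
    if np.ptp(x) > 0:
        slope, intercept = np.polyfit(x, y, 1)
        r = float(np.corrcoef(x, y)[0, 1])
        rho = float(scipy.stats.spearmanr(x, y).statistic)
    else:
        slope, intercept, r, rho = np.nan, np.nan, 0.0, 0.0
    return AgreementReport(
        n=n,
        slope=float(slope),
        intercept=float(intercept),
        pearson_r=r,
        spearman_rho=rho,
        rmse=float(np.sqrt(np.mean(d**2))),
        diff_std=float(np.std(d, ddof=1)),
        diff_median=median,
        diff_iqr=float(iqr),
        rpc=float(rpc),
        limit_low=median - rpc,
        limit_high=median + rpc,
        pct_within_limits=within,
        skewness=float(scipy.stats.skew(d)),
        kurtosis=float(scipy.stats.kurtosis(d, fisher=False)),
        means=means,
        diffs=d,
    )


def comparison_summary(x, y) -> pd.Series:
    """All comparison-table fields as a flat series (serializable to CSV)."""
    return bland_altman_np(x, y).to_series()
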