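"""Method-agreement statistics for automated-vs-manual count comparison.

Counts from two raters or methods, paired by sample, are compared with:

* Spearman rank correlation (Pearson correlation of average ranks, two-sided
  p-value via the t approximation) — robust to outliers and monotone
  nonlinearity in count data;
* a percentile bootstrap of the correlation (pair resampling with
  replacement; 2.5th/97.5th percentile bounds at the default 5000 draws);
* Bland-Altman bias and 95% limits of agreement (mean difference
  ± 1.96 × sample SD of the differences);
* a median [IQR] summary of absolute errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairedCounts",
    "AgreementReport",
    "spearman",
    "bootstrap_spearman_ci",
    "bland_altman",
    "absolute_error_summary",
    "method_comparison",
]


@dataclass(frozen=True)
class PairedCounts:
    """Counts from two methods/observers aligned on the same samples."""

    ids: tuple[str, ...]
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or len(x) != len(y) or len(x) != len(self.ids):
            raise ValueError("ids, x and y must be 1-D and of equal length")
        if len(x) < 2:
            raise ValueError("need at least 2 paired observations")
        if np.isnan(x).any() or np.isnan(y).any():
            raise ValueError("missing values are not allowed")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class AgreementReport:
    """Full agreement summary for one method-vs-reference comparison."""

    rho: float
    p_value: float
    ci_low: float
    ci_high: float
    bias: float
    loa_low: float
    loa_high: float
    abs_err_median: float
    abs_err_q1: float
    abs_err_q3: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must be <= ci_high")
        if not self.loa_low <= self.bias <= self.loa_high:
            raise ValueError("limits of agreement must bracket the bias")


def spearman(pc: PairedCounts) -> tuple[float, float]:
    """Spearman rho with a two-sided t-approximation p-value.

    Constant x or y leaves ranks undefined; that raises rather than
    returning NaN.
    """
    if np.unique(pc.x).size < 2 or np.unique(pc.y).size < 2:
        raise ValueError("rank correlation undefined for constant input")
    res = stats.spearmanr(pc.x, pc.y)
    return float(res.statistic), float(res.pvalue)


def _fast_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx -= rx.mean()
    ry -= ry.mean()
    denom = np.sqrt((rx * rx).sum() * (ry * ry).sum())
    return float((rx * ry).sum() / denom)


def bootstrap_spearman_ci(
    pc: PairedCounts, n_boot: int = 5000, seed: int = 0
) -> tuple[float, float, float]:
    """Percentile-bootstrap mean and 95% CI of the Spearman correlation.

    Pairs are resampled with replacement; resamples with constant ranks in
    either variable are redrawn (not scored as NaN) so that all ``n_boot``
    draws are effective. Fully reproducible for a fixed seed.
    """
    if pc.n < 5:
        raise ValueError("bootstrap needs at least 5 pairs")
    if np.unique(pc.x).size < 2 or np.unique(pc.y).size < 2:
        raise ValueError("degenerate data: constant input")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; interval will be unstable")
    rng = np.random.default_rng(seed)
    x, y, n = pc.x, pc.y, pc.n
    rhos = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        for _ in range(1000):
            idx = rng.integers(0, n, n)
            xb, yb = x[idx], y[idx]
            if np.unique(xb).size > 1 and np.unique(yb).size > 1:
                break
            redraws += 1
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
        rhos[b] = _fast_rho(xb, yb)
    if redraws:
        warnings.warn(f"redrew {redraws} degenerate bootstrap resamples")
    ci_low, ci_high = np.percentile(rhos, [2.5, 97.5])
    return float(rhos.mean()), float(ci_low), float(ci_high)


def bland_altman(pc: PairedCounts) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement of the paired differences x - y.

    Uses the sample SD (n-1 denominator); limits are bias ± 1.96 SD.
    """
    d = pc.x - pc.y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def absolute_error_summary(pc: PairedCounts) -> tuple[float, float, float]:
    """Median and quartiles (linear interpolation) of |x - y|."""
    a = np.abs(pc.x - pc.y)
    q1, med, q3 = np.percentile(a, [25, 50, 75])
    return float(med), float(q1), float(q3)


def agreement_report(pc: PairedCounts, n_boot: int = 5000, seed: int = 0) -> AgreementReport:
    """All agreement statistics for one paired comparison."""
    rho, p = spearman(pc)
    _, ci_low, ci_high = bootstrap_spearman_ci(pc, n_boot=n_boot, seed=seed)
    bias, loa_low, loa_high = bland_altman(pc)
    med, q1, q3 = absolute_error_summary(pc)
    return AgreementReport(
        rho=rho,
        p_value=p,
        ci_low=ci_low,
        ci_high=ci_high,
        bias=bias,
        loa_low=loa_low,
        loa_high=loa_high,
        abs_err_median=med,
        abs_err_q1=q1,
        abs_err_q3=q3,
        n_boot=n_boot,
        seed=seed,
    )


def method_comparison(
    manual: Mapping[str, float],
    methods: Mapping[str, Mapping[str, float]],
    n_boot: int = 5000,
    seed: int = 0,
    out_csv: Path | str | None = None,
):
    """Compare each automated method against the manual reference.

    ``manual`` maps sample_id -> count; each entry of ``methods`` maps a
    method name to its own sample_id -> count mapping, which must cover
    exactly the manual ids. Returns a DataFrame with one row per method
    (method, n, rho, p_value, ci_low, ci_high, bias, loa_low, loa_high,
    abs_err_median, abs_err_q1, abs_err_q3) and optionally writes it as a
    forest-plot-ready CSV.
    """
    import pandas as pd

    ids = sorted(manual)
    rows = []
    for name, series in methods.items():
        missing = sorted(set(ids) - set(series))
        extra = sorted(set(series) - set(ids))
        if missing or extra:
            raise ValueError(
                f"method {name!r} ids misaligned with manual counts: "
                f"missing={missing} extra={extra}"
            )
        pc = PairedCounts(
            ids=tuple(ids),
            x=np.array([series[i] for i in ids], dtype=float),
            y=np.array([manual[i] for i in ids], dtype=float),
        )
        rep = agreement_report(pc, n_boot=n_boot, seed=seed)
        rows.append({"method": name, "n": pc.n, **rep.__dict__})
    df = pd.DataFrame(rows)
    if out_csv is not None:
        out_csv = Path(out_csv)
        out_csv.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_csv, index=False, float_format="%.10g")
    return df


def forest_plot(df, out_png: Path | str) -> Path:
    """Basic forest plot of rho with bootstrap CIs per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 0.6 * len(df) + 1.2), dpi=100)
    ypos = np.arange(len(df))[::-1]
    ax.errorbar(
        df["rho"],
        ypos,
        xerr=[df["rho"] - df["ci_low"], df["ci_high"] - df["rho"]],
        fmt="o",
        capsize=3,
    )
    ax.set_yticks(ypos)
    ax.set_yticklabels(df["method"])
    ax.set_xlabel("Spearman rho (95% bootstrap CI)")
    ax.axvline(0.0, color="gray", lw=0.5)
    fig.tight_layout()
    out_png = Path(out_png)
    out_png.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_png)
    plt.close(fig)
    return out_png
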