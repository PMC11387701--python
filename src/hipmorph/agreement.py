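"""Reliability and agreement statistics for repeated hip measurements.

Implements the single-rater intraclass correlation coefficients (two-way
models, absolute-agreement and consistency forms, exact F-based 95 %
confidence intervals), Bland-Altman analysis with domain systematic-error
rules, categorical percent agreement with the qualitative rating scale, a
combined reliability report over named measurement batches, and the
Walter-Eliasziw-Donner sample-size formula for planning reliability studies.

ICC forms (two-way ANOVA with subjects as rows and raters/rounds as columns;
MSR, MSC, MSE are the row, column, and error mean squares for n subjects and
k raters):

- absolute agreement, single rater:
  (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
- consistency, single rater:
  (MSR - MSE) / (MSR + (k-1) MSE)

For the single-rater forms the two-way *random* and *mixed* models share the
same point estimate and interval; the model choice documents whether the
raters are considered a sample of a population of raters (random) or the
only raters of interest (mixed).

Systematic-error rules for the Bland-Altman bias: a mean difference larger
than 2.5 degrees for the angle measurements (mAI, AA, WCEA, LCEA, NSA), and
larger than 1 % of the measurement (interpreted as 1 % of the grand mean of
the pairwise averages; configurable) for the ratio measurements (ADR, EI,
TIR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .diagnosis import Thresholds, classify_frame, diagnostic_agreement
from .morphometry import ANGLE_MEASUREMENTS, MEASUREMENT_NAMES

__all__ = [
    "AgreementResult",
    "BlandAltmanResult",
    "AgreementError",
    "icc",
    "rate_icc",
    "bland_altman",
    "percent_agreement",
    "rate_percent",
    "reliability_report",
    "icc_sample_size",
    "bland_altman_plot",
]

ICC_MODELS = ("two-way-random", "two-way-mixed")
ICC_TYPES = ("absolute-agreement", "consistency")

#: Bland-Altman limits-of-agreement multiplier (the conventional 1.96).
LOA_MULTIPLIER = 1.96

ANGLE_BIAS_LIMIT_DEG = 2.5
RATIO_BIAS_LIMIT_FRACTION = 0.01


class AgreementError(ValueError):
    """Raised when agreement statistics cannot be computed from the input."""


@dataclass(frozen=True)
class AgreementResult:
    """An ICC estimate with its 95 % CI, qualitative rating, and bookkeeping."""

    estimate: Optional[float]
    ci95: tuple[float, float]
    model: str
    icc_type: str
    rating: Optional[str]
    n_used: int
    n_dropped: int
    reason: str = ""


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa: tuple[float, float]
    sd_diff: float
    systematic_error: bool
    differences: np.ndarray
    means: np.ndarray
    n_used: int
    n_dropped: int


def _mean_squares(values: np.ndarray) -> tuple[float, float, float, int, int]:
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    msr = k * float(((row_means - grand) ** 2).sum()) / (n - 1)
    msc = n * float(((col_means - grand) ** 2).sum()) / (k - 1)
    resid = values - row_means[:, None] - col_means[None, :] + grand
    mse = float((resid**2).sum()) / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc(
    values: np.ndarray | pd.DataFrame,
    model: str = "two-way-random",
    icc_type: str = "absolute-agreement",
    alpha: float = 0.05,
) -> AgreementResult:
    """Single-rater ICC over an (n subjects x k raters) matrix.

    Rows containing missing values are dropped listwise (the dropped count
    is reported).  Zero total variance makes the estimate undefined, which
    is reported as missing with a reason rather than raised.
    """
    if model not in ICC_MODELS:
        raise AgreementError(f"model must be one of {ICC_MODELS}, got {model!r}")
    if icc_type not in ICC_TYPES:
        raise AgreementError(f"type must be one of {ICC_TYPES}, got {icc_type!r}")
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise AgreementError("ratings must be a 2-D (subjects x raters) matrix")
    complete = ~np.isnan(arr).any(axis=1)
    dropped = int((~complete).sum())
    arr = arr[complete]
    n, k = arr.shape
    if n < 2 or k < 2:
        raise AgreementError(
            f"need >= 2 subjects and >= 2 raters after listwise deletion, got {n} x {k}"
        )
    if np.allclose(arr, arr.flat[0]):
        return AgreementResult(
            estimate=None,
            ci95=(np.nan, np.nan),
            model=model,
            icc_type=icc_type,
            rating=None,
            n_used=n,
            n_dropped=dropped,
            reason="zero total variance: ICC undefined",
        )
    msr, msc, mse, n, k = _mean_squares(arr)

    if icc_type == "consistency":
        est = (msr - mse) / (msr + (k - 1) * mse)
        lo, hi = _ci_consistency(msr, mse, n, k, alpha)
    else:
        est = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        lo, hi = _ci_absolute(msr, msc, mse, n, k, alpha)

    est = float(np.clip(est, -1.0, 1.0))
    lo = float(np.clip(min(lo, est), -1.0, 1.0))
    hi = float(np.clip(max(hi, est), -1.0, 1.0))
    return AgreementResult(
        estimate=est,
        ci95=(lo, hi),
        model=model,
        icc_type=icc_type,
        rating=rate_icc(est),
        n_used=n,
        n_dropped=dropped,
    )


def _ci_consistency(msr: float, mse: float, n: int, k: int, alpha: float):
    if mse == 0:
        return 1.0, 1.0
    df2 = (n - 1) * (k - 1)
    fobs = msr / mse
    fl = fobs / stats.f.ppf(1 - alpha / 2, n - 1, df2)
    fu = fobs * stats.f.ppf(1 - alpha / 2, df2, n - 1)
    return (fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1)


def _ci_absolute(msr: float, msc: float, mse: float, n: int, k: int, alpha: float):
    # Exact interval via the Satterthwaite approximation for the
    # between-columns + error composite (McGraw-Wong construction).
    if mse == 0 and msc == 0:
        return 1.0, 1.0
    icc_a = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    a = k * icc_a / (n * (1 - icc_a)) if icc_a < 1 else np.inf
    b = 1 + k * icc_a * (n - 1) / (n * (1 - icc_a)) if icc_a < 1 else np.inf
    if not np.isfinite(a) or not np.isfinite(b):
        return 1.0, 1.0
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else 1.0
    f_star = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_lower = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_star * mse) / (
        f_star * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi = n * (f_lower * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_lower * msr
    )
    return lo, hi


def rate_icc(estimate: float) -> str:
    """Qualitative ICC rating: poor / moderate / good / excellent."""
    if not np.isfinite(estimate):
        raise AgreementError("cannot rate a non-finite ICC")
    if estimate < 0.50:
        return "poor"
    if estimate <= 0.75:
        return "moderate"
    if estimate <= 0.90:
        return "good"
    return "excellent"


def bland_altman(
    x: np.ndarray,
    y: np.ndarray,
    measurement_kind: str = "angle",
) -> BlandAltmanResult:
    """Bland-Altman agreement between two paired measurement series.

    Differences are x - y; limits of agreement are bias +/- 1.96 * sample SD
    of the differences.  The systematic-error flag follows the domain rule:
    |bias| > 2.5 (degrees) for ``angle`` measurements, |bias| > 1 % of the
    grand mean of the pairwise averages for ``ratio`` measurements.
    """
    if measurement_kind not in ("angle", "ratio"):
        raise AgreementError(f"measurement_kind must be 'angle' or 'ratio', got {measurement_kind!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AgreementError("x and y must be 1-D arrays of equal length")
    complete = ~(np.isnan(x) | np.isnan(y))
    dropped = int((~complete).sum())
    x, y = x[complete], y[complete]
    if len(x) < 3:
        raise AgreementError(f"need >= 3 complete pairs, got {len(x)}")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd)
    means = (x + y) / 2.0
    if measurement_kind == "angle":
        systematic = abs(bias) > ANGLE_BIAS_LIMIT_DEG
    else:
        systematic = abs(bias) > RATIO_BIAS_LIMIT_FRACTION * abs(float(means.mean()))
    return BlandAltmanResult(
        bias=bias,
        loa=loa,
        sd_diff=sd,
        systematic_error=bool(systematic),
        differences=d,
        means=means,
        n_used=len(x),
        n_dropped=dropped,
    )


def percent_agreement(a, b) -> tuple[float, str]:
    """Percent agreement between two aligned categorical lists, with rating."""
    a = np.asarray(a, dtype=object)
    b = np.asarray(b, dtype=object)
    if a.shape != b.shape:
        raise AgreementError("lists must be aligned and of equal length")
    comparable = np.array([va is not None and vb is not None for va, vb in zip(a, b)])
    n = int(comparable.sum())
    if n == 0:
        raise AgreementError("zero comparable pairs")
    pct = 100.0 * sum(va == vb for va, vb in zip(a[comparable], b[comparable])) / n
    return float(pct), rate_percent(float(pct))


def rate_percent(pct: float) -> str:
    """Qualitative rating of a percentage of acceptable/matching measurements."""
    if pct < 50.0:
        return "poor"
    if pct <= 70.0:
        return "moderate"
    if pct <= 90.0:
        return "good"
    return "excellent"


def icc_sample_size(
    rho0: float,
    rho1: float,
    k: int = 2,
    alpha: float = 0.05,
    beta: float = 0.20,
    two_sided: bool = False,
) -> int:
    """Minimum subjects for testing H0: ICC = rho0 vs rho1 with k replicates.

    Walter-Eliasziw-Donner asymptotic closed form, rounded up.  ``alpha`` is
    one-sided by default (reliability hypotheses are directional).
    """
    if not (0 < rho0 < rho1 < 1):
        raise AgreementError("need 0 < rho0 < rho1 < 1")
    if k < 2:
        raise AgreementError("need k >= 2 replicates")
    z_a = stats.norm.ppf(1 - (alpha / 2 if two_sided else alpha))
    z_b = stats.norm.ppf(1 - beta)
    theta0 = rho0 / (1 - rho0)
    theta1 = rho1 / (1 - rho1)
    c0 = (1 + k * theta0) / (1 + k * theta1)
    n = 1 + 2 * k * (z_a + z_b) ** 2 / ((k - 1) * math.log(c0) ** 2)
    return int(math.ceil(n))


# ---------------------------------------------------------------------------
# Report tables over named measurement batches
# ---------------------------------------------------------------------------

def reliability_report(
    batches: dict[str, pd.DataFrame],
    model: str = "two-way-random",
    icc_type: str = "absolute-agreement",
    thresholds: Thresholds = Thresholds(),
) -> dict[str, pd.DataFrame]:
    """Per-measurement reliability tables across >= 2 named batches.

    Each batch is a measurements frame (one row per hip, indexed by hip id,
    as produced by ``measurements_frame``), aligned by hip.  Returns three
    machine-readable tables: ``icc`` (one row per measurement: estimate, CI,
    rating, n), ``bland_altman`` (one row per measurement per batch pair:
    bias, limits of agreement, systematic-error flag), and ``diagnosis``
    (per-flag percent agreement and prevalence per batch pair).
    """
    names = list(batches)
    if len(names) < 2:
        raise AgreementError("need at least two named measurement batches")
    base = batches[names[0]].index
    for name in names[1:]:
        other = batches[name].index
        if len(other) != len(base) or set(other) != set(base):
            unmatched = sorted(set(base).symmetric_difference(set(other)))
            raise AgreementError(f"hips not aligned across batches; unmatched ids: {unmatched}")
    aligned = {name: batches[name].loc[base] for name in names}

    icc_rows = []
    ba_rows = []
    for meas in MEASUREMENT_NAMES:
        matrix = np.column_stack([aligned[name][meas].to_numpy(dtype=float) for name in names])
        res = icc(matrix, model=model, icc_type=icc_type)
        icc_rows.append(
            {
                "measurement": meas,
                "icc": np.nan if res.estimate is None else res.estimate,
                "ci95_lo": res.ci95[0],
                "ci95_hi": res.ci95[1],
                "rating": res.rating,
                "model": res.model,
                "type": res.icc_type,
                "n_used": res.n_used,
                "n_dropped": res.n_dropped,
                "note": ("n reduced" if res.n_dropped else "") or res.reason,
            }
        )
        kind = "angle" if meas in ANGLE_MEASUREMENTS else "ratio"
        for i, na in enumerate(names):
            for nb in names[i + 1 :]:
                try:
                    ba = bland_altman(
                        aligned[na][meas].to_numpy(dtype=float),
                        aligned[nb][meas].to_numpy(dtype=float),
                        measurement_kind=kind,
                    )
                except AgreementError as exc:
                    ba_rows.append(
                        {"measurement": meas, "pair": f"{na} vs {nb}", "note": str(exc)}
                    )
                    continue
                ba_rows.append(
                    {
                        "measurement": meas,
                        "pair": f"{na} vs {nb}",
                        "bias": ba.bias,
                        "loa_lo": ba.loa[0],
                        "loa_hi": ba.loa[1],
                        "sd_diff": ba.sd_diff,
                        "systematic_error": ba.systematic_error,
                        "n_used": ba.n_used,
                        "n_dropped": ba.n_dropped,
                        "note": "n reduced" if ba.n_dropped else "",
                    }
                )

    diag_rows = []
    flags = {name: classify_frame(aligned[name], thresholds) for name in names}
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            table = diagnostic_agreement(flags[na], flags[nb])
            table = table.reset_index()
            table.insert(0, "pair", f"{na} vs {nb}")
            diag_rows.append(table)

    return {
        "icc": pd.DataFrame(icc_rows).set_index("measurement"),
        "bland_altman": pd.DataFrame(ba_rows).set_index(["measurement", "pair"]),
        "diagnosis": pd.concat(diag_rows, ignore_index=True).set_index(["pair", "flag"]),
    }


def bland_altman_plot(result: BlandAltmanResult, ax=None, title: str = ""):
    """Scatter of pairwise differences vs means with bias and LoA lines."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.differences, s=18, alpha=0.8)
    ax.axhline(result.bias, color="k", lw=1.2, label=f"bias {result.bias:.2f}")
    for lim in result.loa:
        ax.axhline(lim, color="k", lw=0.8, ls="--")
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    return ax
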