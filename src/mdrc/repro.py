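"""Scan-rescan reproducibility statistics.

Agreement between a first scan and a repeat scan of the same samples is
quantified ROI-by-ROI and metric-by-metric with:

* Lin's concordance correlation coefficient (CCC), which penalizes both
  decorrelation and mean/variance shifts;
* Bland-Altman analysis with limits of agreement (LOA) estimated by sample
  quantiles (the differences need not be Gaussian), flagging bias when the
  LOA interval excludes zero;
* per-sample Pearson correlations across ROIs, which factor out
  sample-specific systematic shifts (e.g. progressive fixation drift);
* the within-subject coefficient of variation CVws = sqrt(MSws)/|μ̄|.

A small mixture-moment toolbox illustrates how partial-volume mixing of two
tissue populations inflates variance metrics non-linearly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate

__all__ = [
    "lin_ccc",
    "strength_of_agreement",
    "BlandAltmanResult",
    "bland_altman",
    "per_sample_pearson",
    "cv_within_subject",
    "mixture_moments",
    "mixture_variance_max",
    "expected_scan_rescan_difference",
    "validate_pair_table",
    "reproducibility_report",
]

PAIR_COLUMNS = ("sample", "roi", "metric", "value_scan", "value_rescan")


def _paired(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("paired values must be finite")
    return x, y


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    CCC = 2 s_xy / (s_x² + s_y² + (x̄ - ȳ)²) with population (1/n) variances.
    Equals Pearson's r scaled by a bias-correction factor, so |CCC| <= |r|;
    CCC = 1 only for exact agreement y = x.
    """
    x, y = _paired(x, y, 3)
    sx2, sy2 = x.var(), y.var()
    dm = x.mean() - y.mean()
    denom = sx2 + sy2 + dm**2
    if denom == 0:
        # both series constant with equal means: perfect concordance
        return 1.0
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2.0 * sxy / denom)


def strength_of_agreement(ccc: float) -> str:
    """Descriptive reproducibility rating of a CCC value.

    > 0.99 almost perfect; 0.95-0.99 substantial; 0.90-0.95 moderate;
    below 0.90 poor.
    """
    if ccc > 0.99:
        return "almost perfect"
    if ccc > 0.95:
        return "substantial"
    if ccc > 0.90:
        return "moderate"
    return "poor"


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland-Altman summary with sample-quantile limits of agreement."""

    bias: float
    loa_low: float
    loa_high: float
    bias_detected: bool
    coverage: float


def bland_altman(x, y, loa_coverage: float = 0.95) -> BlandAltmanResult:
    """Bland-Altman analysis of paired measurements (differences d = y - x).

    The LOA are the empirical (linear-interpolation) sample quantiles of d at
    (1-coverage)/2 and 1-(1-coverage)/2; bias is flagged when the LOA
    interval does not contain zero.
    """
    x, y = _paired(x, y, 4)
    if not 0 < loa_coverage < 1:
        raise ValueError("loa_coverage must be in (0, 1)")
    d = y - x
    alpha = (1.0 - loa_coverage) / 2.0
    lo, hi = np.quantile(d, [alpha, 1.0 - alpha])
    return BlandAltmanResult(
        bias=float(d.mean()),
        loa_low=float(lo),
        loa_high=float(hi),
        bias_detected=bool(not (lo <= 0.0 <= hi)),
        coverage=loa_coverage,
    )


def validate_pair_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a scan-pair table: required columns, finite values, unique keys."""
    missing = [c for c in PAIR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"pair table missing columns: {missing}")
    vals = table[["value_scan", "value_rescan"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("pair table contains non-finite values")
    keys = table[["sample", "roi", "metric"]]
    if keys.duplicated().any():
        raise ValueError("each (sample, roi, metric) must appear exactly once")
    return table


def per_sample_pearson(
    table: pd.DataFrame, metric: str
) -> tuple[dict, float, tuple[float, float]]:
    """Pearson's r between scan and rescan per sample, across its ROIs.

    A per-sample correlation is shift-invariant, so a sample-specific
    systematic offset (e.g. fixation drift) does not lower it — the point of
    this "method-specific" reproducibility statistic.  Samples with constant
    values (undefined r) are excluded with a warning.

    Returns
    -------
    (per_sample, median, (iqr_low, iqr_high))
    """
    validate_pair_table(table)
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    per_sample: dict = {}
    for sample, grp in sub.groupby("sample"):
        x = grp["value_scan"].to_numpy(dtype=float)
        y = grp["value_rescan"].to_numpy(dtype=float)
        if len(x) < 3:
            raise ValueError(f"sample {sample!r} has fewer than 3 ROIs")
        if x.var() == 0 or y.var() == 0:
            warnings.warn(
                f"sample {sample!r}: constant values, correlation undefined; excluded",
                stacklevel=2,
            )
            continue
        per_sample[sample] = float(np.corrcoef(x, y)[0, 1])
    if not per_sample:
        raise ValueError("no sample with a defined correlation")
    r = np.array(list(per_sample.values()))
    q1, q3 = np.quantile(r, [0.25, 0.75])
    return per_sample, float(np.median(r)), (float(q1), float(q3))


def cv_within_subject(x, y) -> float:
    """Within-subject coefficient of variation of paired scan/rescan values.

    CVws = sqrt(MSws)/|μ̄| with the two-replicate within-subject mean square
    MSws = Σ dᵢ²/(2n) and μ̄ the mean over all values of both scans.
    Invariant under common positive scaling.
    """
    x, y = _paired(x, y, 1)
    ms_ws = float(np.sum((y - x) ** 2) / (2 * len(x)))
    mu = float(np.concatenate([x, y]).mean())
    if mu == 0:
        raise ValueError("CVws undefined: grand mean is zero")
    return float(np.sqrt(ms_ws) / abs(mu))


def mixture_moments(
    f: float, mu1: float, v1: float, mu2: float, v2: float
) -> tuple[float, float]:
    """Mean and variance of a two-population mixture with fraction f of pop. 2.

    E = (1-f)μ₁ + fμ₂ ;  V = (1-f)v₁ + f v₂ + f(1-f)(μ₁-μ₂)².
    The mean is monotone in f while the variance is parabolic — the reason
    partial-volume mixing hurts variance metrics more than means.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"mixing fraction must be in [0, 1], got {f}")
    if v1 < 0 or v2 < 0:
        raise ValueError("variances must be >= 0")
    e = (1.0 - f) * mu1 + f * mu2
    v = (1.0 - f) * v1 + f * v2 + f * (1.0 - f) * (mu1 - mu2) ** 2
    return float(e), float(v)


def mixture_variance_max(
    mu1: float, v1: float, mu2: float, v2: float
) -> tuple[float, float]:
    """Mixing fraction and value of the mixture-variance maximum.

    Setting dV/df = 0 gives f* = 1/2 + (v₂ - v₁)/(2(μ₁ - μ₂)²); when f* lies
    outside [0, 1] the maximum is at the nearer endpoint.
    """
    d2 = (mu1 - mu2) ** 2
    if d2 == 0:
        f_star = 0.0 if v1 >= v2 else 1.0
    else:
        f_star = float(np.clip(0.5 + (v2 - v1) / (2.0 * d2), 0.0, 1.0))
    return f_star, mixture_moments(f_star, mu1, v1, mu2, v2)[1]


def expected_scan_rescan_difference(
    mu1: float,
    v1: float,
    mu2: float,
    v2: float,
    f_distribution: str | Callable = "uniform",
    n_draws: int = 200_000,
    rng=None,
    method: str = "auto",
) -> tuple[float, float]:
    """Expected |scan - rescan| differences of mixture mean and variance.

    Models a boundary voxel whose mixing fraction f is re-drawn independently
    at each scan (voxel placement on the boundary is not reproducible):
    returns (E|E(f₁)-E(f₂)|, E|V(f₁)-V(f₂)|).

    With ``f_distribution='uniform'`` the mean difference has the closed form
    |μ₁-μ₂|·E|f₁-f₂| = |μ₁-μ₂|/3; the variance difference is computed by 2D
    quadrature over (f₁, f₂) (``method='quadrature'``) or Monte Carlo
    (``method='mc'``, used for any callable sampler).
    """
    def v_of(f):
        return (1.0 - f) * v1 + f * v2 + f * (1.0 - f) * (mu1 - mu2) ** 2

    if callable(f_distribution):
        if method == "quadrature":
            raise ValueError("quadrature requires the uniform f distribution")
        method = "mc"
    elif f_distribution != "uniform":
        raise ValueError("f_distribution must be 'uniform' or a sampler callable")
    if method == "auto":
        method = "quadrature"

    if method == "quadrature":
        e_abs_de = abs(mu1 - mu2) / 3.0
        e_abs_dv, _ = integrate.dblquad(
            lambda f2, f1: abs(v_of(f1) - v_of(f2)), 0.0, 1.0, 0.0, 1.0,
            epsabs=1e-8, epsrel=1e-8,
        )
        return float(e_abs_de), float(e_abs_dv)

    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    sampler = f_distribution if callable(f_distribution) else (
        lambda size: rng.uniform(0.0, 1.0, size))
    f1 = np.asarray(sampler(n_draws), dtype=float)
    f2 = np.asarray(sampler(n_draws), dtype=float)
    if np.any((f1 < 0) | (f1 > 1) | (f2 < 0) | (f2 > 1)):
        raise ValueError("f samples must lie in [0, 1]")
    e1 = (1.0 - f1) * mu1 + f1 * mu2
    e2 = (1.0 - f2) * mu1 + f2 * mu2
    return float(np.abs(e1 - e2).mean()), float(np.abs(v_of(f1) - v_of(f2)).mean())


def reproducibility_report(
    table: pd.DataFrame,
    metrics: Sequence[str] | None = None,
    loa_coverage: float = 0.95,
) -> dict:
    """Full reproducibility report over a scan-pair table.

    For each metric: CCC with a strength-of-agreement label, Bland-Altman
    bias/LOA, per-sample Pearson median and IQR, and CVws (overall and per
    ROI when samples repeat within ROIs).
    """
    validate_pair_table(table)
    if metrics is None:
        metrics = sorted(table["metric"].unique())
    report: dict = {}
    for metric in metrics:
        sub = table[table["metric"] == metric]
        x = sub["value_scan"].to_numpy(dtype=float)
        y = sub["value_rescan"].to_numpy(dtype=float)
        ccc = lin_ccc(x, y)
        ba = bland_altman(x, y, loa_coverage)
        try:
            _, r_median, r_iqr = per_sample_pearson(table, metric)
        except ValueError:
            r_median, r_iqr = float("nan"), (float("nan"), float("nan"))
        report[metric] = {
            "ccc": ccc,
            "strength": strength_of_agreement(ccc),
            "bland_altman": {
                "bias": ba.bias,
                "loa": [ba.loa_low, ba.loa_high],
                "bias_detected": ba.bias_detected,
            },
            "pearson_per_sample": {"median": r_median, "iqr": list(r_iqr)},
            "cv_ws": cv_within_subject(x, y),
            "n_pairs": int(len(sub)),
        }
    return report
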