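"""Cohort statistics for the healthy-vs-OA synovial-fluid comparisons.

This module reproduces the statistical layer tying the biophysical
measurements together:

* a normality-gated two-group test: skewed variables are cube-root (right
  skew) or log (left skew) transformed; if both groups then pass
  Shapiro-Wilk at alpha = 0.05 an unpaired t-test with means +/- SEM is
  used, otherwise a Wilcoxon rank-sum test with medians +/- IQR;
* flooring of undetectable cytokine concentrations at an arbitrary value
  below the assay's detection limit;
* relative gene expression via 2^-ddCT anchored so the healthy group's
  median fold change is 1.0;
* five-parameter logistic (5PL) immunoassay calibration
  y = a + b/(1 + (x/c)^d)^f and its closed-form inversion;
* the viscosity-vs-concentration quadratic constrained through (0, 1):
  y = 1 + B2 x^2, with the closed-form least-squares solution
  B2 = sum(x^2 (y-1)) / sum(x^4);
* Spearman rank correlations, intra-assay CV, and the viscometer
  replicate-filtering rule (drop all segments at the lowest flow rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "GatedTestReport",
    "normality_gated_test",
    "floor_undetectable",
    "ddct_fold_change",
    "FiveParamLogistic",
    "fit_5pl",
    "invert_5pl",
    "ConstrainedQuadFit",
    "constrained_quad_fit",
    "spearman",
    "intra_assay_cv",
    "serial_dilution_factor",
    "viscometer_replicate_filter",
    "run_cohort_analysis",
]


# ---------------------------------------------------------------------------
# normality-gated two-group testing


@dataclass(frozen=True)
class GatedTestReport:
    variable: str
    transform: str              # "none" | "cbrt" | "log"
    branch: str                 # "t-test" | "wilcoxon"
    p_value: float
    statistic: float
    shapiro_p: Tuple[float, float]
    group_summaries: dict       # per group: mean/sem or median/iqr per branch
    effect: float               # group2 center - group1 center (original scale)


def _summaries(values: np.ndarray, groups: np.ndarray, branch: str) -> dict:
    out = {}
    for g in pd.unique(groups):
        v = values[groups == g]
        if branch == "t-test":
            out[g] = {
                "mean": float(np.mean(v)),
                "sem": float(np.std(v, ddof=1) / math.sqrt(len(v))),
                "n": int(len(v)),
            }
        else:
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            out[g] = {"median": float(med), "iqr": float(q3 - q1), "n": int(len(v))}
    return out


def normality_gated_test(
    values: Sequence[float],
    groups: Sequence,
    skew_policy: str = "auto",
    alpha: float = 0.05,
    variable: str = "",
) -> GatedTestReport:
    """Two-group comparison with the study's transform-then-test gate.

    ``skew_policy``: "auto" picks cube root for right-skewed data (positive
    pooled sample skewness) and log for left-skewed; "cbrt", "log" or
    "none" force a transform.  If the transformed data pass Shapiro-Wilk in
    both groups, an unpaired two-sample t-test is run on the transformed
    values (means +/- SEM reported); otherwise a Wilcoxon rank-sum test
    (medians +/- IQR).  Rank-sum p-values are unchanged by these monotone
    transforms, so the transform only matters on the t-test branch.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape != g.shape:
        raise ValueError("values and groups must align")
    mask = np.isfinite(v)
    v, g = v[mask], g[mask]
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(labels)}")
    n_per = [int(np.sum(g == lab)) for lab in labels]
    if min(n_per) < 3:
        raise ValueError(f"need >= 3 observations per group, got {n_per}")

    if skew_policy == "auto":
        skew = sps.skew(v, bias=False)
        if skew > 0:
            transform = "cbrt"
        elif skew < 0 and np.all(v > 0):
            transform = "log"
        else:
            transform = "none"
    else:
        transform = skew_policy
    if transform == "cbrt":
        tv = np.cbrt(v)
    elif transform == "log":
        if np.any(v <= 0):
            raise ValueError("log transform requires strictly positive values")
        tv = np.log(v)
    elif transform == "none":
        tv = v
    else:
        raise ValueError(f"unknown skew_policy {skew_policy!r}")

    a, b = tv[g == labels[0]], tv[g == labels[1]]
    sh_a = _shapiro_p(a)
    sh_b = _shapiro_p(b)
    if sh_a > alpha and sh_b > alpha:
        branch = "t-test"
        stat, p = sps.ttest_ind(a, b)
        summaries = _summaries(v, g, branch)
        effect = float(np.mean(v[g == labels[1]]) - np.mean(v[g == labels[0]]))
    else:
        branch = "wilcoxon"
        method = "exact" if max(n_per) <= 20 and len(np.unique(tv)) == len(tv) else "asymptotic"
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        summaries = _summaries(v, g, branch)
        effect = float(
            np.median(v[g == labels[1]]) - np.median(v[g == labels[0]])
        )
    return GatedTestReport(
        variable, transform, branch, float(p), float(stat), (sh_a, sh_b), summaries, effect
    )


def _shapiro_p(x: np.ndarray) -> float:
    # identical values make Shapiro-Wilk undefined; treat as non-normal
    if np.ptp(x) == 0:
        return 0.0
    return float(sps.shapiro(x).pvalue)


# ---------------------------------------------------------------------------
# undetectable-value flooring and 2^-ddCT expression


def floor_undetectable(values: Sequence[float], floor: float = 1.0) -> np.ndarray:
    """Replace undetectable (zero) readings with an arbitrary floor value.

    The floor must sit below the assay's lowest detectable concentration
    (the caller's responsibility); positives pass through unchanged and
    negatives are rejected.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("concentrations cannot be negative")
    return np.where(v == 0, floor, v)


def ddct_fold_change(
    ct_gene: Sequence[float],
    ct_ref: Sequence[float],
    group_labels: Sequence,
    healthy_label="healthy",
    center: str = "median",
) -> np.ndarray:
    """Relative expression by the 2^-ddCT method.

    dCT = CT_gene - CT_ref per sample; ddCT subtracts the healthy group's
    dCT center (median by default, so the healthy median fold change is
    exactly 1.0; ``center="mean"`` uses the healthy average instead).
    Samples with a missing CT yield NaN.
    """
    cg = np.asarray(ct_gene, dtype=float)
    cr = np.asarray(ct_ref, dtype=float)
    g = np.asarray(group_labels)
    if not (cg.shape == cr.shape == g.shape):
        raise ValueError("ct_gene, ct_ref and group_labels must align")
    dct = cg - cr
    healthy = dct[(g == healthy_label) & np.isfinite(dct)]
    if healthy.size == 0:
        raise ValueError(f"no finite dCT values in group {healthy_label!r}")
    if center == "median":
        anchor = np.median(healthy)
    elif center == "mean":
        anchor = np.mean(healthy)
    else:
        raise ValueError(f"unknown center {center!r}")
    return 2.0 ** -(dct - anchor)


# ---------------------------------------------------------------------------
# 5-parameter logistic immunoassay calibration


@dataclass(frozen=True)
class FiveParamLogistic:
    """y = a + b / (1 + (x/c)^d)^f with c > 0.

    With d > 0, y -> a + b as x -> 0 and y -> a as x -> inf; b may be
    negative for an ascending curve.
    """

    a: float
    b: float
    c: float
    d: float
    f: float
    rss: float = float("nan")

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be positive")

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a + self.b / (1.0 + (x / self.c) ** self.d) ** self.f


def _5pl(x, a, b, c, d, f):
    with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
        return a + b / (1.0 + (x / c) ** d) ** f


def fit_5pl(conc_standards: Sequence[float], responses: Sequence[float]) -> FiveParamLogistic:
    """Least-squares fit of the 5PL standard curve.

    Uses a deterministic multi-start over (d, f) shape pairs, since the two
    shape parameters partially trade off and a single start can stall in a
    local minimum.  Raises on degenerate (flat) response data or
    non-convergence.
    """
    x = np.asarray(conc_standards, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 5:
        raise ValueError("need >= 5 standard points")
    if np.any(x <= 0):
        raise ValueError("standard concentrations must be positive")
    if np.ptp(y) == 0:
        raise ValueError("degenerate standard curve: responses all equal")

    c0 = float(np.exp(np.mean(np.log(x))))
    a0 = float(y[np.argmax(x)])
    b0 = float(y[np.argmin(x)] - a0)
    best = None
    for d0 in (0.5, 1.0, 2.0, 4.0):
        for f0 in (0.5, 1.0, 2.0):
            try:
                popt, _ = optimize.curve_fit(
                    _5pl,
                    x,
                    y,
                    p0=[a0, b0, c0, d0, f0],
                    maxfev=20000,
                    ftol=1e-14,
                    xtol=1e-14,
                )
            except (RuntimeError, ValueError):
                continue
            if popt[2] <= 0 or popt[4] <= 0:
                continue
            rss = float(np.sum((_5pl(x, *popt) - y) ** 2))
            if best is None or rss < best[0]:
                best = (rss, popt)
    if best is None:
        raise RuntimeError("5PL fit failed to converge from any start")
    rss, popt = best
    return FiveParamLogistic(*map(float, popt), rss=rss)


class InvertedConc(NamedTuple):
    conc: float
    censored: Optional[str]  # None | "below-range" | "above-range"


def invert_5pl(y: float, params: FiveParamLogistic) -> InvertedConc:
    """Closed-form 5PL inversion x = c*((b/(y-a))^(1/f) - 1)^(1/d).

    Responses at or beyond the asymptotes (a and a+b) are censored with a
    range flag instead of producing a concentration.
    """
    a, b, c, d, f = params.a, params.b, params.c, params.d, params.f
    lo, hi = sorted((a, a + b))
    if not (lo < y < hi):
        # descending curve (b>0, d>0): y<=a means x beyond the top of the range
        at_far_asymptote = (y <= lo) if (b > 0) == (d > 0) else (y >= hi)
        return InvertedConc(float("nan"), "above-range" if at_far_asymptote else "below-range")
    x = c * ((b / (y - a)) ** (1.0 / f) - 1.0) ** (1.0 / d)
    return InvertedConc(float(x), None)


# ---------------------------------------------------------------------------
# constrained quadratic viscosity-concentration fit


@dataclass(frozen=True)
class ConstrainedQuadFit:
    """y = B0 + B1 x + B2 x^2 with B0 = 1, B1 = 0 imposed."""

    B2: float
    r_squared: float
    n: int
    constraint: str = "B0=1, B1=0"

    def __call__(self, x) -> np.ndarray:
        return 1.0 + self.B2 * np.asarray(x, dtype=float) ** 2


def constrained_quad_fit(x_conc: Sequence[float], y_visc: Sequence[float]) -> ConstrainedQuadFit:
    """Least squares of y = 1 + B2 x^2; closed form B2 = sum(x^2(y-1))/sum(x^4).

    R^2 = 1 - SS_res/SS_tot against the mean of y; it can be <= 0 and is
    reported as-is.
    """
    x = np.asarray(x_conc, dtype=float)
    y = np.asarray(y_visc, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 points")
    s4 = float(np.sum(x**4))
    if s4 == 0:
        raise ValueError("all x are zero; B2 is unidentified")
    b2 = float(np.sum(x**2 * (y - 1.0)) / s4)
    resid = y - (1.0 + b2 * x**2)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return ConstrainedQuadFit(b2, r2, int(x.size))


# ---------------------------------------------------------------------------
# correlations, CVs, replicate filtering


class SpearmanResult(NamedTuple):
    rho: float
    p_value: float
    undefined: bool


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties, two-sided p."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return SpearmanResult(float("nan"), float("nan"), True)
    rho, p = sps.spearmanr(xa, ya)
    return SpearmanResult(float(rho), float(p), False)


def intra_assay_cv(replicates: pd.DataFrame, sample_col: str = "sample_id", value_col: str = "value") -> float:
    """Mean intra-assay CV%% across samples: 100 * sd/mean per sample.

    Uses the sample standard deviation (n-1).  Samples with zero mean are
    excluded (they carry no defined CV).
    """
    cvs = []
    for _, sub in replicates.groupby(sample_col):
        v = sub[value_col].to_numpy(dtype=float)
        if len(v) < 2:
            raise ValueError("need >= 2 replicates per sample")
        m = v.mean()
        if m == 0:
            continue
        cvs.append(100.0 * v.std(ddof=1) / m)
    if not cvs:
        raise ValueError("no sample with a defined CV")
    return float(np.mean(cvs))


def serial_dilution_factor(factors: Sequence[float]) -> float:
    """Overall dilution of a serial-dilution chain: the product of its steps.

    E.g. a 1:20 dilution followed by a 100-fold dilution is 2000-fold.
    """
    f = np.asarray(list(factors), dtype=float)
    if f.size == 0:
        raise ValueError("need at least one dilution step")
    if np.any(f <= 0):
        raise ValueError("dilution factors must be positive")
    return float(np.prod(f))


class FilterResult(NamedTuple):
    retained: List[Tuple[float, float]]
    excluded_flow_rate: float
    empty: bool


def viscometer_replicate_filter(
    segments: Sequence[Tuple[float, float]]
) -> FilterResult:
    """Drop all viscometer test segments at the lowest flow rate.

    The lowest flow rate corresponds to the lowest shear rate, where the
    readings are excessively variable; the remaining segments are the
    technical replicates used for analysis (e.g. 7 segments at flow rates
    2x50, 2x75, 2x100, 1x125 uL/min -> 5 retained).
    """
    segs = list(segments)
    if not segs:
        raise ValueError("empty segment list")
    lowest = min(fr for fr, _ in segs)
    retained = [(fr, v) for fr, v in segs if fr != lowest]
    return FilterResult(retained, float(lowest), len(retained) == 0)


# ---------------------------------------------------------------------------
# cohort-level driver


def run_cohort_analysis(
    table: pd.DataFrame,
    variables: Optional[Sequence[str]] = None,
    group_col: str = "group",
    skew_overrides: Optional[Dict[str, str]] = None,
    spearman_pairs: Optional[Sequence[Tuple[str, str]]] = None,
    quad_fit: Optional[Tuple[str, str]] = None,
) -> dict:
    """Per-variable gated tests, correlations and per-group constrained fits.

    ``quad_fit = (conc_col, visc_col)`` requests a per-group constrained
    quadratic viscosity-concentration fit.  Variables with fewer than 3
    finite values in either group are skipped with a warning entry; a
    single-group table yields summaries only.
    """
    skew_overrides = skew_overrides or {}
    groups = table[group_col].to_numpy()
    labels = list(pd.unique(groups))
    if variables is None:
        variables = [
            c
            for c in table.columns
            if c != group_col and pd.api.types.is_numeric_dtype(table[c])
        ]
    report: dict = {"variables": {}, "spearman": {}, "quad_fit": {}, "warnings": []}
    for var in variables:
        v = table[var].to_numpy(dtype=float)
        if len(labels) < 2:
            q1, med, q3 = np.nanpercentile(v, [25, 50, 75])
            report["variables"][var] = {
                "summary_only": True,
                "median": float(med),
                "iqr": float(q3 - q1),
            }
            continue
        counts = [np.sum(np.isfinite(v[groups == lab])) for lab in labels]
        if min(counts) < 3:
            report["warnings"].append(f"{var}: skipped (insufficient data per group)")
            continue
        rep = normality_gated_test(
            v, groups, skew_policy=skew_overrides.get(var, "auto"), variable=var
        )
        report["variables"][var] = {
            "branch": rep.branch,
            "transform": rep.transform,
            "p_value": rep.p_value,
            "effect": rep.effect,
            "group_summaries": rep.group_summaries,
        }
    for xcol, ycol in spearman_pairs or []:
        sub = table[[xcol, ycol]].dropna()
        res = spearman(sub[xcol], sub[ycol])
        report["spearman"][f"{xcol}~{ycol}"] = {
            "rho": res.rho,
            "p_value": res.p_value,
            "undefined": res.undefined,
        }
    if quad_fit is not None:
        xcol, ycol = quad_fit
        for lab in labels:
            sub = table[table[group_col] == lab][[xcol, ycol]].dropna()
            if len(sub) < 2:
                continue
            fit = constrained_quad_fit(sub[xcol], sub[ycol])
            report["quad_fit"][lab] = {"B2": fit.B2, "r_squared": fit.r_squared, "n": fit.n}
    return report
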