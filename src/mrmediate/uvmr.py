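"""Univariable two-sample MR estimators and sensitivity analyses.

Given a :class:`~mrmediate.gwas_io.HarmonizedSet` of J instruments with
SNP–exposure effects βXⱼ (SE σXⱼ) and SNP–outcome effects βYⱼ (SE σYⱼ), the
per-SNP Wald ratio βYⱼ/βXⱼ estimates the causal effect of the exposure on the
outcome under the instrumental-variable assumptions.  This module combines the
ratios five ways:

* **IVW** — weighted regression of βY on βX through the origin with weights
  1/σY²; the multiplicative random-effects variant inflates the SE by
  √max(1, Q/(J−1)) where Q is Cochran's heterogeneity statistic.
* **MR-Egger** — the same regression with an intercept after orienting all
  βX ≥ 0; the intercept estimates directional pleiotropy, the slope remains
  consistent under InSIDE.
* **Weighted median** — the weighted 50th percentile of the ratio
  distribution; consistent when ≥50% of the weight lies on valid instruments.
* **Weighted / simple mode** — the kernel-density mode of the ratios;
  consistent when the largest group of instruments shares a ratio.

Sensitivity tools: Cochran's Q (IVW and Egger flavors), the Egger intercept
test for directional pleiotropy, MR-PRESSO global/outlier tests with outlier
removal, Benjamini–Hochberg FDR adjustment, and the directional-consistency
check used to screen estimator agreement.

All confidence intervals are normal-approximation β ± 1.96·SE and p-values
two-sided normal, matching the symmetric intervals reported by the standard
two-sample MR stacks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._exceptions import DataError, IdentificationError
from .gwas_io import HarmonizedSet

Z95 = 1.959963984540054  # Phi^-1(0.975)


@dataclass
class MrEstimate:
    """One estimator's causal-effect estimate on the log scale."""

    method: str  # ivw | egger | weighted_median | weighted_mode | simple_mode
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snp: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "n_snp": self.n_snp,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
        }


@dataclass
class HeterogeneityResult:
    method: str  # ivw | egger
    q: float
    df: int
    pvalue: float


@dataclass
class PleiotropyResult:
    intercept: float
    se: float
    pvalue: float


@dataclass
class PressoResult:
    global_p: float
    outlier_rsids: list[str]
    corrected_estimate: MrEstimate
    n_sim: int
    seed: int
    outlier_p: dict[str, float] = field(default_factory=dict)


def _finish(method: str, beta: float, se: float, n_snp: int, **kw) -> MrEstimate:
    p = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else (1.0 if beta == 0 else 0.0)
    return MrEstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pvalue=float(max(p, np.finfo(float).tiny)),
        n_snp=n_snp,
        **kw,
    )


def _check(h: HarmonizedSet, min_snp: int, what: str) -> None:
    if h.n_snp < min_snp:
        raise DataError(f"{what} requires at least {min_snp} SNPs, got {h.n_snp}")


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

def ivw_estimate(h: HarmonizedSet, random_effects: bool = True) -> MrEstimate:
    """Inverse-variance-weighted estimate: WLS of βY on βX through the origin.

    weights wⱼ = 1/σYⱼ²; β = Σ wⱼβXⱼβYⱼ / Σ wⱼβXⱼ²; fixed-effect
    SE = (Σ wⱼβXⱼ²)^{-1/2}.  With ``random_effects`` the SE is inflated by
    √max(1, Q/(J−1)) — never deflated, so the fixed-effect SE is a lower
    bound.  A single SNP degrades to the Wald ratio with a warning.
    """
    bx, _sx, by, sy = h.arrays()
    if np.all(bx == 0.0):
        raise IdentificationError("all exposure betas are zero: effect not identified")
    if h.n_snp == 1:
        warnings.warn("single instrument: returning the Wald ratio", stacklevel=2)
        beta = by[0] / bx[0]
        se = sy[0] / abs(bx[0])
        return _finish("ivw", beta, se, 1)
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / sxx
    se = sxx**-0.5
    if random_effects:
        q = float(np.sum(w * (by - beta * bx) ** 2))
        se *= np.sqrt(max(1.0, q / (h.n_snp - 1)))
    return _finish("ivw", beta, se, h.n_snp)


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def _egger_fit(bx, by, sy):
    """Oriented weighted regression with intercept; returns coefficients and
    fixed/inflated SEs via the weighted normal equations."""
    sgn = np.where(bx < 0, -1.0, 1.0)
    x = sgn * bx
    y = sgn * by
    w = 1.0 / sy**2
    sw, swx = w.sum(), (w * x).sum()
    swxx, swy, swxy = (w * x * x).sum(), (w * y).sum(), (w * x * y).sum()
    det = sw * swxx - swx**2
    if det <= 0:
        raise IdentificationError("degenerate exposure betas: Egger fit not identified")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    # (X'WX)^{-1} diagonal
    var_slope = sw / det
    var_int = swxx / det
    resid = y - intercept - slope * x
    q = float((w * resid**2).sum())
    return intercept, slope, np.sqrt(var_int), np.sqrt(var_slope), q


def egger_estimate(h: HarmonizedSet, random_effects: bool = True) -> MrEstimate:
    """MR-Egger regression: slope = causal effect, intercept = average
    directional pleiotropy.  Inputs are oriented so every βX ≥ 0 first."""
    _check(h, 3, "MR-Egger")
    bx, _sx, by, sy = h.arrays()
    intercept, slope, se_int, se_slope, q = _egger_fit(bx, by, sy)
    if random_effects:
        infl = np.sqrt(max(1.0, q / (h.n_snp - 2)))
        se_int *= infl
        se_slope *= infl
    p_int = 2.0 * stats.norm.sf(abs(intercept / se_int))
    return _finish(
        "egger",
        slope,
        se_slope,
        h.n_snp,
        intercept=float(intercept),
        intercept_se=float(se_int),
        intercept_p=float(p_int),
    )


def egger_intercept_test(h: HarmonizedSet, random_effects: bool = True) -> PleiotropyResult:
    """Two-sided test of Egger intercept = 0 (directional pleiotropy)."""
    est = egger_estimate(h, random_effects=random_effects)
    return PleiotropyResult(
        intercept=est.intercept, se=est.intercept_se, pvalue=est.intercept_p
    )


# ---------------------------------------------------------------------------
# Weighted median
# ---------------------------------------------------------------------------

def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Linear interpolation of the weighted empirical CDF at probability 0.5."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cs = np.cumsum(w) - 0.5 * w  # midpoint cumulative weight per observation
    if 0.5 <= cs[0]:
        return float(r[0])
    if 0.5 >= cs[-1]:
        return float(r[-1])
    return float(np.interp(0.5, cs, r))


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MrEstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Ratios βYⱼ/βXⱼ are weighted by wⱼ = (βXⱼ/σYⱼ)² (the first-order inverse
    variance of the ratio); the estimate interpolates the weighted empirical
    distribution at cumulative weight 0.5.  Consistent when at least half the
    weight lies on valid instruments.
    """
    _check(h, 3, "weighted median")
    if n_boot <= 0:
        raise DataError("n_boot must be positive")
    bx, sx, by, sy = h.arrays()
    if np.any(bx == 0.0):
        keep = bx != 0.0
        warnings.warn("excluding SNP(s) with zero exposure beta", stacklevel=2)
        bx, sx, by, sy = bx[keep], sx[keep], by[keep], sy[keep]
    ratios = by / bx
    weights = (bx / sy) ** 2
    beta = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        ok = bx_b != 0.0
        boots[i] = _weighted_median(by_b[ok] / bx_b[ok], (bx_b[ok] / sy[ok]) ** 2)
    se = float(np.std(boots, ddof=1))
    return _finish("weighted_median", beta, se, int(len(ratios)))


# ---------------------------------------------------------------------------
# Mode estimators
# ---------------------------------------------------------------------------

def _kde_mode(ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float) -> float:
    w = weights / weights.sum()
    n = len(ratios)
    sd = np.std(ratios, ddof=1) if n > 1 else 0.0
    mad = stats.median_abs_deviation(ratios, scale="normal")
    s = 0.9 * min(sd, mad) * n ** (-1 / 5) if min(sd, mad) > 0 else 0.0
    if s == 0.0:
        # degenerate spread: fall back to the weighted median of a point mass
        return _weighted_median(ratios, w)
    hbw = bandwidth_factor * s
    grid = np.linspace(ratios.min() - 3 * hbw, ratios.max() + 3 * hbw, 512)
    dens = (w[:, None] * stats.norm.pdf(grid[None, :], ratios[:, None], hbw)).sum(axis=0)
    return float(grid[np.argmax(dens)])


def mode_estimate(
    h: HarmonizedSet,
    weighted: bool = True,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MrEstimate:
    """Mode-based estimate: kernel-density mode of the Wald ratios.

    The weighted variant weights each ratio by its delta-method inverse
    variance (var = σY²/βX² + βY²σX²/βX⁴); the simple variant weights
    equally.  Normal kernel with a Silverman-type bandwidth scaled by
    ``bandwidth_factor``; SE by parametric bootstrap.
    """
    _check(h, 3, "mode estimator")
    if n_boot <= 0:
        raise DataError("n_boot must be positive")
    bx, sx, by, sy = h.arrays()
    if np.any(bx == 0.0):
        warnings.warn("excluding SNP(s) with zero exposure beta", stacklevel=2)
        keep = bx != 0.0
        bx, sx, by, sy = bx[keep], sx[keep], by[keep], sy[keep]

    def _weights(bx_, sx_, by_, sy_):
        if weighted:
            var = sy_**2 / bx_**2 + by_**2 * sx_**2 / bx_**4
            return 1.0 / var
        return np.ones_like(bx_)

    ratios = by / bx
    beta = _kde_mode(ratios, _weights(bx, sx, by, sy), bandwidth_factor)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        ok = bx_b != 0.0
        boots[i] = _kde_mode(
            by_b[ok] / bx_b[ok], _weights(bx_b[ok], sx[ok], by_b[ok], sy[ok]), bandwidth_factor
        )
    se = float(np.std(boots, ddof=1))
    method = "weighted_mode" if weighted else "simple_mode"
    return _finish(method, beta, se, int(len(ratios)))


# ---------------------------------------------------------------------------
# Heterogeneity and pleiotropy
# ---------------------------------------------------------------------------

def cochran_q(h: HarmonizedSet, method: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q heterogeneity statistic around the IVW or Egger fit.

    Q = Σ wⱼ (βYⱼ − fitted(βXⱼ))², wⱼ = 1/σYⱼ²; df = J−1 (IVW) or J−2
    (Egger); p from the chi-square upper tail.
    """
    bx, _sx, by, sy = h.arrays()
    w = 1.0 / sy**2
    if method == "ivw":
        df = h.n_snp - 1
        if df <= 0:
            raise DataError("Cochran's Q (IVW) needs at least 2 SNPs")
        slope = ivw_estimate(h, random_effects=False).beta
        q = float(np.sum(w * (by - slope * bx) ** 2))
    elif method == "egger":
        df = h.n_snp - 2
        if df <= 0:
            raise DataError("Cochran's Q (Egger) needs at least 3 SNPs")
        *_, q = _egger_fit(bx, by, sy)
    else:
        raise DataError(f"unknown Q method {method!r}")
    return HeterogeneityResult(method=method, q=q, df=df, pvalue=float(stats.chi2.sf(q, df)))


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    random_effects: bool = True,
) -> PressoResult:
    """MR-PRESSO global heterogeneity test and outlier removal.

    For each SNP j the expected outcome effect is β₋ⱼ·βXⱼ with β₋ⱼ the IVW
    slope leaving j out.  The observed weighted residual sum of squares is
    compared against a parametric null (βX, βY resampled from their sampling
    distributions around the leave-one-out expectations, ``n_sim`` draws) to
    give a global p; per-SNP empirical p-values are Bonferroni-adjusted and
    SNPs below ``alpha`` are removed, with IVW re-run on the remainder.
    """
    if h.n_snp < 4:
        raise DataError(
            "MR-PRESSO requires at least 4 SNPs; run plain IVW for smaller sets"
        )
    bx, sx, by, sy = h.arrays()
    j = h.n_snp
    w = 1.0 / sy**2

    # leave-one-out IVW slopes
    swxy = np.sum(w * bx * by)
    swxx = np.sum(w * bx * bx)
    loo = (swxy - w * bx * by) / (swxx - w * bx * bx)

    resid_obs = (by - loo * bx) ** 2 * w
    rss_obs = float(resid_obs.sum())

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sx, size=(n_sim, j))
    by_sim = rng.normal(loo * bx, sy, size=(n_sim, j))
    resid_sim = (by_sim - loo * bx_sim) ** 2 * w
    rss_sim = resid_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    p_snp = (1 + np.sum(resid_sim >= resid_obs, axis=0)) / (n_sim + 1)
    p_adj = np.minimum(p_snp * j, 1.0)
    outlier_mask = p_adj < alpha
    rsids = h.table["rsid"].tolist()
    outliers = [r for r, m in zip(rsids, outlier_mask) if m]

    keep = [r for r in rsids if r not in set(outliers)]
    if len(keep) < 2:
        raise DataError("MR-PRESSO removed too many SNPs to re-estimate")
    corrected = ivw_estimate(h.subset(keep), random_effects=random_effects)
    return PressoResult(
        global_p=global_p,
        outlier_rsids=outliers,
        corrected_estimate=corrected,
        n_sim=n_sim,
        seed=seed,
        outlier_p=dict(zip(rsids, p_adj)),
    )


# ---------------------------------------------------------------------------
# Multiple testing and consistency screening
# ---------------------------------------------------------------------------

def bh_fdr(pvalues) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(pvalues), float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise DataError("p-values must lie in (0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adj]


def directional_consistency(estimates: list[MrEstimate]) -> tuple[bool, pd.DataFrame]:
    """Whether every non-IVW estimate shares the IVW estimate's sign.

    A zero beta counts as consistent.  Returns the verdict and a per-method
    report table.
    """
    ivw = [e for e in estimates if e.method == "ivw"]
    if not ivw:
        raise DataError("directional consistency requires an IVW estimate")
    ref = np.sign(ivw[0].beta)
    rows = []
    consistent = True
    for e in estimates:
        if e.method == "ivw":
            ok = True
        else:
            ok = e.beta == 0.0 or np.sign(e.beta) == ref or ref == 0.0
        consistent &= ok
        rows.append({"method": e.method, "beta": e.beta, "consistent_with_ivw": ok})
    return bool(consistent), pd.DataFrame(rows)


def all_estimates(
    h: HarmonizedSet, n_boot: int = 1000, seed: int = 0, random_effects: bool = True
) -> list[MrEstimate]:
    """Run all five estimators on one harmonized set (IVW first)."""
    out = [ivw_estimate(h, random_effects=random_effects)]
    if h.n_snp >= 3:
        out.append(egger_estimate(h, random_effects=random_effects))
        out.append(weighted_median(h, n_boot=n_boot, seed=seed))
        out.append(mode_estimate(h, weighted=True, n_boot=n_boot, seed=seed + 1))
        out.append(mode_estimate(h, weighted=False, n_boot=n_boot, seed=seed + 2))
    return out
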