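"""Instrument-strength metrics: per-SNP variance explained and F-statistics.

For a SNP with per-allele effect β, standard error SE, minor allele frequency
MAF and exposure-GWAS sample size N, the variance in the exposure explained by
the SNP is approximated by

    R² = 2·MAF·(1−MAF)·β² / (SE²·N)

and instrument strength by

    F = ((N−K−1)/K) · R²/(1−R²)

with K the number of instruments entering the R² numerator.  F > 10 is the
conventional threshold for a non-weak instrument.

The report exposes two F readings: ``f_mean_per_snp`` applies K=1 to the mean
per-SNP R² (the mean single-SNP F, the quantity typically tabulated alongside
per-study instrument counts), and ``f_joint`` applies K=k to the summed R²
(joint strength of the whole instrument set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import DataError
from .gwas_io import GwasSummary

WEAK_INSTRUMENT_F = 10.0

_EPS = 1e-12


def snp_r2(beta: float, se: float, maf: float, n: float) -> float:
    """Variance explained by one SNP: 2·MAF·(1−MAF)·β²/(SE²·N).

    Clipped at 1−ε (with a warning) should rounding push it to or past 1.
    """
    if not 0.0 < maf < 1.0:
        raise DataError(f"maf {maf} outside (0,1)")
    if not se > 0.0:
        raise DataError("se must be strictly positive")
    if not n > 0:
        raise DataError("n must be positive")
    r2 = 2.0 * maf * (1.0 - maf) * beta * beta / (se * se * n)
    if r2 >= 1.0:
        warnings.warn(f"per-SNP R² {r2:g} ≥ 1; clipped", stacklevel=2)
        r2 = 1.0 - _EPS
    return r2


def f_statistic(r2: float, n: float, k: int = 1) -> float:
    """Instrument F-statistic ((N−K−1)/K)·R²/(1−R²)."""
    if not 0.0 <= r2 < 1.0:
        raise DataError(f"r2 {r2} outside [0,1)")
    if k < 1:
        raise DataError("k must be a positive integer")
    if not n > k + 1:
        raise DataError(f"n={n} must exceed k+1={k + 1}")
    return ((n - k - 1) / k) * r2 / (1.0 - r2)


@dataclass
class StrengthReport:
    """Instrument-strength summary for one exposure's instrument set."""

    trait: str
    r2: np.ndarray  # per-SNP variance explained
    mean_r2: float
    k: int
    n: float
    f_mean_per_snp: float  # K=1 applied to the mean per-SNP R²
    f_joint: float  # K=k applied to the summed R²

    @property
    def weak(self) -> bool:
        """True when the mean per-SNP F falls below the conventional F=10 bar."""
        return self.f_mean_per_snp < WEAK_INSTRUMENT_F

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait": [self.trait],
                "sample_size": [self.n],
                "n_snps": [self.k],
                "r2": [self.mean_r2],
                "f": [self.f_mean_per_snp],
                "f_joint": [self.f_joint],
                "weak": [self.weak],
            }
        )


def strength_report(g: GwasSummary) -> StrengthReport:
    """Compute per-SNP R² and both F readings for an instrument set."""
    t = g.table
    maf = np.minimum(t["eaf"].to_numpy(float), 1.0 - t["eaf"].to_numpy(float))
    beta = t["beta"].to_numpy(float)
    se = t["se"].to_numpy(float)
    n_col = t["n"].to_numpy(float)
    r2 = np.array(
        [snp_r2(b, s, m, nn) for b, s, m, nn in zip(beta, se, maf, n_col)]
    )
    k = len(r2)
    n = float(np.mean(n_col))
    mean_r2 = float(np.mean(r2))
    sum_r2 = min(float(np.sum(r2)), 1.0 - _EPS)
    return StrengthReport(
        trait=g.trait,
        r2=r2,
        mean_r2=mean_r2,
        k=k,
        n=n,
        f_mean_per_snp=f_statistic(mean_r2, n, 1),
        f_joint=f_statistic(sum_r2, n, k),
    )
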