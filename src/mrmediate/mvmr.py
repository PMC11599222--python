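"""Multivariable MR: joint estimation of direct effects of several exposures.

The instrument set is the union of each exposure's genome-wide-significant
instruments; for every retained SNP the per-exposure betas and the outcome
beta are aligned to a common effect allele.  The direct effects are then the
coefficients of a weighted least-squares regression of βY on the exposure-beta
matrix with no intercept and weights 1/σY² — each coefficient is an exposure's
effect on the outcome conditional on the co-exposures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from scipy import stats

from ._exceptions import DataError, IdentificationError
from .gwas_io import GwasSummary, HarmonizedSet, _align_row, _is_palindromic, select_instruments
from .uvmr import Z95


@dataclass
class MultiHarmonizedSet:
    """Union-of-instruments design for E ≥ 2 exposures and one outcome.

    ``table`` columns: rsid, beta_<exposure> and se_<exposure> per exposure,
    beta_outcome, se_outcome.  ``source`` maps each rsid to the exposures
    whose instrument sets contributed it; ``exclusions`` maps dropped rsids
    to reasons.
    """

    exposure_traits: list[str]
    outcome_trait: str
    table: pd.DataFrame
    source: dict[str, list[str]] = field(default_factory=dict)
    exclusions: dict[str, str] = field(default_factory=dict)

    @property
    def n_snp(self) -> int:
        return len(self.table)

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_traits)

    def design(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(X: J×E exposure-beta matrix, y: outcome betas, sy: outcome SEs)."""
        x = np.column_stack(
            [self.table[f"beta_{t}"].to_numpy(float) for t in self.exposure_traits]
        )
        y = self.table["beta_outcome"].to_numpy(float)
        sy = self.table["se_outcome"].to_numpy(float)
        return x, y, sy


@dataclass
class MvmrEstimate:
    """Per-exposure direct effects conditional on the co-exposures."""

    exposure_traits: list[str]
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalue: np.ndarray
    n_snp: int

    def conditioned_on(self, trait: str) -> list[str]:
        return [t for t in self.exposure_traits if t != trait]

    def for_exposure(self, trait: str) -> dict:
        i = self.exposure_traits.index(trait)
        return {
            "exposure": trait,
            "beta": float(self.beta[i]),
            "se": float(self.se[i]),
            "ci_low": float(self.ci_low[i]),
            "ci_high": float(self.ci_high[i]),
            "pvalue": float(self.pvalue[i]),
            "conditioned_on": self.conditioned_on(trait),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure": self.exposure_traits,
                "beta": self.beta,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "pvalue": self.pvalue,
                "n_snp": self.n_snp,
            }
        )


def build_multi_set(
    exposures: list[GwasSummary],
    outcome: GwasSummary,
    p_threshold: float = 5e-8,
    maf_min: float = 0.3,
    ld=None,
    r2_max: float = 0.01,
    window_kb: float = 1000.0,
    drop_palindromes: bool = True,
) -> MultiHarmonizedSet:
    """Select instruments per exposure, take the union, harmonize all studies.

    Every retained SNP was genome-wide significant for at least one exposure;
    SNPs missing from any exposure's or the outcome's summary (or with
    unresolvable alleles) are dropped and logged.  When an LD matrix is
    supplied the union is re-clumped across exposures (smallest p over the
    contributing exposures wins).
    """
    if len(exposures) < 2:
        raise DataError("multivariable MR needs at least 2 exposures")
    traits = [g.trait for g in exposures]
    if len(set(traits)) != len(traits):
        raise DataError("exposure traits must be distinct")

    source: dict[str, list[str]] = {}
    ref_alleles: dict[str, tuple[str, str, float]] = {}  # rsid -> (ea, oa, min p)
    for g in exposures:
        inst = select_instruments(
            g, p_threshold=p_threshold, maf_min=maf_min, ld=ld, r2_max=r2_max, window_kb=window_kb
        )
        for r in inst.table.itertuples(index=False):
            source.setdefault(r.rsid, []).append(g.trait)
            prev = ref_alleles.get(r.rsid)
            if prev is None or r.pvalue < prev[2]:
                ref_alleles[r.rsid] = (r.effect_allele, r.other_allele, r.pvalue)

    exclusions: dict[str, str] = {}
    by_rsid = {g.trait: g.table.set_index("rsid") for g in exposures}
    out_by_rsid = outcome.table.set_index("rsid")

    rows = []
    for rsid, (ea, oa, _p) in ref_alleles.items():
        if drop_palindromes and _is_palindromic(ea, oa):
            exclusions[rsid] = "palindromic"
            continue
        row = {"rsid": rsid}
        ok = True
        for trait in traits:
            tab = by_rsid[trait]
            if rsid not in tab.index:
                exclusions[rsid] = f"missing_in_{trait}"
                ok = False
                break
            r = tab.loc[rsid]
            rel = _align_row(ea, oa, r["effect_allele"], r["other_allele"])
            if rel is None:
                exclusions[rsid] = "allele_mismatch"
                ok = False
                break
            sign = 1.0 if rel == "same" else -1.0
            row[f"beta_{trait}"] = sign * float(r["beta"])
            row[f"se_{trait}"] = float(r["se"])
        if not ok:
            continue
        if rsid not in out_by_rsid.index:
            exclusions[rsid] = "missing_in_outcome"
            continue
        o = out_by_rsid.loc[rsid]
        rel = _align_row(ea, oa, o["effect_allele"], o["other_allele"])
        if rel is None:
            exclusions[rsid] = "allele_mismatch"
            continue
        row["beta_outcome"] = (1.0 if rel == "same" else -1.0) * float(o["beta"])
        row["se_outcome"] = float(o["se"])
        rows.append(row)

    if len(rows) <= len(traits):
        raise IdentificationError(
            f"multivariable design under-identified: {len(rows)} SNPs for {len(traits)} exposures"
        )
    cols = ["rsid"]
    for t in traits:
        cols += [f"beta_{t}", f"se_{t}"]
    cols += ["beta_outcome", "se_outcome"]
    table = pd.DataFrame(rows)[cols].sort_values("rsid").reset_index(drop=True)
    return MultiHarmonizedSet(
        exposure_traits=traits,
        outcome_trait=outcome.trait,
        table=table,
        source={k: v for k, v in source.items() if k in set(table["rsid"])},
        exclusions=exclusions,
    )


def mvmr_ivw(m, random_effects: bool = True) -> MvmrEstimate:
    """Multivariable IVW: WLS of βY on the exposure-beta matrix, no intercept.

    Accepts a :class:`MultiHarmonizedSet`, or a univariable
    :class:`~mrmediate.gwas_io.HarmonizedSet` (E=1), in which case the result
    reduces exactly to :func:`~mrmediate.uvmr.ivw_estimate`.

    SEs come from the weighted normal equations (X'WX)^{-1}, inflated by
    √max(1, Q/(J−E)) when ``random_effects``.
    """
    if isinstance(m, HarmonizedSet):
        bx, sx, by, sy = m.arrays()
        x = bx[:, None]
        traits = [m.exposure_trait]
    else:
        x, by, sy = m.design()
        traits = list(m.exposure_traits)
    j, e = x.shape
    if j <= e:
        raise IdentificationError(f"{j} SNPs cannot identify {e} exposures")
    if np.linalg.matrix_rank(x) < e:
        # name the collinear exposures by inspecting pairwise correlation
        c = np.corrcoef(x, rowvar=False)
        bad = [
            f"{traits[a]}~{traits[b]}"
            for a in range(e)
            for b in range(a + 1, e)
            if abs(c[a, b]) > 0.999
        ]
        raise IdentificationError(
            f"exposure-beta matrix is rank deficient (collinear: {bad or 'unknown pair'})"
        )
    w = 1.0 / sy**2
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * by)
    beta = np.linalg.solve(xtwx, xtwy)
    cov = np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov))
    q = float(np.sum(w * (by - x @ beta) ** 2))
    if random_effects:
        se = se * np.sqrt(max(1.0, q / (j - e)))
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return MvmrEstimate(
        exposure_traits=traits,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pvalue=np.maximum(p, np.finfo(float).tiny),
        n_snp=j,
    )
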