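"""Reading, validation, filtering and harmonization of GWAS summary statistics.

The unit of input is a delimited text table with one row per SNP carrying the
association of that SNP with one trait: rsid, effect allele, other allele,
effect-allele frequency, beta, standard error, p-value and sample size.
Betas are on the log-odds scale for binary traits and in SD units for
continuous traits.

Harmonization aligns two such tables (an exposure study and an outcome study)
to a common effect allele per SNP, resolving allele swaps and strand flips and
excluding strand-ambiguous palindromic variants, producing the
:class:`HarmonizedSet` consumed by every univariable MR estimator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import DataError

logger = logging.getLogger(__name__)

#: canonical column order of the TSV dialect written and read by this module
CANONICAL_COLUMNS = [
    "rsid",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: allele pairs whose strand cannot be resolved from the pair itself
_PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def _is_palindromic(ea: str, oa: str) -> bool:
    return (ea, oa) in _PALINDROMIC_PAIRS


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's summary association with one trait."""

    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: float

    def validate(self) -> None:
        if self.effect_allele not in _VALID_ALLELES:
            raise DataError(f"{self.rsid}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in _VALID_ALLELES:
            raise DataError(f"{self.rsid}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise DataError(f"{self.rsid}: alleles must differ")
        if not 0.0 < self.eaf < 1.0:
            raise DataError(f"{self.rsid}: eaf {self.eaf} outside (0,1)")
        if not self.se > 0.0:
            raise DataError(f"{self.rsid}: se must be strictly positive")
        if not 0.0 < self.pvalue <= 1.0:
            raise DataError(f"{self.rsid}: pvalue {self.pvalue} outside (0,1]")
        if not self.n > 0:
            raise DataError(f"{self.rsid}: sample size must be positive")


@dataclass
class GwasSummary:
    """A validated GWAS summary-statistics table for one trait.

    ``table`` holds the canonical columns (see :data:`CANONICAL_COLUMNS`);
    rsids are unique.  ``dropped`` records rows excluded at read time,
    keyed by rsid (or by row index for rows without a usable rsid).
    """

    trait: str
    trait_type: str  # "binary" | "continuous"
    table: pd.DataFrame
    dropped: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise DataError(f"trait_type must be binary or continuous, got {self.trait_type!r}")
        if len(self.table) == 0:
            raise DataError(f"{self.trait}: summary contains no valid rows")
        if self.table["rsid"].duplicated().any():
            dups = self.table.loc[self.table["rsid"].duplicated(), "rsid"].tolist()
            raise DataError(f"{self.trait}: duplicate rsids {dups[:5]}")

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def record(self, rsid: str) -> SnpAssociation:
        row = self.table.loc[self.table["rsid"] == rsid]
        if len(row) == 0:
            raise KeyError(rsid)
        r = row.iloc[0]
        return SnpAssociation(
            rsid=r["rsid"],
            effect_allele=r["effect_allele"],
            other_allele=r["other_allele"],
            eaf=float(r["eaf"]),
            beta=float(r["beta"]),
            se=float(r["se"]),
            pvalue=float(r["pvalue"]),
            n=float(r["n"]),
        )

    def write(self, path) -> None:
        """Write the canonical tab-separated dialect with a header row."""
        self.table[CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedSet:
    """Exposure and outcome effects aligned to a common effect allele.

    ``table`` columns: rsid, beta_exposure, se_exposure, beta_outcome,
    se_outcome, eaf_exposure.  ``exclusions`` maps each dropped rsid to the
    reason it was dropped (palindromic | allele_mismatch | missing_in_outcome
    | maf_filtered).
    """

    exposure_trait: str
    outcome_trait: str
    table: pd.DataFrame
    exclusions: dict[str, str] = field(default_factory=dict)

    @property
    def n_snp(self) -> int:
        return len(self.table)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exposure, se_exposure, beta_outcome, se_outcome) as float arrays."""
        t = self.table
        return (
            t["beta_exposure"].to_numpy(float),
            t["se_exposure"].to_numpy(float),
            t["beta_outcome"].to_numpy(float),
            t["se_outcome"].to_numpy(float),
        )

    def subset(self, rsids) -> "HarmonizedSet":
        keep = self.table["rsid"].isin(set(rsids))
        return HarmonizedSet(
            exposure_trait=self.exposure_trait,
            outcome_trait=self.outcome_trait,
            table=self.table.loc[keep].reset_index(drop=True),
            exclusions=dict(self.exclusions),
        )

    def write_exclusions(self, path) -> None:
        pd.DataFrame(
            {"rsid": list(self.exclusions), "reason": list(self.exclusions.values())}
        ).to_csv(path, sep="\t", index=False)


def read_gwas(
    path,
    column_map: dict[str, str] | None = None,
    trait_type: str = "binary",
    trait: str | None = None,
    sep: str = "\t",
    p_consistency_tol: float = 1.0,
) -> GwasSummary:
    """Read a delimited summary-statistics file into a validated GwasSummary.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Mapping from canonical names (:data:`CANONICAL_COLUMNS`) to the
        file's column names; canonical names present in the file need not be
        mapped.
    trait_type
        "binary" (betas are log-odds) or "continuous" (SD units).
    trait
        Trait label; defaults to the file stem.
    p_consistency_tol
        Rows whose reported p-value differs from the two-sided normal
        p implied by beta/se by more than this factor on the log10 scale are
        flagged with a warning (never dropped).

    Rows failing validation (bad alleles, eaf outside (0,1), se ≤ 0, p outside
    (0,1], non-positive n, non-finite beta) are dropped and logged with a
    reason.  A missing required column or zero surviving rows is fatal.
    """
    column_map = column_map or {}
    raw = pd.read_csv(path, sep=sep)
    rename = {v: k for k, v in column_map.items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in CANONICAL_COLUMNS if c not in raw.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}")

    df = raw[CANONICAL_COLUMNS].copy()
    df["rsid"] = df["rsid"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    dropped: dict[str, str] = {}

    def _drop(mask: pd.Series, reason: str) -> None:
        for rid in df.loc[mask, "rsid"]:
            dropped.setdefault(rid, reason)

    bad_allele = ~(
        df["effect_allele"].isin(_VALID_ALLELES)
        & df["other_allele"].isin(_VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
    )
    _drop(bad_allele, "invalid_alleles")
    bad_eaf = ~((df["eaf"] > 0) & (df["eaf"] < 1))
    _drop(bad_eaf & ~bad_allele, "eaf_out_of_range")
    bad_se = ~(df["se"] > 0)
    _drop(bad_se & ~bad_allele & ~bad_eaf, "nonpositive_se")
    bad_p = ~((df["pvalue"] > 0) & (df["pvalue"] <= 1))
    _drop(bad_p & ~bad_allele & ~bad_eaf & ~bad_se, "pvalue_out_of_range")
    bad_n = ~(df["n"] > 0)
    bad_beta = ~np.isfinite(df["beta"])
    _drop(bad_n & ~(bad_allele | bad_eaf | bad_se | bad_p), "nonpositive_n")
    _drop(bad_beta & ~(bad_allele | bad_eaf | bad_se | bad_p | bad_n), "nonfinite_beta")

    bad = bad_allele | bad_eaf | bad_se | bad_p | bad_n | bad_beta
    df = df.loc[~bad].reset_index(drop=True)
    if len(df) == 0:
        raise DataError(f"{path}: no valid rows after validation")
    if df["rsid"].duplicated().any():
        dup_mask = df["rsid"].duplicated(keep="first")
        _drop(dup_mask, "duplicate_rsid")
        df = df.loc[~dup_mask].reset_index(drop=True)

    # p-value consistency check against the two-sided normal approximation
    with np.errstate(divide="ignore"):
        implied = 2.0 * stats.norm.sf(np.abs(df["beta"] / df["se"]))
        implied = np.clip(implied, 1e-300, 1.0)
        diff = np.abs(np.log10(implied) - np.log10(df["pvalue"].to_numpy()))
    n_inconsistent = int((diff > p_consistency_tol).sum())
    if n_inconsistent:
        warnings.warn(
            f"{path}: {n_inconsistent} row(s) have p-values inconsistent with "
            f"beta/se under the normal approximation (kept)",
            stacklevel=2,
        )

    if dropped:
        logger.info("read_gwas(%s): dropped %d invalid rows", path, len(dropped))
    trait = trait if trait is not None else str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return GwasSummary(trait=trait, trait_type=trait_type, table=df, dropped=dropped)


def select_instruments(
    g: GwasSummary,
    p_threshold: float = 5e-8,
    maf_min: float = 0.3,
    ld: pd.DataFrame | np.ndarray | None = None,
    r2_max: float = 0.01,
    window_kb: float = 1000.0,
) -> GwasSummary:
    """Select genome-wide-significant, common, independent instruments.

    Retains SNPs with pvalue strictly below ``p_threshold`` and
    min(eaf, 1−eaf) ≥ ``maf_min``.  If a pairwise r² matrix ``ld`` is supplied
    (a DataFrame indexed by rsid, or an array in the row order of ``g.table``),
    correlated groups (r² ≥ ``r2_max``) are greedily clumped keeping the
    smallest-p member; locality (the ``window_kb`` window) is assumed already
    encoded in the matrix.  Without LD input the SNPs are assumed pre-clumped
    and a warning is logged.
    """
    df = g.table
    sig = df["pvalue"] < p_threshold
    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    common = maf >= maf_min
    kept = df.loc[sig & common].reset_index(drop=True)

    if len(kept) == 0:
        n_sig = int(sig.sum())
        binding = "p_threshold" if n_sig == 0 else "maf_min"
        raise DataError(
            f"{g.trait}: no instruments survive selection (binding filter: {binding}; "
            f"{n_sig}/{len(df)} pass p < {p_threshold:g}, "
            f"{int((sig & common).sum())} also pass MAF ≥ {maf_min:g})"
        )

    if ld is None:
        logger.warning(
            "%s: no LD matrix supplied; instruments assumed pre-clumped", g.trait
        )
    else:
        if isinstance(ld, pd.DataFrame):
            sub = ld.loc[kept["rsid"], kept["rsid"]].to_numpy(float)
        else:
            ld = np.asarray(ld, float)
            idx = df.index[(sig & common).to_numpy()]
            sub = ld[np.ix_(idx, idx)]
        order = np.argsort(kept["pvalue"].to_numpy(), kind="stable")
        keep_pos: list[int] = []
        for i in order:
            if all(sub[i, j] < r2_max for j in keep_pos):
                keep_pos.append(i)
        kept = kept.iloc[sorted(keep_pos)].reset_index(drop=True)

    return GwasSummary(trait=g.trait, trait_type=g.trait_type, table=kept, dropped=dict(g.dropped))


def _align_row(ea_x, oa_x, ea_y, oa_y):
    """How the outcome row relates to the exposure row's allele pair.

    Returns "same", "swap", or None (incompatible), trying the reported
    alleles first and their strand complements second.
    """
    if (ea_y, oa_y) == (ea_x, oa_x):
        return "same"
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "swap"
    cea, coa = _COMPLEMENT[ea_y], _COMPLEMENT[oa_y]
    if (cea, coa) == (ea_x, oa_x):
        return "same"
    if (cea, coa) == (oa_x, ea_x):
        return "swap"
    return None


def harmonize(
    exposure: GwasSummary,
    outcome: GwasSummary,
    drop_palindromes: bool = True,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele, per rsid.

    Same allele pair → kept as is; swapped alleles → outcome beta negated and
    eaf replaced by 1−eaf; strand flips resolved by complementing before
    comparison; incompatible pairs excluded; palindromic (A/T, C/G) exposure
    variants excluded when ``drop_palindromes`` (their strand cannot be
    resolved); rsids absent from the outcome excluded.  Zero surviving SNPs is
    fatal.
    """
    out_by_rsid = outcome.table.set_index("rsid")
    rows = []
    exclusions: dict[str, str] = {}
    for r in exposure.table.itertuples(index=False):
        if drop_palindromes and _is_palindromic(r.effect_allele, r.other_allele):
            exclusions[r.rsid] = "palindromic"
            continue
        if r.rsid not in out_by_rsid.index:
            exclusions[r.rsid] = "missing_in_outcome"
            continue
        o = out_by_rsid.loc[r.rsid]
        rel = _align_row(r.effect_allele, r.other_allele, o["effect_allele"], o["other_allele"])
        if rel is None:
            exclusions[r.rsid] = "allele_mismatch"
            continue
        beta_out = float(o["beta"]) if rel == "same" else -float(o["beta"])
        rows.append(
            (r.rsid, r.beta, r.se, beta_out, float(o["se"]), r.eaf)
        )
    if not rows:
        raise DataError(
            f"harmonize({exposure.trait} → {outcome.trait}): zero SNPs survive harmonization"
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "rsid",
            "beta_exposure",
            "se_exposure",
            "beta_outcome",
            "se_outcome",
            "eaf_exposure",
        ],
    )
    return HarmonizedSet(
        exposure_trait=exposure.trait,
        outcome_trait=outcome.trait,
        table=table,
        exclusions=exclusions,
    )
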