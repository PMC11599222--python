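"""Config-driven end-to-end runner: UVMR screen → mediator filter → MVMR
models → mediation report.

The flow mirrors the standard two-sample MR mediation workflow: univariable
MR of exposure→outcome, exposure→mediator and mediator→outcome with BH-FDR
across the family of IVW tests; mediators whose exposure→mediator or
mediator→outcome IVW fails FDR significance are dropped from the
multivariable stage; MVMR models estimate direct effects; the mediation
report decomposes the total effect by the product method (per mediator) and
the difference method (combined), on both log-odds and odds-ratio scales.

Heterogeneity (Cochran's Q) and pleiotropy (Egger intercept) tables are always
produced; when the IVW Q test indicates heterogeneity (p < 0.05) MR-PRESSO is
run to remove outlying instruments and re-estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._exceptions import ConfigError, MrError
from .gwas_io import GwasSummary, harmonize, read_gwas, select_instruments
from .instruments import strength_report
from .mediation import (
    EffectWithSe,
    difference_mediation,
    or_conversion,
    product_mediation,
)
from .mvmr import build_multi_set, mvmr_ivw
from .uvmr import (
    all_estimates,
    bh_fdr,
    cochran_q,
    directional_consistency,
    egger_intercept_test,
    mr_presso,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Everything a full pipeline run needs.

    ``exposure``/``outcome``/``mediators`` may be file paths (the canonical
    TSV dialect) or in-memory :class:`~mrmediate.gwas_io.GwasSummary` objects.
    """

    exposure: object
    outcome: object
    mediators: list = field(default_factory=list)
    exposure_trait_type: str = "binary"
    outcome_trait_type: str = "binary"
    mediator_trait_types: list[str] | None = None
    p_threshold: float = 5e-8
    maf_min: float = 0.3
    r2_max: float = 0.01
    window_kb: float = 1000.0
    drop_palindromes: bool = True
    random_effects: bool = True
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0
    fdr_alpha: float = 0.05
    models: dict[str, list[str]] | None = None  # model name -> mediator traits
    mediation_mode: str = "unadjusted"  # unadjusted | adjusted
    ci_method: str = "bootstrap"
    n_boot_mediation: int = 10_000

    def __post_init__(self) -> None:
        if self.exposure is None or self.outcome is None:
            raise ConfigError("config needs exactly one exposure and one outcome")
        if self.mediation_mode not in ("unadjusted", "adjusted"):
            raise ConfigError(f"unknown mediation_mode {self.mediation_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        try:
            kw: dict = {}
            kw["exposure"] = raw["exposure"]["path"]
            kw["exposure_trait_type"] = raw["exposure"].get("trait_type", "binary")
            kw["outcome"] = raw["outcome"]["path"]
            kw["outcome_trait_type"] = raw["outcome"].get("trait_type", "binary")
            meds = raw.get("mediators", []) or []
            kw["mediators"] = [m["path"] for m in meds]
            kw["mediator_trait_types"] = [m.get("trait_type", "continuous") for m in meds]
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"{path}: missing required config key: {exc}") from exc
        for section in ("thresholds", "estimators", "mediation"):
            for k, v in (raw.get(section) or {}).items():
                key = {
                    "mode": "mediation_mode",
                    "n_boot": "n_boot_mediation" if section == "mediation" else "n_boot",
                }.get(k, k)
                kw[key] = v
        for k in ("fdr_alpha", "models", "seed"):
            if k in raw:
                kw[k] = raw[k]
        return cls(**kw)


@dataclass
class ReportBundle:
    """All tables a pipeline run produces, writable as TSVs."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        with open(out / "run_meta.yaml", "w") as fh:
            yaml.safe_dump(self.meta, fh, sort_keys=True)


def _load(obj, trait_type: str) -> GwasSummary:
    if isinstance(obj, GwasSummary):
        return obj
    return read_gwas(obj, trait_type=trait_type)


def _uvmr_block(
    left: GwasSummary, right: GwasSummary, cfg: RunConfig, seed: int
) -> dict:
    """One univariable analysis: instrument selection on ``left``, harmonize
    against ``right``, all estimators + sensitivity analyses."""
    inst = select_instruments(
        left,
        p_threshold=cfg.p_threshold,
        maf_min=cfg.maf_min,
        r2_max=cfg.r2_max,
        window_kb=cfg.window_kb,
    )
    h = harmonize(inst, right, drop_palindromes=cfg.drop_palindromes)
    ests = all_estimates(h, n_boot=cfg.n_boot, seed=seed, random_effects=cfg.random_effects)
    consistent, _ = directional_consistency(ests)
    q_ivw = cochran_q(h, "ivw") if h.n_snp >= 2 else None
    q_egger = cochran_q(h, "egger") if h.n_snp >= 3 else None
    pleio = egger_intercept_test(h) if h.n_snp >= 3 else None
    presso = None
    if q_ivw is not None and q_ivw.pvalue < 0.05 and h.n_snp >= 4:
        presso = mr_presso(h, n_sim=cfg.n_sim, seed=seed + 7, random_effects=cfg.random_effects)
    return {
        "exposure": left.trait,
        "outcome": right.trait,
        "instruments": inst,
        "harmonized": h,
        "estimates": ests,
        "directionally_consistent": consistent,
        "q_ivw": q_ivw,
        "q_egger": q_egger,
        "pleiotropy": pleio,
        "presso": presso,
    }


def run_analysis(cfg: RunConfig, out_dir=None) -> ReportBundle:
    """Execute the full pipeline and return the report bundle.

    Identical configs and seeds produce byte-identical reports.  A fatal
    error in any stage aborts with the stage name; tables completed before
    the failure are still written when ``out_dir`` is given.
    """
    bundle = ReportBundle(
        meta={
            "mrmediate_version": __version__,
            "seed": cfg.seed,
            "p_threshold": cfg.p_threshold,
            "maf_min": cfg.maf_min,
            "fdr_alpha": cfg.fdr_alpha,
            "random_effects": cfg.random_effects,
            "n_boot": cfg.n_boot,
            "n_sim": cfg.n_sim,
            "mediation_mode": cfg.mediation_mode,
        }
    )
    stage = "load"
    try:
        exposure = _load(cfg.exposure, cfg.exposure_trait_type)
        outcome = _load(cfg.outcome, cfg.outcome_trait_type)
        med_types = cfg.mediator_trait_types or ["continuous"] * len(cfg.mediators)
        mediators = [_load(m, t) for m, t in zip(cfg.mediators, med_types)]

        # ------------------------------------------------------------------
        stage = "uvmr"
        pairs = [(exposure, outcome)]
        pairs += [(exposure, m) for m in mediators]
        pairs += [(m, outcome) for m in mediators]
        blocks = {}
        for i, (left, right) in enumerate(pairs):
            blocks[(left.trait, right.trait)] = _uvmr_block(
                left, right, cfg, seed=cfg.seed + 100 * i
            )

        est_rows, het_rows, pleio_rows, presso_rows, strength_rows = [], [], [], [], []
        ivw_keys, ivw_ps = [], []
        for key, blk in blocks.items():
            strength_rows.append(strength_report(blk["instruments"]).to_frame())
            for e in blk["estimates"]:
                row = {"exposure": key[0], "outcome": key[1], **e.to_row()}
                row["odds_ratio"] = float(np.exp(e.beta))
                row["or_ci_low"] = float(np.exp(e.ci_low))
                row["or_ci_high"] = float(np.exp(e.ci_high))
                row["directionally_consistent"] = blk["directionally_consistent"]
                est_rows.append(row)
                if e.method == "ivw":
                    ivw_keys.append(key)
                    ivw_ps.append(e.pvalue)
            for q in (blk["q_ivw"], blk["q_egger"]):
                if q is not None:
                    het_rows.append(
                        {
                            "exposure": key[0],
                            "outcome": key[1],
                            "method": q.method,
                            "q": q.q,
                            "df": q.df,
                            "pvalue": q.pvalue,
                        }
                    )
            if blk["pleiotropy"] is not None:
                p = blk["pleiotropy"]
                pleio_rows.append(
                    {
                        "exposure": key[0],
                        "outcome": key[1],
                        "egger_intercept": p.intercept,
                        "se": p.se,
                        "pvalue": p.pvalue,
                    }
                )
            if blk["presso"] is not None:
                pr = blk["presso"]
                presso_rows.append(
                    {
                        "exposure": key[0],
                        "outcome": key[1],
                        "global_p": pr.global_p,
                        "n_outliers": len(pr.outlier_rsids),
                        "outliers": ",".join(pr.outlier_rsids),
                        "corrected_beta": pr.corrected_estimate.beta,
                        "corrected_se": pr.corrected_estimate.se,
                        "corrected_n_snp": pr.corrected_estimate.n_snp,
                    }
                )

        # ------------------------------------------------------------------
        stage = "fdr"
        qvals = bh_fdr(ivw_ps)
        fdr_by_key = dict(zip(ivw_keys, qvals))
        for row in est_rows:
            if row["method"] == "ivw":
                row["fdr_q"] = fdr_by_key[(row["exposure"], row["outcome"])]

        bundle.tables["uvmr_estimates"] = pd.DataFrame(est_rows)
        bundle.tables["heterogeneity"] = pd.DataFrame(het_rows)
        bundle.tables["pleiotropy"] = pd.DataFrame(pleio_rows)
        if presso_rows:
            bundle.tables["mr_presso"] = pd.DataFrame(presso_rows)
        bundle.tables["instrument_strength"] = (
            pd.concat(strength_rows, ignore_index=True) if strength_rows else pd.DataFrame()
        )

        # ------------------------------------------------------------------
        stage = "mediator_filter"
        retained = []
        filter_rows = []
        for m in mediators:
            q_em = fdr_by_key[(exposure.trait, m.trait)]
            q_mo = fdr_by_key[(m.trait, outcome.trait)]
            keep = q_em < cfg.fdr_alpha and q_mo < cfg.fdr_alpha
            filter_rows.append(
                {
                    "mediator": m.trait,
                    "fdr_q_exposure_to_mediator": q_em,
                    "fdr_q_mediator_to_outcome": q_mo,
                    "retained": keep,
                }
            )
            if keep:
                retained.append(m)
        bundle.tables["mediator_filter"] = pd.DataFrame(filter_rows)
        logger.info(
            "retained %d/%d mediators: %s",
            len(retained),
            len(mediators),
            [m.trait for m in retained],
        )

        # ------------------------------------------------------------------
        stage = "mvmr"
        models: dict[str, list[str]] = {}
        if cfg.models is not None:
            retained_traits = {m.trait for m in retained}
            for name, meds in cfg.models.items():
                unknown = [t for t in meds if t not in retained_traits]
                if unknown:
                    logger.warning("model %s skipped: mediators %s not retained", name, unknown)
                    continue
                models[name] = list(meds)
        else:
            for i, m in enumerate(retained, 1):
                models[f"model{i}"] = [m.trait]
            if len(retained) > 1:
                models["full"] = [m.trait for m in retained]
            elif len(retained) == 1:
                models["full"] = [retained[0].trait]

        med_by_trait = {m.trait: m for m in mediators}
        mvmr_rows = []
        mvmr_fits = {}
        for name, med_traits in models.items():
            mset = build_multi_set(
                [exposure] + [med_by_trait[t] for t in med_traits],
                outcome,
                p_threshold=cfg.p_threshold,
                maf_min=cfg.maf_min,
                r2_max=cfg.r2_max,
                window_kb=cfg.window_kb,
                drop_palindromes=cfg.drop_palindromes,
            )
            fit = mvmr_ivw(mset, random_effects=cfg.random_effects)
            mvmr_fits[name] = fit
            frame = fit.to_frame()
            frame.insert(0, "model", name)
            frame["odds_ratio"] = np.exp(frame["beta"])
            frame["or_ci_low"] = np.exp(frame["ci_low"])
            frame["or_ci_high"] = np.exp(frame["ci_high"])
            mvmr_rows.append(frame)
        if mvmr_rows:
            bundle.tables["mvmr_estimates"] = pd.concat(mvmr_rows, ignore_index=True)

        # ------------------------------------------------------------------
        stage = "mediation"
        if retained and "full" in mvmr_fits:
            ivw_of = {
                key: next(e for e in blk["estimates"] if e.method == "ivw")
                for key, blk in blocks.items()
            }
            c_est = ivw_of[(exposure.trait, outcome.trait)]
            c = EffectWithSe(c_est.beta, c_est.se, "total")
            full = mvmr_fits["full"]
            direct = full.for_exposure(exposure.trait)
            c_prime = EffectWithSe(direct["beta"], direct["se"], "direct")

            med_rows = []
            for k, m in enumerate(retained):
                a_est = ivw_of[(exposure.trait, m.trait)]
                a = EffectWithSe(a_est.beta, a_est.se, m.trait)
                if cfg.mediation_mode == "adjusted":
                    bd = full.for_exposure(m.trait)
                    b = EffectWithSe(bd["beta"], bd["se"], m.trait)
                else:
                    b_est = ivw_of[(m.trait, outcome.trait)]
                    b = EffectWithSe(b_est.beta, b_est.se, m.trait)
                rec = product_mediation(
                    a, b, c, ci_method=cfg.ci_method,
                    n_boot=cfg.n_boot_mediation, seed=cfg.seed + 1000 + k,
                )
                med_rows.append(_mediation_row("product", rec, c))
            combined = difference_mediation(
                c, c_prime, ci_method=cfg.ci_method,
                n_boot=cfg.n_boot_mediation, seed=cfg.seed + 999,
            )
            med_rows.append(_mediation_row("difference", combined, c))
            table = pd.DataFrame(med_rows)
            table.insert(0, "exposure", exposure.trait)
            table.insert(1, "outcome", outcome.trait)
            total_or, total_lo, total_hi = or_conversion(c)
            bundle.meta["total_effect_beta"] = c.beta
            bundle.meta["total_effect_or"] = total_or
            bundle.meta["direct_effect_beta"] = c_prime.beta
            bundle.tables["mediation"] = table

        stage = "write"
        if out_dir is not None:
            bundle.write(out_dir)
        return bundle
    except MrError as exc:
        if out_dir is not None:
            bundle.write(out_dir)  # preserve partial outputs
        raise type(exc)(f"[stage: {stage}] {exc}") from exc


def _mediation_row(method: str, rec, c: EffectWithSe) -> dict:
    return {
        "method": method,
        "mediator": rec.label,
        "indirect_beta": rec.indirect.beta,
        "indirect_se": rec.indirect.se,
        "proportion_mediated": rec.proportion,
        "prop_ci_low": rec.prop_ci_low,
        "prop_ci_high": rec.prop_ci_high,
        "ci_method": rec.ci_method,
        "total_beta": c.beta,
    }
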