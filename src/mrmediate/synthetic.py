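"""Synthetic GWAS summary statistics under a known causal chain.

The generator emulates the structure of real two-sample MR inputs — per-SNP
betas, standard errors, allele frequencies and p-values at stated sample
sizes — for an exposure, any number of mediators, and an outcome linked by
the path diagram

    exposure --a_i--> mediator_i --b_i--> outcome
    exposure --------c_direct-----------> outcome

so the implied total effect is c = c_direct + Σ aᵢ·bᵢ, exact by construction.

Each trait's instruments are independent SNPs (LD identity): the exposure has
``n_snp_exposure`` instruments whose standardized effects are drawn uniformly
from ``instrument_z_range`` (so they clear genome-wide significance), and
each mediator additionally carries its own instrument block.  Binary-trait
effects are generated directly on the log-odds scale.  Observed betas add
normal noise with the frequency-and-sample-size-implied standard error
se = 1/√(2·MAF·(1−MAF)·N), and p-values follow the two-sided normal.

Horizontal pleiotropy (direct SNP→outcome paths bypassing the chain) can be
injected on the exposure instruments: ``balanced`` draws mean-zero normal
offsets with SD ``pleiotropy_magnitude``; ``directional`` adds a constant
offset of that magnitude on the exposure-increasing allele (i.e. the offset
carries the sign of the SNP's exposure effect, so it survives the βX ≥ 0
orientation used by Egger regression).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import ConfigError
from .gwas_io import CANONICAL_COLUMNS, GwasSummary

# ordered, non-palindromic allele pairs (strand-resolvable by construction)
_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]

EFFECT_CAP = 2.0  # |log-odds| above this is implausible for complex traits


@dataclass(frozen=True)
class SimScenario:
    """Generative parameters for one synthetic GWAS triplet (or chain)."""

    seed: int
    n_snp_exposure: int = 100
    n_snp_mediator: tuple[int, ...] = (60,)
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exposure: int = 100_000
    n_mediator: tuple[int, ...] = (100_000,)
    n_outcome: int = 100_000
    true_a: tuple[float, ...] = (0.3,)
    true_b: tuple[float, ...] = (0.25,)
    true_c_direct: float = 0.2
    pleiotropy: str = "none"  # none | balanced | directional
    pleiotropy_magnitude: float = 0.0
    instrument_z_range: tuple[float, float] = (8.0, 15.0)
    exposure_name: str = "exposure"
    mediator_names: tuple[str, ...] = ()
    outcome_name: str = "outcome"

    def __post_init__(self) -> None:
        m = len(self.true_a)
        if not (len(self.true_b) == len(self.n_snp_mediator) == len(self.n_mediator) == m):
            raise ConfigError("true_a, true_b, n_snp_mediator, n_mediator must align")
        if self.mediator_names and len(self.mediator_names) != m:
            raise ConfigError("mediator_names length must match the mediator count")
        if not self.mediator_names:
            object.__setattr__(
                self, "mediator_names", tuple(f"mediator{i + 1}" for i in range(m))
            )
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ConfigError(f"degenerate MAF range {self.maf_range}")
        for n in (self.n_exposure, self.n_outcome, *self.n_mediator):
            if n <= 0:
                raise ConfigError("sample sizes must be positive")
        if self.n_snp_exposure <= 0 or any(k < 0 for k in self.n_snp_mediator):
            raise ConfigError("instrument counts must be positive")
        for eff in (*self.true_a, *self.true_b, self.true_c_direct):
            if abs(eff) > EFFECT_CAP:
                raise ConfigError(f"|effect| {eff} exceeds cap {EFFECT_CAP}")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ConfigError(f"unknown pleiotropy mode {self.pleiotropy!r}")

    @property
    def n_mediators(self) -> int:
        return len(self.true_a)

    @property
    def c_total(self) -> float:
        """Implied total exposure→outcome effect, c_direct + Σ aᵢbᵢ."""
        return self.true_c_direct + float(
            np.sum(np.asarray(self.true_a) * np.asarray(self.true_b))
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimScenario":
        d = dict(d)
        for key in ("n_snp_mediator", "n_mediator", "true_a", "true_b",
                    "maf_range", "instrument_z_range", "mediator_names"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimTruth:
    """Realized per-SNP true effects and the implied path coefficients."""

    per_snp: pd.DataFrame  # rsid + true betas per trait + pleiotropy offset
    true_a: tuple[float, ...]
    true_b: tuple[float, ...]
    true_c_direct: float

    @property
    def c_total(self) -> float:
        return self.true_c_direct + float(
            np.sum(np.asarray(self.true_a) * np.asarray(self.true_b))
        )


def _se(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def simulate_summary_stats(s: SimScenario) -> tuple[dict[str, GwasSummary], SimTruth]:
    """Draw one synthetic GWAS dataset per trait in the causal chain.

    Returns ``(summaries, truth)`` where ``summaries`` maps trait name →
    :class:`~mrmediate.gwas_io.GwasSummary` (exposure first, mediators in
    order, outcome last) and all traits report the full SNP universe, so
    harmonization attrition is zero by construction.  Identical seeds give
    identical output bit for bit.
    """
    rng = np.random.default_rng(s.seed)
    m = s.n_mediators
    blocks = [s.n_snp_exposure, *s.n_snp_mediator]
    total = int(np.sum(blocks))
    starts = np.concatenate([[0], np.cumsum(blocks)])

    rsids = np.array([f"rs{i + 1:07d}" for i in range(total)])
    maf = rng.uniform(s.maf_range[0], s.maf_range[1], total)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), total)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    se_x = _se(maf, s.n_exposure)
    se_med = [_se(maf, n) for n in s.n_mediator]
    se_y = _se(maf, s.n_outcome)

    def _instrument_effects(idx: slice, se_trait: np.ndarray) -> np.ndarray:
        k = idx.stop - idx.start
        z = rng.uniform(*s.instrument_z_range, k)
        sign = rng.choice([-1.0, 1.0], k)
        out = np.zeros(total)
        out[idx] = sign * z * se_trait[idx]
        return out

    exp_idx = slice(int(starts[0]), int(starts[1]))
    bx_true = _instrument_effects(exp_idx, se_x)

    bm_true = []
    for i in range(m):
        med_idx = slice(int(starts[i + 1]), int(starts[i + 2]))
        own = _instrument_effects(med_idx, se_med[i])
        bm_true.append(s.true_a[i] * bx_true + own)

    pleio = np.zeros(total)
    if s.pleiotropy == "balanced" and s.pleiotropy_magnitude > 0:
        pleio[exp_idx] = rng.normal(0.0, s.pleiotropy_magnitude, blocks[0])
    elif s.pleiotropy == "directional" and s.pleiotropy_magnitude > 0:
        pleio[exp_idx] = s.pleiotropy_magnitude * np.sign(bx_true[exp_idx])

    by_true = s.true_c_direct * bx_true + pleio
    for i in range(m):
        by_true = by_true + s.true_b[i] * bm_true[i]

    def _observe(true_beta: np.ndarray, se_trait: np.ndarray, n: float,
                 trait: str, trait_type: str) -> GwasSummary:
        beta_obs = true_beta + rng.normal(0.0, se_trait)
        z = np.abs(beta_obs) / se_trait
        pval = np.clip(2.0 * stats.norm.sf(z), np.finfo(float).tiny, 1.0)
        table = pd.DataFrame(
            {
                "rsid": rsids,
                "effect_allele": ea,
                "other_allele": oa,
                "eaf": maf,
                "beta": beta_obs,
                "se": se_trait,
                "pvalue": pval,
                "n": float(n),
            }
        )[CANONICAL_COLUMNS]
        return GwasSummary(trait=trait, trait_type=trait_type, table=table)

    summaries: dict[str, GwasSummary] = {}
    summaries[s.exposure_name] = _observe(bx_true, se_x, s.n_exposure, s.exposure_name, "binary")
    for i, name in enumerate(s.mediator_names):
        summaries[name] = _observe(bm_true[i], se_med[i], s.n_mediator[i], name, "continuous")
    summaries[s.outcome_name] = _observe(by_true, se_y, s.n_outcome, s.outcome_name, "binary")

    truth_cols = {"rsid": rsids, f"true_beta_{s.exposure_name}": bx_true}
    for i, name in enumerate(s.mediator_names):
        truth_cols[f"true_beta_{name}"] = bm_true[i]
    truth_cols[f"true_beta_{s.outcome_name}"] = by_true
    truth_cols["pleiotropy_offset"] = pleio
    truth = SimTruth(
        per_snp=pd.DataFrame(truth_cols),
        true_a=s.true_a,
        true_b=s.true_b,
        true_c_direct=s.true_c_direct,
    )
    return summaries, truth


def validation_scenario(
    seed: int,
    pleiotropy: str = "none",
    pleiotropy_magnitude: float = 0.0,
    true_a: float = 0.3,
    true_b: float = 0.25,
    true_c_direct: float = 0.2,
) -> SimScenario:
    """A one-mediator scenario designed for estimator-recovery validation.

    100 exposure instruments and 60 mediator instruments at N=100,000 per
    study, with deliberately strong instruments (standardized effects drawn
    from U(40, 70), per-SNP F ≈ 1600–4900).  At that strength the
    weak-instrument regression-dilution bias of summary-data MR (of order
    1/F̄ relative) is an order of magnitude below the Monte-Carlo resolution
    of a 500-replicate recovery study, so any detectable bias indicates an
    estimator defect rather than the known finite-sample attenuation.
    """
    return SimScenario(
        seed=seed,
        n_snp_exposure=100,
        n_snp_mediator=(60,),
        n_exposure=100_000,
        n_mediator=(100_000,),
        n_outcome=100_000,
        true_a=(true_a,),
        true_b=(true_b,),
        true_c_direct=true_c_direct,
        pleiotropy=pleiotropy,
        pleiotropy_magnitude=pleiotropy_magnitude,
        instrument_z_range=(40.0, 70.0),
    )


def study_scale_scenario(seed: int = 1) -> SimScenario:
    """A scenario at the scale of the real insomnia→MI study.

    Sample sizes and instrument counts follow the source GWASs (insomnia
    N=1,207,228 / 429 instruments; smoking initiation N=1,232,091 / 77;
    alcohol consumption N=941,280 / 34; BMI N=806,834 / 60; MI N=395,795) and
    the path coefficients reproduce the reported log-odds: a_smoking=−0.626,
    b_smoking=−0.317, a_bmi=0.264, b_bmi=0.391, with c_direct chosen so the
    implied total effect is exactly c=0.674.  Alcohol consumption enters as a
    null mediator (a=ln 0.95, b=0), mirroring its exclusion from the
    multivariable stage in the real analysis.
    """
    a = (-0.626, -0.051293294387550536, 0.264)  # smoking, alcohol (ln 0.95), bmi
    b = (-0.317, 0.0, 0.391)
    c_direct = 0.674 - (a[0] * b[0] + a[1] * b[1] + a[2] * b[2])
    return SimScenario(
        seed=seed,
        n_snp_exposure=429,
        n_snp_mediator=(77, 34, 60),
        n_exposure=1_207_228,
        n_mediator=(1_232_091, 941_280, 806_834),
        n_outcome=395_795,
        true_a=a,
        true_b=b,
        true_c_direct=c_direct,
        instrument_z_range=(5.6, 9.0),
        exposure_name="insomnia",
        mediator_names=("smoking_initiation", "alcohol_consumption", "bmi"),
        outcome_name="myocardial_infarction",
    )
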