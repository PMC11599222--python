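"""Mediation decomposition of a total causal effect into direct and indirect
components, on the log-odds scale.

Notation follows the standard two-step MR mediation framework: ``c`` is the
total effect of the exposure on the outcome (univariable MR), ``a`` the
effect of the exposure on a mediator, ``b`` the effect of that mediator on
the outcome, and ``c′`` the direct effect of the exposure conditional on the
mediators (multivariable MR).  The product method estimates a mediator's
indirect effect as a·b; the difference method estimates the combined indirect
effect as c − c′.  The proportion mediated is the indirect effect divided by
the total effect.

Standard errors: first-order delta method (√(a²se_b² + b²se_a²) for the
product, √(se_c² + se_c′²) for the difference — the latter assumes c and c′
independent, an approximation since both are estimated from the same outcome
data) or a parametric bootstrap that resamples a, b, c (and c′) jointly from
independent normals; proportion CIs come from the chosen method, defaulting
to the bootstrap percentile interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import DataError
from .uvmr import Z95

DEFAULT_N_BOOT = 10_000


@dataclass(frozen=True)
class EffectWithSe:
    """A log-scale effect estimate with its standard error."""

    beta: float
    se: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise DataError(f"{self.label or 'effect'}: se must be strictly positive")


@dataclass
class MediationRecord:
    """One indirect-effect record (per-mediator or combined)."""

    label: str
    indirect: EffectWithSe
    proportion: float
    prop_ci_low: float
    prop_ci_high: float
    ci_method: str
    a: EffectWithSe | None = None
    b: EffectWithSe | None = None


@dataclass
class MediationResult:
    """Full decomposition: total, direct, per-mediator and combined records."""

    total: EffectWithSe
    direct: EffectWithSe
    per_mediator: list[MediationRecord]
    combined: MediationRecord
    ci_method: str


def _prop_ci_bootstrap(sampler, n_boot: int, seed: int) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    props = sampler(rng, n_boot)
    return (
        float(np.percentile(props, 2.5)),
        float(np.percentile(props, 97.5)),
    )


def product_mediation(
    a: EffectWithSe,
    b: EffectWithSe,
    c: EffectWithSe,
    ci_method: str = "bootstrap",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> MediationRecord:
    """Product-method indirect effect a·b and proportion mediated a·b/c.

    Delta-method SE of the product: √(a²·se_b² + b²·se_a²).  The bootstrap
    resamples a, b and c from independent normal sampling distributions.
    """
    if c.beta == 0.0:
        raise DataError("total effect is zero: proportion mediated undefined")
    indirect_beta = a.beta * b.beta
    se_delta = float(np.sqrt(a.beta**2 * b.se**2 + b.beta**2 * a.se**2))
    if se_delta == 0.0:  # a = b = 0 exactly
        se_delta = float(np.sqrt(a.se**2 * b.se**2))
    proportion = indirect_beta / c.beta

    if ci_method == "delta":
        # delta method on p = ab/c
        g = np.array([b.beta / c.beta, a.beta / c.beta, -indirect_beta / c.beta**2])
        var = float(g @ np.diag([a.se**2, b.se**2, c.se**2]) @ g)
        half = Z95 * np.sqrt(var)
        lo, hi = proportion - half, proportion + half
    elif ci_method == "bootstrap":
        def sampler(rng, n):
            a_s = rng.normal(a.beta, a.se, n)
            b_s = rng.normal(b.beta, b.se, n)
            c_s = rng.normal(c.beta, c.se, n)
            return a_s * b_s / c_s
        lo, hi = _prop_ci_bootstrap(sampler, n_boot, seed)
    else:
        raise DataError(f"unknown ci_method {ci_method!r}")
    label = a.label or b.label or "mediator"
    return MediationRecord(
        label=label,
        indirect=EffectWithSe(indirect_beta, se_delta, f"indirect({label})"),
        proportion=proportion,
        prop_ci_low=lo,
        prop_ci_high=hi,
        ci_method=ci_method,
        a=a,
        b=b,
    )


def difference_mediation(
    c: EffectWithSe,
    c_prime: EffectWithSe,
    ci_method: str = "bootstrap",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> MediationRecord:
    """Difference-method combined indirect effect c − c′ and proportion
    (c − c′)/c.  SE √(se_c² + se_c′²) under an independence approximation."""
    if c.beta == 0.0:
        raise DataError("total effect is zero: proportion mediated undefined")
    indirect_beta = c.beta - c_prime.beta
    se = float(np.sqrt(c.se**2 + c_prime.se**2))
    proportion = indirect_beta / c.beta

    if ci_method == "delta":
        g = np.array([c_prime.beta / c.beta**2, -1.0 / c.beta])
        var = float(g @ np.diag([c.se**2, c_prime.se**2]) @ g)
        half = Z95 * np.sqrt(var)
        lo, hi = proportion - half, proportion + half
    elif ci_method == "bootstrap":
        def sampler(rng, n):
            c_s = rng.normal(c.beta, c.se, n)
            cp_s = rng.normal(c_prime.beta, c_prime.se, n)
            return (c_s - cp_s) / c_s
        lo, hi = _prop_ci_bootstrap(sampler, n_boot, seed)
    else:
        raise DataError(f"unknown ci_method {ci_method!r}")
    return MediationRecord(
        label="combined",
        indirect=EffectWithSe(indirect_beta, se, "indirect(combined)"),
        proportion=proportion,
        prop_ci_low=lo,
        prop_ci_high=hi,
        ci_method=ci_method,
    )


def or_conversion(e: EffectWithSe) -> tuple[float, float, float]:
    """Log-odds → odds-ratio scale: (exp β, exp(β − 1.96·se), exp(β + 1.96·se))."""
    return (
        float(np.exp(e.beta)),
        float(np.exp(e.beta - Z95 * e.se)),
        float(np.exp(e.beta + Z95 * e.se)),
    )


def logodds_from_or(odds_ratio: float, ci_low: float, ci_high: float, label: str = "") -> EffectWithSe:
    """Inverse of :func:`or_conversion`: recover (β, se) from a printed OR and
    its symmetric 95% CI."""
    if odds_ratio <= 0 or ci_low <= 0 or ci_high <= 0:
        raise DataError("odds ratios and CI bounds must be positive")
    beta = float(np.log(odds_ratio))
    se = float((np.log(ci_high) - np.log(ci_low)) / (2.0 * Z95))
    return EffectWithSe(beta=beta, se=se, label=label)
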