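"""Shared fixtures and fast-path builders for the test suite.

The builders construct HarmonizedSet / MultiHarmonizedSet containers directly
from generator output.  The generator emits every trait on the same SNP
universe with identical allele assignments, so alignment is the identity and
the loops inside ``harmonize``/``build_multi_set`` (unit-tested separately)
can be bypassed in the replicate-heavy recovery studies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mrmediate.gwas_io import HarmonizedSet
from mrmediate.mvmr import MultiHarmonizedSet

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_hset(bx, sx, by, sy, rsids=None, eaf=None) -> HarmonizedSet:
    """HarmonizedSet straight from effect arrays (already aligned)."""
    bx = np.asarray(bx, float)
    j = len(bx)
    table = pd.DataFrame(
        {
            "rsid": rsids if rsids is not None else [f"rs{i + 1}" for i in range(j)],
            "beta_exposure": bx,
            "se_exposure": np.broadcast_to(np.asarray(sx, float), (j,)),
            "beta_outcome": np.asarray(by, float),
            "se_outcome": np.broadcast_to(np.asarray(sy, float), (j,)),
            "eaf_exposure": eaf if eaf is not None else np.full(j, 0.3),
        }
    )
    return HarmonizedSet("exposure", "outcome", table)


def aligned_hset(summaries, left: str, right: str, rsids) -> HarmonizedSet:
    """Identity-alignment HarmonizedSet between two generated summaries."""
    lt = summaries[left].table.set_index("rsid").loc[rsids]
    rt = summaries[right].table.set_index("rsid").loc[rsids]
    table = pd.DataFrame(
        {
            "rsid": list(rsids),
            "beta_exposure": lt["beta"].to_numpy(float),
            "se_exposure": lt["se"].to_numpy(float),
            "beta_outcome": rt["beta"].to_numpy(float),
            "se_outcome": rt["se"].to_numpy(float),
            "eaf_exposure": lt["eaf"].to_numpy(float),
        }
    )
    return HarmonizedSet(left, right, table)


def aligned_multiset(summaries, exposures: list[str], outcome: str, rsids) -> MultiHarmonizedSet:
    """Identity-alignment MultiHarmonizedSet over generated summaries."""
    cols = {"rsid": list(rsids)}
    for trait in exposures:
        t = summaries[trait].table.set_index("rsid").loc[rsids]
        cols[f"beta_{trait}"] = t["beta"].to_numpy(float)
        cols[f"se_{trait}"] = t["se"].to_numpy(float)
    o = summaries[outcome].table.set_index("rsid").loc[rsids]
    cols["beta_outcome"] = o["beta"].to_numpy(float)
    cols["se_outcome"] = o["se"].to_numpy(float)
    return MultiHarmonizedSet(list(exposures), outcome, pd.DataFrame(cols))


@pytest.fixture
def proportional_hset() -> HarmonizedSet:
    """Exactly proportional data: βY = 0.5·βX, so every ratio estimator
    returns 0.5 and heterogeneity is zero."""
    bx = np.array([0.08, 0.12, 0.2, 0.15, 0.1])
    return make_hset(bx, 0.01, 0.5 * bx, 0.01)


@pytest.fixture
def gwas_tsv(tmp_path):
    """Write a small well-formed summary-statistics TSV; returns the path."""

    def _write(rows, name="gwas.tsv", header=None):
        header = header or "rsid\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn"
        path = tmp_path / name
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path

    return _write
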