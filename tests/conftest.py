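import numpy as np
import pandas as pd
import pytest

from mrnetwork.iv_selection import InstrumentSet
from mrnetwork.sumstats_io import SummaryRecord, TraitMeta


def make_record(
    variant_id="rs1",
    effect_allele="A",
    other_allele="G",
    beta=0.1,
    se=0.01,
    pval=0.5,
    chrom="1",
    pos=1000,
    eaf=0.3,
    n=10_000,
):
    return SummaryRecord(
        variant_id=variant_id,
        chrom=chrom,
        pos=pos,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pval=pval,
        n=n,
    )


def make_iset(b_X, b_Y, se_Y, se_X=None, exposure="X", outcome="Y"):
    """Instrument set from raw effect arrays (defaults: tiny exposure se)."""
    b_X = np.asarray(b_X, dtype=float)
    b_Y = np.asarray(b_Y, dtype=float)
    se_Y = np.broadcast_to(np.asarray(se_Y, dtype=float), b_X.shape)
    if se_X is None:
        se_X = np.full_like(b_X, 1e-4)
    else:
        se_X = np.broadcast_to(np.asarray(se_X, dtype=float), b_X.shape)
    rows = pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(len(b_X))],
            "b_X": b_X,
            "se_X": se_X,
            "pval_X": 1e-10,
            "b_Y": b_Y,
            "se_Y": se_Y,
            "pval_Y": 0.5,
            "eaf": 0.5,
            "n_X": 100_000,
            "n_Y": 100_000,
        }
    )
    return InstrumentSet(exposure_id=exposure, outcome_id=outcome, rows=rows)


def random_records(rng, n=20, prefix="rs"):
    recs = []
    for i in range(n):
        eaf = float(rng.uniform(0.05, 0.95))
        se = float(rng.uniform(0.005, 0.05))
        recs.append(
            SummaryRecord(
                variant_id=f"{prefix}{i}",
                chrom=str(int(rng.integers(1, 23))),
                pos=int(rng.integers(1, 10**8)),
                effect_allele="A",
                other_allele="G",
                eaf=eaf,
                beta=float(rng.normal(0, 0.1)),
                se=se,
                pval=float(rng.uniform(1e-12, 1.0)),
                n=int(rng.integers(1_000, 500_000)),
            )
        )
    return recs


@pytest.fixture
def rng():
    return np.random.default_rng(87125413)


@pytest.fixture
def two_trait_registry():
    return {
        "X": TraitMeta("X", "cell", label="exposure trait"),
        "Y": TraitMeta("Y", "sarcopenia", label="outcome trait"),
    }
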