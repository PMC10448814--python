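import numpy as np
import pandas as pd
import pytest

from gutmr.harmonize import HarmonizedSet
from gutmr.io import GwasTable, ReferencePanel


def make_gwas_df(nrows=3, **overrides):
    """Small valid canonical frame; any column overridable with a list."""
    base = {
        "variant_id": [f"rs{i}" for i in range(nrows)],
        "chrom": ["1"] * nrows,
        "pos": list(range(1000, 1000 + 10_000 * nrows, 10_000)),
        "effect_allele": ["A"] * nrows,
        "other_allele": ["G"] * nrows,
        "eaf": [0.3] * nrows,
        "beta": [0.1] * nrows,
        "se": [0.02] * nrows,
        "pval": [1e-6] * nrows,
        "n": [10_000.0] * nrows,
    }
    base.update(overrides)
    return pd.DataFrame(base)


def make_table(nrows=3, trait_label="taxon", trait_type="exposure", **overrides):
    return GwasTable(trait_label, trait_type, make_gwas_df(nrows, **overrides))


def make_hset(gamma, Gamma, se_Gamma, se_gamma=None, ids=None):
    gamma = np.asarray(gamma, float)
    Gamma = np.asarray(Gamma, float)
    se_Gamma = np.asarray(se_Gamma, float)
    se_gamma = np.full_like(gamma, 0.01) if se_gamma is None else np.asarray(se_gamma, float)
    n = len(gamma)
    ids = [f"rs{i}" for i in range(n)] if ids is None else list(ids)
    df = pd.DataFrame({
        "variant_id": ids,
        "gamma": gamma, "se_gamma": se_gamma,
        "Gamma": Gamma, "se_Gamma": se_Gamma,
        "eaf_exposure": 0.3, "eaf_outcome": 0.3,
        "action": "as_is",
    })
    return HarmonizedSet("exposure", "outcome", df)


@pytest.fixture
def tiny_panel():
    """4 samples x 3 variants; rs2 monomorphic-free, all polymorphic."""
    vmap = pd.DataFrame({
        "variant_id": ["rs0", "rs1", "rs2"],
        "chrom": ["1", "1", "1"],
        "pos": [1000, 2000, 5_000_000],
        "allele_a": ["A", "C", "G"],
        "allele_b": ["G", "T", "A"],
    })
    dosages = np.array([
        [0, 2, 1],
        [1, 1, 0],
        [2, 0, 2],
        [1, 1, 1],
    ])
    return ReferencePanel(variant_map=vmap, dosages=dosages)
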