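import numpy as np
import pandas as pd
import pytest

from protmr.gwas_io import HARMONIZED_COLUMNS, SUMMARY_COLUMNS


def make_stats(rows: list[dict], trait_id: str = "trait") -> pd.DataFrame:
    """Summary-stat frame from partial row dicts with sensible defaults."""
    defaults = {
        "variant_id": None,
        "chrom": "1",
        "pos": 0,
        "effect_allele": "A",
        "other_allele": "G",
        "beta": 0.1,
        "se": 0.01,
        "pval": 1e-10,
        "eaf": 0.3,
        "n": 10_000,
        "trait_id": trait_id,
    }
    if not rows:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    recs = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["variant_id"] = f"rs{i + 1}"
        rec["pos"] = 1_000_000 + i * 10_000
        rec.update(row)
        recs.append(rec)
    return pd.DataFrame(recs)[SUMMARY_COLUMNS]


def make_pairs(
    beta_exp,
    beta_out,
    se_out=None,
    se_exp=None,
    variant_ids=None,
) -> pd.DataFrame:
    """Harmonized-pair frame straight from effect arrays."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    k = len(beta_exp)
    se_out = np.full(k, 0.05) if se_out is None else np.asarray(se_out, dtype=float)
    se_exp = np.full(k, 0.01) if se_exp is None else np.asarray(se_exp, dtype=float)
    vids = variant_ids or [f"rs{i + 1}" for i in range(k)]
    df = pd.DataFrame(
        {
            "variant_id": vids,
            "chrom": "1",
            "pos": 1_000_000 + 10_000 * np.arange(k),
            "effect_allele": "A",
            "other_allele": "G",
            "beta_exp": beta_exp,
            "se_exp": se_exp,
            "pval_exp": 1e-10,
            "eaf_exp": 0.3,
            "beta_out": beta_out,
            "se_out": se_out,
            "pval_out": 0.5,
            "eaf_out": 0.3,
            "palindromic": False,
            "flipped": False,
        }
    )
    return df[HARMONIZED_COLUMNS]


@pytest.fixture
def rng():
    return np.random.default_rng(20240829)
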