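"""Synthetic GWAS summary statistics with the structure the analysis assumes.

Generates exposure/outcome summary-statistic pairs for instrument-level
MR testing, AR(1)-LD regions for colocalization testing, and multi-protein
panels exercising the cross-protein pleiotropy filter — all on the
summary-statistic (normal-approximation) scale, with a single integer
seed driving deterministic, per-operation substreams.

The two-sample generative model, per variant j:

    maf_j      ~ Uniform(maf_range)
    b_j        ~ Normal(0, exp_effect_sd²)           true variant→exposure effect
    se_exp_j   = 1 / sqrt(2·maf_j(1−maf_j)·n_exp)
    beta_exp_j = b_j + Normal(0, se_exp_j²)
    alpha_j    ~ Normal(pleiotropy_mean, pleiotropy_sd²) w.p. pleiotropy_frac, else 0
    se_out_j   = 1 / sqrt(2·maf_j(1−maf_j)·n_out)
    beta_out_j = theta_true·b_j + sign(b_j)·alpha_j + Normal(0, se_out_j²)

Direct (pleiotropic) outcome effects are expressed relative to the
exposure-increasing allele — ``sign(b_j)·alpha_j`` — so a non-zero
``pleiotropy_mean`` produces *directional* pleiotropy that survives the
standard Egger exposure orientation; with mean 0 this is distributionally
identical to an unsigned draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwas_io import SUMMARY_COLUMNS

#: Non-palindromic allele pairs assigned cyclically to simulated variants.
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic two-sample design.

    Defaults mirror a plasma-pQTL exposure (N = 35,559) against a
    FinnGen-like binary endpoint: ``n_out`` is the effective sample size
    4/(1/cases + 1/controls) of the largest endpoint (carpal tunnel
    syndrome, 22,426 cases / 330,377 controls → ≈ 84,000).
    ``exp_effect_sd`` = 0.15 SD per allele reflects the strong cis
    signals that survive genome-wide-significance instrument selection.
    """

    n_variants: int = 50
    n_exp: int = 35_559
    n_out: int = 84_000
    theta_true: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    exp_effect_sd: float = 0.15
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    ld_rho: float = 0.9
    region_length_bp: int = 1_000_000
    variant_offset: int = 0  # shifts IDs/positions so panels can be disjoint
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimulationConfig.seed is mandatory")
        if self.n_variants < 1:
            raise ValueError(f"invalid n_variants: {self.n_variants}")
        if self.n_exp < 2 or self.n_out < 2:
            raise ValueError("invalid sample size: n_exp and n_out must be ≥ 2")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"invalid maf_range: must lie within (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.pleiotropy_frac <= 1.0:
            raise ValueError(f"invalid pleiotropy_frac: {self.pleiotropy_frac}")
        if self.pleiotropy_sd < 0:
            raise ValueError(f"invalid pleiotropy_sd: {self.pleiotropy_sd}")
        if not abs(self.ld_rho) < 1.0:
            raise ValueError(f"invalid ld_rho: |rho| must be < 1, got {self.ld_rho}")
        if self.region_length_bp < 1:
            raise ValueError(f"invalid region_length_bp: {self.region_length_bp}")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    """Deterministic per-operation substream of the config's seed."""
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def _stats_frame(
    variant_ids, chroms, positions, alleles, betas, ses, eafs, n, trait_id
) -> pd.DataFrame:
    from scipy import stats as sps

    z = betas / ses
    df = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chrom": chroms,
            "pos": positions,
            "effect_allele": [a[0] for a in alleles],
            "other_allele": [a[1] for a in alleles],
            "beta": betas,
            "se": ses,
            "pval": 2.0 * sps.norm.sf(np.abs(z)),
            "eaf": eafs,
            "n": n,
            "trait_id": trait_id,
        }
    )
    return df[SUMMARY_COLUMNS]


def _panel_positions(m: int, offset: int = 0) -> tuple[list[str], np.ndarray]:
    """Spread m variants over chromosomes 1–22, ≥2 Mb apart, clear of the MHC."""
    idx = [j + offset for j in range(m)]
    chroms = [str(1 + (j % 22)) for j in idx]
    pos = np.array([40_000_000 + (j // 22) * 2_000_000 for j in idx], dtype=np.int64)
    return chroms, pos


def simulate_instrument_panel(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one exposure and one outcome panel of independent instruments.

    Variants are placed far apart on alternating chromosomes so the panel
    is LD-free.  Returns (exposure stats, outcome stats, truth) where the
    truth table carries the latent b_j, the direct effect alpha_j on the
    exposure-increasing-allele frame, and theta_true.
    """
    m = config.n_variants
    rng = _rng(config, 0)

    maf = rng.uniform(*config.maf_range, size=m)
    b = rng.normal(0.0, config.exp_effect_sd, size=m)
    se_exp = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exp)
    beta_exp = b + rng.normal(0.0, se_exp)

    pleio = rng.random(m) < config.pleiotropy_frac
    alpha = np.where(pleio, rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=m), 0.0)
    se_out = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_out)
    sign_b = np.where(b < 0, -1.0, 1.0)
    beta_out = config.theta_true * b + sign_b * alpha + rng.normal(0.0, se_out)

    vids = [f"rs{1000 + config.variant_offset + j}" for j in range(m)]
    chroms, pos = _panel_positions(m, config.variant_offset)
    alleles = [_ALLELE_PAIRS[j % 4] for j in range(m)]

    exp_df = _stats_frame(vids, chroms, pos, alleles, beta_exp, se_exp, maf, config.n_exp, "exposure")
    out_df = _stats_frame(vids, chroms, pos, alleles, beta_out, se_out, maf, config.n_out, "outcome")
    truth = pd.DataFrame(
        {
            "variant_id": vids,
            "b": b,
            "alpha": alpha,
            "pleiotropic": pleio,
            "theta_true": config.theta_true,
        }
    )
    return exp_df, out_df, truth


def ar1_correlation(m: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix: R[i, j] = rho^|i−j|."""
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_coloc_region(
    config: SimulationConfig,
    scenario: str = "shared",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate two traits' marginal summaries over one LD region.

    Variants sit equally spaced along ``region_length_bp`` on chromosome
    1 with AR(1) LD (parameter ``ld_rho``).  Scenarios plant causal
    variants: ``shared`` (one variant causal for both traits, trait-1
    effect ``exp_effect_sd``, trait-2 effect ``theta_true·exp_effect_sd``),
    ``distinct`` (different causal variants at the 1/4 and 3/4 points),
    ``null_one`` (trait 2 null), ``null_both``.  Marginal z-scores follow
    the standard summary-statistic model z ~ Normal(R·z_true, R).
    """
    scenarios = ("shared", "distinct", "null_one", "null_both")
    if scenario not in scenarios:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {scenarios}")
    m = config.n_variants
    if scenario == "distinct" and m < 2:
        raise ValueError("'distinct' scenario needs at least 2 variants")
    rng = _rng(config, 1)

    maf = rng.uniform(*config.maf_range, size=m)
    se1 = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exp)
    se2 = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_out)

    b1 = np.zeros(m)
    b2 = np.zeros(m)
    c_mid, c_q1, c_q3 = m // 2, m // 4, (3 * m) // 4
    causal1 = causal2 = None
    eff2 = config.theta_true * config.exp_effect_sd
    if scenario == "shared":
        causal1 = causal2 = c_mid
        b1[c_mid] = config.exp_effect_sd
        b2[c_mid] = eff2
    elif scenario == "distinct":
        causal1, causal2 = c_q1, c_q3
        b1[c_q1] = config.exp_effect_sd
        b2[c_q3] = eff2
    elif scenario == "null_one":
        causal1 = c_mid
        b1[c_mid] = config.exp_effect_sd

    corr = ar1_correlation(m, config.ld_rho)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(m))
    z1 = corr @ (b1 / se1) + chol @ rng.standard_normal(m)
    z2 = corr @ (b2 / se2) + chol @ rng.standard_normal(m)

    vids = [f"rs{50_000 + j}" for j in range(m)]
    chroms = ["1"] * m
    step = max(1, config.region_length_bp // max(1, m - 1)) if m > 1 else 1
    pos = np.int64(1_000_000) + step * np.arange(m, dtype=np.int64)
    alleles = [_ALLELE_PAIRS[j % 4] for j in range(m)]

    df1 = _stats_frame(vids, chroms, pos, alleles, z1 * se1, se1, maf, config.n_exp, "trait1")
    df2 = _stats_frame(vids, chroms, pos, alleles, z2 * se2, se2, maf, config.n_out, "trait2")
    truth = {
        "scenario": scenario,
        "causal1": vids[causal1] if causal1 is not None else None,
        "causal2": vids[causal2] if causal2 is not None else None,
        "effect1": config.exp_effect_sd if causal1 is not None else 0.0,
        "effect2": eff2 if causal2 is not None else 0.0,
    }
    return df1, df2, truth


def simulate_protein_panel(
    config: SimulationConfig,
    n_proteins: int = 6,
    shared_snp_frac: float = 0.2,
) -> tuple[dict[str, pd.DataFrame], dict[str, int]]:
    """Simulate several protein exposure panels with planted cross-protein SNPs.

    A fraction ``shared_snp_frac`` of each protein's variants come from a
    common pool significant for all ``n_proteins`` proteins (so their
    protein count equals ``n_proteins``); the rest are protein-specific
    (count 1).  Returns the per-protein stats and the exact
    variant → protein-count map consumed by the pleiotropy filter.
    """
    if n_proteins < 1:
        raise ValueError(f"invalid n_proteins: {n_proteins}")
    if not 0.0 <= shared_snp_frac <= 1.0:
        raise ValueError(f"invalid shared_snp_frac: {shared_snp_frac}")
    rng = _rng(config, 2)
    m = config.n_variants
    n_shared = int(round(shared_snp_frac * m))
    n_own = m - n_shared

    shared_ids = [f"rs{900_000 + j}" for j in range(n_shared)]
    chroms_s, pos_s = _panel_positions(n_shared)
    panels: dict[str, pd.DataFrame] = {}
    counts: dict[str, int] = {v: n_proteins for v in shared_ids}

    for p in range(n_proteins):
        own_ids = [f"rs{910_000 + p * 10_000 + j}" for j in range(n_own)]
        for v in own_ids:
            counts[v] = 1
        chroms_o, pos_o = _panel_positions(n_own)
        # offset protein-specific variants so panels do not collide positionally
        pos_o = pos_o + 1_000_000 + 17 * (p + 1)

        vids = shared_ids + own_ids
        chroms = chroms_s + chroms_o
        pos = np.concatenate([pos_s, pos_o]) if n_shared and n_own else (pos_s if n_shared else pos_o)
        maf = rng.uniform(*config.maf_range, size=m)
        b = rng.normal(0.0, config.exp_effect_sd, size=m)
        # keep planted instruments genome-wide significant
        se = np.minimum(
            1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exp), np.abs(b) / 6.0 + 1e-12
        )
        alleles = [_ALLELE_PAIRS[j % 4] for j in range(m)]
        panels[f"protein_{p + 1}"] = _stats_frame(
            vids, chroms, pos, alleles, b, se, maf, config.n_exp, f"protein_{p + 1}"
        )
    return panels, counts
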