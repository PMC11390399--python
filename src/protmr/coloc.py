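"""Five-hypothesis Bayesian colocalization via approximate Bayes factors.

Given single-variant association summaries for two traits over a shared
genomic region, the method asks whether the traits are driven by the
same causal variant.  Assuming at most one causal variant per trait, the
region's evidence is partitioned over five hypotheses:

* H0 — neither trait has a causal variant in the region;
* H1 / H2 — only trait 1 / only trait 2 has one;
* H3 — both have one, but different variants;
* H4 — both share one causal variant.

Per variant, Wakefield's approximate Bayes factor compares association
against the null from (beta, se) and a prior SD on the true effect;
regional sums of these ABFs, weighted by per-variant priors p1, p2 and
p12, give posterior probabilities PPH0..PPH4.  All accumulation is done
in log space with log-sum-exp since regional Bayes factors routinely
overflow double precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp


@dataclass
class ColocConfig:
    """Priors and windowing for a colocalization run.

    p1 / p2 are the per-variant prior probabilities of being causal for
    trait 1 / trait 2 alone; p12 of being causal for both.  prior_sd_*
    are the prior SDs of true effect sizes — 0.15 per SD for a
    quantitative trait, 0.2 on the log-odds for a case-control trait,
    the method's conventional defaults.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    window_bp: int = 500_000
    prior_sd_quant: float = 0.15
    prior_sd_cc: float = 0.2
    pph4_threshold: float = 0.75

    def __post_init__(self) -> None:
        if not (0.0 < self.p12 <= min(self.p1, self.p2) < 1.0):
            raise ValueError("priors must satisfy 0 < p12 ≤ p1, p2 < 1")
        if self.p1 + self.p2 + self.p12 >= 1.0:
            raise ValueError("per-variant prior mass must leave room for H0")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.prior_sd_quant <= 0 or self.prior_sd_cc <= 0:
            raise ValueError("prior effect SDs must be positive")


@dataclass
class ColocResult:
    """Posterior probabilities over H0–H4 for one region pair."""

    n_snps: int
    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    colocalized: bool
    config: ColocConfig = field(repr=False, default_factory=ColocConfig)

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pph0, self.pph1, self.pph2, self.pph3, self.pph4])


def extract_region(stats: pd.DataFrame, center_variant: str, window_bp: int = 500_000) -> pd.DataFrame:
    """All records on the center variant's chromosome within ±window_bp (inclusive)."""
    hit = stats.loc[stats["variant_id"] == center_variant]
    if hit.empty:
        raise ValueError(f"center variant {center_variant!r} not present in the summary statistics")
    chrom = hit["chrom"].iloc[0]
    pos = int(hit["pos"].iloc[0])
    mask = (stats["chrom"] == chrom) & (stats["pos"].sub(pos).abs() <= window_bp)
    return stats.loc[mask].reset_index(drop=True)


def wakefield_labf(beta, se, prior_sd: float):
    """Wakefield's log approximate Bayes factor for association vs. null.

    With V = se², W = prior_sd², z = beta/se and shrinkage r = W/(V+W):

        log ABF = 0.5·[log(1−r) + r·z²]

    Positive values favor association at the variant.  Vectorized over
    ``beta`` and ``se``.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    v = se**2
    w = prior_sd**2
    r = w / (v + w)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + r * z**2)
    return float(out) if out.ndim == 0 else out


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) − exp(b)); −inf when the difference is non-positive."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_abf(
    region1: pd.DataFrame,
    region2: pd.DataFrame,
    config: ColocConfig | None = None,
    trait_types: tuple[str, str] = ("quant", "cc"),
) -> ColocResult:
    """Colocalize two traits' association summaries over a shared region.

    Regions are intersected on variant_id (orientation does not matter:
    the ABF depends on z² only).  Unnormalized log posterior weights:

        H0 = 0
        H1 = log p1 + logΣᵢ ABF1ᵢ
        H2 = log p2 + logΣᵢ ABF2ᵢ
        H3 = log p1 + log p2 + log(Σᵢ ABF1ᵢ · Σⱼ ABF2ⱼ − Σᵢ ABF1ᵢABF2ᵢ)
        H4 = log p12 + logΣᵢ ABF1ᵢABF2ᵢ

    With a single shared variant the H3 term is exactly zero.
    """
    cfg = config or ColocConfig()
    merged = region1.merge(region2, on="variant_id", suffixes=("_1", "_2"), how="inner")
    n = len(merged)
    if n == 0:
        raise ValueError("no overlap: the two regions share no variants")

    sd = {"quant": cfg.prior_sd_quant, "cc": cfg.prior_sd_cc}
    try:
        sd1, sd2 = sd[trait_types[0]], sd[trait_types[1]]
    except KeyError as exc:
        raise ValueError(f"trait types must be 'quant' or 'cc', got {trait_types}") from exc

    l1 = wakefield_labf(merged["beta_1"].to_numpy(), merged["se_1"].to_numpy(), sd1)
    l2 = wakefield_labf(merged["beta_2"].to_numpy(), merged["se_2"].to_numpy(), sd2)
    l1 = np.atleast_1d(l1)
    l2 = np.atleast_1d(l2)

    s1 = float(logsumexp(l1))
    s2 = float(logsumexp(l2))
    s12 = float(logsumexp(l1 + l2))

    log_w = np.array(
        [
            0.0,
            np.log(cfg.p1) + s1,
            np.log(cfg.p2) + s2,
            np.log(cfg.p1) + np.log(cfg.p2) + _logdiffexp(s1 + s2, s12),
            np.log(cfg.p12) + s12,
        ]
    )
    post = np.exp(log_w - logsumexp(log_w))
    return ColocResult(
        n_snps=n,
        pph0=float(post[0]),
        pph1=float(post[1]),
        pph2=float(post[2]),
        pph3=float(post[3]),
        pph4=float(post[4]),
        colocalized=bool(post[4] > cfg.pph4_threshold),
        config=cfg,
    )
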