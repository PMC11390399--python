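"""Instrument (IV) quality control for protein exposures.

Five filters are applied in sequence to each exposure's summary
statistics: genome-wide significance, MHC exclusion, LD clumping,
a cross-protein pleiotropy filter, and finally a weak-instrument check
via the F-statistic

    F = R² (N − 1 − k) / [(1 − R²) k]

where R² is the variance in the exposure explained jointly by the k
instruments and N is the exposure GWAS sample size.  Sets with F < 10
are flagged weak and excluded from causal estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas_io import harmonize

logger = logging.getLogger(__name__)

#: MHC interval on chromosome 6 per genome build, 1-based, both ends inclusive.
MHC_REGIONS = {
    "GRCh37": (26_000_000, 34_000_000),
    "GRCh38": (29_000_000, 33_000_000),
}


@dataclass
class LDMatrix:
    """Squared-correlation (r²) matrix over an ordered set of variants."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise ValueError("LD matrix shape does not match the variant list")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("LD matrix diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("LD r² entries must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def lookup(self, a: str, b: str) -> float | None:
        """r² between two variants, or None if either is absent."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        """Read a square TSV whose header and first column are variant IDs."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))


@dataclass
class IVConfig:
    """Thresholds for the instrument-selection filters."""

    p_threshold: float = 5e-8
    build: str = "GRCh37"
    clump_r2: float = 0.001
    clump_kb: int = 500
    max_proteins: int = 5
    f_min: float = 10.0
    palindrome_eaf_band: float = 0.08
    r2_convention: str = "maf_beta"  # or "beta_se_n"


@dataclass
class InstrumentSet:
    """Post-QC instruments for one exposure with strength diagnostics."""

    trait_id: str
    variants: pd.DataFrame  # harmonized pairs, one row per instrument
    per_variant_r2: np.ndarray
    r2_total: float
    n_exposure: int
    k: int
    f_stat: float
    filter_log: dict[str, int] = field(default_factory=dict)
    weak: bool = False


def filter_significance(stats: pd.DataFrame, p_threshold: float = 5e-8) -> pd.DataFrame:
    """Keep records at genome-wide significance, p ≤ threshold (inclusive)."""
    return stats.loc[stats["pval"] <= p_threshold].reset_index(drop=True)


def exclude_mhc(stats: pd.DataFrame, build: str) -> pd.DataFrame:
    """Drop chromosome-6 records inside the MHC region for the given build."""
    try:
        lo, hi = MHC_REGIONS[build]
    except KeyError:
        raise ValueError(f"unknown genome build {build!r}; expected one of {sorted(MHC_REGIONS)}") from None
    in_mhc = (stats["chrom"].astype(str) == "6") & stats["pos"].between(lo, hi)
    return stats.loc[~in_mhc].reset_index(drop=True)


def _clump_order(stats: pd.DataFrame) -> pd.DataFrame:
    return stats.sort_values(
        ["pval", "chrom", "pos", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)


def ld_clump(
    stats: pd.DataFrame,
    ld: LDMatrix | None = None,
    r2_threshold: float = 0.001,
    window_kb: int = 500,
) -> pd.DataFrame:
    """Greedy LD clumping: keep index SNPs, discard their LD partners.

    Records are ranked by ascending p-value (ties broken by chromosome,
    position, variant_id).  The most significant remaining record becomes
    an index; every remaining same-chromosome record within ±window_kb
    whose r² with the index exceeds ``r2_threshold`` is discarded.  With
    no LD matrix — or for pairs missing from it — every same-chromosome
    pair inside the window is treated as linked (distance-only clumping,
    the conservative fallback).
    """
    if stats.empty:
        return stats.reset_index(drop=True)
    ordered = _clump_order(stats)
    window_bp = window_kb * 1000
    chroms = ordered["chrom"].astype(str).to_numpy()
    pos = ordered["pos"].to_numpy()
    vids = ordered["variant_id"].to_numpy()

    alive = np.ones(len(ordered), dtype=bool)
    keep: list[int] = []
    warned_missing = False
    for i in range(len(ordered)):
        if not alive[i]:
            continue
        keep.append(i)
        for j in range(i + 1, len(ordered)):
            if not alive[j] or chroms[j] != chroms[i]:
                continue
            if abs(int(pos[j]) - int(pos[i])) > window_bp:
                continue
            r2 = ld.lookup(vids[i], vids[j]) if ld is not None else None
            if r2 is None:
                if ld is not None and not warned_missing:
                    logger.warning(
                        "ld_clump: variant pair missing from LD matrix; using distance-only rule"
                    )
                    warned_missing = True
                alive[j] = False  # distance-only: treat as linked
            elif r2 > r2_threshold:
                alive[j] = False
    return ordered.iloc[keep].reset_index(drop=True)


def cross_protein_pleiotropy_filter(
    stats: pd.DataFrame,
    snp_to_protein_count: dict[str, int],
    max_proteins: int = 5,
) -> pd.DataFrame:
    """Drop variants significantly associated with ≥ max_proteins proteins.

    The count includes the variant's own protein; variants absent from
    the map default to a count of 1 (associated with this protein only).
    """
    counts = stats["variant_id"].map(lambda v: snp_to_protein_count.get(v, 1))
    return stats.loc[counts < max_proteins].reset_index(drop=True)


def variant_r2(beta: float, eaf: float, variant_id: str = "?") -> float:
    """Exposure variance explained by one variant: 2·eaf·(1−eaf)·beta².

    Assumes an SD-standardized exposure, so beta is in SD units per
    effect-allele copy.
    """
    if eaf is None or (isinstance(eaf, float) and np.isnan(eaf)):
        raise ValueError(f"variant {variant_id}: eaf required to compute explained variance")
    if not 0.0 < eaf < 1.0:
        raise ValueError(f"variant {variant_id}: eaf must lie in (0,1), got {eaf}")
    return 2.0 * eaf * (1.0 - eaf) * beta * beta


def variant_r2_from_se(beta: float, se: float, n: int) -> float:
    """Alternative explained-variance convention: beta² / (beta² + N·se²)."""
    return beta * beta / (beta * beta + n * se * se)


def f_statistic(r2_total: float, n: int, k: int) -> float:
    """Joint instrument-strength F = R²(N−1−k) / [(1−R²)k]."""
    if not 0.0 <= r2_total < 1.0:
        raise ValueError(f"r2_total must lie in [0,1), got {r2_total}")
    if k < 1:
        raise ValueError(f"k must be ≥ 1, got {k}")
    if n <= k + 1:
        raise ValueError(f"sample size n={n} must exceed k+1={k + 1}")
    return (r2_total * (n - 1 - k)) / ((1.0 - r2_total) * k)


def build_instrument_set(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: LDMatrix | None = None,
    config: IVConfig | None = None,
    snp_to_protein_count: dict[str, int] | None = None,
) -> InstrumentSet:
    """Run the full instrument-QC cascade for one exposure/outcome pair.

    Order: significance → MHC exclusion → LD clumping → cross-protein
    pleiotropy filter → harmonization against the outcome → explained
    variance and F-statistic.  A set with F < ``config.f_min`` is flagged
    weak; an empty set (k = 0) is returned flagged, not raised.
    """
    cfg = config or IVConfig()
    counts = snp_to_protein_count or {}
    trait_id = str(exposure["trait_id"].iloc[0]) if len(exposure) else "exposure"
    log: dict[str, int] = {}

    stage = filter_significance(exposure, cfg.p_threshold)
    log["significance"] = len(exposure) - len(stage)

    prev = stage
    stage = exclude_mhc(stage, cfg.build)
    log["mhc"] = len(prev) - len(stage)

    prev = stage
    stage = ld_clump(stage, ld, cfg.clump_r2, cfg.clump_kb)
    log["clump"] = len(prev) - len(stage)

    prev = stage
    stage = cross_protein_pleiotropy_filter(stage, counts, cfg.max_proteins)
    log["cross_protein"] = len(prev) - len(stage)

    prev = stage
    pairs = harmonize(stage, outcome, cfg.palindrome_eaf_band)
    log["harmonization"] = len(prev) - len(pairs)

    k = len(pairs)
    n_exp = int(exposure["n"].max()) if len(exposure) else 0
    if k == 0:
        return InstrumentSet(trait_id, pairs, np.array([]), 0.0, n_exp, 0, float("nan"), log, weak=True)

    if cfg.r2_convention == "beta_se_n":
        per_r2 = np.array(
            [variant_r2_from_se(r.beta_exp, r.se_exp, n_exp) for r in pairs.itertuples()]
        )
    else:
        per_r2 = np.array(
            [variant_r2(r.beta_exp, r.eaf_exp, r.variant_id) for r in pairs.itertuples()]
        )
    r2_total = float(per_r2.sum())
    f = f_statistic(r2_total, n_exp, k)
    weak = f < cfg.f_min
    if weak:
        logger.info("instrument set for %s is weak (F=%.3f < %.1f)", trait_id, f, cfg.f_min)
    return InstrumentSet(trait_id, pairs, per_r2, r2_total, n_exp, k, f, log, weak)
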