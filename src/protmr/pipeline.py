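"""Proteome-wide screen orchestration: MR across all exposure–outcome
pairs, multiplicity control, pleiotropy-based exclusion, and
colocalization of the significant hits.

The screen runs each exposure against each outcome: instrument QC
(:mod:`protmr.iv_selection`), the count-selected primary estimator plus
Egger and weighted-median secondaries, a sensitivity report, and an
outcome-level exclusion when the Egger intercept test indicates
directional pleiotropy (p < 0.05).  Primary p-values across all retained
pairs form one Benjamini–Hochberg family; a Bonferroni flag at
alpha/m is reported alongside.  Pairs passing the significance gate are
followed up with colocalization around their top instrument.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import mr_core
from .coloc import ColocConfig, coloc_abf, extract_region
from .iv_selection import IVConfig, LDMatrix, build_instrument_set
from .mr_core import MREstimate

logger = logging.getLogger(__name__)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Sorted ascending, q_i = min_{j ≥ i} p_j·m/j clipped at 1, returned
    in the original order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0,1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of tests must be ≥ 1, got {m}")
    return alpha / m


def outcome_pleiotropy_exclusion(report: mr_core.SensitivityReport) -> tuple[bool, str]:
    """Exclude a pair whose Egger intercept test is significant (p < 0.05)."""
    if report.egger_intercept_pval < 0.05:
        return True, "egger_intercept_p<0.05"
    return False, ""


@dataclass
class PipelineConfig:
    """All thresholds and knobs for one screen run."""

    iv: IVConfig = field(default_factory=IVConfig)
    coloc: ColocConfig = field(default_factory=ColocConfig)
    alpha: float = 0.05
    m_tests: int | None = None  # Bonferroni family size; None → retained pairs
    coloc_gate: str = "bonferroni"  # or "bh"
    bh_q_threshold: float = 0.05
    n_boot: int = 10_000
    seed: int = 0
    primary_method_override: str | None = None


@dataclass
class PipelineResult:
    """Output tables of one screen run."""

    results: pd.DataFrame
    sensitivity: pd.DataFrame
    loo: pd.DataFrame
    coloc: pd.DataFrame
    log: list[str] = field(default_factory=list)


_EST_COLS = ["theta", "se", "ci_low", "ci_high", "pval", "or_", "or_low", "or_high"]


def _est_dict(est: MREstimate | None, prefix: str = "") -> dict:
    if est is None:
        return {prefix + c: np.nan for c in _EST_COLS}
    return {
        prefix + "theta": est.theta,
        prefix + "se": est.se,
        prefix + "ci_low": est.ci_low,
        prefix + "ci_high": est.ci_high,
        prefix + "pval": est.pval,
        prefix + "or_": est.or_,
        prefix + "or_low": est.or_low,
        prefix + "or_high": est.or_high,
    }


def run_pipeline(
    exposures: dict[str, pd.DataFrame],
    outcomes: dict[str, pd.DataFrame],
    ld: LDMatrix | None = None,
    config: PipelineConfig | None = None,
    snp_to_protein_count: dict[str, int] | None = None,
) -> PipelineResult:
    """Screen every exposure against every outcome.

    Per pair: instrument QC → primary estimate (method chosen by
    instrument count) → Egger and weighted-median secondaries when k ≥ 3
    → sensitivity report → pleiotropy exclusion.  BH-FDR is applied once
    across all retained primary p-values; the Bonferroni flag uses
    ``config.m_tests`` (defaulting to the retained-family size).  Pairs
    passing the configured significance gate get a colocalization run
    centered on their most significant instrument.  Row order is
    deterministic: exposure, then outcome, sorted lexically.
    """
    cfg = config or PipelineConfig()
    log: list[str] = []
    rows: list[dict] = []
    sens_rows: list[dict] = []
    loo_rows: list[dict] = []
    keep_pairs: dict[tuple[str, str], pd.DataFrame] = {}

    for exp_name in sorted(exposures):
        for out_name in sorted(outcomes):
            row: dict = {"exposure": exp_name, "outcome": out_name}
            iv_set = build_instrument_set(
                exposures[exp_name],
                outcomes[out_name],
                ld,
                cfg.iv,
                snp_to_protein_count,
            )
            row["k"] = iv_set.k
            row["f_stat"] = iv_set.f_stat
            row["r2_total"] = iv_set.r2_total
            for stage, n_removed in iv_set.filter_log.items():
                row[f"removed_{stage}"] = n_removed

            if iv_set.k == 0:
                row["excluded_reason"] = "no_iv"
                rows.append(row)
                log.append(f"{exp_name}~{out_name}: no instruments survived QC")
                continue
            if iv_set.weak:
                row["excluded_reason"] = "weak_iv"
                rows.append(row)
                log.append(f"{exp_name}~{out_name}: weak instruments (F={iv_set.f_stat:.3f})")
                continue

            pairs = iv_set.variants
            try:
                method = cfg.primary_method_override or mr_core.select_primary_method(iv_set.k)
                primary = mr_core.estimate(pairs, method, seed=cfg.seed)
            except Exception as exc:  # pragma: no cover - defensive
                row["excluded_reason"] = f"estimation_failed:{exc}"
                rows.append(row)
                log.append(f"{exp_name}~{out_name}: estimation failed: {exc}")
                continue

            row["method"] = primary.method
            row.update(_est_dict(primary))

            if iv_set.k >= 3:
                egger = mr_core.mr_egger(pairs)
                wm = mr_core.weighted_median(pairs, n_boot=cfg.n_boot, seed=cfg.seed)
                report = mr_core.sensitivity_report(pairs)
                row.update(_est_dict(egger.slope, "egger_"))
                row.update(_est_dict(wm, "wm_"))
                sens_rows.append(
                    {
                        "exposure": exp_name,
                        "outcome": out_name,
                        "q_stat": report.q_stat,
                        "q_df": report.q_df,
                        "q_pval": report.q_pval,
                        "egger_intercept": report.egger_intercept,
                        "egger_intercept_se": report.egger_intercept_se,
                        "egger_intercept_pval": report.egger_intercept_pval,
                        "pleiotropy_flag": report.pleiotropy_flag,
                    }
                )
                for vid, est in report.loo:
                    loo_rows.append(
                        {
                            "exposure": exp_name,
                            "outcome": out_name,
                            "removed_variant": vid,
                            "method": est.method,
                            **_est_dict(est),
                        }
                    )
                excluded, reason = outcome_pleiotropy_exclusion(report)
                if excluded:
                    # excluded rows carry no downstream estimates
                    for prefix in ("", "egger_", "wm_"):
                        for c in _EST_COLS:
                            row.pop(prefix + c, None)
                    row.pop("method", None)
                    row["excluded_reason"] = reason
                    rows.append(row)
                    log.append(f"{exp_name}~{out_name}: excluded, {reason}")
                    continue

            row["excluded_reason"] = ""
            keep_pairs[(exp_name, out_name)] = iv_set.variants
            rows.append(row)

    results = pd.DataFrame(rows)
    if results.empty:
        raise ValueError("pipeline produced no rows: need ≥1 exposure and ≥1 outcome")
    retained = results["excluded_reason"] == ""
    results["fdr_qval"] = np.nan
    results["bonferroni_pass"] = False
    m = cfg.m_tests if cfg.m_tests is not None else int(retained.sum())
    if retained.any():
        pvals = results.loc[retained, "pval"].to_numpy()
        results.loc[retained, "fdr_qval"] = bh_fdr(pvals)
        thr = bonferroni_threshold(cfg.alpha, max(m, 1))
        results.loc[retained, "bonferroni_pass"] = pvals < thr
        log.append(f"multiplicity: {int(retained.sum())} retained tests, Bonferroni m={max(m, 1)}")

    # colocalization follow-up for pairs passing the significance gate
    coloc_rows: list[dict] = []
    for idx, row in results.loc[retained].iterrows():
        passes = (
            bool(row["bonferroni_pass"])
            if cfg.coloc_gate == "bonferroni"
            else row["fdr_qval"] < cfg.bh_q_threshold
        )
        if not passes:
            continue
        key = (row["exposure"], row["outcome"])
        pairs = keep_pairs[key]
        top = pairs.sort_values(["pval_exp", "variant_id"]).iloc[0]["variant_id"]
        try:
            reg1 = extract_region(exposures[row["exposure"]], top, cfg.coloc.window_bp)
            reg2 = extract_region(outcomes[row["outcome"]], top, cfg.coloc.window_bp)
            res = coloc_abf(reg1, reg2, cfg.coloc, ("quant", "cc"))
        except ValueError as exc:
            log.append(f"{key[0]}~{key[1]}: colocalization skipped: {exc}")
            continue
        coloc_rows.append(
            {
                "exposure": row["exposure"],
                "outcome": row["outcome"],
                "center_variant": top,
                "n_snps": res.n_snps,
                "pph0": res.pph0,
                "pph1": res.pph1,
                "pph2": res.pph2,
                "pph3": res.pph3,
                "pph4": res.pph4,
                "colocalized": res.colocalized,
            }
        )

    sens = pd.DataFrame(sens_rows)
    loo = pd.DataFrame(loo_rows)
    coloc_df = pd.DataFrame(coloc_rows)
    return PipelineResult(results, sens, loo, coloc_df, log)
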