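"""Two-sample MR estimators and sensitivity analysis.

All estimators consume a harmonized pair table (columns ``beta_exp``,
``se_exp``, ``beta_out``, ``se_out``; see :mod:`protmr.gwas_io`) and
report the causal effect ``theta`` on the log-odds-per-SD scale together
with its odds-ratio rendering exp(theta).

Method selection follows the instrument count: a single instrument gets
the Wald ratio, two or three the fixed-effect inverse-variance-weighted
(IVW) estimator, four or more the multiplicative random-effects IVW,
which inflates the fixed-effect SE by max(1, sqrt(Q/(k−1))) to absorb
between-instrument heterogeneity.  MR-Egger (weighted regression with a
free intercept) and the weighted median serve as pleiotropy-robust
secondary estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

Z95 = 1.96  # fixed 95% CI multiplier


@dataclass
class MREstimate:
    """One causal estimate: log-odds scale plus its odds-ratio rendering."""

    method: str
    theta: float
    se: float
    pval: float
    k: int
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    or_: float = field(init=False)
    or_low: float = field(init=False)
    or_high: float = field(init=False)

    def __post_init__(self) -> None:
        self.ci_low = self.theta - Z95 * self.se
        self.ci_high = self.theta + Z95 * self.se
        self.or_, self.or_low, self.or_high = to_odds_ratio(self.theta, self.se)


@dataclass
class EggerResult:
    """MR-Egger slope estimate plus the pleiotropy intercept test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


@dataclass
class SensitivityReport:
    """Heterogeneity, pleiotropy and leave-one-out diagnostics for one pair."""

    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_pval: float
    loo: list[tuple[str, MREstimate]]
    pleiotropy_flag: bool


def to_odds_ratio(theta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds effect and its 95% CI to the OR scale."""
    if se < 0:
        raise ValueError("se must be non-negative")
    return (
        float(np.exp(theta)),
        float(np.exp(theta - Z95 * se)),
        float(np.exp(theta + Z95 * se)),
    )


def select_primary_method(k: int) -> str:
    """Primary estimator by instrument count: 1 → Wald, 2–3 → fixed IVW, ≥4 → random IVW."""
    if k <= 0:
        raise ValueError(f"instrument count must be positive, got {k}")
    if k == 1:
        return "wald_ratio"
    if k <= 3:
        return "ivw_fixed"
    return "ivw_random"


def _arrays(pairs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    return (
        pairs["beta_exp"].to_numpy(dtype=float),
        pairs["se_exp"].to_numpy(dtype=float),
        pairs["beta_out"].to_numpy(dtype=float),
        pairs["se_out"].to_numpy(dtype=float),
    )


def _normal_p(z: float) -> float:
    return float(2.0 * sps.norm.sf(abs(z)))


def wald_ratio(pair: pd.DataFrame | pd.Series) -> MREstimate:
    """Single-instrument ratio estimate theta = beta_out / beta_exp.

    The SE uses the first-order delta method, se_out / |beta_exp|,
    ignoring exposure-side sampling error (the convention matching IVW
    weighting).
    """
    if isinstance(pair, pd.DataFrame):
        if len(pair) != 1:
            raise ValueError("wald_ratio takes exactly one instrument")
        pair = pair.iloc[0]
    bx, bo, so = float(pair["beta_exp"]), float(pair["beta_out"]), float(pair["se_out"])
    if bx == 0.0:
        raise ValueError("undefined ratio: exposure beta is zero")
    theta = bo / bx
    se = so / abs(bx)
    return MREstimate("wald_ratio", theta, se, _normal_p(theta / se), 1)


def _ivw_core(bx: np.ndarray, bo: np.ndarray, so: np.ndarray) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Fixed-effect IVW via ratio weights; returns (theta, se_fixed, ratios, w)."""
    ratios = bo / bx
    w = bx**2 / so**2
    theta = float(np.sum(w * ratios) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return theta, se, ratios, w


def ivw(pairs: pd.DataFrame, model: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted meta-analysis of per-variant ratio estimates.

    Equivalent to weighted least squares of beta_out on beta_exp through
    the origin with weights 1/se_out².  ``model="random"`` applies the
    multiplicative overdispersion correction: the fixed-effect SE is
    scaled by max(1, sqrt(Q/(k−1))), never deflated below the
    fixed-effect value.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown IVW model {model!r}")
    k = len(pairs)
    if k < 2:
        raise ValueError("IVW requires ≥2 instruments; use wald_ratio for a single IV")
    bx, _, bo, so = _arrays(pairs)
    theta, se, ratios, w = _ivw_core(bx, bo, so)
    if model == "random":
        q = float(np.sum(w * (ratios - theta) ** 2))
        se *= max(1.0, np.sqrt(q / (k - 1)))
    method = "ivw_fixed" if model == "fixed" else "ivw_random"
    return MREstimate(method, theta, se, _normal_p(theta / se), k)


def cochran_q(pairs: pd.DataFrame, theta_ref: float) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic about a reference estimate.

    Q = Σ wⱼ(θⱼ − theta_ref)² with IVW weights; df = k−1; upper-tail
    chi-square p-value.  ``theta_ref`` should be the fixed-effect IVW
    estimate.
    """
    bx, _, bo, so = _arrays(pairs)
    ratios = bo / bx
    w = bx**2 / so**2
    q = float(np.sum(w * (ratios - theta_ref) ** 2))
    df = len(pairs) - 1
    pval = float(sps.chi2.sf(q, df)) if df > 0 else float("nan")
    return q, df, pval


def mr_egger(pairs: pd.DataFrame) -> EggerResult:
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    Each pair is re-signed so beta_exp ≥ 0 before fitting (the standard
    exposure orientation; the slope is unchanged by this joint sign
    flip).  Weights are 1/se_out²; SEs carry the multiplicative
    overdispersion factor max(1, sqrt(RSS_w/(k−2))); inference uses the
    t distribution with k−2 degrees of freedom.  A non-zero intercept
    indicates directional horizontal pleiotropy.
    """
    k = len(pairs)
    if k < 3:
        raise ValueError("Egger requires ≥3 instruments")
    bx, _, bo, so = _arrays(pairs)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, bo = bx * sign, bo * sign
    w = 1.0 / so**2

    x = np.column_stack([np.ones(k), bx])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * bo)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = bo - x @ coef
    rss_w = float(np.sum(w * resid**2))
    phi = max(1.0, rss_w / (k - 2))
    cov = phi * np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov))

    df = k - 2
    p_slope = float(2.0 * sps.t.sf(abs(coef[1] / se[1]), df))
    p_int = float(2.0 * sps.t.sf(abs(coef[0] / se[0]), df))
    slope = MREstimate("egger", float(coef[1]), float(se[1]), p_slope, k)
    return EggerResult(slope, float(coef[0]), float(se[0]), p_int)


def weighted_median(pairs: pd.DataFrame, n_boot: int = 10_000, seed: int | None = None) -> MREstimate:
    """Weighted median of the per-variant ratio estimates.

    Consistent when instruments carrying up to half the total weight are
    invalid.  Ratios are ordered ascending with normalized
    inverse-variance weights; the estimate interpolates linearly where
    the cumulative weight midpoint crosses 0.5.  The SE comes from a
    parametric bootstrap (ratios resampled from Normal(θⱼ, se_θⱼ),
    weights fixed) and is reproducible given ``seed``.
    """
    k = len(pairs)
    if k < 3:
        raise ValueError("weighted median requires ≥3 instruments")
    if seed is None:
        raise ValueError("weighted_median requires an explicit bootstrap seed")
    bx, _, bo, so = _arrays(pairs)
    ratios = bo / bx
    se_ratio = so / np.abs(bx)
    w = 1.0 / se_ratio**2

    theta = _weighted_median_point(ratios, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(ratios, se_ratio, size=(n_boot, k))
    boots = np.array([_weighted_median_point(d, w) for d in draws])
    se = float(boots.std(ddof=1))
    pval = _normal_p(theta / se) if se > 0 else (1.0 if theta == 0 else 0.0)
    return MREstimate("weighted_median", theta, se, pval, k)


def _weighted_median_point(ratios: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    wn = w[order] / w.sum()
    s = np.cumsum(wn) - 0.5 * wn  # cumulative-weight midpoints
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] <= 0.5:
        return float(r[-1])
    j = int(np.searchsorted(s, 0.5, side="right")) - 1
    return float(r[j] + (r[j + 1] - r[j]) * (0.5 - s[j]) / (s[j + 1] - s[j]))


def estimate(pairs: pd.DataFrame, method: str | None = None, seed: int | None = None) -> MREstimate:
    """Fit the named estimator, or the count-selected primary method."""
    m = method or select_primary_method(len(pairs))
    if m == "wald_ratio":
        return wald_ratio(pairs)
    if m == "ivw_fixed":
        return ivw(pairs, "fixed")
    if m == "ivw_random":
        return ivw(pairs, "random")
    if m == "egger":
        return mr_egger(pairs).slope
    if m == "weighted_median":
        return weighted_median(pairs, seed=seed)
    raise ValueError(f"unknown MR method {m!r}")


def leave_one_out(pairs: pd.DataFrame) -> list[tuple[str, MREstimate]]:
    """Re-estimate with each instrument removed in turn.

    Each reduced fit uses the primary method selected for k−1
    instruments.  Returns (removed variant_id, estimate) in input order.
    """
    k = len(pairs)
    if k < 3:
        raise ValueError("leave-one-out requires ≥3 instruments")
    out = []
    for i in range(k):
        rest = pairs.drop(pairs.index[i])
        out.append((str(pairs.iloc[i]["variant_id"]), estimate(rest)))
    return out


def sensitivity_report(pairs: pd.DataFrame) -> SensitivityReport:
    """Cochran's Q, Egger intercept test and leave-one-out for one pair set.

    Requires ≥3 instruments (Egger and leave-one-out are undefined
    below that); the pleiotropy flag is raised when the Egger intercept
    p-value falls below 0.05.
    """
    theta_fixed = ivw(pairs, "fixed").theta
    q, df, q_p = cochran_q(pairs, theta_fixed)
    egger = mr_egger(pairs)
    loo = leave_one_out(pairs)
    return SensitivityReport(
        q_stat=q,
        q_df=df,
        q_pval=q_p,
        egger_intercept=egger.intercept,
        egger_intercept_se=egger.intercept_se,
        egger_intercept_pval=egger.intercept_pval,
        loo=loo,
        pleiotropy_flag=egger.intercept_pval < 0.05,
    )
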