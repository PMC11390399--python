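"""Reading, validation, harmonization and writing of GWAS summary statistics.

Summary statistics are held as pandas DataFrames with one row per variant
and the canonical columns listed in :data:`SUMMARY_COLUMNS`.  Exposure
betas are on the SD scale of the (protein) trait; outcome betas are
log-odds.  Harmonization expresses exposure and outcome effects on a
common effect allele so that downstream MR estimators can consume
(beta_exp, beta_out) pairs directly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column order for a summary-statistic table.
SUMMARY_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
    "eaf",
    "n",
    "trait_id",
]

#: Canonical columns of a harmonized exposure/outcome pair table.
HARMONIZED_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta_exp",
    "se_exp",
    "pval_exp",
    "eaf_exp",
    "beta_out",
    "se_out",
    "pval_out",
    "eaf_out",
    "palindromic",
    "flipped",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_MANDATORY_FIELDS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
    "n",
]


def _complement(allele: str) -> str | None:
    """Reverse-strand complement of an allele string, or None if ambiguous."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(allele))
    except KeyError:
        return None


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for A/T and C/G single-base pairs, whose strand is unresolvable."""
    return (
        len(effect_allele) == 1
        and len(other_allele) == 1
        and _COMPLEMENT.get(effect_allele) == other_allele
    )


def _allele_key(ea: pd.Series, oa: pd.Series) -> pd.Series:
    """Order-free allele-pair key for positional joins."""
    lo = np.minimum(ea.to_numpy(dtype=object), oa.to_numpy(dtype=object))
    hi = np.maximum(ea.to_numpy(dtype=object), oa.to_numpy(dtype=object))
    return pd.Series(lo, index=ea.index).str.cat(pd.Series(hi, index=ea.index), sep="/")


def validate_summary_stats(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop rows violating the record invariants; return (clean, drop tally).

    Rules: se > 0 and finite; pval in [0, 1]; eaf missing or strictly in
    (0, 1); effect allele differs from the other allele; beta finite;
    n > 0; (chrom, pos, allele pair) unique within the trait.
    """
    drops: dict[str, int] = {}
    n0 = len(df)

    bad_se = ~(df["se"] > 0) | ~np.isfinite(df["se"])
    bad_beta = ~np.isfinite(df["beta"])
    bad_pval = ~df["pval"].between(0.0, 1.0) | df["pval"].isna()
    eaf = df["eaf"]
    bad_eaf = eaf.notna() & ~((eaf > 0.0) & (eaf < 1.0))
    bad_alleles = df["effect_allele"] == df["other_allele"]
    bad_n = ~(df["n"] > 0)

    mask = bad_se | bad_beta | bad_pval | bad_eaf | bad_alleles | bad_n
    for name, m in [
        ("invalid_se", bad_se),
        ("invalid_beta", bad_beta & ~bad_se),
        ("invalid_pval", bad_pval),
        ("invalid_eaf", bad_eaf),
        ("identical_alleles", bad_alleles),
        ("invalid_n", bad_n),
    ]:
        if int(m.sum()):
            drops[name] = int(m.sum())
    out = df.loc[~mask].copy()

    key = list(zip(out["chrom"], out["pos"], _allele_key(out["effect_allele"], out["other_allele"])))
    dup = pd.Series(key, index=out.index).duplicated(keep="first")
    if int(dup.sum()):
        drops["duplicate_variant"] = int(dup.sum())
        out = out.loc[~dup]

    total = n0 - len(out)
    if total:
        logger.info("validate_summary_stats: dropped %d/%d rows: %s", total, n0, drops)
    return out.reset_index(drop=True), drops


def read_summary_stats(
    path,
    column_map: dict[str, str] | None = None,
    trait_id: str | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a headered TSV/CSV of GWAS summary statistics.

    Parameters
    ----------
    path:
        Tab- or comma-separated file with a header row.
    column_map:
        Maps canonical field names ("variant_id", "chrom", ...) to the
        column names used in the file.  Fields already canonically named
        may be omitted.  ``eaf`` is optional in the source.
    trait_id:
        Trait label attached to every record; defaults to the file's
        trait_id column, if present, else the file stem.
    sep:
        Field separator; sniffed from the header line when None.

    Returns a validated DataFrame with :data:`SUMMARY_COLUMNS`; rows
    failing invariants are dropped, with per-rule counts in
    ``df.attrs["drop_counts"]``.  A missing mandatory column or an empty
    file is a hard error.
    """
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    raw = pd.read_csv(path, sep=sep, dtype={})
    if raw.empty:
        raise ValueError(f"empty summary-statistic file: {path}")

    cmap = dict(column_map or {})
    df = pd.DataFrame()
    for field in _MANDATORY_FIELDS + ["eaf"]:
        src = cmap.get(field, field)
        if src in raw.columns:
            df[field] = raw[src]
        elif field == "eaf":
            df["eaf"] = np.nan
        else:
            raise ValueError(f"mandatory column missing from {path}: {field!r} (looked for {src!r})")

    df["chrom"] = df["chrom"].astype(str).str.removeprefix("chr")
    df["pos"] = df["pos"].astype(np.int64)
    for c in ("beta", "se", "pval", "eaf"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df["n"] = pd.to_numeric(df["n"], errors="coerce").fillna(0).astype(np.int64)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    if trait_id is None:
        src = cmap.get("trait_id", "trait_id")
        if src in raw.columns:
            df["trait_id"] = raw[src].astype(str)
        else:
            import os

            df["trait_id"] = os.path.splitext(os.path.basename(str(path)))[0]
    else:
        df["trait_id"] = trait_id

    df, drops = validate_summary_stats(df[SUMMARY_COLUMNS])
    df.attrs["drop_counts"] = drops
    return df


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_eaf_band: float = 0.08,
) -> pd.DataFrame:
    """Express outcome effects on the exposure's effect allele.

    Variants are joined on (chrom, pos, order-free allele pair), falling
    back to variant_id for rows that do not match positionally.  For each
    shared variant:

    * outcome alleles equal to the exposure's as-is → kept unchanged;
    * equal after swapping effect/other → outcome beta negated, eaf
      complemented, ``flipped`` set;
    * equal after reverse-strand complementing (with or without swap) →
      treated as the corresponding case above (non-palindromic only);
    * palindromic (A/T, C/G) variants are kept only when both EAFs are
      present, both lie outside ``0.5 ± palindrome_eaf_band``, and the
      allele labels and the minor-allele side agree; otherwise dropped
      with reason ``palindromic_ambiguous``;
    * anything else is dropped with reason ``allele_mismatch``.

    Drop-reason tallies are stored in ``result.attrs["drop_reasons"]``.
    """
    exp = exposure.copy()
    out = outcome.copy()
    exp["_key"] = (
        exp["chrom"].astype(str) + ":" + exp["pos"].astype(str) + ":" + _allele_key(exp["effect_allele"], exp["other_allele"])
    )
    out["_key"] = (
        out["chrom"].astype(str) + ":" + out["pos"].astype(str) + ":" + _allele_key(out["effect_allele"], out["other_allele"])
    )

    merged = exp.merge(out, on="_key", suffixes=("_e", "_o"), how="inner")
    # rsID fallback for exposure rows without a positional match
    unmatched = exp.loc[~exp["_key"].isin(merged["_key"])]
    out_left = out.loc[~out["_key"].isin(merged["_key"])]
    if len(unmatched) and len(out_left):
        by_id = unmatched.merge(
            out_left, on="variant_id", suffixes=("_e", "_o"), how="inner"
        )
        if len(by_id):
            by_id = by_id.rename(columns={"variant_id": "variant_id_e"})
            by_id["variant_id_o"] = by_id["variant_id_e"]
            merged = pd.concat([merged, by_id], ignore_index=True)
    if "variant_id" in merged.columns:
        merged = merged.rename(columns={"variant_id": "variant_id_e"})

    rows: list[dict] = []
    reasons: dict[str, int] = {"allele_mismatch": 0, "palindromic_ambiguous": 0}
    band_lo, band_hi = 0.5 - palindrome_eaf_band, 0.5 + palindrome_eaf_band

    for rec in merged.itertuples(index=False):
        ea_e, oa_e = rec.effect_allele_e, rec.other_allele_e
        ea_o, oa_o = rec.effect_allele_o, rec.other_allele_o
        palin = is_palindromic(ea_e, oa_e)

        flipped: bool | None = None
        if palin:
            eaf_e, eaf_o = rec.eaf_e, rec.eaf_o
            ambiguous = (
                pd.isna(eaf_e)
                or pd.isna(eaf_o)
                or band_lo <= eaf_e <= band_hi
                or band_lo <= eaf_o <= band_hi
            )
            if not ambiguous:
                if (ea_o, oa_o) == (ea_e, oa_e):
                    cand_flip = False
                elif (ea_o, oa_o) == (oa_e, ea_e):
                    cand_flip = True
                else:
                    cand_flip = None  # non-ACGT palindromic cannot occur, guard anyway
                if cand_flip is not None:
                    aligned_eaf = (1.0 - eaf_o) if cand_flip else eaf_o
                    if (eaf_e < 0.5) == (aligned_eaf < 0.5):
                        flipped = cand_flip
            if flipped is None:
                reasons["palindromic_ambiguous"] += 1
                continue
        else:
            if (ea_o, oa_o) == (ea_e, oa_e):
                flipped = False
            elif (ea_o, oa_o) == (oa_e, ea_e):
                flipped = True
            else:
                cea, coa = _complement(ea_o), _complement(oa_o)
                if (cea, coa) == (ea_e, oa_e):
                    flipped = False
                elif (cea, coa) == (oa_e, ea_e):
                    flipped = True
            if flipped is None:
                reasons["allele_mismatch"] += 1
                continue

        beta_out = -rec.beta_o if flipped else rec.beta_o
        eaf_out = (1.0 - rec.eaf_o) if (flipped and not pd.isna(rec.eaf_o)) else rec.eaf_o
        rows.append(
            {
                "variant_id": rec.variant_id_e,
                "chrom": rec.chrom_e,
                "pos": rec.pos_e,
                "effect_allele": ea_e,
                "other_allele": oa_e,
                "beta_exp": rec.beta_e,
                "se_exp": rec.se_e,
                "pval_exp": rec.pval_e,
                "eaf_exp": rec.eaf_e,
                "beta_out": beta_out,
                "se_out": rec.se_o,
                "pval_out": rec.pval_o,
                "eaf_out": eaf_out,
                "palindromic": palin,
                "flipped": flipped,
            }
        )

    result = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    result.attrs["drop_reasons"] = {k: v for k, v in reasons.items() if v}
    if any(reasons.values()):
        logger.info("harmonize: dropped variants by reason: %s", result.attrs["drop_reasons"])
    return result


def write_results(records: pd.DataFrame, path) -> None:
    """Write a tabular result set as headered, tab-separated UTF-8.

    Floats are rendered with 9 significant digits so a write/read round
    trip preserves values to well below 1e-6 relative error.  An empty
    table produces a header-only file and a logged warning.
    """
    if records.empty:
        logger.warning("write_results: writing header-only file (empty result set): %s", path)
    records.to_csv(path, sep="\t", index=False, float_format="%.9g", encoding="utf-8")
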