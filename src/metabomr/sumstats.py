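"""GWAS summary-statistic records and their canonical TSV dialect.

One :class:`SumStats` holds the per-variant association records of a
single trait (quantitative, in SD units, or binary, on the log-odds
scale).  The canonical on-disk form is a tab-delimited UTF-8 table with
columns ``SNP CHR POS EA OA EAF BETA SE P N NCASE NCONTROL`` preceded by
a single comment line carrying the trait id and type; foreign headers
are accommodated through a column-name mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical column order of the TSV dialect -> internal names
CANONICAL_COLUMNS = {
    "SNP": "snp_id",
    "CHR": "chrom",
    "POS": "pos",
    "EA": "effect_allele",
    "OA": "other_allele",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "pval",
    "N": "n",
    "NCASE": "ncase",
    "NCONTROL": "ncontrol",
}

_NUCLEOTIDES = frozenset("ACGT")
#: relative tolerance for the |beta/se| vs p-value consistency check
PVAL_RTOL = 0.10


@dataclass
class SumStats:
    """Per-variant GWAS summary records for one trait."""

    df: pd.DataFrame
    trait_id: str
    trait_type: str = "quantitative"  # or "binary"
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "reason"])
    )

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "SumStats":
        return SumStats(
            df=self.df.loc[mask].reset_index(drop=True),
            trait_id=self.trait_id,
            trait_type=self.trait_type,
        )

    def lookup(self, snp_ids) -> "SumStats":
        return self.subset(self.df["snp_id"].isin(set(snp_ids)))


def _row_problems(df: pd.DataFrame) -> pd.Series:
    """Reason string per row, empty where the row satisfies all invariants."""
    reason = pd.Series("", index=df.index, dtype=object)

    def flag(mask, why):
        sel = mask & (reason == "")
        reason[sel] = why

    flag(~df["effect_allele"].isin(_NUCLEOTIDES) | ~df["other_allele"].isin(_NUCLEOTIDES),
         "invalid_allele")
    flag(df["effect_allele"] == df["other_allele"], "identical_alleles")
    flag(~np.isfinite(df["se"]) | (df["se"] <= 0), "nonpositive_se")
    flag(~np.isfinite(df["beta"]), "nonfinite_beta")
    flag(~np.isfinite(df["eaf"]) | (df["eaf"] <= 0) | (df["eaf"] >= 1), "eaf_out_of_range")
    flag(~np.isfinite(df["pval"]) | (df["pval"] <= 0) | (df["pval"] > 1), "pval_out_of_range")
    # p-value must agree with the two-sided normal p of beta/se (10% relative)
    from scipy import stats

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(df["beta"] / df["se"])
        implied = 2.0 * stats.norm.sf(z)
    ok = reason == ""
    both = ok & np.isfinite(implied)
    # below ~1e-290 the implied p underflows; a stated p anywhere near the
    # representable range is then still wildly inconsistent
    checkable = both & (implied > 1e-290)
    rel = np.abs(df["pval"] - implied) / np.where(implied > 0, implied, 1.0)
    flag(checkable & (rel > PVAL_RTOL), "pval_inconsistent")
    flag(both & (implied <= 1e-290) & (df["pval"] > 1e-200), "pval_inconsistent")
    flag(df["snp_id"].duplicated(keep=False), "duplicate_id")
    return reason


def validate(df: pd.DataFrame, trait_id: str, trait_type: str) -> SumStats:
    """Enforce the per-record invariants, rejecting (and logging) violators."""
    reason = _row_problems(df)
    bad = reason != ""
    rejected = pd.DataFrame({"snp_id": df.loc[bad, "snp_id"], "reason": reason[bad]})
    return SumStats(
        df=df.loc[~bad].reset_index(drop=True),
        trait_id=trait_id,
        trait_type=trait_type,
        rejected=rejected.reset_index(drop=True),
    )


def read_sumstats(path, dialect: dict | None = None,
                  trait_id: str | None = None,
                  trait_type: str | None = None) -> SumStats:
    """Read one trait's summary statistics from delimited text.

    ``dialect`` maps canonical column names (``SNP``, ``CHR``, ...) to the
    file's own header names; omit it for files in the canonical dialect.
    A leading ``#trait_id=...<tab>trait_type=...`` comment line, written by
    :func:`write_sumstats`, supplies the trait metadata unless overridden.
    """
    meta: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].strip().split("\t"):
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
    raw = pd.read_csv(path, sep="\t", comment="#", dtype={"CHR": str})
    if dialect:
        raw = raw.rename(columns={v: k for k, v in dialect.items()})
    missing = [c for c in ("SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N")
               if c not in raw.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    for c in ("NCASE", "NCONTROL"):
        if c not in raw.columns:
            raw[c] = np.nan
    df = raw[list(CANONICAL_COLUMNS)].rename(columns=CANONICAL_COLUMNS)
    df["chrom"] = df["chrom"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    numeric_bad = pd.Series(False, index=df.index)
    for c in ("pos", "eaf", "beta", "se", "pval", "n", "ncase", "ncontrol"):
        coerced = pd.to_numeric(df[c], errors="coerce")
        if c not in ("ncase", "ncontrol"):
            numeric_bad |= coerced.isna()
        df[c] = coerced
    unparsed = pd.DataFrame({"snp_id": df.loc[numeric_bad, "snp_id"],
                             "reason": "unparseable_numeric"})
    df = df.loc[~numeric_bad]
    out = validate(
        df,
        trait_id=trait_id or meta.get("trait_id", "trait"),
        trait_type=trait_type or meta.get("trait_type", "quantitative"),
    )
    if len(unparsed):
        out.rejected = pd.concat([unparsed, out.rejected], ignore_index=True)
    return out


def write_sumstats(stats: SumStats, path) -> None:
    """Write in the canonical TSV dialect (missing optionals as NA)."""
    inv = {v: k for k, v in CANONICAL_COLUMNS.items()}
    out = stats.df.rename(columns=inv)[list(CANONICAL_COLUMNS)]
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"#trait_id={stats.trait_id}\ttrait_type={stats.trait_type}\n")
        out.to_csv(fh, sep="\t", index=False, na_rep="NA",
                   float_format="%.17g", lineterminator="\n")
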