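"""Allele harmonisation of exposure-outcome pairs and LD proxy lookup.

Two-sample MR requires the outcome effect to be reported for the same
effect allele as the exposure effect.  Variants are aligned by direct
match, allele swap (beta sign flipped, EAF complemented), or strand
flip (A<->T, C<->G complement), in that order.  Palindromic variants
(A/T or C/G) carry no strand information in their alleles: those with a
minor-allele frequency above ``palindrome_maf_max`` (default 0.42) in
either study are discarded as ambiguous, while the rest are oriented by
effect-allele-frequency concordance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import ReferencePanel
from .sumstats import SumStats

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROME_MAF_MAX = 0.42

ALIGNED_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
                   "beta_exp", "se_exp", "eaf_exp", "pval_exp",
                   "beta_out", "se_out", "eaf_out", "pval_out"]


@dataclass
class HarmonisedSet:
    """Allele-aligned exposure/outcome effect pairs plus an exclusion audit."""

    aligned: pd.DataFrame
    exclusion_log: pd.DataFrame  # columns: snp_id, reason
    exposure_id: str
    outcome_id: str
    outcome_type: str = "quantitative"

    @property
    def n_snp(self) -> int:
        return len(self.aligned)

    def drop(self, snp_ids) -> "HarmonisedSet":
        """Return a copy without the given variants (e.g. a pleiotropy list)."""
        keep = ~self.aligned["snp_id"].isin(set(snp_ids))
        return HarmonisedSet(
            aligned=self.aligned.loc[keep].reset_index(drop=True),
            exclusion_log=self.exclusion_log.copy(),
            exposure_id=self.exposure_id,
            outcome_id=self.outcome_id,
            outcome_type=self.outcome_type,
        )


def _is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    return ((ea == "A") & (oa == "T")) | ((ea == "T") & (oa == "A")) | \
           ((ea == "C") & (oa == "G")) | ((ea == "G") & (oa == "C"))


def harmonise(exposure: SumStats, outcome: SumStats,
              palindrome_maf_max: float = PALINDROME_MAF_MAX) -> HarmonisedSet:
    """Align outcome effects onto the exposure's effect alleles.

    Every exposure variant ends up exactly once in either the aligned
    table or the exclusion log (reasons: ``absent_in_outcome``,
    ``allele_mismatch``, ``ambiguous_palindrome``, ``duplicate``).
    """
    exp = exposure.df
    out = outcome.df
    log: list[pd.DataFrame] = []

    dup_exp = exp["snp_id"].duplicated(keep=False)
    if dup_exp.any():
        log.append(pd.DataFrame({"snp_id": exp.loc[dup_exp, "snp_id"].unique(),
                                 "reason": "duplicate"}))
        exp = exp.loc[~dup_exp]
    dup_out = set(out.loc[out["snp_id"].duplicated(keep=False), "snp_id"])
    if dup_out:
        both = exp["snp_id"].isin(dup_out)
        log.append(pd.DataFrame({"snp_id": exp.loc[both, "snp_id"],
                                 "reason": "duplicate"}))
        exp = exp.loc[~both]
        out = out.loc[~out["snp_id"].isin(dup_out)]

    m = exp.merge(out, on="snp_id", how="left", suffixes=("_exp", "_out"))
    absent = m["beta_out"].isna()
    if absent.any():
        log.append(pd.DataFrame({"snp_id": m.loc[absent, "snp_id"],
                                 "reason": "absent_in_outcome"}))
        m = m.loc[~absent]

    ea_e, oa_e = m["effect_allele_exp"], m["other_allele_exp"]
    ea_o, oa_o = m["effect_allele_out"], m["other_allele_out"]
    ea_oc = ea_o.map(COMPLEMENT)
    oa_oc = oa_o.map(COMPLEMENT)

    palin = _is_palindromic(ea_e, oa_e)
    same = (ea_o == ea_e) & (oa_o == oa_e)
    swap = (ea_o == oa_e) & (oa_o == ea_e)
    flip_same = (ea_oc == ea_e) & (oa_oc == oa_e)
    flip_swap = (ea_oc == oa_e) & (oa_oc == ea_e)

    # palindromic: alleles alone cannot distinguish same/swap from the
    # strand-flipped versions, so orientation comes from EAF concordance
    maf_e = np.minimum(m["eaf_exp"], 1 - m["eaf_exp"])
    maf_o = np.minimum(m["eaf_out"], 1 - m["eaf_out"])
    ambiguous = palin & ((maf_e > palindrome_maf_max) | (maf_o > palindrome_maf_max))
    d_keep = np.abs(m["eaf_exp"] - m["eaf_out"])
    d_flip = np.abs(m["eaf_exp"] - (1 - m["eaf_out"]))
    ambiguous |= palin & (d_keep == d_flip)  # tie -> exclude
    pal_keep = palin & ~ambiguous & (d_keep < d_flip)
    pal_flip = palin & ~ambiguous & (d_flip < d_keep)

    mismatch = ~palin & ~(same | swap | flip_same | flip_swap)
    for mask, why in ((ambiguous, "ambiguous_palindrome"), (mismatch, "allele_mismatch")):
        if mask.any():
            log.append(pd.DataFrame({"snp_id": m.loc[mask, "snp_id"], "reason": why}))
    keep = ~(ambiguous | mismatch)
    m = m.loc[keep]
    need_flip = ((swap | flip_swap) & ~palin) | pal_flip
    need_flip = need_flip.loc[keep]

    beta_out = np.where(need_flip, -m["beta_out"], m["beta_out"])
    eaf_out = np.where(need_flip, 1 - m["eaf_out"], m["eaf_out"])

    aligned = pd.DataFrame({
        "snp_id": m["snp_id"],
        "chrom": m["chrom_exp"],
        "pos": m["pos_exp"],
        "effect_allele": m["effect_allele_exp"],
        "other_allele": m["other_allele_exp"],
        "beta_exp": m["beta_exp"], "se_exp": m["se_exp"],
        "eaf_exp": m["eaf_exp"], "pval_exp": m["pval_exp"],
        "beta_out": beta_out, "se_out": m["se_out"],
        "eaf_out": eaf_out, "pval_out": m["pval_out"],
    }).reset_index(drop=True)

    exclusion = (pd.concat(log, ignore_index=True) if log
                 else pd.DataFrame(columns=["snp_id", "reason"]))
    return HarmonisedSet(aligned=aligned, exclusion_log=exclusion,
                         exposure_id=exposure.trait_id, outcome_id=outcome.trait_id,
                         outcome_type=outcome.trait_type)


def find_proxies(panel: ReferencePanel, target: str, candidates: SumStats,
                 r2_min: float = 0.8, window: int = 500_000) -> pd.DataFrame:
    """LD proxies for a variant absent from the outcome GWAS.

    Returns candidates on the target's chromosome within ``window`` bp
    whose panel r² exceeds ``r2_min``, sorted by descending r².  The
    ``sign`` column maps the proxy's alt allele onto the target's: a
    negative dosage correlation means the proxy's alt allele travels
    with the target's ref allele, so the proxy's effect estimate must be
    flipped when substituting.
    """
    if target not in panel:
        raise KeyError(f"proxy target {target!r} absent from reference panel")
    row = panel.variants.iloc[panel.column(target)]
    cand = candidates.df
    near = cand.loc[(cand["chrom"].astype(str) == str(row["chrom"]))
                    & (np.abs(cand["pos"] - row["pos"]) <= window)
                    & (cand["snp_id"] != target)]
    near = near.loc[near["snp_id"].isin(panel.variants["snp_id"])]
    if near.empty:
        return pd.DataFrame(columns=["snp_id", "r2", "sign"])
    r = panel.r_with(target, list(near["snp_id"]))
    res = pd.DataFrame({"snp_id": near["snp_id"].to_numpy(),
                        "r2": r ** 2,
                        "sign": np.where(r >= 0, 1, -1)})
    res = res.loc[res["r2"] > r2_min]
    return res.sort_values("r2", ascending=False, kind="mergesort").reset_index(drop=True)
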