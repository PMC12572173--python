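"""Instrumental-variable selection and strength diagnostics.

Instruments are genome-wide-significant, common variants pruned to
approximate linkage independence by greedy p-value-ordered clumping
against a reference panel, after removal of the MHC region whose
extreme LD and pleiotropy violate MR assumptions.  Strength is
summarised by per-instrument F statistics ((beta/se)^2, weak below 10)
and an asymptotic post-hoc power approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .harmonise import HarmonisedSet
from .panel import ReferencePanel
from .sumstats import SumStats

P_INSTRUMENT = 5e-8
R2_CLUMP = 0.01
CLUMP_WINDOW = 500_000
MAF_MIN = 0.01
F_WEAK = 10.0


@dataclass
class InstrumentSet:
    """Clumping result: index variants plus a full pruning audit."""

    index_snps: list
    clump_audit: dict            # index snp_id -> list of pruned snp_ids
    dropped: pd.DataFrame        # snp_id, reason (e.g. absent_from_panel)
    p_max: float = P_INSTRUMENT
    r2_max: float = R2_CLUMP
    window: int = CLUMP_WINDOW
    maf_min: float = MAF_MIN

    def __len__(self) -> int:
        return len(self.index_snps)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"index_snp": i, "pruned": ",".join(self.clump_audit.get(i, []))}
                for i in self.index_snps]
        return pd.DataFrame(rows, columns=["index_snp", "pruned"])


@dataclass
class FReport:
    """Per-instrument F statistics with the weak-instrument verdict."""

    f_stats: pd.Series           # indexed by snp_id
    min_F: float = field(init=False)
    mean_F: float = field(init=False)
    weak_flag: bool = field(init=False)

    def __post_init__(self) -> None:
        self.min_F = float(self.f_stats.min())
        self.mean_F = float(self.f_stats.mean())
        self.weak_flag = bool(self.min_F < F_WEAK)


def exclude_region(statistics: SumStats, chrom: str, start: int, end: int) -> SumStats:
    """Drop variants inside [start, end] (closed, 1-based) on ``chrom``."""
    if start > end:
        raise ValueError("start must not exceed end")
    df = statistics.df
    inside = (df["chrom"].astype(str) == str(chrom)) & \
             (df["pos"] >= start) & (df["pos"] <= end)
    return statistics.subset(~inside)


def clump(statistics: SumStats, panel: ReferencePanel,
          p_max: float = P_INSTRUMENT, r2_max: float = R2_CLUMP,
          window: int = CLUMP_WINDOW, maf_min: float = MAF_MIN,
          ranking: pd.Series | None = None) -> InstrumentSet:
    """Greedy LD clumping: best remaining p-value becomes an index variant
    and prunes everything within ``window`` bp at r² >= ``r2_max``.

    ``ranking`` optionally overrides the ranking p-value per variant
    (used when reclumping the union of several traits by each variant's
    smallest p-value across the GWAS).  Ties break on smaller position,
    then lexicographic snp_id, for determinism.
    """
    df = statistics.df
    maf = np.minimum(df["eaf"], 1 - df["eaf"])
    rank_p = df["pval"] if ranking is None else \
        df["snp_id"].map(ranking).fillna(df["pval"])
    eligible = df.loc[(rank_p < p_max) & (maf > maf_min)].copy()
    eligible["_rank_p"] = rank_p.loc[eligible.index]

    in_panel = eligible["snp_id"].isin(panel.variants["snp_id"])
    dropped = pd.DataFrame({"snp_id": eligible.loc[~in_panel, "snp_id"],
                            "reason": "absent_from_panel"}).reset_index(drop=True)
    eligible = eligible.loc[in_panel]

    order = eligible.sort_values(["_rank_p", "pos", "snp_id"],
                                 kind="mergesort")
    remaining = list(order["snp_id"])
    info = order.set_index("snp_id")
    index_snps, audit = [], {}
    while remaining:
        lead = remaining.pop(0)
        index_snps.append(lead)
        lead_chrom = str(info.at[lead, "chrom"])
        lead_pos = info.at[lead, "pos"]
        nearby = [s for s in remaining
                  if str(info.at[s, "chrom"]) == lead_chrom
                  and abs(info.at[s, "pos"] - lead_pos) <= window]
        pruned = []
        if nearby:
            r = panel.r_with(lead, nearby)
            pruned = [s for s, ri in zip(nearby, r) if ri ** 2 >= r2_max]
        audit[lead] = pruned
        remaining = [s for s in remaining if s not in set(pruned)]
    return InstrumentSet(index_snps=index_snps, clump_audit=audit, dropped=dropped,
                         p_max=p_max, r2_max=r2_max, window=window, maf_min=maf_min)


def instrument_strength(h: HarmonisedSet) -> FReport:
    """Per-instrument F = (beta_exp/se_exp)^2; weak if min F < 10."""
    if h.n_snp < 1:
        raise ValueError("instrument_strength needs at least one aligned record")
    f = (h.aligned["beta_exp"] / h.aligned["se_exp"]) ** 2
    return FReport(f_stats=pd.Series(f.to_numpy(), index=h.aligned["snp_id"]))


def mr_power(n_cases: int, n_controls: int, r2_exposure: float, or_sd: float,
             alpha: float = 0.05) -> float:
    """Asymptotic two-sided power of an MR test on a binary outcome.

    power = Phi( sqrt(N * r2 * phi * (1 - phi)) * |log OR_SD| - z_{1-alpha/2} )
    with N the total sample size, phi the case fraction, and r2 the
    exposure variance explained by the instruments.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 < r2_exposure < 1:
        raise ValueError("r2_exposure must be in (0, 1)")
    if or_sd <= 0:
        raise ValueError("or_sd must be positive")
    n_total = n_cases + n_controls
    phi = n_cases / n_total
    ncp = np.sqrt(n_total * r2_exposure * phi * (1 - phi)) * abs(np.log(or_sd))
    return float(stats.norm.cdf(ncp - stats.norm.ppf(1 - alpha / 2)))


def mr_power_quantitative(n: int, r2_exposure: float, beta_sd: float,
                          alpha: float = 0.05) -> float:
    """Analogous power for a quantitative outcome (effect in SD units)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 < r2_exposure < 1:
        raise ValueError("r2_exposure must be in (0, 1)")
    ncp = np.sqrt(n * r2_exposure) * abs(beta_sd)
    return float(stats.norm.cdf(ncp - stats.norm.ppf(1 - alpha / 2)))
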