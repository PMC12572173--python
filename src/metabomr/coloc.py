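"""Enumeration colocalisation with Wakefield approximate Bayes factors.

Under the single-causal-variant assumption, a region's evidence is
summarised by five hypotheses: H0 neither trait associated, H1/H2 only
trait 1/2, H3 both but with distinct causal variants, H4 both sharing
one causal variant.  Per-SNP approximate Bayes factors combine with
per-SNP priors (p1, p2, p12) into posterior probabilities; PP(H4) above
0.8 is the conventional evidence threshold for a shared variant.
Priors are scaled to locus size: p1 = p2 = 1/(10·nSNPs), p12 = p1/10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .sumstats import SumStats

#: prior SD of a true effect, per trait type (SD units / log-odds)
PRIOR_SD_QUANTITATIVE = 0.20
PRIOR_SD_BINARY = 0.15
PP_SHARED_MIN = 0.8


@dataclass(frozen=True)
class ColocPriors:
    p1: float
    p2: float
    p12: float

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ValueError("require 0 < p12 <= min(p1, p2)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("p1 + p2 + p12 must be < 1")


@dataclass
class ColocResult:
    pp: np.ndarray               # posterior of H0..H4
    n_snps: int
    priors: ColocPriors
    top_shared_snp: str | None
    per_snp_h4: pd.Series | None = None

    @property
    def pp_shared(self) -> float:
        return float(self.pp[4])


def locus_priors(n_snps: int) -> ColocPriors:
    """Locus-size-adjusted priors: p1 = p2 = 1/(10·nSNPs), p12 = p1/10."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    p1 = 1.0 / (10.0 * n_snps)
    return ColocPriors(p1=p1, p2=p1, p12=p1 / 10.0)


def wakefield_abf(beta, se, trait_type: str = "quantitative",
                  prior_sd: float | None = None):
    """Log approximate Bayes factor for one association estimate.

    With V = se², W = prior_sd², r = W/(V+W):
    log ABF = 0.5·log(1−r) + 0.5·r·(beta/se)².
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if prior_sd is None:
        prior_sd = PRIOR_SD_BINARY if trait_type == "binary" else PRIOR_SD_QUANTITATIVE
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    v = se ** 2
    w = prior_sd ** 2
    r = w / (v + w)
    out = 0.5 * np.log(1 - r) + 0.5 * r * (beta / se) ** 2
    return out if out.ndim else float(out)


def extract_region(statistics: SumStats, center: str, half_window: int = 500_000) -> SumStats:
    """Variants on the center's chromosome within ±half_window bp (closed)."""
    df = statistics.df
    hit = df.loc[df["snp_id"] == center]
    if hit.empty:
        raise KeyError(f"center variant {center!r} absent from summary statistics")
    chrom, pos = hit.iloc[0]["chrom"], hit.iloc[0]["pos"]
    mask = (df["chrom"] == chrom) & (np.abs(df["pos"] - pos) <= half_window)
    return statistics.subset(mask)


def coloc_enumerate(region1: SumStats, region2: SumStats,
                    priors: ColocPriors | None = None) -> ColocResult:
    """Posterior probabilities of H0..H4 over the shared variants of a region.

    Computed in log space throughout (log-sum-exp), so arbitrarily
    strong signals do not overflow.
    """
    m = region1.df.merge(region2.df, on="snp_id", suffixes=("_1", "_2"))
    if m.empty:
        raise ValueError("regions share no variants; colocalisation not computable")
    if priors is None:
        priors = locus_priors(len(m))
    l1 = wakefield_abf(m["beta_1"], m["se_1"], region1.trait_type)
    l2 = wakefield_abf(m["beta_2"], m["se_2"], region2.trait_type)
    l1 = np.asarray(l1)
    l2 = np.asarray(l2)

    s1, s2, s12 = logsumexp(l1), logsumexp(l2), logsumexp(l1 + l2)
    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(priors.p1) + s1
    lh[2] = np.log(priors.p2) + s2
    # H3: sum over ordered pairs i != j  =  (sum_i ABF1_i)(sum_j ABF2_j) - sum_i ABF1_i·ABF2_i
    pairs = s1 + s2
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = pairs + np.log1p(-np.exp(np.minimum(s12 - pairs, 0.0)))
    lh[3] = np.log(priors.p1) + np.log(priors.p2) + \
        (diff if np.isfinite(diff) else -np.inf)
    lh[4] = np.log(priors.p12) + s12

    pp = np.exp(lh - logsumexp(lh[np.isfinite(lh)]))
    pp[~np.isfinite(pp)] = 0.0
    pp = pp / pp.sum()
    contrib = l1 + l2
    top = str(m["snp_id"].iloc[int(np.argmax(contrib))])
    per_snp = pd.Series(np.exp(contrib - logsumexp(contrib)),
                        index=m["snp_id"].to_numpy())
    return ColocResult(pp=pp, n_snps=len(m), priors=priors,
                       top_shared_snp=top, per_snp_h4=per_snp)


def coloc_sensitivity(region1: SumStats, region2: SumStats,
                      p12_grid=None, p1: float | None = None,
                      p2: float | None = None) -> pd.DataFrame:
    """PP(H4) as a function of the shared-causal prior p12.

    Default grid: 8 log-spaced points from 1e-8 up to min(p1, p2).
    Invalid grid points (violating the prior constraints) are skipped
    and reported with pp4 = NaN.
    """
    n = len(region1.df.merge(region2.df, on="snp_id"))
    base = locus_priors(max(n, 1))
    p1 = base.p1 if p1 is None else p1
    p2 = base.p2 if p2 is None else p2
    if p12_grid is None:
        p12_grid = np.geomspace(1e-8, min(p1, p2), 8)
    rows = []
    for p12 in np.asarray(p12_grid, dtype=float):
        try:
            pri = ColocPriors(p1=p1, p2=p2, p12=float(p12))
            res = coloc_enumerate(region1, region2, pri)
            rows.append({"p12": float(p12), "pp4": res.pp_shared, "valid": True})
        except ValueError:
            rows.append({"p12": float(p12), "pp4": np.nan, "valid": False})
    return pd.DataFrame(rows)
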