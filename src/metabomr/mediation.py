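"""Mediation of the obesity -> cancer effect through metabolites.

Two estimators of the mediated (indirect) effect:

* difference method — total effect (univariable MR) minus the direct
  effect from multivariable MR (MVMR) conditioning on the mediator;
  valid only when the MVMR instruments are conditionally strong
  (conditional F >= 10) and show no pleiotropy (modified Cochran's Q);
* product method — beta(exposure->mediator) x beta(mediator->outcome)
  from the univariable stages, used as the fallback when the MVMR
  diagnostics fail, with delta-method uncertainty.

Both divide the indirect effect by the total effect to give the
proportion mediated.  Supporting filters: sign-consistency of the
mediated path with the total effect, and removal of instruments shared
between exposure and mediator (from the larger-sample GWAS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .harmonise import harmonise
from .instruments import (CLUMP_WINDOW, F_WEAK, InstrumentSet, MAF_MIN,
                          P_INSTRUMENT, R2_CLUMP, clump)
from .panel import ReferencePanel
from .sumstats import SumStats
from .uvmr import MRResult, Z95


@dataclass
class MVMRResult:
    """Direct effects per exposure with conditional-strength diagnostics."""

    effects: pd.DataFrame        # exposure, beta, se, pval
    conditional_F: dict
    modified_Q: float
    Q_pval: float
    snp_ids: list
    collinear: bool = False
    weak_flag: bool = field(init=False)
    pleiotropy_flag: bool = field(init=False)

    def __post_init__(self) -> None:
        self.weak_flag = bool(min(self.conditional_F.values()) < F_WEAK)
        self.pleiotropy_flag = bool(self.Q_pval < 0.05)

    def direct_effect(self, exposure: str) -> tuple[float, float]:
        row = self.effects.loc[self.effects["exposure"] == exposure]
        if row.empty:
            raise KeyError(f"no direct effect for exposure {exposure!r}")
        return float(row.iloc[0]["beta"]), float(row.iloc[0]["se"])


@dataclass
class MediationResult:
    method: str                  # difference | product
    beta_total: float
    se_total: float
    beta_indirect: float
    se_indirect: float
    proportion_mediated: float
    se_proportion: float
    beta_direct: float | None = None
    se_direct: float | None = None
    sign_consistent: bool | None = None
    usable: bool = True
    notes: str = ""

    def ci(self, which: str = "indirect") -> tuple[float, float]:
        b, s = {"indirect": (self.beta_indirect, self.se_indirect),
                "total": (self.beta_total, self.se_total),
                "proportion": (self.proportion_mediated, self.se_proportion)}[which]
        return b - Z95 * s, b + Z95 * s

    @property
    def pval_indirect(self) -> float:
        if self.se_indirect <= 0:
            return 1.0 if self.beta_indirect == 0 else 0.0
        return float(2 * stats.norm.sf(abs(self.beta_indirect) / self.se_indirect))


# ----------------------------------------------------------------------
# multivariable MR
# ----------------------------------------------------------------------
def _aligned_matrix(exposures: list[SumStats], outcome: SumStats,
                    snp_ids: list[str]):
    """Align every trait onto the first exposure's effect alleles over
    the instrument set; returns (ids, X, SE_X, y, se_y)."""
    anchor = exposures[0].lookup(snp_ids)
    frames = []
    for tr in exposures[1:] + [outcome]:
        h = harmonise(anchor, tr)
        frames.append(h.aligned.set_index("snp_id")[["beta_out", "se_out"]]
                      .rename(columns={"beta_out": f"b_{tr.trait_id}",
                                       "se_out": f"s_{tr.trait_id}"}))
    base = anchor.df.set_index("snp_id")[["beta", "se"]].rename(
        columns={"beta": f"b_{exposures[0].trait_id}",
                 "se": f"s_{exposures[0].trait_id}"})
    tab = base.join(frames, how="inner").dropna()
    ids = list(tab.index)
    X = np.column_stack([tab[f"b_{e.trait_id}"] for e in exposures])
    SX = np.column_stack([tab[f"s_{e.trait_id}"] for e in exposures])
    y = tab[f"b_{outcome.trait_id}"].to_numpy()
    sy = tab[f"s_{outcome.trait_id}"].to_numpy()
    return ids, X, SX, y, sy


def _conditional_f(X, SX, k: int, pheno_corr: np.ndarray) -> float:
    """Two-sample conditional F for exposure k given the others:
    Q from an errors-adjusted weighted regression of X_k on X_{-k},
    divided by L - K + 1."""
    L, K = X.shape
    xk, sk = X[:, k], SX[:, k]
    others = [j for j in range(K) if j != k]
    if not others:
        q = float(np.sum((xk / sk) ** 2))
        return q / L
    Xo, So = X[:, others], SX[:, others]
    delta = np.zeros(len(others))
    for _ in range(6):
        var = sk ** 2 + (So ** 2 * delta ** 2).sum(axis=1)
        for a, ja in enumerate(others):   # cross terms from phenotypic corr
            for b, jb in enumerate(others):
                if a != b:
                    var = var + delta[a] * delta[b] * \
                        pheno_corr[ja, jb] * So[:, a] * So[:, b]
            var = var - 2 * delta[a] * pheno_corr[k, ja] * sk * So[:, a]
        var = np.clip(var, 1e-12, None)
        w = 1.0 / var
        XtW = Xo.T * w
        delta_new = np.linalg.pinv(XtW @ Xo) @ XtW @ xk
        if np.allclose(delta_new, delta, atol=1e-10):
            delta = delta_new
            break
        delta = delta_new
    resid = xk - Xo @ delta
    q = float(np.sum(resid ** 2 / var))
    return q / (L - K + 1)


def mvmr_ivw(exposures: list[SumStats], outcome: SumStats,
             instruments: InstrumentSet,
             covariance: np.ndarray | None = None) -> MVMRResult:
    """MVMR-IVW: weighted regression of outcome effects on the matrix of
    exposure effects, no intercept, weights 1/se_out².

    ``covariance`` is the phenotypic correlation matrix between the
    exposures (identity when omitted); it enters the conditional-F and
    modified-Q weights through per-variant genetic covariance terms
    rho_kl·se_k·se_l.  Exact collinearity is reported via the
    ``collinear`` flag (the fit falls back to a pseudo-inverse) rather
    than raised, so degenerate designs still yield diagnostics.
    """
    K = len(exposures)
    if K < 1:
        raise ValueError("at least one exposure required")
    ids, X, SX, y, sy = _aligned_matrix(exposures, outcome, instruments.index_snps)
    L = len(ids)
    if L < K + 1:
        raise ValueError(f"need at least {K + 1} instruments, have {L}")
    pheno = np.eye(K) if covariance is None else np.asarray(covariance, float)

    w = 1.0 / sy ** 2
    XtW = X.T * w
    A = XtW @ X
    collinear = np.linalg.cond(A) > 1e10
    Ainv = np.linalg.pinv(A)
    theta = Ainv @ XtW @ y
    se = np.sqrt(np.clip(np.diag(Ainv), 0, None))

    effects = pd.DataFrame({
        "exposure": [e.trait_id for e in exposures],
        "beta": theta, "se": se,
        "pval": 2 * stats.norm.sf(np.divide(np.abs(theta), se,
                                            out=np.full(K, np.inf),
                                            where=se > 0)),
    })
    cond_f = {exposures[k].trait_id: _conditional_f(X, SX, k, pheno)
              for k in range(K)}

    # modified Q: residual heterogeneity with error-in-exposures weights
    var_q = sy ** 2 + (SX ** 2 * theta ** 2).sum(axis=1)
    for a in range(K):
        for b in range(K):
            if a != b:
                var_q = var_q + theta[a] * theta[b] * pheno[a, b] * SX[:, a] * SX[:, b]
    var_q = np.clip(var_q, 1e-12, None)
    resid = y - X @ theta
    q_mod = float(np.sum(resid ** 2 / var_q))
    q_p = float(stats.chi2.sf(q_mod, max(L - K, 1)))
    return MVMRResult(effects=effects, conditional_F=cond_f, modified_Q=q_mod,
                      Q_pval=q_p, snp_ids=ids, collinear=bool(collinear))


def reclump_union(exposure_stats: list[SumStats], panel: ReferencePanel,
                  p_max: float = P_INSTRUMENT, r2_max: float = R2_CLUMP,
                  window: int = CLUMP_WINDOW, maf_min: float = MAF_MIN) -> InstrumentSet:
    """Clump the union of the traits' significant variants, ranking each
    variant by its smallest p-value in any of the GWAS."""
    if len(exposure_stats) < 2:
        raise ValueError("reclump_union needs at least two traits")
    pooled = pd.concat([s.df for s in exposure_stats], ignore_index=True)
    best = pooled.sort_values("pval", kind="mergesort").drop_duplicates(
        "snp_id", keep="first")
    union = best.loc[best["pval"] < p_max].reset_index(drop=True)
    if union.empty:
        raise ValueError("no genome-wide-significant variants in any trait")
    stats_union = SumStats(df=union, trait_id="union",
                           trait_type=exposure_stats[0].trait_type)
    return clump(stats_union, panel, p_max=p_max, r2_max=r2_max,
                 window=window, maf_min=maf_min)


def build_phenotypic_covariance(exposure_stats: list[SumStats],
                                p_null_min: float = 0.01,
                                min_overlap: int = 1000) -> np.ndarray:
    """Phenotypic correlation between traits from the correlation of
    their z-scores over variants that are null (p > 0.01) in every
    trait.  Falls back to the identity, with a warning, when fewer than
    ``min_overlap`` such variants overlap."""
    K = len(exposure_stats)
    z_cols = []
    common: pd.Index | None = None
    for s in exposure_stats:
        df = s.df.set_index("snp_id")
        common = df.index if common is None else common.intersection(df.index)
    tabs = [s.df.set_index("snp_id").loc[common] for s in exposure_stats]
    null_mask = np.logical_and.reduce(
        [(t["pval"] > p_null_min).to_numpy() for t in tabs])
    m = int(null_mask.sum())
    if m < min_overlap:
        warnings.warn(f"only {m} overlapping null variants (<{min_overlap}); "
                      "using identity phenotypic correlation", stacklevel=2)
        return np.eye(K)
    for t in tabs:
        z_cols.append((t["beta"] / t["se"]).to_numpy()[null_mask])
    raw = np.corrcoef(np.vstack(z_cols))
    # conditioning on p > p_null_min clips the z tails in every trait,
    # attenuating the correlation; invert the doubly-truncated
    # bivariate-normal moment to undo the bias
    c = stats.norm.isf(p_null_min / 2)
    out = np.eye(K)
    for a in range(K):
        for b in range(a + 1, K):
            out[a, b] = out[b, a] = _detruncate_corr(raw[a, b], c)
    return out


def _truncated_corr(rho: float, c: float, nodes=None) -> float:
    """Correlation of a unit bivariate normal truncated to |z1|,|z2| <= c."""
    x, w = nodes
    xx, yy = np.meshgrid(x, x)
    ww = np.outer(w, w)
    det = 1 - rho ** 2
    pdf = np.exp(-(xx ** 2 - 2 * rho * xx * yy + yy ** 2) / (2 * det)) \
        / (2 * np.pi * np.sqrt(det))
    m00 = float((ww * pdf).sum())
    m11 = float((ww * xx * yy * pdf).sum())
    m20 = float((ww * xx ** 2 * pdf).sum())
    return (m11 / m00) / (m20 / m00)


def _detruncate_corr(r_obs: float, c: float) -> float:
    from scipy.optimize import brentq

    if abs(r_obs) < 1e-12:
        return float(r_obs)
    if abs(r_obs) > 1 - 1e-9:   # identical traits: no attenuation possible
        return float(np.sign(r_obs))
    x, w = np.polynomial.legendre.leggauss(48)
    nodes = (x * c, w * c)
    hi = 0.999
    r_max = _truncated_corr(hi, c, nodes)
    if abs(r_obs) >= r_max:
        return float(np.sign(r_obs) * hi)
    return float(brentq(lambda r: _truncated_corr(r, c, nodes) - abs(r_obs),
                        0.0, hi, xtol=1e-8) * np.sign(r_obs))


def genetic_covariance(pheno_corr: np.ndarray, se_matrix: np.ndarray) -> np.ndarray:
    """Per-variant genetic covariance blocks Sigma_j[k,l] = rho_kl·se_kj·se_lj."""
    L, K = se_matrix.shape
    out = np.empty((L, K, K))
    for j in range(L):
        out[j] = pheno_corr * np.outer(se_matrix[j], se_matrix[j])
    return out


# ----------------------------------------------------------------------
# mediation estimators and filters
# ----------------------------------------------------------------------
def _ratio_se(num: float, se_num: float, den: float, se_den: float) -> float:
    """Delta-method SE of num/den treating the two as independent."""
    if den == 0:
        return float("inf")
    ratio = num / den
    rel = 0.0
    if num != 0:
        rel += (se_num / num) ** 2
    rel += (se_den / den) ** 2
    return abs(ratio) * float(np.sqrt(rel)) if num != 0 else se_num / abs(den)


def difference_method(total: MRResult, mvmr: MVMRResult,
                      obesity_trait: str) -> MediationResult:
    """Indirect effect = total - direct, proportion = indirect/total.

    The total (univariable) and direct (MVMR) estimates are treated as
    independent when combining uncertainties — a documented
    approximation, conservative in the two-sample setting.  The result
    is flagged unusable when the MVMR shows weak instruments or
    pleiotropy (the product method is the prescribed fallback).
    """
    if total.beta == 0:
        raise ZeroDivisionError("proportion mediated undefined: total effect is 0")
    direct, se_direct = mvmr.direct_effect(obesity_trait)
    indirect = total.beta - direct
    se_ind = float(np.hypot(total.se, se_direct))
    prop = indirect / total.beta
    se_prop = _ratio_se(indirect, se_ind, total.beta, total.se)
    usable = not (mvmr.weak_flag or mvmr.pleiotropy_flag)
    notes = "" if usable else "mvmr diagnostics failed: " + ", ".join(
        fl for fl, on in (("weak_instruments", mvmr.weak_flag),
                          ("pleiotropy", mvmr.pleiotropy_flag)) if on)
    return MediationResult(method="difference", beta_total=total.beta,
                           se_total=total.se, beta_direct=direct,
                           se_direct=se_direct, beta_indirect=indirect,
                           se_indirect=se_ind, proportion_mediated=prop,
                           se_proportion=se_prop, usable=usable, notes=notes)


def product_method(beta_EM: MRResult, beta_MO: MRResult,
                   total: MRResult) -> MediationResult:
    """Indirect effect = beta(E->M) x beta(M->O), with product
    delta-method SE sqrt(bEM²·seMO² + bMO²·seEM²)."""
    if total.beta == 0:
        raise ZeroDivisionError("proportion mediated undefined: total effect is 0")
    indirect = beta_EM.beta * beta_MO.beta
    se_ind = float(np.sqrt(beta_EM.beta ** 2 * beta_MO.se ** 2
                           + beta_MO.beta ** 2 * beta_EM.se ** 2))
    prop = indirect / total.beta
    se_prop = _ratio_se(indirect, se_ind, total.beta, total.se)
    keep = sign_consistency_filter(beta_EM.beta, beta_MO.beta, total.beta)
    return MediationResult(method="product", beta_total=total.beta,
                           se_total=total.se, beta_indirect=indirect,
                           se_indirect=se_ind, proportion_mediated=prop,
                           se_proportion=se_prop,
                           sign_consistent=(keep == "keep"))


def sign_consistency_filter(beta_EM: float, beta_MO: float,
                            beta_total: float) -> str:
    """'keep' iff sgn(beta_EM x beta_MO) equals sgn(beta_total);
    any zero input excludes with reason 'zero-effect'."""
    for b in (beta_EM, beta_MO, beta_total):
        if not np.isfinite(b):
            raise ValueError("sign filter requires finite effects")
    if beta_EM == 0 or beta_MO == 0 or beta_total == 0:
        return "exclude:zero-effect"
    return "keep" if np.sign(beta_EM * beta_MO) == np.sign(beta_total) else "exclude"


def overlap_iv_filter(exposure_ivs: InstrumentSet, mediator_ivs: InstrumentSet,
                      panel: ReferencePanel, n_exposure: float, n_mediator: float,
                      r2_max: float = R2_CLUMP, window: int = CLUMP_WINDOW):
    """Remove instruments shared between exposure and mediator.

    A pair overlaps when the two variants sit within ``window`` bp on
    the same chromosome with panel r² >= ``r2_max``; the member from
    the larger-sample GWAS is removed (tie: the exposure's, whose
    instrument count is typically larger).  Returns the two filtered
    sets plus a removal audit.
    """
    pos = panel.variants.set_index("snp_id")[["chrom", "pos"]]
    removals = []
    drop_exp, drop_med = set(), set()
    for e in exposure_ivs.index_snps:
        if e not in pos.index:
            continue
        ce, pe = pos.at[e, "chrom"], pos.at[e, "pos"]
        for m in mediator_ivs.index_snps:
            if m in drop_med or e in drop_exp or m not in pos.index:
                continue
            if str(pos.at[m, "chrom"]) != str(ce) or abs(pos.at[m, "pos"] - pe) > window:
                continue
            r2 = panel.r2(e, m) if e != m else 1.0
            if r2 < r2_max:
                continue
            from_exposure = n_exposure >= n_mediator   # tie -> exposure side
            (drop_exp if from_exposure else drop_med).add(e if from_exposure else m)
            removals.append({"exposure_snp": e, "mediator_snp": m, "r2": r2,
                             "removed_from": "exposure" if from_exposure
                             else "mediator"})
    def filtered(ivs: InstrumentSet, drop: set) -> InstrumentSet:
        keep = [s for s in ivs.index_snps if s not in drop]
        return InstrumentSet(index_snps=keep,
                             clump_audit={s: ivs.clump_audit.get(s, [])
                                          for s in keep},
                             dropped=ivs.dropped, p_max=ivs.p_max,
                             r2_max=ivs.r2_max, window=ivs.window,
                             maf_min=ivs.maf_min)
    audit = pd.DataFrame(removals, columns=["exposure_snp", "mediator_snp",
                                            "r2", "removed_from"])
    return filtered(exposure_ivs, drop_exp), filtered(mediator_ivs, drop_med), audit


def select_mediation_method(mvmr: MVMRResult) -> str:
    """Difference method unless the MVMR diagnostics flag weak
    instruments or pleiotropy, in which case the product method."""
    return "product" if (mvmr.weak_flag or mvmr.pleiotropy_flag) else "difference"
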