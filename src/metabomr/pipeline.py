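"""Orchestration of the three-stage screen.

Stage 1 estimates the effect of each obesity trait on every metabolite
(univariable MR with the full sensitivity battery, Bonferroni over the
harmonised-metabolite count, and a bidirectional check); Stage 2 takes
the obesity-driven metabolites into cancer outcomes (Wald/IVW routing,
proxy substitution, optional replication, and a colocalisation gate);
Stage 3 estimates the metabolite-mediated share of the obesity->cancer
effect (MVMR difference method with product-method fallback).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from . import mediation as med
from .harmonise import find_proxies, harmonise
from .instruments import clump, exclude_region
from .panel import ReferencePanel
from .sumstats import SumStats
from .uvmr import MRResult, run_mr_suite

MHC_REGION = ("6", 28_477_897, 33_448_354)


@dataclass
class StageConfig:
    """All analysis thresholds, with the screen's canonical defaults."""

    alpha: float = 0.05
    p_instr: float = 5e-8
    r2_clump: float = 0.01
    clump_window: int = 500_000
    maf_min: float = 0.01
    palindrome_maf: float = 0.42
    proxy_r2: float = 0.8
    proxy_window: int = 500_000
    mhc_region: tuple = MHC_REGION
    pp_shared_min: float = 0.8
    master_seed: int = 0
    n_boot: int = 1000
    stage2_bonferroni: str = "global"   # or "per_outcome"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.stage2_bonferroni not in ("global", "per_outcome"):
            raise ValueError("stage2_bonferroni must be 'global' or 'per_outcome'")
        self.mhc_region = (str(self.mhc_region[0]), int(self.mhc_region[1]),
                           int(self.mhc_region[2]))

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["mhc_region"] = list(d["mhc_region"])
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StageConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class ScreenReport:
    table: pd.DataFrame
    details: dict = field(default_factory=dict)

    def survivors(self) -> pd.DataFrame:
        return self.table.loc[self.table["survivor"]].reset_index(drop=True)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise corrected per-test threshold alpha/m."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def _pair_seed(master_seed: int, *labels: str) -> int:
    """Deterministic per-pair bootstrap seed, independent of pair order."""
    digest = hashlib.blake2b(
        ("|".join((str(master_seed),) + labels)).encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2 ** 31)


def _stage1_instruments(statistics: SumStats, panel: ReferencePanel,
                        config: StageConfig):
    cleaned = exclude_region(statistics, *config.mhc_region)
    ivs = clump(cleaned, panel, p_max=config.p_instr, r2_max=config.r2_clump,
                window=config.clump_window, maf_min=config.maf_min)
    return ivs, statistics.lookup(ivs.index_snps)


def _primary_fit(h, alpha, n_boot, seed, reverse=None):
    return run_mr_suite(h, alpha=alpha, n_boot=n_boot, seed=seed, reverse=reverse)


def _reverse_result(outcome_stats: SumStats, exposure_stats: SumStats,
                    panel: ReferencePanel, config: StageConfig) -> MRResult | None:
    """Role-swapped MR (outcome's instruments onto the exposure)."""
    ivs, iv_stats = _stage1_instruments(outcome_stats, panel, config)
    if not ivs.index_snps:
        return None
    h = harmonise(iv_stats, exposure_stats, config.palindrome_maf)
    if h.n_snp == 0:
        return None
    primary, _, _ = run_mr_suite(h, alpha=config.alpha, n_boot=100, seed=0)
    return primary


# ----------------------------------------------------------------------
# Stage 1
# ----------------------------------------------------------------------
def run_stage1(exposure_stats: list[SumStats], metabolite_stats: list[SumStats],
               panel: ReferencePanel, config: StageConfig) -> ScreenReport:
    """Obesity trait -> metabolite screen; survivors are the
    'exposure-driven' metabolites."""
    rows, details = [], {}
    for exposure in exposure_stats:
        ivs, iv_stats = _stage1_instruments(exposure, panel, config)
        pair_results = []
        for metab in metabolite_stats:
            h = harmonise(iv_stats, metab, config.palindrome_maf)
            seed = _pair_seed(config.master_seed, exposure.trait_id, metab.trait_id)
            reverse = _reverse_result(metab, exposure, panel, config) \
                if h.n_snp else None
            primary, sens, verdict = _primary_fit(
                h, config.alpha, config.n_boot, seed, reverse)
            pair_results.append((metab.trait_id, h, primary, sens, verdict))
        m_harmonised = sum(1 for _, h, *_ in pair_results if h.n_snp > 0)
        thr = bonferroni_threshold(config.alpha, max(m_harmonised, 1))
        for metab_id, h, primary, sens, verdict in pair_results:
            testable = primary is not None
            bonf = bool(testable and primary.pval < thr)
            survivor = bool(bonf and verdict.passed)
            rows.append({
                "exposure": exposure.trait_id, "outcome": metab_id,
                "n_snp": h.n_snp, "method": primary.method if testable else "none",
                "beta": primary.beta if testable else np.nan,
                "se": primary.se if testable else np.nan,
                "pval": primary.pval if testable else np.nan,
                "Q_pval": sens.Q_pval, "egger_intercept_pval": sens.egger_intercept_pval,
                "driver_snp": sens.driver_snp,
                "reverse_significant": sens.reverse_significant,
                "bonferroni_threshold": thr, "bonferroni_pass": bonf,
                "sensitivity_pass": verdict.passed,
                "fail_reasons": ",".join(verdict.reasons),
                "survivor": survivor,
            })
            details[(exposure.trait_id, metab_id)] = {
                "harmonised": h, "primary": primary, "sensitivity": sens,
                "verdict": verdict, "instruments": ivs}
    table = pd.DataFrame(rows).sort_values(["exposure", "outcome"],
                                           kind="mergesort").reset_index(drop=True)
    return ScreenReport(table=table, details=details)


# ----------------------------------------------------------------------
# Stage 2
# ----------------------------------------------------------------------
def _substitute_proxies(ivs, metab: SumStats, cancer: SumStats,
                        panel: ReferencePanel, config: StageConfig) -> list[str]:
    """Best proxy (by r²) present in both GWAS, for each lost instrument."""
    cancer_ids = set(cancer.df["snp_id"])
    metab_ids = set(metab.df["snp_id"])
    chosen = []
    for iv in ivs.index_snps:
        if iv in cancer_ids:
            chosen.append(iv)
            continue
        if iv not in panel:
            continue
        prox = find_proxies(panel, iv, cancer, r2_min=config.proxy_r2,
                            window=config.proxy_window)
        for cand in prox["snp_id"]:
            if cand in metab_ids:
                chosen.append(cand)
                break
    return chosen


def _coloc_gate(metab: SumStats, cancer: SumStats, iv_ids: list[str],
                config: StageConfig):
    """Colocalisation over each IV's ±0.5 Mb region; the pair passes if
    any region reaches PP(H4) > pp_shared_min."""
    results = []
    for iv in iv_ids:
        try:
            r1 = coloc_mod.extract_region(metab, iv, config.proxy_window)
            r2 = coloc_mod.extract_region(cancer, iv, config.proxy_window)
            res = coloc_mod.coloc_enumerate(r1, r2)
        except (KeyError, ValueError):
            continue
        results.append((iv, res))
    passed = any(res.pp_shared > config.pp_shared_min for _, res in results)
    best = max((res.pp_shared for _, res in results), default=np.nan)
    return passed, best, results


def run_stage2(metabolite_stats: list[SumStats], cancer_stats: list[SumStats],
               panel: ReferencePanel, config: StageConfig,
               replication_stats: list[SumStats] | None = None) -> ScreenReport:
    """Obesity-driven metabolite -> cancer screen with replication and
    colocalisation gates."""
    replication_stats = replication_stats or []
    repl_by_id = {s.trait_id: s for s in replication_stats}
    prelim, details = [], {}
    for metab in metabolite_stats:
        ivs, iv_stats = _stage1_instruments(metab, panel, config)
        for cancer in cancer_stats:
            h = harmonise(iv_stats, cancer, config.palindrome_maf)
            used_ids = list(h.aligned["snp_id"])
            if h.n_snp == 0 and ivs.index_snps:
                proxy_ids = _substitute_proxies(ivs, metab, cancer, panel, config)
                if proxy_ids:
                    h = harmonise(metab.lookup(proxy_ids), cancer,
                                  config.palindrome_maf)
                    used_ids = list(h.aligned["snp_id"])
            seed = _pair_seed(config.master_seed, metab.trait_id, cancer.trait_id)
            reverse = _reverse_result(cancer, metab, panel, config) \
                if h.n_snp else None
            primary, sens, verdict = _primary_fit(
                h, config.alpha, config.n_boot, seed, reverse)
            prelim.append({"metab": metab, "cancer": cancer, "h": h,
                           "used_ids": used_ids, "primary": primary,
                           "sens": sens, "verdict": verdict})

    testable = [p for p in prelim if p["primary"] is not None]
    if config.stage2_bonferroni == "global":
        m_global = max(len(testable), 1)
        thr_for = {id(p): bonferroni_threshold(config.alpha, m_global)
                   for p in testable}
    else:
        counts: dict[str, int] = {}
        for p in testable:
            counts[p["cancer"].trait_id] = counts.get(p["cancer"].trait_id, 0) + 1
        thr_for = {id(p): bonferroni_threshold(config.alpha,
                                               counts[p["cancer"].trait_id])
                   for p in testable}

    # replication: Bonferroni over the replicated-pair count, sign agreement
    repl_candidates = [p for p in testable
                       if p["primary"].pval < thr_for[id(p)] and p["verdict"].passed
                       and p["cancer"].trait_id in repl_by_id]
    m_repl = max(len(repl_candidates), 1)
    thr_repl = bonferroni_threshold(config.alpha, m_repl)

    rows = []
    for p in prelim:
        primary, sens, verdict, h = p["primary"], p["sens"], p["verdict"], p["h"]
        ok = primary is not None
        thr = thr_for.get(id(p), np.nan)
        bonf = bool(ok and primary.pval < thr)
        repl_pass: bool | None = None
        if ok and bonf and verdict.passed and p["cancer"].trait_id in repl_by_id:
            repl = repl_by_id[p["cancer"].trait_id]
            hr = harmonise(p["metab"].lookup(p["used_ids"]), repl,
                           config.palindrome_maf)
            r_primary, _, _ = run_mr_suite(hr, alpha=config.alpha, n_boot=100,
                                           seed=_pair_seed(config.master_seed,
                                                           "repl",
                                                           p["metab"].trait_id,
                                                           repl.trait_id))
            repl_pass = bool(r_primary is not None
                             and r_primary.pval < thr_repl
                             and np.sign(r_primary.beta) == np.sign(primary.beta))
        coloc_pass, best_pp4, coloc_results = (False, np.nan, [])
        if ok and bonf and verdict.passed and (repl_pass is not False):
            coloc_pass, best_pp4, coloc_results = _coloc_gate(
                p["metab"], p["cancer"], p["used_ids"], config)
        survivor = bool(ok and bonf and verdict.passed
                        and (repl_pass is not False) and coloc_pass)
        or_sd = primary.or_sd if ok and primary.or_sd else (np.nan,) * 3
        rows.append({
            "exposure": p["metab"].trait_id, "outcome": p["cancer"].trait_id,
            "n_snp": h.n_snp, "method": primary.method if ok else "none",
            "beta": primary.beta if ok else np.nan,
            "se": primary.se if ok else np.nan,
            "pval": primary.pval if ok else np.nan,
            "or_sd": or_sd[0], "or_low": or_sd[1], "or_high": or_sd[2],
            "Q_pval": sens.Q_pval, "egger_intercept_pval": sens.egger_intercept_pval,
            "driver_snp": sens.driver_snp,
            "reverse_significant": sens.reverse_significant,
            "bonferroni_threshold": thr, "bonferroni_pass": bonf,
            "sensitivity_pass": verdict.passed,
            "fail_reasons": ",".join(verdict.reasons),
            "replication_pass": repl_pass, "pp_shared_best": best_pp4,
            "coloc_pass": coloc_pass, "survivor": survivor,
        })
        details[(p["metab"].trait_id, p["cancer"].trait_id)] = {
            "harmonised": h, "primary": primary, "sensitivity": sens,
            "verdict": verdict, "coloc": coloc_results}
    table = pd.DataFrame(rows).sort_values(["exposure", "outcome"],
                                           kind="mergesort").reset_index(drop=True)
    return ScreenReport(table=table, details=details)


# ----------------------------------------------------------------------
# Stage 3
# ----------------------------------------------------------------------
def run_stage3(obesity_stats: list[SumStats], mediator_stats: list[SumStats],
               cancer_stats: list[SumStats], panel: ReferencePanel,
               config: StageConfig, exclusion_list=()):
    """Mediation of each Bonferroni-significant obesity->cancer total
    effect through the Stage-2 surviving metabolites.

    ``exclusion_list`` holds user-identified pleiotropic instrument ids
    (the screen's stand-in for a manual pleiotropy-catalogue check);
    affected estimates are recomputed after their removal.
    """
    exclusion = set(exclusion_list)
    totals = []
    for obesity in obesity_stats:
        ivs, iv_stats = _stage1_instruments(obesity, panel, config)
        if exclusion:
            keep = [s for s in ivs.index_snps if s not in exclusion]
            ivs.index_snps = keep
            iv_stats = obesity.lookup(keep)
        for cancer in cancer_stats:
            h = harmonise(iv_stats, cancer, config.palindrome_maf)
            primary, _, _ = run_mr_suite(
                h, alpha=config.alpha, n_boot=100,
                seed=_pair_seed(config.master_seed, obesity.trait_id,
                                cancer.trait_id))
            totals.append({"obesity": obesity, "cancer": cancer,
                           "ivs": ivs, "total": primary})
    n_pairs = max(sum(1 for t in totals if t["total"] is not None), 1)
    thr = bonferroni_threshold(config.alpha, n_pairs)

    results = []
    for t in totals:
        total = t["total"]
        if total is None:
            continue
        passed_total = total.pval < thr
        for mediator in mediator_stats:
            row = {"obesity": t["obesity"].trait_id,
                   "cancer": t["cancer"].trait_id,
                   "mediator": mediator.trait_id,
                   "beta_total": total.beta, "se_total": total.se,
                   "total_pval": total.pval, "total_bonferroni_pass": passed_total,
                   "bonferroni_threshold": thr}
            if not passed_total:
                row.update({"status": "total_failed_bonferroni"})
                results.append(row)
                continue
            med_ivs, med_iv_stats = _stage1_instruments(mediator, panel, config)
            if exclusion:
                keep = [s for s in med_ivs.index_snps if s not in exclusion]
                med_ivs.index_snps = keep
                med_iv_stats = mediator.lookup(keep)
            # instruments shared between exposure and mediator are
            # pleiotropic for the univariable path estimates: filter them
            # (removal from the larger-sample GWAS) before estimating
            exp_f, med_f, _ = med.overlap_iv_filter(
                t["ivs"], med_ivs, panel,
                n_exposure=float(t["obesity"].df["n"].iloc[0]),
                n_mediator=float(mediator.df["n"].iloc[0]),
                r2_max=config.r2_clump, window=config.clump_window)
            h_em = harmonise(t["obesity"].lookup(exp_f.index_snps),
                             mediator, config.palindrome_maf)
            beta_em, _, _ = run_mr_suite(h_em, alpha=config.alpha, n_boot=100,
                                         seed=1)
            h_mo = harmonise(mediator.lookup(med_f.index_snps), t["cancer"],
                             config.palindrome_maf)
            beta_mo, _, _ = run_mr_suite(h_mo, alpha=config.alpha, n_boot=100,
                                         seed=2)
            if beta_em is None or beta_mo is None:
                row.update({"status": "path_not_estimable"})
                results.append(row)
                continue
            sign = med.sign_consistency_filter(beta_em.beta, beta_mo.beta,
                                               total.beta)
            if sign != "keep":
                row.update({"status": f"sign_filter_{sign}"})
                results.append(row)
                continue
            try:
                union = med.reclump_union([t["obesity"], mediator], panel,
                                          p_max=config.p_instr,
                                          r2_max=config.r2_clump,
                                          window=config.clump_window,
                                          maf_min=config.maf_min)
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    pheno = med.build_phenotypic_covariance(
                        [t["obesity"], mediator])
                mvmr = med.mvmr_ivw([t["obesity"], mediator], t["cancer"],
                                    union, covariance=pheno)
            except ValueError as exc:
                row.update({"status": f"mvmr_failed:{exc}"})
                results.append(row)
                continue
            method = med.select_mediation_method(mvmr)
            if method == "difference":
                result = med.difference_method(total, mvmr,
                                               t["obesity"].trait_id)
            else:
                result = med.product_method(beta_em, beta_mo, total)
            row.update({
                "status": "ok", "method": result.method,
                "beta_direct": result.beta_direct,
                "beta_indirect": result.beta_indirect,
                "se_indirect": result.se_indirect,
                "proportion_mediated": result.proportion_mediated,
                "se_proportion": result.se_proportion,
                "conditional_F_min": min(mvmr.conditional_F.values()),
                "modified_Q_pval": mvmr.Q_pval,
                "weak_flag": mvmr.weak_flag,
                "pleiotropy_flag": mvmr.pleiotropy_flag,
                "n_overlap_removed": len(t["ivs"].index_snps)
                - len(exp_f.index_snps) + len(med_ivs.index_snps)
                - len(med_f.index_snps),
            })
            results.append(row)
    table = pd.DataFrame(results)
    if len(table):
        table = table.sort_values(["obesity", "cancer", "mediator"],
                                  kind="mergesort").reset_index(drop=True)
    return table


# ----------------------------------------------------------------------
# reporting
# ----------------------------------------------------------------------
def make_report(stage1: ScreenReport | None = None,
                stage2: ScreenReport | None = None,
                stage3: pd.DataFrame | None = None) -> dict[str, pd.DataFrame]:
    """Tabular bundle: volcano-style (effect vs p) and forest-style
    (OR_SD, CI, nSNP) tables plus the mediation summary, deterministically
    ordered; every number traces to a stage output."""
    bundle: dict[str, pd.DataFrame] = {}
    if stage1 is not None:
        volcano = stage1.table[["exposure", "outcome", "beta", "se", "pval",
                                "survivor"]].copy()
        bundle["volcano"] = volcano.sort_values(
            ["exposure", "outcome"], kind="mergesort").reset_index(drop=True)
    if stage2 is not None:
        cols = ["exposure", "outcome", "method", "n_snp", "or_sd", "or_low",
                "or_high", "pval", "pp_shared_best", "survivor"]
        forest = stage2.table[[c for c in cols if c in stage2.table.columns]].copy()
        bundle["forest"] = forest.sort_values(
            ["outcome", "exposure"], kind="mergesort").reset_index(drop=True)
    if stage3 is not None and len(stage3):
        bundle["mediation"] = stage3.copy()
    elif stage3 is not None:
        bundle["mediation"] = stage3
    return bundle


def write_report(bundle: dict[str, pd.DataFrame], out_dir) -> None:
    import os

    os.makedirs(out_dir, exist_ok=True)
    for name, df in bundle.items():
        df.to_csv(os.path.join(out_dir, f"{name}.tsv"), sep="\t", index=False)
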