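"""Seeded synthetic GWAS: reference panels and summary-statistic triads.

The generator emulates the statistical structure a three-stage
summary-level MR screen assumes: an exposure trait (think BMI/WHR)
instrumented by many common variants, metabolites partially caused by
the exposure, a binary outcome (cancer) receiving both a direct
exposure effect and a metabolite-mediated effect on the log-odds scale,
plus the nuisance features the pipeline must defend against —
LD-block structure, directional pleiotropy, palindromic variants with
near-0.5 allele frequencies, and an MHC-like high-pleiotropy region on
chromosome 6.

Everything is a pure function of (arguments, seed).  A single master
seed is expanded into independent per-component streams with
``numpy.random.SeedSequence(seed).spawn``; stream order is fixed, so
identical calls reproduce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.optimize import brentq

from .panel import ReferencePanel
from .sumstats import SumStats

MHC_CHROM = "6"
MHC_START = 28_477_897
MHC_END = 33_448_354

_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                 ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]
_PALINDROME_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


# ----------------------------------------------------------------------
# configuration & ground truth
# ----------------------------------------------------------------------
@dataclass
class SimulationConfig:
    """Study-design knobs for one synthetic triad.

    Defaults mirror the asymmetry of the real screen at desk scale: a
    large exposure GWAS (50k) with many modest instruments, a much
    smaller metabolite GWAS (8k, the scale of plasma-metabolomics
    cohorts) in which the exposure's variants are *not* genome-wide
    significant, and a metabolite driven by a couple of strong
    cis-acting loci — so mediator instruments are few but strong
    (F well above 10), as in metabolite GWAS practice.
    """

    n_exposure_gwas: int = 50_000
    n_metabolite_gwas: int = 8_000
    n_outcome_cases: int = 20_000
    n_outcome_controls: int = 20_000
    n_causal_snps: int = 50
    heritability_exposure: float = 0.25
    pleiotropy_fraction: float = 0.0
    palindrome_fraction: float = 0.1
    seed: int = 0
    # fix the exposure side (causal architecture, effects, sampling noise,
    # allele labels) across calls so several metabolites can share one
    # exposure GWAS; defaults to `seed`
    exposure_seed: int | None = None
    # secondary structure: the metabolite's own (cis-like) genetics and
    # the outcome's own susceptibility loci (log-odds-scale variance),
    # which serve as reverse-MR instruments
    n_metabolite_snps: int = 2
    heritability_metabolite: float = 0.10
    n_outcome_snps: int = 10
    heritability_outcome: float = 0.05
    # direct SNP->outcome contamination (log-odds per allele), applied to
    # a pleiotropy_fraction subset of the exposure instruments
    pleiotropy_mean: float = 0.05
    pleiotropy_sd: float = 0.02

    def __post_init__(self) -> None:
        for name in ("n_exposure_gwas", "n_metabolite_gwas", "n_outcome_cases",
                     "n_outcome_controls", "n_causal_snps", "n_metabolite_snps",
                     "n_outcome_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.heritability_exposure < 1:
            raise ValueError("heritability_exposure must be in (0, 1)")
        if not 0 <= self.heritability_metabolite < 1:
            raise ValueError("heritability_metabolite must be in [0, 1)")
        for name in ("pleiotropy_fraction", "palindrome_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    def to_yaml(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class TriadTruth:
    """Ground-truth causal structure of one simulated triad.

    Effects are on the scales the analysis reports: SD units for the
    exposure->metabolite path and log-odds per SD for the two paths into
    the binary outcome, so ``exp(beta)`` is an odds ratio per SD.
    """

    beta_EM_true: float = 0.3
    beta_MO_true: float = 0.2
    beta_EO_direct_true: float = 0.14
    pleiotropic_snps: frozenset = field(default_factory=frozenset)
    coloc_mode: str | None = None

    def __post_init__(self) -> None:
        for name in ("beta_EM_true", "beta_MO_true", "beta_EO_direct_true"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.coloc_mode not in (None, "shared", "distinct", "null"):
            raise ValueError(f"invalid coloc_mode {self.coloc_mode!r}")

    @property
    def beta_total_true(self) -> float:
        return self.beta_EM_true * self.beta_MO_true + self.beta_EO_direct_true

    @property
    def proportion_mediated_true(self) -> float:
        total = self.beta_total_true
        if total == 0:
            raise ZeroDivisionError("proportion mediated undefined: total effect is 0")
        return self.beta_EM_true * self.beta_MO_true / total


# ----------------------------------------------------------------------
# reference panel
# ----------------------------------------------------------------------
def _latent_correlation(target_r: float, maf: float) -> float:
    """Latent Gaussian correlation whose thresholded-Bernoulli correlation
    equals ``target_r`` at allele frequency ``maf`` (tetrachoric inversion)."""
    if target_r <= 0:
        return 0.0
    t = stats.norm.ppf(maf)
    pq = maf * (1 - maf)

    def gap(rho):
        joint = stats.multivariate_normal.cdf(
            [t, t], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
        return (joint - maf ** 2) / pq - target_r

    if gap(0.999999) < 0:  # numerically unreachable; saturate
        return 0.999999
    return brentq(gap, 0.0, 0.999999, xtol=1e-8)


def _block_layout(n_blocks: int) -> list[tuple[str, int]]:
    """(chromosome, base position) per block: consecutive block pairs share
    a chromosome (so multi-block regions exist on one chromosome), blocks
    2 Mb apart within a chromosome; the first chr6 block sits inside the
    MHC-like window so region-exclusion is exercisable."""
    layout = []
    seen_per_chrom: dict[str, int] = {}
    for b in range(n_blocks):
        chrom = str(1 + (b // 2) % 22)
        k = seen_per_chrom.get(chrom, 0)
        seen_per_chrom[chrom] = k + 1
        if chrom == MHC_CHROM and k == 0:
            base = 28_600_000  # inside chr6:28,477,897-33,448,354
        elif chrom == MHC_CHROM:
            base = 40_000_000 + (k - 1) * 2_000_000
        else:
            base = 1_000_000 + k * 2_000_000
        layout.append((chrom, base))
    return layout


def simulate_reference_panel(n_individuals: int, n_blocks: int, snps_per_block: int,
                             within_block_r: float, maf_range=(0.05, 0.5),
                             seed: int = 0) -> ReferencePanel:
    """Block-diagonal LD panel from a latent Gaussian copula.

    Each block draws one minor-allele frequency from ``maf_range``
    (variants in tight LD share allele frequencies) and an
    equicorrelated latent factor whose correlation is calibrated so the
    *dosage-level* correlation between block members is
    ``within_block_r``; different blocks are generated independently.
    """
    if n_individuals <= 0 or n_blocks <= 0 or snps_per_block <= 0:
        raise ValueError("counts must be positive")
    if not 0 <= within_block_r < 1:
        raise ValueError("within_block_r must be in [0, 1)")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be within (0, 0.5]")

    streams = np.random.SeedSequence(seed).spawn(3)
    rng_maf = np.random.default_rng(streams[0])
    rng_geno = np.random.default_rng(streams[1])
    rng_allele = np.random.default_rng(streams[2])

    layout = _block_layout(n_blocks)
    dosage_cols, rows = [], []
    for b, (chrom, base) in enumerate(layout):
        maf = float(rng_maf.uniform(lo, hi))
        rho = _latent_correlation(within_block_r, maf)
        t = stats.norm.ppf(maf)
        # two haplotypes per individual, shared factor per haplotype copy
        u = rng_geno.standard_normal((n_individuals, 2, 1))
        eps = rng_geno.standard_normal((n_individuals, 2, snps_per_block))
        latent = np.sqrt(rho) * u + np.sqrt(1 - rho) * eps
        dosage = (latent < t).sum(axis=1).astype(float)
        dosage_cols.append(dosage)
        for v in range(snps_per_block):
            ref, alt = _ALLELE_PAIRS[rng_allele.integers(len(_ALLELE_PAIRS))]
            rows.append({"snp_id": f"rs{b}_{v}", "chrom": chrom,
                         "pos": base + v * 1_000, "ref_allele": ref,
                         "alt_allele": alt, "block": b})
    variants = pd.DataFrame(rows)
    return ReferencePanel(variants=variants, dosages=np.hstack(dosage_cols))


# ----------------------------------------------------------------------
# triad summary statistics
# ----------------------------------------------------------------------
def _blockwise(panel: ReferencePanel):
    """Cache per-block dosage moments: (cols, cov, corr_chol, var)."""
    out = []
    for _, grp in panel.variants.groupby("block", sort=True):
        cols = grp.index.to_numpy()
        g = panel.dosages[:, cols]
        cov = np.cov(g, rowvar=False, ddof=0)
        cov = np.atleast_2d(cov)
        var = np.clip(np.diag(cov).copy(), 1e-8, None)
        corr = cov / np.sqrt(np.outer(var, var))
        chol = np.linalg.cholesky(corr + 1e-8 * np.eye(len(cols)))
        out.append((cols, cov, chol, var))
    return out


def _marginal(blocks, b_true: np.ndarray, n_var: int) -> np.ndarray:
    """Per-allele marginal effects implied by causal effects under block LD."""
    marg = np.zeros(n_var)
    for cols, cov, _, var in blocks:
        marg[cols] = cov @ b_true[cols] / var
    return marg


def _observed(blocks, marg: np.ndarray, se: np.ndarray, rng) -> np.ndarray:
    """Marginal truth plus LD-correlated estimation noise."""
    beta_hat = np.empty_like(marg)
    for cols, _, chol, _ in blocks:
        z = rng.standard_normal(len(cols))
        beta_hat[cols] = marg[cols] + se[cols] * (chol @ z)
    return beta_hat


def _scaled_effects(rng, idx: np.ndarray, var_g: np.ndarray, h2: float,
                    n_var: int) -> np.ndarray:
    """Random causal effects at ``idx`` rescaled to explain exactly h2."""
    b = np.zeros(n_var)
    raw = rng.standard_normal(len(idx))
    expl = float((var_g[idx] * raw ** 2).sum())
    if h2 > 0 and expl > 0:
        b[idx] = raw * np.sqrt(h2 / expl)
    return b


def simulate_triad_study(panel: ReferencePanel, config: SimulationConfig,
                         truth: TriadTruth):
    """Exposure, metabolite and outcome GWAS with known causal structure.

    The three samples are independent (two-sample MR throughout).  All
    quantitative traits are standardised to unit variance; the outcome
    is binary with effects on the log-odds scale.  Returns
    ``(exposure, metabolite, outcome, truth)`` where the echoed truth
    carries the realised pleiotropic-variant set.
    """
    exposure_seed = (config.exposure_seed if config.exposure_seed is not None
                     else config.seed)
    # distinct entropy tags keep the exposure-side and metabolite/outcome-side
    # streams independent even when exposure_seed == seed
    e_streams = np.random.SeedSequence([exposure_seed, 1]).spawn(5)
    rng_pick, rng_eff, rng_exp, rng_eaf, rng_pal = (
        np.random.default_rng(s) for s in e_streams)
    m_streams = np.random.SeedSequence([config.seed, 2]).spawn(5)
    rng_pick_m, rng_eff_m, rng_met, rng_out, rng_pleio = (
        np.random.default_rng(s) for s in m_streams)

    nv = panel.n_variants
    variants = panel.variants
    f_alt = panel.dosages.mean(axis=0) / 2.0
    blocks = _blockwise(panel)
    var_g = np.concatenate([v for *_, v in blocks])[
        np.argsort(np.concatenate([c for c, *_ in blocks]))]

    in_mhc = ((variants["chrom"] == MHC_CHROM)
              & (variants["pos"] >= MHC_START)
              & (variants["pos"] <= MHC_END)).to_numpy()
    usable_blocks = sorted(set(variants.loc[~in_mhc, "block"]))
    need = (config.n_causal_snps + config.n_metabolite_snps
            + config.n_outcome_snps)
    if len(usable_blocks) < need:
        raise ValueError(
            f"panel has {len(usable_blocks)} non-MHC LD blocks; "
            f"{need} required for the requested causal architecture")
    exp_blocks = rng_pick.choice(usable_blocks, size=config.n_causal_snps,
                                 replace=False)
    remaining = sorted(set(usable_blocks) - set(exp_blocks))
    met_blocks = rng_pick_m.choice(remaining, size=config.n_metabolite_snps,
                                   replace=False)
    remaining2 = sorted(set(remaining) - set(met_blocks))
    out_blocks = rng_pick_m.choice(remaining2, size=config.n_outcome_snps,
                                   replace=False)

    def one_snp_per_block(block_ids, rng):
        idx = []
        for b in block_ids:
            members = variants.index[(variants["block"] == b).to_numpy() & ~in_mhc]
            idx.append(int(rng.choice(members)))
        return np.array(idx, dtype=int)

    exp_idx = one_snp_per_block(exp_blocks, rng_pick)
    met_idx = one_snp_per_block(met_blocks, rng_pick_m)
    out_idx = one_snp_per_block(out_blocks, rng_pick_m)

    # causal (per-allele) effects on the standardised traits
    b_x = _scaled_effects(rng_eff, exp_idx, var_g, config.heritability_exposure, nv)
    a_m = _scaled_effects(rng_eff_m, met_idx, var_g,
                          config.heritability_metabolite, nv)
    b_m = truth.beta_EM_true * b_x + a_m

    n_pleio = int(round(config.pleiotropy_fraction * len(exp_idx)))
    pleio_idx = (rng_pleio.choice(exp_idx, size=n_pleio, replace=False)
                 if n_pleio else np.array([], dtype=int))
    a_o = _scaled_effects(rng_eff_m, out_idx, var_g,
                          config.heritability_outcome, nv)
    b_o = truth.beta_EO_direct_true * b_x + truth.beta_MO_true * b_m + a_o
    if n_pleio:
        # directional with respect to the exposure-increasing allele, the
        # convention the Egger intercept is designed to detect
        orient = np.sign(b_x[pleio_idx])
        orient[orient == 0] = 1.0
        b_o[pleio_idx] += orient * rng_pleio.normal(
            config.pleiotropy_mean, config.pleiotropy_sd, n_pleio)

    # marginal effects + sampling noise, blockwise-correlated
    def se_quantitative(n):
        return np.sqrt(1.0 / (n * var_g))

    phi = config.n_outcome_cases / (config.n_outcome_cases + config.n_outcome_controls)
    n_out = config.n_outcome_cases + config.n_outcome_controls
    se_x = se_quantitative(config.n_exposure_gwas)
    se_m = se_quantitative(config.n_metabolite_gwas)
    se_o = np.sqrt(1.0 / (var_g * n_out * phi * (1 - phi)))

    bh_x = _observed(blocks, _marginal(blocks, b_x, nv), se_x, rng_exp)
    bh_m = _observed(blocks, _marginal(blocks, b_m, nv), se_m, rng_met)
    bh_o = _observed(blocks, _marginal(blocks, b_o, nv), se_o, rng_out)

    # palindromic relabelling: alleles become A/T or C/G and the reported
    # EAF is redrawn near 0.5 (both sides of the 0.42 rule); the effect
    # sizes — hence the truth — are untouched
    ea = variants["alt_allele"].to_numpy().copy()
    oa = variants["ref_allele"].to_numpy().copy()
    n_pal = int(round(config.palindrome_fraction * nv))
    pal_idx = (rng_pal.choice(nv, size=n_pal, replace=False)
               if n_pal else np.array([], dtype=int))
    f_base = f_alt.copy()
    if n_pal:
        pairs = rng_pal.integers(len(_PALINDROME_PAIRS), size=n_pal)
        ea[pal_idx] = [_PALINDROME_PAIRS[k][0] for k in pairs]
        oa[pal_idx] = [_PALINDROME_PAIRS[k][1] for k in pairs]
        f_base[pal_idx] = rng_pal.uniform(0.40, 0.60, size=n_pal)

    def eaf_observed(n):
        noisy = f_base + rng_eaf.normal(0.0, np.sqrt(f_base * (1 - f_base) / (2 * n)))
        return np.clip(noisy, 1e-3, 1 - 1e-3)

    def assemble(beta, se, n, trait_id, trait_type, ncase=None, ncontrol=None):
        with np.errstate(over="ignore"):
            p = 2.0 * stats.norm.sf(np.abs(beta / se))
        p = np.clip(p, 5e-324, 1.0)
        df = pd.DataFrame({
            "snp_id": variants["snp_id"], "chrom": variants["chrom"],
            "pos": variants["pos"], "effect_allele": ea, "other_allele": oa,
            "eaf": eaf_observed(n), "beta": beta, "se": se, "pval": p,
            "n": float(n),
            "ncase": np.nan if ncase is None else float(ncase),
            "ncontrol": np.nan if ncontrol is None else float(ncontrol),
        })
        return SumStats(df=df, trait_id=trait_id, trait_type=trait_type)

    exposure = assemble(bh_x, se_x, config.n_exposure_gwas, "exposure", "quantitative")
    metabolite = assemble(bh_m, se_m, config.n_metabolite_gwas, "metabolite",
                          "quantitative")
    outcome = assemble(bh_o, se_o, n_out, "outcome", "binary",
                       config.n_outcome_cases, config.n_outcome_controls)

    echoed = TriadTruth(
        beta_EM_true=truth.beta_EM_true, beta_MO_true=truth.beta_MO_true,
        beta_EO_direct_true=truth.beta_EO_direct_true,
        pleiotropic_snps=frozenset(variants["snp_id"].iloc[pleio_idx]),
        coloc_mode=truth.coloc_mode)
    return exposure, metabolite, outcome, echoed


# ----------------------------------------------------------------------
# colocalisation loci
# ----------------------------------------------------------------------
def simulate_coloc_locus(panel: ReferencePanel, mode: str, z_strength: float,
                         seed: int = 0, n: int = 50_000):
    """Two traits' summary statistics over a two-LD-block region.

    shared   — one causal variant (in the first block) drives both traits;
    distinct — each trait has its own causal variant, in different blocks;
    null     — neither trait has any association.
    ``z_strength`` is the causal variant's expected association z-score.
    """
    if mode not in ("shared", "distinct", "null"):
        raise ValueError(f"mode must be shared|distinct|null, got {mode!r}")
    if mode != "null" and z_strength <= 0:
        raise ValueError("z_strength must be positive for non-null modes")

    variants = panel.variants
    pair = None
    for _, grp in variants.groupby("chrom", sort=False):
        bs = sorted(set(grp["block"]))
        if len(bs) >= 2:
            pair = bs[:2]
            break
    if pair is None:
        raise ValueError("panel needs two LD blocks on one chromosome")
    region = variants.index[variants["block"].isin(pair)].to_numpy()

    streams = np.random.SeedSequence(seed).spawn(3)
    rng_pick = np.random.default_rng(streams[0])
    rngs = [np.random.default_rng(streams[1]), np.random.default_rng(streams[2])]

    sub = ReferencePanel(variants=variants.iloc[region].copy(),
                         dosages=panel.dosages[:, region])
    blocks = _blockwise(sub)
    var_g = np.concatenate([v for *_, v in blocks])[
        np.argsort(np.concatenate([c for c, *_ in blocks]))]
    se = np.sqrt(1.0 / (n * var_g))

    sub_blocks = sub.variants["block"].to_numpy()
    cand_a = np.flatnonzero(sub_blocks == pair[0])
    cand_b = np.flatnonzero(sub_blocks == pair[1])
    causal_a = int(rng_pick.choice(cand_a))
    causal_b = int(rng_pick.choice(cand_b))

    def trait_stats(causal: int | None, rng, trait_id: str) -> SumStats:
        b_true = np.zeros(len(region))
        if causal is not None:
            b_true[causal] = z_strength * se[causal]
        marg = _marginal(blocks, b_true, len(region))
        beta = _observed(blocks, marg, se, rng)
        with np.errstate(over="ignore"):
            p = np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), 5e-324, 1.0)
        f_alt = sub.dosages.mean(axis=0) / 2.0
        df = pd.DataFrame({
            "snp_id": sub.variants["snp_id"], "chrom": sub.variants["chrom"],
            "pos": sub.variants["pos"],
            "effect_allele": sub.variants["alt_allele"],
            "other_allele": sub.variants["ref_allele"],
            "eaf": np.clip(f_alt, 1e-3, 1 - 1e-3),
            "beta": beta, "se": se, "pval": p, "n": float(n),
            "ncase": np.nan, "ncontrol": np.nan,
        })
        return SumStats(df=df, trait_id=trait_id, trait_type="quantitative")

    if mode == "null":
        c1 = c2 = None
    elif mode == "shared":
        c1 = c2 = causal_a
    else:
        c1, c2 = causal_a, causal_b
    return trait_stats(c1, rngs[0], "trait1"), trait_stats(c2, rngs[1], "trait2")
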