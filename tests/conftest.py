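"""Shared synthetic fixtures.

Panels are session-scoped (they are the expensive part); summary
statistics are cheap and regenerated per test where ground truth
matters.
"""

import numpy as np
import pandas as pd
import pytest

from metabomr import (HarmonisedSet, SimulationConfig, SumStats, TriadTruth,
                      simulate_reference_panel, simulate_triad_study)


@pytest.fixture(scope="session")
def panel_ld():
    """12 blocks x 5 SNPs with strong within-block LD (r = 0.9)."""
    return simulate_reference_panel(2000, 12, 5, 0.9, seed=11)


@pytest.fixture(scope="session")
def panel_instr():
    """64 independent single-SNP blocks: fast instrument-level panel."""
    return simulate_reference_panel(1000, 64, 1, 0.0, seed=12)


@pytest.fixture(scope="session")
def panel_coloc():
    """Two 25-SNP blocks on one chromosome, tight LD inside each."""
    return simulate_reference_panel(2000, 2, 25, 0.8, seed=13)


@pytest.fixture(scope="session")
def triad_default(panel_instr):
    """One default triad (beta_EM=0.3, beta_MO=0.2, direct=0.14)."""
    config = SimulationConfig(seed=21, n_causal_snps=40, n_metabolite_snps=8)
    truth = TriadTruth()
    return simulate_triad_study(panel_instr, config, truth)


def make_sumstats(betas, ses, trait_id="trait", trait_type="quantitative",
                  snp_ids=None, eaf=0.3, chrom="1", pos0=1_000_000, n=10_000,
                  ea="A", oa="C"):
    """Hand-built SumStats for arithmetic-level tests."""
    from scipy import stats as st

    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    k = len(betas)
    ids = snp_ids if snp_ids is not None else [f"rs{i}" for i in range(k)]
    df = pd.DataFrame({
        "snp_id": ids, "chrom": chrom,
        "pos": pos0 + 1000 * np.arange(k),
        "effect_allele": ea if isinstance(ea, str) else list(ea),
        "other_allele": oa if isinstance(oa, str) else list(oa),
        "eaf": eaf, "beta": betas, "se": ses,
        "pval": 2 * st.norm.sf(np.abs(betas / ses)),
        "n": float(n), "ncase": np.nan, "ncontrol": np.nan,
    })
    return SumStats(df=df, trait_id=trait_id, trait_type=trait_type)


def make_harmonised(bx, sx, by, sy, outcome_type="quantitative"):
    """HarmonisedSet straight from effect arrays (alignment assumed)."""
    bx, sx, by, sy = (np.asarray(a, float) for a in (bx, sx, by, sy))
    k = len(bx)
    aligned = pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(k)], "chrom": "1",
        "pos": 1_000_000 + 1000 * np.arange(k),
        "effect_allele": "A", "other_allele": "C",
        "beta_exp": bx, "se_exp": sx, "eaf_exp": 0.3, "pval_exp": 1e-9,
        "beta_out": by, "se_out": sy, "eaf_out": 0.3, "pval_out": 0.5,
    })
    return HarmonisedSet(aligned=aligned,
                         exclusion_log=pd.DataFrame(columns=["snp_id", "reason"]),
                         exposure_id="exp", outcome_id="out",
                         outcome_type=outcome_type)
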