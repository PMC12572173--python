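"""Stage 1: which metabolites does the obesity trait causally influence?

Instruments are genome-wide-significant exposure variants (p < 5e-8,
MAF > 0.01) clumped at r² < 0.01 within 0.5 Mb after MHC removal; the
primary estimator is IVW random-effects with the full sensitivity
battery (Cochran's Q, Egger intercept, leave-one-out, bidirectional
MR); significance is Bonferroni-corrected over the harmonised
metabolites.

Run after 01:  python analysis/02_stage1_obesity_to_metabolites.py
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from metabomr import ReferencePanel, StageConfig, read_sumstats, run_stage1

DATA = os.path.join("scratch", "data")
METABOLITES = ["met_linoleoyl_gpc", "met_oleoyl_gpc", "met_null_carnitine",
               "met_reverse_signal"]


def main() -> None:
    panel = ReferencePanel.read(os.path.join(DATA, "panel_variants.tsv"),
                                os.path.join(DATA, "panel_dosages.tsv"))
    bmi = read_sumstats(os.path.join(DATA, "bmi.tsv"))
    mets = [read_sumstats(os.path.join(DATA, f"{m}.tsv"))
            for m in METABOLITES]
    config = StageConfig(master_seed=1, n_boot=300)
    report = run_stage1([bmi], mets, panel, config)

    os.makedirs("results", exist_ok=True)
    report.table.to_csv(os.path.join("results", "stage1.tsv"), sep="\t",
                        index=False)
    shown = report.table[["outcome", "n_snp", "beta", "se", "pval",
                          "bonferroni_pass", "fail_reasons", "survivor"]]
    print(shown.to_string(index=False))
    surv = report.survivors()["outcome"].tolist()
    print(f"\nBonferroni threshold: "
          f"{report.table['bonferroni_threshold'].iloc[0]:.3g} "
          f"(0.05 / {len(mets)} harmonised metabolites)")
    print(f"obesity-driven metabolites: {surv}")
    print("results/stage1.tsv written")


if __name__ == "__main__":
    main()
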