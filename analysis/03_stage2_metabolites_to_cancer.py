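"""Stage 2: do the obesity-driven metabolites alter cancer risk?

Each surviving metabolite is instrumented by its own clumped variants
(proxies r² > 0.8 within 0.5 Mb substituted when an IV is missing from
the cancer GWAS); effects are reported as OR per SD with Wald/IVW-RE
routing; pairs must clear Bonferroni, the Stage-1 sensitivity battery,
sign-consistent replication in an independent cancer GWAS, and an
enumeration-colocalisation gate (PP_shared > 0.8 in at least one IV
region).

Run after 02:  python analysis/03_stage2_metabolites_to_cancer.py
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from metabomr import ReferencePanel, StageConfig, read_sumstats, run_stage2

DATA = os.path.join("scratch", "data")


def main() -> None:
    panel = ReferencePanel.read(os.path.join(DATA, "panel_variants.tsv"),
                                os.path.join(DATA, "panel_dosages.tsv"))
    stage1 = pd.read_csv(os.path.join("results", "stage1.tsv"), sep="\t")
    survivors = stage1.loc[stage1["survivor"], "outcome"].tolist()
    print(f"stage-1 survivors taken forward: {survivors}")
    mets = [read_sumstats(os.path.join(DATA, f"{m}.tsv")) for m in survivors]
    crc = read_sumstats(os.path.join(DATA, "crc.tsv"))
    repl = read_sumstats(os.path.join(DATA, "crc_replication.tsv"))
    config = StageConfig(master_seed=2, n_boot=300)
    report = run_stage2(mets, [crc], panel, config, replication_stats=[repl])

    report.table.to_csv(os.path.join("results", "stage2.tsv"), sep="\t",
                        index=False)
    shown = report.table[["exposure", "n_snp", "method", "or_sd", "or_low",
                          "or_high", "pval", "replication_pass",
                          "pp_shared_best", "survivor"]]
    print(shown.to_string(index=False))
    print("\nresults/stage2.tsv written")


if __name__ == "__main__":
    main()
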