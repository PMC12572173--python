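"""Stage 3: how much of the obesity -> cancer effect do metabolites mediate?

The total effect comes from univariable MR (Stage-1 instruments,
Bonferroni over the obesity-cancer pairs).  Mediators pass the
sign-consistency filter and the overlapping-IV filter (shared
instruments removed from the larger-sample GWAS); the reclumped union
of obesity and metabolite instruments feeds MVMR-IVW with conditional-F
and modified-Q diagnostics, which select the difference method or, on
weak instruments/pleiotropy, the product method.  The final report
bundle (volcano/forest/mediation tables) is also assembled here.

Run after 03:  python analysis/04_stage3_mediation.py
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from metabomr import (ReferencePanel, StageConfig, make_report, read_sumstats,
                      run_stage3, write_report)
from metabomr.pipeline import ScreenReport

DATA = os.path.join("scratch", "data")
TRUE_PROPORTION = 0.3 * 0.2 / (0.3 * 0.2 + 0.14)


def main() -> None:
    panel = ReferencePanel.read(os.path.join(DATA, "panel_variants.tsv"),
                                os.path.join(DATA, "panel_dosages.tsv"))
    stage2 = pd.read_csv(os.path.join("results", "stage2.tsv"), sep="\t")
    survivors = stage2.loc[stage2["survivor"], "exposure"].tolist()
    print(f"stage-2 survivors taken forward: {survivors}")
    bmi = read_sumstats(os.path.join(DATA, "bmi.tsv"))
    crc = read_sumstats(os.path.join(DATA, "crc.tsv"))
    mediators = [read_sumstats(os.path.join(DATA, f"{m}.tsv"))
                 for m in survivors]
    config = StageConfig(master_seed=3, n_boot=300)
    table = run_stage3([bmi], mediators, [crc], panel, config)
    table.to_csv(os.path.join("results", "stage3.tsv"), sep="\t", index=False)

    cols = ["mediator", "status", "method", "beta_total", "beta_indirect",
            "proportion_mediated", "se_proportion", "conditional_F_min",
            "weak_flag", "pleiotropy_flag"]
    print(table[[c for c in cols if c in table.columns]].to_string(index=False))
    ok = table.loc[table["status"] == "ok"]
    if len(ok):
        row = ok.iloc[0]
        print(f"\n{row['mediator']}: {row['method']} method, proportion "
              f"mediated = {row['proportion_mediated']:.3f} "
              f"(+/- {row['se_proportion']:.3f}); simulated truth = "
              f"{TRUE_PROPORTION:.3f}")

    stage1 = ScreenReport(pd.read_csv(os.path.join("results", "stage1.tsv"),
                                      sep="\t"))
    bundle = make_report(stage1, ScreenReport(stage2), table)
    write_report(bundle, os.path.join("results", "report"))
    print("results/stage3.tsv and results/report/ written")


if __name__ == "__main__":
    main()
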