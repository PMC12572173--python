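"""Generate the synthetic study: reference panel and GWAS summary statistics.

One obesity-like exposure GWAS (50k), four plasma-metabolite GWAS (8k
each, sharing the exposure's causal architecture): two true
obesity-driven metabolites, one null metabolite, and one "reverse"
metabolite whose genetics drive the exposure signal; one binary cancer
outcome GWAS (20k/20k) mediated by the first metabolite, plus an
independent replication outcome.  Large arrays go to scratch/, summary
tables to results/.

Run from the repository root:  python analysis/01_simulate_cohorts.py
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from metabomr import (SimulationConfig, TriadTruth, simulate_reference_panel,
                      simulate_triad_study, write_sumstats)

PANEL_SEED = 12
BASE_SEED = 51
DATA_DIR = os.path.join("scratch", "data")
TRUTH = TriadTruth(beta_EM_true=0.3, beta_MO_true=0.2,
                   beta_EO_direct_true=0.14)


def main() -> None:
    os.makedirs(DATA_DIR, exist_ok=True)
    panel = simulate_reference_panel(1000, 64, 1, 0.0, seed=PANEL_SEED)
    panel.write(os.path.join(DATA_DIR, "panel_variants.tsv"),
                os.path.join(DATA_DIR, "panel_dosages.tsv"))
    print(f"reference panel: {panel.n_individuals} individuals x "
          f"{panel.n_variants} variants in independent LD blocks "
          f"(one block inside the MHC window on chr6)")

    specs = [
        ("met_linoleoyl_gpc", BASE_SEED, TRUTH),          # true mediator
        ("met_oleoyl_gpc", BASE_SEED + 1,
         TriadTruth(-0.25, 0.2, 0.14)),                   # true, negative EM
        ("met_null_carnitine", BASE_SEED + 4,
         TriadTruth(0.0, 0.2, 0.14)),                     # null metabolite
    ]
    for name, seed, truth in specs:
        cfg = SimulationConfig(seed=seed, n_causal_snps=30,
                               exposure_seed=BASE_SEED)
        exposure, metab, outcome, echoed = simulate_triad_study(panel, cfg,
                                                                truth)
        metab.trait_id = name
        write_sumstats(metab, os.path.join(DATA_DIR, f"{name}.tsv"))
        if name == "met_linoleoyl_gpc":
            exposure.trait_id = "bmi"
            outcome.trait_id = "crc"
            write_sumstats(exposure, os.path.join(DATA_DIR, "bmi.tsv"))
            write_sumstats(outcome, os.path.join(DATA_DIR, "crc.tsv"))
        print(f"{name}: true beta(exposure->metabolite) = "
              f"{truth.beta_EM_true:+.2f}")

    # a metabolite whose own genetics drive the exposure (reverse signal)
    cfg = SimulationConfig(seed=60, n_causal_snps=30,
                           heritability_metabolite=0.02)
    _, met_rev, _, _ = simulate_triad_study(panel, cfg, TriadTruth(0.9, 0, 0))
    met_rev.trait_id = "met_reverse_signal"
    write_sumstats(met_rev, os.path.join(DATA_DIR, "met_reverse_signal.tsv"))
    print("met_reverse_signal: planted reverse-causation metabolite")

    # independent replication outcome, same causal structure, new sample
    cfg = SimulationConfig(seed=BASE_SEED + 20, n_causal_snps=30,
                           exposure_seed=BASE_SEED)
    _, _, repl, _ = simulate_triad_study(panel, cfg, TRUTH)
    repl.trait_id = "crc"
    write_sumstats(repl, os.path.join(DATA_DIR, "crc_replication.tsv"))
    print("crc_replication: independent outcome sample for validation")
    print(f"\nground truth: total effect = {TRUTH.beta_total_true:.3f} "
          f"log-odds/SD, proportion mediated = "
          f"{TRUTH.proportion_mediated_true:.3f}")
    print(f"wrote GWAS summary statistics to {DATA_DIR}/")


if __name__ == "__main__":
    main()
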