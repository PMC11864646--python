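#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Emulates the four data types of the study: (i) a proteome with planted
KFERQ-like motifs, (ii) CMA-network expression for a lamp2a-knockout
design and a hypoxia-like stressor design, (iii) a two-group label-free
ion-abundance experiment with planted regulation, and (iv) a qPCR Ct
table with a known 2-fold induction.  All outputs land in
results/data/ together with their ground truth.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cmakit import (
    MotifClass,
    example_network,
    generate_ion_abundances,
    generate_network_expression,
    generate_proteome,
    generate_qpcr_table,
    write_expression_table,
    write_fasta,
    write_network_config,
)

SEED = 20240915
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    network = example_network()
    write_network_config(network, OUT / "cma_network.tsv")

    # (i) proteome with 30 planted motifs per class
    records, motif_truth = generate_proteome(
        n_proteins=150, planted={cls: 30 for cls in MotifClass}, seed=SEED
    )
    write_fasta(records, OUT / "proteome.fasta")
    motif_truth.to_csv(OUT / "proteome.truth.tsv", sep="\t", index=False)

    # (ii) knockout and stressor expression designs (n = 7 and n = 6)
    ko_expr, ko_truth = generate_network_expression(
        network, {"kind": "knockout", "gene_id": "lamp2a_c31"},
        n_per_group=7, seed=SEED + 1,
    )
    write_expression_table(ko_expr, OUT / "expression_knockout.tsv")
    stress_expr, stress_truth = generate_network_expression(
        network, {"kind": "stressor", "fold": 2.0}, n_per_group=6, seed=SEED + 2
    )
    write_expression_table(stress_expr, OUT / "expression_stressor.tsv")
    with open(OUT / "expression.truth.json", "w") as fh:
        json.dump({"knockout": ko_truth, "stressor": stress_truth}, fh, indent=2)

    # (iii) label-free experiment: 400 proteins, 4 wt vs 4 ko runs,
    # 10 planted up and 10 planted down (log2 effect ±1.5)
    runs = [f"wt_{i + 1}" for i in range(4)] + [f"ko_{i + 1}" for i in range(4)]
    rng = np.random.default_rng(SEED + 3)
    n_prot, n_up, n_down = 400, 10, 10
    lfc = np.zeros(n_prot)
    lfc[:n_up] = 1.5
    lfc[n_up : n_up + n_down] = -1.5
    factors = pd.DataFrame(
        np.ones((n_prot, 8)),
        index=[f"prot{p + 1:04d}" for p in range(n_prot)], columns=runs,
    )
    factors.loc[:, [r for r in runs if r.startswith("ko")]] = 2.0 ** lfc[:, None]
    factors *= 2.0 ** rng.normal(0.0, 0.1, size=factors.shape)
    ions, ion_truth = generate_ion_abundances(
        n_proteins=n_prot, runs=runs, true_run_factors=factors,
        ions_per_protein=5, noise_sd_log2=0.15, missing_rate=0.05, seed=SEED + 4,
    )
    ions.to_csv(OUT / "ion_abundances.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"protein_id": factors.index, "planted_log2fc": lfc}
    ).to_csv(OUT / "ion_abundances.truth.tsv", sep="\t", index=False)
    pd.DataFrame({"run_id": runs,
                  "group": ["wt"] * 4 + ["ko"] * 4}).to_csv(
        OUT / "run_groups.tsv", sep="\t", index=False)

    # (iv) qPCR: 2-fold induction, n = 7 per group
    qpcr, qpcr_truth = generate_qpcr_table(
        groups={"control": 7, "treated": 7},
        true_fold_changes={"control": 1.0, "treated": 2.0},
        seed=SEED + 5,
    )
    qpcr.to_csv(OUT / "qpcr_ct.tsv", sep="\t", index=False)
    with open(OUT / "qpcr.truth.json", "w") as fh:
        json.dump(qpcr_truth, fh, indent=2)

    print(f"wrote synthetic inputs to {OUT}")
    print(f"  proteome: {len(records)} proteins, {len(motif_truth)} planted motifs")
    print(f"  expression: knockout 7+7 samples, stressor 6+6 samples")
    print(f"  ions: {n_prot} proteins x 8 runs ({n_up} up, {n_down} down planted)")
    print(f"  qpcr: 14 samples, true fold 2.0")


if __name__ == "__main__":
    main()
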