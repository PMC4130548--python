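#!/usr/bin/env python
"""Rare-variant set test on a simulated resequencing cohort.

Simulates an annotated variant table for one transcript in 800 cases and
500 controls in which controls carry a ten-fold excess of qualifying
alleles (the control-enriched direction observed for a cytokine-receptor
transcript: ~2.0% of controls vs ~0.23% of cases carrying), applies the
rare-conserved set-inclusion cascade, and runs the ancestry-adjusted
variance-component/burden test with permutation-calibrated min-p, plus
the Bonferroni adjustment for a 16-transcript, two-mode design.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from foundercnv import association as assoc
from foundercnv import filters, simulate

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    records, case_ids, control_ids = simulate.simulate_variant_table(
        n_variants=30, n_cases=800, n_controls=500,
        base_allele_freq=2e-4, control_enrichment=10.0, seed=seed,
    )
    kept = filters.select_set_variants(records, "TX1", mode="rare_conserved")
    samples = case_ids + control_ids
    G = np.array(
        [[np.nan if r.genotypes.get(s) is None else r.genotypes[s] for r in kept]
         for s in samples], dtype=float)
    y = np.r_[np.ones(len(case_ids)), np.zeros(len(control_ids))]
    rng = np.random.default_rng(seed)
    ancestry = rng.dirichlet((2.0, 2.0, 1.0), size=len(samples))[:, :2]

    res = assoc.set_score_test(G, y, covariates=ancestry, seed=seed, target_id="TX1")
    p_bonf = assoc.bonferroni(res.p_value, n_transcripts=16, n_modes=2)

    table = pd.DataFrame(
        [{"transcript": "TX1", "qualifying_variants": res.extra["n_variants"],
          "case_carrier_rate": res.case_freq, "control_carrier_rate": res.control_freq,
          "p_nominal": res.p_value, "p_bonferroni": p_bonf,
          **{f"p_rho_{rho}": p for rho, p in res.extra["p_by_rho"].items()}}]
    )
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "set_test.tsv", sep="\t", index=False, float_format="%.4g")
    print(table.to_string(index=False))
    print(
        f"\n{res.extra['n_variants']} variants qualified; carriers: "
        f"{100 * res.control_freq:.2f}% of controls vs {100 * res.case_freq:.2f}% of "
        f"cases; set test p = {res.p_value:.4g} "
        f"(Bonferroni over 16 transcripts x 2 modes: {p_bonf:.4g})."
    )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
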