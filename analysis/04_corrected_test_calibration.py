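#!/usr/bin/env python
"""Type-I-error calibration of the kinship-corrected allelic test.

Simulates one three-generation founder pedigree (16 founders, mean six
offspring per couple) and, over 10,000 replicates, drops a null variant
(per-allele OR = 1) and a familially clustered phenotype (liability
heritability ~0.5) through it, then applies both the kinship-corrected
chi-square and the naive allelic chi-square.  The corrected test should
hold its 5% level; the naive test, blind to the family clustering of
both genotype and case status, inflates far beyond it.
"""

import sys
from pathlib import Path

import pandas as pd

from foundercnv import scenarios

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1, n_replicates: int = 10_000) -> None:
    res = scenarios.type_i_error_pedigree(n_replicates=n_replicates, seed=seed)
    table = pd.DataFrame(
        [
            {"test": "kinship_corrected_chisq", "rejection_rate_at_0.05":
                res["corrected_rejection_rate"]},
            {"test": "naive_allelic_chisq", "rejection_rate_at_0.05":
                res["naive_rejection_rate"]},
        ]
    )
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "corrected_test_calibration.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print(
        f"\nOn a {res['pedigree_size']}-member pedigree over {res['n_replicates']} "
        f"null replicates the corrected test rejected at "
        f"{100 * res['corrected_rejection_rate']:.2f}% (nominal 5%), while the naive "
        f"chi-square rejected at {100 * res['naive_rejection_rate']:.2f}% — ignoring "
        f"relatedness would flood a founder-population scan with false positives."
    )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
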