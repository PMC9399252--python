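#!/usr/bin/env python
"""Rhythmic-gene calling on a synthetic liver-style expression matrix.

Generates 1,000 genes (30% rhythmic, 2-fold amplitude, lognormal noise,
6 timepoints x 3 replicates), applies the three-criteria caller, and writes
calls.csv, the CT phase histogram and the row-standardized heat-map matrix
to results/expression_rhythmicity/, with sensitivity/specificity against
the generator truth printed at the end.
"""

from pathlib import Path

from rreclock.caller import phase_histogram, row_standardize
from rreclock.workflows import rhythmic_gene_benchmark

OUT = Path(__file__).resolve().parents[1] / "results" / "expression_rhythmicity"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bench = rhythmic_gene_benchmark(
        n_genes=1000, frac_rhythmic=0.3, fold_amplitude=2.0,
        noise_sigma=0.15, n_reps=3, seed=101,
    )
    bench.calls.to_csv(OUT / "calls.csv", index=False)
    phase_histogram(bench.calls).to_csv(OUT / "phase_histogram.csv")

    from rreclock.synthetic import gen_expression_matrix

    matrix, _ = gen_expression_matrix(n_genes=1000, seed=101)
    value_cols = [c for c in matrix.columns if c != "gene"]
    standardized, flagged = row_standardize(matrix[value_cols])
    standardized.insert(0, "gene", matrix["gene"].to_numpy())
    standardized.to_csv(OUT / "standardized_matrix.csv", index=False)

    n_called = int(bench.calls["is_rhythmic"].sum())
    print(f"{n_called}/1000 genes called rhythmic "
          f"({bench.n_rhythmic_true} truly rhythmic)")
    print(f"sensitivity {bench.sensitivity:.3f}, "
          f"specificity {bench.specificity:.3f}")
    print(f"{int(flagged.sum())} zero-variance rows flagged in the heat-map "
          f"matrix")


if __name__ == "__main__":
    main()
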