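#!/usr/bin/env python
"""Kinase activity scoring on a synthetic phosphoproteome.

Generates a WT-vs-mutant phosphosite table in which one kinase's substrates
are shifted by a known log2 delta, normalizes each site to its WT mean,
scores every kinase as the mean substrate log2 fold change, and writes
scores.csv plus the residue composition to results/kinase_activity/.
"""

from pathlib import Path

import pandas as pd

from rreclock.ksea import residue_composition
from rreclock.synthetic import gen_kinase_map, gen_phospho_dataset
from rreclock.workflows import ksea_recovery_benchmark

OUT = Path(__file__).resolve().parents[1] / "results" / "kinase_activity"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bench = ksea_recovery_benchmark(
        delta=1.0, shifted_kinase="KIN00", n_kinases=8, n_substrates=20,
        n_per_group=4, noise_sigma=0.3, seed=202,
    )
    bench.scores.to_csv(OUT / "scores.csv", index=False)

    kmap = gen_kinase_map(n_kinases=8, n_substrates=20)
    table, _ = gen_phospho_dataset(kmap, {"KIN00": 1.0}, seed=202)
    comp = residue_composition(table)
    pd.Series(comp, name="fraction").rename_axis("residue").to_csv(
        OUT / "residue_composition.csv"
    )

    print(f"injected delta = {bench.injected_delta:+.2f} for KIN00; "
          f"recovered score {bench.recovered_score:+.3f}")
    print(f"largest |score| among unshifted kinases: "
          f"{bench.max_abs_null_score:.3f}")
    print("residue composition: "
          + ", ".join(f"{r}: {f:.1%}" for r, f in sorted(comp.items())))


if __name__ == "__main__":
    main()
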