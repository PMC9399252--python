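#!/usr/bin/env python
"""Simulate the three clock genotypes and summarize their limit cycles.

Writes per-genotype trajectory excerpts (last 72 hr of the attractor) and
limit-cycle summaries under results/clock_variants/, and prints the headline
comparison: the constitutive-Bmal1 mutant keeps a clear clock with a flat
Bmal1 mRNA, a slightly longer period than wild type, and an almost
unchanged p-BMAL1 rhythm.
"""

from pathlib import Path

from rreclock.model import DEFAULT_CONFIG, Genotype, build_model, simulate, summarize_limit_cycle

OUT = Path(__file__).resolve().parents[1] / "results" / "clock_variants"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summaries = {}
    for genotype in Genotype:
        model = build_model(genotype)
        traj = simulate(model, DEFAULT_CONFIG.t_end)
        summary = summarize_limit_cycle(traj)
        summaries[genotype] = summary
        tail = traj.window(DEFAULT_CONFIG.t_end - 72.0, DEFAULT_CONFIG.t_end)
        tail.to_wide_frame().to_csv(
            OUT / f"trajectory_{genotype.value}.csv", index=False
        )
        (OUT / f"limit_cycle_{genotype.value}.json").write_text(
            summary.to_json() + "\n"
        )

    wt, mut = summaries[Genotype.WT], summaries[Genotype.DRRE_BMAL1]
    print(f"WT period: {wt.period:.2f} hr; mutant period: {mut.period:.2f} hr "
          f"(+{mut.period - wt.period:.2f} hr)")
    print("Bmal1 mRNA relative amplitude: "
          f"WT {wt.relative_amplitude['Bmal1_mRNA']:.3f}, "
          f"mutant {mut.relative_amplitude['Bmal1_mRNA']:.2e} (flat)")
    print("p-BMAL1 relative amplitude: "
          f"WT {wt.relative_amplitude['pBMAL1']:.3f}, "
          f"mutant {mut.relative_amplitude['pBMAL1']:.3f}")
    double = summaries[Genotype.DRRE_BMAL1_CLOCK]
    print("Bmal1+Clock double clamp still oscillates: "
          f"{double.oscillating} (p-BMAL1 amp "
          f"{double.relative_amplitude['pBMAL1']:.3f})")


if __name__ == "__main__":
    main()
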