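#!/usr/bin/env python
"""Drug-mimicking perturbations: CRY stabilization and REV-ERB agonism.

Sweeps the CRY-stabilization fraction (KL001-like) and the REV-ERB agonism
fraction (SR9009-like) for the wild type and the constitutive-Bmal1 mutant,
writing both dose-response tables to results/drug_perturbations/.  The
mutant clock is the fragile one: its period shifts more per dose and its
CRY1/p-BMAL1 rhythms die at doses the wild type survives.
"""

from pathlib import Path

from rreclock.workflows import cry_stabilization_response, reverb_agonism_response

OUT = Path(__file__).resolve().parents[1] / "results" / "drug_perturbations"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cry = cry_stabilization_response(fractions=(0.0, 0.2, 0.4, 0.6, 0.8))
    cry.to_csv(OUT / "cry_stabilization.csv", index=False)
    piv = cry.set_index(["genotype", "fraction"])
    for fraction in (0.2, 0.4, 0.6):
        d_wt = abs(piv.loc[("wt", fraction), "period_change_hr"])
        d_mut = abs(piv.loc[("drre", fraction), "period_change_hr"])
        print(f"CRY stabilization {fraction:.0%}: |period change| "
              f"WT {d_wt:.2f} hr vs mutant {d_mut:.2f} hr")
    print(f"CRY stabilization 80%: p-BMAL1 amplitude "
          f"WT {piv.loc[('wt', 0.8), 'pbmal1_relamp']:.3f} (rhythm persists) "
          f"vs mutant {piv.loc[('drre', 0.8), 'pbmal1_relamp']:.3f} (lost)")

    ago = reverb_agonism_response(fractions=(0.0, 0.5, 0.9))
    ago.to_csv(OUT / "reverb_agonism.csv", index=False)
    at90 = ago.query("fraction == 0.9").set_index("genotype")
    print(f"REV-ERB agonism 90%: CRY1 amplitude WT "
          f"{at90.loc['wt', 'cry1_relamp']:.3f} vs mutant "
          f"{at90.loc['drre', 'cry1_relamp']:.1e}; p-BMAL1 "
          f"{at90.loc['wt', 'pbmal1_relamp']:.3f} vs "
          f"{at90.loc['drre', 'pbmal1_relamp']:.1e}")


if __name__ == "__main__":
    main()
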