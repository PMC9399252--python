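# rreclock

Analysis pipeline for asking what the RRE-mediated *Bmal1* feedback loop
buys the mammalian circadian clock. The package models the clock as two
interlocked transcriptional feedback loops — the E-box core loop, in which
the CLOCK–BMAL1 activator drives *Per2*/*Cry1*/*Rev-erb* and is sequestered
by the PER–CRY repressor, and the RRE loop, in which REV-ERB represses the
ROR/REV-ERB response elements (RREs) of *Bmal1*, *Cry1* and *Clock* — and
compares the wild type against a ΔRRE mutant whose *Bmal1* mRNA is
constitutive. Around the model it provides the circadian data analytics
needed to read such experiments: bioluminescence-trace metrics, a
chi-square periodogram for locomotor activity, a three-criteria
rhythmic-gene caller for short expression time courses, and
kinase-substrate enrichment scoring for phosphoproteomes. Seeded synthetic
generators emulate each data type with known ground truth, so the whole
pipeline runs without any external download.

Intended users: systems-biology and chronobiology researchers who want a
compact, testable model of the interlocked clock and reference
implementations of the standard circadian analytics.

## The model in brief

Fifteen species (five mRNAs, eight proteins, two complexes) under mass
action, with three regulatory nonlinearities:

* **E-box activation.** Free activator is the CLOCK–BMAL1 not sequestered
  by nuclear PER–CRY, from 1:1 quasi-equilibrium binding with dissociation
  constant `K_seq`:
  `A_free = ((A−R−K) + sqrt((A−R−K)² + 4AK))/2`. E-box transcription is
  `ebox_basal + (1−ebox_basal)·A_free/(K_act + A_free)` times a per-gene
  rate.
* **RRE repression.** Transcription of *Bmal1*, *Cry1*, *Clock* scales with
  `Kd/(Kd + REV-ERB)`, `Kd = unbind/bind` per element.
* **BMAL1 phosphorylation.** CLOCK-bound BMAL1 is phosphorylated at rate
  `k_phos/(1 + CRY1/K_cry1_inhib)`; phospho-BMAL1 degrades faster. Its
  relative amplitude, `(max−min)/max`, is the functional-rhythm readout.

The ΔRRE mutant replaces the *Bmal1* RRE synthesis term with a constant
whose steady-state mRNA level equals the time-averaged *Bmal1* mRNA of the
wild-type model under the same (possibly drug-transformed) parameters.
Drugs are parameter transforms: CRY stabilization scales the nuclear CRY
degradation rates `uro`/`urt` by `1−fraction`; REV-ERB agonism scales the
RRE unbinding rates `unbinrevb`/`unbinrev` the same way.

## Worked example

```sh
python analysis/01_simulate_clock_variants.py
python analysis/02_drug_perturbations.py
python analysis/03_robustness_screen.py
```

prints

```
WT period: 23.87 hr; mutant period: 25.22 hr (+1.36 hr)
Bmal1 mRNA relative amplitude: WT 0.298, mutant 0.00e+00 (flat)
p-BMAL1 relative amplitude: WT 0.121, mutant 0.113
Bmal1+Clock double clamp still oscillates: True (p-BMAL1 amp 0.151)

CRY stabilization 20%: |period change| WT 0.22 hr vs mutant 0.54 hr
CRY stabilization 40%: |period change| WT 0.63 hr vs mutant 1.35 hr
CRY stabilization 60%: |period change| WT 1.35 hr vs mutant 2.58 hr
CRY stabilization 80%: p-BMAL1 amplitude WT 0.081 (rhythm persists) vs mutant 0.028 (lost)
REV-ERB agonism 90%: CRY1 amplitude WT 0.210 vs mutant 1.1e-05; p-BMAL1 0.205 vs 2.3e-06

of 400 completed sets (threshold 0.1): both=244, wt_only=33, mut_only=0, neither=123
strict threshold 0.4: both=215, wt_only=49, mut_only=0, neither=136
WT-only exceeds mutant-only: 33 > 0 -> the RRE loop buffers the clock
```

Reading: losing the *Bmal1* mRNA rhythm does not stop the clock — the
p-BMAL1 rhythm is nearly unchanged and the period only lengthens by about
1.4 hr — but it makes the clock fragile. Stabilizing CRYs shifts the
mutant's period roughly twice as much as the wild type's and extinguishes
its p-BMAL1 rhythm at an 80% dose the wild type survives; hyperactivating
REV-ERB (90% drop in the RRE dissociation constants) silences CRY1 and
p-BMAL1 only in the mutant; and under random ±50% perturbation of all rate
constants, parameter sets in which only the wild type keeps oscillating
far outnumber the reverse.

Drivers `04`–`06` run the trace metrics, the rhythmic-gene caller
(sensitivity 0.997 / specificity 0.991 on the 1,000-gene benchmark) and
the kinase scoring (injected log2 shift of 1.0 recovered as 1.116 with the
largest null score at 0.071) on synthetic data; all tables land under
`results/`.

The same operations are available as a CLI (`rreclock simulate|screen|
rhythm|call|ksea|synth`); see `rreclock --help`.

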