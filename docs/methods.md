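# Methods

## The reduced interlocked clock model

The model is a deliberately compact (15-species) representation of the
mammalian circadian network, keeping only the regulatory topology that the
analyses depend on. Species: *Bmal1*, *Per2*, *Cry1*, *Rev-erb* and
*Clock* mRNAs; BMAL1, phospho-BMAL1, CLOCK, PER, CRY1, CRY2 and REV-ERB
proteins; the CLOCK–BMAL1 activator complex; and cytoplasmic and nuclear
PER–CRY complexes. All reactions are mass action except three regulatory
functions:

* **Activator sequestration.** Nuclear PER–CRY binds CLOCK–BMAL1 1:1 with
  dissociation constant `K_seq` (default 0.002, concentration units) under
  a quasi-equilibrium assumption; E-box transcription responds to the free
  activator through `A_free/(K_act + A_free)` (`K_act` = 0.2). Tight
  sequestration makes the E-box response ultrasensitive near 1:1
  activator–repressor stoichiometry, which is what lets a loop of
  first-order stages (mRNA → PER → cytoplasmic complex → nuclear complex)
  oscillate with a circadian period.
* **RRE repression.** REV-ERB occupies each RRE with probability
  `R/(R + Kd)`, `Kd = unbind/bind`, so transcription scales with
  `Kd/(Kd + R)`. *Bmal1* has its own unbinding constant (`unbinrevb`);
  *Cry1* and *Clock* share one (`unbinrev`). *Cry1* is driven by the sum
  of an E-box term and an RRE term.
* **BMAL1 phosphorylation.** Only CLOCK-bound BMAL1 is phosphorylated,
  at rate `k_phos_bmal1/(1 + CRY1/K_cry1_inhib)`; CRY1 inhibition makes
  the phospho-BMAL1 rhythm track the CRY1 rhythm even when total BMAL1 is
  constant, which is exactly the behaviour the ΔRRE comparison probes.
  Dephosphorylation returns BMAL1 to the free pool; phospho-BMAL1 degrades
  ~3.5× faster than the unphosphorylated protein.

**Basal E-box activity.** E-box transcription retains a small
activator-independent component (`ebox_basal`, default 0.07 of the maximal
rate). This is both biochemically reasonable (E-box promoters are never
fully silent) and dynamically essential to the fragility phenotypes: the
basal leak sustains a small repressor pool even when the activator is
fully sequestered, so a strong repressor excess — stabilized CRYs, or
REV-ERB locked onto the RREs — can hold the system in a stable
over-repressed state. The wild type escapes that state because falling
REV-ERB de-represses the *Bmal1* RREs and the activator surges back; the
constitutive-*Bmal1* mutant cannot, and its rhythm dies. Without the leak
the core loop is an unconditional relaxation oscillator and neither drug
regime can extinguish it.

**Genotypes.** The ΔRRE mutant replaces the *Bmal1* RRE synthesis term
with the constant `deg_bmal1_mrna × ⟨Bmal1 mRNA⟩_WT`, so the clamped mRNA
settles exactly at the wild-type time average; the double mutant clamps
*Clock* mRNA the same way. The clamp level is always recomputed from the
wild-type model under the *same* parameter set — including drug transforms
and random screen draws — so every comparison is against its matching wild
type. (Whether per-draw recomputation is the only defensible convention is
genuinely open; we chose it because clamping a perturbed mutant to an
unperturbed wild-type average would conflate the perturbation with the
genotype.)

**Drug transforms.** CRY stabilization multiplies the nuclear CRY
degradation rates `uro` (CRY1) and/or `urt` (CRY2) by `1−fraction`;
REV-ERB agonism multiplies the RRE unbinding rates by `1−fraction`,
lowering the dissociation constants by the same factor since binding rates
are untouched. Only nuclear CRY degradation is scaled; cytoplasmic
turnover of CRY within the PER–CRY pool is a separate rate.

**Default parameters.** No published rate constants exist for a model of
this size, so the defaults (see `rreclock.parameters.DEFAULT_VALUES`) were
chosen during implementation, by numerical search, to satisfy the
qualitative behaviour the analyses require: a wild-type limit cycle at
23.9 hr with a strong *Per2* mRNA rhythm; a viable ΔRRE mutant with a
slightly longer period and near-identical p-BMAL1 amplitude; monotone loss
of the mutant p-BMAL1 rhythm under CRY stabilization with the mutant dying
before the wild type; death of the mutant but not the wild type under
strong REV-ERB agonism; and greater wild-type robustness under random
parameter perturbation. They are a representative operating point of the
topology, not a fit to any measured kinetics, and all conclusions here are
qualitative comparisons between genotypes under identical parameters.

**Integration.** LSODA with relative tolerance 1e−8 and absolute
tolerance 1e−10 (drug/dose sweeps use 1e−7/1e−9 and the screen 1e−6/1e−8,
where only threshold classifications are needed); 600 hr of transient
discarded and the next 240 hr analysed, which stabilizes default-parameter
period estimates to < 0.01 hr. Peak times are refined by local quadratic
interpolation on the 0.1-hr output grid. States that undershoot below
−1e−8 abort the run (the literal absolute tolerance would false-alarm on
legitimate interpolation error); smaller negatives are clipped to zero on
output. Oscillation calls use the relative amplitude `(max−min)/max` of
*Per2* mRNA with a strict `> 0.1` threshold ("weak rhythmicity"; 0.4 is
the strict variant), and a window with fewer than three reference peaks
returns an explicit "inconclusive" status rather than a period.

## Robustness screen

Each draw multiplies every one of the 41 rate constants by an independent
uniform factor in `[1−r, 1+r]` (default r = 0.5). The distributional law
is a choice — the multiplicative uniform is the simplest law consistent
with "each parameter within ±50%" — as is the handling of failed
integrations: failed draws are excluded from the Venn tally (never
imputed), reported per draw, and more than 5% failures is a hard error.
Draws are identified by index and tallied in index order, so results are
independent of any execution interleaving.

## Trace metrics

Smoothing is a centered 2-hr moving mean and detrending subtracts a
centered 24-hr moving mean; in both cases edge samples without a full
window are dropped, so the record shortens. Peaks and troughs of the
detrended trace need 12 hr of separation and a prominence of 10% of the
trace maximum, and are reconciled to strict alternation by keeping the
more extreme of same-type neighbours. The period is the mean of four
intervals: the two between the first three peaks and the two between the
first three troughs. The area amplitude integrates `|detrended|` from the
first trough to the second peak and divides by that span — the printed
description of the original area rule is ambiguous about which arcs
constitute it, so this definition (mean rectified amplitude over
trough→peak→trough→peak) is adopted and documented rather than guessed as
the original's intent.

The chi-square periodogram folds the binned record at each candidate
period P into `K = round(P/Δ)` columns (truncated to complete rows) and
computes `Qp = N·Var(column means)/Var(data)` with population variances,
which is chi-square with K−1 degrees of freedom under an arrhythmic null
— a calibration the tests verify by simulation (the fraction of candidate
periods significant on i.i.d. noise tracks α). Some period-scan
formulations carry an extra factor of K; that variant is not chi-square
calibrated and is not used. The candidate grid spans 20–28 hr at the bin
width, matching the rhythmicity-detection range.

## Rhythmic-gene caller

A gene is rhythmic when all three criteria hold: (1) rhythmicity p-value
< 0.3; (2) the highest per-time mean is ≥ 1.5× the lowest (a zero trough
with a positive peak passes by convention; an all-zero profile never
does); (3) the largest per-time SD is ≤ 1.5× the amplitude (peak −
trough). Time points with a single replicate carry no sample SD and are
excluded from criterion 3; if no time point has two replicates the
criterion passes by exclusion and the SD is reported as NaN. Criteria 2
and 3 are invariant to positive scaling of a gene, and no multiple-testing
correction is applied across genes — the criteria are per-gene.

The p-value stands in for a trained deep-learning rhythm detector that
cannot be redistributed here. It scans harmonic (intercept + cosine +
sine) regressions over a 20–28 hr period grid (0.5-hr steps) and takes the
minimum residual sum of squares. Because the grid's fits are strongly
correlated, a Bonferroni adjustment of the per-period F-tests is massively
conservative (measured null rate of p < 0.3 ≈ 0.03 instead of 0.3), so
the statistic `1 − RSS_min/RSS_0` — which is pivotal under an i.i.d.
normal null, depending only on the sampling design — is instead calibrated
against a 20,000-draw Monte Carlo null table computed once per design
from a fixed internal seed. The resulting p-values are uniform under the
null by construction (verified by KS test) and resolve down to 5e−5.
The acrophase is the fitted cosine maximum at the best-grid period,
reported modulo that period and binned to the nearest sampled circadian
time for histograms. Phase histograms count each rhythmic gene once.

Row standardization for heat maps sets each row to mean 0 and population
variance 1; zero-variance rows pass through as zeros and are flagged.

## Kinase scoring

Each phosphosite is normalized to the mean of its WT samples and
log2-transformed; zero abundances are treated as missing before the log
(no pseudocount), sites with no usable WT mean are dropped with a logged
count, and missing values are excluded pairwise from all means. A kinase's
activity score is the unweighted mean of its substrates' log2 fold changes
in the chosen condition; substrates shared between kinases count for each,
and kinases with no measured substrate are omitted. Whether the original
analyses averaged per time point or across all mutant samples is not
stated; the condition argument exposes both and the default averages all
samples of the condition.

## Synthetic data

The generators emulate the statistical shape of the real data types:
expression matrices with 6 timepoints × 4-hr intervals and 2–4 replicates,
a rhythmic fraction with von Mises phase structure (default centered at
CT8, the phase band where E-box output genes concentrate) and
multiplicative lognormal noise; damped-cosine bioluminescence traces on a
drifting baseline; Poisson wheel-revolution counts in 5-min bins with a
daily active bout; and lognormal phosphosite intensities with kinase-level
log2 shifts (2^δ on the mutant mean, so the generating score is exactly
δ). Lognormal noise is used for intensities because they are positive and
right-skewed; Poisson for event counts. Defaults mirror the benchmark
conditions used throughout: 1,000 genes, 30% rhythmic, 2-fold amplitude,
σ = 0.15, n = 3 for expression; 20 substrates, σ = 0.3 (log2), n = 4 per
group, δ = 1 for phospho.

What the generators do **not** reproduce: read-level sequencing or
spectrum-level mass-spectrometry artifacts, missingness structure of real
phosphoproteomes (values are missing only where generated as zero),
gene–gene correlation, non-sinusoidal waveforms, and cross-replicate batch
effects. Passing benchmarks on these data therefore demonstrates that the
algorithms recover the truth under their own noise model at realistic
sizes — not field performance on real measurements.

## Problem sizes and numerical choices

The robustness screen ships with 400 draws by default; the direction of
the wild-type/mutant asymmetry is stable well below that (it is already
10:1 at 80 draws). The caller benchmark uses 1,000 genes, the kinase
benchmark 5–8 kinases × 20 substrates, and the actogram 14 days of 5-min
bins. Dose–response sweeps reuse the 1e−7/1e−9 tolerance tier: at those
settings period estimates are stable to ~1e−3 hr, far below the effects
measured.

## Known limitations

* The model is a reduced topology; its periods, amplitudes and Venn counts
  are not comparable number-for-number with detailed SCN models (hundreds
  of state variables), only in direction and mechanism.
* The harmonic-regression p-value is a calibrated stand-in, not a
  re-implementation of any trained rhythm detector; with 6 timepoints its
  power against non-sinusoidal rhythms is limited.
* No SCN network coupling, light input, or drug pharmacokinetics: drugs
  are instantaneous parameter scalings.
* The screen perturbs parameters independently; correlated parameter
  uncertainty and bifurcation structure are out of scope.
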