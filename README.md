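# circasense

Consensus circadian rhythm calling and sense/antisense analysis for short
expression time courses.

## The problem

Circadian transcriptome experiments in plants typically sample leaves every
4 h for 48 h under constant light — 12 points per probe, often with two
dye-swap replicates.  At that length no single rhythm test is trustworthy:
spectral tests, cosine-fitting tests and rank-concordance tests each carry
their own biases.  The robust convention is to run three independent
detectors over the circadian period band (20–28 h) and call a transcript
*circadian* only when at least two reject the null at p < 0.05.  On
two-channel oligoarrays the same pipeline applies separately to probes for
sense transcripts (SS) and natural antisense transcripts (AS), which opens
three follow-up questions this package also answers: are SS/AS pairs of the
same gene model co-regulated, do ortholog clusters keep their phase across
species/platforms, and do functional categories cluster in phase?

`circasense` implements that pipeline as a library for anyone analysing
12-point (or similar) expression time courses: preprocessing, the three
detectors with exact or permutation nulls, consensus calling and reporting,
SS/AS pair correlation, ortholog phase concordance, category phase
summaries and enrichment — plus a generator of ground-truth-labelled
synthetic datasets so every stage is testable without downloads.

## The statistics

All detectors consume a Z-scored series *y(t)*, *t = 0, 4, …, 44* h
(population SD; probes expressed in ≥ 10 of 12 arrays).

**Fisher's exact G-test.**  With periodogram ordinates *I₁ … I_m* at the
Fourier frequencies (*m* = ⌊(n−1)/2⌋ = 5 for n = 12; Nyquist excluded),

&nbsp;&nbsp;G = max_k I_k / Σ_k I_k,&nbsp;&nbsp;
p = Σ_{j=1}^{⌊1/G⌋} (−1)^{j−1} C(m, j) (1 − jG)^{m−1}.

The argmax period must fall in the 20–28 h band (for this design, the 24 h
line) for the test to count as a circadian vote.

**JTK (rank concordance).**  Reference waveforms cos(2π(t−φ)/τ) on the
lattice τ ∈ {20, 24, 28} h, φ stepping by 4 h, are reduced to ranks with
ties preserved.  For each reference, Kendall's S between the data and the
reference has an exact null distribution under uniform orderings given the
reference tie groups (t₁, …, t_G): the number of arrangements with a given
between-group concordance count is a Gaussian-multinomial coefficient,
computed by convolution.  The best reference's one-sided exact p is
Bonferroni-scaled by the number of distinct alternatives (a waveform and
its rank reversal count once).  JTK supplies the consensus phase.

**COSOPT (cosine grid + surrogates).**  For each trial period τ on a 0.2 h
grid, fit y ≈ a + b·cos(2πt/τ) + c·sin(2πt/τ) by least squares; the
statistic is 1 − RSS/TSS at the best τ, amplitude √(b²+c²), phase the ZT
time of the fitted peak.  Significance is empirical over seeded random
permutations of the series: p = (1 + #{surrogate ≥ observed}) / (N + 1).
COSOPT supplies the consensus period.

**Downstream.**  SS/AS pairs: Spearman ρ with |ρ| > 0.56 significant (the
bound for 12-point series).  Ortholog clusters: circadian if any member
probe is; cluster phase = circular median; cross-dataset phase concordance
r² = squared Pearson correlation of cluster phase pairs after circular
difference minimization (ZT2 vs ZT22 compares as ZT26 vs ZT22).  Category
phases: circular median ± MAD with gap-based bimodality detection;
enrichment: upper-tail hypergeometric with Bonferroni correction.

## Worked example

```sh
python examples/01_rhythm_calling.py
```

simulates 1,000 sense probes (two replicates, ~70% expressed, 32% of the
expressed probes rhythmic at signal-to-noise 3), runs the full pipeline and
prints:

```
expressed (>=10 of 12 arrays): 703/1000 (70.3%)
circadian (>=2 of 3 detectors): 217 (30.9% of expressed)
per-method counts: {'cosopt': 225, 'jtk': 225, 'fisher_g': 197}
COSOPT period over circadian probes: 24.24 +/- 2.1 h (mean +/- sd)
phase-bin fractions: {'ZT0': 0.19, 'ZT4': 0.12, 'ZT8': 0.16, 'ZT12': 0.25, 'ZT16': 0.17, 'ZT20': 0.11}
detector agreement (Venn regions): {'cosopt_only': 8, 'jtk_only': 8, 'fisher_only': 1, 'cosopt_jtk': 21, 'cosopt_fisher': 0, 'jtk_fisher': 0, 'all_three': 196}
vs planted truth: consensus sensitivity 0.995, false-positive rate 0.016
COSOPT period RMSE 0.66 h, JTK circular phase RMSE 1.50 h
```

Reading it: 703 of 1,000 probes pass the expression filter; the 2-of-3
consensus recovers 99.5% of the planted rhythms while keeping false calls
at 1.6% (well under the per-test α = 0.05); the consensus period and phase
histograms recover the planted distributions; most rhythmic probes are
flagged by all three detectors.

The other examples cover SS/AS pair classification
(`02_antisense_pairs.py`), ortholog phase concordance
(`03_ortholog_phase_comparison.py`) and category phase structure plus
enrichment (`04_functional_phases_and_enrichment.py`).

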