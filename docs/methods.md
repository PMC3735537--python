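# Methods

This note documents the models, conventions and numerical choices behind
`circasense`, in the order data flows through the package.

## Sampling design and preprocessing

The canonical design is 12 samples at 4 h intervals over 48 h of constant
light, the first sample at subjective dawn (ZT0), with two dye-swap
replicate hybridizations per time point.  Other regular designs (n ≥ 4) are
supported; the JTK reference lattice and the Fisher frequency grid adapt to
the design.

Preprocessing order is **merge → filter → normalize**:

* *Replicate merging*: arithmetic mean per time point.  A time point is
  flagged expressed when a majority of replicates flag it, with ties
  (1 of 2) counting as expressed — the permissive rule, consistent with the
  high expressed fractions this kind of array reports.  Whether merging
  precedes normalization is a genuine free choice; merge-then-normalize is
  implemented because the detectors consume one series per probe.
* *Expression filter*: a probe is analysed only if flagged expressed in at
  least 10 of the 12 arrays (`min_timepoints=10`).
* *Z-score*: (y − mean)/SD with the population (n) SD, i.e. the classic
  z-transform of a complete series.  Zero-variance series cannot be scored
  by any of the detectors; they are flagged `zero_variance`/not-analyzable
  and carried through as marker rows rather than raised, so batch runs
  complete and report.

All three detectors are invariant to adding a constant; Fisher's G and JTK
are also invariant to positive scaling, so normalization affects only the
COSOPT amplitude, which is therefore reported on the normalized scale.

## Detectors

### Fisher's exact G-test

Periodogram ordinates I_k = |Σ_t y_c(t) e^(−2πikt/n)|² / n at
k = 1 … m, m = ⌊(n−1)/2⌋ (mean-centred series; the Nyquist ordinate of an
even-length series is excluded because the exact null below assumes m
exchangeable exponential ordinates).  G = max I_k / Σ I_k with the exact
tail p = Σ_{j=1}^{⌊1/G⌋} (−1)^{j−1} C(m,j)(1−jG)^{m−1}.  The statistic is
global in frequency, so the detector's circadian vote additionally requires
the argmax period to lie in the band — for the 12 × 4 h design the
periodogram grid is {48, 24, 16, 12, 9.6} h and only the 24 h line
qualifies.  Consequence: a Fisher result may carry a reported period
outside 20–28 h; that is information for the consensus stage, not a bug.

The closed form was verified against a 200,000-draw Gaussian Monte-Carlo
oracle.  Note that the *permutation* distribution of G for a fixed series
is a different (conditional) null; it matches the closed form only on
average across Gaussian series, which is how the permutation cross-check in
the test suite is aggregated.

### JTK rank concordance

Reference waveforms cos(2π(t−φ)/τ) with τ restricted to integer multiples
of the sampling interval inside the band ({20, 24, 28} h at 4 h sampling —
the rank-pattern construction needs lattice-aligned waveforms) and φ
stepping by `phase_step_h` (default 4 h) across one period.  Each waveform
is reduced to average ranks with ties preserved (cosine symmetry produces
genuine ties, e.g. tie groups (2, 4, 4, 2) for the 24 h references).

For one reference with tie groups (t₁ … t_G), the concordance count
JT = (S + P)/2 (S = Kendall numerator over the P pairs where the reference
differs) has an exact null under uniform random orderings of tie-free data:
the number of arrangements with a given between-group inversion count is a
Gaussian-multinomial coefficient, computed exactly in integer arithmetic as
a product of Gaussian binomials (each obtained by polynomial
multiplication/division).  Tail probabilities are cached per tie structure.
The suite verifies exact equality with full enumeration for all default
references at n ≤ 8.

Per series, the best (minimal-p) reference supplies period and phase (ZT of
the waveform peak, mod 24); the reported p is min(1, best p × family size)
where the family counts a waveform and its rank reversal once (antiphase
pairs exist on-grid only for the 24 h period at 4 h phase steps, so the
default family is 18 − 3 = 15).  The Bonferroni bound over dependent
references makes JTK conservative: its white-noise rejection rate sits
below α by design.

Ties in the data (rare after Z-scoring; certain for noiseless waveforms)
are broken with a seeded uniform jitter bounded by a quarter of the
smallest nonzero value gap — reproducible, and too small to reorder
non-tied values.

Phase resolution equals the phase step: a 4 h lattice bounds single-probe
phase error by 2 h.  Quantities that *difference* two phases (SS/AS lag)
double that bound, so pair-level analyses in the tests and examples use
`phase_step_h=2.0`.  Period mismatch (a true 21 h rhythm scored against the
20/24/28 h lattice) adds phase bias of a few hours; phase-critical
comparisons are most reliable for rhythms near 24 h.

### COSOPT cosine grid with permutation surrogates

For each trial period on the grid (20 to 28 h, step `cosopt_step_h` =
0.2 h, about 1% period resolution), fit y ≈ a + b cos + c sin by least
squares; the per-period bases are centred, orthonormalized and cached, so a
fit is one matrix product.  The statistic is the captured variance fraction
1 − RSS/TSS at the best period; amplitude √(b²+c²); phase the fitted peak
ZT mod 24.  Significance is the add-one-corrected empirical tail over
`n_surrogates` (default 1000; ≥ 99 enforced) seeded random permutations of
the series refit on the same grid — an exact-level test whose white-noise
rejection at p < 0.05 with 199 surrogates is 10/200 = 0.05 by construction.
The original COSOPT significance recipe ("pMMC-β") is under-specified in
the literature; this permutation construction preserves its cosine-fit
ranking while giving a defensible null.

### Consensus

A method votes *rhythmic* if p < α (default 0.05, raw per-probe — no
cross-probe correction, matching the field convention for these designs)
and its reported period lies in the band.  A probe is *circadian* with ≥ 2
votes (`min_methods=2`).  A not-analyzable method counts as a non-vote and
never blocks the other two.  The consensus period is COSOPT's and the
phase JTK's, reported even when that single method was sub-threshold.
Circadian phases are binned into six 4 h bins centred at ZT0…ZT20; a phase
on a boundary (centre + 2 h) goes to the later bin.  Printed percentages
round half-up to 1 decimal.

## Randomness and reproducibility

One pipeline seed fans out per probe through content-keyed streams
(`SeedSequence(entropy=(seed, crc32(probe_id:direction:stream)))`), so
detector surrogates, JTK jitter and simulated probes are identical no
matter how many probes are processed or in what order.

## Sense/antisense pairs

Pairs are gene models whose SS and AS probes both pass the expression
filter.  Spearman ρ (average ranks) classifies a pair positive iff
ρ > 0.56, negative iff ρ < −0.56, else uncorrelated — the bound is adopted
as a fixed constant for 12-point series (its originating α is not stated
anywhere authoritative; at n = 12 it corresponds to roughly the 5% two-sided
point, and white-noise pairs exceed |ρ| = 0.56 about 6% of the time).
The phase lag of a doubly circadian pair is the unsigned circular
difference of the JTK phases, in [0, 12] h.

## Ortholog phase comparison

A cluster is circadian in a dataset when ≥ 1 mapped probe is (clusters with
several probes count once); its phase is the **circular median**: the value
on a 0.1 h grid minimizing summed circular distance to the member phases,
lowest grid value on ties.  A plain median is wrong on the circle (ZT2 and
ZT22 must summarize near ZT0, not ZT12).  Tie plateaus do occur (the
minimizing set can be an arc), so the lowest-value rule is a convention;
it makes the median rotation-equivariant only up to tie choice.

Phase pairs of clusters circadian in both datasets are compared after
circular difference minimization: the first phase is shifted by −24, 0 or
+24 h so |a′ − b| ≤ 12 (exactly-12 ties keep the phase unshifted), then the
minimized pair is placed in a canonical frame by shifting both coordinates
by the same multiple of 24 h so the pair midpoint lies in [0, 24).  The
canonical frame matters: correlating the raw (a′, b) pairs is not symmetric
under swapping the datasets (only one member is unwrapped), while the
midpoint frame is, except on measure-zero 12 h ties.  r² is the squared
Pearson correlation of these pairs, reported only for ≥ 3 pairs.

## Category phases and enrichment

Per functional category (one category per probe, ~30 in a typical
annotation), circadian probes are summarized by circular median ± MAD
(MAD = median circular distance to the median, so at least half the phases
lie within one MAD).  Bimodality — biologically, two co-regulated subsets
such as dawn- and dusk-peaking signalling components — is declared when the
2 h circular phase histogram shows exactly two occupied arcs separated by
empty gaps ≥ `bimodality_gap_h` (default 8 h) on both sides; the larger
mode is reported first.  A 2 h histogram is used because coarser 4 h bins
cannot separate modes ~11 h apart (two 8 h gaps around 4 h bins force
single-bin modes exactly 12 h apart), defeating the rule's purpose.

Enrichment of a study set against a background is the upper-tail
hypergeometric p per category (unannotated probes pooled as "Unknown"),
Bonferroni-corrected over the categories tested; raw p is reported
alongside.

## The synthetic generator

`simulate_dataset` emulates the statistical structure of a two-channel
circadian oligoarray experiment, with planted per-probe truth:

| parameter | default | what it emulates |
|---|---|---|
| design | 12 × 4 h, 2 replicates | constant-light harvest series |
| expressed fraction | 0.70 (SS), 0.10 (AS) | probes passing the ≥10/12 filter |
| rhythmic fraction of expressed | 0.32 (SS), 0.22 (AS) | consensus-circadian fractions |
| period | truncated normal, mean 24.5 h, sd 2.5 h on [20, 28] | circadian period spread |
| phase bin weights | SS peaked at ZT12 (0.29), AS at ZT4 (0.28) | day-peaked SS, dawn-peaked AS |
| amplitude / noise sd | 1.0 / (1/3) → SNR 3 | clearly rhythmic transcripts |
| flag dropout | 0.05 | sporadic below-background calls |
| pair modes (same/anti/lag/indep/arrhythmic) | 0.20/0.10/0.10/0.10/0.50 | SS/AS coupling spectrum |

Rhythmic probes are amplitude·cos(2π(t−φ)/τ) plus i.i.d. Gaussian noise per
replicate on the normalized scale (no published noise characterization
exists for these arrays; Gaussian-on-z-scale is the neutral choice);
arrhythmic probes are pure noise.  Periods are drawn by rejection from the
truncated normal, so the realized moments are those of the truncated
distribution (mean ≈ 24.3 h, sd ≈ 1.9 h), which the generator tests assert
against the scipy truncated-normal oracle.  Phases draw a 4 h bin by weight
then uniform within the bin.  When the sense partner is rhythmic the drawn
pair mode drives the AS rhythm (same phase, +12 h, +`lag_h`, independent
rhythm, or none); an AS whose sense partner is arrhythmic cannot be coupled
and is independently rhythmic with the AS rhythmic fraction.  Optionally
(`category_phase_concentration`), phases concentrate around evenly spaced
per-category base phases instead of the bin weights, for testing category
summaries.

What the generator does **not** emulate: dye bias and spatial artifacts,
non-Gaussian heavy-tailed noise, correlated noise across time points,
probe cross-hybridization in a polyploid background, non-sinusoidal
(spiky/asymmetric) waveforms, and amplitude heterogeneity.  Passing the
recovery tests therefore shows the pipeline is correct and calibrated under
its own model assumptions — not that real arrays achieve these error rates.
An "independent rhythm" AS has no defined correlation class (its phase can
land anywhere relative to the sense partner), so classification accuracy is
assessed on same-phase / antiphase / arrhythmic-AS modes; independent pairs
appear in the confusion table only.

## Problem sizes used in the tests

Null calibration uses 2,000 white-noise series (199 COSOPT surrogates);
exact-null oracles use full enumeration at n ≤ 8 and 10,000 permutations ×
50 series; recovery experiments use 1,000-probe cohorts at SNR 3 with 199
surrogates; the generator-marginal checks use 6,000 probes.  These sizes
give Monte-Carlo error comfortably inside the asserted tolerances while
keeping the whole suite around ten seconds.

## Known limitations

* Exact JTK nulls assume tie-free data; the seeded jitter makes that true
  but adds an O(gap/4) perturbation to tau.
* The Fisher band rule can only ever accept the 24 h line for the 12 × 4 h
  design; rhythms at 21 or 27 h rely on COSOPT and JTK for their votes.
* COSOPT period estimates at the band edges (20, 28 h) are truncated by the
  grid, biasing period summaries of populations with wide period spread.
* The 0.56 Spearman bound is fixed for n = 12; use
  `classify_pair(..., threshold=...)` with a recomputed critical value for
  other designs.
* r² compares phases linearly after unwrapping; widely dispersed phase
  pairs (near-uniform differences) make it unstable, which is why it is
  suppressed below 3 pairs.
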