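# Methods

## The assay model

A solid-state (glass nanopipette) nanopore immersed in a high-salt
measurement buffer passes a steady open-pore ionic current under bias. A DNA
molecule translocating the pore transiently excludes ions and produces a
current blockade; its depth grows with fragment size, so a mixture of a
short cfDNA-like target (~150 bp), a 1 kbp marker and ~10 kbp genomic DNA
produces three resolvable populations on the blockage-amplitude axis.

Capture is modelled as diffusion-limited: each species s arrives as an
independent homogeneous Poisson process with rate

    lambda_s = k_capture * C_s        [events/s],

proportional to concentration C_s and independent of fragment length. This
single assumption carries the whole quantification: with a marker spiked at
known C_M, the target concentration is C_T = C_M * f_T / f_M, and the
qualification metric is %cfDNA = 100 * f_T / (f_T + f_gDNA), where f_s are
per-species event frequencies. Frequencies — counts divided by the
*effective* (unclogged) recording duration — rather than raw counts make
both metrics invariant to data loss from timed pore clogging; this
invariance is tested explicitly (rescaling all frequencies by any positive
constant leaves C_T unchanged, and a simulated 300 s clog leaves the
recovered concentration unbiased).

## Pore geometry

The pipette is a truncated cone whose base is pinned at the capillary bore
(0.5 mm inner diameter for the quartz stock modelled here), in series with
the single-sided access resistance of the tip:

    G = [ 4L / (sigma·pi·d_tip·d_base) + 1 / (sigma·d_tip) ]^-1 .

Exactly one of {half-cone angle, taper length} is specified; the other is
derived through the bore. The diameter of a fabricated pore is estimated by
inverting this model at the measured open-pore conductance (IV slope) with a
bracketed Brent search over d_tip in [0.1 nm, 10 µm]; the forward/inverse
round trip is exact to < 1e-6 nm over the working range. Published
treatments of pipette conductance add terms (surface conduction, double
layer); this package deliberately uses the minimal cone + access form
because it is monotone, invertible and sufficient for diameter bookkeeping.
No default buffer conductivity is shipped: sigma is a required config input,
since the true value for a specific buffer lot is an experimental quantity.

Pore-size dependence of the signal is captured by one scale factor
(d_ref/d_tip)^exponent applied to mean blockade amplitudes, with exponent 2
(cross-sectional exclusion) by default and configurable. Wider pores give
proportionally shallower relative blockades, which reproduces the observed
shrinkage of amplitude distributions with increasing diameter without
asserting a particular electrokinetic model.

## Synthetic data: what it emulates, what it does not

The simulator reproduces the statistical structure of a recording —
Poisson arrivals per species, Gaussian amplitude populations (truncated at
zero), log-normal dwells, white baseline noise, a 4-pole Bessel-like
low-pass at the acquisition filter cutoff (defaults: 100 kHz sampling, 5 kHz
cutoff), and clogs as depressed plateaus with no captures. Defaults:

| parameter | default | why |
|---|---|---|
| capture rate constant | 0.02 events/s/pM | gives ~3.6k marker events in a 30-min, 100 pM measurement — enough for stable mixture fits at desk scale |
| amplitude means (target/marker/gDNA) | 60 / 150 / 300 pA at d_ref = 10 nm | synthetic fixtures; well separated relative to their sds across the 6–19 nm pore range after (10/d)^2 scaling |
| amplitude sds | 5 / 9 / 15 pA | keeps >2.5 sd separation even at 18.9 nm |
| dwell log-normals | medians 0.2 / 0.8 / 4 ms | ordered by length; longer than the ~70 µs filter rise time |
| open-pore current / noise sd | 5000 / 8 pA | plausible for ~10 nm pores under a few hundred mV in high salt |

No published amplitude, dwell or rate statistics exist for this assay's
exact conditions, so these magnitudes are package fixtures, not measured
constants. Consequently, passing tests demonstrate that the *pipeline*
recovers what the generator injects under realistic counting statistics;
they do not certify hardware-level effects the generator omits: folded or
partial translocations, 1/f noise, electrode drift, pore-to-pore amplitude
miscalibration beyond the diameter scaling, and co-capture beyond simple
pulse summation. The surrogate %CV values are therefore driven by Poisson
counting and mixture-assignment noise only and sit well below the bounds
physical recordings meet.

## Event detection

The baseline is a two-pass robust estimate: candidate event samples (5 MAD
below the global median) are masked, a centred running median (default
window 2001 samples) is taken over the rest, and the noise sd is 1.4826x the
MAD of event-free residuals (machine-epsilon floor, flagged, for noiseless
traces). Detection is a hysteresis threshold: open below baseline −
k_sigma·sd (default k = 5), close above baseline − 1·sd; amplitude is
baseline minus the minimum sample in the event — more robust for short,
filter-attenuated pulses than the mean blocked level. Events shorter than
min_dwell (default 100 µs, ≈ two filter rise times at 5 kHz) are discarded.
Any sub-baseline excursion longer than max_block_duration (default 1 s,
orders of magnitude above any dwell) is reclassified as a clog, excluded
from events and subtracted from the effective duration. On noiseless
rectangular-pulse traces the detector is an exact oracle match in count,
amplitude and start sample; raising k_sigma can only reduce the count.

The renderer's digital Bessel filter shows a small step overshoot that grows
with the cutoff-to-sampling ratio (≈1% at the default 0.05 ratio); tests of
full-depth rendering therefore run at the default acquisition regime.

## Mixture fitting

EM runs on the raw 1-D amplitude sample (histograms, Freedman–Diaconis by
default, are for reporting only — the fit must not depend on binning), with
10 k-means++-seeded restarts, convergence tolerance 1e-6, and a 1e-3 pA sd
floor below which a component counts as degenerate and the fit restarts with
a perturbed seed. Fits are bit-reproducible given (data, K, seed). Species
counts are soft counts — responsibilities summed per component, i.e. the
area under each fitted Gaussian — which conserve the total event count
exactly and degrade gracefully under overlap, unlike hard assignment.

Mixture order: the standard mock is fitted with K = 3 fixed (three species
by construction); for unknown samples K is selected by BIC over K = 1..4
(ties toward smaller K), since real plasma extracts can lack the gDNA
population entirely — a two-component fit then yields f_gDNA = 0 and
%cfDNA = 100 by construction. Labeling is deterministic: for K = 3,
ascending mean amplitude maps to target/marker/gDNA; for K < 3 a marker
amplitude hint anchors the scale (nearest component = marker, below =
target, above = gDNA); for K > 3 the surplus smallest-weight components are
left unassigned with a warning. K = 1 with no hint is an error rather than a
guess.

## Uncertainty analysis

Each pore records in 5-min chunks for 90 min; for every combination of
P ∈ {1..4} pores and T ∈ {5,10,...,30} min, n = 3 replicates are assembled
as *disjoint* blocks of consecutive chunks (T/5 chunks from each of the
first P pores per replicate) — modelling independent physical repeat
measurements, not bootstrap resamples (a seeded shuffle mode exists for
sensitivity checks). Chunk windows are half-open, so a boundary event
belongs to the later chunk. Each pooled replicate runs the full mixture +
quantification pipeline; the cell statistic is %CV = 100·sd/mean over
replicates for both metrics, and a failed fit marks a cell missing rather
than aborting the grid. CV decreases along the duration axis and with pore
count on seed average, as expected from event-count scaling of the
estimator variance. (Pooling across pores assumes their diameters are close
enough that the per-species amplitude populations remain unimodal; the grid
surrogate uses diameters within 9.7 ± 0.8 nm. One body of text describing
this design states the pore-count trend in both directions in different
sections; the decreasing trend follows from counting statistics and is the
one implemented and tested.)

## Unit conversions

pM ↔ ng/mL uses an average dsDNA base-pair mass of 650 g/mol/bp
(configurable): ng/mL = pM · length_bp · 650 · 1e-6. Plasma back-calculation
multiplies the measured molar concentration by the measurement dilution
(default 40×) and the extraction concentration factor (default 55 µL eluate
from 1 mL plasma), assuming 100% extraction recovery by default
(configurable). With these defaults the 10–200 pM assay window corresponds
to ≈2.1–43 ng/mL of plasma cfDNA, matching the intended working range.

## Problem sizes and numerical choices

Desk-scale surrogates use event-level simulation (the Poisson stream and
amplitude draws) rather than rendering multi-hour 100 kHz traces; the trace
path (render → detect) is validated separately on short recordings and
agrees with the event path within 5% on frequencies for dwells ≥ 2 filter
rise times. Acceptance surrogates use 30-minute streams (~11.5k events per
measurement), 4 pores × 90 min for the grid (~138k events), and n = 3
replicates throughout — matching the assay's own measurement design.
Degenerate inputs are defined errors, not silent results: zero marker
frequency (marker not detected), zero effective duration, zero target and
gDNA frequency, insufficient chunks for a pooling combination, and
un-bracketable conductances all raise typed exceptions.

## Out of scope

Wet-lab plasma processing, capillary-electrophoresis electropherogram
analysis, physical pore fabrication recipes, amplifier vendor file formats
(traces are accepted as delimited text or `.npz`; patch-clamp binary formats
are not parsed), multi-level (folded-DNA) sub-event segmentation, and 2-D
amplitude × dwell clustering.
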