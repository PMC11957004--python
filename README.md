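# poreqc

Quality control of cell-free DNA (cfDNA) samples with a solid-state nanopore
sensor, as a tested software pipeline. Sequencing workflows need two numbers
before library preparation: how much cfDNA a plasma extract contains, and how
much of the DNA is actually short cfDNA rather than high-molecular-weight
(HMW) genomic contamination from leukocyte lysis. A glass nanopore can read
both off a single ionic-current recording, label-free: every DNA molecule
that translocates the pore produces a transient current blockade whose depth
depends on fragment size, so the species in the sample separate on the
blockage-amplitude axis.

`poreqc` implements the full assay:

1. **Simulate** (or load) ionic current–time traces for a mix of a short
   cfDNA-like target (~150 bp), a 1 kbp internal marker spiked at known
   concentration C_M, and a ~10 kbp HMW gDNA contaminant. In the
   diffusion-limited capture regime each species arrives as a Poisson process
   with rate proportional to its concentration and independent of its length.
2. **Detect** translocation events with a robust running-median baseline and
   a hysteresis threshold (open at k·σ below baseline, close at 1·σ);
   prolonged blockades are flagged as clogs and removed from the effective
   recording duration.
3. **Fit** a multi-Gaussian mixture to the raw blockage amplitudes by EM
   (order fixed at 3 for mocks, or BIC-selected) and read each species'
   expected event count as the soft count — the area under its Gaussian.
4. **Quantify** with the internal-calibrator relations

       C_T = C_M · f_T / f_M
       %cfDNA = 100 · f_T / (f_T + f_gDNA)

   where f_s are per-species event *frequencies* (soft count / effective
   duration), which makes both metrics invariant to pore clogging. Optional
   unit conversions map the molar result back to ng/mL of original plasma
   through the dilution and extraction chain.
5. **Analyze uncertainty** by pooling event data across {1..4 pores} ×
   {5..30 min} acquisition windows and reporting the %CV heatmap of both
   metrics over disjoint triplicate pooled measurements.

A pore-geometry module models the nanopipette as a truncated cone in series
with the tip access resistance, estimates the pore diameter from open-pore
conductance (IV slope), and supplies the (d_ref/d_tip)² amplitude scaling the
simulator uses to emulate different pore sizes.

## Worked example

`examples/03_mock_quantification.py` simulates a 30-minute event stream of
the standard mock — 150 bp target at 120 pM, 1 kbp marker and 10 kbp gDNA at
100 pM each — and runs the full mixture + quantification pipeline:

```
events: 11458 over 1800 s

fitted mixture components:
   target: mean   60.1 pA, sd   5.1 pA, soft count  4234.0
   marker: mean  149.9 pA, sd   8.9 pA, soft count  3567.0
     gdna: mean  300.0 pA, sd  14.9 pA, soft count  3657.0

frequencies: f_T=2.352, f_M=1.982, f_gDNA=2.032 /s
C_T      =   118.7 pM   (true 120 pM)
%target  =    53.7 %    (true 54.5 %)
plasma equivalent = 25.46 ng/mL
```

The three Gaussians recover the injected populations; the frequency ratio
f_T/f_M ≈ 1.19 times the 100 pM marker concentration gives the target
concentration within Poisson counting noise, and %target is close to the
analytic 100·120/220 = 54.5% of the mock composition. The other examples
cover pore-diameter estimation (`01`), trace rendering and event detection
(`02`), and the 24-combination uncertainty grid (`04`).

A thin CLI wraps the same library calls:

```sh
poreqc simulate --config run.yaml --out out/
poreqc qc out/trace.npz --out qc/          # detect -> fit -> quantify
poreqc uncertainty pore*.tsv --out grid    # %CV pooling grid
```

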