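# Methods

`nphys` quantifies four kinds of neuronal-physiology data — current-clamp
step recordings, two-photon somatic calcium fluorescence, exon junction
counts, and rodent behavior tables — and ties them together with
nonparametric group statistics. Every quantification stage has a paired
synthetic generator with exact ground truth, so the whole chain is
verifiable without any recorded data. This note documents the models,
the conventions chosen where the procedures were genuinely open, and the
limits of what the synthetic tests demonstrate.

## Current-clamp feature extraction (`ephys_features`)

**Protocols.** Two step families are analysed: a subthreshold family
(six 500-ms steps of 10 pA starting at −30 pA) for passive properties,
and an excitability family (500-ms steps, 0–400 pA in 20-pA increments)
for firing properties. Sweeps are uniform grids at ≥ 5 kHz (10 or
20 kHz typical).

**Passive properties.**

- *RMP* — mean voltage over the pre-stimulus window (≥ 50 ms required).
- *Input resistance* — OLS slope of steady-state ΔV (mean over the last
  100 ms of the step, minus the sweep's own RMP) against injected
  current, over AP-free subthreshold sweeps (≥ 3 required). The slope in
  mV/pA equals GΩ and is reported in MΩ. The 100-ms steady-state window
  assumes τ ≲ 35 ms, so ≥ 3τ have elapsed before it starts.
- *Membrane time constant* — per hyperpolarizing sweep, a three-parameter
  exponential `V(t) = V_ss + (V0 − V_ss)·exp(−(t−onset)/τ)` is fit over
  the first min(200 ms, step duration) after onset (trust-region least
  squares, τ bounded to (0.1, 200) ms); failed or boundary fits are
  dropped and the mean over surviving sweeps is returned. Only
  hyperpolarizing steps are used because depolarizing steps can engage
  voltage-gated conductances. Averaging across sweeps (rather than
  fitting one sweep) was an open choice; it reduces the estimator
  variance at no cost.
- *Capacitance* — Cm = τ/Rin (ms/MΩ = nF), reported in pF. The identity
  `Cm·Rin = τ` holds to machine precision by construction.

**Action potentials.** An AP is a local maximum above −10 mV *or* at
least 70 mV above the pre-stimulus baseline, with a 1-ms minimum peak
separation (FS cells at ~160 Hz leave ≥ 6 ms between peaks, so 1 ms only
deduplicates digitization doublets). Per AP:

- *threshold* — the sample where dV/dt first exceeds 5% of that AP's
  maximal upstroke dV/dt, searched up to 5 ms before the peak; dV/dt is
  computed by central differences on the raw grid at ≥ 10 kHz, with
  3-point smoothing below 10 kHz. If dV/dt never drops below the 5%
  level inside the back-window the threshold is undefined and the event
  is flagged rather than guessed.
- *fAHP nadir* — minimum voltage between the peak and the next AP's
  threshold (or peak + 10 ms).
- *amplitude* — peak minus nadir.
- *half-width* — time between the two linear-interpolated crossings of
  the level midway between peak and threshold voltage. The reference
  level for "half-height" was an open convention (amplitude is defined
  from the nadir, but a nadir-based half-height would sit far below the
  spike base); midpoint-of-(peak, threshold) is the convention used by
  common ephys feature extractors and is adopted here.
- *slopes* — max dV/dt on (threshold, peak], min dV/dt on (peak, nadir].

**Excitability.** The input–output curve maps step amplitude to AP
count; rheobase is the smallest amplitude with ≥ 1 AP, reported on the
20-pA protocol grid without interpolation. Latency to the first AP,
first inter-spike interval, and fAHP (threshold voltage minus post-peak
minimum, averaged over the first five APs, flagged when fewer) are
measured on the sweep at rheobase + 100 pA and left absent when that
amplitude exceeds 400 pA or the sweep holds fewer than two APs.

**Classification and QC.** Fast-spiking interneurons: τ < 15 ms *and*
more than 35 APs at the 400-pA step (> 70 Hz over 500 ms); both
inequalities strict. Cells are excluded, with itemized reasons, when
RMP ≥ −55 mV, access resistance ≥ 25 MΩ (unless its drift across the
recording stays under 30%), input resistance ≥ 1000 MΩ, or at most one
AP is evoked over the whole 0–400 pA range. Voltages are reported
uncorrected for the liquid junction potential.

## LIF ground-truth generator (`ephys_synth`)

Subthreshold dynamics `τ dV/dt = −(V − E_L) + R·I(t)` are advanced with
the exact exponential update, so the analytic step response holds to
1e-9 mV and closed-form expectations (ΔV_ss = R·I, rheobase
I = (V_th − E_L)/R) are exact test oracles. Threshold crossings are
detected with a 1e-9 mV tolerance: at the boundary current, where the
steady state equals V_th exactly, the trajectory approaches the
threshold asymptotically and would otherwise never cross in float
arithmetic; the tolerance makes the closed-form rheobase attainable
within a 500-ms step for τ ≤ ~20 ms. Spikes are rendered as a
stereotyped waveform — 1-ms linear rise to +30 mV, 1-ms fall to 5 mV
below V_reset, then a clamp at V_reset for the refractory period —
chosen so both AP-detection criteria are met unambiguously. Noise is
white Gaussian *recording* noise added to the sampled trace; it does not
feed back into the dynamics, so the logged spike times are exact at any
noise level. This is the main idealization: real noise perturbs spike
timing near rheobase, and real neurons adapt, neither of which the
generator emulates. Passing the recovery tests therefore demonstrates
correctness of the extraction arithmetic, not robustness to biological
variability.

## Calcium quantification (`calcium_quant`)

Per ROI, fluorescence is the mean pixel intensity inside the ROI minus
the mean of a background mask, sampled at ~1.7 Hz (default,
overridable). ΔF/F₀ uses F₀ = the minimum over all contiguous 3.5-s
window means — the quietest stretch of the recording; the ΔF/F₀ mean
inside that window is exactly zero by construction. Frames flagged by a
motion/struggle exclusion mask are excised before any computation.

The event threshold is 3× the baseline noise s.d. of ΔF/F₀. The noise
s.d. is estimated robustly as 1.4826 × the median absolute deviation of
ΔF/F₀ over the whole recording: transients occupy a small fraction of
frames, so the MAD tracks the baseline noise, whereas an s.d. taken
from the ~6 frames of the 3.5-s window is far too unstable to threshold
against (its sampling error produces several spurious events per
trace). The estimate is floored at 1e-4 so noiseless synthetic traces
remain finite. Events are maximal contiguous supra-threshold segments
of ≥ 2 frames (single-frame crossings at 0.59-s frame intervals are
treated as noise, since GCaMP6s decay far outlasts one frame); duration
is the segment width plus one frame interval, i.e. width at threshold —
"full width" was an open convention and width-at-threshold is adopted.

Per-cell statistics: AUC = signed trapezoidal integral of ΔF/F₀ per
complete 35-s window, averaged over windows (partial tails dropped;
shorter traces integrated whole and flagged); amplitude = mean event
peak; duration = mean event width; frequency = events per minute.
ΔF/F₀ and everything downstream are invariant to rescaling the raw
fluorescence but *not* to additive offsets, which is why background
subtraction happens upstream.

## Calcium generator (`calcium_synth`)

Homogeneous Poisson event times (default 1.0 events/min over 105 s) are
convolved with a one-frame rise + 1.5-s exponential-decay kernel
(GCaMP6s-like) and rendered additively on a multiplicative baseline,
`F = F_b·(1 + Σ kernels) + N(0, σ)`, so the generator's true ΔF/F₀
equals the injected kernel sum exactly. The event amplitude parameter is
expressed in multiples of the ΔF/F₀ noise s.d. (taken literally as the
ΔF/F₀ peak when noise is zero); the default 8σ is a clearly
supra-threshold transient. Optional rendering places non-overlapping
disk ROIs in an image stack with per-pixel noise to exercise the
extraction path. Not emulated: correlated network activity, motion
artifacts, neuropil contamination, indicator saturation — recovery
results bound arithmetic correctness, not segmentation or registration
quality.

## Percent spliced-in (`splicing_psi`)

Ψ = I_eff/(I_eff + S), with I_eff the mean of the available inclusion
junction counts (one or two) and S the skipping count; undefined below
10 effective reads, where the ratio is sampling noise. Differential
inclusion between two groups pools counts per group into a 2×2 table and
applies the two-sided Fisher exact test with the probability-mass rule
(sum over tables no more probable than observed — exact on asymmetric
tables, unlike doubling), followed by Benjamini–Hochberg adjustment
across exons. This Fisher/BH route is a deliberately simple,
transparent surrogate for full junction-count pipelines; it ignores
overdispersion between biological replicates and is exact only
conditional on the pooled margins. RT-PCR band intensities convert to Ψ
as inc/(inc+skip), optionally dividing each band by its amplicon length
first (molar correction).

## Statistics (`stats`)

- *Mann-Whitney U*: U from midrank sums; exact two-sided p (full
  enumeration) when the combined n ≤ 16 without ties — enumeration cost
  2¹⁶ is trivial and the small per-group cell counts of slice
  experiments sit in this regime — otherwise the normal approximation
  with tie and continuity corrections. The exact test is conservative
  under discreteness: at n = 5+5 the attainable rejection rate at
  α = 0.05 is ≈ 0.032.
- *Two-way mixed ANOVA* for input–output curves: genotype as the
  between-subject factor, current step as the repeated measure; cells
  missing any step are dropped listwise; the between-factor F is
  reported on (1, n−2) degrees of freedom with no sphericity
  correction, matching the uncorrected df convention of slice-physiology
  reports. Implemented on pingouin's `mixed_anova`; tests verify it
  against a manual sums-of-squares partition.
- *BH FDR*: step-up with monotonicity enforcement, order-preserving.
- *describe*: mean ± SEM (sample s.d./√n), SEM undefined at n = 1.

## Behavior (`behavior_metrics`)

Y-maze alternation counts overlapping triads of three distinct
consecutive arm entries over (entries − 2); the sequence is taken
verbatim (immediate re-entries count as entries). The chance level is
100·(n−1)(n−2)/n² — for three arms the product 2/3 × 1/3 ≈ 22% — and a
Monte-Carlo sampler of the same uniform-entry model is included as a
cross-check. EPM percentages divide arm dwell times by the 300-s trial.
Gait metrics are means of labeled paw-pair distances; the label mapping
(A: left fore, B: left hind, C: right fore, D: right hind) is fixed so
that AB/CD are ipsilateral fore–hind pairs and AC/BD left–right pairs,
the only mapping under which the published formulas (FP-HP =
mean(AB, CD), stance width = mean(AC, BD)) are anatomically coherent.
The alternation coefficient is implemented literally as the AB/BD
distance ratio (undefined at BD = 0).

## Pipeline (`pipeline`, `cli`)

`RunConfig` carries every threshold, defaulting to the study constants
(−10 mV / 70 mV AP rule, 3σ events, 3.5-s baseline, 35-s AUC window,
1.7 Hz, 15 ms / 35 AP FS classifier, −55 mV / 25 MΩ / 1000 MΩ QC), one
master seed (per-cell substreams are spawned deterministically), and
round-trips losslessly through YAML. Runs are bit-reproducible for a
fixed config; reports embed the config hash (output paths excluded from
the hash) and list every QC exclusion with its reasons. Missing optional
metrics are rendered `NA`, never dropped.

## Verification experiment sizes

The experiments behind `scripts/acceptance.py` and the end-to-end test
suite use: 100 seeded LIF sweep sets for Rin/τ recovery (reference cell
200 MΩ / 15 ms / 0.3 mV noise) and 100 noise-free randomized cells
(R ∈ 120–280 MΩ, τ ∈ 8–18 ms, V_th ∈ −53…−47 mV; τ ≤ 18 ms keeps the
boundary-current threshold crossing inside the 500-ms step, so the
closed-form grid rheobase is exact truth for every draw); 200 synthetic
calcium cells at 1.0 events/min, 8σ, 105 s; 10⁴ null simulations for
Mann-Whitney calibration; 100 runs × 100 cells/group for the
interneuron-specific contrast; and 200 binomial replicates at Ψ 0.65 vs
0.14 with 200 reads/group. At 200 reads/group a single replicate's ΔΨ
estimate has s.d. ≈ 0.042, so individual replicates scatter beyond
±0.05 about a quarter of the time even for a perfect estimator; the
recovery checks therefore assert unbiasedness of the mean estimate and
per-replicate FDR significance, and the per-replicate ±0.05 count is
reported alongside for transparency.

## Known limitations

- The LIF and kernel-convolution generators are idealizations; passing
  recovery tests does not establish performance on real recordings with
  drift, adaptation, bursting, or motion.
- The tau fit assumes a single-exponential passive response; real cells
  with dendritic filtering show multi-exponential charging.
- The Fisher/BH differential-splicing route ignores between-replicate
  overdispersion.
- ABF/NWB ingestion, voltage-clamp analysis, synaptic event detection,
  ROI segmentation, spike inference, and video tracking are out of
  scope; masks, traces, and event tables are inputs.
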