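# nphys

Quantification pipeline for neuronal-physiology experiments that probe
how a neuron-type-specific microexon shapes interneuron excitability:
intrinsic-excitability features from current-clamp step recordings,
somatic calcium-transient statistics from two-photon ROI fluorescence,
exon percent-spliced-in (Ψ) from junction counts and RT-PCR bands,
closed-form behavior metrics, and the nonparametric group statistics
that tie them together. Every quantification stage is paired with a
synthetic-data generator carrying exact ground truth, so the entire
chain is testable without any recorded data.

It is written for slice electrophysiologists, imaging labs, and RNA
folks who want the quantification arithmetic of such a study as an
auditable, reusable library rather than a pile of one-off scripts.

## The quantities it computes

**Electrophysiology** (500-ms current steps): resting membrane
potential; input resistance R_in from the OLS slope of the steady-state
V–I relation over subthreshold steps; membrane time constant τ from
exponential fits to the hyperpolarizing-step onset; capacitance
C_m = τ/R_in. Action potentials are maxima above −10 mV or ≥ 70 mV over
baseline; per AP the threshold (first crossing of 5% of the maximal
dV/dt), amplitude (peak − fAHP nadir), half-width, and maximal
rise/decay slopes. From the 0–400 pA family: the input–output curve,
rheobase, latency / first ISI / fAHP at rheobase + 100 pA. Cells with
τ < 15 ms and > 35 APs at 400 pA (> 70 Hz) are classed fast-spiking;
QC excludes cells with RMP ≥ −55 mV, access resistance ≥ 25 MΩ, input
resistance ≥ 1000 MΩ, or ≤ 1 evoked AP.

**Calcium** (~1.7 Hz ROI traces): ΔF/F₀ with F₀ the minimal-mean 3.5-s
window; events are ≥ 2-frame excursions above 3× the baseline noise
s.d.; per cell the AUC of ΔF/F₀ per 35-s window, mean event amplitude,
mean width, and frequency per minute.

**Splicing**: Ψ = I_eff/(I_eff + S) from inclusion/skipping junction
counts; group differences by two-sided Fisher exact test on pooled
counts with Benjamini–Hochberg FDR; RT-PCR band ratios with optional
molar (amplicon-length) correction.

**Behavior**: Y-maze spontaneous alternation (triads of three distinct
consecutive arms over entries − 2; chance level 100·(n−1)(n−2)/n² ≈ 22%
for three arms), elevated-plus-maze dwell percentages, and gait
footfall distances (FP–HP distance, step length, stance width,
alternation coefficient).

**Statistics**: Mann-Whitney U (exact by enumeration for small tie-free
samples), two-way mixed ANOVA for input–output curves (between-subject
genotype × repeated current step), BH FDR, mean ± SEM.

See `docs/methods.md` for models, conventions, and limitations.

## Worked example

Simulate a ground-truth cell (leaky integrate-and-fire, R = 200 MΩ,
τ = 12 ms, 0.3 mV recording noise) and run the full extraction chain:

```python
from nphys.ephys_synth import LifParams, simulate_protocol_set
from nphys.ephys_features import load_sweep_set, summarize_cell

params = LifParams(r_in=200.0, tau=12.0, noise_sigma=0.3, seed=7)
manifest = simulate_protocol_set(params, "demo", cell_id="cell01")
meta, sweeps = load_sweep_set(manifest)
print(summarize_cell(meta, sweeps).as_row())
```

prints (abridged):

```
rmp_mv                 = -70.02   # generator E_L = -70
input_resistance_mohm  = 199.67   # truth 200
tau_ms                 = 12.46    # truth 12
capacitance_pf         = 62.42    # tau / R_in
rheobase_pa            = 100.0    # closed form (V_th - E_L)/R = 100 pA
latency_ms             = 9.4      # first AP at rheobase + 100 pA
first_isi_ms           = 10.9
fahp_mv                = 20.05
max_ap_count           = 74       # at 400 pA -> 148 Hz
class_label            = FS       # tau < 15 ms and > 35 APs
qc                     = included
```

The passive properties land within the recording-noise sampling error
of the generator truth, the rheobase equals the closed-form value on
the 20-pA grid, and the cell is classed fast-spiking.

The same round trip exists for calcium (`nphys.calcium_synth` →
`nphys.calcium_quant`), splicing, and behavior; the `nphys` command
line exposes each stage (`nphys ephys simulate|extract`,
`nphys ca simulate|quantify`, `nphys psi`, `nphys behavior`).

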