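# Methods

This note documents the models, numerical conventions and design choices
behind `croaker`, in the package's own terms. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Mother wavelet

The pulse prototype ψ is a compactly supported orthogonal wavelet with a
length-14 conjugate-quadrature filter. The Fejér–Korovkin family was the
design target because its defining goal — maximal frequency localization
of the filter response — matches what the croaker pulse needs: a smooth,
near-symmetric oscillation with one dominant positive lobe and fast decay
on both sides. No installed library ships the family's coefficient
tables, and the family's exact published construction could not be
reproduced with certainty offline, so the package derives its own filter
from the same design goal and documents it as such:

1. valid half-band magnitude responses are parameterized as
   `P(ξ) = 1 + Σ_{k odd ≤ 13} p_k cos kξ` with `Σ p_k = 1`
   (hence `P(0) = 2`, `P(π) = 0`, one vanishing moment) and `P ≥ 0`;
2. the passband energy concentration `∫_{−π/2}^{π/2} P` is maximized — a
   linear program in the seven odd cosine moments;
3. the optimum is spectral-factorized; among the eight root assignments
   of its three off-circle conjugate quadruples the most nearly
   symmetric factor with a positive main lobe is kept;
4. Newton iteration polishes the 14 coefficients onto the
   conjugate-quadrature identities (residuals ≈ 1e-16).

The frozen coefficients live in `croaker.wavelets.FK14_FILTER`;
`scripts/derive_fk14_filter.py` regenerates them (agreement ≈ 3e-9,
limited by the LP grid). They need not agree digit for digit with
Fejér–Korovkin tables distributed by other software; every number the
package reports is computed self-consistently with this ψ. Other
orthogonal filters can be registered in `FAMILY_FILTERS` as a pluggable
hook.

ψ itself is evaluated by the exact dyadic cascade: values at the integers
are the eigenvector of the refinement transition matrix, midpoints follow
from the two-scale relation level by level, so the samples are exact
values on the grid `k/2^level` over the support `[0, 13]`
(`13·2^level + 1` samples, peak-normalized, level 8 by default, valid
range 4–12). The test suite cross-checks against PyWavelets' iterative
cascade on the same filter bank.

## Synthesis conventions

A component `(A, τ, σ)` renders ψ with its support stretched to σ
samples, the extremum aligned to window index `window/2 + τ`, and the
rendered extremum magnitude equal to A exactly. The default window is
1536 samples (32 ms at 48 kHz). Rendering is *continuous* in τ and σ —
ψ is linearly interpolated at fractional positions — because the model
is a continuous dilation; for integer parameters this coincides exactly
with resampling the mother to σ points. Portions falling outside the
window are truncated with a logged warning (never triggered inside the
default search space). Calls are plain sums of components: linear in the
amplitudes, shift-covariant in the delays, bit-deterministic.

The five-component reference parameter set
(`REFERENCE_CALL_COMPONENTS`: A = 0.59/0.52/0.56/0.22/0.44,
τ = 67/12/58/2/−11, σ = 397/635/438/480/702) is the canonical
representative call used as the reference for sensitivity analysis and
the synthetic datasets. With the σ-as-support convention its energy
spectral density peaks at 843.75 Hz (31.25 Hz bins), inside the species'
300–900 Hz band; treating σ as a standard deviation instead would leave
that band by a large factor, which is how the convention was fixed.
Component delays printed alongside the reference set are read as sample
counts: values like 67 and −11 are only plausible as samples given the
±100 search bounds.

## Inversion

`WaveletInversion.fit()` minimizes `J = w₁(1 − r) + w₂·NMSE`
(`w₁ = w₂ = 1` by default; the weighting is configurable because only the
composite form is prescribed). The swarm uses the canonical
constriction parameterization: inertia 0.7298, c₁ = c₂ = 1.49618, fresh
per-dimension uniform gains, velocities clamped to 20% of each bound
range, positions reflecting off the box, Latin-hypercube initialization,
zero initial velocities, lower-index tie-breaking, and a global best that
is non-increasing by construction. The textbook rule with inertia 1.0
and c₁ = c₂ = 2.0 is available through the config but stalls well short
of convergence within the 80-iteration budget on the reference problem,
which is why the constriction values are the default (chosen on a
12-seed benchmark of the reference inversion). Non-finite objective
values demote the particle to +inf with a warning. Fixed seeds give
bit-identical results.

Three strategies are provided:

* **joint** (default) — one swarm over all 3N parameters; the faithful
  single-stage protocol used for the headline reference-call numbers.
* **greedy** — matching-pursuit-style: components fitted one at a time
  against the running residual with proportionally reduced swarms.
* **hybrid** — greedy, two cycles of backfitting (each component re-fit
  against the others' residual, accepted only when the joint objective
  improves), then a joint swarm with half the particles warm-started
  within 3% of the refined estimate (which is itself a particle, so the
  joint stage cannot regress in objective), and a final backfit cycle.
  This is the most reliable estimator for arbitrary unknown calls, where
  a cold joint swarm can settle into a wrong component assignment.

Whether the original procedure fitted components jointly or sequentially
is not documented; joint is the default and the others are explicit
modes. Results report correlation and RMSE recomputed from the returned
specification (never cached swarm scores), with components sorted by
delay (the sum is permutation-invariant). `best_of_seeds` runs one fit
per seed and keeps the lowest objective — the protocol used for the
reference-call quality numbers.

## Bartlett sensitivity

With L = 1 snapshot the normalized Bartlett processor reduces to the
squared cosine between unit-norm, band-limited (50–5000 Hz by default)
magnitude spectra; the multi-snapshot form with a trace-normalized
averaged cross-spectral matrix is retained for L > 1. The printed form of
the processor carries a leading "1 −", which conflicts with its use as a
similarity ("≥ 0.98 indicates similarity"); the similarity reading is
adopted, so B = 1 at a perfect match. Magnitude (not complex) spectra
make B invariant to rigid time shifts of the whole call; delay
sensitivity then arises through inter-component interference, which is
the documented behavior. Sweeps sample 201 grid points over a
parameter's search range, always including the current optimum exactly;
valid intervals are the maximal contiguous region around the optimum
with B ≥ 0.98, endpoints linearly interpolated between grid points.
Raising the threshold can only shrink an interval (asserted).

## Features

Pressure calibration follows the hydrophone's receiving voltage
sensitivity (−164.6 dB re 1 V/µPa, 0 dB gain, 48 kHz by default):
`p = v·10^(−(S+G)/20)`, exactly invertible. SPL₀₋ₚₖ = 20 log₁₀ max |p|.
Pulse detection thresholds local maxima of |p| at `min_height` (6) times
the Gaussian-consistent MAD of the signed record; the minimum peak
separation defaults to 10 ms — large enough that the wavelet's own side
lobes (support ≈ ±8 ms) are never detected as pulses, and comfortably
below the smallest credible IPI of the ≈21 ms regime. Gaps above 100 ms
split trains; per-peak flags mark clipping (≥ 0.99 of full scale, for
normalized records) and overlap. All thresholds are package choices
exposed in `DetectionConfig`; the originating study states only
qualitative exclusion rules. ESD is the one-sided `2|X(f)Δt|²` with the
Nyquist bin un-doubled, dB re 1 µPa²·s/Hz, satisfying Parseval's
identity to 1e-6 relative (asserted on every call of the test); ensemble
summaries give 1/5/50/95/99% percentile curves, a per-bin density map
and the RMS level.

## Trains, variability models and noise

IPI variability is lognormal (positive support, near-log-symmetric
printed quartiles): `µ = ln median`, `σ = ln(q3/q1)/(2·0.6745)`. SPL in
dB is normal: `mean = median`, `sd = (q3 − q1)/1.349`. Both match the
median and the quartile spread exactly; a two-parameter family cannot
also absorb the slight asymmetry of the printed triplets, so the
individual quartiles are reproduced to ≈1e-3 relative, not exactly.
Trains are overlap-added with peak-to-peak spacing `round(IPI·fs/1000)`
samples and each pulse scaled to its SPL target before placement;
detection + IPI extraction recovers the generating intervals within one
sample on clean trains. IPI is measured peak-to-peak (the reference
point is not otherwise defined). Noise degradation is white Gaussian at
a target SNR with powers computed over the pulse-active window by
default (samples above 1% of peak) — the window convention is explicit
because it changes the measured SNR of padded records. The generator is
unbiased by construction: sampled IPIs are placed as drawn, so the
reconstructed-IPI shift reported for the original study's generator is
deliberately not emulated.

## Synthetic datasets

The measured recordings are not public; `generate_dataset` emulates the
dataset's *shape*: 1023 "measured-like" trains with chain composition
{1: 519, 3: 158, 5: 118, 7: 79, 9: 92, 11: 53, 13: 4} ("chain k" read as
a k-pulse train), per-chain reconstructed sets (500 by default), and
SNR-degraded copies (15 and 10 dB) of the measured-like set with
identical per-chain counts. Per-pulse wavelet parameters are drawn
uniformly inside the per-parameter valid intervals and accepted only if
the resulting call reaches B ≥ 0.98 against the reference synthesis.
Because the intervals were derived one parameter at a time, *joint*
draws reach the threshold only ≈5% of the time, so the redraw cap is
400 (the spec-sketched cap of 10 would abort almost surely). Everything
derives from one master seed; manifests are byte-reproducible, and
generating a subset of roles burns the same seed stream so the shared
trains are identical across subsets. These are synthetic stand-ins:
they emulate published summary statistics (quartiles, counts, band), not
sea-state noise, propagation, depth-dependent multipath or behavioral
context — tests passing on them validate the pipeline's internal
consistency, not field performance.

## Similarity validation

Spectrograms are dB-magnitude STFTs clipped to [60, 120] dB, mapped
affinely to [0, 1] (60 → 0, 120 → 1), and bilinearly resized
(224×224 default; desk-scale tests use 64×64). The twin encoder is a
weight-sharing numpy MLP over an average-pooled spectrogram with a
512-dimensional linear embedding by default, hand-derived gradients
(verified against finite differences in the tests) and Adam. Training
follows the stated protocol shape: contrastive loss
`(1−y)d² + y·max(0, m−d)²` on the cosine distance `d = 1 − cos`,
margin 0.3, batch 64, learning rate 1e-5 by default, evaluation every
100 steps, early stopping after 5 stalled evaluations, disjoint 7:3
per-class split, label 0 for same-chain pairs. The encoder is
deliberately compact — enough to separate chain classes of the
synthetic datasets on one CPU; its parameter count is reported, not
asserted, and a ResNet-scale twin is out of scope. Chain-wise
evaluation averages cosine similarity over index-matched pairs and
appends an overall average row.

## Problem sizes and checks

The acceptance script and tests run: the reference-call inversion at the
full protocol (population 1000, 80 iterations, best of seeds derived
from the CLI seed); 15 Bartlett sweeps at 51 grid points; 522 rendered
SPL draws; 97 trains totalling exactly 1157 detected intervals; a
20-trial random-spec recovery study at population 500 with the hybrid
estimator (specs redrawn until amplitude-feasible after peak
normalization, i.e. `max Aᵢ ≤ peak`, so the ground truth is
representable inside the search box — without this the recovery question
is ill-posed for ≈10% of draws); and a two-class (2- versus 9-pulse)
separability run with monotone SNR degradation over {∞, 15, 10} dB.

## Known limitations

* The mother wavelet is this package's own frequency-localization
  construction, not a digit-for-digit Fejér–Korovkin table.
* Valid intervals computed against the synthetic reference call are
  qualitatively, not numerically, comparable to intervals derived from
  private measured recordings.
* The swarm recovers the *waveform*, not necessarily the generating
  parameters: component sets are identifiable only up to permutation and
  near-degenerate configurations; for a minority of random targets the
  optimizer converges reproducibly to a near-miss (r ≈ 0.95) attractor.
* The similarity encoder is a compact MLP twin; absolute cosine values
  are not comparable to results from a deep convolutional twin, only the
  orderings (separability, monotone degradation) are meaningful here.
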