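# croaker

Synthesis, inversion and validation of the pulsed vocalizations of the
brown croaker (*Miichthys miiuy*), a soniferous fish whose low-frequency
calls (energy concentrated around 300–900 Hz) are a key target for passive
acoustic monitoring. High-quality recordings of the species are scarce, so
the package provides a complete reconstruction framework that can
synthesize realistic calls, fit the synthesis model to measured or target
waveforms, quantify how far each model parameter can be perturbed without
losing the species' acoustic signature, and validate reconstructions with
a learned similarity measure — all runnable end to end on synthetic
stand-ins for the (non-public) measured dataset.

## The model

A single pulse is a linear combination of N dilated, delayed wavelet
components,

    S(t) = Σᵢ Aᵢ ψ((t − τᵢ)/σᵢ),     i = 1 … N  (default N = 5),

where ψ is a compactly supported orthogonal wavelet of the
Fejér–Korovkin type (length-14 filter, constructed in-package by
maximizing the passband energy concentration of its magnitude response —
see `docs/methods.md`), Aᵢ ∈ [0, 1] the peak excursion, τᵢ the offset of
the component's extremum from the window midpoint (samples), and σᵢ the
rendered support (samples).

The inverse problem — find {Aᵢ, τᵢ, σᵢ} reproducing a target call — is
solved by particle swarm optimization of the composite objective

    J = (1 − r) + NMSE,   r = Pearson correlation,
                          NMSE = Σ(target − candidate)² / Σ target²,

over the box A ∈ [0, 1], τ ∈ [−100, 100], σ ∈ [10, 1000] (population
1000, 80 iterations by default). Parameter tolerances are mapped with a
normalized Bartlett processor: B(ref, cand) is the squared cosine between
band-limited magnitude spectra (1 at a perfect match), and each
parameter's *valid range* is the interval around its optimum where
B ≥ 0.98. Multipulse "chain" calls are assembled by overlap-adding pulses
at inter-pulse intervals (IPI) and per-pulse zero-to-peak sound pressure
levels (SPL₀₋ₚₖ) drawn from quartile-matched lognormal/normal models
(IPI quartiles 19.75/20.95/22.21 ms; SPL quartiles
154.30/154.99/156.06 dB re 1 µPa). A twin weight-sharing spectrogram
encoder trained with contrastive loss scores cosine similarity between
call sets, e.g. clean versus noise-degraded copies.

## Worked example

```python
import croaker as ck

mother = ck.build_mother_wavelet()                 # fk14-type, level 8
spec = ck.reference_call_spec()                    # 5-component reference call
target = ck.synthesize_call(spec, mother).peak_normalized()
print("ESD peak: %.1f Hz" % ck.esd_peak_frequency(target))

model = ck.WaveletInversion(target, mother=mother,
                            config=ck.PSOConfig(population=300,
                                                max_iterations=40))
res = model.fit(seed=1)
print(res.summary())

curve = ck.sweep_parameter(spec, 1, "delay", ck.SearchBounds(), target,
                           mother=mother)
print("delay-2 valid range (B >= 0.98): %.1f to %.1f samples"
      % curve.valid_interval)
```

prints

```
ESD peak: 843.8 Hz
Wavelet inversion results
============================================================
components:        5
population:        300
iterations run:    40
seed:              1
final objective J: 0.058942
correlation r:     0.980229
RMSE (norm.):      0.033834
------------------------------------------------------------
comp  amplitude      delay     length
   1     0.3616     -54.84      625.5
   2     0.4760     -25.12      642.4
   3     0.4897      -4.47      657.7
   4     0.5554      12.01      633.7
   5     0.7267      62.38      420.9
delay-2 valid range (B >= 0.98): 3.1 to 17.0 samples
```

The ESD peak falls inside the species' 300–900 Hz band. The reduced-size
swarm above already reaches r ≈ 0.98 in seconds; the full protocol
(population 1000, 80 iterations, best of three seeds) reaches r ≈ 0.99
with RMSE ≈ 0.02 on the peak-normalized scale. The recovered component
set differs from the generating one — the sum is what is identified, and
the narrow delay valid-range (±7 samples around the optimum) shows why
delay is the most sensitive parameter.

Command-line equivalents are available via the `croaker` entry point
(`croaker synth-call`, `croaker fit`, `croaker sensitivity`,
`croaker extract`, `croaker synth-train`, `croaker degrade`,
`croaker make-dataset`, `croaker train-siamese`, `croaker evaluate`).

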