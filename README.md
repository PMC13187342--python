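# tuslab

Desk-scale computational pipeline for pulsed transcranial ultrasound
(TUS) neuromodulation of the basal ganglia: personalised acoustic-lens
treatment planning with thermal safety verification, synthetic
deep-brain electrophysiology with planted ground truth, sham-normalised
beta-band spectral analysis, an electrode-artefact model, and the
small-sample statistics of a randomised cross-over design.

## Who this is for

Researchers who want to prototype, teach or stress-test the
computational chain behind low-intensity TUS experiments in Parkinson's
disease — where 130 Hz-pulsed ultrasound delivered to the globus
pallidus internus (GPi) through a phase-correcting lens is evaluated
against subthalamic (STN) beta-band local field potentials — without
access to patient imaging or recordings. Everything runs in minutes on
one CPU from synthetic inputs whose ground truth is known exactly.

## The models at the core

**Lens planning (time reversal).** A point source at the deep target r₀
is propagated backward through the labelled head model by solving the
first-order linear acoustics equations with a k-space-corrected
pseudospectral scheme; on a receiver plane outside the head the complex
field P(r) = A(r)·e^{iψ(r)} is recorded. The transducer is centred where
the aperture-averaged amplitude is maximal, and a lens encodes the
conjugate phase −ψ as material thickness with wrap quantum
t₂π = 1/(f·|1/c_lens − 1/c_water|) ≈ 6.75 mm for PDMS at 500 kHz. A
forward simulation through the lens, rescaled so the in-brain peak is
600 kPa, verifies focusing (targeting error, −6 dB focal region,
electrode clearance).

**Thermal safety (Pennes bioheat).** The verified field becomes a heat
source Q = α|p|²/(ρc), pulsed per protocol (90 µs pulses at 130 Hz,
800 ms trains every 2.5 s → duty factor 0.0117 × 0.32), and
ρC ∂T/∂t = ∇·(k∇T) + Q − ρ_b C_b w (T − T_a) is solved over a 5-minute
block; planning passes only if ΔT < 2 °C everywhere and the focus clears
the DBS electrode by > 5 mm.

**Spectral contrast.** Channels are band-passed 4–45 Hz (zero phase),
Welch spectra (Hann 1 s, 600 ms overlap) are broadband-normalised, and
beta power (13–30 Hz; low 13–20, high 21–30) is contrasted
active-minus-sham within each day, then GPi-day minus Ventricle-day
across stimulation sites — cancelling day-level baseline drift.

**Artefact dichotomy.** A rectangular pulse train has harmonics at k·PRF
with amplitude ∝ 2d·|sinc(kd)|. At 5 Hz PRF these land inside beta; at
130 Hz the fundamental is above the device's 100 Hz hardware low-pass,
so no coherent power can reach the beta band.

## Worked example

```bash
python examples/plan_lens.py
```

prints, for the default seeded phantom:

```
transducer centre        : [46. 72.] mm
lens wrap thickness t_2pi: 6.75 mm
targeting error          : 0.00 mm
peak pressure in brain   : 600 kPa
-6 dB focal area         : 26.8 mm^2
electrode clearance      : 6.5 mm
```

i.e. the phase-conjugate lens refocuses the aberrated beam back onto the
pallidal target to within the 0.5 mm grid, with the focal region well
clear of the electrode. `examples/thermal_safety.py` then reports a
maximum rise of ~0.27 °C for a full active block (limit 2 °C), and
`examples/beta_suppression.py`, `examples/behaviour_rt.py`,
`examples/artefact_dichotomy.py` and `examples/session_io_alignment.py`
walk through the analysis side. A
config-driven runner covering all stages is available as the `tuslab`
console script (`tuslab run-all --outdir out --seed 1`).

## Scope

The package deliberately works at desk scale: 2D phantoms at 0.5 mm
(3D supported on small grids), literature-default material properties,
and a documented JSON+binary session format rather than any proprietary
device dialect. See `docs/methods.md` for the modelling assumptions,
parameter defaults and known limitations.
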