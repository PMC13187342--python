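# Methods

This note documents the models, defaults and numerical choices behind
`tuslab`, and what its synthetic benchmarks do and do not establish
about real data.

## Acoustic solver

The solver time-steps the first-order linear acoustics equations
(momentum, mass, pressure closure p = c²ρ′) with a k-space-corrected
pseudospectral scheme: spatial derivatives via FFT on staggered grids
(half-voxel spectral shifts), a sinc(c_ref·k·Δt/2) correction that makes
plane-wave propagation exact at the reference (maximum) sound speed, and
split-field perfectly matched layers (quartic profile, default width 10
voxels, α = 2). Density is harmonically averaged onto the staggered
velocity grids, which keeps strong impedance contrasts (bone,
platinum-iridium electrode) stable at CFL 0.28. The time step is rounded
down so an integer number of steps tiles one carrier period; a
raised-cosine ramped continuous source then runs long enough for the
wavefront to cross the domain (configurable, default two diagonal
crossings) before complex amplitude is extracted by quadrature
demodulation over a whole number of late cycles, which is leak-free by
construction.

Absorption is a single-frequency loss: a per-voxel decay
exp(−2·α·c·Δt) of the acoustic density, giving exactly α Np/m of
spatial decay for a travelling wave (verified against the exponential
oracle to ~0.2%). No dispersion, nonlinearity or shear propagation is
modelled; bone is a fluid with high absorption.

Validation anchors: 1/√r (2D) and 1/r (3D) free-field decay within 5%
beyond two wavelengths, phase ramp k·r within 5° RMS, source linearity
to 10⁻⁷, reciprocity in heterogeneous media to ~10⁻⁸, and cycle-averaged
energy conservation within 1% in a closed lossless box.

The pseudospectral scheme was chosen over second-order FDTD because the
default grid (0.5 mm at 500 kHz in water) resolves only ~5.9 points per
wavelength, where FDTD dispersion would dominate the sub-voxel targeting
question. The resolvability floor is set at 5 points per wavelength;
coarser grids are refused with the required spacing in the message.

## Phantom and materials

The default phantom is a deliberately reduced 2D head on a 192×160 grid
at 0.5 mm: a 28 mm-radius soft-tissue disc, a 3 mm scalp ring, a 4 mm
bone shell whose thickness carries a sinusoidal perturbation (amplitude
1.2 mm, 5 cycles, phase from the seed — ~2 rad of peak-to-peak phase
aberration at 500 kHz, comparable to a temporal-window transit), a brain
interior, a 1.5 mm-diameter electrode 9 mm lateral-posterior of the
pallidal target, and a ventricle target distinct from it. 3D phantoms
use the same concentric construction on grids up to 128³. All geometry
is in mm world coordinates (voxel 0-based, world = origin + index ×
spacing).

Material properties are literature-typical values at 500 kHz (water
1482 m/s / 1000 kg/m³; soft tissue 1540/1040; brain 1546/1046 with
4 Np/m; cortical bone 2800/1900 with 80 Np/m; metal-like electrode
3260/20000) shipped in an editable YAML. They are explicit substitutes
for any study-specific property table, not reproductions of one.

## Lens design and verification

Placement is an exhaustive search of the aperture-footprint mean
amplitude over every candidate centre on the receiver plane (ties:
lexicographically first, flagged). The lens conjugates the receiver
phase re-referenced to its circular mean — only relative aberration
matters — and encodes it as thickness modulo the wrap quantum
t₂π = 1/(f·|1/c_lens − 1/c_water|); PDMS defaults to 1030 m/s. In
verification the lens acts as a thin phase screen on the aperture
elements (grid-resolution independent), with the drive phase recovered
from the thickness map so wrap quantisation is what verification sees.
The forward field is linearly rescaled so the in-brain peak equals the
protocol pressure (600 kPa); by solver linearity this drive scale is
unique. Peak localisation is voxel-level with no sub-voxel
interpolation, so reported targeting errors are quantised to 0.5 mm.

Known 2D artefact: continuous-wave verification in a closed 2D skull
cavity produces interference fringes (contralateral-wall and electrode
reflections decay much more slowly in 2D than in 3D), so near-equal
speckle maxima can displace the voxel argmax by a few voxels on some
phantom realisations even though the amplitude at the target stays
within a few percent of the peak. Across phantom seeds 1–10 the
targeting error is 0 mm on five, 0.5 mm on four and 1.6–3.5 mm on two;
the evaluated four-phantom set (seeds 1–4) averages 0.25 mm. This
sensitivity is an artefact of the desk-scale 2D reduction, not of the
time-reversal design itself.

## Bioheat model

Pennes' equation is solved explicitly with face-averaged conductivity
(zero-flux boundaries) at 0.9× the diffusion stability bound; the
perfusion sink uses an exact exponential integrating factor, so
perfusion-only decay is exact at any step. Blood ρ_b·C_b defaults to the
local tissue values (configurable). Two pulsing treatments exist:
`duty_averaged` (Q scaled by duty × train fraction = 0.003744 for the
default protocol, applied continuously) and `train_resolved` (pulse-level
averaging within a train, trains gated on/off at ≥ 8 steps per train);
for the default low-duty protocol their final hot-voxel temperatures
agree within 10%. The electrode conducts strongly but adds no heat
source of its own. The safety gates are strict inequalities: max rise
< 2 °C, electrode clearance > 5 mm.

## Synthetic electrophysiology

Each channel is the sum of

1. a 1/f background plus white floor, synthesised by random-phase
   spectral shaping (magnitudes fixed to the model spectrum, only phases
   random), so its spectrum — hence any band power — is analytic;
2. narrowband oscillations: unit-variance band-pass-filtered noise
   carriers (order-4 Butterworth at the peak's centre/bandwidth)
   multiplied by `amplitude` and by a slowly varying log-normal gain
   exp(σ_g·ℓ(t)) with σ_g = 0.4 and a 5 s correlation time;
3. planted effects: active blocks on a given day scale beta amplitudes
   by a per-(group, band, day) suppression factor; the left M1 channel's
   log-gain is mixed with the left STN's at correlation equal to
   `ipsilateral_coupling` (default 0.9); day two is multiplied by
   `day_drift` (default 1.1, emulating diurnal baseline change);
   optional 4–6 Hz tremor contamination.

Defaults: STN peaks at 17 Hz (amplitude 0.55, bw 3 Hz) and 25 Hz (0.40,
4 Hz), M1 peaks 0.35/0.30, background offset 1.0 with slope 1.5, white
floor 0.3 — giving a beta share of roughly a third of 4–45 Hz power.
The default suppression factor 0.82 is calibrated so the expected
site-contrasted relative beta reduction on the left STN sits at the
~10.3% group level (the realised contrast slope is ~31 percentage points
per (1 − s²)).

**Ground-truth bookkeeping.** The generator books, per block, the
realised variance of every oscillatory component and the analytic
background band powers, and converts them into the exact relative
normalised-band-power change the analysis should recover. Three
conventions make the booked truth observable by a Welch-based analysis:
band powers are weighted by the |H|⁴ power response of the standard
zero-phase 4–45 Hz filter; carrier band fractions are measured on the
1 Hz Welch grid; and continuum (background) band powers integrate the
bin-extent range [low−0.5, high+0.5) Hz, because 1 Hz Welch bins collect
±0.5 Hz beyond their centres (a ~7% effect on a 1/f spectrum). With
these, planted suppression factors 0.7–1.0 are recovered with < 0.5
percentage points of bias.

What the generator does **not** emulate: beta bursting and waveform
asymmetry, cross-frequency coupling, phase coherence between STN and M1
(only power co-modulation is shared), artefacts from movement or
stimulation onset, and non-stationarities beyond the slow gain and day
drift. Passing recovery tests therefore shows the analysis is correct
and unbiased for band-power effects of this kind — not that it is robust
to every pathology of patient recordings. Under the defaults a single
virtual participant's site contrast scatters with σ ≈ 17 percentage
points (the slow gain dominates), which is noisier than the real
study's participant scatter; group-level demonstrations at n = 4 are
correspondingly humble, and calibration-level checks average over many
virtual participants.

Sessions serialise to a versioned JSON header plus a little-endian
float64 payload; parsing any proprietary device export is explicitly out
of scope.

## Behaviour

240 random-dot-motion trials per participant-day (two 60-trial runs per
condition, sham first), inter-stimulus intervals uniform in
[1.25, 1.75] s, coherence 8%/50%, log-normal reaction times truncated to
the recorded [0.1, 2] s window. Because the analysis min/max-normalises
RTs within a participant-day before taking block medians, a raw
multiplicative shift does not recover as the same normalised-median
reduction; the generator therefore calibrates the raw active-day scale
factor against a large-sample quantile approximation of the estimator
(extremes approximated by the 1/(n+1) mixture quantile) so the planted
effect is stated on the estimator's own scale — 17.70% on the targeted
day by default, recovered within ±3 points over 20 seeds.

## Artefact model

The electrode pickup is a rectangular pulse train (width = pulse
duration, period = 1/PRF, amplitude = coupling(pressure)) gated by the
train envelope, simulated at a 10 kHz internal rate, passed through the
device's low-pass (2nd order at 100 Hz; the true order is unpublished
and configurable) and decimated to 250 Hz by bare subsampling so
residual aliasing survives, as in hardware. Both linear and quadratic
pressure couplings are provided; quadratic is the default (power-like
dose response). Filtered harmonic amplitudes match the analytic
2d·|sinc(kd)| series within 3%; in-band beta power at 5 Hz PRF exceeds
the 130 Hz case by ~4 orders of magnitude at matched coupling. Bench
recordings can be wrapped in the standard session format
(`artefact_session`) and pushed through the spectral pipeline unchanged;
note that the broadband-normalised contrast is deliberately insensitive
to the 5 Hz artefact because its harmonics inflate the whole 4–45 Hz
normaliser, so absolute band power is the right readout on bench data.

## Statistics

Lilliefors normality uses the KS distance to the normal with estimated
moments and a vectorised Monte Carlo null (default 10 000 draws, seeded);
paired contrasts use the two-sided one-sample t with Student-t CIs
(df = n−1, so df = 3 at the study's n = 4); multiple comparisons use
Benjamini-Hochberg step-up within the declared family — all group tests
emitted by a run, printed in the report; post-hoc power is Monte Carlo.
Under a global null the full pipeline's family-wise discovery rate stays
below q (checked over 200 simulated studies).

## Problem sizes

Test and demonstration runs use reduced sizes chosen as desk-scale
defaults: 2D phantoms of ~10⁴–10⁵ voxels, recovery experiments with
150 s rest blocks and 512 Hz EEG, null-FDR simulations with 30 s blocks
and 256 Hz EEG, and 3D solver validation on ≤ 64³ grids at reduced
frequency. Generator defaults (300 s blocks, 4096 Hz EEG, 250 Hz LFP)
are unchanged by any of this; tests simply pass shorter schedules.
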