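# Methods

This note documents the models, conventions and numerical choices behind
cardiomotion, and what the synthetic-data generators do and do not emulate.

## Motion quantification

Bright-field movies of beating monolayers are reduced to a motion-amplitude
signal in two steps. First, a dense displacement field is estimated for
every consecutive frame pair; the default estimator is iterative
Lucas–Kanade (`skimage.registration.optical_flow_ilk`, window radius 7 px),
with total-variation L1 flow available for larger displacements. Both are
deterministic for a fixed configuration. Second, the magnitude of every
vector is reduced over the image and divided by the frame interval. The
spatial **mean** is the default reduction (rather than the sum) so that the
signal is independent of image resolution; a `sum` mode provides the raw
integral when absolute pixel counts matter. Sample *k* is timestamped at
the midpoint of frames *k* and *k+1*, so an *n*-frame movie yields an
*n − 1*-sample signal.

Optional pre-processing (Gaussian pre-smoothing, integer downsampling with
magnitudes rescaled to original pixels) trades accuracy for speed;
downsampling 2× changes the mean signal by well under 10% on the default
synthetic fixtures.

## Beat kinetics

The motion signal is an unsigned speed, so each twitch appears as a
contraction lobe followed by a relaxation lobe with the speed touching zero
in between. Detection proceeds as:

1. peaks with prominence ≥ 4 robust SDs (1.4826·MAD) of the signal;
2. a rolling 10th-percentile baseline over two expected periods (expected
   period from the pacing frequency when supplied — tissue recordings are
   often paced — otherwise from the every-other-peak spacing, since there
   are two speed peaks per beat);
3. contiguous regions above baseline + 12% of the 95th-percentile
   amplitude, with regions separated by less than a quarter period merged
   (this re-joins the two lobes split by the intra-beat zero crossing);
4. each region holding at least two peaks becomes one cycle: first
   prominent peak = contraction, last = relaxation, inter-peak minimum =
   trough. Regions clipped by the record edges are discarded as incomplete.

Per-beat readouts: the contraction phase runs from cycle start to trough,
relaxation from trough to cycle end. *Amplitude of contraction* is the
time-integral of speed over the contraction phase — a displacement proxy,
deliberately distinct from the velocity readouts. *AUC* integrates the
whole cycle. The 10→90% contraction and 90→10% relaxation times are read
off the cumulative phase displacement with linear interpolation. *Peak
duration* (not uniquely defined in common usage) defaults to the
10%-to-10% width of the twitch complex, measured against each lobe's own
peak height; the fraction is configurable (e.g. 0.5 for a half-height
width). Beat rate is 60 / median contraction-peak spacing. Mean phase
velocities are per-phase means of the speed trace; whole-trace lobe means
are a documented alternative reading, not the default.

The averaged cycle aligns beats on the contraction peak by resampling the
pre- and post-peak segments to fixed lengths before pointwise mean/SD.

Calcium-style transients use the simpler convention: amplitude = peak minus
the rolling-percentile baseline, rising slope = max derivative on the
upstroke, falling slope = min derivative on the decay (signed negative).

## Screen statistics

The plate Z score uses the sample SD (ddof = 1), the usual screening
convention; population SD is available by configuration. Negative-control
wells are included in µ/σ by default, with an exclusion flag. Two-sided
normal tail probabilities accompany each z. The hit rule is implemented
with ≥ comparisons at a configurable threshold (default 2) — at exactly
z = 2.0 the strict/non-strict distinction is ambiguous in common usage, so
the comparison is inclusive and the threshold explicit. No multiple-testing
correction is applied by default, matching single-statistic screening
practice; the p-values are provided so a correction can be layered on.

ΔΔCt: ΔCt = target Ct − reference Ct per sample; ΔΔCt subtracts the control
group's mean ΔCt; RQ = 2^(−ΔΔCt). Undetermined Ct values propagate as
missing and are counted in the result's metadata rather than imputed.

## Tissue force

Post tips are localized by intensity-weighted centroids after subtracting
the ROI's 10th-percentile background; on noiseless synthetic blobs the RMS
error is below 0.1 px. Deflection is defined on the **inter-tip distance**
(not a single tip), so rigid stage drift cancels; the diastolic baseline is
a high percentile of the distance, robust to incomplete relaxation. Frames
whose centroid reaches the ROI border are flagged as gaps, never silently
interpolated.

Force conversion uses the tip-loaded cantilever relation F = 3EIδ/L³ with
I = πr⁴/4. The post constants (E, L, r) vary between post batches and are
mandatory inputs with no defaults.

Twitch metrics delegate beat segmentation to the beat-kinetics detector
applied to |dF/dt| — per twitch this trace has exactly the two-lobe
morphology the detector expects. Developed force is the mean over twitches
of (peak force − preceding diastolic baseline).

Time-course normalization: post-transfection values are divided by the same
tissue's pre-transfection (0 h) value; the 0 h values themselves are
expressed relative to the group mean of all 0 h values, so baseline spread
remains visible while later timepoints read as per-tissue fold changes.
This reading is isolated in one function so the alternative (normalizing
0 h against later timepoints) is a one-line change. Tissues with a zero or
missing baseline are excluded with a diagnostic.

## Single-cell staircase mechanics

The staircase protocol defaults to 6 µm steps at 62.5 µm/s every 10 s on a
120 µm cell — 5% strain per step, with exact cumulative-strain bookkeeping
(k·step/initial length). Segmentation trusts the commanded motor clock
rather than detecting ramps from the stress signal; this is robust at low
SNR and matches a motor-driven protocol.

Per step: peak stress is the maximum over the ramp plus the first 0.5 s of
the hold; steady-state stress is the mean of the final 2 s of the hold;
relaxation stress is their difference by definition (the identity
relaxation = peak − steady holds to machine precision). Both windows are
configurable. A steady estimate whose coefficient of variation exceeds 10%
is flagged but still returned. An optional median prefilter (`despike`) is
available for recordings where spontaneous twitches ride on the holds
(measurements without contraction inhibitors); it is off by default because
the plain mean is the unbiased estimator on quiet holds and its error obeys
the σ/√n law exactly.

The constitutive model is the standard linear solid (Zener): a parallel
spring E_parallel plus a Maxwell arm (spring E_series, dashpot η,
τ = η/E_series). It is the minimal model whose step response shows exactly
the peak/steady/relaxation decomposition: an instantaneous step ε gives
peak (E_parallel + E_series)·ε, steady E_parallel·ε, relaxation
E_series·ε·e^(−t/τ). The forward model integrates the Maxwell stress
exactly segment by segment (linear ODE, closed form on each ramp and hold),
so synthetic traces carry no solver error; during a ramp at strain rate R
the arm stress is s₀e^(−Δt/τ) + E_series·R·τ·(1 − e^(−Δt/τ)).

`fit_sls` starts from closed-form estimates — E_parallel from the
steady-vs-strain slope, τ from a log-linear fit of the first hold's decay,
E_series from the mean relaxation amplitude corrected for the finite ramp
(factor (τ/t_ramp)(1 − e^(−t_ramp/τ))) — and refines all three by bounded
least squares against the exact staircase response over the whole trace.
τ is flagged unidentifiable when the fitted value exceeds the trace
duration (no complete relaxation observed); the moduli are still reported,
as the cumulative decay across several holds usually constrains them even
then. Noiseless recovery is exact to ~1e-9; at 5% additive noise the median
worst-parameter error over 100 seeds is ~4%.

Stress from force is σ = F/A with A = width × thickness of the
micropatterned cross-section; thickness is not optically observable and is
a mandatory input, and a force-units mode runs the entire decomposition
without any area assumption.

## Synthetic data

The generators define the test conditions; all randomness flows from
explicit seeds, regeneration is bit-identical, and ground truth is always
returned next to the artifact.

*Beating videos* advect a band-limited speckle texture with a uniaxial
displacement field u(x,t) = −d(t)·φ(x), φ odd about the vertical center
line with spatial-mean magnitude 1 — a monolayer shortening toward its
midline. The instantaneous spatial-mean speed therefore equals |d′(t)|,
the prescribed beat waveform, which is exactly what the flow stage should
report. The default waveform is a 1 Hz beat with a 0.20 s contraction
half-sine peaking at 40 px/s and a 0.32 s relaxation half-sine peaking at
25 px/s (relaxation slower than contraction, as in spontaneously beating
monolayers; the two displacements balance so the tissue returns to rest
each beat), plus 2 px/s additive Gaussian velocity noise — a mid-range
signal-to-noise choice, since well-to-well noise figures are not something
the generator claims to match to any particular instrument. Frames warp by
cubic interpolation with reflective boundaries, which keeps the mean frame
intensity constant to within 1% (advection, not intensity modulation);
per-frame displacements above 25% of the image are refused as
flow-unrecoverable. The movies are not photorealistic: no cell borders,
focus drift, or illumination flicker — passing tests demonstrate correct
signal extraction under ideal optics, not robustness to those artifacts.

*Staircase traces* reuse the exact SLS forward model plus additive Gaussian
transducer noise, so the analytic per-step truth (model stress at ramp end
and hold end) is exact.

*Planted screens* draw non-hit wells i.i.d. normal around a plate mean and
shift hit wells by a chosen number of plate-SD units, in each of three
replicates, mirroring a triplicate screening design. Real screens add
spatial plate effects (edge evaporation, gradients) that this generator
deliberately omits — the statistics module likewise offers no B-score
correction, keeping generator and analysis assumptions aligned.

*Post-tip movies* render two Gaussian blobs whose sub-pixel positions close
in by half the twitch displacement each; geometry is specified in image
pixels (separation, diameter), separately from the beam-mechanics
constants used for force conversion.

## Problem sizes

The test suite and the acceptance script run movies of 96–128 px and
150–370 frames, 24-well screens in triplicate, and 100-seed Monte-Carlo
loops for the SLS fit — sizes chosen so the whole suite completes in a
couple of minutes on a single CPU while every check still exercises the
full code path at realistic sampling rates (37 fps video, 100 Hz force
traces).

## Known limitations

* Flow-based velocity peaks are biased slightly low (finite window, 37 fps
  sampling of ~0.2 s lobes); recovery is validated to 10%, not to
  sub-percent accuracy.
* The beat detector assumes the two-lobe speed morphology; heavily fused or
  arrhythmic twitch complexes are out of scope.
* The SLS model is linear; real cardiomyocytes stiffen nonlinearly with
  stretch. The decomposition (peak/steady/relaxation) remains meaningful
  per step, but the fitted moduli are effective, small-strain quantities.
* Absolute stress levels depend on the assumed cell thickness; use
  force-units mode when thickness is unknown.
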