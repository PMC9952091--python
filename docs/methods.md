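# Methods

`chemowave` analyses single-cell chemotaxis movies in which each cell reports
the activities of two kinases — ERK and Akt — through kinase translocation
reporters (KTRs), alongside a nuclear marker.  Because no public dataset with
this exact structure is available, the package ships a first-class synthetic
generator whose outputs carry known ground truth for every quantity the
analysis estimates.  This note describes the models, the defaults and their
rationale, the numerical choices, and what the synthetic benchmarks do and do
not establish about real microscopy data.

## The synthetic movie

### Signals

Each cell `c` carries two latent oscillation amplitudes, `A_short,c` and
`A_long,c`, drawn from log-normal distributions (median 0.25 and 0.30 log2
units, shape 0.5).  Log-normality reflects the right-skewed single-cell
amplitude distributions typical of KTR data; the family is configurable.  The
ERK activity trace is a two-tone superposition

    ERK_c(t) = b + A_long,c sin(2πt/T_long + ψ_c)
                 + A_short,c sin(2πt/T_short + φ_c) + ε(t)

with baseline `b = 0.5` log2 cytoplasm/nucleus units, periods
`T_short = 40 min` and `T_long = 108 min` (the centres of the analysis bands,
28–60 and 92–124 min), phases `ψ_c, φ_c ~ U(0, 2π)` independent across cells,
and Gaussian measurement noise (SD 0.05 log2 units per frame).  Akt shares
both phases with a per-cell amplitude factor (0.8 with log-normal jitter),
emulating the tight Akt–ERK co-oscillation with independent gain.  Sinusoidal
superposition with independent per-cell phases is a modelling assumption of
this generator: real KTR traces have pulse-like, non-stationary waveforms,
and no cross-cell phase structure is claimed.

The morphological aspect ratio oscillates in the long band only, in
anti-phase with the long ERK wave (aspect-ratio maxima at long-ERK minima):

    AR_c(t) = 1.6 + 0.5 A_long,c sin(2πt/T_long + ψ_c + π) + ε(t)

so that cells with large long-wave ERK excursions also elongate strongly —
this makes the elongation increment proportional to the (negative) ERK drop
across a fluctuation, which the event analysis must recover as a negative
quantile-regression slope.

Nuclear polarization (nucleus-to-cell-centroid distance over minor-axis
length) is `0.5 · A_long,c` plus frame noise, tying polarization to the same
latent long-wave amplitude.

### Motion

Positions follow a discrete advection–diffusion law,
`x(t+dt) = x(t) + v dt + sqrt(2 D dt) η`, with two operating modes:

* **speed coupling off** (`speed_coupling=None`): every cell uses the global
  `D_true`; mean-squared displacement is exactly `4 D t` and the population
  obeys the advection–diffusion PDE.  This mode feeds the motility-inference
  benchmarks.
* **speed coupling on** (default, `(0.2, 1.2)`): each cell's step lengths are
  rescaled so its realised mean speed equals `0.2 + 1.2 A_short,c` µm/min
  exactly (median ≈ 0.5 µm/min, the scale of mesenchymal breast-cancer cells).
  The per-cell diffusivity implied by that speed replaces `D_true`.  The two
  modes are mutually exclusive because exact per-cell speed control and an
  exact global diffusivity cannot hold simultaneously.

Cells reflect off a rectangle inset by `edge_margin` (40 µm) from the field
boundary, so rendered cells are never clipped by the frame border; an
unbounded mode serves the closed-form motion tests.

### Speed bursts

After each aspect-ratio maximum, a raised-cosine burst kernel (half-width
20 min) multiplies the instantaneous speed, peaking `burst_gain = 0.25` above
baseline `burst_lag = 20 min` after the peak.  Two design choices matter:

* the kernel is mean-compensated within each track, so bursts redistribute
  motility within the elongation cycle without changing the cell's mean
  speed — mean speed remains governed solely by the short-amplitude coupling;
* bursts occur in cells whose polarization exceeds the population median
  (computed in closed form from the log-normal law), and are absent below it.
  A threshold rather than a proportional gain makes the top-quartile
  polarization stratum carry the full 25% burst and the bottom stratum none,
  which is the pattern the event analysis is designed to detect; a
  proportional gain would smear the burst height continuously across strata
  and the stratified mean would understate it.

### Mitosis and rendering

Divisions (off by default, Poisson-rate configurable) truncate the parent
track and spawn two half-area daughters one frame later and a few µm apart —
the minimal geometry the tracker's division resolution requires.

The renderer draws each cell as a filled ellipse (area 400 µm², the scale of
spread MDA-MB-231 cells) and its nucleus as a smaller ellipse (110 µm²)
offset along the major axis by polarization × minor-axis length.  KTR channel
intensities are set so log2(cytoplasm mean / nucleus mean) equals the track's
true KTR value exactly; Gaussian camera noise (SD 5 at background 100,
nuclear marker 1000, KTR nucleus level 300) gives a realistic but benign
SNR.  Intensities are painted in cell order, so when two ellipses
interpenetrate the later one occludes the earlier: the occluded pixels simply
do not exist in the image.  Ground-truth label masks are emitted alongside.

## Imaging

Nuclei: local-mean adaptive threshold (window ≈ 3 nucleus diameters, margin
the larger of 5% of the frame's 1–99 percentile spread and 5 robust noise
SDs — the noise floor prevents the background from flooding the mask in
sparse fields), hole filling, a 30 µm² size floor, and distance-transform
watershed splitting of touching nuclei.  Cells: adaptive threshold of the
summed KTR channels (sum averages noise relative to either channel alone),
then marker-controlled watershed on the inverted summed intensity seeded by
the nucleus labels, so each cell inherits its nucleus label and seedless
blobs vanish.  KTR activity is log2(mean cytoplasm / mean nucleus); the
ellipse comes from unweighted second moments; polarization is the
centroid-offset over the minor axis.

Observations whose mask touches another cell's mask carry a `contact` flag.
Shape and intensity of touching cells are split by the watershed rather than
observed — the merged-mask scenario — and in the synthetic benchmark the
occluded cell's latent values are not even present in the rendered pixels,
so round-trip accuracy is reported over non-contact detections while
detection rates count every cell.  On the 50-cells/mm², 24 h benchmark the
pipeline detects ≈ 99.5% of cells per frame with KTR RMSE ≈ 0.02–0.03 log2
units and aspect-ratio RMSE ≈ 3–4% on non-contact cells.

## Tracking

Frame-to-frame linking is a gated Hungarian assignment on
`(d/d_gate)² + |ΔA| / mean(A)` with `d_gate = 30 µm` per 4-min interval
(several times the largest plausible step) and unit area weight.  Unmatched
tracks survive up to 2 missed frames with the gate inflated by `sqrt(gap+1)`;
longer absences close the track as lost.  A division is recognised when a
track terminus (or a track passing straight through, when the linker carried
the parent into one daughter) coincides with births whose combined area
matches the parent within 35%; the parent's last 3 frames (12 min) are
trimmed because signalling and morphology are unreliable during rounding and
cytokinesis.  Three or more candidate daughters are left unresolved rather
than guessed.

## Band decomposition

Series are detrended by subtracting a centred 200-min moving average (longer
than any analysed band; series shorter than the window fall back to a linear
fit), then filtered with a zero-phase discrete-Fourier brick-wall filter that
retains periods inside the band.  The brick wall was chosen over IIR designs
because it is exact on integer-cycle tones, introduces no phase shift, and
its leakage on non-integer tones is boundable in tests.  The per-cell band
amplitude is `sqrt(2) ×` RMS of the filtered series, which equals the peak
amplitude for a single tone; an analytic-envelope mean is a reasonable
alternative the package does not implement.  Tracks shorter than 60 frames
(4 h — two long-band cycles) or with gaps longer than 2 frames are excluded
rather than imputed.  The aspect-ratio amplitude uses the long band, which
matches the period range of morphological oscillation.

The period sweep re-filters every cell in a ±16 min band around each centre
and reports the Pearson correlation between per-cell amplitude and mean
speed with 95% Fisher-z intervals; on generator defaults the curve peaks at
the short period, the generator's only speed-coupled component.

## Heterogeneity statistics

Quantile regression (τ = 0.2, 0.5, 0.8) is solved exactly as the standard
pinball-loss linear program; standard errors, the 99% CI, and the median-fit
p-value come from a seeded case-resampling bootstrap (B = 1000 by default) —
reproducible and distribution-free, with no asymptotic sparsity estimate
required.  The Wasserstein-1 distance is the integral of |F_a − F_b| over
the pooled support; its replicate-normalised form divides the mean EMD from
the test condition to each control replicate by the mean inter-replicate
control EMD, skipping a control identical to the test set (a relabelled
replicate would contribute a spurious zero).  Top-quartile proportions use
linear-interpolation quartiles and strict inequalities.  Polar histograms
bin net-displacement angles relative to a configurable gradient axis
(default +x) with the forward bin centred on the gradient.

## Aspect-ratio peak events

Peaks are local maxima of the 3-frame moving-average aspect ratio with
prominence ≥ 0.1 and spacing ≥ 48 min (one peak per long-band cycle for a
single tone); each peak's time is then refined within ±8 min on the
long-band-filtered aspect ratio, which is nearly noise-free.  The matched
ERK minimum is the nearest local minimum of the long-band component of the
detrended ERK within ±60 min (half a long period): short waves would
otherwise scatter spurious minima across the window and mask injected lags.
ERK and aspect-ratio differences are taken at the aspect-ratio extrema on
the detrended (full-band) series.  Events are stratified at the 25th/75th
polarization percentiles; each event's speed trace is normalised by its
cell's mean speed and then by the grand mean of that ratio over
non-polarized events, pinning the non-polarized baseline at 1 by
construction.

## Motility inference

Tracked positions are histogrammed onto a 20 µm node grid, converted to
cells/µm², smoothed with a Gaussian of 3 node spacings, and averaged into
20-min blocks.  The smoothing bandwidth matters: at 2 spacings, sampling
noise in the density regressors attenuates the least-squares diffusivity by
roughly 20% at 2000 cells (errors-in-variables); 3 spacings removes the bias
without affecting smooth analytic fields, for which Gaussian smoothing
commutes with the constant-coefficient PDE.

The model `∂ρ/∂t = D ∇²ρ − v·∇ρ` is fitted in weak form: for every interior
bilinear nodal test function and consecutive frame pair, the mass, stiffness
and advection stencils of the Q1 element produce one scalar equation with
midpoint densities; stacking over nodes and frames gives an overdetermined
system solved by ordinary least squares for `(D, v_x, v_y)`, with the
velocity rotated into components along and across the gradient axis.
Integration by parts is applied to the diffusion term only; advection stays
in non-divergence form (constant coefficients make the two equivalent), and
a one-element boundary band is excluded so no boundary fluxes or chamber
boundary conditions enter.  Rank deficiency (e.g. a spatially uniform
density, which carries no information about any operator) is reported as an
error naming the cause.  A backward-elimination pass drops the operator
whose removal increases the residual sum of squares by the smallest factor,
while that factor stays below 1.5; eliminating every operator is reported as
model inadequacy rather than silently returning zeros.  Constant
coefficients only: spatially varying D(x), v(x) is out of scope, as are
confidence intervals on the PDE parameters (point estimates plus residual
and condition diagnostics are reported).

Drug-vs-control comparisons use the normalised random migration
`D_drug / D_control` and normalised directed motion
`[v∥/|v|]_drug / [v∥/|v|]_control`; the latter is undefined (flagged) when
the control's directed fraction is numerically zero.

## Benchmark sizes and determinism

Synthetic benchmarks use 100–300 cells for signal/event analyses, 2000 cells
for PDE parameter recovery, and 50 rendered cells over 360 frames for the
imaging round trip — sizes at which every recovered quantity's sampling
error is several times smaller than its acceptance margin.  All randomness
flows from a single integer seed through `numpy.random.default_rng`; equal
seeds give byte-identical artifacts end to end, including rendered TIFFs.

## What passing these benchmarks does not show

The generator's cells are rigid ellipses with sinusoidal signals, additive
Gaussian noise, flat illumination and no photobleaching, focus drift,
debris, or cell-cell adhesion; segmentation and tracking performance on real
microscopy will be worse and parameter defaults (thresholds, gates) will
need retuning.  The anti-phase and lag couplings are inserted by
construction — recovering them validates the estimators' correctness, not
any biological claim.  Waveform shape, cross-cell phase coherence, and the
causal structure among polarization, signalling and motion are assumptions
or abstentions, not findings.
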