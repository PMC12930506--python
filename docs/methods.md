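# Methods

This note documents the models behind `mimicomm`, the defaults it ships,
the reasoning behind the genuinely open design choices, and what the
synthetic benchmarks can and cannot say about real cell-mimic experiments.

## The AND-gate response

The reporter construct is gated twice: transcription terminates unless a
STAR anneals to the nascent transcript, and translation is blocked unless a
trigger RNA opens the toehold stem-loop. We model the combined effect as a
product of two leaky Hill functions,

    h(S, T) = [α_term + (1 − α_term)·S^n_S/(K_S^n_S + S^n_S)]
            · [α_toe  + (1 − α_toe) ·T^n_T/(K_T^n_T + T^n_T)]

with the leak ordering 0 < α_toe < α_term < 1 enforced as a class
invariant: terminator read-through (the leak seen with trigger alone) is
substantially worse than toehold leakage (STAR alone). No rate equations
for the switches are available, so the functional form is a modelling
choice; the Hill shape is the standard phenomenology for cooperative
RNA–RNA switching and the product structure encodes the independence of
the two regulatory layers.

Defaults: `α_term = 0.286`, `α_toe = 0.03`, `n_S = n_T = 2`,
`K_S = K_T = 10` field units. α_term is pinned by the observed bulk
separation between the full gate and the trigger-only condition (~3.5×,
since the saturated ratio is 1/α_term), and α_toe by requiring the ON/OFF
separation to exceed 25× with margin (saturated ratio
1/(α_term·α_toe) ≈ 117). Concentrations carry nM-equivalent "field units"
so the bulk simulator and the spatial fields drive the same Hill
functions.

## Bulk TXTL kinetics

`simulate_bulk` integrates

    dS/dt = k_tx·[template]·e^(−t/τ_res) − S/τ_RNA
    rate  = β·([reporter]/2)·h(S, T)·e^(−t/τ_res)

and convolves the synthesis rate with a first-order maturation/capture
response (τ_mat = 45 min) to produce the observed, sigmoidal reporter
trace. A single exponential resource decay (τ_res = 120 min) stands in
for NTP/amino-acid depletion and produces the characteristic plateau; no
explicit resource bookkeeping is attempted. RNA lifetime τ_RNA = 17 min is
the canonical mRNA lifetime in these lysates. β, k_tx and the absolute
intensity scale are arbitrary calibration constants — the analyses only
ever use ratios and correlations.

## RNA concentration fields

The sandwiched droplet (millimetres wide, tens of micrometres high) is
treated as a thin film, so transport is two-dimensional. A sender emitting
at constant rate Q with first-order RNA decay produces the steady-state
field

    c(r) = (Q / 2πD) · K₀(r/λ),   λ = √(D·τ)

and the transient field is the emission-history integral of the 2-D
diffusion–decay Green's function, evaluated by Gauss–Legendre quadrature
after a logarithmic substitution in the age variable (80 nodes; the
integrand's support spans four decades). Distances are clipped at one
mimic radius (35 µm) so the logarithmic singularity is never sampled;
emission starts after a transcription onset delay (15 min). Diffusion
coefficients are consumed as parameters — 8.48×10⁻⁷ cm²/s (STAR) and
6.49×10⁻⁷ cm²/s (trigger), giving λ = 294 µm and 257 µm: the trigger acts
more locally. Emission is held constant over the reaction; resource decay
is applied once, at the receiver's synthesis step, which keeps the field
kernels time-invariant and the superposition cheap.

For community simulations the kernel F(r, t) is tabulated on a dense
logarithmic r-grid (1024 points) per acquisition frame and interpolated
over all sender–receiver pairs; the table agrees with direct quadrature to
~10⁻⁴ and with an independent Crank–Nicolson finite-volume solver of the
radial PDE to <0.1% (the FD solver lives in the test suite as an oracle
only). Q is normalised so that a unit-load sender produces concentration 2.5 K
at distance λ — one sender strongly activates its own neighbourhood out
to roughly a signaling length. Together with K this is the calibration
that places the benchmark's optimal correlation radius at the
few-hundred-micrometre scale of the analyses.

## The synthetic community generator

A sample is a droplet of radius 1.5 mm (2.1 mm for the centrally arranged
layouts) in which mimics with diameters uniform in 60–80 µm are placed by
rejection sampling without overlap, uniformly at random or as a central
dual-sender patch ringed by receivers. Per-mimic DNA load is lognormal
with mean 1 and CV 0.35 (loading heterogeneity is documented
qualitatively but not quantified; the CV is a placeholder). Dual senders
split their load equally between the two species.

Each receiver integrates

    dG/dt = load·β·[h(S_local, T_local) − h(0,0)]·e^(−t/τ_res)     (signal)
          + load·β·h(0,0)·(1 − e^(−t/τ_leak))·e^(−t/τ_res)        (own leak)

convolved with the maturation response, on top of two signal-independent
terms shared with the senders: a well-mixed background (a fraction
`escape_fraction = 0.1` of all reporter synthesis leaves its mimic and is
re-captured after a first-order mixing lag τ_mix = 120 min — reporter
mRNA and protein are not confined to the producing compartment) and a
constant per-mimic shell autofluorescence (30 ± 15 a.u.). The slow leak
build-up (τ_leak = 180 min) makes sender-omitted controls flat early and
rising late, as observed; the load-scaling of the leak follows from the
leak transcripts originating on the receiver's own reporter template.
Simulation is deterministic given a layout: stochasticity enters only
through layout, load and autofluorescence sampling.

These ingredients reproduce, from one seed, the qualitative spatiotemporal
phenomenology the analyses are designed to detect: sequential outward
activation from a central sender patch (near receivers, <0.8 mm, reach
half-maximum around 2.3 h, distant ones an hour later); a density–fluorescence correlation that rises,
peaks at intermediate times and then declines as saturation and
late-rising white leak decorrelate intensity from density; and a
positional x/y null, since no positional covariate exists by construction.
The correlation peak sits earlier (~0.75–1 h) than in the real time-lapse
data (1.5–3.5 h), because the deterministic model omits slow TXTL start-up
and measurement noise; tests therefore assert the shape, not the window.

Rendering mirrors the acquisition scheme: bright-field (dark ring per
mimic), Cy5 (trigger-sender membranes), mCherry (STAR-sender membranes)
and sfGFP concentrated in a nucleus disc of half the mimic diameter, at
4 µm/px with Poisson shot noise (gain 0.5 count/photon) and Gaussian read
noise (σ = 5).

## Image analysis

Fluorescence channels are background-corrected with a rolling-ball-style
morphological opening (flat footprint, radius ≈ 3 mimic diameters) of a
median-pre-smoothed copy — opening a raw noisy image tracks the noise
floor rather than the background level. Mimics are segmented in the
bright field by a circular Hough transform over nine candidate radii
spanning 25–45 µm, with peaks accepted while their perimeter-normalised
accumulator support exceeds 0.5 and suppressed when centres fall within
0.8 of the sum of radii (tangent circles survive; duplicate radii do
not); a frame whose intensity deviations are all noise-scale (8×MAD
guard) yields no detections. Each accepted radius is refined to the
minimum of the radial bright-field profile. Classification thresholds the
membrane annulus (0.55–1.1 r) in the two dye channels; fixed, manually
chosen thresholds take precedence, with a per-channel Otsu estimate as
fallback, and detections above both thresholds are flagged unclassified.
sfGFP is extracted as the mean over the central disc (0.4 r, safely
inside the nucleus under ±1 px centre error). On 100 rendered benchmark
layouts segmentation precision and recall and label accuracy all exceed
0.95. Coordinates convert to droplet-centred mm with the frame centre as
origin, x right / y down.

## Spatial and kinetic statistics

Local density is the plain n/A count within radius r of a receiver
(receiver self-excluded from receiver counts; no edge correction by
default, matching the published definition — an exact circle–droplet
intersection area is available behind a flag). The radius scan computes
the per-sample Pearson r between receiver end-point sfGFP and each
population's local density over the grid 200–1200 µm in 100 µm steps,
averaging r over samples with ≥5 receivers, ≥1 scored member and
non-degenerate variance; the joint optimum is the argmax of the mean of
the two sender curves. Fold changes divide by the mean receiver intensity
pooled over sender-free control samples. The response surface is a
hand-rolled 2-D LOESS (locally linear, tricube weights over the nearest
span-fraction of points in standardised density coordinates, span 0.5
default); no installed package provides two-dimensional LOESS. Kymographs
order receivers by distance from the sender centroid and average
equal-count groups into 15 rows (fixed-width bins behind a flag); onsets
are the first crossing of a threshold fraction (default 0.25) of the
final baseline-subtracted value, linearly interpolated, and are exactly
affine-invariant.

## Benchmarks, determinism, problem sizes

Three shipped configurations define the study conditions: 29 end point
samples with total counts log-uniform in 30–500 and Dirichlet(4,2,2)
population fractions plus 5 sender-free controls (seed 42); 5 time-lapse
samples at 21 frames; one central-patch layout (2.1 mm droplet, senders
within 0.5 mm). The default single-sample configuration is 200 receivers
with 60 + 60 senders — with markedly fewer senders the RNA field becomes
lumpy enough that spatial autocorrelation inflates per-sample chance
correlations with the coordinate axes beyond the experimentally observed
null bound, so the default sits in the many-sender regime the experiments
occupied. The full end point benchmark simulates and analyses in well
under a minute on one CPU, which sets the problem sizes used throughout
the tests. Every random draw flows from `numpy.random.default_rng` seeds
derived from a single base seed; re-running a benchmark reproduces every
CSV/JSON byte for byte.

## Known limitations

- All rate constants (β, k_tx, K, Q, τ_res, τ_mat, τ_leak, escape
  fraction) are calibration choices, not measurements; only the
  diffusion coefficients, RNA lifetime, geometry and acquisition schedule
  are taken from the experimental description.
- The generator omits convective flow, drying, temperature gradients,
  mimic movement, chemical noise and clay–RNA binding kinetics, and
  treats the droplet as strictly 2-D. Passing the synthetic benchmarks
  therefore validates the analysis pipeline and the internal consistency
  of the model, not the biology of any particular lysate.
- Classification assumes exactly two dye channels with single-stained
  senders; dual-stained populations are deliberately reported as
  unclassified rather than guessed.
- The loading calibration assumes a linear dye response through the
  origin region and droplets gated to the mimic size range.
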