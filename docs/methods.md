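# Methods

This note records the models implemented in `speckleflow`, the numerical
choices behind them, and what the synthetic benchmarks do and do not
establish about real data.

## Dynamic speckle synthesis

**Spatial statistics.** A speckle field is synthesised as a complex
circular-Gaussian random field band-limited by a circular pupil in the
spatial-frequency domain. On an `N`-pixel grid the pupil diameter is
`N / px_per_speckle`, so the intensity spectrum (twice the pupil support)
just satisfies the sampling theorem at `px_per_speckle = 2`; the default of
3 oversamples the grain. Only the `M ≈ π(N/(2s))²` pupil modes are stored
and evolved; frames are materialised by batched inverse FFTs in single
complex precision, with mode amplitudes normalised so the mean intensity
is 1. Per-pixel intensity of one field is exponential (fully developed
speckle, global contrast 1), and the nearest-neighbour intensity
correlation follows the pupil's Airy profile `|2J₁(πΔ/s)/(πΔ/s)|²`.

**Temporal statistics.** The pupil coefficients evolve by a first-order
autoregressive update whose per-step coefficient is the field correlation
`g1(dt)`. For the negative-exponential form `g1(τ) = e^{−τ/τc}` (multiple
scattering in ordered flow — the regime of the simulated benchmark) the
process is Markovian and the prescribed `g1` holds *exactly at every lag*,
so the intensity autocorrelation obeys the Siegert relation
`g2(τ) − 1 = β_pol |g1(τ)|²`. For the Gaussian and square-root-exponential
forms the update uses the progressive ratio `g1(t_{k+1})/g1(t_k)`; the
correlation against the initial field is then exact but the sequence is not
pairwise-stationary — a documented approximation, as only the exponential
form is generated by a Markov process.

**Detection model.** The detected intensity is the mean of
`n_polarization` independent field intensities. The default is 2:
multiply scattered light is depolarized, so an analyser-free detector sums
two independent speckle patterns, which halves the intensity-correlation
amplitude (`β_pol = 1/2`) and lowers the windowed short-exposure contrast
plateau into the physical fitting box `β ≤ 0.5`. With a single polarized
field (`n_polarization = 1`, used by the statistical contract tests) the
plateau sits near `β ≈ 0.6–0.75` for 5×5/7×7 windows at 3 px/speckle,
which no bounded MESI fit with `β < 0.5` can represent; the two-channel
default is therefore both the physically appropriate model for the
simulated scattering regime and the condition under which windowed contrast
and the MESI bounds are mutually consistent.

**Time integration.** An exposure `T` is the mean of `n = ceil(T/dt)`
consecutive correlated frames with `dt = τc · dt_rule` (default `τc/20`,
capped at `T`). For an exponential `g1` the discrete sum overestimates the
continuous-integration contrast by `(dt/τc)·(1+ρ_d)/(1−ρ_d)` with
`ρ_d = e^{−2dt/τc}` — below 0.1% in `K²` at the default step. A sub-frame
safety cap (default 20 000 per exposure) raises an error rather than
silently subsampling. Per-exposure random streams are spawned from one
master seed, so stacks are bit-reproducible and exposures statistically
independent.

**Quantization.** Frames are linearly scaled so the mean sits at
`mean_fill_fraction` (default 0.25) of the 12-bit full scale, clipped and
rounded; the saturated fraction is reported. At quarter-scale fill the
clipped tail of a one-field exponential marginal is `e⁻⁴ ≈ 1.8%` (far less
for the two-field gamma marginal), and quantization perturbs mean contrast
by well under a percent — the scaling is bookkeeping, not physics, which is
why it is configurable.

## Contrast estimators

The `direct` engine evaluates the definition per window by explicit
summation (population divisor by default, matching `Ks = σ/⟨I⟩` with σ the
plain RMS deviation; the `n−1` divisor is an option whose effect is the
exact factor `√(N/(N−1))`). The sums engines compute local means of `I`
and `I²` by box or disc convolution and take
`Ks = √(max(E[I²]−E[I]², 0))/E[I]`; all accumulation is double precision
(12-bit squared data overflows 32-bit accumulators on large kernels), and
variances below `10⁻¹²·E[I²]` are treated as exact zeros because the
subtraction of two nearly equal `O(E[I²])` terms cannot resolve them —
genuinely negative results are clamped and counted. On the valid interior
every engine matches the direct reference to better than `1e−9`; padding
(reflect / constant-zero / symmetric, names following
`scipy.ndimage.uniform_filter`) only influences the `size//2` border,
which `crop_edges` removes before any mean-`Ks` statistic is taken.

Disc kernels default to the ImageJ rank-filter mask
(`dy²+dx² ≤ r²+1`: 21 members at diameter 5, 37 at 7), which tracks the
equal-sized square kernel to within ~3.5% on correlated speckle; the plain
Euclidean rule (13/29 members) is available as `disc_rule="euclidean"` but
deviates by ~11% because its much smaller support samples fewer speckles
per window. Kernel size drives the dominant bias: windows hold few
independent speckle grains at 3 px/speckle, so `Ks` is systematically low,
less so at 7×7 than 5×5 — the reason larger kernels yield decorrelation
times closer to truth for every engine.

## Decorrelation-time estimation

`mesi_model` evaluates `K(T)` with `(e^{−y}−1+y)/y²` switched to its
alternating series below `y = 0.05` (both branches accurate to ~1e−13 at
the switchover, so `K(T)` is smooth there). `fit_mesi` minimises residuals
in `K` — the printed observable, avoiding the reweighting ambiguity of
fitting `K²` — with bounded trust-region least squares, multi-started from
8 log-spaced `τc` values in [0.01, 10] ms (β init 0.25, ρ init 0.9) because
the objective has shallow valleys in (β, τc); the best start wins and the
procedure is deterministic for a given point set. Simulation-mode fits pin
`ρ = 1, v_ne = v_noise = 0` (purely dynamic, noise-free fields);
experimental mode frees `β, ρ, τc, v_noise` and pools the nonergodic term
into `v_noise`. `ρ = 1` is included in the feasible box so the
simulation-mode pin is consistent with the experimental-mode bound.

The single-exposure estimator is reported as `τ̂ = T·Ks²/β` with a
caller-supplied β — in the comparison pipeline, each engine's own fitted β,
so that the asymptotic and MESI estimates are normalised consistently per
method. Estimates carry an "unreliable" flag when `T/τ̂ < 100`, the
estimator's own validity condition; even on exact model contrast it has an
intrinsic bias of `−1/(2x)` (−0.08% at `x = 600`).

## Benchmark scales and expected values

The reference study conditions are: negative-exponential `g1`,
`τc ∈ {0.1, 1} ms`, 3 px/speckle, 15 exposures 0.05–60 ms, 12-bit frames,
unpolarized detection, noise-free. Tests and the acceptance script run
them at 256×256 (the per-exposure mean `Ks` is an intensive statistic, so
image size only sets its seed-to-seed scatter, not its expectation), with
smaller 48–128 px images for unit-level checks. Under these
conditions the bounded MESI regression on direct/square contrast recovers
`τc = 0.1 ms` as ≈0.105–0.110 and `τc = 1 ms` as ≈0.97–1.03 across seeds
and kernel sizes — a few-percent bias from the finite-window sampling of
`Ks`, reproduced rather than corrected because it is a property of the
estimators under study.

## What the synthetic benchmarks do not show

The simulator emulates a homogeneous, purely diffusive, noise-free medium:
no camera noise (dark, read, shot, fixed pattern), no static-scatterer
mixtures (`ρ < 1` geometries), no illumination drift, vibration or
specular contamination, and no heterogeneous optical properties. Passing
benchmarks therefore demonstrate correctness of the estimators and the
fitting machinery, not robustness to experimental noise — on real data the
additive noise terms dominate the short-exposure plateau and the limited
maximum exposure restricts the asymptotic estimator, effects that must be
absorbed by the free `v_noise` term. The composite two-region stacks
stitch independently simulated intensities along a mask; window statistics
are wrong within a kernel radius of the seam, so ROI masks are eroded away
from it, and no attempt is made to model vessel walls or partial-volume
gradients.
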