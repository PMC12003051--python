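# speckleflow

Laser speckle contrast imaging (LSCI) maps microcirculation by exploiting the
blur of speckle patterns recorded over a camera exposure `T`: moving red
blood cells decorrelate the scattered field over a time `τc`, and the local
spatial speckle contrast

    Ks = σ / ⟨I⟩

computed over small sliding windows (5×5 or 7×7 pixels) drops as `T/τc`
grows. Flow is quantified either from a single exposure via the asymptotic
blood flow index `BFI = 1/(T·Ks²)` (valid for `T/τc > 100`), or by fitting
the multi-exposure speckle imaging (MESI) model to `Ks(T)`:

    K(T)² = β ρ² (e^{−2x} − 1 + 2x) / (2x²)
          + 4 β ρ (1−ρ) (e^{−x} − 1 + x) / x²
          + v_ne + v_noise,       x = T/τc,

with coherence factor `β`, dynamic-scatterer fraction `ρ`, and nonergodic /
noise variance offsets, fitted within the physical box
`0.05 ≤ β ≤ 0.5`, `0.1 ≤ ρ ≤ 1`, `0 < τc < 10 ms`, `0 ≤ v_noise < 0.3`.

In practice `Ks` is rarely computed by its definition: production pipelines
use vectorized "sums algorithm" convolution filters that differ in kernel
shape (square vs disc), border padding and variance divisor — and those
numerical choices bias `Ks` and therefore every flow index derived from it.
This package reimplements that comparison end to end for anyone validating
an LSCI/MESI processing chain:

* **specklesim** — synthesis of dynamic speckle stacks with exact speckle
  grain size (pixels per speckle) and prescribed field decorrelation
  `g1(τ)` (negative-exponential, Gaussian or square-root-exponential),
  time-integrated over arbitrary exposure ladders and 12-bit quantized;
* **contrast** — a nested-summation `direct` reference estimator plus the
  convolution engines (`sums_uniform`, `sums_correlate_pad`, `sums_disc`)
  with configurable kernel shape, size, padding, divisor and disc-mask
  convention, edge cropping and relative-error maps;
* **flowmodels** — the MESI model with a numerically stable small-`x`
  branch, bounded multi-start least-squares fitting, and the LSCI
  asymptotic estimator with its validity flag;
* **pipeline** — the comparison study (method × kernel × exposure tables of
  mean `Ks`, relative error and `τc`), exposure-cycled sequence averaging
  and ROI-level fits;
* **io / cli** — TIFF stack + JSON sidecar I/O, YAML run configs, and the
  `speckleflow` command with `simulate`, `contrast`, `fit`, `compare` and
  `mesi-roi` subcommands.

The numbered scripts under `analysis/` run the study at desk scale and
write their tables under `results/`.

## Worked example

Simulate a multi-exposure stack at `τc = 0.1 ms` (3 pixels per speckle,
15 exposures from 0.05 to 60 ms, unpolarized detection), compute mean 7×7
contrast per exposure and fit the MESI model:

```python
import numpy as np
from speckleflow import (DecorrelationSpec, KernelSpec, SimulationConfig,
                         contrast_variant, fit_mesi, mean_ks, simulate_mesi_stack)

config = SimulationConfig(
    decorrelation=DecorrelationSpec(tau_c=0.1),      # ms
    image_shape=(128, 128), seed=1,
)
stack = simulate_mesi_stack(config)

kernel = KernelSpec(size=7, padding="reflect", engine="sums_uniform")
points = [
    (T, mean_ks(contrast_variant(frame.astype(float), kernel, T)))
    for frame, T in zip(stack.frames, stack.exposure_time_per_frame)
]
for T, k in points[:3] + points[-1:]:
    print(f"T = {T:5.2f} ms   mean Ks = {k:.4f}")

fit = fit_mesi(points, fixed={"rho": 1.0, "v_ne": 0.0, "v_noise": 0.0})
print(f"fitted tau_c = {fit.tau_c:.4f} ms   beta = {fit.beta:.3f}")
```

prints

```
T =  0.05 ms   mean Ks = 0.5187
T =  0.10 ms   mean Ks = 0.4745
T =  0.20 ms   mean Ks = 0.3708
T = 60.00 ms   mean Ks = 0.0260
fitted tau_c = 0.1067 ms   beta = 0.366
```

The contrast falls from ≈0.52 at the shortest exposure (where the window
statistics, spatial sampling and unpolarized detection set the plateau
`√β`) to ≈0.03 at 60 ms, and the bounded regression recovers the simulated
decorrelation time within a few percent; the residual upward bias is the
finite-window sampling bias of `Ks` itself, which shrinks with kernel size.

The same comparison across engines (run `python analysis/02_contrast_methods.py`
then `python analysis/03_decorrelation_times.py`) shows the box-filter sums
engine agreeing with the direct reference to machine precision on the
cropped interior, disc kernels sitting within a few percent, and every
method's MESI `τc` landing far closer to truth than its single-exposure
asymptotic estimate at short exposures.

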