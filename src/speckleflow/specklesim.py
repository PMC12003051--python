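"""Synthesis of dynamic speckle image stacks.

The simulator produces fully developed speckle whose spatial grain size and
temporal field decorrelation are prescribed exactly:

* A complex circular-Gaussian field is synthesised in the spatial-frequency
  domain on a circular pupil whose radius sets the pixels-per-speckle ratio
  (a pupil of diameter ``N / px_per_speckle`` on an ``N``-pixel grid; the
  intensity spectrum then just satisfies the sampling theorem at
  ``px_per_speckle = 2``).
* Temporal evolution is a first-order autoregressive update of the pupil
  coefficients whose per-step coefficient equals the field correlation
  ``g1(dt)``, so the negative-exponential ``g1`` holds exactly at every lag.
* Detection sums ``n_polarization`` statistically independent speckle fields.
  The default of 2 models unpolarized detection of multiply scattered light
  (multiple scattering depolarizes), which halves the intensity-correlation
  amplitude relative to a single polarized field.
* Time-integrated frames are means of ``ceil(T / dt)`` consecutive correlated
  raw frames with ``dt = tau_c * dt_rule``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
import scipy.fft as _fft

__all__ = [
    "DEFAULT_EXPOSURES_MS",
    "DecorrelationSpec",
    "SimulationConfig",
    "SpeckleStack",
    "generate_field_sequence",
    "integrate_exposure",
    "quantize",
    "simulate_mesi_stack",
    "simulate_two_region_stack",
]

#: The 15-exposure MESI ladder (ms) spanning two orders of magnitude.
DEFAULT_EXPOSURES_MS: Tuple[float, ...] = (
    0.05, 0.1, 0.2, 0.5, 0.8, 1.0, 2.0, 3.5, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 60.0,
)

_FORMS = ("neg_exponential", "gaussian", "sqrt_exponential")


@dataclass(frozen=True)
class DecorrelationSpec:
    """Normalized field autocorrelation g1(tau) and its decorrelation time.

    Parameters
    ----------
    tau_c : float
        Decorrelation time in ms, strictly positive.
    form : str
        ``neg_exponential`` (multiple scattering, ordered flow; the form used
        for the simulated dataset), ``gaussian`` (single scattering, ordered
        flow) or ``sqrt_exponential`` (multiple scattering, unordered flow).
    static : bool
        If True, g1 is identically 1 (the tau_c -> infinity limit); the field
        does not evolve.
    """

    tau_c: float
    form: str = "neg_exponential"
    static: bool = False

    def __post_init__(self) -> None:
        if not self.tau_c > 0:
            raise ValueError(f"tau_c must be > 0, got {self.tau_c}")
        if self.form not in _FORMS:
            raise ValueError(f"unknown decorrelation form {self.form!r}; expected one of {_FORMS}")

    def g1(self, tau):
        """Field autocorrelation at lag ``tau`` (ms); g1(0)=1, non-increasing."""
        tau = np.asarray(tau, dtype=float)
        if np.any(tau < 0):
            raise ValueError("lag tau must be >= 0")
        if self.static:
            return np.ones_like(tau)
        u = tau / self.tau_c
        if self.form == "neg_exponential":
            return np.exp(-u)
        if self.form == "gaussian":
            return np.exp(-(u ** 2))
        return np.exp(-np.sqrt(u))


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic speckle acquisition.

    ``n_polarization`` is the number of independent speckle fields summed on
    the detector: 2 (default) models unpolarized detection of depolarized,
    multiply scattered light; 1 models fully polarized detection (single-field
    speckle with unit global contrast).
    """

    decorrelation: DecorrelationSpec
    image_shape: Tuple[int, int] = (256, 256)
    px_per_speckle: float = 3.0
    exposure_times: Tuple[float, ...] = DEFAULT_EXPOSURES_MS
    bit_depth: int = 12
    mean_fill_fraction: float = 0.25
    dt_rule: float = 1.0 / 20.0  # sub-frame step dt = tau_c * dt_rule
    seed: int = 0
    n_polarization: int = 2
    quantize: bool = True
    max_subframes: int = 20000

    def __post_init__(self) -> None:
        r, c = self.image_shape
        if r < 8 or c < 8:
            raise ValueError(f"image_shape too small: {self.image_shape}")
        if self.px_per_speckle < 2:
            raise ValueError(
                f"px_per_speckle must be >= 2 (Nyquist sampling of speckle grains), got {self.px_per_speckle}"
            )
        exposures = tuple(float(t) for t in self.exposure_times)
        if len(exposures) == 0 or any(t <= 0 for t in exposures):
            raise ValueError("exposure_times must be non-empty and strictly positive")
        if list(exposures) != sorted(exposures):
            raise ValueError("exposure_times must be sorted ascending")
        if not 0 < self.mean_fill_fraction < 1:
            raise ValueError("mean_fill_fraction must be in (0, 1)")
        if not 0 < self.dt_rule <= 1:
            raise ValueError("dt_rule must be in (0, 1]")
        if self.bit_depth < 1 or self.bit_depth > 16:
            raise ValueError("bit_depth must be in [1, 16]")
        if self.n_polarization < 1:
            raise ValueError("n_polarization must be >= 1")

    @property
    def dt(self) -> float:
        return self.decorrelation.tau_c * self.dt_rule


@dataclass
class SpeckleStack:
    """3D stack of speckle frames with per-frame exposure times.

    ``frames`` has shape (n_frames, rows, cols) and non-negative intensities;
    quantized stacks hold integers bounded by ``2**bit_depth - 1``.
    """

    frames: np.ndarray
    exposure_time_per_frame: np.ndarray
    quantized: bool = False
    bit_depth: Optional[int] = None
    provenance: str = ""
    saturation_fractions: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be 3D (frame, row, col)")
        self.exposure_time_per_frame = np.asarray(self.exposure_time_per_frame, dtype=float)
        if self.exposure_time_per_frame.shape != (self.frames.shape[0],):
            raise ValueError("exposure_time_per_frame must have one entry per frame")
        if np.any(self.frames < 0):
            raise ValueError("frame intensities must be non-negative")
        if self.quantized:
            if self.bit_depth is None:
                raise ValueError("quantized stacks must record bit_depth")
            if self.frames.max(initial=0) > 2 ** self.bit_depth - 1:
                raise ValueError("quantized intensities exceed 2**bit_depth - 1")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> Tuple[int, int]:
        return self.frames.shape[1:]


# ---------------------------------------------------------------------------
# field synthesis engine
# ---------------------------------------------------------------------------

class _PupilSynth:
    """Masked-spectrum synthesis of correlated speckle fields.

    Only the pupil modes are stored and evolved; frames are materialised by
    batched inverse FFTs.  Amplitudes are normalised so the per-field mean
    intensity is 1.
    """

    def __init__(self, shape: Tuple[int, int], px_per_speckle: float):
        rows, cols = shape
        fy = np.fft.fftfreq(rows) * rows
        fx = np.fft.fftfreq(cols) * cols
        ry = rows / (2.0 * px_per_speckle)
        rx = cols / (2.0 * px_per_speckle)
        mask = (fy[:, None] / ry) ** 2 + (fx[None, :] / rx) ** 2 <= 1.0
        self.shape = shape
        self.idx = np.flatnonzero(mask.ravel())
        self.n_modes = self.idx.size
        # ifft2 uses 1/(rows*cols); Var(mode) = (rows*cols)**2 / n_modes gives E[|E|^2] = 1
        self.amp = (rows * cols) / np.sqrt(2.0 * self.n_modes)

    def draw_modes(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        z = rng.standard_normal((n, 2 * self.n_modes)).astype(np.float32)
        return (self.amp * z.view(np.complex64)).astype(np.complex64)

    def frames_from_modes(self, modes: np.ndarray) -> np.ndarray:
        """Inverse-transform (n, n_modes) pupil coefficients to intensity frames."""
        n = modes.shape[0]
        rows, cols = self.shape
        flat = np.zeros((n, rows * cols), np.complex64)
        flat[:, self.idx] = modes
        fields = _fft.ifft2(flat.reshape(n, rows, cols), axes=(-2, -1), overwrite_x=True)
        return fields.real ** 2 + fields.imag ** 2


def _ar_coefficients(spec: DecorrelationSpec, dt: float, n: int) -> np.ndarray:
    """Per-step AR coefficients r_k = g1(t_{k+1}) / g1(t_k) for n-1 steps."""
    if n <= 1:
        return np.empty(0)
    t = np.arange(n, dtype=float) * dt
    g = spec.g1(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(g[:-1] > 0, g[1:] / np.maximum(g[:-1], 1e-300), 0.0)
    return np.clip(r, 0.0, 1.0)


def _subframe_count(
    config: SimulationConfig, duration: float, collapse_static: bool = True
) -> Tuple[int, float]:
    dt = min(config.dt, duration)
    if config.decorrelation.static and collapse_static:
        # a static field is constant in time: integrating is a no-op
        return 1, duration
    n = int(np.ceil(duration / dt - 1e-9))
    if n > config.max_subframes:
        raise RuntimeError(
            f"integrating {duration} ms at dt={dt} ms requires {n} sub-frames, "
            f"exceeding the safety cap of {config.max_subframes}; raise max_subframes "
            f"or coarsen dt_rule explicitly"
        )
    return max(n, 1), dt


def generate_field_sequence(
    config: SimulationConfig, duration: float, rng: Optional[np.random.Generator] = None
) -> SpeckleStack:
    """Generate raw (un-integrated) correlated speckle frames at step dt.

    Each frame's detected intensity is the mean of ``n_polarization``
    independent field intensities.  For ``n_polarization=1`` the per-pixel
    marginal is exponential (global contrast 1) and the intensity
    autocorrelation obeys the Siegert relation g2(tau) - 1 = |g1(tau)|^2;
    for 2 channels the right-hand side carries an extra factor 1/2.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n, dt = _subframe_count(config, duration, collapse_static=False)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    synth = _PupilSynth(config.image_shape, config.px_per_speckle)
    r = _ar_coefficients(config.decorrelation, dt, n)
    q = np.sqrt(1.0 - r ** 2)
    acc = np.zeros((n,) + tuple(config.image_shape), np.float64)
    for _ in range(config.n_polarization):
        modes = np.empty((n, synth.n_modes), np.complex64)
        modes[0] = state = synth.draw_modes(rng)[0]
        if n > 1:
            innov = synth.draw_modes(rng, n - 1)
            for k in range(1, n):
                state = np.complex64(r[k - 1]) * state + np.complex64(q[k - 1]) * innov[k - 1]
                modes[k] = state
        acc += synth.frames_from_modes(modes)
    acc /= config.n_polarization
    return SpeckleStack(
        frames=acc,
        exposure_time_per_frame=np.zeros(n),
        quantized=False,
        provenance=f"raw field sequence, dt={dt} ms, n={n}, {config.decorrelation}",
    )


def integrate_exposure(
    config: SimulationConfig,
    T: float,
    rng: Optional[np.random.Generator] = None,
    chunk: int = 128,
) -> np.ndarray:
    """Time-integrated speckle frame for exposure ``T`` (ms), mean intensity 1.

    Returns the mean of ``ceil(T / dt)`` consecutive correlated raw frames,
    accumulated on the fly (nothing is stored), so the spatial contrast
    decreases with ``T`` following the multi-exposure speckle model.
    """
    if T <= 0:
        raise ValueError("exposure time T must be positive")
    n, dt = _subframe_count(config, T)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    synth = _PupilSynth(config.image_shape, config.px_per_speckle)
    r = _ar_coefficients(config.decorrelation, dt, n)
    q = np.sqrt(1.0 - r ** 2)
    acc = np.zeros(config.image_shape, np.float64)
    for _ in range(config.n_polarization):
        state = synth.draw_modes(rng)[0]
        done = 0
        first = True
        while done < n:
            c = min(chunk, n - done)
            modes = np.empty((c, synth.n_modes), np.complex64)
            k0 = 0
            if first:
                modes[0] = state
                k0, first = 1, False
            if c - k0 > 0:
                innov = synth.draw_modes(rng, c - k0)
                for k in range(k0, c):
                    j = done + k - 1  # global step index of this transition
                    state = np.complex64(r[j]) * state + np.complex64(q[j]) * innov[k - k0]
                    modes[k] = state
            acc += synth.frames_from_modes(modes).sum(axis=0, dtype=np.float64)
            done += c
    return acc / (n * config.n_polarization)


def quantize(frame: np.ndarray, bit_depth: int = 12, mean_fill_fraction: float = 0.25):
    """Quantize a frame to ``bit_depth`` bits, mean at a fraction of full scale.

    The frame is linearly scaled so its mean sits at
    ``mean_fill_fraction * (2**bit_depth - 1)``, clipped at full scale and
    rounded to the nearest integer.

    Returns
    -------
    (np.ndarray, float)
        The uint16 frame and the fraction of saturated (clipped) pixels.
    """
    frame = np.asarray(frame, dtype=float)
    if np.any(frame < 0):
        raise ValueError("frame must be non-negative")
    mean = frame.mean()
    if mean == 0:
        raise ValueError("cannot quantize an all-zero frame (no scale)")
    if not 0 < mean_fill_fraction < 1:
        raise ValueError("mean_fill_fraction must be in (0, 1)")
    full = 2 ** bit_depth - 1
    scaled = frame * (mean_fill_fraction * full / mean)
    saturated = float(np.mean(scaled > full))
    out = np.rint(np.clip(scaled, 0, full)).astype(np.uint16)
    return out, saturated


def _exposure_rngs(seed: int, n: int):
    """Independent, reproducible per-exposure random streams from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_mesi_stack(config: SimulationConfig) -> SpeckleStack:
    """Simulate one time-integrated frame per configured exposure time.

    Exposures use statistically independent streams derived from the master
    seed, so the stack is bit-reproducible for a given config.
    """
    rngs = _exposure_rngs(config.seed, len(config.exposure_times))
    frames = []
    sat = []
    for T, rng in zip(config.exposure_times, rngs):
        frame = integrate_exposure(config, T, rng)
        if config.quantize:
            frame, s = quantize(frame, config.bit_depth, config.mean_fill_fraction)
            sat.append(s)
        frames.append(frame)
    return SpeckleStack(
        frames=np.stack(frames),
        exposure_time_per_frame=np.asarray(config.exposure_times, dtype=float),
        quantized=config.quantize,
        bit_depth=config.bit_depth if config.quantize else None,
        provenance=(
            f"simulated MESI stack: tau_c={config.decorrelation.tau_c} ms "
            f"({config.decorrelation.form}), {config.px_per_speckle} px/speckle, "
            f"{config.n_polarization} polarization channel(s), seed={config.seed}"
        ),
        saturation_fractions=tuple(sat) if sat else None,
    )


def simulate_two_region_stack(
    config: SimulationConfig,
    inner_decorrelation: DecorrelationSpec,
    inner_mask: np.ndarray,
) -> SpeckleStack:
    """Composite stack: ``inner_mask`` pixels follow ``inner_decorrelation``.

    Emulates a vessel-in-parenchyma geometry by stitching, per exposure, two
    independently simulated homogeneous frames along a boolean mask.  Window
    statistics are only exact away from the boundary; regions of interest
    should stay inside each region.
    """
    inner_mask = np.asarray(inner_mask, dtype=bool)
    if inner_mask.shape != tuple(config.image_shape):
        raise ValueError("inner_mask shape must match image_shape")
    if not inner_mask.any() or inner_mask.all():
        raise ValueError("inner_mask must be a proper non-empty subset of the image")
    inner_cfg = replace(config, decorrelation=inner_decorrelation)
    outer_rngs = _exposure_rngs(config.seed, len(config.exposure_times))
    inner_rngs = _exposure_rngs(config.seed + 1, len(config.exposure_times))
    frames = []
    for T, r_out, r_in in zip(config.exposure_times, outer_rngs, inner_rngs):
        outer = integrate_exposure(config, T, r_out)
        inner = integrate_exposure(inner_cfg, T, r_in)
        frame = np.where(inner_mask, inner, outer)
        if config.quantize:
            frame, _ = quantize(frame, config.bit_depth, config.mean_fill_fraction)
        frames.append(frame)
    return SpeckleStack(
        frames=np.stack(frames),
        exposure_time_per_frame=np.asarray(config.exposure_times, dtype=float),
        quantized=config.quantize,
        bit_depth=config.bit_depth if config.quantize else None,
        provenance=(
            f"two-region composite: outer tau_c={config.decorrelation.tau_c} ms, "
            f"inner tau_c={inner_decorrelation.tau_c} ms, seed={config.seed}"
        ),
    )
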