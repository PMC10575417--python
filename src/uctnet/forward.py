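"""Time-domain finite-difference acoustic wave propagation.

Solves the variable-density acoustic wave equation

    rho(r) div( (1/rho(r)) grad p ) = (1/c(r)^2) d^2 p / dt^2

with a 2nd-order leapfrog scheme in time and a 2nd- or 4th-order stencil in
space on a collocated grid; 1/rho is averaged harmonically onto cell faces so
the discrete divergence form stays symmetric (which is what gives the solver
its source-receiver reciprocity). A ``constant_density`` switch reduces the
operator to the plain Laplacian form c^2 lap(p).

Each survey shot injects a zero-phase Ricker wavelet additively at one sensor
cell (scaled by dt^2 c^2, the conventional monopole source) and records the
pressure at every sensor cell each time step. Outgoing energy is absorbed by
an exponential sponge taper at the grid edge. Shots are simulated on a fresh
zero field, so there is no cross-talk between consecutive excitations
regardless of record length.

The analytic 3D free-space Green's function exp(ikR)/(4 pi R) is provided as
a correctness oracle: amplitude falls off as 1/(4 pi R), which the FD solver
must reproduce in a homogeneous medium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

from .phantom import HeadPhantom, SensorArray

__all__ = [
    "SourceWavelet",
    "SimConfig",
    "ShotRecord",
    "SurveyData",
    "ricker_wavelet",
    "stable_dt",
    "default_sim_config",
    "simulate_shot",
    "simulate_survey",
    "green3d_analytic",
]

_EXPLOSION_FACTOR = 1e6  # |p| beyond this multiple of the peak source is an instability


@dataclass(frozen=True)
class SourceWavelet:
    """Peak-normalized zero-phase excitation pulse."""

    samples: np.ndarray  # pressure amplitude, max |.| == 1
    dt: float  # s
    center_frequency: float  # Hz
    center_index: int  # sample index of the peak

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", s)
        if s.size < 3:
            raise ValueError("wavelet too short")
        peak = float(np.max(np.abs(s)))
        if peak != 0.0 and not math.isclose(peak, 1.0, rel_tol=1e-12):
            raise ValueError("wavelet must be peak-normalized (or identically zero)")

    @property
    def duration(self) -> float:
        return self.samples.size * self.dt

    @property
    def center_delay(self) -> float:
        """Time of the wavelet peak relative to the start of injection (s)."""
        return self.center_index * self.dt

    def resampled(self, dt: float) -> "SourceWavelet":
        """Linearly resample onto a new time step (used to match solver dt)."""
        t_old = np.arange(self.samples.size) * self.dt
        n_new = int(round(self.duration / dt))
        t_new = np.arange(n_new) * dt
        s = np.interp(t_new, t_old, self.samples)
        peak = np.max(np.abs(s))
        if peak > 0:
            s /= peak
        return SourceWavelet(
            samples=s,
            dt=dt,
            center_frequency=self.center_frequency,
            center_index=int(np.argmax(np.abs(s))),
        )


@dataclass(frozen=True)
class SimConfig:
    """Discretization and boundary parameters of one simulation."""

    dt: float  # s
    n_steps: int
    cfl_safety: float = 0.6
    sponge_width: int = 20  # cells
    sponge_strength: float = 0.015
    spatial_order: int = 2  # 2 | 4
    constant_density: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.n_steps < 1:
            raise ValueError("dt and n_steps must be positive")
        if self.sponge_width < 0:
            raise ValueError("sponge_width must be >= 0")
        if self.spatial_order not in (2, 4):
            raise ValueError("spatial_order must be 2 or 4")


@dataclass
class ShotRecord:
    """Traces of one excitation: pressure at every receiver over time."""

    source_index: int
    traces: np.ndarray  # (n_receivers, n_steps)
    dt: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("shot traces contain non-finite values (solver blow-up?)")


@dataclass
class SurveyData:
    """The full shot-gather cube: every sensor fires once, all record."""

    shots: list
    sensors: SensorArray
    wavelet: SourceWavelet
    dt: float

    def __post_init__(self) -> None:
        if len(self.shots) != self.sensors.count:
            raise ValueError("need exactly one shot per sensor")
        for s in self.shots:
            if s.traces.shape[0] != self.sensors.count:
                raise ValueError("each shot must record at every sensor")
            if s.dt != self.dt:
                raise ValueError("all shots must share dt")

    @property
    def n_sensors(self) -> int:
        return self.sensors.count

    @property
    def n_steps(self) -> int:
        return int(self.shots[0].traces.shape[1])

    def trace(self, source: int, receiver: int) -> np.ndarray:
        return self.shots[source].traces[receiver]


def ricker_wavelet(f0: float, dt: float, duration: float) -> SourceWavelet:
    """Zero-phase Ricker pulse (1 - 2 pi^2 f0^2 t^2) exp(-pi^2 f0^2 t^2).

    The pulse is centered in the window, peak-normalized (the Ricker already
    peaks at 1 at t=0). ``duration`` must cover the +-3/f0 support within
    which the pulse decays to numerical zero.
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    if dt >= 1.0 / (4.0 * f0):
        raise ValueError("dt too coarse to sample the wavelet (need dt < 1/(4 f0))")
    if duration < 6.0 / f0:
        raise ValueError("duration too short for the +-3/f0 wavelet support")
    n = int(round(duration / dt))
    center = n // 2
    t = (np.arange(n) - center) * dt
    a = (np.pi * f0 * t) ** 2
    samples = (1.0 - 2.0 * a) * np.exp(-a)
    return SourceWavelet(samples=samples, dt=dt, center_frequency=f0, center_index=center)


def stable_dt(
    spacing_mm: float, c_max: float, safety: float = 0.6, dimensionality: int = 2,
    spatial_order: int = 2,
) -> float:
    """CFL-stable time step for the leapfrog scheme.

    2nd order in space: dt = safety * h / (c_max * sqrt(ndim)).
    4th order: the stencil's spectral radius tightens the bound by
    sum|w| = 4/3 relative to 2nd order (standard result for the
    (-1/12, 4/3, -5/2, 4/3, -1/12) stencil).
    """
    if spacing_mm <= 0 or c_max <= 0 or safety <= 0:
        raise ValueError("arguments must be positive")
    if safety > 1:
        raise ValueError("safety must be <= 1")
    h = spacing_mm * 1e-3  # m
    dt = safety * h / (c_max * math.sqrt(dimensionality))
    if spatial_order == 4:
        dt *= math.sqrt(3.0 / 4.0)
    return dt


def default_sim_config(
    phantom: HeadPhantom,
    record_time: Optional[float] = None,
    cfl_safety: float = 0.6,
    sponge_width: int = 20,
    sponge_strength: float = 0.015,
    spatial_order: int = 2,
    constant_density: bool = False,
) -> SimConfig:
    """SimConfig with CFL-stable dt and the default record length.

    Record length defaults to max(0.2 ms, 2.5 x the longest straight-ray
    traversal time at the water velocity): the 0.2 ms floor guarantees that
    residual energy from one excitation has left the aperture before the next
    record would start, and the traversal factor guarantees full-aperture
    coverage on large grids.
    """
    c_max = float(phantom.velocity.max())
    dt = stable_dt(phantom.spacing, c_max, cfl_safety, phantom.ndim, spatial_order)
    if record_time is None:
        diag_mm = math.sqrt(sum((n * phantom.spacing) ** 2 for n in phantom.shape))
        c_min = float(phantom.velocity.min())
        record_time = max(0.2e-3, 2.5 * diag_mm * 1e-3 / c_min)
    return SimConfig(
        dt=dt,
        n_steps=int(math.ceil(record_time / dt)),
        cfl_safety=cfl_safety,
        sponge_width=sponge_width,
        sponge_strength=sponge_strength,
        spatial_order=spatial_order,
        constant_density=constant_density,
    )


def _sponge_taper(shape: Tuple[int, ...], width: int, strength: float) -> Optional[np.ndarray]:
    """Cerjan-style multiplicative damping mask, 1 in the interior."""
    if width <= 0:
        return None
    mask = np.ones(shape, dtype=np.float64)
    for ax, n in enumerate(shape):
        prof = np.ones(n)
        ramp = np.exp(-((strength * (width - np.arange(width))) ** 2))
        prof[:width] = ramp
        prof[n - width:] = ramp[::-1]
        sl = [None] * len(shape)
        sl[ax] = slice(None)
        mask *= prof[tuple(sl)]
    return mask


def _laplacian_const(p: np.ndarray, h2: float, order: int, ndim_spatial: int) -> np.ndarray:
    """Laplacian over the trailing ``ndim_spatial`` axes (batch leading axis)."""
    out = np.zeros_like(p)
    for ax in range(p.ndim - ndim_spatial, p.ndim):
        if order == 2:
            out += (np.roll(p, 1, axis=ax) - 2.0 * p + np.roll(p, -1, axis=ax)) / h2
        else:
            out += (
                -np.roll(p, 2, axis=ax) / 12.0
                + 4.0 / 3.0 * np.roll(p, 1, axis=ax)
                - 2.5 * p
                + 4.0 / 3.0 * np.roll(p, -1, axis=ax)
                - np.roll(p, -2, axis=ax) / 12.0
            ) / h2
    return out


def _vardensity_div(p: np.ndarray, buoy_faces: list, h2: float) -> np.ndarray:
    """div((1/rho) grad p) with harmonic face-averaged buoyancy (2nd order).

    buoy_faces[ax] has the spatial shape of p with one fewer cell along ax and
    holds 1/rho averaged onto the face between cell i and i+1.
    """
    nsp = len(buoy_faces)
    out = np.zeros_like(p)
    for ax_sp, bf in enumerate(buoy_faces):
        ax = p.ndim - nsp + ax_sp
        diff = np.diff(p, axis=ax)  # p[i+1]-p[i] on faces
        flux = bf * diff
        # divergence: flux[i] - flux[i-1] at cell i, zero-flux at the two ends
        pad = [(0, 0)] * p.ndim
        pad[ax] = (1, 1)
        flux = np.pad(flux, pad)
        sl_hi = [slice(None)] * p.ndim
        sl_lo = [slice(None)] * p.ndim
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(0, -1)
        out += (flux[tuple(sl_hi)] - flux[tuple(sl_lo)]) / h2
    return out


def _propagate(
    phantom: HeadPhantom,
    source_cells: np.ndarray,  # (n_src, ndim) cell indices, one field per source
    receiver_cells: np.ndarray,  # (n_rec, ndim)
    wavelet: SourceWavelet,
    cfg: SimConfig,
) -> np.ndarray:
    """Advance one independent wavefield per source; return (n_src, n_rec, n_steps)."""
    c = phantom.velocity
    h = phantom.spacing * 1e-3  # m
    h2 = h * h
    cfl = cfg.dt * float(c.max()) * math.sqrt(phantom.ndim) / h
    limit = 1.0 if cfg.spatial_order == 2 else math.sqrt(3.0 / 4.0)
    if cfl > limit * (1.0 + 1e-9):
        raise ValueError(f"dt violates the CFL bound (Courant number {cfl:.3f} > {limit:.3f})")

    n_src = source_cells.shape[0]
    shape = (n_src,) + phantom.shape
    dtype = np.float64
    p_prev = np.zeros(shape, dtype=dtype)
    p_curr = np.zeros(shape, dtype=dtype)

    c2dt2 = (c.astype(dtype) * cfg.dt) ** 2  # broadcast over batch
    taper = _sponge_taper(phantom.shape, cfg.sponge_width, cfg.sponge_strength)

    buoy_faces = None
    if not cfg.constant_density:
        rho = phantom.density.astype(dtype)
        b = 1.0 / rho
        buoy_faces = []
        for ax in range(phantom.ndim):
            sl_lo = [slice(None)] * phantom.ndim
            sl_hi = [slice(None)] * phantom.ndim
            sl_lo[ax] = slice(0, -1)
            sl_hi[ax] = slice(1, None)
            # harmonic mean of rho == arithmetic mean of buoyancy at the face
            buoy_faces.append(0.5 * (b[tuple(sl_lo)] + b[tuple(sl_hi)]))
        rho_full = rho

    wav = wavelet.samples if wavelet.dt == cfg.dt else wavelet.resampled(cfg.dt).samples
    src_idx = (np.arange(n_src),) + tuple(source_cells.T)
    rec_idx = tuple(receiver_cells.T)

    traces = np.empty((n_src, receiver_cells.shape[0], cfg.n_steps), dtype=dtype)
    explosion = _EXPLOSION_FACTOR

    for step in range(cfg.n_steps):
        if buoy_faces is None:
            lap = _laplacian_const(p_curr, h2, cfg.spatial_order, phantom.ndim)
            p_next = 2.0 * p_curr - p_prev + c2dt2 * lap
        else:
            div = _vardensity_div(p_curr, buoy_faces, h2)
            p_next = 2.0 * p_curr - p_prev + c2dt2 * rho_full * div
        if step < wav.size:
            p_next[src_idx] += c2dt2[tuple(source_cells.T)] * wav[step] / h2
        if taper is not None:
            p_next *= taper
            p_curr *= taper
        p_prev, p_curr = p_curr, p_next
        traces[:, :, step] = p_curr[(slice(None),) + rec_idx]
        if step % 200 == 0:
            m = float(np.max(np.abs(p_curr)))
            if not math.isfinite(m) or m > explosion:
                raise RuntimeError(f"wavefield exploded at step {step} (max |p| = {m:.3g})")
    if not np.all(np.isfinite(traces)):
        raise RuntimeError("non-finite values in recorded traces")
    return traces


def simulate_shot(
    phantom: HeadPhantom,
    source_position: Sequence[float],
    sensors: SensorArray,
    wavelet: SourceWavelet,
    cfg: SimConfig,
    source_index: int = 0,
) -> ShotRecord:
    """Propagate one excitation and record traces at all sensors."""
    src = np.floor(np.asarray(source_position, dtype=float) / phantom.spacing).astype(np.int64)
    for k, n in enumerate(phantom.shape):
        if not (0 <= src[k] < n):
            raise ValueError("source position outside the grid")
    rec = sensors.cell_indices(phantom.spacing)
    traces = _propagate(phantom, src[None, :], rec, wavelet, cfg)[0]
    return ShotRecord(source_index=source_index, traces=traces, dt=cfg.dt)


def simulate_survey(
    phantom: HeadPhantom,
    sensors: SensorArray,
    wavelet: SourceWavelet,
    cfg: SimConfig,
    progress: Optional[Callable[[int, int], None]] = None,
    batch_size: int = 16,
) -> SurveyData:
    """Fire every sensor once, recording at all sensors each time.

    Shots are mutually independent wavefields (each starts from a zero field),
    which realizes the required inter-record separation exactly. Internally
    shots are advanced in batches that share the stencil work.
    """
    cells = sensors.cell_indices(phantom.spacing)
    n = sensors.count
    shots: list = [None] * n
    for start in range(0, n, batch_size):
        stop = min(start + batch_size, n)
        try:
            block = _propagate(phantom, cells[start:stop], cells, wavelet, cfg)
        except RuntimeError as exc:
            raise RuntimeError(f"shot batch [{start}, {stop}) failed: {exc}") from exc
        for i in range(start, stop):
            shots[i] = ShotRecord(source_index=i, traces=block[i - start], dt=cfg.dt)
        if progress is not None:
            progress(stop, n)
    return SurveyData(shots=shots, sensors=sensors, wavelet=wavelet, dt=cfg.dt)


def green3d_analytic(k: float, R: float) -> complex:
    """Free-space 3D Helmholtz Green's function exp(ikR) / (4 pi R)."""
    if R <= 0:
        raise ValueError("R must be positive (Green's function is singular at R=0)")
    return complex(np.exp(1j * k * R) / (4.0 * np.pi * R))
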