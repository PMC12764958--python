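"""Synthetic skin phantoms, PORH hemodynamics and simulated raw scans.

Everything downstream (reconstruction, segmentation, biomarker extraction,
cohort statistics) is testable against known ground truth produced here:

* voxelized skin phantoms — a melanin surface layer plus cylindrical vessels
  at epidermal/subpapillary/reticular depths;
* a post-occlusive reactive hyperemia (PORH) modulation curve with
  closed-form biomarker truths (baseline level 1, occlusion floor
  ``1 - mvc_true``, peak ``1/(1 - hr_true)`` exactly at
  ``t_release + tp_true``);
* a linear optoacoustic forward model (bipolar N-shaped pulses, 50 MHz
  Gaussian transducer response, 60 degree acceptance cone) producing raw
  sinograms;
* synthetic cohorts whose per-subject biomarker truths are drawn from
  truncated normal distributions parameterized by printed group statistics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .recon import AcquisitionGeometry, RawScan, sensitivity_weight

__all__ = [
    "PORHProtocol",
    "LONG_PROTOCOL",
    "SHORT_PROTOCOL",
    "Vessel",
    "PhantomSpec",
    "Phantom",
    "generate_phantom",
    "HemodynamicParams",
    "hemodynamic_modulation",
    "simulate_raw_scan",
    "line_scan_positions",
    "raster_scan_positions",
    "CohortPreset",
    "COHORT_PRESETS",
    "CohortResult",
    "draw_cohort_truths",
    "generate_cohort",
    "simulate_frame_sinograms",
    "two_layer_phantom",
    "load_phantom_spec",
    "load_preset",
]

LAYER_CODES = {"BG": 0, "EP": 1, "SD": 2, "RD": 3}


# --------------------------------------------------------------------------
# PORH protocol
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PORHProtocol:
    """Timing of a post-occlusive reactive hyperemia test.

    The long protocol is 2 min baseline / 5 min arterial occlusion / 3 min
    rest (marks at 2/7/10 min); the short protocol is 1/3/2 min (marks at
    1/4/6 min).  Frames are acquired every ``frame_interval_s`` seconds
    (one frame per second by default, 0.5 s supported by the scanner).
    """

    t_baseline_end_min: float = 2.0
    t_release_min: float = 7.0
    t_total_min: float = 10.0
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.t_baseline_end_min < self.t_release_min < self.t_total_min:
            raise ValueError("require 0 < baseline end < release < total")
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be positive")

    def times_min(self) -> np.ndarray:
        """Frame time stamps in minutes, covering [0, t_total]."""
        dt = self.frame_interval_s / 60.0
        n = int(np.floor(self.t_total_min / dt + 1e-9)) + 1
        return np.arange(n) * dt

    @property
    def occlusion_min(self) -> float:
        return self.t_release_min - self.t_baseline_end_min


LONG_PROTOCOL = PORHProtocol(2.0, 7.0, 10.0, 1.0)
SHORT_PROTOCOL = PORHProtocol(1.0, 4.0, 6.0, 1.0)


# --------------------------------------------------------------------------
# phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Vessel:
    """Cylindrical absorber along the slow axis: center (x, z) in um within
    the cross-section, radius in um, optical absorption in a.u., and the skin
    layer it belongs to ('EP', 'SD' or 'RD')."""

    x_um: float
    z_um: float
    radius_um: float
    absorption: float = 1.0
    layer: str = "SD"

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("vessel radius must be positive")
        if self.layer not in LAYER_CODES:
            raise ValueError(f"unknown layer {self.layer!r}")


@dataclass
class PhantomSpec:
    """Geometry of a skin phantom volume.

    ``melanin`` is (depth offset um, thickness um, absorption); vessels are
    cylinders along the slow (y) axis.  The volume spans
    ``lateral_extent_mm`` x ``slow_extent_mm`` x ``depth_extent_mm``.
    """

    lateral_extent_mm: float = 1.5
    depth_extent_mm: float = 1.5
    slow_extent_mm: float = 0.1
    melanin: tuple[float, float, float] = (0.0, 60.0, 2.0)
    vessels: list[Vessel] = field(default_factory=list)
    voxel_um: tuple[float, float, float] = (12.0, 12.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.melanin[1] <= 0:
            raise ValueError("melanin thickness must be positive")
        if any(v <= 0 for v in self.voxel_um):
            raise ValueError("voxel sizes must be positive")


@dataclass
class Phantom:
    """Voxelized absorption map plus per-voxel layer labels and per-vessel
    metadata. Axes are (fast x, slow y, depth z)."""

    absorption: np.ndarray
    labels: np.ndarray
    voxel_um: tuple[float, float, float]
    vessels: list[Vessel]
    spec: PhantomSpec

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.absorption.shape

    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * v * 1e-3 for n, v in zip(self.shape, self.voxel_um))


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize a phantom spec onto its voxel grid (deterministic).

    Raises a ``ValueError`` naming the offending vessel if any cylinder does
    not fit inside the volume.
    """
    dx, dy, dz = spec.voxel_um
    nx = max(1, int(round(spec.lateral_extent_mm * 1000 / dx)))
    ny = max(1, int(round(spec.slow_extent_mm * 1000 / dy)))
    nz = max(1, int(round(spec.depth_extent_mm * 1000 / dz)))
    xc = (np.arange(nx) + 0.5) * dx
    zc = (np.arange(nz) + 0.5) * dz
    absorption = np.zeros((nx, ny, nz))
    labels = np.zeros((nx, ny, nz), dtype=np.uint8)

    m_off, m_thick, m_abs = spec.melanin
    mel = (zc >= m_off) & (zc < m_off + m_thick)
    absorption[:, :, mel] += m_abs
    labels[:, :, mel] = LAYER_CODES["EP"]

    x_max = spec.lateral_extent_mm * 1000
    z_max = spec.depth_extent_mm * 1000
    for i, v in enumerate(spec.vessels):
        if not (v.radius_um <= v.x_um <= x_max - v.radius_um
                and v.radius_um <= v.z_um <= z_max - v.radius_um):
            raise ValueError(
                f"vessel {i} (x={v.x_um} um, z={v.z_um} um, r={v.radius_um} um) "
                f"does not fit inside the {x_max:g} x {z_max:g} um volume"
            )
        mask = ((xc[:, None] - v.x_um) ** 2 + (zc[None, :] - v.z_um) ** 2
                <= v.radius_um ** 2)
        absorption[mask[:, None, :].repeat(ny, axis=1)] = v.absorption
        labels[mask[:, None, :].repeat(ny, axis=1)] = LAYER_CODES[v.layer]
    return Phantom(absorption=absorption, labels=labels, voxel_um=spec.voxel_um,
                   vessels=list(spec.vessels), spec=spec)


def two_layer_phantom(n_sd: int = 4, n_rd: int = 4, seed: int = 0,
                      lateral_mm: float = 1.5, depth_mm: float = 1.5,
                      voxel_um: tuple[float, float, float] = (24.0, 100.0, 12.0),
                      sd_depth_um: tuple[float, float] = (250.0, 550.0),
                      rd_depth_um: tuple[float, float] = (950.0, 1300.0),
                      radius_um: tuple[float, float] = (25.0, 50.0)) -> Phantom:
    """Convenience phantom with vessels in two dermal bands (deterministic
    for a fixed seed); used for image-level series with depth-dependent
    hemodynamics."""
    rng = np.random.default_rng(seed)
    vessels = []
    margin = radius_um[1] + 2 * voxel_um[0]
    for layer, n, (z0, z1) in (("SD", n_sd, sd_depth_um), ("RD", n_rd, rd_depth_um)):
        xs = np.linspace(margin, lateral_mm * 1000 - margin, n)
        xs = xs + rng.uniform(-0.4, 0.4) * (xs[1] - xs[0] if n > 1 else 0.0)
        for x in xs:
            vessels.append(Vessel(
                x_um=float(np.clip(x, margin, lateral_mm * 1000 - margin)),
                z_um=float(rng.uniform(z0, z1)),
                radius_um=float(rng.uniform(*radius_um)),
                absorption=1.0, layer=layer))
    spec = PhantomSpec(lateral_extent_mm=lateral_mm, depth_extent_mm=depth_mm,
                       slow_extent_mm=voxel_um[1] * 1e-3, melanin=(0.0, 60.0, 2.0),
                       vessels=vessels, voxel_um=voxel_um, seed=seed)
    return generate_phantom(spec)


# --------------------------------------------------------------------------
# hemodynamic modulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HemodynamicParams:
    """Ground-truth hemodynamics of one subject/layer.

    ``mvc_true`` in (0, 1) sets the occlusion floor ``1 - mvc_true``;
    ``hr_true`` in [0, 1) sets the hyperemic peak ``1/(1 - hr_true)``;
    ``tp_true`` (minutes) is the delay from cuff release to the peak.
    ``occlusion_decay_tau`` and ``recovery_tau`` (minutes) shape the decay
    toward the floor and the relaxation back to baseline;
    ``depth_tp_offset_s`` shifts the peak time (negative = earlier), used to
    emulate deeper vessels peaking before superficial ones.
    """

    mvc_true: float
    hr_true: float
    tp_true: float
    occlusion_decay_tau: float = 0.25
    recovery_tau: float = 1.0
    gamma_shape: float = 3.0
    depth_tp_offset_s: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.mvc_true < 1:
            raise ValueError("mvc_true must lie in (0, 1)")
        if not 0 <= self.hr_true < 1:
            raise ValueError("hr_true must lie in [0, 1)")
        if self.tp_true <= 0:
            raise ValueError("tp_true must be positive")
        if self.occlusion_decay_tau <= 0 or self.recovery_tau <= 0:
            raise ValueError("time constants must be positive")

    @property
    def piv_true(self) -> float:
        """Peak of the normalized curve, 1/(1 - hr_true) >= 1."""
        return 1.0 / (1.0 - self.hr_true)

    @property
    def floor_true(self) -> float:
        """Occlusion plateau, 1 - mvc_true."""
        return 1.0 - self.mvc_true

    def effective_tp_min(self) -> float:
        return self.tp_true + self.depth_tp_offset_s / 60.0


def hemodynamic_modulation(params: HemodynamicParams, protocol: PORHProtocol,
                           t) -> np.ndarray | float:
    """Dimensionless intensity scale factor at time ``t`` (minutes).

    Piecewise continuous curve: constant 1 during baseline; exponential decay
    toward the floor ``1 - mvc_true`` during occlusion; after release a
    gamma-variate-weighted blend between an exponential relaxation toward 1
    and the peak value, which attains its global maximum ``1/(1 - hr_true)``
    exactly at ``t_release + tp`` and relaxes toward 1 afterward.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if np.any(t_arr < -1e-9) or np.any(t_arr > protocol.t_total_min + 1e-9):
        raise ValueError(
            f"time outside protocol range [0, {protocol.t_total_min}] min")
    tb, tr = protocol.t_baseline_end_min, protocol.t_release_min
    mvc, tau_o = params.mvc_true, params.occlusion_decay_tau
    out = np.ones_like(t_arr)

    occ = (t_arr >= tb) & (t_arr < tr)
    out[occ] = 1.0 - mvc * (1.0 - np.exp(-(t_arr[occ] - tb) / tau_o))

    post = t_arr >= tr
    if np.any(post):
        tau = t_arr[post] - tr
        tp = max(params.effective_tp_min(), 1e-6)
        v_release = 1.0 - mvc * (1.0 - np.exp(-(tr - tb) / tau_o))
        backbone = 1.0 + (v_release - 1.0) * np.exp(-tau / params.recovery_tau)
        g = np.zeros_like(tau)
        pos = tau > 0
        a = params.gamma_shape
        g[pos] = (tau[pos] / tp) ** a * np.exp(a * (1.0 - tau[pos] / tp))
        out[post] = (1.0 - g) * backbone + g * params.piv_true
    return float(out[0]) if scalar else out


# --------------------------------------------------------------------------
# optoacoustic forward model
# --------------------------------------------------------------------------

def line_scan_positions(geometry: AcquisitionGeometry, extent_mm: float,
                        y_mm: float = 0.0) -> np.ndarray:
    """Fast-axis line scan positions across ``extent_mm`` at the configured
    fast-axis step, at slow-axis coordinate ``y_mm``."""
    step = geometry.step_fast_um * 1e-3
    n = max(2, int(np.floor(extent_mm / step)) + 1)
    x = (np.arange(n) + 0.5) * (extent_mm / n)
    return np.column_stack([x, np.full(n, y_mm)])


def raster_scan_positions(geometry: AcquisitionGeometry, extent_x_mm: float,
                          extent_y_mm: float) -> np.ndarray:
    """3D raster: fast axis at step_fast_um, slow axis at step_slow_um."""
    sx = geometry.step_fast_um * 1e-3
    sy = geometry.step_slow_um * 1e-3
    nx = max(2, int(np.floor(extent_x_mm / sx)) + 1)
    ny = max(1, int(np.floor(extent_y_mm / sy)) + 1)
    x = (np.arange(nx) + 0.5) * (extent_x_mm / nx)
    y = (np.arange(ny) + 0.5) * (extent_y_mm / max(ny, 1))
    X, Y = np.meshgrid(x, y, indexing="ij")
    return np.column_stack([X.ravel(order="F"), Y.ravel(order="F")])


def _pulse_template(geometry: AcquisitionGeometry, source_radius_um: float,
                    sigma_mhz: float = 30.0) -> np.ndarray:
    """Band-limited bipolar N-pulse of a uniform spherical absorber.

    The ideal time-domain response of a uniform sphere of radius ``a`` is a
    bipolar ramp ``p(tau) = -tau`` for ``|tau| <= a/c`` (an "N" shape) with
    amplitude proportional to ``a``.  It is band-limited by a Gaussian
    transducer response centered at the 50 MHz central frequency.
    """
    a_us = source_radius_um * 1e-3 / geometry.c_mm_us  # half-duration, us
    dt = geometry.dt_us
    half = max(4, int(np.ceil(4.0 * a_us / dt)), int(np.ceil(0.2 / dt)))
    tau = (np.arange(-half, half + 1)) * dt
    n_pulse = np.where(np.abs(tau) <= a_us, -tau / max(a_us, dt), 0.0)
    n_pulse *= source_radius_um * 1e-3  # amplitude scales with source size
    # Gaussian band-limitation around the central frequency
    f = np.fft.rfftfreq(n_pulse.size, d=dt)  # MHz
    h = np.exp(-0.5 * ((f - geometry.center_freq_mhz) / sigma_mhz) ** 2)
    return np.fft.irfft(np.fft.rfft(n_pulse) * h, n=n_pulse.size)


def simulate_raw_scan(phantom: Phantom, geometry: AcquisitionGeometry,
                      noise_sd: float = 0.0, seed: int = 0,
                      positions_mm: Optional[np.ndarray] = None,
                      n_samples: Optional[int] = None,
                      frame_index: int = 0, time_min: float = 0.0) -> RawScan:
    """Simulate one raw scan of a phantom (linear in absorption).

    Every voxelized absorber contributes a band-limited N-shaped pulse
    centered at its time of flight (distance / speed of sound), with
    amplitude scaled by absorption, source size, spherical spreading (1/r)
    and the transducer sensitivity (zero outside the 60 degree acceptance
    cone).  Additive white Gaussian noise of the given standard deviation is
    applied last; the result is deterministic for a fixed seed.  An empty
    phantom yields a noise-only sinogram.
    """
    ex, ey, ez = phantom.extent_mm()
    if positions_mm is None:
        positions_mm = line_scan_positions(geometry, ex, y_mm=ey / 2.0)
    positions_mm = np.asarray(positions_mm, dtype=float)

    dxv, dyv, dzv = phantom.voxel_um
    a_vox = (3.0 * dxv * dyv * dzv / (4.0 * np.pi)) ** (1.0 / 3.0)
    template = _pulse_template(geometry, a_vox)
    margin = template.size

    if n_samples is None:
        span_x = max(ex, positions_mm[:, 0].max()) + ex
        span_y = max(ey, np.abs(positions_mm[:, 1]).max()) + ey
        d_max = np.sqrt(span_x ** 2 + span_y ** 2
                        + (ez + geometry.focal_depth_mm) ** 2)
        n_samples = int(np.ceil(d_max / geometry.c_mm_us / geometry.dt_us)) + margin

    sino = np.zeros((len(positions_mm), n_samples + margin))
    idx = np.argwhere(phantom.absorption != 0)
    if idx.size:
        vx = (idx[:, 0] + 0.5) * dxv * 1e-3
        vy = (idx[:, 1] + 0.5) * dyv * 1e-3
        vz = (idx[:, 2] + 0.5) * dzv * 1e-3
        amp0 = phantom.absorption[idx[:, 0], idx[:, 1], idx[:, 2]]
        for p, (px, py) in enumerate(positions_mm):
            lateral = np.hypot(vx - px, vy - py)
            dz = vz + geometry.focal_depth_mm
            dist = np.hypot(lateral, dz)
            w = sensitivity_weight(geometry, lateral, vz)
            keep = w > 0
            if not np.any(keep):
                continue
            tof = dist[keep] / geometry.c_mm_us / geometry.dt_us
            amp = amp0[keep] * w[keep] / dist[keep]
            i0 = np.floor(tof).astype(np.int64)
            frac = tof - i0
            ok = (i0 >= 0) & (i0 < n_samples + margin - 1)
            np.add.at(sino[p], i0[ok], amp[ok] * (1.0 - frac[ok]))
            np.add.at(sino[p], i0[ok] + 1, amp[ok] * frac[ok])
        # convolve impulse field with the band-limited N-pulse (shared template)
        from scipy.signal import fftconvolve
        sino = fftconvolve(sino, template[None, :], mode="same", axes=1)
    sino = sino[:, :n_samples]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sino = sino + rng.normal(0.0, noise_sd, size=sino.shape)
    return RawScan(sinogram=sino, positions_mm=positions_mm, geometry=geometry,
                   frame_index=frame_index, time_min=time_min)


def simulate_frame_sinograms(phantom: Phantom,
                             layer_params: dict[str, HemodynamicParams],
                             protocol: PORHProtocol,
                             geometry: AcquisitionGeometry,
                             noise_sd: float = 0.0, seed: int = 0,
                             times_min: Optional[np.ndarray] = None,
                             ) -> tuple[np.ndarray, Iterator[RawScan]]:
    """Lazily simulate an fRSOM frame series of a hemodynamically modulated
    phantom.

    Vessels of each labeled layer are scaled by that layer's modulation
    curve; the melanin (EP) layer stays constant, serving as the intensity
    reference.  The forward model's linearity lets each frame be assembled
    from per-layer component sinograms computed once, so a full-protocol
    series is cheap; noise is drawn fresh per frame (deterministic for a
    fixed seed).  Returns (frame times in minutes, iterator of RawScan).
    """
    if times_min is None:
        times_min = protocol.times_min()
    labels_present = [name for name, code in LAYER_CODES.items()
                      if code and np.any(phantom.labels == code)]
    components = {}
    n_samples = None
    for name in labels_present:
        sub = dataclasses.replace(
            phantom,
            absorption=np.where(phantom.labels == LAYER_CODES[name],
                                phantom.absorption, 0.0))
        comp = simulate_raw_scan(sub, geometry, noise_sd=0.0,
                                 n_samples=n_samples)
        n_samples = comp.n_samples
        components[name] = comp
    first = components[labels_present[0]]
    rng = np.random.default_rng(seed)

    def frames() -> Iterator[RawScan]:
        for k, t in enumerate(times_min):
            sino = np.zeros_like(first.sinogram)
            for name in labels_present:
                if name in layer_params:
                    scale = hemodynamic_modulation(layer_params[name], protocol,
                                                   float(t))
                else:
                    scale = 1.0  # e.g. the melanin reference layer
                sino += scale * components[name].sinogram
            if noise_sd > 0:
                sino = sino + rng.normal(0.0, noise_sd, size=sino.shape)
            yield RawScan(sinogram=sino, positions_mm=first.positions_mm,
                          geometry=geometry, frame_index=k, time_min=float(t))

    return np.asarray(times_min, dtype=float), frames()


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass
class CohortPreset:
    """Per-layer biomarker distributions (mean, sd) of one study group.

    ``layers`` maps a layer label ('DV', 'SD', 'RD') to a dict with keys
    'mvc' (a.u.), 'hr_pct' (percent) and 'tp_min' (minutes), each a
    (mean, sd) tuple in the printed units.
    """

    name: str
    layers: dict[str, dict[str, tuple[float, float]]]
    n_subjects: int = 10

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for layer, marks in self.layers.items():
            for key, (mean, sd) in marks.items():
                if sd < 0:
                    raise ValueError(f"{self.name}/{layer}/{key}: sd must be >= 0")
            m = marks["mvc"][0]
            if not 0 < m < 1:
                raise ValueError(f"{self.name}/{layer}: mvc mean outside (0,1)")
            h = marks["hr_pct"][0]
            if not 0 <= h < 100:
                raise ValueError(f"{self.name}/{layer}: hr mean outside [0,100)")
            if marks["tp_min"][0] <= 0:
                raise ValueError(f"{self.name}/{layer}: tp mean must be positive")


# Group statistics as printed for the smoker and cardiovascular-disease
# studies (mean, sd); MVC in a.u. on MVB-normalized profiles, HR in percent,
# TP in minutes.
COHORT_PRESETS: dict[str, CohortPreset] = {
    "smoker": CohortPreset("smoker", {
        "DV": {"mvc": (0.34, 0.082), "hr_pct": (9.54, 4.37), "tp_min": (1.89, 0.38)},
        "SD": {"mvc": (0.26, 0.095), "hr_pct": (7.67, 3.52), "tp_min": (1.77, 0.38)},
        "RD": {"mvc": (0.38, 0.079), "hr_pct": (10.52, 2.83), "tp_min": (2.01, 0.41)},
    }),
    "non_smoker": CohortPreset("non_smoker", {
        "DV": {"mvc": (0.48, 0.062), "hr_pct": (20.38, 4.43), "tp_min": (1.42, 0.40)},
        "SD": {"mvc": (0.44, 0.054), "hr_pct": (19.65, 4.84), "tp_min": (1.29, 0.40)},
        "RD": {"mvc": (0.49, 0.063), "hr_pct": (20.62, 7.94), "tp_min": (1.46, 0.37)},
    }),
    "cvd": CohortPreset("cvd", {
        "DV": {"mvc": (0.16, 0.048), "hr_pct": (7.13, 3.41), "tp_min": (2.18, 0.20)},
        "SD": {"mvc": (0.11, 0.024), "hr_pct": (4.91, 3.04), "tp_min": (2.05, 0.16)},
        "RD": {"mvc": (0.21, 0.073), "hr_pct": (9.16, 3.45), "tp_min": (2.36, 0.20)},
    }),
    "non_cvd": CohortPreset("non_cvd", {
        "DV": {"mvc": (0.38, 0.068), "hr_pct": (16.38, 2.99), "tp_min": (1.69, 0.27)},
        "SD": {"mvc": (0.34, 0.050), "hr_pct": (15.13, 3.21), "tp_min": (1.53, 0.26)},
        "RD": {"mvc": (0.40, 0.048), "hr_pct": (17.48, 3.69), "tp_min": (1.78, 0.31)},
    }),
}


def _truncated_normal(mean: float, sd: float, lo: float, hi: float, size: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Truncated (not clipped) normal draws on (lo, hi)."""
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def draw_cohort_truths(preset: CohortPreset, rng: np.random.Generator,
                       layers: Optional[list[str]] = None) -> pd.DataFrame:
    """Per-subject ground-truth biomarkers drawn from the preset's truncated
    normal distributions (mvc in (0,1), hr fraction in [0,1), tp > 0)."""
    layers = layers or list(preset.layers)
    rows = []
    for layer in layers:
        marks = preset.layers[layer]
        n = preset.n_subjects
        mvc = _truncated_normal(*marks["mvc"], 1e-3, 1 - 1e-3, n, rng)
        hr = _truncated_normal(marks["hr_pct"][0] / 100.0,
                               marks["hr_pct"][1] / 100.0, 0.0, 0.999, n, rng)
        tp = _truncated_normal(*marks["tp_min"], 1e-3, np.inf, n, rng)
        for s in range(n):
            rows.append({"subject_id": f"s{s + 1:02d}", "layer": layer,
                         "mvc_true": mvc[s], "hr_true": hr[s], "tp_true": tp[s]})
    return pd.DataFrame(rows)


@dataclass
class CohortResult:
    """Synthetic cohort: tidy per-frame profiles (or modulated phantom frames
    in image mode) plus the ground truths they were generated from."""

    truths: pd.DataFrame
    profiles: Optional[pd.DataFrame]
    frames: Optional[dict]
    preset: CohortPreset
    protocol: PORHProtocol
    mode: str


def generate_cohort(preset: CohortPreset, protocol: PORHProtocol,
                    noise_sd: float = 0.02, seed: int = 0,
                    mode: str = "profile",
                    layers: Optional[list[str]] = None,
                    phantom: Optional[Phantom] = None) -> CohortResult:
    """Generate a synthetic cohort with known ground-truth biomarkers.

    Profile mode emits noisy normalized layer intensity profiles directly
    (columns: subject_id, layer, t_min, intensity).  Image mode emits, per
    subject, a stack of 2D cross-sectional absorption frames of a phantom
    whose dermal layers are modulated by that subject's hemodynamics (dict
    subject_id -> array of shape (n_frames, nx, nz)).  Deterministic for a
    fixed seed.
    """
    if preset.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if mode not in ("profile", "image"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    truths = draw_cohort_truths(preset, rng, layers=layers)
    t = protocol.times_min()

    if mode == "profile":
        records = []
        for (sid, layer), row in truths.set_index(["subject_id", "layer"]).iterrows():
            params = HemodynamicParams(mvc_true=row["mvc_true"],
                                       hr_true=row["hr_true"],
                                       tp_true=row["tp_true"])
            y = hemodynamic_modulation(params, protocol, t)
            y = y + rng.normal(0.0, noise_sd, size=t.size)
            records.append(pd.DataFrame({"subject_id": sid, "layer": layer,
                                         "t_min": t, "intensity": y}))
        profiles = pd.concat(records, ignore_index=True)
        return CohortResult(truths=truths, profiles=profiles, frames=None,
                            preset=preset, protocol=protocol, mode=mode)

    if phantom is None:
        phantom = two_layer_phantom(seed=seed)
    frames: dict[str, np.ndarray] = {}
    wide = truths.pivot(index="subject_id", columns="layer")
    for sid in wide.index:
        stack = np.empty((t.size,) + (phantom.shape[0], phantom.shape[2]))
        layer_params = {}
        for layer in truths["layer"].unique():
            layer_params[layer] = HemodynamicParams(
                mvc_true=wide.loc[sid, ("mvc_true", layer)],
                hr_true=wide.loc[sid, ("hr_true", layer)],
                tp_true=wide.loc[sid, ("tp_true", layer)])
        for k, tk in enumerate(t):
            frame = phantom.absorption[:, phantom.shape[1] // 2, :].copy()
            for layer, params in layer_params.items():
                code = LAYER_CODES.get(layer)
                if code is None:
                    continue
                mask = phantom.labels[:, phantom.shape[1] // 2, :] == code
                frame[mask] *= hemodynamic_modulation(params, protocol, float(tk))
            if noise_sd > 0:
                frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
            stack[k] = frame
        frames[sid] = stack
    return CohortResult(truths=truths, profiles=None, frames=frames,
                        preset=preset, protocol=protocol, mode=mode)


# --------------------------------------------------------------------------
# YAML configuration
# --------------------------------------------------------------------------

def load_phantom_spec(path) -> PhantomSpec:
    """Read a PhantomSpec from YAML (vessels as lists of mappings)."""
    import yaml

    with open(path) as f:
        cfg = yaml.safe_load(f)
    vessels = [Vessel(**v) for v in cfg.pop("vessels", [])]
    if "melanin" in cfg:
        cfg["melanin"] = tuple(cfg["melanin"])
    if "voxel_um" in cfg:
        cfg["voxel_um"] = tuple(cfg["voxel_um"])
    return PhantomSpec(vessels=vessels, **cfg)


def load_preset(path) -> CohortPreset:
    """Read a CohortPreset from YAML."""
    import yaml

    with open(path) as f:
        cfg = yaml.safe_load(f)
    layers = {layer: {k: tuple(v) for k, v in marks.items()}
              for layer, marks in cfg["layers"].items()}
    return CohortPreset(name=cfg["name"], layers=layers,
                        n_subjects=int(cfg.get("n_subjects", 10)))
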