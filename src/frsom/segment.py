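"""Skin-surface flattening and depth partition into EP / SD / RD layers.

The melanin-rich epidermis produces a bright superficial band in
reconstructed images.  Its first arrival per lateral column defines the skin
surface; columns are shifted so the surface maps to depth 0 ("flattening"),
after which depth intervals partition the volume into epidermis (EP),
subpapillary dermis (SD) and reticular dermis (RD); DV denotes the whole
dermal vasculature SD + RD.

The EP/dermis boundary is located adaptively as the depth where the
laterally-averaged intensity falls below a set fraction of its superficial
peak, bounded to a configured plausible range; the SD/RD split is a fixed
configurable depth below the EP boundary (the anatomical split used by the
original analysis is unpublished).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .recon import ReconImage

__all__ = [
    "SkinSurface",
    "LayerBounds",
    "SegmentationError",
    "detect_surface",
    "flatten",
    "unflatten",
    "segment_layers",
    "layer_mask",
]

LAYER_NAMES = ("EP", "SD", "RD", "DV")


class SegmentationError(RuntimeError):
    """Raised when no skin surface can be detected."""


@dataclass
class SkinSurface:
    """Per-lateral-position surface depth (voxels and um) of shape (nx, ny)."""

    depth_vox: np.ndarray
    voxel_z_um: float
    smooth: int

    @property
    def depth_um(self) -> np.ndarray:
        return self.depth_vox * self.voxel_z_um


@dataclass(frozen=True)
class LayerBounds:
    """Contiguous depth intervals in flattened coordinates (um):
    EP = [0, d_ep), SD = [d_ep, d_ep + d_sd), RD = [d_ep + d_sd, d_max)."""

    d_ep_um: float
    d_sd_um: float
    d_max_um: float
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.d_ep_um < self.d_ep_um + self.d_sd_um < self.d_max_um:
            raise ValueError("layer intervals must be contiguous with positive length")

    def interval_um(self, layer: str) -> tuple[float, float]:
        if layer == "EP":
            return (0.0, self.d_ep_um)
        if layer == "SD":
            return (self.d_ep_um, self.d_ep_um + self.d_sd_um)
        if layer == "RD":
            return (self.d_ep_um + self.d_sd_um, self.d_max_um)
        if layer == "DV":
            return (self.d_ep_um, self.d_max_um)
        raise ValueError(f"unknown layer {layer!r}")

    def to_dict(self) -> dict:
        return {"d_ep_um": self.d_ep_um, "d_sd_um": self.d_sd_um,
                "d_max_um": self.d_max_um, "config": dict(self.config)}


def layer_mask(bounds: LayerBounds, z_centers_um: np.ndarray, layer: str) -> np.ndarray:
    """Boolean depth mask of a layer over voxel-center depths (um)."""
    lo, hi = bounds.interval_um(layer)
    z = np.asarray(z_centers_um)
    return (z >= lo) & (z < hi)


def detect_surface(image: ReconImage, frac: float = 0.3,
                   smooth: int = 7) -> SkinSurface:
    """Detect the skin surface from the bright superficial (melanin) band.

    Per lateral column, the surface is the first depth where intensity
    exceeds ``frac`` of that column's maximum (a relative threshold, so
    detection is invariant to global intensity scaling), median-smoothed
    laterally.

    Raises
    ------
    SegmentationError
        If more than 20% of columns never exceed the threshold.
    """
    data = image.data
    nx, ny, nz = data.shape
    col_max = data.max(axis=2)
    valid = col_max > 0
    thr = frac * np.where(valid, col_max, np.inf)
    above = data > thr[:, :, None]
    first = np.where(above.any(axis=2), above.argmax(axis=2), -1)
    valid &= first >= 0
    n_invalid = int(np.count_nonzero(~valid))
    if n_invalid > 0.2 * nx * ny:
        raise SegmentationError(
            f"surface undetectable on {n_invalid} of {nx * ny} columns")
    surface = first.astype(float)
    if n_invalid:
        fill = np.median(surface[valid])
        surface[~valid] = fill
    size = (smooth, 1) if ny == 1 else (smooth, smooth)
    surface = ndimage.median_filter(surface, size=size, mode="nearest")
    return SkinSurface(depth_vox=np.round(surface).astype(int),
                       voxel_z_um=image.grid.voxel_um[2], smooth=smooth)


def flatten(image: ReconImage, surface: SkinSurface) -> ReconImage:
    """Shift each column up so the detected surface maps to depth 0.

    Out-of-range voxels are zero-padded; the applied shifts are retained in
    the image metadata so :func:`unflatten` can invert the operation (up to
    edge padding).
    """
    data = image.data
    nx, ny, nz = data.shape
    if surface.depth_vox.shape != (nx, ny):
        raise ValueError("surface does not match image lateral shape")
    out = np.zeros_like(data)
    for i in range(nx):
        for j in range(ny):
            s = int(surface.depth_vox[i, j])
            if s <= 0:
                out[i, j] = data[i, j]
            else:
                out[i, j, : nz - s] = data[i, j, s:]
    meta = dict(image.meta)
    meta["flatten_shift_vox"] = surface.depth_vox.copy()
    return image.replace(data=out, meta=meta)


def unflatten(image: ReconImage) -> ReconImage:
    """Invert :func:`flatten` using the stored shifts (edge voxels that were
    padded away remain zero)."""
    shifts = image.meta.get("flatten_shift_vox")
    if shifts is None:
        raise ValueError("image carries no flattening metadata")
    data = image.data
    nx, ny, nz = data.shape
    out = np.zeros_like(data)
    for i in range(nx):
        for j in range(ny):
            s = int(shifts[i, j])
            if s <= 0:
                out[i, j] = data[i, j]
            else:
                out[i, j, s:] = data[i, j, : nz - s]
    meta = {k: v for k, v in image.meta.items() if k != "flatten_shift_vox"}
    return image.replace(data=out, meta=meta)


def segment_layers(flat: ReconImage, d_sd_um: float = 200.0,
                   ep_range_um: tuple[float, float] = (60.0, 200.0),
                   ep_default_um: float = 100.0,
                   ep_drop_frac: float = 0.5) -> LayerBounds:
    """Partition a flattened image's depth axis into EP / SD / RD.

    The EP/dermis boundary ``d_ep`` is the first depth at which the
    laterally-averaged intensity falls below ``ep_drop_frac`` of its
    superficial peak (peak searched within the plausible EP range).  A
    boundary outside ``ep_range_um`` falls back to ``ep_default_um`` with a
    warning.  The SD/RD split sits a fixed ``d_sd_um`` below the EP boundary.
    """
    data = flat.data
    dz = flat.grid.voxel_um[2]
    nz = data.shape[2]
    d_max = nz * dz
    profile = data.mean(axis=(0, 1))
    z = (np.arange(nz) + 0.5) * dz

    search = z <= ep_range_um[1]
    d_ep = None
    if np.any(search) and profile[search].max() > 0:
        k_peak = int(np.argmax(profile[search]))
        peak = profile[k_peak]
        below = np.nonzero(profile[k_peak:] < ep_drop_frac * peak)[0]
        if below.size:
            d_ep = float(z[k_peak + below[0]])
    if d_ep is None or not ep_range_um[0] <= d_ep <= ep_range_um[1]:
        warnings.warn(
            f"EP boundary {'undetected' if d_ep is None else f'{d_ep:.0f} um'} "
            f"outside plausible range {ep_range_um}; falling back to "
            f"{ep_default_um:.0f} um", stacklevel=2)
        d_ep = ep_default_um
    return LayerBounds(d_ep_um=d_ep, d_sd_um=d_sd_um, d_max_um=d_max,
                       config={"d_sd_um": d_sd_um, "ep_range_um": ep_range_um,
                               "ep_default_um": ep_default_um,
                               "ep_drop_frac": ep_drop_frac})
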