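import numpy as np
import pytest

from frsom import (AcquisitionGeometry, PhantomSpec, ReconGrid, Vessel,
                   generate_phantom)


@pytest.fixture(scope="session")
def geometry():
    """Test-scale geometry: coarser fast-axis step keeps sinograms small."""
    return AcquisitionGeometry(step_fast_um=30.0)


@pytest.fixture()
def point_phantom():
    """Single small absorber at (300, 400) um in a 0.6 x 0.8 mm section."""
    spec = PhantomSpec(lateral_extent_mm=0.6, depth_extent_mm=0.8,
                       slow_extent_mm=0.06, melanin=(0.0, 6.0, 0.0),
                       vessels=[Vessel(x_um=300, z_um=400, radius_um=10,
                                       absorption=1.0, layer="SD")],
                       voxel_um=(12.0, 60.0, 3.0))
    return generate_phantom(spec)


@pytest.fixture()
def point_grid():
    return ReconGrid(voxel_um=(12.0, 60.0, 3.0), extent_mm=(0.6, 0.06, 0.8))


def naive_delay_and_sum(raw, grid):
    """Brute-force triple-loop delay-and-sum oracle (pre-envelope).

    Intentionally written as plain loops over voxels and positions so that it
    shares no code path with the fast beamformer beyond the sensitivity
    weight definition.
    """
    from frsom import sensitivity_weight

    geom = raw.geometry
    nx, ny, nz = grid.shape
    xs, ys, zs = (grid.centers_mm(a) for a in range(3))
    out = np.zeros((nx, ny, nz))
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                acc = 0.0
                for p in range(raw.n_positions):
                    px, py = raw.positions_mm[p]
                    lat = np.hypot(xs[i] - px, ys[j] - py)
                    dz = zs[k] + geom.focal_depth_mm
                    dist = np.hypot(lat, dz)
                    w = float(sensitivity_weight(geom, lat, zs[k]))
                    if w <= 0:
                        continue
                    tof = dist / geom.c_mm_us / geom.dt_us
                    i0 = int(np.floor(tof))
                    if 0 <= i0 < raw.n_samples - 1:
                        frac = tof - i0
                        s = (raw.sinogram[p, i0] * (1 - frac)
                             + raw.sinogram[p, i0 + 1] * frac)
                        acc += w * s
                out[i, j, k] = acc
    return out
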