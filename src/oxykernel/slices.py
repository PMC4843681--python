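"""Simulated 2D histology: slab extraction, planar maps, 3D comparison.

A histological vessel stain reveals the endothelium inside a slab of
thickness ΔW around the cutting plane and collapses it to a single image
plane.  :func:`flatten_slab` reproduces that: segments whose axes
intersect the slab are clipped to it and their geometry projected onto
the central plane.  :func:`planar_oxygen_map` then runs the same 3D
kernel machinery on the flattened network, evaluated on the in-plane
grid, and :func:`compare_slice` tabulates how the 2D approximations
distort mean oxygen and hypoxic/anoxic fractions relative to the true
slice through the 3D map.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import PerfusionScenario
from .kernels import DEFAULT_SPACING, network_oxygen_map
from .network_io import VesselNetwork, VesselSegment
from .stats import compute_stats
from .volume_io import OxygenMap

__all__ = ["flatten_slab", "planar_grid", "planar_oxygen_map", "compare_slice"]

_MIN_PLANAR_LENGTH = 1e-3  # µm; floor for segments that flatten to a point


def flatten_slab(
    network: VesselNetwork, z_center: float, delta_w: float
) -> VesselNetwork:
    """Clip the network to the slab ``z_center ± ΔW/2`` and project the
    retained geometry onto the plane ``z = z_center``.

    Radii are preserved.  A segment crossing the slab perpendicular to the
    plane flattens to a near-point; it is retained with a minimal in-plane
    length so it remains a valid (if tiny) source.  Returns an empty
    planar network if nothing intersects the slab.
    """
    if not delta_w > 0:
        raise ValueError(f"slab thickness must be positive, got {delta_w}")
    z_lo, z_hi = z_center - delta_w / 2.0, z_center + delta_w / 2.0
    kept: list[VesselSegment] = []
    for seg in network:
        z1, z2 = seg.p1[2], seg.p2[2]
        if max(z1, z2) < z_lo or min(z1, z2) > z_hi:
            continue
        # clip parametrically in z (t in [0, 1] along p1 -> p2)
        t0, t1 = 0.0, 1.0
        dz = z2 - z1
        if dz != 0.0:
            ta, tb = (z_lo - z1) / dz, (z_hi - z1) / dz
            t0 = max(t0, min(ta, tb))
            t1 = min(t1, max(ta, tb))
        if t1 <= t0:
            continue
        q1 = seg.p1 + t0 * (seg.p2 - seg.p1)
        q2 = seg.p1 + t1 * (seg.p2 - seg.p1)
        q1[2] = q2[2] = z_center
        if np.linalg.norm(q2 - q1) < _MIN_PLANAR_LENGTH:
            mid = 0.5 * (q1 + q2)
            u = seg.p2[:2] - seg.p1[:2]
            n = np.linalg.norm(u)
            u = u / n if n > 0 else np.array([1.0, 0.0])
            q1 = mid - 0.5 * _MIN_PLANAR_LENGTH * np.array([u[0], u[1], 0.0])
            q2 = mid + 0.5 * _MIN_PLANAR_LENGTH * np.array([u[0], u[1], 0.0])
        kept.append(VesselSegment(q1, q2, seg.r_v, seg.id))
    meta = dict(network.metadata)
    meta.update(slab_z_center_um=z_center, slab_delta_w_um=delta_w)
    return VesselNetwork(kept, meta)


def planar_grid(
    lo_xy, hi_xy, voxel: float, z_center: float, meta: dict | None = None
) -> OxygenMap:
    """One-voxel-thick grid whose single z layer of voxel centres lies
    exactly in the plane ``z = z_center``."""
    lo = np.array([lo_xy[0], lo_xy[1], z_center - voxel / 2.0])
    hi = np.array([hi_xy[0], hi_xy[1], z_center + voxel / 2.0])
    return OxygenMap.from_box(lo, hi, voxel, meta)


def planar_oxygen_map(
    planar_network: VesselNetwork,
    scenario: PerfusionScenario,
    grid: OxygenMap,
    spacing: float = DEFAULT_SPACING,
) -> OxygenMap:
    """2D analogue of the 3D method: the same 3D kernels and normalization,
    with every source lying in the grid's single plane and the field
    evaluated on the in-plane voxel centres.

    An empty planar network yields the grid unchanged (all zero).
    """
    if grid.shape[2] != 1:
        raise ValueError(
            f"planar grid must be one voxel thick in z, got shape {grid.shape}"
        )
    if len(planar_network) == 0:
        return grid
    return network_oxygen_map(planar_network, scenario, grid, spacing)


def compare_slice(
    map3d: OxygenMap,
    z_index: int,
    planar_maps: dict[float, OxygenMap],
    hypoxia_max: float = 2.5,
) -> pd.DataFrame:
    """Tabulate oxygen statistics of the true 3D slice against each 2D
    approximation (keyed by slab thickness ΔW, µm).

    Rows: ``3d`` then one per ΔW in the given order; columns: mean, sd,
    hypoxic %, anoxic %.  All planar grids must match the 3D slice shape.
    """
    slice3d = map3d.values[:, :, z_index]
    rows = []
    st = compute_stats(slice3d, hypoxia_max=hypoxia_max)
    rows.append({"slice": "3d", "delta_w_um": np.nan, **_four_cols(st)})
    for dw, pm in planar_maps.items():
        if pm.values.shape[:2] != slice3d.shape:
            raise ValueError(
                f"planar map for ΔW={dw} has in-plane shape "
                f"{pm.values.shape[:2]}, expected {slice3d.shape}"
            )
        st = compute_stats(pm.values, hypoxia_max=hypoxia_max)
        rows.append(
            {"slice": f"2d_{dw:g}um", "delta_w_um": dw, **_four_cols(st)}
        )
    return pd.DataFrame(rows)


def _four_cols(st) -> dict:
    return {
        "mean_mmHg": st.mean,
        "sd_mmHg": st.sd,
        "hypoxic_pct": st.hypoxic_fraction,
        "anoxic_pct": st.anoxic_fraction,
    }
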