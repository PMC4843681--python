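"""Regular-grid oxygen maps and volumetric file I/O (NRRD, TIFF).

An :class:`OxygenMap` is a 3D scalar field of partial pressure (mmHg) on an
axis-aligned regular grid with cubic voxels.  Axis order is (x, y, z);
voxel centres sit at ``origin + (index + 0.5) * voxel``.

NRRD output uses the detached-header-free NRRD0004 layout with raw
little-endian float64 payload so that values and grid metadata round-trip
bit-exactly; scenario provenance travels in custom ``key:=value`` fields.
TIFF output is a multi-page float32 stack (one page per z slice) via
tifffile, with grid metadata in the image description.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["OxygenMap", "write_nrrd", "read_nrrd", "write_tiff_stack"]


@dataclass
class OxygenMap:
    """Partial-pressure field (mmHg) on a regular grid.

    Attributes
    ----------
    origin:
        Minimum corner of the grid (µm) — not the first voxel centre.
    voxel:
        Isotropic voxel edge length (µm).
    values:
        Array of shape (nx, ny, nz), axis order x, y, z.
    meta:
        Free-form provenance strings (scenario, spacing, ...).
    """

    origin: np.ndarray
    voxel: float
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got shape {self.values.shape}")
        if not self.voxel > 0:
            raise ValueError(f"voxel size must be positive, got {self.voxel}")

    @classmethod
    def empty(cls, origin, shape, voxel: float, meta: dict | None = None):
        return cls(origin, voxel, np.zeros(tuple(shape)), meta or {})

    @classmethod
    def from_box(cls, lo, hi, voxel: float, meta: dict | None = None):
        """Grid covering the box [lo, hi] (µm); extent rounded up to whole
        voxels, anchored at ``lo``."""
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        if np.any(hi <= lo):
            raise ValueError("box upper corner must exceed lower corner")
        shape = np.maximum(np.ceil((hi - lo) / voxel - 1e-9).astype(int), 1)
        return cls.empty(lo, shape, voxel, meta)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_centres(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel

    def centre_grids(self, sl: tuple[slice, slice, slice] | None = None):
        """Broadcastable voxel-centre coordinate arrays (X, Y, Z) for the
        whole grid or an index slice of it."""
        if sl is None:
            sl = (slice(None),) * 3
        axes = []
        for ax in range(3):
            c = self.axis_centres(ax)[sl[ax]]
            shape = [1, 1, 1]
            shape[ax] = c.size
            axes.append(c.reshape(shape))
        return tuple(axes)

    def sample(self, points, mode: str = "linear"):
        """Sample the field at continuous points (µm) by trilinear (default)
        or nearest-voxel interpolation.  Points outside the grid raise."""
        from scipy.interpolate import RegularGridInterpolator

        pts = np.atleast_2d(np.asarray(points, dtype=float))
        interp = RegularGridInterpolator(
            tuple(self.axis_centres(ax) for ax in range(3)),
            self.values,
            method="linear" if mode == "linear" else "nearest",
        )
        out = interp(pts)
        return float(out[0]) if np.asarray(points).ndim == 1 else out


def write_nrrd(omap: OxygenMap, path) -> None:
    """Write the map as NRRD0004 (raw little-endian float64)."""
    path = Path(path)
    nx, ny, nz = omap.shape
    header = [
        "NRRD0004",
        "# oxygen partial-pressure map (mmHg); axes x y z in micrometres",
        "type: double",
        "dimension: 3",
        "space: left-posterior-superior",
        f"sizes: {nx} {ny} {nz}",
        "space directions: "
        f"({omap.voxel},0,0) (0,{omap.voxel},0) (0,0,{omap.voxel})",
        "kinds: domain domain domain",
        "endian: little",
        "encoding: raw",
        "space origin: ({},{},{})".format(*(repr(float(v)) for v in omap.origin)),
        f"oxykernel_voxel_um:={float(omap.voxel)!r}",
    ]
    for key, val in omap.meta.items():
        header.append(f"oxykernel_{key}:={val}")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n\n").encode())
        fh.write(np.ascontiguousarray(omap.values, dtype="<f8").tobytes(order="F"))


def read_nrrd(path) -> OxygenMap:
    """Read a map written by :func:`write_nrrd`."""
    path = Path(path)
    with open(path, "rb") as fh:
        raw = fh.read()
    head, _, payload = raw.partition(b"\n\n")
    fields: dict[str, str] = {}
    meta: dict[str, str] = {}
    for line in head.decode().splitlines()[1:]:
        if not line or line.startswith("#"):
            continue
        if ":=" in line:
            key, val = line.split(":=", 1)
            if key.startswith("oxykernel_"):
                meta[key[len("oxykernel_"):]] = val
        elif ":" in line:
            key, val = line.split(":", 1)
            fields[key.strip()] = val.strip()
    if fields.get("encoding") != "raw" or fields.get("type") != "double":
        raise ValueError(f"{path}: unsupported NRRD variant")
    shape = tuple(int(s) for s in fields["sizes"].split())
    origin = [float(v) for v in fields["space origin"].strip("()").split(",")]
    voxel = float(meta.pop("voxel_um"))
    values = np.frombuffer(payload, dtype="<f8").reshape(shape, order="F").copy()
    return OxygenMap(origin, voxel, values, meta)


def write_tiff_stack(omap: OxygenMap, path) -> None:
    """Write the map as a multi-page float32 TIFF, one page per z slice
    (page index = z, rows = y, columns = x)."""
    import tifffile

    desc = json.dumps(
        {
            "origin_um": list(omap.origin),
            "voxel_um": omap.voxel,
            "axes_pages_rows_cols": "z y x",
            **{k: str(v) for k, v in omap.meta.items()},
        }
    )
    stack = np.ascontiguousarray(omap.values.T, dtype=np.float32)  # (z, y, x)
    tifffile.imwrite(path, stack, description=desc)
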