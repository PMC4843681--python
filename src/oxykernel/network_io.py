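"""Vessel-network containers and tabular I/O.

A network is a flat list of straight cylindrical segments, each defined by
two 3D endpoints and a radius, all in micrometres.  This is the geometry a
segmentation/skeletonization pipeline hands over; curved vessels are
polyline approximations made of several straight segments.

File formats:

* CSV — one row per segment, header ``x1,y1,z1,x2,y2,z2,r`` (µm), comma
  separated, '.' decimal, UTF-8.  An optional ``id`` column carries labels.
* JSON — ``{"units": "um", "metadata": {...}, "segments": [{"p1": [...],
  "p2": [...], "r": ..., "id": ...}, ...]}``.

Both round-trip segment tables losslessly (repr-exact floats).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VesselSegment",
    "VesselNetwork",
    "NetworkParseError",
    "read_network",
    "write_network",
    "skeleton_to_segments",
]

CSV_COLUMNS = ["x1", "y1", "z1", "x2", "y2", "z2", "r"]


class NetworkParseError(ValueError):
    """Raised when a network file or table fails validation."""


@dataclass(frozen=True)
class VesselSegment:
    """Straight cylindrical vessel segment: endpoints ``p1``, ``p2`` (µm)
    and radius ``r_v`` (µm)."""

    p1: np.ndarray
    p2: np.ndarray
    r_v: float
    id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "p1", np.asarray(self.p1, dtype=float).reshape(3))
        object.__setattr__(self, "p2", np.asarray(self.p2, dtype=float).reshape(3))
        if not self.r_v > 0:
            raise ValueError(f"segment radius must be positive, got {self.r_v}")
        if self.length == 0.0:
            raise ValueError("degenerate segment: endpoints coincide")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p2 - self.p1))

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from p1 to p2."""
        return (self.p2 - self.p1) / self.length

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.p1 + self.p2)


@dataclass
class VesselNetwork:
    """A collection of vessel segments with provenance metadata."""

    segments: list[VesselSegment]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.segments = list(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(min corner, max corner) over all endpoints, µm."""
        if not self.segments:
            raise ValueError("empty network has no bounding box")
        pts = np.array([p for s in self.segments for p in (s.p1, s.p2)])
        return pts.min(axis=0), pts.max(axis=0)

    @property
    def max_radius(self) -> float:
        return max(s.r_v for s in self.segments)

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "x1": [s.p1[0] for s in self.segments],
            "y1": [s.p1[1] for s in self.segments],
            "z1": [s.p1[2] for s in self.segments],
            "x2": [s.p2[0] for s in self.segments],
            "y2": [s.p2[1] for s in self.segments],
            "z2": [s.p2[2] for s in self.segments],
            "r": [s.r_v for s in self.segments],
        }
        frame = pd.DataFrame(rows)
        if any(s.id is not None for s in self.segments):
            frame["id"] = [s.id for s in self.segments]
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, metadata: dict | None = None):
        missing = [c for c in CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise NetworkParseError(f"missing columns: {missing}")
        segments = []
        for i, row in enumerate(frame.itertuples(index=False)):
            try:
                seg = VesselSegment(
                    p1=(row.x1, row.y1, row.z1),
                    p2=(row.x2, row.y2, row.z2),
                    r_v=float(row.r),
                    id=str(row.id) if "id" in frame.columns else None,
                )
            except (ValueError, TypeError) as exc:
                raise NetworkParseError(f"row {i}: {exc}") from exc
            segments.append(seg)
        if not segments:
            raise NetworkParseError("network table contains no segments")
        return cls(segments, metadata or {})


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "json"):
        return suffix
    raise NetworkParseError(f"cannot infer network format from {path.name!r}")


def read_network(path, fmt: str | None = None) -> VesselNetwork:
    """Read a vessel network from CSV or JSON (format inferred from the
    suffix unless given). Row order is preserved; units are µm."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        try:
            frame = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise NetworkParseError(f"{path}: empty network file") from exc
        return VesselNetwork.from_frame(frame, {"source": str(path)})
    if fmt == "json":
        with open(path) as fh:
            doc = json.load(fh)
        segs = doc.get("segments", [])
        if not segs:
            raise NetworkParseError(f"{path}: no segments in JSON document")
        segments = []
        for i, rec in enumerate(segs):
            try:
                segments.append(
                    VesselSegment(rec["p1"], rec["p2"], float(rec["r"]), rec.get("id"))
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise NetworkParseError(f"segment {i}: {exc}") from exc
        return VesselNetwork(segments, doc.get("metadata", {}))
    raise NetworkParseError(f"unsupported format {fmt!r}")


def write_network(network: VesselNetwork, path, fmt: str | None = None) -> None:
    """Write a network to CSV or JSON, losslessly (inverse of
    :func:`read_network`)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        network.to_frame().to_csv(path, index=False)
    elif fmt == "json":
        doc = {
            "units": "um",
            "metadata": network.metadata,
            "segments": [
                {
                    "p1": list(s.p1),
                    "p2": list(s.p2),
                    "r": s.r_v,
                    **({"id": s.id} if s.id is not None else {}),
                }
                for s in network.segments
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    else:
        raise NetworkParseError(f"unsupported format {fmt!r}")


def skeleton_to_segments(nodes: dict, edges) -> VesselNetwork:
    """Convert a skeleton graph to a segment network.

    Parameters
    ----------
    nodes:
        Mapping ``label -> (position (3,), radius)`` in µm.
    edges:
        Iterable of ``(label_a, label_b)`` pairs.

    One segment per edge; the segment radius is the mean of the two node
    radii (skeleton pipelines report a per-node thickness from a distance
    map; averaging is the symmetric per-edge aggregate).
    """
    segments = []
    for i, (a, b) in enumerate(edges):
        if a not in nodes or b not in nodes:
            raise NetworkParseError(f"edge {i} ({a!r}, {b!r}) references unknown node")
        pa, ra = nodes[a]
        pb, rb = nodes[b]
        segments.append(
            VesselSegment(pa, pb, 0.5 * (float(ra) + float(rb)), id=f"{a}-{b}")
        )
    if not segments:
        raise NetworkParseError("skeleton has no edges")
    return VesselNetwork(segments, {"source": "skeleton"})
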