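"""Seeded synthetic vessel networks.

Stand-ins for microscopy-derived tumour vessel maps: collections of
straight segments with radii spanning capillaries to venules, optionally
chained into tortuous polyline paths.  Two presets emulate the scale of
published tumour stacks — a 104-segment 555×525×215 µm carcinoma block and
a 357-segment 425×425×272 µm confocal stack — plus the canonical single
straight vessel (200 µm long, 5 µm radius) used for worked examples.

Randomness comes from :class:`numpy.random.Generator` seeded with PCG64,
so a fixed seed reproduces the identical network on any platform.
Coordinates are rounded to 1e-6 µm for file-format stability.
"""

from __future__ import annotations

import numpy as np

from .network_io import VesselNetwork, VesselSegment

__all__ = ["canonical_vessel", "random_network", "preset_network", "PRESETS"]

PRESETS = {
    # name: (n_segments, box dims µm)
    "rat": (104, (555.0, 525.0, 215.0)),
    "mouse": (357, (425.0, 425.0, 272.0)),
}


def canonical_vessel(box: float = 400.0) -> VesselNetwork:
    """Single straight 200 µm vessel of radius 5 µm, axis along z, centred
    in a cubic box of the given side (µm)."""
    c = box / 2.0
    seg = VesselSegment((c, c, c - 100.0), (c, c, c + 100.0), 5.0, id="canonical")
    return VesselNetwork([seg], {"preset": "single", "box_um": [box] * 3})


def random_network(
    seed: int,
    n_segments: int,
    box,
    radius_range: tuple[float, float] = (1.0, 50.0),
    length_range: tuple[float, float] = (10.0, 200.0),
    tortuosity: float = 0.5,
) -> VesselNetwork:
    """Reproducible random network of straight segments inside a box.

    Radii are log-uniform in ``radius_range`` (vessel calibres are roughly
    log-distributed), lengths uniform in ``length_range``.  With
    probability ``tortuosity`` a segment continues the previous one from
    its endpoint with a perturbed direction, forming tortuous polyline
    paths; otherwise it starts at a fresh uniform position.  All endpoints
    lie inside the box.
    """
    if n_segments < 1:
        raise ValueError(f"need at least one segment, got {n_segments}")
    box = np.asarray(box, dtype=float)
    if box.shape != (3,) or np.any(box <= 0):
        raise ValueError(f"box must be three positive extents, got {box}")
    r_lo, r_hi = radius_range
    l_lo, l_hi = length_range
    if not (0 < r_lo <= r_hi and 0 < l_lo <= l_hi):
        raise ValueError(
            f"infeasible ranges: radii {radius_range}, lengths {length_range}"
        )
    if l_lo > np.linalg.norm(box):
        raise ValueError("minimum length exceeds the box diagonal")
    if not 0.0 <= tortuosity <= 1.0:
        raise ValueError(f"tortuosity must be in [0, 1], got {tortuosity}")

    rng = np.random.default_rng(seed)
    segments: list[VesselSegment] = []
    prev_end: np.ndarray | None = None
    prev_dir: np.ndarray | None = None
    prev_r: float | None = None
    while len(segments) < n_segments:
        chain = prev_end is not None and rng.random() < tortuosity
        start = prev_end if chain else rng.uniform(0.0, 1.0, 3) * box
        length = rng.uniform(l_lo, l_hi)
        end = None
        for _ in range(64):
            if chain and prev_dir is not None:
                d = prev_dir + 0.6 * rng.standard_normal(3)
            else:
                d = rng.standard_normal(3)
            norm = np.linalg.norm(d)
            if norm == 0.0:
                continue
            cand = start + (d / norm) * length
            if np.all(cand >= 0.0) and np.all(cand <= box):
                end = cand
                direction = d / norm
                break
        if end is None:
            # crowded corner: restart from a fresh interior position
            prev_end = prev_dir = prev_r = None
            continue
        radius = (
            prev_r
            if chain and prev_r is not None
            else float(np.exp(rng.uniform(np.log(r_lo), np.log(r_hi))))
        )
        seg = VesselSegment(
            np.round(start, 6), np.round(end, 6), radius, id=f"s{len(segments)}"
        )
        segments.append(seg)
        prev_end, prev_dir, prev_r = end, direction, radius
    return VesselNetwork(
        segments,
        {
            "preset": "random",
            "seed": seed,
            "box_um": list(box),
            "rng": "numpy PCG64",
        },
    )


def preset_network(name: str, seed: int = 1, **kwargs) -> VesselNetwork:
    """Named fixture network: ``single`` (canonical vessel), ``rat`` or
    ``mouse`` scale presets."""
    if name == "single":
        return canonical_vessel()
    try:
        n, box = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; expected one of 'single', "
            + ", ".join(repr(k) for k in PRESETS)
        )
    net = random_network(seed, n, box, **kwargs)
    net.metadata["preset"] = name
    return net
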