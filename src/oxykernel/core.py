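"""Analytical line-source oxygen model.

A perfused vessel is treated as a continuum of spherical point sources of
oxygen along its axis.  Each point source obeys steady-state diffusion with
uniform consumption, with the boundary conditions that the partial pressure
and its gradient both vanish at the diffusion distance ``r_n`` from the
source.  Integrating the point solution along the axis gives a closed-form
line-source pressure field.  The model is calibrated per perfusion scenario
by demanding the reference wall pressure ``p_o`` at the wall of a reference
capillary (radius ``r_o``, diffusion distance ``r_n``); all physiological
constants (diffusion coefficient, consumption rate, per-length source
strength, Henry's-law conversion) collapse into a single composite source
strength ``kappa`` and are never used individually.

Units: geometry in micrometres, pressure in mmHg, ``kappa`` in mmHg/µm³.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PhysioConstants",
    "PerfusionScenario",
    "LineSourceGeometry",
    "point_source_pressure",
    "line_source_pressure",
    "calibrate",
    "high_perfusion",
    "low_perfusion",
    "scenario_by_name",
    "scaled_diffusion_distance",
    "diffusion_distance_table",
    "wall_pressure_short_segment",
    "longitudinal_drop",
]


@dataclass(frozen=True)
class PhysioConstants:
    """Physiological constants retained as metadata only.

    The oxygen diffusion coefficient ``D`` (m²/s), Henry's-law conversion
    ``Omega``, tissue consumption rate ``a`` and per-length source strength
    ``s_L`` are mutually degenerate in this model: only the composite
    strength ``kappa`` of a calibrated :class:`PerfusionScenario` enters any
    computation.
    """

    D: float = 2e-9
    Omega: float | None = None
    a: float | None = None
    s_L: float | None = None


@dataclass(frozen=True)
class PerfusionScenario:
    """A named boundary-condition set for the oxygen model.

    Parameters
    ----------
    name:
        Label, conventionally ``"high"`` (well perfused: wall pressure
        40 mmHg, diffusion distance 150 µm) or ``"low"`` (poorly perfused:
        20 mmHg, 100 µm).
    p_o:
        Partial pressure at the wall of the reference capillary (mmHg).
    r_n:
        Diffusion distance from the reference capillary (µm).
    r_o:
        Reference capillary radius (µm).
    kappa:
        Composite source strength (mmHg/µm³); ``None`` until calibrated.
    """

    name: str
    p_o: float
    r_n: float
    r_o: float = 5.0
    kappa: float | None = None
    constants: PhysioConstants = field(default_factory=PhysioConstants)

    def __post_init__(self) -> None:
        if not self.p_o > 0:
            raise ValueError(f"wall pressure p_o must be positive, got {self.p_o}")
        if not self.r_n > self.r_o > 0:
            raise ValueError(
                f"need r_n > r_o > 0, got r_n={self.r_n}, r_o={self.r_o}"
            )
        if self.kappa is not None and not self.kappa > 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")

    @property
    def calibrated(self) -> bool:
        return self.kappa is not None

    def require_kappa(self) -> float:
        if self.kappa is None:
            raise ValueError(
                f"scenario {self.name!r} is not calibrated; call calibrate() first"
            )
        return self.kappa


@dataclass(frozen=True)
class LineSourceGeometry:
    """Axial integration limits for a line source, relative to the foot of
    the perpendicular from the field point to the axis.

    Limits are clipped to the maximal contributing half-length
    ``z_m = sqrt(r_n² − d²)`` at evaluation time; ``±inf`` therefore means
    "the whole effectively infinite vessel".
    """

    z_a: float = -math.inf
    z_b: float = math.inf

    def __post_init__(self) -> None:
        if self.z_a > self.z_b:
            raise ValueError(f"require z_a <= z_b, got ({self.z_a}, {self.z_b})")

    @classmethod
    def full(cls) -> "LineSourceGeometry":
        return cls()

    @classmethod
    def half_length(cls, z_l: float) -> "LineSourceGeometry":
        """Symmetric limits ±z_l for a segment of length L = 2·z_l centred
        on the foot of the perpendicular."""
        if z_l < 0:
            raise ValueError(f"half-length must be non-negative, got {z_l}")
        return cls(-z_l, z_l)


FULL_LENGTH = LineSourceGeometry.full()


def point_source_pressure(r, r_n: float, kappa: float):
    """Pressure-density contribution of a unit-length point source.

    ``kappa · (r² + 2·r_n³/r − 3·r_n²)`` for ``r ≤ r_n`` and exactly 0
    beyond: the steady-state spherical diffusion solution with uniform
    consumption, zero pressure and zero flux at ``r_n``, diverging like
    1/r towards the source.

    Parameters
    ----------
    r:
        Radial distance from the source (µm), scalar or array, strictly
        positive (the solution is singular at the source itself).
    r_n:
        Diffusion distance of the source (µm).
    kappa:
        Composite source strength (mmHg/µm³).
    """
    if not r_n > 0:
        raise ValueError(f"r_n must be positive, got {r_n}")
    if kappa < 0:
        raise ValueError(f"kappa must be non-negative, got {kappa}")
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("point_source_pressure is singular at r <= 0")
    inside = r < r_n
    out = np.zeros_like(r)
    ri = r[inside]
    out[inside] = kappa * (ri * ri + 2.0 * r_n**3 / ri - 3.0 * r_n**2)
    return out if out.ndim else float(out)


def _line_antiderivative(z, d, r_n: float, kappa: float):
    """Antiderivative G(z) of the point-source kernel along the axis with
    r = sqrt(d² + z²):  G(z) = κ(d²·z + z³/3 + 2·r_n³·asinh(z/d) − 3·r_n²·z)."""
    return kappa * (
        d * d * z + z**3 / 3.0 + 2.0 * r_n**3 * np.arcsinh(z / d) - 3.0 * r_n**2 * z
    )


def line_source_pressure(
    d,
    r_n: float,
    kappa: float,
    geometry: LineSourceGeometry = FULL_LENGTH,
):
    """Partial pressure at perpendicular distance ``d`` from a line source.

    Closed-form integral of :func:`point_source_pressure` along the axis,
    with the axial limits of ``geometry`` clipped to ``±z_m`` where
    ``z_m = sqrt(r_n² − d²)`` bounds the contributing length.  Returns 0
    for ``d ≥ r_n``.  Vectorized over ``d``.
    """
    if not r_n > 0:
        raise ValueError(f"r_n must be positive, got {r_n}")
    if kappa < 0:
        raise ValueError(f"kappa must be non-negative, got {kappa}")
    d_arr = np.asarray(d, dtype=float)
    scalar = d_arr.ndim == 0
    d_arr = np.atleast_1d(d_arr)
    if np.any(d_arr <= 0):
        raise ValueError("line_source_pressure is singular on the axis (d <= 0)")
    out = np.zeros_like(d_arr)
    inside = d_arr < r_n
    if np.any(inside):
        di = d_arr[inside]
        z_m = np.sqrt(r_n * r_n - di * di)
        z_a = np.clip(geometry.z_a, -z_m, z_m)
        z_b = np.clip(geometry.z_b, -z_m, z_m)
        vals = _line_antiderivative(z_b, di, r_n, kappa) - _line_antiderivative(
            z_a, di, r_n, kappa
        )
        out[inside] = np.maximum(vals, 0.0)
    return float(out[0]) if scalar else out


def calibrate(scenario: PerfusionScenario) -> PerfusionScenario:
    """Fix the composite strength ``kappa`` from the scenario's reference
    condition: an effectively infinite vessel of radius ``r_o`` with
    diffusion distance ``r_n`` must show ``p_o`` at its wall."""
    unit = line_source_pressure(scenario.r_o, scenario.r_n, 1.0)
    return replace(scenario, kappa=scenario.p_o / unit)


def high_perfusion() -> PerfusionScenario:
    """Well-perfused scenario: 40 mmHg at the wall, 150 µm diffusion
    distance from a 5 µm reference capillary."""
    return calibrate(PerfusionScenario("high", p_o=40.0, r_n=150.0, r_o=5.0))


def low_perfusion() -> PerfusionScenario:
    """Poorly perfused scenario: 20 mmHg at the wall, 100 µm diffusion
    distance from a 5 µm reference capillary."""
    return calibrate(PerfusionScenario("low", p_o=20.0, r_n=100.0, r_o=5.0))


def scenario_by_name(name: str) -> PerfusionScenario:
    try:
        return {"high": high_perfusion, "low": low_perfusion}[name]()
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}; expected 'high' or 'low'")


def scaled_diffusion_distance(r_v: float, scenario: PerfusionScenario) -> float:
    """Effective diffusion distance ``r_f`` of a vessel of radius ``r_v``.

    Solves ``line_source_pressure(r_v, r_f, kappa) = p_o`` for ``r_f`` by
    bracketed Brent search: larger vessels push oxygen further under the
    same boundary condition, in analogy with the Krogh cylinder.
    """
    if not r_v > 0:
        raise ValueError(f"vessel radius must be positive, got {r_v}")
    kappa = scenario.require_kappa()
    p_o = scenario.p_o

    def deficit(r_f: float) -> float:
        return line_source_pressure(r_v, r_f, kappa) - p_o

    lo, hi = r_v * 1.0001, 10.0 * scenario.r_n
    f_lo, f_hi = deficit(lo), deficit(hi)
    if not f_lo < 0 < f_hi:
        raise RuntimeError(
            "diffusion-distance root not bracketed in "
            f"[{lo:.4g}, {hi:.4g}] µm for r_v={r_v} (f={f_lo:.3g}, {f_hi:.3g})"
        )
    return brentq(deficit, lo, hi, xtol=1e-9, rtol=8.9e-16)


def diffusion_distance_table(radii, scenarios=None):
    """Effective diffusion distances for a range of vessel radii.

    Returns a :class:`pandas.DataFrame` with column ``r_v_um`` and one
    ``r_f_<name>_um`` column per scenario (default: high and low).
    """
    import pandas as pd

    if scenarios is None:
        scenarios = [high_perfusion(), low_perfusion()]
    data = {"r_v_um": list(radii)}
    for sc in scenarios:
        data[f"r_f_{sc.name}_um"] = [
            scaled_diffusion_distance(r_v, sc) for r_v in radii
        ]
    return pd.DataFrame(data)


def wall_pressure_short_segment(
    L: float, r_v: float, r_f: float, scenario: PerfusionScenario
) -> float:
    """Partial pressure at the wall of a segment of finite length ``L``.

    A wall point receives contributions from axial positions within
    ``sqrt(r_f² − r_v²)`` of its perpendicular foot; if the half-length
    ``L/2`` reaches that far the wall sees the full reference pressure
    ``p_o``, otherwise the truncated line integral gives a strictly lower
    pressure.  Continuous and monotone non-decreasing in ``L``.
    """
    if not L > 0:
        raise ValueError(f"segment length must be positive, got {L}")
    if not 0 < r_v < r_f:
        raise ValueError(f"need 0 < r_v < r_f, got r_v={r_v}, r_f={r_f}")
    kappa = scenario.require_kappa()
    z_l = L / 2.0
    z_crit = math.sqrt(r_f * r_f - r_v * r_v)
    if z_l >= z_crit:
        return scenario.p_o
    return line_source_pressure(
        r_v, r_f, kappa, LineSourceGeometry.half_length(z_l)
    )


def longitudinal_drop(
    length: float, gradient: float = 0.07, gradient_sd: float = 0.04
) -> tuple[float, float]:
    """Estimated intravascular pressure drop along a vessel of given length.

    Reporting utility only: the drop (mean, sd) = (gradient·L, sd·L) is
    quoted alongside maps but never applied inside them, since flow
    direction is not part of the model's inputs.  Default gradient
    0.07 ± 0.04 mmHg/µm (measured longitudinal capillary gradient).
    """
    if length < 0:
        raise ValueError(f"length must be non-negative, got {length}")
    return (gradient * length, gradient_sd * length)
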