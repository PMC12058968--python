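"""Torque-balance analyses for idealized sheet geometries.

A probe particle sits at the edge of a sheet of particles that all share one
orientation (taken parallel to the sheet edge, or to the symmetry axis for
the triangular tip).  The net interaction torque on the probe as a function
of its orientation angle follows from summing the pair torque

    T0 [ sin(phi_sheet - alpha) - (1/ratio) sin(theta) ]

over the sheet region within the interaction radius R — a continuum integral
for uniform sheets (2D Gauss-Legendre product quadrature in polar
coordinates) or a lattice sum for the hexagonally packed sheet.  The stable
orientation is the root of the net torque with negative slope; because T0
multiplies the whole expression, the root depends only on the
alignment-to-cohesion ratio.

For the uniform half-plane the integral is elementary,

    T(alpha) ∝ -pi sin(alpha) - (2/ratio) cos(alpha),

so the stable tilt is -atan(2 / (pi * ratio)), inward toward the sheet;
this closed form serves as the quadrature's cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq

from .params import R_C

__all__ = [
    "SheetGeometry",
    "net_torque_on_probe",
    "stable_orientation",
    "tilt_vs_radius",
    "halfplane_tilt_exact",
]

#: hex-packing number density at spacing r_c, 2 / (sqrt(3) a^2)
HEX_DENSITY = 2.0 / (math.sqrt(3.0) * R_C**2)


@dataclass(frozen=True)
class SheetGeometry:
    """Idealized sheet with a probe at its edge (or apex).

    kind: ``uniform_halfplane`` (continuum sheet filling the half-plane on
    ``interior_side`` of the edge through the probe), ``hex_packed_halfplane``
    (rows of a triangular lattice at ``spacing``, the probe being an edge-row
    site), or ``uniform_triangle`` (continuum wedge of half-angle
    ``apex_half_angle`` behind the probe at its tip).  The sheet particles
    are oriented along +x; ``R`` is the interaction radius in sigma.
    """

    kind: str = "uniform_halfplane"
    R: float = 2.0 * R_C
    ratio: float = 2.0
    T0: float = 1.0
    density: float = HEX_DENSITY
    spacing: float = R_C
    apex_half_angle: float = math.pi / 6.0
    interior_side: int = -1  # -1: sheet below the edge (y < 0); +1: above

    KINDS = ("uniform_halfplane", "hex_packed_halfplane", "uniform_triangle")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown geometry kind {self.kind!r}")
        if self.R <= 0 or self.ratio <= 0:
            raise ValueError("R and ratio must be positive")
        if self.interior_side not in (-1, 1):
            raise ValueError("interior_side must be -1 or +1")


def _torque_from_sites(alpha: float, sx: np.ndarray, sy: np.ndarray,
                       weights: np.ndarray, T0: float, ratio: float) -> float:
    """Weighted pair-torque sum over sheet sites (sheet orientation +x).

    theta is the signed angle from the probe orientation u(alpha) to the
    unit vector along (r_probe - r_site); its sine is the 2D cross product.
    """
    r = np.hypot(sx, sy)
    rhx, rhy = -sx / r, -sy / r
    ca, sa = math.cos(alpha), math.sin(alpha)
    sin_theta = ca * rhy - sa * rhx
    vals = math.sin(-alpha) - sin_theta / ratio
    return float(T0 * np.sum(weights * vals))


def _quadrature_sites(geom: SheetGeometry, n_r: int, n_psi: int):
    """Polar Gauss-Legendre nodes covering (sheet region) ∩ (disk of radius R).

    Nodes are laid out symmetrically about the geometry's mirror axis so that
    symmetry-forced cancellations hold to machine precision.
    """
    xr, wr = leggauss(n_r)
    r = 0.5 * geom.R * (xr + 1.0)
    wr = 0.5 * geom.R * wr
    xp, wp = leggauss(n_psi)
    if geom.kind == "uniform_halfplane":
        lo, hi = math.pi, 2.0 * math.pi  # interior y < 0
    elif geom.kind == "uniform_triangle":
        g = geom.apex_half_angle
        lo, hi = math.pi - g, math.pi + g  # wedge behind the apex (x < 0)
    else:
        raise ValueError("quadrature applies to continuum sheets only")
    psi = 0.5 * (hi - lo) * xp + 0.5 * (hi + lo)
    wpsi = 0.5 * (hi - lo) * wp
    R_, P_ = np.meshgrid(r, psi, indexing="ij")
    W = np.outer(wr * r, wpsi) * geom.density  # r dr dpsi, number weighted
    sx = (R_ * np.cos(P_)).ravel()
    sy = (R_ * np.sin(P_)).ravel()
    if geom.interior_side > 0 and geom.kind == "uniform_halfplane":
        sy = -sy
    return sx, sy, W.ravel()


def _lattice_sites(geom: SheetGeometry):
    """Triangular-lattice half-plane sites within R of the probe.

    The probe occupies the origin site of the edge row (row 0); rows extend
    toward the interior with the standard alternating offset.  Inclusion is
    on the closed disk (distance <= R up to rounding): lattice shells sit
    exactly at rational multiples of the spacing, so the open disk would
    make the nominal radii R = k * r_c degenerate.
    """
    a = geom.spacing
    row_h = a * math.sqrt(3.0) / 2.0
    n_rows = int(geom.R / row_h) + 2
    n_cols = int(geom.R / a) + 2
    xs, ys = [], []
    for k in range(0, n_rows):
        y = -k * row_h
        off = 0.5 * a * (k % 2)
        for m in range(-n_cols, n_cols + 1):
            x = m * a + off
            if k == 0 and m == 0:
                continue  # the probe itself
            if x * x + y * y <= geom.R**2 * (1.0 + 1e-12):
                xs.append(x)
                ys.append(y)
    sx = np.array(xs)
    sy = np.array(ys)
    if geom.interior_side > 0:
        sy = -sy
    return sx, sy, np.ones_like(sx)


def net_torque_on_probe(geom: SheetGeometry, probe_angle: float,
                        n_r: int = 64, n_psi: int = 64,
                        check_convergence: bool = False) -> float:
    """Net interaction torque on the probe as a function of its orientation.

    Continuum sheets use polar Gauss-Legendre product quadrature of order
    (n_r, n_psi); ``check_convergence=True`` re-evaluates at doubled order
    and raises if the relative change exceeds 1e-6.
    """
    if geom.kind == "hex_packed_halfplane":
        sx, sy, w = _lattice_sites(geom)
        return _torque_from_sites(probe_angle, sx, sy, w, geom.T0, geom.ratio)
    sx, sy, w = _quadrature_sites(geom, n_r, n_psi)
    val = _torque_from_sites(probe_angle, sx, sy, w, geom.T0, geom.ratio)
    if check_convergence:
        sx2, sy2, w2 = _quadrature_sites(geom, 2 * n_r, 2 * n_psi)
        val2 = _torque_from_sites(probe_angle, sx2, sy2, w2, geom.T0, geom.ratio)
        scale = max(abs(val), abs(val2), 1e-30)
        if abs(val - val2) / scale > 1e-6:
            raise RuntimeError(
                f"quadrature not converged: {val} vs {val2} "
                f"(rel. err {abs(val - val2) / scale:.2e})")
    return val


def stable_orientation(geom: SheetGeometry, bracket: tuple[float, float] = None,
                       xtol: float = 1e-10) -> tuple[float, bool]:
    """Stable probe orientation: torque root with negative torque slope.

    Returns (tilt, stable) where tilt is the equilibrium angle relative to
    the sheet orientation (+x); negative tilt points toward the interior
    for ``interior_side=-1``.  Raises if no root lies in the bracket.
    """
    if bracket is None:
        bracket = (-0.5 * math.pi * 0.999, 0.5 * math.pi * 0.999)

    def f(a: float) -> float:
        return net_torque_on_probe(geom, a)

    fa, fb = f(bracket[0]), f(bracket[1])
    if fa == 0.0:
        root = bracket[0]
    elif fb == 0.0:
        root = bracket[1]
    elif fa * fb > 0:
        raise ValueError(
            f"no torque root in bracket {bracket}: f={fa:.3g}, {fb:.3g}")
    else:
        root = brentq(f, bracket[0], bracket[1], xtol=xtol)
    h = 1e-6
    slope = (f(root + h) - f(root - h)) / (2 * h)
    return float(root), bool(slope < 0)


def halfplane_tilt_exact(ratio: float, interior_side: int = -1) -> float:
    """Closed-form stable tilt of the uniform half-plane edge particle.

    The root of -pi sin(a) - (2/ratio) cos(a) on the stable branch, signed
    toward the sheet interior.
    """
    return interior_side * math.atan(2.0 / (math.pi * ratio))


def tilt_vs_radius(R_values, ratio: float = 2.0,
                   kind: str = "hex_packed_halfplane",
                   spacing: float = R_C) -> np.ndarray:
    """Stable edge tilt for each interaction radius (explains why larger R
    gives rounder, less elongated worms)."""
    tilts = []
    for R in R_values:
        geom = SheetGeometry(kind=kind, R=float(R), ratio=ratio, spacing=spacing)
        tilt, stable = stable_orientation(geom)
        if not stable:
            raise RuntimeError(f"unstable equilibrium at R={R}")
        tilts.append(tilt)
    return np.array(tilts)
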