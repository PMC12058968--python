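"""Initial-condition families used to probe multistability.

Four families: random orientations on a box-spanning triangular lattice,
a hexagonally close-packed cluster with inward (aster) or random
orientations, and an elongated hex-packed worm strip with near-parallel
orientations.  All constructions keep pairwise distances >= 0.9 sigma and
positions inside [0, L)^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import SimParams
from .state import ParticleState

__all__ = [
    "InitialCondition",
    "build_initial_state",
    "init_lattice_random",
    "init_hex_cluster",
    "init_worm",
]


@dataclass(frozen=True)
class InitialCondition:
    """Named initial-condition family with its geometry knobs.

    kind: one of ``lattice_random``, ``hex_cluster_inward``,
    ``hex_cluster_random``, ``worm``.
    """

    kind: str = "lattice_random"
    worm_width: int | None = None  # particles across the strip; None = narrowest fit
    worm_jitter: float = 0.1  # axial orientation jitter std, radians

    KINDS = ("lattice_random", "hex_cluster_inward", "hex_cluster_random", "worm")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown init kind {self.kind!r}; choose from {self.KINDS}")


def build_initial_state(params: SimParams, init: InitialCondition,
                        rng: np.random.Generator) -> ParticleState:
    if init.kind == "lattice_random":
        return init_lattice_random(params, rng)
    if init.kind == "hex_cluster_inward":
        return init_hex_cluster(params, rng, inward=True)
    if init.kind == "hex_cluster_random":
        return init_hex_cluster(params, rng, inward=False)
    return init_worm(params, rng, width=init.worm_width, jitter=init.worm_jitter)


def _hex_lattice_points(spacing: float, n_needed: int, center: np.ndarray) -> np.ndarray:
    """First n_needed sites of a triangular lattice, ordered by distance from
    center (hexagonal close-packed disk)."""
    # generous shell count
    m = int(math.ceil(math.sqrt(n_needed))) + 3
    pts = []
    for row in range(-m, m + 1):
        for col in range(-m, m + 1):
            x = (col + 0.5 * (row % 2)) * spacing
            y = row * spacing * math.sqrt(3.0) / 2.0
            pts.append((x, y))
    pts = np.array(pts)
    d = np.hypot(pts[:, 0], pts[:, 1])
    pts = pts[np.argsort(d, kind="stable")][:n_needed]
    return pts + center


def init_lattice_random(params: SimParams, rng: np.random.Generator) -> ParticleState:
    """N sites of a triangular lattice spanning the box, random orientations.

    The lattice constant is chosen so the rows tile [0, L)^2 with N sites;
    because a triangular lattice needs an even number of rows to tile
    periodically, the aspect of cells is near- but not exactly equilateral.
    """
    L = params.L
    n = params.N
    ncol = int(round(math.sqrt(n * 2.0 / math.sqrt(3.0))))
    ncol = max(ncol, 1)
    nrow = int(math.ceil(n / ncol))
    ax = L / ncol
    ay = L / nrow
    pos = np.empty((n, 2))
    k = 0
    for row in range(nrow):
        for col in range(ncol):
            if k >= n:
                break
            pos[k, 0] = (col + 0.5 * (row % 2)) * ax % L
            pos[k, 1] = (row + 0.5) * ay % L
            k += 1
    phi = rng.uniform(-math.pi, math.pi, size=n)
    return ParticleState(pos, phi, np.zeros((n, 2), dtype=np.int64))


def init_hex_cluster(params: SimParams, rng: np.random.Generator,
                     inward: bool) -> ParticleState:
    """Hexagonally close-packed disk (spacing r_c) at the box center.

    ``inward=True`` gives the aster initialization: every orientation points
    from the particle toward the cluster center.
    """
    L = params.L
    n = params.N
    center = np.array([L / 2.0, L / 2.0])
    pos = _hex_lattice_points(params.r_c, n, center)
    if np.any(pos < 0) or np.any(pos >= L):
        raise ValueError("hex cluster does not fit inside the box")
    if inward:
        d = center - pos
        phi = np.arctan2(d[:, 1], d[:, 0])
        # the central site has zero radius; give it a random heading
        r = np.hypot(d[:, 0], d[:, 1])
        central = r < 1e-12
        phi[central] = rng.uniform(-math.pi, math.pi, size=int(central.sum()))
    else:
        phi = rng.uniform(-math.pi, math.pi, size=n)
    return ParticleState(pos % L, phi, np.zeros((n, 2), dtype=np.int64))


def init_worm(params: SimParams, rng: np.random.Generator,
              width: int | None = None, jitter: float = 0.1) -> ParticleState:
    """Elongated hex-packed strip with near-parallel orientations.

    The strip runs along +x through the box center; orientations are the
    strip axis plus Gaussian jitter.  ``width=None`` picks the narrowest
    strip (>= 5 particles) whose length still fits in the box.
    """
    L = params.L
    n = params.N
    spacing = params.r_c
    if width is None:
        width = max(5, int(math.ceil(n * spacing / (0.9 * L))))
    length = int(math.ceil(n / width))
    if length * spacing > L:
        raise ValueError("worm strip longer than the box; increase width")
    pos = np.empty((n, 2))
    k = 0
    y0 = L / 2.0
    for col in range(length):
        for row in range(width):
            if k >= n:
                break
            pos[k, 0] = (col + 0.5 * (row % 2)) * spacing
            pos[k, 1] = y0 + (row - (width - 1) / 2.0) * spacing * math.sqrt(3.0) / 2.0
            k += 1
    phi = rng.normal(0.0, jitter, size=n)
    return ParticleState(pos % L, phi, np.zeros((n, 2), dtype=np.int64))
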