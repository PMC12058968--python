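"""Snapshot and trajectory containers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import SimParams

__all__ = ["ParticleState", "Trajectory"]


@dataclass
class ParticleState:
    """One simulation snapshot.

    pos components are always wrapped into [0, L); the unwrapped position of
    a particle is ``pos + image * L``.  Orientation angles live in (-pi, pi].
    """

    pos: np.ndarray  # (N, 2), sigma
    phi: np.ndarray  # (N,), radians
    image: np.ndarray  # (N, 2), integer periodic-image counters
    t: float = 0.0

    def __post_init__(self) -> None:
        self.pos = np.ascontiguousarray(self.pos, dtype=np.float64)
        self.phi = np.ascontiguousarray(self.phi, dtype=np.float64)
        self.image = np.ascontiguousarray(self.image, dtype=np.int64)
        n = self.pos.shape[0]
        if self.pos.shape != (n, 2) or self.phi.shape != (n,) or self.image.shape != (n, 2):
            raise ValueError("inconsistent state array shapes")

    @property
    def N(self) -> int:
        return self.pos.shape[0]

    @property
    def u(self) -> np.ndarray:
        """Unit orientation vectors (N, 2)."""
        return np.column_stack((np.cos(self.phi), np.sin(self.phi)))

    def unwrapped(self, L: float) -> np.ndarray:
        return self.pos + self.image * L

    def copy(self) -> "ParticleState":
        return ParticleState(self.pos.copy(), self.phi.copy(), self.image.copy(), self.t)


@dataclass
class Trajectory:
    """Time-ordered sequence of snapshots produced by the simulator.

    Frames are sampled during the collection window; times are measured from
    the end of equilibration.  Unwrapped coordinates (needed for the MSD) are
    reconstructed from the wrapped positions and the integer image counters.
    """

    times: np.ndarray  # (F,), tau_R
    pos: np.ndarray  # (F, N, 2) wrapped, sigma
    images: np.ndarray  # (F, N, 2) int
    phi: np.ndarray  # (F, N)
    params: SimParams

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def N(self) -> int:
        return self.pos.shape[1]

    @property
    def unwrapped(self) -> np.ndarray:
        """(F, N, 2) unwrapped positions."""
        return self.pos + self.images * self.params.L

    @property
    def u(self) -> np.ndarray:
        """(F, N, 2) unit orientation vectors."""
        return np.stack((np.cos(self.phi), np.sin(self.phi)), axis=-1)

    def frame(self, k: int) -> ParticleState:
        return ParticleState(self.pos[k].copy(), self.phi[k].copy(),
                             self.images[k].copy(), float(self.times[k]))
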