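"""Simulation parameters and the unit convention.

Units: particle diameter sigma = 1, thermal energy k_B T = 1, and time in
units of the reorientation time tau_R = 1/D_R = 1.  With the rotational
mobility mu_R = 1 this fixes the translational mobility through
mu / mu_R = sigma^2 / 3, hence mu = D = 1/3 and the self-propulsion speed
v0 = Pe * D / sigma = Pe / 3.

The interaction radius ``R`` is specified in units of the WCA cutoff
r_c = 2^(1/6) sigma, matching how state-diagram axes are usually quoted;
it is converted to sigma internally (``R_sigma``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

__all__ = ["SimParams", "R_C", "MAX_PACKING"]

#: WCA cutoff (potential minimum) in units of sigma.
R_C: float = 2.0 ** (1.0 / 6.0)

#: Hexagonal close packing fraction of disks, pi/(2*sqrt(3)).
MAX_PACKING: float = math.pi / (2.0 * math.sqrt(3.0))


@dataclass(frozen=True)
class SimParams:
    """All model and protocol constants for one simulation run.

    Parameters
    ----------
    N : int
        Number of particles.
    Pe : float
        Peclet number sigma*v0/D (dimensionless self-propulsion strength).
    Phi : float
        Packing fraction N*pi*sigma^2/(4*A).
    eps : float
        WCA energy scale in k_B T.
    T0 : float
        Torque strength T_0 = T_A in k_B T.
    ratio : float
        Alignment-to-cohesion torque ratio T_A / T_C.
    R : float
        Interaction radius of both torques, in units of r_c.
    dt : float
        Integration time step in tau_R.
    t_equil, t_collect : float
        Equilibration and data-collection durations in tau_R.
    seed : int
        Master RNG seed; expands into independent init and noise streams.
    sample_interval : float
        Period between stored trajectory frames, in tau_R.
    min_separation : float
        Pair distance below which an overlap error is raised (time step
        too large for the steric repulsion).
    """

    N: int = 1000
    Pe: float = 80.0
    Phi: float = 0.025
    eps: float = 100.0
    T0: float = 0.0
    ratio: float = 2.0
    R: float = 1.0
    dt: float = 5e-5
    t_equil: float = 1000.0
    t_collect: float = 1000.0
    seed: int = 0
    sample_interval: float = 0.5
    min_separation: float = 0.5

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if not (0.0 < self.Phi <= 0.9069):
            raise ValueError(f"Phi must lie in (0, 0.9069], got {self.Phi}")
        if self.Pe < 0:
            raise ValueError(f"Pe must be >= 0, got {self.Pe}")
        if self.eps <= 0:
            raise ValueError(f"eps must be > 0, got {self.eps}")
        if self.T0 < 0:
            raise ValueError(f"T0 must be >= 0, got {self.T0}")
        if self.ratio <= 0:
            raise ValueError(f"ratio must be > 0, got {self.ratio}")
        if self.R < 1.0:
            raise ValueError(f"R must be >= 1 (in r_c units), got {self.R}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.t_equil < 0 or self.t_collect < 0:
            raise ValueError("durations must be >= 0")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")

    # ---- derived values (pure functions of the fields) ----

    @property
    def sigma(self) -> float:
        return 1.0

    @property
    def mu_R(self) -> float:
        return 1.0

    @property
    def mu(self) -> float:
        return 1.0 / 3.0  # mu / mu_R = sigma^2 / 3

    @property
    def D_R(self) -> float:
        return 1.0

    @property
    def D(self) -> float:
        return 1.0 / 3.0

    @property
    def v0(self) -> float:
        """Self-propulsion speed, Pe * D / sigma."""
        return self.Pe * self.D / self.sigma

    @property
    def r_c(self) -> float:
        return R_C * self.sigma

    @property
    def R_sigma(self) -> float:
        """Interaction radius converted to sigma units."""
        return self.R * self.r_c

    @property
    def L(self) -> float:
        """Periodic box side length from N and Phi."""
        return math.sqrt(self.N * math.pi * self.sigma**2 / (4.0 * self.Phi))

    @property
    def T_A(self) -> float:
        return self.T0

    @property
    def T_C(self) -> float:
        return self.T0 / self.ratio

    @property
    def max_step_displacement(self) -> float:
        """Deterministic displacement at the steepest guarded WCA separation."""
        return self.mu * 24.0 * self.eps * self.dt / self.sigma

    def validate_timestep(self) -> None:
        """Warn when the steric force could move a particle too far per step."""
        if self.max_step_displacement > 0.1:
            import warnings

            warnings.warn(
                f"dt={self.dt} gives a near-contact WCA displacement of "
                f"{self.max_step_displacement:.3g} sigma per step (> 0.1); "
                "consider reducing dt.",
                stacklevel=2,
            )

    def replace(self, **changes) -> "SimParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)
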