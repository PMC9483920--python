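"""Interaction model for a SALR colloidal fluid confined in a spherical shell.

The colloids are monodisperse hard spheres of diameter ``sigma`` carrying a
short-range attraction and a long-range repulsion (SALR), modelled with the
square-well-linear potential: a hard core for ``r < sigma``, a square well of
depth ``epsilon`` on ``sigma <= r < lam*sigma`` and a linear repulsive ramp
``epsilon*zeta*(kappa - r/sigma)`` on ``lam*sigma <= r < kappa*sigma``.  The
ramp is continuous at the outer cutoff ``kappa*sigma`` and discontinuous at
the well edge.

All quantities are expressed in reduced units: lengths in particle diameters
``sigma``, energies in well depths ``epsilon``.  Confinement is a hard-walled
spherical shell; particle *centers* may sit exactly on either wall, so the
configurational volume for the centers is the geometric shell volume, while
the *reported* number density uses a shell padded by half a diameter on both
sides to account for the hard cores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist


__all__ = [
    "PotentialParams",
    "ShellGeometry",
    "ThermoState",
    "Configuration",
    "pair_potential",
    "external_potential",
    "total_energy",
    "particle_energy",
    "accessible_volume",
    "number_density",
]


@dataclass(frozen=True)
class PotentialParams:
    """Constants of the square-well-linear SALR pair potential.

    Parameters
    ----------
    sigma : float
        Particle diameter; the unit of length (1 in reduced units).
    epsilon : float
        Depth of the attractive well; the unit of energy (1 in reduced units).
    zeta : float
        Repulsion strength (dimensionless ramp amplitude).
    lam : float
        Attractive range in units of ``sigma``.
    kappa : float
        Repulsion range in units of ``sigma``.
    """

    sigma: float = 1.0
    epsilon: float = 1.0
    zeta: float = 0.05
    lam: float = 1.5
    kappa: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.zeta < 0:
            raise ValueError("zeta must be non-negative")
        if not (1.0 < self.lam < self.kappa):
            raise ValueError("require 1 < lam < kappa")


DEFAULT_PARAMS = PotentialParams()


@dataclass(frozen=True)
class ShellGeometry:
    """Hard-walled spherical shell between concentric spheres.

    ``r_inn`` below about 1.5 sigma lets particles on opposite sides of the
    inner sphere interact through it, which destabilizes ordered structures;
    a warning is emitted in that regime.
    """

    r_inn: float
    r_out: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_inn < self.r_out):
            raise ValueError("require 0 <= r_inn < r_out")
        if self.r_inn < 1.5:
            warnings.warn(
                "r_inn < 1.5 sigma: particles on opposite sides of the inner "
                "sphere are within the repulsive range; ordered structures "
                "may be short-lived",
                stacklevel=2,
            )

    @property
    def width(self) -> float:
        """Shell width W = r_out - r_inn."""
        return self.r_out - self.r_inn

    @property
    def mid_radius(self) -> float:
        """Radius of the mid-shell sphere, R_c = r_inn + W/2."""
        return 0.5 * (self.r_inn + self.r_out)

    @property
    def volume(self) -> float:
        """Geometric shell volume accessible to particle centers."""
        return (4.0 * math.pi / 3.0) * (self.r_out**3 - self.r_inn**3)


@dataclass(frozen=True)
class ThermoState:
    """Reduced thermodynamic state (T* = kT/epsilon, mu* = mu/epsilon)."""

    t_star: float = 0.35
    mu_star: float = -2.17

    def __post_init__(self) -> None:
        if self.t_star <= 0:
            raise ValueError("t_star must be positive")

    @property
    def beta(self) -> float:
        return 1.0 / self.t_star

    @property
    def activity(self) -> float:
        """Activity z = exp(beta mu*) / sigma^3 with de Broglie length sigma."""
        return math.exp(self.beta * self.mu_star)


@dataclass
class Configuration:
    """Particle positions (N, 3) in sigma units, origin at the shell center."""

    positions: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3), dtype=float)
    )

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def empty(cls) -> "Configuration":
        return cls(np.empty((0, 3), dtype=float))

    def validate(
        self,
        shell: ShellGeometry,
        params: PotentialParams = DEFAULT_PARAMS,
        tol: float = 1e-9,
    ) -> None:
        """Raise ValueError if any particle is out of shell or overlapping."""
        if self.n == 0:
            return
        r = np.linalg.norm(self.positions, axis=1)
        if np.any(r < shell.r_inn - tol) or np.any(r > shell.r_out + tol):
            raise ValueError("particle outside the shell")
        if self.n > 1 and pdist(self.positions).min() < params.sigma - tol:
            raise ValueError("hard-core overlap between particles")


def pair_potential(r, params: PotentialParams = DEFAULT_PARAMS):
    """Square-well-linear SALR pair energy at center-to-center distance r.

    Accepts a scalar or array of distances (sigma units); returns energy in
    epsilon units.  ``+inf`` inside the hard core (r < sigma), ``-epsilon``
    across the square well ``sigma <= r < lam*sigma``, the linear ramp
    ``epsilon*zeta*(kappa - r/sigma)`` on ``lam*sigma <= r < kappa*sigma``
    and exactly zero beyond the repulsion range.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("pair distance must be positive")
    x = arr / params.sigma
    out = np.where(
        x < params.kappa, params.epsilon * params.zeta * (params.kappa - x), 0.0
    )
    out = np.where(x < params.lam, -params.epsilon, out)
    out = np.where(x < 1.0, np.inf, out)
    if np.isscalar(r) or arr.ndim == 0:
        return float(out)
    return out


def external_potential(position, shell: ShellGeometry):
    """Hard-wall confinement energy: 0 inside the shell (walls inclusive),
    +inf outside.  Accepts a single point (3,) or an array (N, 3)."""
    pos = np.asarray(position, dtype=float)
    single = pos.ndim == 1
    pos = pos.reshape(-1, 3)
    r = np.linalg.norm(pos, axis=1)
    out = np.where((r >= shell.r_inn) & (r <= shell.r_out), 0.0, np.inf)
    if single:
        return float(out[0])
    return out


def total_energy(
    config: Configuration,
    params: PotentialParams = DEFAULT_PARAMS,
    shell: ShellGeometry | None = None,
) -> float:
    """Total energy: sum of pair energies over unordered pairs plus the
    hard-wall term of every particle.  Returns +inf for configurations with
    overlaps or out-of-shell particles."""
    pos = config.positions
    if shell is not None and config.n > 0:
        if np.any(np.isinf(external_potential(pos, shell))):
            return math.inf
    if config.n < 2:
        return 0.0
    d = pdist(pos)
    if d.min() < params.sigma:
        return math.inf
    x = d / params.sigma
    well = np.count_nonzero(x < params.lam)
    ramp_mask = (x >= params.lam) & (x < params.kappa)
    ramp = params.zeta * np.sum(params.kappa - x[ramp_mask])
    return params.epsilon * (ramp - well)


def particle_energy(
    config: Configuration,
    index: int | None = None,
    position=None,
    params: PotentialParams = DEFAULT_PARAMS,
    shell: ShellGeometry | None = None,
) -> float:
    """Interaction energy of one particle with all the others plus its wall
    term.

    Either ``index`` selects an existing particle (optionally with a trial
    ``position`` replacing its current one), or ``index=None`` with a trial
    ``position`` evaluates a ghost insertion against the whole configuration.
    """
    pos = config.positions
    if position is None:
        if index is None:
            raise ValueError("need an index or a trial position")
        p = pos[index]
    else:
        p = np.asarray(position, dtype=float).reshape(3)
    if shell is not None and math.isinf(external_potential(p, shell)):
        return math.inf
    others = pos if index is None else np.delete(pos, index, axis=0)
    if others.shape[0] == 0:
        return 0.0
    d = np.linalg.norm(others - p, axis=1)
    if d.min() < params.sigma:
        return math.inf
    x = d / params.sigma
    well = np.count_nonzero(x < params.lam)
    ramp_mask = (x >= params.lam) & (x < params.kappa)
    ramp = params.zeta * np.sum(params.kappa - x[ramp_mask])
    return params.epsilon * (ramp - well)


def accessible_volume(shell: ShellGeometry, sigma: float = 1.0) -> float:
    """Volume used for the reported number density: the shell padded by
    sigma/2 on both sides, (4 pi/3) [(r_out + sigma/2)^3 - (r_inn - sigma/2)^3],
    accounting for the hard cores of particles whose centers sit at the
    walls."""
    if shell.r_inn < 0.5 * sigma:
        raise ValueError("accessible volume requires r_inn >= sigma/2")
    return (4.0 * math.pi / 3.0) * (
        (shell.r_out + 0.5 * sigma) ** 3 - (shell.r_inn - 0.5 * sigma) ** 3
    )


def number_density(n: int, shell: ShellGeometry, sigma: float = 1.0) -> float:
    """Reduced number density rho* = N sigma^3 / V with the padded volume."""
    if n < 0:
        raise ValueError("particle count must be non-negative")
    return n * sigma**3 / accessible_volume(shell, sigma)
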