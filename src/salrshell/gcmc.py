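"""Grand-canonical Metropolis Monte Carlo for SALR colloids.

The engine samples the (mu, V, T) ensemble with three trial moves:
particle displacement (default 95% of attempts) and particle insertion or
deletion (the remaining 5%, split evenly).  One MC step is one trial move.
Acceptance follows the standard grand-canonical Metropolis rules with the
de Broglie wavelength set to sigma, so the activity is
``z = exp(mu*/T*) / sigma^3`` and printed reduced chemical potentials are
directly usable.

Insertion positions are proposed uniformly over the configurational volume:
the geometric shell between ``R_inn`` and ``R_out`` (radius by inverse CDF,
direction isotropic) or the periodic box.  The volume entering the
insertion/deletion acceptance is that same configurational volume; the
half-sigma-padded "accessible" volume is only the convention used to report
the number density.

Energies are tracked incrementally by the numba kernel; the running total
can be checked at any time against a full recomputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .model import (
    Configuration,
    PotentialParams,
    ShellGeometry,
    ThermoState,
    number_density,
    total_energy,
)

__all__ = [
    "MoveMix",
    "RunSchedule",
    "PeriodicBox",
    "ObservableLog",
    "SimState",
    "GCMCSimulation",
]


@dataclass(frozen=True)
class MoveMix:
    """Trial-move mix: displacements vs particle exchange (insertion or
    deletion, split 50/50)."""

    p_displacement: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_displacement <= 1.0):
            raise ValueError("p_displacement must lie in [0, 1]")

    @property
    def p_exchange(self) -> float:
        return 1.0 - self.p_displacement


@dataclass(frozen=True)
class RunSchedule:
    """Run lengths and sampling cadence.

    One MC step is a single trial move.  ``sample_interval`` sets the step
    distance between sampled configurations (the headline runs of the study
    record one configuration every 1e5 steps; desk-scale defaults here are
    much shorter).
    """

    n_equilibration_steps: int = 1_000_000
    n_production_steps: int = 1_000_000
    sample_interval: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_equilibration_steps, self.n_production_steps) < 0:
            raise ValueError("step counts must be non-negative")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")


@dataclass(frozen=True)
class PeriodicBox:
    """Cubic periodic box [0, L)^3 (bulk mode, used for reference runs)."""

    length: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("box length must be positive")

    @property
    def volume(self) -> float:
        return self.length**3


@dataclass
class ObservableLog:
    """Per-sample observable records: step, N, U (total, epsilon units),
    u* = U/(N epsilon) and rho*."""

    step: np.ndarray
    n: np.ndarray
    u: np.ndarray
    u_star: np.ndarray
    rho_star: np.ndarray

    def __len__(self) -> int:
        return len(self.step)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.step,
                "N": self.n,
                "U": self.u,
                "u_star": self.u_star,
                "rho_star": self.rho_star,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def mean_n(self) -> float:
        return float(np.mean(self.n)) if len(self) else math.nan

    @property
    def mean_rho_star(self) -> float:
        return float(np.mean(self.rho_star)) if len(self) else math.nan

    @property
    def mean_u_star(self) -> float:
        return float(np.mean(self.u_star)) if len(self) else math.nan


@dataclass
class SimState:
    """Snapshot of the simulation state."""

    positions: np.ndarray
    n: int
    energy: float
    step: int


class GCMCSimulation:
    """Grand-canonical MC in a hard-walled shell or a periodic box.

    Parameters
    ----------
    params:
        SALR potential constants (must be in reduced units, sigma=epsilon=1).
    geometry:
        :class:`ShellGeometry` (confined mode) or :class:`PeriodicBox`.
    thermo:
        Reduced temperature and chemical potential.
    mix:
        Trial-move probabilities.
    max_displacement:
        Half-width of the cubic displacement proposal (sigma units).  Fixed
        during production; optionally tuned during equilibration only, which
        preserves detailed balance where averages are taken.
    interacting:
        With ``False`` the pair potential (hard core included) is switched
        off, leaving an ideal gas in the confining geometry — the closed-form
        limit used for validation.
    """

    def __init__(
        self,
        params: PotentialParams = PotentialParams(),
        geometry: ShellGeometry | PeriodicBox = ShellGeometry(6.0, 11.0),
        thermo: ThermoState = ThermoState(),
        mix: MoveMix = MoveMix(),
        max_displacement: float = 0.5,
        interacting: bool = True,
        max_particles: int | None = None,
    ) -> None:
        if not (params.sigma == 1.0 and params.epsilon == 1.0):
            raise ValueError("the engine works in reduced units: sigma = epsilon = 1")
        self.params = params
        self.geometry = geometry
        self.thermo = thermo
        self.mix = mix
        self.max_displacement = float(max_displacement)
        self.interacting = bool(interacting)

        self.periodic = isinstance(geometry, PeriodicBox)
        if self.periodic:
            self.box_l = geometry.length
            self._lo = 0.0
            dom = geometry.length
            self.volume = geometry.volume
            self._r_inn = 0.0
            self._r_out = 0.0
        else:
            self.box_l = 1.0  # unused
            self._lo = -(geometry.r_out + 0.55)
            dom = 2.0 * (geometry.r_out + 0.55)
            self.volume = geometry.volume
            self._r_inn = geometry.r_inn
            self._r_out = geometry.r_out

        nc = int(dom // params.kappa)
        if self.periodic and nc < 3:
            nc = 1
        self._nc = max(nc, 1)
        self._inv_edge = self._nc / dom

        if max_particles is None:
            max_particles = int(self.volume * 0.8) + 128
        self._cap = max_particles
        self.positions = np.empty((self._cap, 3), dtype=np.float64)
        self._head = np.full(self._nc**3, -1, dtype=np.int64)
        self._next = np.full(self._cap, -1, dtype=np.int64)
        self._cell_of = np.full(self._cap, -1, dtype=np.int64)
        self.n = 0
        self.energy = 0.0
        self.step = 0
        self.move_stats = {
            k: 0
            for k in (
                "att_disp",
                "acc_disp",
                "att_ins",
                "acc_ins",
                "att_del",
                "acc_del",
            )
        }
        self._z_vol = thermo.activity * self.volume

    # -- state management ---------------------------------------------------

    def seed(self, seed: int) -> None:
        """Seed the kernel RNG (bit-reproducible trajectories)."""
        _kernels.seed_rng(int(seed) & 0x7FFFFFFF)

    def set_configuration(self, config: Configuration) -> None:
        """Install a starting configuration and recompute its energy."""
        n = config.n
        if n > self._cap:
            raise ValueError("configuration exceeds the particle capacity")
        self.positions[:n] = config.positions
        self.n = n
        self._rebuild_cells()
        self.energy = self.total_energy_recomputed() if self.interacting else 0.0
        if math.isinf(self.energy):
            raise ValueError("starting configuration has infinite energy")

    def configuration(self) -> Configuration:
        return Configuration(self.positions[: self.n].copy())

    def state(self) -> SimState:
        return SimState(
            positions=self.positions[: self.n].copy(),
            n=self.n,
            energy=self.energy,
            step=self.step,
        )

    def _rebuild_cells(self) -> None:
        _kernels.build_cells(
            self.positions,
            self.n,
            self._head,
            self._next,
            self._cell_of,
            self._lo,
            self._inv_edge,
            self._nc,
        )

    def total_energy_recomputed(self) -> float:
        """Full O(N^2) recomputation of the configuration energy (the
        bookkeeping oracle for the incremental kernel energy)."""
        if not self.interacting:
            return 0.0
        cfg = self.configuration()
        if self.periodic:
            return _periodic_total_energy(cfg.positions, self.box_l, self.params)
        return total_energy(cfg, self.params, self.geometry)

    def check_energy(self, tol_per_particle: float = 1e-8) -> float:
        """Assert incremental-vs-recomputed energy agreement; returns the
        absolute drift."""
        ref = self.total_energy_recomputed()
        drift = abs(self.energy - ref)
        if drift > tol_per_particle * max(self.n, 1):
            raise AssertionError(
                f"energy bookkeeping drift {drift:g} eps for N={self.n}"
            )
        return drift

    # -- running ------------------------------------------------------------

    def run_steps(self, n_steps: int) -> dict:
        """Advance ``n_steps`` trial moves; returns move statistics and the
        per-step mean particle number over the chunk."""
        p = self.params
        (
            self.n,
            self.energy,
            sum_n,
            att_d,
            acc_d,
            att_i,
            acc_i,
            att_x,
            acc_x,
        ) = _kernels.run_steps(
            self.positions,
            self._head,
            self._next,
            self._cell_of,
            self.n,
            self.energy,
            int(n_steps),
            self.mix.p_displacement,
            self.max_displacement,
            self.thermo.beta,
            self._z_vol,
            self._r_inn,
            self._r_out,
            self.box_l,
            self._lo,
            self._inv_edge,
            self._nc,
            self.periodic,
            self.interacting,
            p.zeta,
            p.lam**2,
            p.kappa,
            p.kappa**2,
        )
        self.step += int(n_steps)
        for key, val in zip(
            ("att_disp", "acc_disp", "att_ins", "acc_ins", "att_del", "acc_del"),
            (att_d, acc_d, att_i, acc_i, att_x, acc_x),
        ):
            self.move_stats[key] += int(val)
        return {
            "mean_n": sum_n / max(n_steps, 1),
            "att_disp": att_d,
            "acc_disp": acc_d,
            "att_ins": att_i,
            "acc_ins": acc_i,
            "att_del": att_x,
            "acc_del": acc_x,
        }

    def _rho_star(self) -> float:
        if self.periodic:
            return self.n / self.volume
        return number_density(self.n, self.geometry)

    def equilibrate(
        self,
        n_steps: int,
        tune_displacement: bool = False,
        chunk: int = 200_000,
        target_acceptance: tuple[float, float] = (0.3, 0.5),
    ) -> None:
        """Equilibration phase; optionally adapts the maximum displacement
        toward the target acceptance window, then freezes it."""
        done = 0
        while done < n_steps:
            this = min(chunk, n_steps - done)
            stats = self.run_steps(this)
            done += this
            if tune_displacement and stats["att_disp"] > 0:
                rate = stats["acc_disp"] / stats["att_disp"]
                if rate < target_acceptance[0]:
                    self.max_displacement = max(0.05, self.max_displacement * 0.9)
                elif rate > target_acceptance[1]:
                    self.max_displacement = min(2.0, self.max_displacement * 1.1)

    def run(
        self,
        schedule: RunSchedule,
        log_trajectory: bool = True,
        tune_displacement: bool = False,
    ) -> tuple[ObservableLog, list[Configuration]]:
        """Execute a schedule: seed, equilibrate, then produce samples every
        ``sample_interval`` steps.  Deterministic for a given seed and
        starting state."""
        self.seed(schedule.seed)
        if schedule.n_equilibration_steps:
            self.equilibrate(
                schedule.n_equilibration_steps, tune_displacement=tune_displacement
            )
        rows = []
        trajectory: list[Configuration] = []
        produced = 0
        while produced < schedule.n_production_steps:
            this = min(schedule.sample_interval, schedule.n_production_steps - produced)
            self.run_steps(this)
            produced += this
            n = self.n
            u = self.energy
            rows.append(
                (
                    self.step,
                    n,
                    u,
                    u / n if n else 0.0,
                    self._rho_star(),
                )
            )
            if log_trajectory:
                trajectory.append(self.configuration())
        if rows:
            step, n, u, u_star, rho = (np.array(col) for col in zip(*rows))
        else:
            step = n = u = u_star = rho = np.array([])
        log = ObservableLog(
            step=step,
            n=n.astype(int) if len(n) else n,
            u=u,
            u_star=u_star,
            rho_star=rho,
        )
        return log, trajectory

    def run_to_plateau(
        self,
        seed: int = 0,
        window: int = 1_000_000,
        rel_tol: float = 0.01,
        min_windows: int = 10,
        max_windows: int = 40,
        stable_windows: int = 2,
    ) -> tuple[float, list[float], bool]:
        """Run from the current state until the window-averaged particle
        number plateaus.

        The run proceeds in windows of ``window`` steps; it stops once the
        relative change of the window mean stays below ``rel_tol`` for
        ``stable_windows`` consecutive windows (after at least
        ``min_windows``), or at ``max_windows``.  Returns ``(plateau mean N,
        window means, converged flag)``.
        """
        self.seed(seed)
        means: list[float] = []
        stable = 0
        for w in range(max_windows):
            stats = self.run_steps(window)
            means.append(stats["mean_n"])
            if w >= 1:
                prev, cur = means[-2], means[-1]
                if abs(cur - prev) / max(cur, 1.0) < rel_tol:
                    stable += 1
                else:
                    stable = 0
                if w + 1 >= min_windows and stable >= stable_windows:
                    return means[-1], means, True
        return means[-1], means, False


def _periodic_total_energy(
    positions: np.ndarray, box_l: float, params: PotentialParams
) -> float:
    """Brute-force minimum-image total energy (oracle for the box mode)."""
    n = positions.shape[0]
    if n < 2:
        return 0.0
    d = positions[:, None, :] - positions[None, :, :]
    d -= box_l * np.rint(d / box_l)
    dist = np.sqrt((d**2).sum(axis=-1))
    iu = np.triu_indices(n, k=1)
    r = dist[iu]
    if r.min() < params.sigma:
        return math.inf
    well = np.count_nonzero(r < params.lam)
    mask = (r >= params.lam) & (r < params.kappa)
    return params.epsilon * (
        params.zeta * np.sum(params.kappa - r[mask]) - well
    )
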