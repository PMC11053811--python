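import numpy as np
import pytest

from demicell.engine import (SimulationProtocol, compute_forces,
                             kinetic_temperature, run_protocol, step_langevin)
from demicell.system import assemble_system
from demicell.templates import TAG_TO_CODE


def brute_force_reference(state, table):
    """O(n^2) all-pairs + bond forces straight from the potential formulas."""
    n = state.n_beads
    L = state.box.length
    pos = state.positions
    f = np.zeros((n, 3))
    bonded = {tuple(sorted(b)) for b in map(tuple, state.active_bonds)}
    for i in range(n):
        for j in range(i + 1, n):
            d = pos[i] - pos[j]
            d -= L * np.round(d / L)
            r = np.linalg.norm(d)
            if (i, j) in bonded:
                # FENE + WCA composition
                fmag = -table.fene_k * r / (1.0 - (r / table.fene_R0) ** 2)
                if r < 2 ** (1 / 6):
                    sr6 = r ** -6
                    fmag += 24 * (2 * sr6 ** 2 - sr6) / r
                f[i] += fmag * d / r
                f[j] -= fmag * d / r
                continue
            eps, rc = table.eps[state.types[i], state.types[j]], \
                table.rcut[state.types[i], state.types[j]]
            if r <= rc:
                sr6 = r ** -6
                fmag = 24 * eps * (2 * sr6 ** 2 - sr6) / r
                f[i] += fmag * d / r
                f[j] -= fmag * d / r
    return f


@pytest.mark.parametrize("trial", range(5))
def test_forces_match_brute_force_oracle(trial, default_table):
    state = assemble_system({"A30B30": 2, "C3": 3, "T": 5}, 0.12, seed=100 + trial)
    forces, _ = compute_forces(state, default_table)
    ref = brute_force_reference(state, default_table)
    assert np.allclose(forces, ref, atol=1e-10)


def test_net_force_vanishes(strong_cargo_table):
    state = assemble_system({"A30(B10)3": 3, "C3": 4}, 0.12, seed=9)
    forces, _ = compute_forces(state, strong_cargo_table)
    assert np.allclose(forces.sum(axis=0), 0.0, atol=1e-9)


def test_two_beads_at_wca_minimum_feel_no_force(state_factory, default_table):
    r = 2 ** (1 / 6)
    st = state_factory([[5, 5, 5], [5 + r, 5, 5]],
                       [TAG_TO_CODE["A"], TAG_TO_CODE["A"]], L=20.0,
                       mol=[0, 1], species=["T", "T"])
    forces, energy = compute_forces(st, default_table)
    assert np.allclose(forces, 0.0, atol=1e-9)
    assert energy == pytest.approx(0.0, abs=1e-12)


def test_minimum_image_attraction_across_boundary(state_factory, default_table):
    # beads at x = 0.2 and x = L - 0.3: separation 0.5 through the wall
    st = state_factory([[0.2, 5, 5], [9.7, 5, 5]],
                       [TAG_TO_CODE["B"], TAG_TO_CODE["B"]], L=10.0,
                       mol=[0, 1], species=["T", "T"])
    forces, _ = compute_forces(st, default_table)
    # r = 0.5 sigma: strongly repulsive, pushing beads apart through the wall
    assert forces[0, 0] > 1e3
    assert forces[1, 0] < -1e3


def test_kinetic_temperature_thermostatted_to_target(default_table):
    """Block-averaged kinetic temperature within 2% of T* = 1.8; samples
    span ~120 tau so they decorrelate (velocity correlation time 1/gamma)."""
    state = assemble_system({"A30B30": 10}, 0.12, seed=21)
    proto = SimulationProtocol(n_pushoff=0, n_equil=0, n_prod=0, gamma=1.0)
    step_langevin(state, proto, 1000, 3, default_table.pushoff_copy())
    temps = []
    for rep in range(200):
        step_langevin(state, proto, 100, 1000 + rep, default_table)
        temps.append(kinetic_temperature(state))
    assert np.mean(temps) == pytest.approx(1.8, rel=0.02)


def test_nve_energy_conservation_when_thermostat_off(default_table):
    """With gamma = 0 the integrator is plain velocity Verlet; on a 10-bead
    chain with the smooth (WCA) pair table the secular energy drift must be
    below 1e-4 per 1000 steps.  The smooth table isolates integrator error:
    the 2.5-sigma truncation has a force step at the cutoff that adds
    bounded fluctuation unrelated to the integrator."""
    table = default_table.pushoff_copy(force_cap=np.inf)
    state = assemble_system({"C10": 1}, 0.01, seed=33)
    relax = SimulationProtocol(n_pushoff=0, n_equil=0, n_prod=0, gamma=1.0)
    step_langevin(state, relax, 2000, 5, table)
    nve = SimulationProtocol(n_pushoff=0, n_equil=0, n_prod=0, gamma=0.0)

    def total_energy(st):
        _, pot = compute_forces(st, table)
        return pot + 0.5 * np.sum(st.velocities ** 2)

    energies = []
    for _ in range(60):
        step_langevin(state, nve, 50, 6, table)
        energies.append(total_energy(state))
    energies = np.array(energies)
    slope = np.polyfit(np.arange(60) * 50.0, energies, 1)[0]
    assert abs(slope) * 1000 / abs(energies.mean()) < 1e-4


def test_free_bead_diffusion_exponent_is_one(default_table):
    from demicell.kinetics import cargo_msd

    # repulsive-only table: dilute beads diffuse freely (attractive T-T
    # interactions would aggregate them and bias the exponent)
    table = default_table.pushoff_copy(force_cap=np.inf)
    state = assemble_system({"T": 200}, 0.01, seed=8)
    proto = SimulationProtocol(n_pushoff=0, n_equil=0, n_prod=0, gamma=1.0)
    frames = []
    times = []
    # sample to t = 240 tau so the default last-decade window sits well past
    # the 1/gamma ballistic-to-diffusive transient
    for k in range(400):
        step_langevin(state, proto, 100, 500 + k, table)
        frames.append(state.unwrapped_positions.copy())
        times.append(state.time)
    _, fit = cargo_msd(np.array(frames), np.array(times) - times[0] + 0.6)
    assert fit.alpha == pytest.approx(1.0, abs=0.05)


def test_integration_preserves_topology_and_bond_bounds(strong_cargo_table):
    state = assemble_system({"A30(B15)2": 4, "C3": 8}, 0.12, seed=77)
    before = (state.n_beads, state.types.copy(), state.molecule_id.copy())
    proto = SimulationProtocol(n_pushoff=0, n_equil=0, n_prod=0)
    step_langevin(state, proto, 500, 2, strong_cargo_table.pushoff_copy())
    step_langevin(state, proto, 1500, 3, strong_cargo_table)
    assert state.n_beads == before[0]
    assert np.array_equal(state.types, before[1])
    assert np.array_equal(state.molecule_id, before[2])
    assert state.bond_lengths().max() < 1.5


def test_integration_deterministic_for_fixed_seed(default_table):
    proto = SimulationProtocol(n_pushoff=0, n_equil=0, n_prod=0)
    runs = []
    for _ in range(2):
        st = assemble_system({"A30B30": 2}, 0.12, seed=4)
        step_langevin(st, proto, 300, 11, default_table)
        runs.append(st.positions.copy())
    assert np.array_equal(runs[0], runs[1])


def test_protocol_stage_scaling_and_frame_count(default_table):
    proto = SimulationProtocol(n_pushoff=2_000_000, n_equil=30_000_000,
                               n_prod=300_000_000, snapshot_every=100_000,
                               scale_factor=100_000)
    assert proto.stage_steps == (20, 300, 3000)
    state = assemble_system({"C3": 10}, 0.1, seed=2)
    traj = run_protocol(state, proto, default_table, seed=12)
    # scaled n_prod / scaled snapshot_every + 1 frames (origin included)
    assert len(traj) == 3000 + 1


def test_pushoff_stage_has_no_attractive_tail(default_table):
    push = default_table.pushoff_copy()
    assert push.rcut.max() == pytest.approx(2 ** (1 / 6))
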