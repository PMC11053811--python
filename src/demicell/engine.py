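"""Langevin dynamics engine and the three-stage simulation protocol.

Integration uses the BAOAB splitting of Langevin dynamics: a velocity-Verlet
core with an exact Ornstein-Uhlenbeck velocity refresh in the middle, which
satisfies fluctuation-dissipation at the target temperature and reduces to
plain (symplectic) velocity Verlet when the friction is zero.  Neighbours
come from a periodic cell list with a Verlet skin, rebuilt whenever any
bead has moved more than half the skin.

The production protocol mirrors standard practice for this model:

1. *push-off* — every pair cutoff collapsed to 2^(1/6) sigma (purely
   repulsive) to relax the random initial configuration without bias;
2. *equilibration* — full interaction table;
3. *production* — snapshots collected, optionally with stochastic
   depolymerization sweeps interleaved between integration steps.

The friction gamma is not a property of the model, only of the thermostat;
all kinetic comparisons in this package are therefore made between systems
run at identical gamma, in units of the resulting diffusive time scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .forcefield import BondOverstretchError, InteractionTable, KBT
from .system import SystemState

DEFAULT_DT = 0.006      # tau
DEFAULT_GAMMA = 1.0     # 1/tau


@dataclass
class SimulationProtocol:
    """Step counts and thermostat settings for a push-off/equilibration/
    production run.

    ``scale_factor`` divides the full-scale step counts (2e6 / 30e6 / 3e8)
    so that scaled-down desk runs keep the stage proportions of the
    reference protocol.
    """

    dt: float = DEFAULT_DT
    tstar: float = KBT
    gamma: float = DEFAULT_GAMMA
    n_pushoff: int = 2_000_000
    n_equil: int = 30_000_000
    n_prod: int = 300_000_000
    snapshot_every: int = 100_000
    scale_factor: float = 1.0

    def __post_init__(self):
        if self.dt <= 0 or self.tstar <= 0 or self.gamma < 0:
            raise ValueError("dt and T* must be positive, gamma non-negative")
        if min(self.n_pushoff, self.n_equil, self.n_prod) < 0:
            raise ValueError("stage lengths must be non-negative")
        if self.scale_factor < 1:
            raise ValueError("scale_factor must be >= 1")

    @property
    def stage_steps(self) -> tuple[int, int, int]:
        s = self.scale_factor
        return (int(self.n_pushoff / s), int(self.n_equil / s), int(self.n_prod / s))


@dataclass
class Trajectory:
    """Snapshots collected during a run (positions wrapped; images kept so
    unwrapped coordinates can be reconstructed for MSD work)."""

    times: list[float] = field(default_factory=list)
    positions: list[np.ndarray] = field(default_factory=list)
    images: list[np.ndarray] = field(default_factory=list)
    bond_active: list[np.ndarray] = field(default_factory=list)
    types: list[np.ndarray] = field(default_factory=list)
    box_length: float = 0.0
    molecule_id: np.ndarray | None = None

    def record(self, state: SystemState) -> None:
        if self.molecule_id is None:
            self.molecule_id = state.molecule_id.copy()
            self.box_length = state.box.length
        self.times.append(state.time)
        self.positions.append(state.positions.copy())
        self.images.append(state.images.copy())
        self.bond_active.append(state.bond_active.copy())
        self.types.append(state.types.copy())

    def __len__(self) -> int:
        return len(self.times)

    def frame_state(self, k: int, template: SystemState) -> SystemState:
        """Materialise frame ``k`` as a full SystemState (static topology
        from ``template``, per-frame coordinates/bonds/types restored)."""
        st = template.copy()
        st.positions = self.positions[k].copy()
        st.images = self.images[k].copy()
        st.bond_active = self.bond_active[k].copy()
        st.types = self.types[k].copy()
        st.time = self.times[k]
        for b, br in enumerate(st.branches):
            st.branch_progress[b] = int(np.sum(~st.bond_active[br.bond_indices]))
        return st


class _NeighborList:
    """Verlet pair list over a periodic cell list, rebuilt on a
    half-skin displacement trigger."""

    def __init__(self, skin: float = 0.8):
        self.skin = skin
        self.pairs: np.ndarray | None = None
        self._ref: np.ndarray | None = None
        self._rmax = 0.0
        self._cap_hint = 1024

    def invalidate(self) -> None:
        self.pairs = None

    def update(self, state: SystemState, table: InteractionTable) -> np.ndarray:
        L = state.box.length
        rmax = min(table.max_cutoff, L / 2.001)
        stale = (
            self.pairs is None
            or rmax != self._rmax
            or _kernels.max_sq_displacement(state.positions, self._ref, L)
            > (self.skin / 2.0) ** 2
        )
        if stale:
            pos = np.mod(state.positions, L)
            n = state.n_beads
            ab = state.active_bonds
            codes = np.sort(np.minimum(ab[:, 0], ab[:, 1]) * n
                            + np.maximum(ab[:, 0], ab[:, 1]))
            cap = max(1024, int(self._cap_hint))
            while True:
                cand, count = _kernels.build_pair_list(pos, L, rmax + self.skin,
                                                       codes, cap)
                if count <= cap:
                    break
                cap = int(count * 1.2) + 64
            self._cap_hint = max(self._cap_hint, count * 1.3)
            self.pairs = cand[:count]
            self._ref = state.positions.copy()
            self._rmax = rmax
        return self.pairs


def _shift_matrix(table: InteractionTable) -> np.ndarray:
    """Energy shift per type pair making U continuous (zero) at the cutoff.

    Cached on the table object (its matrices are fixed after construction).
    """
    cached = getattr(table, "_shift_cache", None)
    if cached is None:
        with np.errstate(divide="ignore"):
            src6 = (1.0 / table.rcut) ** 6
        cached = -4.0 * table.eps * (src6 * src6 - src6)
        table._shift_cache = cached
    return cached


def _tables_cache(table: InteractionTable) -> tuple[np.ndarray, np.ndarray]:
    cached = getattr(table, "_kernel_cache", None)
    if cached is None:
        cached = (table.rcut ** 2, _shift_matrix(table))
        table._kernel_cache = cached
    return cached


def compute_forces(state: SystemState, table: InteractionTable,
                   pairs: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Forces and potential energy for the current configuration.

    When ``pairs`` is omitted a fresh all-neighbour list (no skin) is built;
    the integrator passes its own skinned Verlet list instead.
    """
    L = state.box.length
    pos = state.positions
    if np.any(pos < 0.0) or np.any(pos >= L):
        state.wrap()
        pos = state.positions
    if pairs is None:
        nl = _NeighborList(skin=0.0)
        pairs = nl.update(state, table)
    rc2, shift = _tables_cache(table)
    forces = np.zeros_like(pos)
    e_pair = _kernels.pair_forces(pos, pairs, state.types,
                                  table.eps, rc2, shift,
                                  L, table.force_cap, forces)
    e_bond, bad = _kernels.bond_forces(state.positions, state.bonds, state.bond_active,
                                       L, table.fene_k, table.fene_R0,
                                       table.bonded_wca, forces)
    if bad >= 0:
        i, j = state.bonds[bad]
        raise BondOverstretchError(
            f"bond {bad} ({i}-{j}, molecule {state.molecule_id[i]}) reached "
            f"R0 = {table.fene_R0} sigma at t = {state.time:.3f} tau")
    return forces, e_pair + e_bond


def kinetic_temperature(state: SystemState) -> float:
    """Instantaneous kinetic temperature, m <v^2> / 3 (k_B = 1, m = 1)."""
    return float(np.sum(state.velocities ** 2) / (3.0 * state.n_beads))


def step_langevin(state: SystemState, protocol: SimulationProtocol, n_steps: int,
                  seed: int, table: InteractionTable, *,
                  reaction_hook=None, snapshot_every: int = 0,
                  trajectory: Trajectory | None = None,
                  neighbor_list: _NeighborList | None = None) -> SystemState:
    """Advance ``state`` in place by ``n_steps`` BAOAB Langevin steps.

    ``reaction_hook(state, step_rng)``, if given, is called between steps at
    the cadence the hook itself encodes and must return the number of
    topology changes (nonzero forces a neighbour-list refresh).  Snapshots
    are appended to ``trajectory`` every ``snapshot_every`` steps (frame 0
    included).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    nl = neighbor_list or _NeighborList()
    dt, gamma, tstar = protocol.dt, protocol.gamma, protocol.tstar
    c1 = float(np.exp(-gamma * dt))
    c2 = float(np.sqrt(max(0.0, 1.0 - c1 * c1)) * np.sqrt(tstar))

    if trajectory is not None and snapshot_every > 0 and len(trajectory) == 0:
        trajectory.record(state)

    forces, _ = compute_forces(state, table, nl.update(state, table))
    half = 0.5 * dt
    zero_noise = np.zeros_like(state.positions)
    for step in range(n_steps):
        noise = (rng.standard_normal(state.positions.shape) if gamma > 0.0
                 else zero_noise)
        _kernels.baoab_pre(state.positions, state.velocities, state.images,
                           forces, noise, half, c1, c2, state.box.length)
        state.time += dt

        if reaction_hook is not None:
            if reaction_hook(state, rng):
                nl.invalidate()
        forces, _ = compute_forces(state, table, nl.update(state, table))
        _kernels.final_kick(state.velocities, forces, half)

        if trajectory is not None and snapshot_every > 0 and (step + 1) % snapshot_every == 0:
            trajectory.record(state)
    return state


def run_protocol(state: SystemState, protocol: SimulationProtocol,
                 table: InteractionTable, seed: int, *,
                 reaction_hook=None) -> Trajectory:
    """Run push-off, equilibration and production on ``state`` (in place).

    The push-off stage uses the all-repulsive copy of the interaction table;
    reactions, if any, act only during production.  Returns the production
    trajectory (frame 0 = production start).
    """
    ss = np.random.SeedSequence([seed, 0xD3])
    s_push, s_eq, s_prod = (int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(3))
    n_push, n_eq, n_prod = protocol.stage_steps

    nl = _NeighborList()
    if n_push:
        step_langevin(state, protocol, n_push, s_push, table.pushoff_copy(),
                      neighbor_list=nl)
        nl.invalidate()
    if n_eq:
        step_langevin(state, protocol, n_eq, s_eq, table, neighbor_list=nl)

    traj = Trajectory()
    snap = max(1, int(protocol.snapshot_every / protocol.scale_factor))
    step_langevin(state, protocol, n_prod, s_prod, table,
                  reaction_hook=reaction_hook, snapshot_every=snap,
                  trajectory=traj, neighbor_list=nl)
    return traj
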