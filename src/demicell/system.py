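"""System state container and random initial configurations.

This is the synthetic-configuration layer: every downstream stage
(integration, reactions, clustering, kinetics) can be exercised from its
output without any external data.  Molecules are grown as off-lattice
random walks with bond length ~0.97 sigma inside a periodic cube whose
edge follows from the bead number density Phi = N sigma^3 / V (0.12 in
the study conditions); mild insertion overlaps are tolerated because the
repulsive push-off stage removes any initial-conformation bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .forcefield import KBT
from .templates import MoleculeTemplate, TAG_TO_CODE, T as T_CODE, build_template


class PackingError(RuntimeError):
    """Random insertion failed after the allowed number of attempts."""


def box_length(n_beads: int, phi: float) -> float:
    """Edge L of the cubic box holding ``n_beads`` at bead density ``phi``."""
    if n_beads < 1:
        raise ValueError("need at least one bead")
    if not 0.0 < phi < 0.5:
        raise ValueError("bead concentration must lie in (0, 0.5)")
    return float((n_beads / phi) ** (1.0 / 3.0))


@dataclass(frozen=True)
class BoxSpec:
    """Cubic periodic box defined by a bead concentration."""

    phi: float
    n_beads: int
    length: float

    @classmethod
    def from_phi(cls, n_beads: int, phi: float) -> "BoxSpec":
        return cls(phi=phi, n_beads=n_beads, length=box_length(n_beads, phi))


@dataclass(frozen=True)
class BranchState:
    """One hydrophobic branch of one chain, in global bead/bond indices.

    ``bond_indices[i]`` (row of ``SystemState.bonds``) detaches global bead
    ``bead_indices[i]``; index 0 is the end-cap bond.
    """

    molecule_id: int
    bead_indices: np.ndarray
    bond_indices: np.ndarray

    def __len__(self) -> int:
        return len(self.bond_indices)


@dataclass
class SystemState:
    """Positions, velocities, topology and bookkeeping for one configuration.

    ``positions`` are always wrapped into [0, L); ``images`` hold the
    periodic image counts so ``unwrapped_positions`` can serve MSD-type
    analyses.  ``bonds`` is append-only: reactions deactivate rows via
    ``bond_active`` so ledgers can compare against the initial topology and
    the bead count never changes during dynamics or reactions.
    """

    positions: np.ndarray          # (n, 3) float, wrapped
    velocities: np.ndarray         # (n, 3) float
    images: np.ndarray             # (n, 3) int periodic image flags
    types: np.ndarray              # (n,) int8 type codes
    bonds: np.ndarray              # (m, 2) int
    bond_active: np.ndarray        # (m,) bool
    molecule_id: np.ndarray        # (n,) int
    mol_species: list[str]         # species name per molecule id
    box: BoxSpec
    branches: list[BranchState] = field(default_factory=list)
    branch_progress: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    time: float = 0.0
    rng_seed: int | None = None

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_molecules(self) -> int:
        return len(self.mol_species)

    @property
    def unwrapped_positions(self) -> np.ndarray:
        return self.positions + self.images * self.box.length

    @property
    def active_bonds(self) -> np.ndarray:
        return self.bonds[self.bond_active]

    def bond_degrees(self) -> np.ndarray:
        """Number of active bonds per bead."""
        deg = np.zeros(self.n_beads, dtype=np.int64)
        ab = self.active_bonds
        if len(ab):
            np.add.at(deg, ab[:, 0], 1)
            np.add.at(deg, ab[:, 1], 1)
        return deg

    def bond_lengths(self) -> np.ndarray:
        """Minimum-image lengths of all active bonds."""
        ab = self.active_bonds
        if not len(ab):
            return np.zeros(0)
        d = self.positions[ab[:, 0]] - self.positions[ab[:, 1]]
        L = self.box.length
        d -= L * np.round(d / L)
        return np.linalg.norm(d, axis=1)

    def copy(self) -> "SystemState":
        return SystemState(
            positions=self.positions.copy(), velocities=self.velocities.copy(),
            images=self.images.copy(), types=self.types.copy(),
            bonds=self.bonds.copy(), bond_active=self.bond_active.copy(),
            molecule_id=self.molecule_id.copy(), mol_species=list(self.mol_species),
            box=self.box, branches=list(self.branches),
            branch_progress=self.branch_progress.copy(),
            time=self.time, rng_seed=self.rng_seed,
        )

    def wrap(self) -> None:
        """Re-wrap positions into [0, L), updating image flags."""
        L = self.box.length
        shift = np.floor(self.positions / L).astype(np.int64)
        self.images += shift
        self.positions -= shift * L


def maxwell_boltzmann_velocities(n: int, tstar: float, rng: np.random.Generator) -> np.ndarray:
    """Velocities at temperature T* with zero net momentum (m = 1)."""
    v = rng.normal(0.0, np.sqrt(tstar), size=(n, 3))
    v -= v.mean(axis=0, keepdims=True)
    return v


def _grow_molecule(template: MoleculeTemplate, L: float, occupied: cKDTree | None,
                   rng: np.random.Generator, bond_length: float, min_dist: float,
                   n_trials: int = 40) -> np.ndarray:
    """Random-walk placement of one molecule; returns wrapped coordinates.

    Soft-overlap policy: each bead tries ``n_trials`` directions for a site
    clear of other beads by ``min_dist``; failing that, the most distant
    trial site is accepted (the push-off stage relaxes residual overlaps).
    """
    n = template.n_beads
    pos = np.zeros((n, 3))
    placed = np.zeros(n, dtype=bool)

    # BFS order over the bond tree starting from bead 0
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in template.bonds:
        adj[i].append(j)
        adj[j].append(i)
    order = [0]
    parent = {0: None}
    queue = [0]
    while queue:
        u = queue.pop(0)
        for v in adj[u]:
            if v not in parent:
                parent[v] = u
                order.append(v)
                queue.append(v)

    def clearance(p: np.ndarray, exclude: int | None) -> float:
        best = np.inf
        if occupied is not None:
            d, _ = occupied.query(p % L, k=1)
            best = min(best, float(d))
        own = np.flatnonzero(placed)
        if exclude is not None:
            own = own[own != exclude]
        if len(own):
            dd = pos[own] - p
            dd -= L * np.round(dd / L)
            best = min(best, float(np.min(np.linalg.norm(dd, axis=1))))
        return best

    for bead in order:
        par = parent[bead]
        best_p, best_c = None, -1.0
        for _ in range(n_trials):
            if par is None:
                p = rng.uniform(0.0, L, size=3)
            else:
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                p = pos[par] + bond_length * u
            c = clearance(p, exclude=par)
            if c >= min_dist:
                best_p, best_c = p, c
                break
            if c > best_c:
                best_p, best_c = p, c
        pos[bead] = best_p
        placed[bead] = True
    return pos % L


def assemble_system(template_counts: dict, phi: float, seed: int, *,
                    tstar: float = KBT, bond_length: float = 0.97,
                    min_dist: float = 0.8) -> SystemState:
    """Random initial configuration for a mixture of molecule templates.

    ``template_counts`` maps species names (or ``MoleculeTemplate`` objects)
    to copy numbers; the box edge follows from the total bead count and
    ``phi``.  Velocities are Maxwell-Boltzmann at ``tstar`` with zero net
    momentum.  Deterministic for a fixed seed.
    """
    items: list[tuple[MoleculeTemplate, int]] = []
    for key, count in template_counts.items():
        if count < 0:
            raise ValueError("molecule counts must be non-negative")
        if count == 0:
            continue
        tpl = key if isinstance(key, MoleculeTemplate) else build_template(key)
        items.append((tpl, int(count)))
    if not items:
        raise ValueError("at least one template with count >= 1 is required")

    n_beads = sum(t.n_beads * c for t, c in items)
    box = BoxSpec.from_phi(n_beads, phi)
    L = box.length
    rng = np.random.default_rng(seed)

    positions = np.empty((n_beads, 3))
    types = np.empty(n_beads, dtype=np.int8)
    molecule_id = np.empty(n_beads, dtype=np.int64)
    mol_species: list[str] = []
    bonds: list[tuple[int, int]] = []
    branches: list[BranchState] = []

    offset = 0
    mol = 0
    tree: cKDTree | None = None
    tree_size = 0
    for tpl, count in items:
        codes = np.array([TAG_TO_CODE[t] for t in tpl.beads], dtype=np.int8)
        for _ in range(count):
            if offset and offset != tree_size:
                tree = cKDTree(positions[:offset], boxsize=L)
                tree_size = offset
            pos = _grow_molecule(tpl, L, tree, rng, bond_length, min_dist)
            positions[offset:offset + tpl.n_beads] = pos
            types[offset:offset + tpl.n_beads] = codes
            molecule_id[offset:offset + tpl.n_beads] = mol
            for i, j in tpl.bonds:
                bonds.append((offset + i, offset + j))
            for br in tpl.branches:
                bond_lookup = {tuple(sorted(b)): len(bonds) - tpl.n_bonds + k
                               for k, b in enumerate(tpl.bonds)}
                branches.append(BranchState(
                    molecule_id=mol,
                    bead_indices=np.array([offset + b for b in br.bead_order]),
                    bond_indices=np.array([bond_lookup[tuple(sorted(b))]
                                           for b in br.bond_order]),
                ))
            mol_species.append(tpl.species_name)
            offset += tpl.n_beads
            mol += 1

    bonds_arr = (np.array(bonds, dtype=np.int64) if bonds
                 else np.zeros((0, 2), dtype=np.int64))
    state = SystemState(
        positions=positions, velocities=maxwell_boltzmann_velocities(n_beads, tstar, rng),
        images=np.zeros((n_beads, 3), dtype=np.int64), types=types,
        bonds=bonds_arr, bond_active=np.ones(len(bonds_arr), dtype=bool),
        molecule_id=molecule_id, mol_species=mol_species, box=box,
        branches=branches, branch_progress=np.zeros(len(branches), dtype=np.int64),
        rng_seed=seed,
    )
    return state


def insert_triggers(state: SystemState, n_triggers: int, seed: int, *,
                    min_dist: float = 0.8, tstar: float = KBT,
                    max_attempts_per_trigger: int = 2000) -> SystemState:
    """Insert single-bead triggers at random void positions of a snapshot.

    The box is kept fixed, so the overall bead concentration rises
    accordingly.  Each trigger must clear every existing bead by
    ``min_dist``; insertion failure after the attempt budget raises
    :class:`PackingError`.  Returns a new state; the input is untouched.
    """
    rng = np.random.default_rng(seed)
    out = state.copy()
    if n_triggers == 0:
        return out
    if n_triggers < 0:
        raise ValueError("n_triggers must be >= 0")

    L = out.box.length
    new_pos = np.empty((n_triggers, 3))
    placed = 0
    tree = cKDTree(out.positions, boxsize=L)
    attempts = 0
    budget = max_attempts_per_trigger * n_triggers
    while placed < n_triggers:
        if attempts >= budget:
            raise PackingError(
                f"placed only {placed}/{n_triggers} triggers after {attempts} attempts")
        p = rng.uniform(0.0, L, size=3)
        attempts += 1
        d, _ = tree.query(p, k=1)
        ok = d >= min_dist
        if ok and placed:
            dd = new_pos[:placed] - p
            dd -= L * np.round(dd / L)
            ok = float(np.min(np.linalg.norm(dd, axis=1))) >= min_dist
        if ok:
            new_pos[placed] = p
            placed += 1

    n_old = out.n_beads
    out.positions = np.vstack([out.positions, new_pos])
    out.velocities = np.vstack([out.velocities,
                                maxwell_boltzmann_velocities(n_triggers, tstar, rng)])
    out.images = np.vstack([out.images, np.zeros((n_triggers, 3), dtype=np.int64)])
    out.types = np.concatenate([out.types,
                                np.full(n_triggers, T_CODE, dtype=np.int8)])
    first_mol = out.n_molecules
    out.molecule_id = np.concatenate([out.molecule_id,
                                      np.arange(first_mol, first_mol + n_triggers)])
    out.mol_species.extend(["T"] * n_triggers)
    out.box = BoxSpec(phi=(n_old + n_triggers) / L ** 3,
                      n_beads=n_old + n_triggers, length=L)
    return out
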