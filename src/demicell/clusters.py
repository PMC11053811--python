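"""Micelle identification and structural metrics.

Two chains belong to the same micelle when any pair of nonbonded
hydrophobic beads, one from each chain, lies within 1.5 sigma under the
minimum-image convention (Stillinger criterion).  Operationally we build a
contact graph over all participating hydrophobic beads — bonded B/EC beads
of copolymer chains plus cargo C beads — with a periodic k-d tree and take
connected components, which is exactly density clustering with
neighbourhood radius 1.5 sigma and a minimum of two points.  Detached
monomers and trigger beads never participate; a chain stripped of all its
bonded hydrophobic beads can no longer join a micelle and is reported FREE,
as is any chain whose hydrophobic beads touch no other chain.

Aggregation numbers N count copolymer chains only; cargo molecules are
assigned to micelles (for encapsulation accounting) but do not add to N.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .system import SystemState
from .templates import A as A_CODE, B as B_CODE, C as C_CODE, EC as EC_CODE

FREE = -1
STILLINGER_CUTOFF = 1.5


@dataclass
class MicelleAssignment:
    """Cluster labels for one snapshot."""

    chain_labels: dict[int, int]                  # molecule id -> cluster id or FREE
    micelle_chains: dict[int, list[int]]          # cluster id -> copolymer molecule ids
    micelle_cargo: dict[int, list[int]]           # cluster id -> cargo molecule ids
    unwrapped_coords: dict[int, dict[int, np.ndarray]] = field(default_factory=dict)

    @property
    def sizes(self) -> dict[int, int]:
        return {cid: len(mols) for cid, mols in self.micelle_chains.items()}

    def label_of_chain(self, mol_id: int) -> int:
        return self.chain_labels.get(mol_id, FREE)


def identify_chains(state: SystemState) -> dict[int, np.ndarray]:
    """Bead membership of every surviving copolymer chain.

    Beads are nodes and active bonds edges; the connected component holding
    each copolymer's hydrophilic arm is *the* chain, so detached monomers
    (degree-0 beads) are excluded automatically.
    """
    g = nx.Graph()
    g.add_nodes_from(range(state.n_beads))
    g.add_edges_from(map(tuple, state.active_bonds))
    is_copolymer = _copolymer_molecules(state)
    chains: dict[int, np.ndarray] = {}
    for comp in nx.connected_components(g):
        beads = np.fromiter(comp, dtype=np.int64)
        if len(beads) < 2:
            continue
        mol = int(state.molecule_id[beads[0]])
        if is_copolymer[mol]:
            chains[mol] = np.sort(beads)
    return chains


def _copolymer_molecules(state: SystemState) -> np.ndarray:
    return np.array([sp not in ("T",) and not sp.startswith("C")
                     for sp in state.mol_species])


def _cargo_molecules(state: SystemState) -> np.ndarray:
    return np.array([sp.startswith("C") for sp in state.mol_species])


def stillinger_clusters(state: SystemState,
                        cutoff: float = STILLINGER_CUTOFF) -> MicelleAssignment:
    """Partition chains into micelles and FREE chains for one snapshot."""
    if state.n_beads == 0:
        raise ValueError("empty snapshot")
    chains = identify_chains(state)
    is_cargo = _cargo_molecules(state)
    L = state.box.length

    hydro_by_chain: dict[int, np.ndarray] = {}
    participating: list[np.ndarray] = []
    owner_mol: list[np.ndarray] = []
    for mol, beads in chains.items():
        hy = beads[np.isin(state.types[beads], (B_CODE, EC_CODE))]
        hydro_by_chain[mol] = hy
        if len(hy):
            participating.append(hy)
            owner_mol.append(np.full(len(hy), mol))
    cargo_ids = np.flatnonzero(is_cargo)
    for mol in cargo_ids:
        beads = np.flatnonzero(state.molecule_id == mol)
        participating.append(beads)
        owner_mol.append(np.full(len(beads), mol))

    chain_labels = {mol: FREE for mol in chains}
    micelle_chains: dict[int, list[int]] = {}
    micelle_cargo: dict[int, list[int]] = {}
    if not participating:
        return MicelleAssignment(chain_labels, micelle_chains, micelle_cargo)

    beads = np.concatenate(participating)
    owners = np.concatenate(owner_mol)
    tree = cKDTree(np.mod(state.positions[beads], L), boxsize=L)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")

    # union-find over molecules: bead contacts glue their owner molecules
    parent = {}

    def find(a):
        root = a
        while parent.setdefault(root, root) != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    for mol in owners:
        parent.setdefault(int(mol), int(mol))
    for p, q in pairs:
        ra, rb = find(int(owners[p])), find(int(owners[q]))
        if ra != rb:
            parent[rb] = ra

    groups: dict[int, list[int]] = defaultdict(list)
    for mol in sorted(set(int(m) for m in owners)):
        groups[find(mol)].append(mol)

    next_label = 0
    for root in sorted(groups):
        mols = groups[root]
        chain_mols = [m for m in mols if m in chains]
        if len(chain_mols) < 2:
            continue                       # lone chains (even with cargo) stay FREE
        cid = next_label
        next_label += 1
        micelle_chains[cid] = chain_mols
        micelle_cargo[cid] = [m for m in mols if m not in chains]
        for m in chain_mols:
            chain_labels[m] = cid
    return MicelleAssignment(chain_labels, micelle_chains, micelle_cargo)


def _micelle_beads(assignment: MicelleAssignment, state: SystemState,
                   cid: int) -> np.ndarray:
    chains = identify_chains(state)
    beads = [chains[m] for m in assignment.micelle_chains[cid]]
    beads += [np.flatnonzero(state.molecule_id == m)
              for m in assignment.micelle_cargo.get(cid, [])]
    return np.concatenate(beads)


def consolidate_pbc(assignment: MicelleAssignment, state: SystemState,
                    cutoff: float = STILLINGER_CUTOFF) -> MicelleAssignment:
    """Unwrap every micelle across periodic boundaries.

    Beads of each micelle are translated by lattice vectors along a
    spanning tree of the bond-plus-contact graph so that every connected
    pair ends up at its minimum-image separation; the result is unique up
    to a rigid lattice translation of the whole micelle.  Fills
    ``assignment.unwrapped_coords[cid]`` with a bead-index -> coordinate
    map and returns the same assignment object.
    """
    L = state.box.length
    bond_set = {tuple(sorted(b)) for b in map(tuple, state.active_bonds)}
    for cid in assignment.micelle_chains:
        beads = _micelle_beads(assignment, state, cid)
        idx_of = {int(b): k for k, b in enumerate(beads)}
        pos = np.mod(state.positions[beads], L)
        tree = cKDTree(pos, boxsize=L)
        pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
        adj: dict[int, list[int]] = defaultdict(list)
        for p, q in pairs:
            adj[p].append(q)
            adj[q].append(p)
        for i, j in bond_set:
            if i in idx_of and j in idx_of:
                adj[idx_of[i]].append(idx_of[j])
                adj[idx_of[j]].append(idx_of[i])

        out = pos.copy()
        seen = np.zeros(len(beads), dtype=bool)
        for start in range(len(beads)):
            if seen[start]:
                continue
            seen[start] = True
            stack = [start]
            while stack:
                u = stack.pop()
                for v in adj[u]:
                    if not seen[v]:
                        d = pos[v] - out[u]
                        out[v] = out[u] + (d - L * np.round(d / L))
                        seen[v] = True
                        stack.append(v)
        if np.any(out.max(axis=0) - out.min(axis=0) > L / 2):
            warnings.warn(f"micelle {cid} spans more than half the box; "
                          "unwrapping is ambiguous", stacklevel=2)
        assignment.unwrapped_coords[cid] = {int(b): out[k] for k, b in enumerate(beads)}
    return assignment


def mass_distribution(assignments) -> tuple[dict[int, float], int | None]:
    """Chain-weighted micelle mass distribution and the preferential size.

    P(N) is the fraction of micellized chains residing in micelles of
    aggregation number N, pooled over the given snapshots; FREE chains are
    excluded.  N_p is the mode (ties resolved toward smaller N); both are
    empty/None when no micelle exists.
    """
    if isinstance(assignments, MicelleAssignment):
        assignments = [assignments]
    weight: Counter = Counter()
    for asg in assignments:
        for n in asg.sizes.values():
            weight[n] += n
    total = sum(weight.values())
    if not total:
        return {}, None
    dist = {n: weight[n] / total for n in sorted(weight)}
    n_p = max(sorted(dist), key=lambda n: (dist[n], -n))
    return dist, n_p


@dataclass(frozen=True)
class ShapeMetrics:
    """Gyration-tensor size and shape descriptors of one micelle."""

    rg2_total: float
    rg2_core: float
    rg2_corona: float
    kappa2: float


def gyration_tensor(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("need at least two beads for a gyration tensor")
    d = coords - coords.mean(axis=0)
    return d.T @ d / len(coords)


def rg2_kappa2(coords: np.ndarray) -> tuple[float, float]:
    """Squared gyration radius and relative shape anisotropy kappa^2.

    kappa^2 = 1 - 3 (l1 l2 + l2 l3 + l3 l1) / (l1 + l2 + l3)^2 from the
    gyration-tensor eigenvalues: 0 for an isotropic cloud, 1 for a rod.
    """
    lam = np.linalg.eigvalsh(gyration_tensor(coords))
    tr = float(lam.sum())
    if tr <= 0:
        return 0.0, 0.0
    pair_sum = float(lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0])
    return tr, 1.0 - 3.0 * pair_sum / tr ** 2


def gyration_metrics(assignment: MicelleAssignment, state: SystemState,
                     cid: int) -> ShapeMetrics:
    """Shape metrics of one micelle from its unwrapped coordinates.

    Sizes are computed over copolymer beads only (total = whole chains,
    core = hydrophobic B/EC, corona = A), so micelles of equal N compare at
    equal molecular weight; kappa^2 uses the copolymer beads as well.
    """
    if cid not in assignment.unwrapped_coords:
        consolidate_pbc(assignment, state)
    coords_map = assignment.unwrapped_coords[cid]
    chain_mols = set(assignment.micelle_chains[cid])
    beads = np.array([b for b in coords_map if int(state.molecule_id[b]) in chain_mols])
    coords = np.array([coords_map[int(b)] for b in beads])
    t = state.types[beads]
    rg2_total, kappa2 = rg2_kappa2(coords)
    core = coords[np.isin(t, (B_CODE, EC_CODE))]
    corona = coords[t == A_CODE]
    rg2_core = rg2_kappa2(core)[0] if len(core) > 1 else 0.0
    rg2_corona = rg2_kappa2(corona)[0] if len(corona) > 1 else 0.0
    return ShapeMetrics(rg2_total, rg2_core, rg2_corona, kappa2)


def cargo_encapsulated_mask(state: SystemState,
                            assignment: MicelleAssignment | None = None,
                            cutoff: float = STILLINGER_CUTOFF) -> dict[int, bool]:
    """Per-cargo-molecule encapsulation flags.

    A cargo molecule is encapsulated when any of its beads lies within the
    contact cutoff of any bonded hydrophobic bead of a *micellized* chain.
    """
    assignment = assignment or stillinger_clusters(state, cutoff)
    chains = identify_chains(state)
    mic_mols = [m for m, lab in assignment.chain_labels.items() if lab != FREE]
    cargo_ids = np.flatnonzero(_cargo_molecules(state))
    if not len(cargo_ids):
        return {}
    hydro = [chains[m][np.isin(state.types[chains[m]], (B_CODE, EC_CODE))]
             for m in mic_mols]
    flags = {int(m): False for m in cargo_ids}
    if not hydro:
        return flags
    hydro = np.concatenate(hydro)
    L = state.box.length
    tree = cKDTree(np.mod(state.positions[hydro], L), boxsize=L)
    for mol in cargo_ids:
        beads = np.flatnonzero(state.molecule_id == mol)
        hits = tree.query_ball_point(np.mod(state.positions[beads], L), r=cutoff)
        flags[int(mol)] = any(len(h) for h in hits)
    return flags


@dataclass(frozen=True)
class EncapsulationReport:
    """Snapshot- or block-averaged cargo encapsulation summary."""

    frac_encapsulated: float       # fraction of cargo molecules inside micelles
    frac_encapsulated_sem: float
    loading_capacity: float        # w/w % of cargo in the loaded carriers
    n_p: int | None                # preferential aggregation number


def loading_capacity(encapsulated_cargo_beads: float,
                     micellized_copolymer_beads: float) -> float:
    """w/w % of cargo mass in the loaded carrier (all beads have m = 1)."""
    total = encapsulated_cargo_beads + micellized_copolymer_beads
    if total <= 0:
        raise ZeroDivisionError("no mass in the loaded carrier")
    return 100.0 * encapsulated_cargo_beads / total


def block_average(values, n_blocks: int = 10) -> tuple[float, float]:
    """Block-averaged mean and its standard error."""
    values = np.asarray(values, dtype=float)
    n_blocks = max(1, min(n_blocks, len(values)))
    blocks = np.array_split(values, n_blocks)
    means = np.array([b.mean() for b in blocks])
    sem = means.std(ddof=1) / np.sqrt(n_blocks) if n_blocks > 1 else 0.0
    return float(means.mean()), float(sem)


def encapsulation_report(states, assignments=None, *,
                         n_blocks: int = 10,
                         cutoff: float = STILLINGER_CUTOFF) -> EncapsulationReport:
    """Encapsulated fraction, loading capacity and N_p over snapshots.

    ``states`` may be one state or a sequence; ``assignments`` may be
    precomputed.  Fractions and loading capacities are averaged with the
    ten-block method; N_p comes from the pooled mass distribution.
    """
    if isinstance(states, SystemState):
        states = [states]
    if assignments is None:
        assignments = [stillinger_clusters(s, cutoff) for s in states]
    elif isinstance(assignments, MicelleAssignment):
        assignments = [assignments]

    fracs, lcs = [], []
    for state, asg in zip(states, assignments):
        flags = cargo_encapsulated_mask(state, asg, cutoff)
        if not flags:
            raise ValueError("no cargo molecules in the system")
        enc = [m for m, f in flags.items() if f]
        fracs.append(len(enc) / len(flags))
        chains = identify_chains(state)
        mic_mols = [m for m, lab in asg.chain_labels.items() if lab != FREE]
        copoly_beads = sum(len(chains[m]) for m in mic_mols)
        cargo_beads = sum(int(np.sum(state.molecule_id == m)) for m in enc)
        lcs.append(loading_capacity(cargo_beads, copoly_beads)
                   if (cargo_beads + copoly_beads) else 0.0)
    frac, frac_sem = block_average(fracs, n_blocks)
    lc, _ = block_average(lcs, n_blocks)
    _, n_p = mass_distribution(assignments)
    return EncapsulationReport(frac, frac_sem, lc, n_p)
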