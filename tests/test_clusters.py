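import numpy as np
import pytest

from demicell.clusters import (FREE, block_average, cargo_encapsulated_mask,
                               consolidate_pbc, encapsulation_report,
                               loading_capacity, mass_distribution,
                               rg2_kappa2, stillinger_clusters)
from demicell.system import assemble_system
from demicell.templates import TAG_TO_CODE

A, B, EC, C = (TAG_TO_CODE[t] for t in "A B EC C".split())


def place_chain(state, mol, center, spread, rng):
    beads = np.flatnonzero(state.molecule_id == mol)
    base = np.asarray(center, dtype=float)
    offsets = np.cumsum(rng.normal(scale=spread, size=(len(beads), 3)), axis=0)
    state.positions[beads] = np.mod(base + offsets * 0.3, state.box.length)


def oracle_partition(state, cutoff=1.5):
    """Union-find over chains from the full O(n^2) minimum-image distance
    matrix of bonded hydrophobic beads — independent of the k-d tree path."""
    L = state.box.length
    hydro = np.flatnonzero(np.isin(state.types, (B, EC)) & (state.bond_degrees() > 0))
    mols = state.molecule_id[hydro]
    parent = {int(m): int(m) for m in np.unique(mols)}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    pos = np.mod(state.positions[hydro], L)
    d = pos[:, None, :] - pos[None, :, :]
    d -= L * np.round(d / L)
    close = np.einsum("ijk,ijk->ij", d, d) <= cutoff ** 2
    for p, q in zip(*np.nonzero(np.triu(close, k=1))):
        if mols[p] == mols[q]:
            continue
        ra, rb = find(int(mols[p])), find(int(mols[q]))
        if ra != rb:
            parent[rb] = ra
    groups = {}
    for m in parent:
        groups.setdefault(find(m), set()).add(m)
    return {frozenset(g) for g in groups.values() if len(g) >= 2}


def package_partition(assignment):
    return {frozenset(mols) for mols in assignment.micelle_chains.values()}


def two_diblock_stubs(state_factory, dy):
    """Two short A2B2 chains, hydrophobic blocks separated by ``dy``."""
    pos = [[5, 5, 5], [5.9, 5, 5], [6.8, 5, 5], [7.7, 5, 5],
           [5, 5 + dy, 5], [5.9, 5 + dy, 5], [6.8, 5 + dy, 5], [7.7, 5 + dy, 5]]
    types = [A, A, B, B, A, A, B, B]
    bonds = [[0, 1], [1, 2], [2, 3], [4, 5], [5, 6], [6, 7]]
    return state_factory(pos, types, bonds=bonds, L=20.0,
                         mol=[0] * 4 + [1] * 4, species=["A30B30"] * 2)


def test_two_chains_within_cutoff_form_one_micelle(state_factory):
    asg = stillinger_clusters(two_diblock_stubs(state_factory, 1.4))
    assert asg.sizes == {0: 2}
    # same geometry at 1.6 sigma: both FREE
    asg = stillinger_clusters(two_diblock_stubs(state_factory, 1.6))
    assert asg.micelle_chains == {}
    assert set(asg.chain_labels.values()) == {FREE}


def test_contact_between_hydrophilic_blocks_does_not_cluster(state_factory):
    # A blocks touching (0.6 sigma apart), hydrophobic blocks far away
    pos = [[5, 5, 5], [5.9, 5, 5], [15, 5, 5], [15.9, 5, 5],
           [5, 5.6, 5], [5.9, 5.6, 5], [5, 15, 5], [5.9, 15, 5]]
    types = [A, A, B, B, A, A, B, B]
    bonds = [[0, 1], [1, 2], [2, 3], [4, 5], [5, 6], [6, 7]]
    st = state_factory(pos, types, bonds=bonds, L=30.0,
                       mol=[0] * 4 + [1] * 4, species=["A30B30"] * 2)
    asg = stillinger_clusters(st)
    assert asg.micelle_chains == {}


@pytest.mark.parametrize("seed", range(20))
def test_partition_matches_brute_force_oracle(seed):
    """Random compact boxes of up to 30 chains, including cross-boundary
    micelles, agree with the O(n^2) union-find reference."""
    rng = np.random.default_rng(seed)
    n_chains = int(rng.integers(5, 30))
    arch = ("A30B30", "A30(B15)2", "A30(B10)3")[seed % 3]
    st = assemble_system({arch: n_chains}, 0.12, seed=seed)
    for mol in range(n_chains):
        place_chain(st, mol, rng.uniform(0, st.box.length, 3), 1.0, rng)
    asg = stillinger_clusters(st)
    assert package_partition(asg) == oracle_partition(st)


def test_partition_invariant_under_rigid_translation():
    st = assemble_system({"A30B30": 12}, 0.12, seed=5)
    ref = package_partition(stillinger_clusters(st))
    st.positions = np.mod(st.positions + [3.123, -7.7, 11.1], st.box.length)
    assert package_partition(stillinger_clusters(st)) == ref


def test_depolymerized_chain_is_free():
    st = assemble_system({"A30B30": 2}, 0.001, seed=3)
    # collapse both hydrophobic blocks onto adjacent lattice sites: micelle
    for mol, y in ((0, 0.0), (1, 1.2)):
        beads = np.flatnonzero(st.molecule_id == mol)[30:]
        st.positions[beads] = np.column_stack(
            [10 + 0.9 * np.arange(30), np.full(30, 20 + y), np.full(30, 20.0)])
    assert stillinger_clusters(st).sizes == {0: 2}
    # strip every hydrophobic bead off chain 0: it can no longer micellize
    st.bond_active[st.branches[0].bond_indices] = False
    st.branch_progress[0] = len(st.branches[0])
    asg = stillinger_clusters(st)
    assert asg.micelle_chains == {}
    assert asg.chain_labels[0] == FREE


def test_unwrap_across_one_face(state_factory):
    L = 10.0
    # one bonded 5-bead hydrophobic chain straddling the x = 0 face:
    # a single chain never forms a micelle however it wraps
    xs = np.array([9.2, 9.8, 0.4, 1.0, 1.6])
    st = state_factory([[x, 5, 5] for x in xs], [B] * 5,
                       bonds=[[0, 1], [1, 2], [2, 3], [3, 4]], L=L,
                       mol=[0] * 5, species=["A30B30"])
    asg = stillinger_clusters(st)
    assert asg.micelle_chains == {}

    # two straddling chains -> one micelle; unwrap must shrink the span
    st2 = state_factory([[9.3, 5, 5], [9.9, 5, 5], [0.5, 5, 5],
                         [9.3, 6.2, 5], [9.9, 6.2, 5], [0.5, 6.2, 5]],
                        [B] * 6, bonds=[[0, 1], [1, 2], [3, 4], [4, 5]], L=L,
                        mol=[0, 0, 0, 1, 1, 1], species=["A30B30"] * 2)
    asg2 = stillinger_clusters(st2)
    assert asg2.sizes == {0: 2}
    consolidate_pbc(asg2, st2)
    coords = np.array(list(asg2.unwrapped_coords[0].values()))
    assert coords[:, 0].max() - coords[:, 0].min() < 2.0   # raw wrapped span ~9.4


def test_unwrap_interior_micelle_unchanged(state_factory):
    st = state_factory([[5, 5, 5], [5.9, 5, 5], [5, 6.1, 5], [5.9, 6.1, 5]],
                       [B] * 4, bonds=[[0, 1], [2, 3]], L=20.0,
                       mol=[0, 0, 1, 1], species=["A30B30"] * 2)
    asg = consolidate_pbc(stillinger_clusters(st), st)
    coords = asg.unwrapped_coords[0]
    for bead, xyz in coords.items():
        assert np.allclose(xyz, st.positions[bead])


def test_unwrap_corner_straddle_rg_translation_invariant(state_factory):
    """A micelle wrapped through a box corner has the same Rg^2 as the same
    geometry rigidly shifted to the box centre."""
    rng = np.random.default_rng(3)
    L = 12.0
    base = rng.uniform(-1.2, 1.2, size=(12, 3))          # compact blob at origin
    base.sort(axis=0)                                     # keep contacts likely
    bonds = [[i, i + 1] for i in range(5)] + [[6 + i, 7 + i] for i in range(5)]

    from conftest import make_state

    st_corner = make_state(base, [B] * 12, bonds=bonds, L=L,
                           mol=[0] * 6 + [1] * 6, species=["A30B30"] * 2)
    st_center = make_state(base + L / 2, [B] * 12, bonds=bonds, L=L,
                           mol=[0] * 6 + [1] * 6, species=["A30B30"] * 2)
    rgs = []
    for st in (st_corner, st_center):
        asg = consolidate_pbc(stillinger_clusters(st), st)
        assert asg.sizes == {0: 2}
        coords = np.array(list(asg.unwrapped_coords[0].values()))
        rgs.append(rg2_kappa2(coords)[0])
    assert rgs[0] == pytest.approx(rgs[1], rel=1e-9)


def test_mass_distribution_counting_and_mode():
    class Fake:
        def __init__(self, sizes):
            self.sizes = sizes

    dist, n_p = mass_distribution([Fake({0: 2, 1: 2, 2: 6})])
    assert dist == {2: pytest.approx(0.4), 6: pytest.approx(0.6)}
    assert n_p == 6
    # single micelle of five chains + free chains: P(5) = 1
    dist, n_p = mass_distribution([Fake({0: 5})])
    assert dist == {5: 1.0}
    assert n_p == 5
    # no micelles
    dist, n_p = mass_distribution([Fake({})])
    assert dist == {} and n_p is None
    # tie (9 chains in size-3 micelles vs 9 in one size-9) resolves smaller
    dist, n_p = mass_distribution([Fake({0: 3, 1: 3, 2: 3, 3: 9})])
    assert dist[3] == pytest.approx(dist[9])
    assert n_p == 3
    assert sum(dist.values()) == pytest.approx(1.0)


def test_gyration_reference_geometries():
    # collinear beads: rod limit
    rod = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
    assert rg2_kappa2(rod)[1] == pytest.approx(1.0)
    # regular tetrahedron: isotropic
    tetra = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
    assert rg2_kappa2(tetra)[1] == pytest.approx(0.0, abs=1e-12)
    # planar cross: Rg^2 = 1, kappa^2 = 0.25
    cross = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], dtype=float)
    rg2, k2 = rg2_kappa2(cross)
    assert rg2 == pytest.approx(1.0)
    assert k2 == pytest.approx(0.25)


def test_gyration_invariant_under_rotation_translation(rng):
    pts = rng.normal(size=(40, 3)) * [3.0, 1.0, 0.4]
    rg2, k2 = rg2_kappa2(pts)
    # random rotation via QR
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    rot = pts @ q + [17.0, -4.0, 2.5]
    rg2_r, k2_r = rg2_kappa2(rot)
    assert rg2_r == pytest.approx(rg2, rel=1e-10)
    assert k2_r == pytest.approx(k2, rel=1e-9)
    assert 0.0 <= k2 <= 1.0


def test_loading_capacity_worked_examples():
    # all 2000 trimers in micelles of all 1000 chains: 6000/66000
    assert loading_capacity(6000, 60_000) == pytest.approx(100 * 6000 / 66_000)
    # the reference mixtures: 82% of 2000 or 4000 trimers encapsulated
    assert loading_capacity(0.82 * 2000 * 3, 60_000) == pytest.approx(7.58, abs=0.05)
    assert loading_capacity(0.82 * 4000 * 3, 60_000) == pytest.approx(14.09, abs=0.05)


def test_encapsulation_report_counts_molecules(state_factory):
    # two chains forming a micelle, one cargo adjacent, one far away
    pos = [[5, 5, 5], [5.9, 5, 5], [5, 6.1, 5], [5.9, 6.1, 5],
           [5, 7.0, 5], [5.9, 7.0, 5], [5.9, 7.9, 5],     # cargo 1 touching
           [15, 15, 15], [15.9, 15, 15], [15.9, 15.9, 15]]  # cargo 2 far
    types = [B, B, B, B, C, C, C, C, C, C]
    st = state_factory(pos, types, bonds=[[0, 1], [2, 3], [4, 5], [5, 6],
                                          [7, 8], [8, 9]], L=30.0,
                       mol=[0, 0, 1, 1, 2, 2, 2, 3, 3, 3],
                       species=["A30B30", "A30B30", "C3", "C3"])
    flags = cargo_encapsulated_mask(st)
    assert flags == {2: True, 3: False}
    rep = encapsulation_report(st)
    assert rep.frac_encapsulated == pytest.approx(0.5)
    # LC: 3 cargo beads vs 4 micellized copolymer beads
    assert rep.loading_capacity == pytest.approx(100 * 3 / 7)


def test_block_average_matches_manual_blocks():
    x = np.arange(20.0)
    mean, sem = block_average(x, n_blocks=10)
    assert mean == pytest.approx(x.mean())
    assert sem > 0


def test_empty_snapshot_raises(state_factory):
    st = state_factory(np.zeros((0, 3)), [], L=10.0, mol=[], species=[])
    with pytest.raises(ValueError):
        stillinger_clusters(st)
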