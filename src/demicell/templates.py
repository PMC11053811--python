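"""Molecule templates for the coarse-grained species.

Five species make up every mixture studied here:

* linear diblock copolymer ``A30B30`` — 30 hydrophilic A beads followed by
  a 30-bead hydrophobic block whose free end is the labile end-cap;
* miktoarm stars ``A30(B15)2`` and ``A30(B10)3`` — one 30-bead A arm with
  two or three hydrophobic branches joined at the last A bead, one end-cap
  per branch;
* cargo ``C3`` — a linear trimer of hydrophobic C beads;
* trigger ``T`` — a single hydrophobic bead.

All beads share mass m = 1 and diameter sigma = 1 (reduced units).  The
end-cap (tag ``EC``) is chemically distinct only for the reaction engine;
its pair interactions are those of a B bead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

# Integer type codes used throughout the package (and, +1, in LAMMPS-style files).
A, B, EC, C, T, X = range(6)
TYPE_TAGS = ("A", "B", "EC", "C", "T", "X")
TAG_TO_CODE = {tag: code for code, tag in enumerate(TYPE_TAGS)}

#: bead types that count as hydrophobic in the cluster (Stillinger) criterion
HYDROPHOBIC_TAGS = frozenset({"B", "EC", "C"})
HYDROPHOBIC_CODES = frozenset({B, EC, C})

COPOLYMER_SPECIES = ("A30B30", "A30(B15)2", "A30(B10)3")

_MIKTO_RE = re.compile(r"^A(\d+)\(B(\d+)\)(\d+)$")
_LINEAR_RE = re.compile(r"^A(\d+)B(\d+)$")


@dataclass(frozen=True)
class BeadSpec:
    """A single coarse-grained bead. All species use unit mass and diameter."""

    type_tag: str
    mass: float = 1.0
    diameter: float = 1.0

    def __post_init__(self):
        if self.type_tag not in TAG_TO_CODE:
            raise ValueError(f"unknown bead type tag {self.type_tag!r}")
        if self.mass != 1.0 or self.diameter != 1.0:
            raise ValueError("all bead types share mass = 1 and diameter = 1 sigma")


@dataclass(frozen=True)
class BranchSpec:
    """Scission order of one hydrophobic branch, from the end-cap inward.

    ``bond_order[i]`` is the (local bead index) pair whose rupture detaches
    ``bead_order[i]``; ``bond_order[0]`` is the labile end-cap bond and the
    final entry is the junction bond to the hydrophilic arm, so breaking the
    whole sequence strips every hydrophobic bead off the branch head-to-tail.
    """

    bead_order: tuple[int, ...]
    bond_order: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.bond_order)


@dataclass(frozen=True)
class MoleculeTemplate:
    """Per-species bead/bond layout with end-cap annotations."""

    species_name: str
    beads: tuple[str, ...]                      # type tags, in bead order
    bonds: tuple[tuple[int, int], ...]          # local bead-index pairs
    endcap_indices: tuple[int, ...] = ()
    branches: tuple[BranchSpec, ...] = field(default=())

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def n_endcaps(self) -> int:
        return len(self.endcap_indices)

    def __post_init__(self):
        seen = set()
        for i, j in self.bonds:
            key = (min(i, j), max(i, j))
            if i == j or key in seen:
                raise ValueError(f"duplicate or degenerate bond {(i, j)} in {self.species_name}")
            seen.add(key)
        # chains and stars only: connected, acyclic
        if self.n_beads > 1 and self.n_bonds != self.n_beads - 1:
            raise ValueError(f"{self.species_name}: bond graph must be a tree "
                             f"({self.n_bonds} bonds for {self.n_beads} beads)")
        deg = [0] * self.n_beads
        for i, j in self.bonds:
            deg[i] += 1
            deg[j] += 1
        for idx in self.endcap_indices:
            if self.beads[idx] != "EC":
                raise ValueError(f"bead {idx} flagged as end-cap but typed {self.beads[idx]}")
            if deg[idx] != 1:
                raise ValueError(f"end-cap bead {idx} must have exactly one bond")


def copolymer_template(species_name: str, n_hydrophilic: int,
                       branch_lengths: tuple[int, ...]) -> MoleculeTemplate:
    """Build an amphiphile with one A arm and any number of hydrophobic branches.

    Each branch of length ``b`` contributes ``b - 1`` B beads plus one terminal
    end-cap, all attached to the free end of the A arm (the conventional
    miktoarm junction).  ``branch_lengths == (b,)`` gives the linear diblock.
    """
    if n_hydrophilic < 1:
        raise ValueError("need at least one hydrophilic bead")
    if not branch_lengths or any(b < 1 for b in branch_lengths):
        raise ValueError("every hydrophobic branch needs at least one bead")

    beads: list[str] = ["A"] * n_hydrophilic
    bonds: list[tuple[int, int]] = [(i, i + 1) for i in range(n_hydrophilic - 1)]
    junction = n_hydrophilic - 1
    endcaps: list[int] = []
    branches: list[BranchSpec] = []

    for blen in branch_lengths:
        first = len(beads)
        beads.extend(["B"] * (blen - 1) + ["EC"])
        branch_beads = list(range(first, first + blen))
        prev = junction
        branch_bonds = []
        for bead in branch_beads:
            branch_bonds.append((prev, bead))
            prev = bead
        bonds.extend(branch_bonds)
        endcaps.append(branch_beads[-1])
        # scission order: end-cap bond first, junction bond last
        branches.append(BranchSpec(
            bead_order=tuple(reversed(branch_beads)),
            bond_order=tuple(reversed(branch_bonds)),
        ))

    return MoleculeTemplate(species_name, tuple(beads), tuple(bonds),
                            tuple(endcaps), tuple(branches))


def cargo_template(n_beads: int = 3) -> MoleculeTemplate:
    beads = tuple(["C"] * n_beads)
    bonds = tuple((i, i + 1) for i in range(n_beads - 1))
    return MoleculeTemplate(f"C{n_beads}", beads, bonds)


def trigger_template() -> MoleculeTemplate:
    return MoleculeTemplate("T", ("T",), ())


def build_template(species_name: str, architecture_params: dict | None = None) -> MoleculeTemplate:
    """Construct the template for one of the named species.

    ``A30B30``, ``A30(B15)2`` and ``A30(B10)3`` (and any ``An(Bm)k`` /
    ``AnBm`` pattern with ``n = 30`` A beads and 30 hydrophobic beads in
    total) give 60-bead amphiphiles; ``C3`` gives the cargo trimer and
    ``T`` the single-bead trigger.  ``architecture_params`` may override the
    parsed layout with keys ``n_hydrophilic`` and ``branch_lengths``.
    """
    params = dict(architecture_params or {})
    if params:
        n_a = params.pop("n_hydrophilic")
        branch_lengths = tuple(params.pop("branch_lengths"))
        if params:
            raise ValueError(f"unknown architecture parameters: {sorted(params)}")
        return copolymer_template(species_name, n_a, branch_lengths)

    if species_name == "T":
        return trigger_template()
    m = re.fullmatch(r"C(\d+)", species_name)
    if m:
        return cargo_template(int(m.group(1)))

    m = _LINEAR_RE.fullmatch(species_name)
    if m:
        n_a, n_b = int(m.group(1)), int(m.group(2))
        branch_lengths: tuple[int, ...] = (n_b,)
    else:
        m = _MIKTO_RE.fullmatch(species_name)
        if not m:
            raise ValueError(f"unknown species {species_name!r}")
        n_a, blen, nbr = (int(g) for g in m.groups())
        branch_lengths = (blen,) * nbr

    if n_a != 30 or sum(branch_lengths) != 30:
        raise ValueError(
            f"{species_name}: copolymers carry 30 A beads and 30 hydrophobic "
            f"beads (got {n_a} A, {sum(branch_lengths)} hydrophobic); use "
            f"architecture_params to build other layouts")
    return copolymer_template(species_name, n_a, branch_lengths)


def endcaps_per_chain(species_name: str) -> int:
    """Number of labile end-caps of a copolymer species (1, 2 or 3 here)."""
    return build_template(species_name).n_endcaps
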