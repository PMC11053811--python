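"""Snapshot and trajectory I/O.

Three plain-text dialects are supported:

* LAMMPS data files (``Atoms # molecular`` + ``Bonds``) for full topology
  round trips;
* LAMMPS dump frames with columns ``id mol type x y z ix iy iz`` — the
  image flags keep unwrapped coordinates recoverable for MSD work;
* extended XYZ with ``type`` and ``mol`` columns for quick visualisation.

Bead types are written 1-based (LAMMPS convention) in the order
A, B, EC, C, T, X.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .system import BoxSpec, SystemState
from .templates import EC as EC_CODE, TYPE_TAGS, TAG_TO_CODE


def write_lammps_data(state: SystemState, path) -> None:
    L = state.box.length
    lines = ["# demicell configuration", "",
             f"{state.n_beads} atoms", f"{len(state.active_bonds)} bonds", "",
             f"{len(TYPE_TAGS)} atom types", "1 bond types", "",
             f"0.0 {L:.10g} xlo xhi", f"0.0 {L:.10g} ylo yhi", f"0.0 {L:.10g} zlo zhi",
             "", "Masses", ""]
    lines += [f"{k + 1} 1.0" for k in range(len(TYPE_TAGS))]
    lines += ["", "Atoms # molecular", ""]
    for i in range(state.n_beads):
        x, y, z = state.positions[i]
        ix, iy, iz = state.images[i]
        lines.append(f"{i + 1} {state.molecule_id[i] + 1} {state.types[i] + 1} "
                     f"{x:.10g} {y:.10g} {z:.10g} {ix} {iy} {iz}")
    ab = state.active_bonds
    if len(ab):
        lines += ["", "Bonds", ""]
        for b, (i, j) in enumerate(ab):
            lines.append(f"{b + 1} 1 {i + 1} {j + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_lammps_data(path) -> SystemState:
    """Read a molecular-style data file back into a SystemState.

    Species names are reconstructed generically per molecule (from bead
    type content) and depolymerization branches are not rebuilt — data
    files round-trip coordinates and topology for analysis-only work.
    """
    text = Path(path).read_text().splitlines()
    n_atoms = n_bonds = 0
    L = None
    section = None
    atoms: dict[int, tuple] = {}
    bonds: list[tuple[int, int]] = []
    for raw in text[1:]:
        line = raw.split("#")[0].strip()
        if not line:
            continue
        if line.endswith("atoms"):
            n_atoms = int(line.split()[0])
            continue
        if line.endswith("bonds"):
            n_bonds = int(line.split()[0])
            continue
        if line.endswith("xhi"):
            lo, hi = (float(v) for v in line.split()[:2])
            L = hi - lo
            continue
        if line.endswith(("yhi", "zhi")) or line.endswith("types"):
            continue
        if line in ("Masses", "Atoms", "Bonds", "Velocities"):
            section = line
            continue
        parts = line.split()
        if section == "Atoms":
            idx = int(parts[0]) - 1
            img = tuple(int(v) for v in parts[6:9]) if len(parts) >= 9 else (0, 0, 0)
            atoms[idx] = (int(parts[1]) - 1, int(parts[2]) - 1,
                          tuple(float(v) for v in parts[3:6]), img)
        elif section == "Bonds":
            bonds.append((int(parts[2]) - 1, int(parts[3]) - 1))

    if len(atoms) != n_atoms or len(bonds) != n_bonds or L is None:
        raise ValueError(f"malformed data file {path}")
    order = sorted(atoms)
    mol = np.array([atoms[i][0] for i in order])
    types = np.array([atoms[i][1] for i in order], dtype=np.int8)
    pos = np.array([atoms[i][2] for i in order])
    images = np.array([atoms[i][3] for i in order], dtype=np.int64)
    n_mol = int(mol.max()) + 1 if len(mol) else 0
    species = []
    for m in range(n_mol):
        t = types[mol == m]
        if np.any(t == TAG_TO_CODE["A"]):
            species.append(_guess_copolymer_name(t, np.array(bonds), mol, m))
        elif np.all(np.isin(t, (TAG_TO_CODE["C"],))):
            species.append(f"C{len(t)}")
        else:
            species.append("T" if len(t) == 1 else "X-mol")
    barr = np.array(bonds, dtype=np.int64) if bonds else np.zeros((0, 2), dtype=np.int64)
    return SystemState(
        positions=pos, velocities=np.zeros_like(pos), images=images, types=types,
        bonds=barr, bond_active=np.ones(len(barr), dtype=bool), molecule_id=mol,
        mol_species=species, box=BoxSpec(phi=n_atoms / L ** 3, n_beads=n_atoms, length=L),
    )


def _guess_copolymer_name(t: np.ndarray, bonds: np.ndarray, mol: np.ndarray,
                          m: int) -> str:
    n_a = int(np.sum(t == TAG_TO_CODE["A"]))
    n_ec = int(np.sum(t == EC_CODE))
    n_hydro = len(t) - n_a
    if n_ec <= 1:
        return f"A{n_a}B{n_hydro}"
    return f"A{n_a}(B{n_hydro // n_ec}){n_ec}"


def write_dump_frame(fh, state: SystemState, timestep: int | None = None) -> None:
    L = state.box.length
    fh.write("ITEM: TIMESTEP\n")
    fh.write(f"{int(state.time / 0.006) if timestep is None else timestep}\n")
    fh.write("ITEM: NUMBER OF ATOMS\n")
    fh.write(f"{state.n_beads}\n")
    fh.write("ITEM: BOX BOUNDS pp pp pp\n")
    for _ in range(3):
        fh.write(f"0.0 {L:.10g}\n")
    fh.write("ITEM: ATOMS id mol type x y z ix iy iz\n")
    for i in range(state.n_beads):
        x, y, z = state.positions[i]
        ix, iy, iz = state.images[i]
        fh.write(f"{i + 1} {state.molecule_id[i] + 1} {state.types[i] + 1} "
                 f"{x:.8g} {y:.8g} {z:.8g} {ix} {iy} {iz}\n")


def write_dump(states, path, timesteps=None) -> None:
    """Write one state or a sequence of states as a LAMMPS dump file."""
    if isinstance(states, SystemState):
        states = [states]
    with open(path, "w") as fh:
        for k, st in enumerate(states):
            write_dump_frame(fh, st, None if timesteps is None else timesteps[k])


def read_dump(path) -> list[dict]:
    """Parse a LAMMPS dump into frame dicts (positions, images, types, mol...)."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].startswith("ITEM: TIMESTEP"):
            i += 1
            continue
        timestep = int(lines[i + 1])
        n = int(lines[i + 3])
        lo, hi = (float(v) for v in lines[i + 5].split()[:2])
        cols = lines[i + 8].split()[2:]
        rows = [lines[i + 9 + k].split() for k in range(n)]
        i += 9 + n
        data = {c: np.array([r[j] for r in rows], dtype=float)
                for j, c in enumerate(cols)}
        order = np.argsort(data["id"])
        frame = {
            "timestep": timestep,
            "box_length": hi - lo,
            "molecule_id": data["mol"][order].astype(np.int64) - 1,
            "types": data["type"][order].astype(np.int8) - 1,
            "positions": np.column_stack([data[c][order] for c in "xyz"]),
        }
        if "ix" in data:
            frame["images"] = np.column_stack(
                [data[c][order] for c in ("ix", "iy", "iz")]).astype(np.int64)
        frames.append(frame)
    return frames


def write_xyz(states, path) -> None:
    """Extended XYZ with per-bead species tag and molecule id."""
    if isinstance(states, SystemState):
        states = [states]
    with open(path, "w") as fh:
        for st in states:
            L = st.box.length
            fh.write(f"{st.n_beads}\n")
            fh.write(f'Lattice="{L} 0 0 0 {L} 0 0 0 {L}" '
                     f'Properties=species:S:1:pos:R:3:mol:I:1 Time={st.time}\n')
            for i in range(st.n_beads):
                x, y, z = st.positions[i]
                fh.write(f"{TYPE_TAGS[st.types[i]]} {x:.8g} {y:.8g} {z:.8g} "
                         f"{st.molecule_id[i] + 1}\n")


def read_xyz(path) -> list[dict]:
    frames = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        header = lines[i + 1]
        L = None
        if 'Lattice="' in header:
            L = float(header.split('Lattice="')[1].split()[0])
        tags, pos, mols = [], [], []
        for k in range(n):
            parts = lines[i + 2 + k].split()
            tags.append(parts[0])
            pos.append([float(v) for v in parts[1:4]])
            mols.append(int(parts[4]) - 1 if len(parts) > 4 else 0)
        frames.append({
            "types": np.array([TAG_TO_CODE[t] for t in tags], dtype=np.int8),
            "positions": np.array(pos),
            "molecule_id": np.array(mols, dtype=np.int64),
            "box_length": L,
        })
        i += 2 + n
    return frames
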