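"""Pair and bond potentials of the bead-spring model.

Non-bonded beads interact through a cut-and-shifted Lennard-Jones potential

    U(r) = 4 eps [ (sigma/r)^12 - (sigma/r)^6 - (sigma/rc)^12 + (sigma/rc)^6 ],  r <= rc

which vanishes continuously at the cutoff.  Repulsive pairs use
rc = 2^(1/6) sigma (the WCA form, shifted up by eps); attractive pairs use
rc = 2.5 sigma.  Bonded neighbours are held by FENE springs

    U_bond(r) = -0.5 k R0^2 ln(1 - (r/R0)^2),   k = 25 eps/sigma^2, R0 = 1.5 sigma

composed, in the usual Kremer-Grest fashion, with a purely repulsive WCA
term; a bond stretched to R0 is unphysical and raises an error.

Attraction strengths are specified as effective pair temperatures T*_ij.
The thermostat runs at k_B T = 1.8 eps, so a pair assigned T*_ij has well
depth eps_ij = 1.8 / T*_ij: lowering T*_ij below 1.8 deepens the well and
makes the pair more attractive (e.g. T*_BC = 1.4 -> eps_BC ~ 1.286).  The
historical inverse convention eps_ij = T*_ij / 1.8 is available via
``invert_eps_mapping`` but is not the default, since it would make low
T*_ij pairs *less* attractive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .templates import A, B, C, EC, T, TAG_TO_CODE, X

SIGMA = 1.0
KBT = 1.8                      # thermostat energy scale k_B T / eps
WCA_CUTOFF = 2.0 ** (1.0 / 6.0)
ATTRACTIVE_CUTOFF = 2.5
FENE_K = 25.0                  # eps / sigma^2
FENE_R0 = 1.5                  # sigma

#: pair tags that are attractive (everything involving A, or X, is repulsive)
ATTRACTIVE_PAIRS = frozenset(
    frozenset(p) for p in [("B", "B"), ("B", "C"), ("C", "C"),
                           ("T", "T"), ("B", "T"), ("T", "C")]
)

DEFAULT_TSTAR_MAP = {
    ("B", "B"): 1.8,
    ("B", "C"): 1.8,
    ("C", "C"): 1.8,
    ("T", "T"): 1.8,
    ("B", "T"): 1.8,
    ("T", "C"): 1.8,
}


class BondOverstretchError(RuntimeError):
    """A FENE bond reached its maximum extension R0."""


def lj_pair_energy(r, eps_ij: float, rc_ij: float):
    """Cut-and-shifted Lennard-Jones energy; zero beyond the cutoff.

    Accepts scalars or arrays; r = 0 raises (overlap singularity).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0.0):
        raise ValueError("pair distance must be positive (bead overlap)")
    sr6 = (SIGMA / r) ** 6
    src6 = (SIGMA / rc_ij) ** 6
    u = 4.0 * eps_ij * (sr6 * sr6 - sr6 - src6 * src6 + src6)
    u = np.where(r <= rc_ij, u, 0.0)
    return float(u) if u.ndim == 0 else u


def lj_pair_force(r, eps_ij: float, rc_ij: float):
    """Magnitude of the radial pair force, -dU/dr (positive = repulsive)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0.0):
        raise ValueError("pair distance must be positive (bead overlap)")
    sr6 = (SIGMA / r) ** 6
    f = 24.0 * eps_ij * (2.0 * sr6 * sr6 - sr6) / r
    f = np.where(r <= rc_ij, f, 0.0)
    return float(f) if f.ndim == 0 else f


def fene_bond_energy(r, k: float = FENE_K, r0: float = FENE_R0):
    """FENE spring energy; diverges (error) at or beyond the maximum extension."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0.0):
        raise ValueError("bond length cannot be negative")
    if np.any(r >= r0):
        raise BondOverstretchError(f"bond length {float(np.max(r)):.4f} sigma >= R0 = {r0} sigma")
    u = -0.5 * k * r0 * r0 * np.log1p(-((r / r0) ** 2))
    return float(u) if u.ndim == 0 else u


def fene_bond_force(r, k: float = FENE_K, r0: float = FENE_R0):
    """Restoring force magnitude -dU/dr of the FENE spring (negative: inward)."""
    r = np.asarray(r, dtype=float)
    if np.any(r >= r0):
        raise BondOverstretchError(f"bond length {float(np.max(r)):.4f} sigma >= R0 = {r0} sigma")
    f = -k * r / (1.0 - (r / r0) ** 2)
    return float(f) if f.ndim == 0 else f


@dataclass
class InteractionTable:
    """Symmetric per-type-pair well depths and cutoffs plus FENE parameters.

    ``eps`` and ``rcut`` are 6x6 arrays indexed by the integer bead-type
    codes; the EC row duplicates B (the end-cap is chemically labile but
    interacts as an ordinary hydrophobic bead) and X (inert/consumed) is
    repulsive toward everything.
    """

    eps: np.ndarray
    rcut: np.ndarray
    fene_k: float = FENE_K
    fene_R0: float = FENE_R0
    kbt: float = KBT
    bonded_wca: bool = True    # Kremer-Grest: bonds feel FENE + repulsive LJ core
    force_cap: float = np.inf  # pair-force limiter; finite only during push-off

    def __post_init__(self):
        self.eps = np.asarray(self.eps, dtype=float)
        self.rcut = np.asarray(self.rcut, dtype=float)
        if self.eps.shape != (6, 6) or self.rcut.shape != (6, 6):
            raise ValueError("interaction matrices must be 6x6 (one row per bead type)")
        if not (np.allclose(self.eps, self.eps.T) and np.allclose(self.rcut, self.rcut.T)):
            raise ValueError("interaction matrices must be symmetric")

    def pair(self, tag_i: str, tag_j: str) -> tuple[float, float]:
        """(eps_ij, rc_ij) for a pair of type tags."""
        i, j = TAG_TO_CODE[tag_i], TAG_TO_CODE[tag_j]
        return float(self.eps[i, j]), float(self.rcut[i, j])

    @property
    def max_cutoff(self) -> float:
        return float(self.rcut.max())

    def pushoff_copy(self, force_cap: float = 200.0) -> "InteractionTable":
        """Table for the push-off stage: every cutoff collapsed to 2^(1/6) sigma,
        leaving only the shifted repulsive core, with the pair force capped so
        residual insertion overlaps relax smoothly instead of exploding."""
        return InteractionTable(self.eps.copy(), np.full((6, 6), WCA_CUTOFF),
                                self.fene_k, self.fene_R0, self.kbt,
                                self.bonded_wca, force_cap)


def _normalise_key(key) -> frozenset:
    if isinstance(key, str):
        parts = tuple(key.replace("-", " ").split())
        if len(parts) != 2:
            raise ValueError(f"cannot parse pair key {key!r}")
        key = parts
    return frozenset(key)


def build_interaction_table(tstar_map: dict | None = None, *, kbt: float = KBT,
                            invert_eps_mapping: bool = False,
                            bonded_wca: bool = True) -> InteractionTable:
    """Build the full pair-interaction table from a map of pair temperatures.

    ``tstar_map`` assigns an effective T* to each attractive pair among
    B-B, B-C, C-C, T-T, B-T, T-C (tuple or "B-C" string keys; unlisted
    attractive pairs default to T* = 1.8).  Attractive pairs get
    eps_ij = kbt / T*_ij and rc = 2.5 sigma; every pair involving A or X is
    repulsive with eps = 1 and rc = 2^(1/6) sigma (shifted to zero at the
    cutoff).  The end-cap inherits B's row.
    """
    tmap = dict(DEFAULT_TSTAR_MAP)
    if tstar_map:
        for key, tstar in tstar_map.items():
            k = _normalise_key(key)
            if k not in ATTRACTIVE_PAIRS:
                raise ValueError(f"pair {sorted(k)} is repulsive; only attractive pairs take a T*")
            tmap[tuple(sorted(k))] = float(tstar)
    tmap = {_normalise_key(k): v for k, v in tmap.items()}
    missing = ATTRACTIVE_PAIRS - set(tmap)
    if missing:
        raise ValueError(f"missing T* for pairs {[sorted(p) for p in missing]}")

    eps = np.ones((6, 6))
    rcut = np.full((6, 6), WCA_CUTOFF)
    base = {"A": A, "B": B, "C": C, "T": T}
    for pair_key, tstar in tmap.items():
        if tstar <= 0:
            raise ValueError(f"T* must be positive for pair {sorted(pair_key)}")
        tags = sorted(pair_key)
        ti, tj = (tags[0], tags[-1]) if len(tags) == 2 else (tags[0], tags[0])
        e = tstar / kbt if invert_eps_mapping else kbt / tstar
        i, j = base[ti], base[tj]
        eps[i, j] = eps[j, i] = e
        rcut[i, j] = rcut[j, i] = ATTRACTIVE_CUTOFF
    # the end-cap interacts exactly as B
    eps[EC, :] = eps[B, :]
    eps[:, EC] = eps[:, B]
    eps[EC, EC] = eps[B, B]
    rcut[EC, :] = rcut[B, :]
    rcut[:, EC] = rcut[:, B]
    rcut[EC, EC] = rcut[B, B]
    # X is inert: purely repulsive toward everything (rows already WCA)
    eps[X, :] = 1.0
    eps[:, X] = 1.0
    rcut[X, :] = WCA_CUTOFF
    rcut[:, X] = WCA_CUTOFF
    return InteractionTable(eps, rcut, kbt=kbt, bonded_wca=bonded_wca)
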