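"""Desk-scale realisations of the study's scenario matrix.

The reference conditions — 1000 chains, 2000-4000 cargo trimers, hundreds
of millions of steps — are deliberately reduced here to a size one
workstation core reruns in minutes while keeping every ratio of the
original mixtures: 20 chains with two cargo trimers per chain at
Phi = 0.12, stoichiometric trigger doses of one per end-cap (20/40/60) or
a constant dose of four per chain (80), and proportionally shortened
push-off/equilibration/production stages.

Two clock compressions make the kinetics observable in short runs, both
uniform across architectures so that orderings and dimensionless fractions
are preserved: reaction sweeps run every integration step, and both
reaction probabilities are scaled up by the same factor (default 100,
RP_T = 1e-4 -> 1e-2, RP_B = 1e-3 -> 1e-1), which compresses the time axis
while keeping the slow-end-cap / fast-propagation regime (RP_T << RP_B)
intact.  Absolute times are not comparable to the full-scale study (whose
thermostat friction is unreported anyway); fractions, ratios and
architecture orderings are the desk-scale observables.
"""

from __future__ import annotations

import numpy as np

from .clusters import mass_distribution, stillinger_clusters
from .config import ExperimentSpec
from .engine import Trajectory
from .experiment import depolymerize, micellize, trajectory_release
from .reactions import ledger_fractions
from .templates import COPOLYMER_SPECIES

DESK_CHAINS = 20
DESK_CARGO_PER_CHAIN = 2
RATE_SCALE = 100.0
STRONG_CARGO_TSTAR = {"B-C": 1.4, "C-C": 1.4}

DESK_PROTOCOL = dict(
    n_pushoff=3_000,
    n_equil=50_000,
    n_prod=60_000,
    n_reaction_steps=100_000,
    snapshot_every=5_000,
    attempt_every=1,
)


def desk_spec(architecture: str, *, seed: int, loaded: bool = True,
              strong_cargo_attraction: bool = True,
              trigger_mode: str = "none", rp_t: float = 1e-4,
              rp_b: float = 1e-3, rate_scale: float = RATE_SCALE,
              **overrides) -> ExperimentSpec:
    """One desk-scale scenario cell; ``rp_t``/``rp_b`` are the full-scale
    probabilities, compressed by ``rate_scale`` for the shortened runs."""
    if architecture not in COPOLYMER_SPECIES:
        raise ValueError(f"unknown architecture {architecture!r}")
    kwargs = dict(
        architecture=architecture,
        n_chains=DESK_CHAINS,
        cargo_count=DESK_CHAINS * DESK_CARGO_PER_CHAIN if loaded else 0,
        phi=0.12,
        tstar_map=dict(STRONG_CARGO_TSTAR) if strong_cargo_attraction else {},
        trigger_mode=trigger_mode,
        rp_t=min(1.0, rp_t * rate_scale),
        rp_b=min(1.0, rp_b * rate_scale),
        seed=seed,
        **DESK_PROTOCOL,
    )
    kwargs.update(overrides)
    return ExperimentSpec(**kwargs)


def production_frames(result_or_traj, template) -> list:
    traj = getattr(result_or_traj, "micellization_traj", result_or_traj)
    return [traj.frame_state(k, template) for k in range(len(traj))]


def frame_bond_fractions(traj: Trajectory, state) -> np.ndarray:
    """(time, frac_ec, frac_b) rows over the frames of a reaction run."""
    ec_rows = np.array([br.bond_indices[0] for br in state.branches])
    all_rows = np.concatenate([br.bond_indices for br in state.branches])
    rows = []
    for k in range(len(traj)):
        active = traj.bond_active[k]
        rows.append((traj.times[k],
                     float(np.mean(~active[ec_rows])),
                     float(np.mean(~active[all_rows]))))
    return np.array(rows)


def time_to_fraction(times: np.ndarray, fractions: np.ndarray,
                     target: float) -> float | None:
    """First (interpolated) time at which a monotone fraction reaches target."""
    idx = np.flatnonzero(fractions >= target)
    if not len(idx):
        return None
    k = idx[0]
    if k == 0:
        return float(times[0])
    f0, f1 = fractions[k - 1], fractions[k]
    t0, t1 = times[k - 1], times[k]
    if f1 == f0:
        return float(t1)
    return float(t0 + (target - f0) / (f1 - f0) * (t1 - t0))


class ScenarioBattery:
    """Shared desk-scale runs behind the qualitative reproductions.

    Micellizes each architecture once (empty, loaded-strong, and the
    loaded-weak linear control) and reuses the loaded snapshots for both
    trigger-dose reaction runs, so the whole matrix costs seven
    micellizations and six reactive runs.  All results are cached per
    instance; create one battery per seed.
    """

    def __init__(self, seed: int):
        self.seed = int(seed)
        self._mic: dict = {}
        self._react: dict = {}

    def micellization(self, architecture: str, *, loaded: bool = True,
                      strong: bool = True):
        key = (architecture, loaded, strong)
        if key not in self._mic:
            spec = desk_spec(architecture, seed=self.seed, loaded=loaded,
                             strong_cargo_attraction=strong)
            state, traj = micellize(spec)
            self._mic[key] = (spec, state, traj)
        return self._mic[key]

    def reaction(self, architecture: str, trigger_mode: str):
        key = (architecture, trigger_mode)
        if key not in self._react:
            _, mic_state, _ = self.micellization(architecture)
            spec = desk_spec(architecture, seed=self.seed, loaded=True,
                             trigger_mode=trigger_mode)
            state, traj, hook = depolymerize(spec, mic_state)
            self._react[key] = (spec, state, traj, hook)
        return self._react[key]

    # --- derived observables -------------------------------------------

    def encapsulated_fraction(self, architecture: str = "A30B30", *,
                              strong: bool = True) -> float:
        from .clusters import encapsulation_report

        spec, state, traj = self.micellization(architecture, strong=strong)
        frames = production_frames(traj, state)
        return encapsulation_report(frames).frac_encapsulated

    def preferential_size(self, architecture: str, *, loaded: bool) -> int | None:
        _, state, traj = self.micellization(architecture, loaded=loaded)
        frames = production_frames(traj, state)
        _, n_p = mass_distribution([stillinger_clusters(f) for f in frames])
        return n_p

    def depolymerization_curve(self, architecture: str, trigger_mode: str
                               ) -> np.ndarray:
        """Fine-grained (time, frac_ec, frac_b) rows from the reaction-sweep
        samples; the clock starts at trigger insertion."""
        _, _, _, hook = self.reaction(architecture, trigger_mode)
        rows = np.array(hook.samples)
        rows[:, 0] -= rows[0, 0]
        return rows

    def release_curve(self, architecture: str, trigger_mode: str):
        _, state, traj, _ = self.reaction(architecture, trigger_mode)
        series = trajectory_release(traj, state)
        return series

    def release_at_breakage(self, architecture: str, trigger_mode: str,
                            target: float = 0.60) -> float | None:
        rows = self.depolymerization_curve(architecture, trigger_mode)
        series = self.release_curve(architecture, trigger_mode)
        t_star = time_to_fraction(rows[:, 0], rows[:, 2], target)
        if t_star is None:
            return None
        t_rel = series.times - series.times[0]
        return float(np.interp(t_star, t_rel, series.released_fraction))

    def final_fractions(self, architecture: str, trigger_mode: str
                        ) -> tuple[float, float]:
        _, _, _, hook = self.reaction(architecture, trigger_mode)
        return ledger_fractions(hook.ledger)
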