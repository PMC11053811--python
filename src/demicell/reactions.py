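"""Two-step stochastic head-to-tail depolymerization.

Step (a): the bond between a labile end-cap and its B neighbour breaks with
probability RP_T per sweep, but only while at least one active trigger bead
sits within R_cutoff = 1 sigma of the end-cap (minimum image).  Step (b):
once a branch has lost its end-cap, the newly exposed terminal hydrophobic
bond breaks spontaneously with probability RP_B per sweep, one monomer at a
time — never deeper in the branch — until the whole branch (including the
junction bond to the hydrophilic arm) has depolymerized.

Beads are never created or destroyed; reactions only deactivate bonds and
retag beads.  By default a successful end-cap scission consumes the nearest
participating trigger (its type becomes the inert X), so a stoichiometric
dose of triggers can open at most every end-cap once, and detached monomers
keep their hydrophobic identity (``detached_bead_fate="keep_type"``); with
``"inert"`` they are retagged X and stop interacting attractively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .system import SystemState
from .templates import T as T_CODE, X as X_CODE


def _branch_lengths(state: SystemState) -> np.ndarray:
    """Scissile-bond count per branch, cached on the state object."""
    cached = getattr(state, "_branch_lengths_cache", None)
    if cached is None or len(cached) != len(state.branches):
        cached = np.array([len(br) for br in state.branches], dtype=np.int64)
        state._branch_lengths_cache = cached
    return cached


@dataclass
class ReactionParams:
    """Reaction probabilities and bookkeeping switches.

    ``rp_t``/``rp_b`` are per-sweep Bernoulli probabilities (the study grid
    spans 1e-2..1e-4 for the trigger step and 1e-3..1e-4 for propagation);
    ``attempt_every`` sets how many integration steps separate reaction
    sweeps, so absolute rates rescale with the cadence while comparisons
    between architectures under the same cadence do not.
    """

    rp_t: float = 1e-4
    rp_b: float = 1e-3
    r_cutoff: float = 1.0
    attempt_every: int = 100
    consume_trigger: bool = True
    detached_bead_fate: str = "keep_type"

    def __post_init__(self):
        if not (0.0 <= self.rp_t <= 1.0 and 0.0 <= self.rp_b <= 1.0):
            raise ValueError("reaction probabilities must lie in [0, 1]")
        if self.r_cutoff <= 0:
            raise ValueError("trigger proximity radius must be positive")
        if self.attempt_every < 1:
            raise ValueError("attempt_every must be >= 1")
        if self.detached_bead_fate not in ("keep_type", "inert"):
            raise ValueError("detached_bead_fate must be 'keep_type' or 'inert'")


@dataclass(frozen=True)
class ReactionEvent:
    time: float
    sweep: int
    kind: str                   # "endcap" | "propagation"
    bond_index: int
    bead_i: int
    bead_j: int
    molecule_id: int


@dataclass
class DepolymerizationLedger:
    """Running counts of broken end-cap and scissile hydrophobic bonds.

    A bond is *scissile* when breaking it releases one hydrophobic bead:
    the end-cap bond, every B-B bond of the branch, and finally the
    junction bond to the hydrophilic arm — 30 per chain for all three
    architectures, so the broken-bond fraction equals the fraction of
    depolymerized hydrophobic beads.
    """

    n_endcap_bonds_0: int
    n_scissile_bonds_0: int
    n_endcap_broken: int = 0
    n_scissile_broken: int = 0
    sweep: int = 0
    events: list[ReactionEvent] = field(default_factory=list)

    @classmethod
    def from_state(cls, state: SystemState) -> "DepolymerizationLedger":
        return cls(n_endcap_bonds_0=len(state.branches),
                   n_scissile_bonds_0=int(sum(len(br) for br in state.branches)),
                   n_endcap_broken=int(np.sum(state.branch_progress >= 1)),
                   n_scissile_broken=int(np.sum(state.branch_progress)))

    def record(self, event: ReactionEvent) -> None:
        self.events.append(event)
        self.n_scissile_broken += 1
        if event.kind == "endcap":
            self.n_endcap_broken += 1


def ledger_fractions(ledger: DepolymerizationLedger) -> tuple[float, float]:
    """(1 - [ec]_t/[ec]_0, 1 - [B]_t/[B]_0): fractions of end-caps removed
    and of hydrophobic beads depolymerized."""
    if ledger.n_endcap_bonds_0 == 0:
        raise ZeroDivisionError("system has no end-cap bonds")
    return (ledger.n_endcap_broken / ledger.n_endcap_bonds_0,
            ledger.n_scissile_broken / ledger.n_scissile_bonds_0)


def _detach_bead(state: SystemState, bead: int, fate: str) -> None:
    if fate == "inert":
        state.types[bead] = X_CODE


def _break(state: SystemState, branch_idx: int, params: ReactionParams,
           ledger: DepolymerizationLedger | None, kind: str) -> ReactionEvent:
    br = state.branches[branch_idx]
    prog = int(state.branch_progress[branch_idx])
    bond = int(br.bond_indices[prog])
    bead = int(br.bead_indices[prog])
    i, j = (int(b) for b in state.bonds[bond])
    state.bond_active[bond] = False
    state.branch_progress[branch_idx] = prog + 1
    _detach_bead(state, bead, params.detached_bead_fate)
    event = ReactionEvent(time=state.time, sweep=ledger.sweep if ledger else 0,
                          kind=kind, bond_index=bond, bead_i=i, bead_j=j,
                          molecule_id=br.molecule_id)
    if ledger is not None:
        ledger.record(event)
    return event


def attempt_endcap_scission(state: SystemState, params: ReactionParams,
                            rng: np.random.Generator,
                            ledger: DepolymerizationLedger | None = None
                            ) -> list[ReactionEvent]:
    """One sweep of trigger-activated end-cap bond scission.

    Each intact end-cap bond whose end-cap bead has at least one active
    trigger within ``r_cutoff`` breaks with probability ``rp_t`` (a single
    Bernoulli draw per bond per sweep, however many triggers are in range).
    With ``consume_trigger`` the nearest still-active participating trigger
    is retagged X; if every in-range trigger was already consumed earlier in
    the same sweep the scission is forgone.
    """
    events: list[ReactionEvent] = []
    intact = np.flatnonzero(state.branch_progress == 0)
    if not len(intact):
        return events
    trigger_idx = np.flatnonzero(state.types == T_CODE)
    if not len(trigger_idx):
        return events

    L = state.box.length
    ec_beads = np.array([state.branches[b].bead_indices[0] for b in intact])
    nearest = _kernels.nearest_in_range(state.positions, ec_beads, trigger_idx,
                                        L, params.r_cutoff ** 2)
    for branch_idx, ec_bead, near in zip(intact, ec_beads, nearest):
        if near < 0:
            continue
        if rng.random() >= params.rp_t:
            continue
        if params.consume_trigger:
            # the nearest trigger may have been consumed earlier in this
            # sweep; fall back to the nearest *still-active* one, and forgo
            # the scission when none remains in range
            tgt = int(trigger_idx[near])
            if state.types[tgt] != T_CODE:
                active = np.flatnonzero(state.types == T_CODE)
                if not len(active):
                    continue
                again = _kernels.nearest_in_range(
                    state.positions, np.array([ec_bead]), active,
                    L, params.r_cutoff ** 2)
                if again[0] < 0:
                    continue
                tgt = int(active[again[0]])
            state.types[tgt] = X_CODE
        events.append(_break(state, int(branch_idx), params, ledger, "endcap"))
    return events


def attempt_propagation(state: SystemState, params: ReactionParams,
                        rng: np.random.Generator,
                        ledger: DepolymerizationLedger | None = None
                        ) -> list[ReactionEvent]:
    """One sweep of spontaneous head-to-tail propagation.

    Only the terminal hydrophobic bond of a branch whose end-cap has already
    detached is eligible — at most one bond per branch per sweep — and it
    breaks with probability ``rp_b`` regardless of any trigger.
    """
    events: list[ReactionEvent] = []
    eligible = np.flatnonzero((state.branch_progress >= 1)
                              & (state.branch_progress < _branch_lengths(state)))
    if not len(eligible):
        return events
    draws = rng.random(len(eligible))
    for branch_idx, u in zip(eligible, draws):
        if u < params.rp_b:
            events.append(_break(state, int(branch_idx), params, ledger, "propagation"))
    return events


def reaction_sweep(state: SystemState, params: ReactionParams,
                   rng: np.random.Generator,
                   ledger: DepolymerizationLedger | None = None) -> int:
    """End-cap scission followed by propagation; returns the event count."""
    if ledger is not None:
        ledger.sweep += 1
    events = attempt_endcap_scission(state, params, rng, ledger)
    events += attempt_propagation(state, params, rng, ledger)
    return len(events)


class ReactionHook:
    """Adapter plugging reaction sweeps into the integrator at the configured
    cadence; collects (time, fractions) samples for kinetics work."""

    def __init__(self, params: ReactionParams,
                 ledger: DepolymerizationLedger | None = None,
                 sample_every: int = 0):
        self.params = params
        self.ledger = ledger
        self.sample_every = sample_every
        self.samples: list[tuple[float, float, float]] = []
        self._step = 0

    def __call__(self, state: SystemState, rng: np.random.Generator) -> int:
        self._step += 1
        if self._step % self.params.attempt_every:
            return 0
        n = reaction_sweep(state, self.params, rng, self.ledger)
        if (self.ledger is not None and self.sample_every
                and self.ledger.sweep % self.sample_every == 0):
            fe, fb = ledger_fractions(self.ledger)
            self.samples.append((state.time, fe, fb))
        return n


def events_to_rows(events: list[ReactionEvent]) -> list[dict]:
    """Flatten events for CSV export."""
    return [dict(sweep=e.sweep, time=e.time, reaction_type=e.kind,
                 bond_i=e.bead_i, bond_j=e.bead_j, molecule_id=e.molecule_id)
            for e in events]
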