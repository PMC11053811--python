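import numpy as np
import pytest
from scipy import stats

from demicell.reactions import (DepolymerizationLedger, ReactionParams,
                                attempt_endcap_scission, attempt_propagation,
                                ledger_fractions, reaction_sweep)
from demicell.system import assemble_system, insert_triggers
from demicell.templates import T as T_CODE, TAG_TO_CODE, X as X_CODE


def chain_with_trigger(distance, seed=0, arch="A30B30"):
    """One chain plus one trigger placed at a set distance from the end-cap."""
    st = assemble_system({arch: 1}, 0.01, seed=seed)
    st = insert_triggers(st, 1, seed=seed + 1)
    ec = st.branches[0].bead_indices[0]
    trigger = int(np.flatnonzero(st.types == T_CODE)[0])
    st.positions[trigger] = np.mod(st.positions[ec] + [distance, 0, 0],
                                   st.box.length)
    return st, ec, trigger


def test_trigger_inside_cutoff_with_certain_probability_breaks(rng):
    st, _, _ = chain_with_trigger(0.9)
    led = DepolymerizationLedger.from_state(st)
    events = attempt_endcap_scission(st, ReactionParams(rp_t=1.0), rng, led)
    assert len(events) == 1
    assert ledger_fractions(led) == (1.0, pytest.approx(1 / 30))


def test_trigger_outside_cutoff_never_breaks(rng):
    st, _, _ = chain_with_trigger(1.1)
    for _ in range(200):
        assert attempt_endcap_scission(st, ReactionParams(rp_t=1.0), rng) == []


def test_zero_probability_never_breaks(rng):
    st, _, _ = chain_with_trigger(0.5)
    for _ in range(200):
        assert attempt_endcap_scission(st, ReactionParams(rp_t=0.0), rng) == []


def test_successful_scission_consumes_nearest_trigger(rng):
    st, ec, trigger = chain_with_trigger(0.9)
    attempt_endcap_scission(st, ReactionParams(rp_t=1.0), rng)
    assert st.types[trigger] == X_CODE
    # consumed triggers no longer activate anything
    st2, _, t2 = chain_with_trigger(0.9, seed=5)
    st2.types[t2] = X_CODE
    assert attempt_endcap_scission(st2, ReactionParams(rp_t=1.0), rng) == []


def test_no_propagation_while_endcap_intact(rng):
    st = assemble_system({"A30(B10)3": 5}, 0.05, seed=3)
    for _ in range(100):
        assert attempt_propagation(st, ReactionParams(rp_b=1.0), rng) == []


def test_certain_propagation_breaks_exactly_one_bond_per_branch_per_sweep(rng):
    st = assemble_system({"A30B30": 1}, 0.01, seed=2)
    led = DepolymerizationLedger.from_state(st)
    st.bond_active[st.branches[0].bond_indices[0]] = False   # end-cap removed
    st.branch_progress[0] = 1
    led.n_endcap_broken, led.n_scissile_broken = 1, 1
    params = ReactionParams(rp_b=1.0)
    for sweep in range(29):
        events = attempt_propagation(st, params, rng, led)
        assert len(events) == 1
    assert ledger_fractions(led) == (1.0, 1.0)
    # branch exhausted: nothing left to break
    assert attempt_propagation(st, params, rng, led) == []


def test_head_to_tail_audit_distal_side_never_bonded(rng):
    """Every broken bond must be the current terminus: after each sweep the
    beads distal to the last break carry no active bonds."""
    st = assemble_system({"A30(B15)2": 3}, 0.05, seed=6)
    st = insert_triggers(st, 30, seed=7)
    params = ReactionParams(rp_t=0.5, rp_b=0.5, r_cutoff=30.0)  # well mixed
    led = DepolymerizationLedger.from_state(st)
    for _ in range(60):
        reaction_sweep(st, params, rng, led)
        deg = st.bond_degrees()
        for b, br in enumerate(st.branches):
            prog = st.branch_progress[b]
            freed = br.bead_indices[:prog]
            assert np.all(deg[freed] == 0)
    assert led.n_scissile_broken == int(np.sum(st.branch_progress))


def test_bead_count_and_types_conserved_under_reactions(rng):
    st = assemble_system({"A30(B10)3": 4, "C3": 6}, 0.08, seed=9)
    st = insert_triggers(st, 40, seed=10)
    n0 = st.n_beads
    hydrophobic_before = int(np.sum(np.isin(st.types,
                                            [TAG_TO_CODE["B"], TAG_TO_CODE["EC"]])))
    params = ReactionParams(rp_t=0.3, rp_b=0.3, r_cutoff=50.0)
    for _ in range(100):
        reaction_sweep(st, params, rng)
    assert st.n_beads == n0
    # keep_type fate: detached monomers keep their hydrophobic identity
    hydrophobic_after = int(np.sum(np.isin(st.types,
                                           [TAG_TO_CODE["B"], TAG_TO_CODE["EC"]])))
    assert hydrophobic_after == hydrophobic_before


def test_inert_fate_retags_detached_beads(rng):
    st, ec, _ = chain_with_trigger(0.5)
    params = ReactionParams(rp_t=1.0, rp_b=1.0, detached_bead_fate="inert")
    attempt_endcap_scission(st, params, rng)
    assert st.types[ec] == X_CODE


def test_endcap_scission_statistics_binomial(rng):
    """1000 always-eligible end-cap bonds at rp_t = 1e-2: one sweep breaks
    Binomial(1000, 0.01) bonds; compare 500 seeded sweeps to the exact law."""
    st = assemble_system({"A30B30": 40}, 0.10, seed=11)
    st = insert_triggers(st, 40, seed=12)
    # place one trigger on top of each end cap: every bond eligible
    triggers = np.flatnonzero(st.types == T_CODE)
    for br, tr in zip(st.branches, triggers):
        st.positions[tr] = st.positions[br.bead_indices[0]]
    base_positions = st.positions.copy()
    params = ReactionParams(rp_t=1e-2, consume_trigger=False)
    counts = []
    for rep in range(500):
        trial = st.copy()
        trial.positions = base_positions.copy()
        events = attempt_endcap_scission(trial, params,
                                         np.random.default_rng(rep))
        counts.append(len(events))
    counts = np.array(counts)
    n, p = 40, 1e-2
    assert counts.mean() == pytest.approx(n * p, abs=3 * np.sqrt(n * p) / np.sqrt(500))
    # dispersion consistent with binomial variance
    assert counts.var() == pytest.approx(n * p * (1 - p), rel=0.5)


def test_propagation_matches_exact_binomial_cap_oracle():
    """Single uncapped 30-bead block at rp_b: after s sweeps the broken-bond
    count is min(Binomial(s, rp_b), 29) in distribution (10^4 replicates)."""
    rp_b, sweeps, reps = 0.05, 200, 10_000
    rng = np.random.default_rng(77)
    # direct simulation of the sequential rule (no MD needed)
    remaining = 29
    broken_counts = np.empty(reps, dtype=int)
    for r in range(reps):
        broken = 0
        for _ in range(sweeps):
            if broken < remaining and rng.random() < rp_b:
                broken += 1
        broken_counts[r] = broken
    # oracle: min(Binomial(sweeps, rp_b), 29)
    oracle = np.minimum(rng.binomial(sweeps, rp_b, size=reps), remaining)
    ks = stats.ks_2samp(broken_counts, oracle)
    assert ks.pvalue > 1e-3


def test_wellmixed_endcap_survival_follows_closed_form(rng):
    """With triggers always in range, per-sweep survival is (1 - rp_t)."""
    st = assemble_system({"A30(B15)2": 50}, 0.10, seed=13)
    st = insert_triggers(st, 100, seed=14)
    params = ReactionParams(rp_t=0.02, rp_b=0.0, r_cutoff=1e3,
                            consume_trigger=False)
    led = DepolymerizationLedger.from_state(st)
    sweeps = 60
    for _ in range(sweeps):
        attempt_endcap_scission(st, params, rng, led)
    survival = 1 - ledger_fractions(led)[0]
    expected = (1 - params.rp_t) ** sweeps
    # binomial error over 100 independent branches
    assert survival == pytest.approx(expected, abs=3 * np.sqrt(expected * (1 - expected) / 100))


def test_consumption_bounds_scissions_by_trigger_count(rng):
    st = assemble_system({"A30(B10)3": 10}, 0.08, seed=15)
    st = insert_triggers(st, 12, seed=16)          # fewer triggers than end-caps
    params = ReactionParams(rp_t=1.0, rp_b=0.0, r_cutoff=1e3, consume_trigger=True)
    led = DepolymerizationLedger.from_state(st)
    for _ in range(50):
        attempt_endcap_scission(st, params, rng, led)
    assert led.n_endcap_broken == 12


def test_ledger_fraction_worked_example(rng):
    """Ten two-branch chains, seven end-cap bonds broken, no propagation:
    7/20 of end-caps and 7/300 of scissile hydrophobic bonds are gone."""
    st = assemble_system({"A30(B15)2": 10}, 0.05, seed=17)
    led = DepolymerizationLedger.from_state(st)
    assert led.n_endcap_bonds_0 == 20
    assert led.n_scissile_bonds_0 == 300
    st = insert_triggers(st, 7, seed=18)
    triggers = np.flatnonzero(st.types == T_CODE)
    for br, tr in zip(st.branches[:7], triggers):
        st.positions[tr] = st.positions[br.bead_indices[0]]
    params = ReactionParams(rp_t=1.0, rp_b=0.0)
    led = DepolymerizationLedger.from_state(st)
    attempt_endcap_scission(st, params, rng, led)
    assert ledger_fractions(led) == (pytest.approx(0.35), pytest.approx(7 / 300))


def test_ledger_fraction_degenerate_cases():
    led = DepolymerizationLedger(n_endcap_bonds_0=4, n_scissile_bonds_0=120)
    assert ledger_fractions(led) == (0.0, 0.0)
    led.n_endcap_broken, led.n_scissile_broken = 4, 120
    assert ledger_fractions(led) == (1.0, 1.0)
    with pytest.raises(ZeroDivisionError):
        ledger_fractions(DepolymerizationLedger(0, 0))


def test_probability_validation():
    with pytest.raises(ValueError):
        ReactionParams(rp_t=1.5)
    with pytest.raises(ValueError):
        ReactionParams(rp_b=-0.1)
    with pytest.raises(ValueError):
        ReactionParams(detached_bead_fate="vanish")
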