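"""Experiment orchestration: the full micellization -> trigger ->
depolymerization -> analysis pipeline for one scenario, with reproducible
outputs.

A single experiment seed is split into named substreams (assembly,
micellization, trigger placement, reaction dynamics) so that toggling one
stage never perturbs the randomness of another.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .clusters import (EncapsulationReport, MicelleAssignment,
                       cargo_encapsulated_mask, encapsulation_report,
                       mass_distribution, stillinger_clusters)
from .config import ExperimentSpec, save_resolved_config
from .engine import SimulationProtocol, Trajectory, run_protocol
from .forcefield import build_interaction_table
from .io import write_dump, write_lammps_data
from .kinetics import KineticsSeries, release_series
from .reactions import (DepolymerizationLedger, ReactionHook, ReactionParams,
                        events_to_rows, ledger_fractions)
from .system import SystemState, assemble_system, insert_triggers

_SUBSTREAMS = {"assembly": 1, "micellization": 2, "triggers": 3, "reactions": 4}


def substream_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the experiment seed."""
    ss = np.random.SeedSequence([int(seed), _SUBSTREAMS[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class ExperimentResult:
    """In-memory bundle produced by :func:`run_experiment`."""

    spec: ExperimentSpec
    final_state: SystemState
    micellized_state: SystemState
    micellization_traj: Trajectory
    reaction_traj: Trajectory | None
    assignments: list[MicelleAssignment]
    mass_dist: dict[int, float]
    n_p: int | None
    encapsulation: EncapsulationReport | None
    ledger: DepolymerizationLedger | None
    kinetics_samples: list[tuple[float, float, float]] = field(default_factory=list)
    release: KineticsSeries | None = None


def _protocol(spec: ExperimentSpec) -> SimulationProtocol:
    return SimulationProtocol(dt=spec.dt, tstar=spec.tstar, gamma=spec.gamma,
                              n_pushoff=spec.n_pushoff, n_equil=spec.n_equil,
                              n_prod=spec.n_prod, snapshot_every=spec.snapshot_every,
                              scale_factor=spec.scale_factor)


def micellize(spec: ExperimentSpec) -> tuple[SystemState, Trajectory]:
    """Assemble the mixture and run push-off/equilibration/production."""
    counts = {spec.architecture: spec.n_chains}
    if spec.cargo_count:
        counts["C3"] = spec.cargo_count
    state = assemble_system(counts, spec.phi, substream_seed(spec.seed, "assembly"),
                            tstar=spec.tstar)
    table = build_interaction_table(spec.tstar_map, kbt=spec.tstar)
    traj = run_protocol(state, _protocol(spec), table,
                        substream_seed(spec.seed, "micellization"))
    return state, traj


def depolymerize(spec: ExperimentSpec, state: SystemState
                 ) -> tuple[SystemState, Trajectory, ReactionHook]:
    """Insert triggers into a micellized snapshot and run reactive dynamics."""
    state = insert_triggers(state, spec.trigger_count,
                            substream_seed(spec.seed, "triggers"),
                            tstar=spec.tstar)
    params = ReactionParams(rp_t=spec.rp_t, rp_b=spec.rp_b,
                            attempt_every=spec.attempt_every,
                            consume_trigger=spec.consume_trigger,
                            detached_bead_fate=spec.detached_bead_fate)
    ledger = DepolymerizationLedger.from_state(state)
    # fine-grained kinetics sampling: every 50 sweeps, plus the origin
    hook = ReactionHook(params, ledger, sample_every=50)
    hook.samples.append((state.time, *ledger_fractions(ledger)))
    table = build_interaction_table(spec.tstar_map, kbt=spec.tstar)
    proto = SimulationProtocol(dt=spec.dt, tstar=spec.tstar, gamma=spec.gamma,
                               n_pushoff=0, n_equil=0,
                               n_prod=spec.n_reaction_steps,
                               snapshot_every=spec.snapshot_every,
                               scale_factor=spec.scale_factor)
    traj = run_protocol(state, proto, table,
                        substream_seed(spec.seed, "reactions"),
                        reaction_hook=hook)
    return state, traj, hook


def trajectory_release(traj: Trajectory, template: SystemState) -> KineticsSeries:
    """Release curve over the frames of a reactive trajectory."""
    flags, cargo_ids = [], None
    for k in range(len(traj)):
        st = traj.frame_state(k, template)
        per_mol = cargo_encapsulated_mask(st)
        if cargo_ids is None:
            cargo_ids = sorted(per_mol)
        flags.append([per_mol[m] for m in cargo_ids])
    return release_series(np.asarray(traj.times), np.asarray(flags, dtype=bool))


def run_experiment(spec: ExperimentSpec, outdir=None) -> ExperimentResult:
    """Run one scenario end to end; optionally write the results bundle.

    With ``outdir`` set, the directory receives the resolved config, final
    configuration (data file), production/reaction trajectories (dump),
    event log and kinetics series (CSV), summary metrics (JSON) and a
    manifest with seeds, config hash and file checksums — byte-identical
    for identical spec and seed.
    """
    mic_state, mic_traj = micellize(spec)

    frames = [mic_traj.frame_state(k, mic_state) for k in range(len(mic_traj))]
    assignments = [stillinger_clusters(f) for f in frames]
    dist, n_p = mass_distribution(assignments)
    enc = (encapsulation_report(frames, assignments)
           if spec.cargo_count else None)

    state = mic_state
    reaction_traj = hook = None
    release = None
    if spec.trigger_mode != "none" and spec.trigger_count:
        state, reaction_traj, hook = depolymerize(spec, mic_state)
        if spec.cargo_count:
            release = trajectory_release(reaction_traj, state)

    result = ExperimentResult(
        spec=spec, final_state=state, micellized_state=mic_state,
        micellization_traj=mic_traj,
        reaction_traj=reaction_traj, assignments=assignments,
        mass_dist=dist, n_p=n_p, encapsulation=enc,
        ledger=hook.ledger if hook else None,
        kinetics_samples=hook.samples if hook else [],
        release=release,
    )
    if outdir is not None:
        _write_bundle(result, Path(outdir))
    return result


def _write_bundle(result: ExperimentResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    spec = result.spec
    save_resolved_config(spec, outdir / "config_resolved.yaml")
    write_lammps_data(result.final_state, outdir / "final.data")
    mt = result.micellization_traj
    write_dump([mt.frame_state(k, result.micellized_state) for k in range(len(mt))],
               outdir / "micellization.dump")
    if result.reaction_traj is not None:
        rt = result.reaction_traj
        write_dump([rt.frame_state(k, result.final_state) for k in range(len(rt))],
                   outdir / "reaction.dump")

    pd.DataFrame([{"N": n, "P": p} for n, p in result.mass_dist.items()]
                 ).to_csv(outdir / "massdist.csv", index=False)
    metrics = {
        "seed": spec.seed,
        "config_hash": spec.config_hash(),
        "n_p": result.n_p,
        "mass_distribution": result.mass_dist,
    }
    if result.encapsulation:
        metrics["frac_encapsulated"] = result.encapsulation.frac_encapsulated
        metrics["loading_capacity"] = result.encapsulation.loading_capacity
    if result.ledger:
        fe, fb = ledger_fractions(result.ledger)
        metrics["frac_endcap_broken"] = fe
        metrics["frac_b_broken"] = fb
        pd.DataFrame(events_to_rows(result.ledger.events)
                     ).to_csv(outdir / "events.csv", index=False)
        pd.DataFrame(result.kinetics_samples,
                     columns=["time", "frac_ec", "frac_b"]
                     ).to_csv(outdir / "depolymerization.csv", index=False)
    if result.release is not None:
        pd.DataFrame({"time": result.release.times,
                      "released_fraction": result.release.released_fraction,
                      "encapsulated_count": result.release.encapsulated_count}
                     ).to_csv(outdir / "release.csv", index=False)
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2, default=str))

    try:
        pkg_version = version("demicell")
    except PackageNotFoundError:
        pkg_version = "unknown"
    manifest = {
        "package": "demicell", "version": pkg_version,
        "seed": spec.seed, "config_hash": spec.config_hash(),
        "files": {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                  for p in sorted(outdir.iterdir()) if p.name != "manifest.json"},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
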