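"""Seeded simulation loop, recordings, batch runner and on-disk formats.

A run advances all 21 cells synchronously at ``dt`` (default 1 ms): external
spike trains and the previous step's internal spikes are delivered along
active edges with a one-step axonal delay, the NMDA-gated LTP rule is applied
at delivery, and the somatic potential of every principal cell is sampled at
each step.  Everything is deterministic given the circuit configuration and
the input trains, which in turn are deterministic given ``(base_seed,
run_index)``.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cell_model import CellClass, CellClassName, CellEnsemble, SynapseSpec
from .circuit import (
    CELL_NAMES,
    CELL_REGION,
    EXTERNAL_LINES,
    PRINCIPAL_CELLS,
    Circuit,
    apply_ad_deletion,
)
from .protocols import (Condition, SpikeTrain, build_condition_inputs,
                        split_input_key)

__all__ = [
    "SpikeRecording",
    "RunManifest",
    "run_simulation",
    "run_batch",
    "write_recording",
    "read_recording",
]

ALL_PRINCIPAL = tuple(c for r in ("DG", "CA3", "CA1") for c in PRINCIPAL_CELLS[r])


@dataclass
class SpikeRecording:
    """Output of one seeded run."""

    condition: Condition
    run_index: int
    spikes: dict[str, SpikeTrain]
    traces: dict[str, np.ndarray]  # somatic potential per principal cell
    dt: float
    duration: float
    weights_initial: pd.DataFrame | None = None
    weights_final: pd.DataFrame | None = None

    def spike_counts(self) -> dict[str, int]:
        return {c: len(tr) for c, tr in self.spikes.items()}


@dataclass
class RunManifest:
    """Metadata sufficient to re-run a batch bit-identically."""

    package_version: str
    condition: dict
    circuit_hash: str
    seeds: list[int]
    created: str

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _circuit_hash(circuit: Circuit) -> str:
    payload = yaml.safe_dump(circuit.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _compile(circuit: Circuit, dt: float, psp_gain: float):
    classes: list[CellClass] = [circuit.cells[c] for c in CELL_NAMES]
    tables: list[list[SynapseSpec]] = [[] for _ in CELL_NAMES]
    idx = {c: i for i, c in enumerate(CELL_NAMES)}
    # all slots are declared (inactive edges keep their kinetics but never
    # receive events)
    for e in circuit.edges:
        tables[idx[e.target]].append(e.synapse)
    ens = CellEnsemble(classes, tables, dt=dt, psp_gain=psp_gain)

    ext_targets: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    ext_targets_principal: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    out_map: list[tuple[np.ndarray, np.ndarray]] = [
        (np.empty(0, int), np.empty(0, int)) for _ in CELL_NAMES
    ]
    principal_classes = (CellClassName.granule, CellClassName.pyramidal)
    ext_acc: dict[str, list[tuple[int, int]]] = {l: [] for l in EXTERNAL_LINES}
    ext_acc_p: dict[str, list[tuple[int, int]]] = {l: [] for l in EXTERNAL_LINES}
    int_acc: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(CELL_NAMES))}
    for e in circuit.edges:
        if not e.active:
            continue
        tgt = (idx[e.target], e.synapse.synapse_id - 1)
        if e.source in EXTERNAL_LINES:
            ext_acc[e.source].append(tgt)
            if circuit.cells[e.target].name in principal_classes:
                ext_acc_p[e.source].append(tgt)
        else:
            int_acc[idx[e.source]].append(tgt)
    for line, pairs in ext_acc.items():
        if pairs:
            arr = np.array(pairs, dtype=int)
            ext_targets[line] = (arr[:, 0], arr[:, 1])
    for line, pairs in ext_acc_p.items():
        if pairs:
            arr = np.array(pairs, dtype=int)
            ext_targets_principal[line] = (arr[:, 0], arr[:, 1])
    for i, pairs in int_acc.items():
        if pairs:
            arr = np.array(pairs, dtype=int)
            out_map[i] = (arr[:, 0], arr[:, 1])
    return ens, ext_targets, ext_targets_principal, out_map


def run_simulation(
    circuit: Circuit,
    inputs: Mapping[str, SpikeTrain],
    duration: float = 10_000.0,
    dt: float = 1.0,
    condition: Condition | None = None,
    run_index: int = 0,
    psp_gain: float = 1.0,
) -> SpikeRecording:
    """Simulate the circuit under the given external inputs.

    ``inputs`` maps external line names to spike trains; lines absent from the
    mapping are silent.  Spikes delivered onto inactive edges are no-ops by
    construction (inactive edges are excluded from the compiled event tables).
    """
    n_steps = int(round(duration / dt))
    ens, ext_targets, ext_targets_principal, out_map = _compile(circuit, dt, psp_gain)

    # bin external spikes onto steps (CSR layout: events sorted by step)
    ev_step: list[np.ndarray] = []
    ev_cell: list[np.ndarray] = []
    ev_slot: list[np.ndarray] = []
    ev_scale: list[np.ndarray] = []
    for key, train in inputs.items():
        line, scale = split_input_key(key)
        # induction trains drive the principal-cell perforant synapses only
        table = ext_targets if scale == 1.0 else ext_targets_principal
        if line not in table or len(train) == 0:
            continue
        steps = np.clip(np.round(train.times / dt).astype(int), 0, n_steps - 1)
        cells, slots = table[line]
        ev_step.append(np.repeat(steps, len(cells)))
        ev_cell.append(np.tile(cells, len(steps)))
        ev_slot.append(np.tile(slots, len(steps)))
        ev_scale.append(np.full(len(steps) * len(cells), scale))
    if ev_step:
        step_arr = np.concatenate(ev_step)
        order = np.argsort(step_arr, kind="stable")
        step_arr = step_arr[order]
        cell_arr = np.concatenate(ev_cell)[order]
        slot_arr = np.concatenate(ev_slot)[order]
        scale_arr = np.concatenate(ev_scale)[order]
        offsets = np.searchsorted(step_arr, np.arange(n_steps + 1))
    else:
        cell_arr = slot_arr = np.empty(0, int)
        scale_arr = np.empty(0)
        offsets = np.zeros(n_steps + 1, int)

    w_init = ens.w.copy()
    princ_idx = np.array([CELL_NAMES.index(c) for c in ALL_PRINCIPAL])
    traces = np.empty((len(princ_idx), n_steps))
    spike_times: list[list[float]] = [[] for _ in CELL_NAMES]

    pending_cells = np.empty(0, int)
    pending_slots = np.empty(0, int)
    for k in range(n_steps):
        t = k * dt
        lo, hi = offsets[k], offsets[k + 1]
        if hi > lo or pending_cells.size:
            ens.deliver(
                np.concatenate([cell_arr[lo:hi], pending_cells]),
                np.concatenate([slot_arr[lo:hi], pending_slots]),
                np.concatenate([scale_arr[lo:hi], np.ones(pending_cells.size)]),
            )
        spiked = ens.step(t)
        traces[:, k] = ens.V[princ_idx, 0]
        if spiked.any():
            (who,) = np.nonzero(spiked)
            pend_c, pend_s = [], []
            for i in who:
                spike_times[i].append(t)
                tc, ts = out_map[i]
                if tc.size:
                    pend_c.append(tc)
                    pend_s.append(ts)
            pending_cells = np.concatenate(pend_c) if pend_c else np.empty(0, int)
            pending_slots = np.concatenate(pend_s) if pend_s else np.empty(0, int)
        else:
            pending_cells = np.empty(0, int)
            pending_slots = np.empty(0, int)

    cond = condition or Condition("control", 0, 0, duration=duration)
    spikes = {
        c: SpikeTrain(c, np.asarray(spike_times[i]), duration)
        for i, c in enumerate(CELL_NAMES)
    }
    wdf = lambda w: pd.DataFrame(
        w, index=list(CELL_NAMES), columns=[f"syn{j}" for j in range(1, 17)]
    )
    return SpikeRecording(
        condition=cond,
        run_index=run_index,
        spikes=spikes,
        traces={c: traces[j].copy() for j, c in enumerate(ALL_PRINCIPAL)},
        dt=dt,
        duration=duration,
        weights_initial=wdf(w_init),
        weights_final=wdf(ens.w.copy()),
    )


def run_batch(
    condition: Condition,
    circuit: Circuit,
    dt: float = 1.0,
    jitter_sd: float = 1.0,
    psp_gain: float = 1.0,
) -> tuple[list[SpikeRecording], RunManifest]:
    """Run ``condition.n_runs`` independent seeded runs of one condition.

    The lesion stage of the condition is applied to a copy of the base
    circuit; run ``i`` uses input seed ``base_seed + i``.
    """
    if condition.n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    lesioned = (
        apply_ad_deletion(circuit, condition.lesion_stage)
        if condition.lesion_stage
        else circuit
    )
    recordings = []
    seeds = []
    for i in range(condition.n_runs):
        inputs = build_condition_inputs(condition, lesioned, run_index=i,
                                        jitter_sd=jitter_sd)
        try:
            rec = run_simulation(
                lesioned, inputs, duration=condition.duration, dt=dt,
                condition=condition, run_index=i, psp_gain=psp_gain,
            )
        except Exception as err:  # annotate with the failing run
            raise RuntimeError(f"run {i} of condition {condition.name} failed") from err
        recordings.append(rec)
        seeds.append(condition.base_seed + i)
    manifest = RunManifest(
        package_version=__version__,
        condition={
            "name": condition.name,
            "lesion_stage": condition.lesion_stage,
            "induction_hz": condition.induction_hz,
            "duration": condition.duration,
            "n_runs": condition.n_runs,
            "base_seed": condition.base_seed,
        },
        circuit_hash=_circuit_hash(lesioned),
        seeds=seeds,
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    return recordings, manifest


# ---------------------------------------------------------------------------
# on-disk round trip (plain text formats)
# ---------------------------------------------------------------------------

def write_recording(rec: SpikeRecording, path) -> None:
    """Write a recording to ``path/`` as CSV tables plus a JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = [
        {"cell": c, "time_ms": t}
        for c in CELL_NAMES
        for t in rec.spikes[c].times
    ]
    pd.DataFrame(rows, columns=["cell", "time_ms"]).to_csv(
        path / "spikes.csv", index=False
    )
    tr = pd.DataFrame(rec.traces)
    tr.insert(0, "time_ms", np.arange(len(tr)) * rec.dt)
    tr.to_csv(path / "traces.csv", index=False, float_format="%.6g")
    if rec.weights_initial is not None:
        rec.weights_initial.to_csv(path / "weights_initial.csv")
    if rec.weights_final is not None:
        rec.weights_final.to_csv(path / "weights_final.csv")
    meta = {
        "condition": {
            "name": rec.condition.name,
            "lesion_stage": rec.condition.lesion_stage,
            "induction_hz": rec.condition.induction_hz,
            "duration": rec.condition.duration,
            "n_runs": rec.condition.n_runs,
            "base_seed": rec.condition.base_seed,
        },
        "run_index": rec.run_index,
        "dt": rec.dt,
        "duration": rec.duration,
    }
    (path / "recording.json").write_text(json.dumps(meta, indent=2))


def read_recording(path) -> SpikeRecording:
    path = Path(path)
    try:
        meta = json.loads((path / "recording.json").read_text())
        sp = pd.read_csv(path / "spikes.csv")
        tr = pd.read_csv(path / "traces.csv")
    except (OSError, ValueError, pd.errors.ParserError) as err:
        raise ValueError(f"malformed recording at {path}: {err}") from err
    cond = Condition(**meta["condition"])
    duration = meta["duration"]
    spikes = {
        c: SpikeTrain(
            c, sp.loc[sp["cell"] == c, "time_ms"].to_numpy(float), duration
        )
        for c in CELL_NAMES
    }
    traces = {
        c: tr[c].to_numpy(float) for c in tr.columns if c != "time_ms"
    }
    weights_initial = weights_final = None
    if (path / "weights_initial.csv").exists():
        weights_initial = pd.read_csv(path / "weights_initial.csv", index_col=0)
    if (path / "weights_final.csv").exists():
        weights_final = pd.read_csv(path / "weights_final.csv", index_col=0)
    return SpikeRecording(
        condition=cond,
        run_index=meta["run_index"],
        spikes=spikes,
        traces=traces,
        dt=meta["dt"],
        duration=duration,
        weights_initial=weights_initial,
        weights_final=weights_final,
    )
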