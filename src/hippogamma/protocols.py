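"""External input protocols: theta-nested bursts, gamma induction, MS-DB gating.

The control protocol drives the perforant-path lines Ex1-Ex7 with bursts of
five spikes at 100 Hz repeating at the 8 Hz theta rhythm, phase-staggered
between lines; Ex8 and Ex9 are silent.  Septal (MS-DB) GABAergic lines
rhythmically inhibit the interneurons, opening a disinhibition window for the
principal cells once per theta cycle, plus one brief late secondary window
that lets through at most an isolated spike.

Gamma induction superimposes a periodic 40/100/130 Hz train on every
perforant-path line (including the otherwise silent Ex8/Ex9), on top of the
theta-burst pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .circuit import Circuit, EC2_LINES, MSDB_LINES, SILENT_EC2_LINES

__all__ = [
    "SpikeTrain",
    "Condition",
    "CONDITIONS",
    "theta_burst_train",
    "gamma_induction_train",
    "ms_db_gating",
    "build_condition_inputs",
    "merge_trains",
    "split_input_key",
    "INDUCTION_SCALE",
    "THETA_HZ",
    "THETA_PERIOD",
]

THETA_HZ = 8.0
THETA_PERIOD = 1000.0 / THETA_HZ  # 125 ms
INDUCTION_FREQS = (40, 100, 130)
#: coincident spikes closer than this are merged when superposing trains
MERGE_TOLERANCE = 0.5

#: Key suffix marking auxiliary induction trains in the inputs mapping; the
#: engine delivers them on the principal cells' perforant-path synapses at
#: INDUCTION_SCALE times the synaptic weight.
INDUCTION_KEY_SUFFIX = "!induction"
INDUCTION_SCALE = 1.4

#: Key suffix for the late septal "echo" spikes; they are delivered at a
#: fraction of the gating weight so the secondary window is brief enough to
#: admit only an isolated spike.  Phase and efficacy are per septal line
#: (T8/T9 gate the DG baskets, T6/T7 the CA3 baskets, T4/T5 the CA1
#: baskets), staggered so each region's secondary window tracks the arrival
#: of its feed-forward drive.
ECHO_KEY_SUFFIX = "!echo"
MSDB_ECHO = {
    "T8": (80.0, 1.0), "T9": (80.0, 1.0),   # DG
    "T6": (84.0, 0.8), "T7": (84.0, 0.8),   # CA3
    "T4": (88.0, 0.8), "T5": (88.0, 0.8),   # CA1
}


def split_input_key(key: str) -> tuple[str, float]:
    """Map an inputs key to (external line, delivery scale)."""
    if key.endswith(INDUCTION_KEY_SUFFIX):
        return key[: -len(INDUCTION_KEY_SUFFIX)], INDUCTION_SCALE
    if key.endswith(ECHO_KEY_SUFFIX):
        line = key[: -len(ECHO_KEY_SUFFIX)]
        return line, MSDB_ECHO[line][1]
    return key, 1.0

#: Phase offsets (ms) of the theta bursts on Ex1..Ex7: the theta cycle is
#: divided into 7 equal offsets, assigned to lines in a stride-3 permutation
#: so that consecutive line indices are well separated in phase.  The union
#: of the seven 40-ms bursts tiles the whole cycle (2-3 lines active at any
#: phase), and a circuit degenerated by the early deletion stages (Ex1-Ex4)
#: keeps partial coverage of the disinhibition window via Ex6.
STAGGER_PHASES = tuple((3 * k) % 7 * 1000.0 / THETA_HZ / 7.0 for k in range(7))


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times (ms) of one unit within [0, duration]."""

    unit_id: str
    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size and (np.diff(t) <= 0).any():
            raise ValueError(f"{self.unit_id}: spike times must strictly increase")
        if t.size and (t[0] < 0 or t[-1] > self.duration):
            raise ValueError(f"{self.unit_id}: spike outside [0, {self.duration}]")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class Condition:
    """One experimental condition of the study design."""

    name: str
    lesion_stage: int
    induction_hz: int
    duration: float = 10_000.0
    n_runs: int = 30
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.name == "control" and (self.lesion_stage or self.induction_hz):
            raise ValueError("control condition must have no lesion and no induction")
        if self.name.startswith("ad") and self.lesion_stage <= 0:
            raise ValueError(f"{self.name}: lesion_stage must be > 0")
        if self.induction_hz not in (0, *INDUCTION_FREQS):
            raise ValueError(f"unsupported induction frequency {self.induction_hz}")


def standard_conditions(
    lesion_stage: int | None = None,
    duration: float = 10_000.0,
    n_runs: int = 30,
    base_seed: int = 0,
) -> dict[str, Condition]:
    """The five study conditions keyed by name."""
    from .circuit import DEFAULT_AD_STAGE

    stage = DEFAULT_AD_STAGE if lesion_stage is None else lesion_stage
    mk = lambda name, s, f: Condition(name, s, f, duration, n_runs, base_seed)
    return {
        "control": mk("control", 0, 0),
        "ad": mk("ad", stage, 0),
        "ad_gamma40": mk("ad_gamma40", stage, 40),
        "ad_gamma100": mk("ad_gamma100", stage, 100),
        "ad_stim130": mk("ad_stim130", stage, 130),
    }


CONDITIONS = tuple(standard_conditions())


def theta_burst_train(
    duration: float,
    theta_hz: float = THETA_HZ,
    spikes_per_burst: int = 5,
    intra_hz: float = 100.0,
    phase: float = 0.0,
    jitter_sd: float = 0.0,
    seed: int | None = None,
    unit_id: str = "theta",
) -> SpikeTrain:
    """Theta-nested burst train: one burst per theta cycle.

    Each burst holds ``spikes_per_burst`` spikes at ``intra_hz`` (10 ms ISI at
    100 Hz) starting at ``cycle_start + phase``; independent Gaussian jitter of
    ``jitter_sd`` ms is added to every spike.  Deterministic given ``seed``.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    period = 1000.0 / theta_hz
    isi = 1000.0 / intra_hz
    burst_len = (spikes_per_burst - 1) * isi
    if burst_len >= period:
        raise ValueError(
            f"burst of {spikes_per_burst} spikes at {intra_hz} Hz "
            f"({burst_len} ms) does not fit in a {period} ms theta cycle"
        )
    n_cycles = int(np.ceil(duration / period)) + 1
    starts = np.arange(n_cycles) * period + phase
    times = (starts[:, None] + np.arange(spikes_per_burst) * isi).ravel()
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        times = times + rng.normal(0.0, jitter_sd, size=times.shape)
    times = np.sort(times)
    times = times[(times >= 0) & (times < duration)]
    times = _dedupe(times)
    return SpikeTrain(unit_id, times, duration)


def gamma_induction_train(
    duration: float,
    freq: int,
    phase: float = 0.0,
    unit_id: str = "induction",
) -> SpikeTrain:
    """Strictly periodic induction train at 40, 100 or 130 Hz."""
    if freq not in INDUCTION_FREQS:
        raise ValueError(
            f"unsupported induction frequency {freq}; expected one of {INDUCTION_FREQS}"
        )
    period = 1000.0 / freq
    start = phase % period
    times = np.arange(start, duration + 1e-9, period)
    times = times[(times >= 0) & (times < duration)]
    return SpikeTrain(unit_id, times, duration)


#: Per-cycle MS-DB volley phases (ms relative to the theta-cycle origin) per
#: septal line.  The volley suppresses the line's basket cells, opening the
#: principal-cell window; the DG volley is one spike longer, giving granule
#: cells a slightly longer window than the CA fields.
MSDB_WINDOW_PHASES = {
    "T8": (0.0, 10.0, 20.0, 30.0, 40.0), "T9": (0.0, 10.0, 20.0, 30.0, 40.0),
    "T6": (0.0, 10.0, 20.0, 30.0, 40.0), "T7": (0.0, 10.0, 20.0, 30.0, 40.0),
    "T4": (0.0, 10.0, 20.0, 30.0, 40.0), "T5": (0.0, 10.0, 20.0, 30.0, 40.0),
}


def ms_db_gating(
    duration: float,
    theta_hz: float = THETA_HZ,
    window_phases: Mapping[str, tuple[float, ...]] | None = None,
    echo: Mapping[str, tuple[float, float]] | None = None,
) -> dict[str, SpikeTrain]:
    """Septal GABAergic gating trains for the six MS-DB lines T4-T9.

    Per theta cycle each line emits a compact volley at ``window_phases``
    (suppressing the interneurons, i.e. disinhibiting the principal cells)
    plus one late "echo" spike per cycle that opens a brief secondary
    window; ``echo`` maps each line to its (phase, efficacy scale) and
    defaults to :data:`MSDB_ECHO`.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    window_phases = MSDB_WINDOW_PHASES if window_phases is None else window_phases
    echo = MSDB_ECHO if echo is None else echo
    period = 1000.0 / theta_hz
    n_cycles = int(np.ceil(duration / period)) + 1
    starts = np.arange(n_cycles) * period

    def cycle_train(offs: list[float]) -> np.ndarray:
        if not offs:
            return np.empty(0)
        t = np.sort((starts[:, None] + np.array(offs)).ravel())
        return t[(t >= 0) & (t < duration)]

    out: dict[str, SpikeTrain] = {}
    for line in MSDB_LINES:
        out[line] = SpikeTrain(line, cycle_train(list(window_phases[line])), duration)
        if line in echo:
            phase, _scale = echo[line]
            out[line + ECHO_KEY_SUFFIX] = SpikeTrain(
                line, cycle_train([phase]), duration
            )
    return out


def _dedupe(times: np.ndarray, tol: float = MERGE_TOLERANCE) -> np.ndarray:
    """Merge near-coincident spikes (< tol apart) keeping the earliest."""
    if times.size == 0:
        return times
    keep = [times[0]]
    for t in times[1:]:
        if t - keep[-1] >= tol:
            keep.append(t)
    return np.asarray(keep)


def merge_trains(a: SpikeTrain, b: SpikeTrain) -> SpikeTrain:
    """Additive superposition of two trains on one line."""
    if a.duration != b.duration:
        raise ValueError("cannot merge trains of different duration")
    times = _dedupe(np.sort(np.concatenate([a.times, b.times])))
    return SpikeTrain(a.unit_id, times, a.duration)


def build_condition_inputs(
    condition: Condition,
    circuit: Circuit,
    run_index: int = 0,
    jitter_sd: float = 1.0,
) -> dict[str, SpikeTrain]:
    """All external line inputs for one seeded run of a condition.

    Ex1-Ex7 carry phase-staggered theta bursts (Ex8/Ex9 silent), MS-DB lines
    carry the gating pattern, and for induction conditions a periodic
    ``induction_hz`` train is superimposed on every perforant-path line as an
    auxiliary entry (key ``<line>!induction``) that the engine delivers on the
    same synapses at reduced efficacy.  The per-run seed is
    ``base_seed + run_index``.
    """
    seed = condition.base_seed + run_index
    duration = condition.duration
    inputs: dict[str, SpikeTrain] = {}
    for k, line in enumerate(EC2_LINES):
        if line in SILENT_EC2_LINES:
            train = SpikeTrain(line, np.empty(0), duration)
        else:
            phase = STAGGER_PHASES[k]
            train = theta_burst_train(
                duration,
                phase=phase,
                jitter_sd=jitter_sd,
                seed=(seed * 64 + k) % (2**31),
                unit_id=line,
            )
        inputs[line] = train
        if condition.induction_hz:
            inputs[line + INDUCTION_KEY_SUFFIX] = gamma_induction_train(
                duration, condition.induction_hz, unit_id=line
            )
    inputs.update(ms_db_gating(duration))
    return inputs
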