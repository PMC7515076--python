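"""Discrete-time compartmental point neurons with double-exponential synapses.

The neuron is a functional (connectionist) model, not a conductance-based one:
each cell is a small tree of 16 iso-potential compartments (soma = compartment
0 plus a binary dendritic tree).  Compartments leak toward the resting
potential, exchange charge with their tree neighbours, and receive postsynaptic
potentials shaped as differences of exponentials.  A spike is emitted when the
somatic potential crosses the class threshold outside the refractory period;
the soma is then reset to rest.

Excitatory synapses on granule, pyramidal and O-LM cells can be plastic: when
a presynaptic spike arrives while the local compartment is depolarised past
the NMDA-unblock level, the synaptic weight is incremented (LTP only, no LTD),
saturating at ``weight_max``.

All state lives in flat numpy arrays over ``(cell, synapse-slot)`` so that a
whole network can be advanced with a handful of vector operations per time
step; :func:`step_cell` exposes the same kernel for a single cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CellClassName",
    "SynapseKind",
    "CellClass",
    "SynapseSpec",
    "CellState",
    "PSPEvent",
    "CellEnsemble",
    "N_COMPARTMENTS",
    "N_SYNAPSES",
    "N_EXCITATORY",
    "N_INHIBITORY",
    "COMPARTMENT_PARENT",
    "deliver_spike",
    "step_cell",
    "ltp_update",
    "psp_kernel_peak_time",
]

N_COMPARTMENTS = 16
N_SYNAPSES = 16
N_EXCITATORY = 13
N_INHIBITORY = 3

#: Binary dendritic tree: parent of compartment i is (i-1)//2, soma is the root.
COMPARTMENT_PARENT = tuple((i - 1) // 2 for i in range(1, N_COMPARTMENTS))

#: Synapse slot -> compartment.  The 13 excitatory slots (ids 1..13) contact
#: dendritic compartments 1..13; the first two inhibitory slots (14, 15) are
#: perisomatic (basket-type) and the last (16) contacts the most distal
#: compartment (O-LM-type).
SLOT_COMPARTMENT = tuple(list(range(1, 14)) + [0, 0, 15])


class CellClassName(str, Enum):
    granule = "granule"
    pyramidal = "pyramidal"
    basket = "basket"
    olm = "olm"
    mossy = "mossy"


class SynapseKind(str, Enum):
    AMPA = "AMPA"
    NMDA = "NMDA"
    GABA = "GABA"


@dataclass(frozen=True)
class CellClass:
    """Integration parameters of one morphological cell class.

    Parameters
    ----------
    resting_potential, threshold:
        Membrane potentials in mV; ``threshold > resting_potential``.
    refractory:
        Minimum inter-spike interval in ms.
    leak_rate:
        Passive decay rate toward rest, 1/ms.
    compartment_coupling:
        Fraction of the neighbour-average difference mixed into each
        compartment per ms, in (0, 1].
    """

    name: CellClassName
    resting_potential: float = -70.0
    threshold: float = -54.0
    refractory: float = 10.0
    leak_rate: float = 0.25
    compartment_coupling: float = 0.6

    def __post_init__(self) -> None:
        if not self.threshold > self.resting_potential:
            raise ValueError(
                f"{self.name}: threshold {self.threshold} must exceed "
                f"resting potential {self.resting_potential}"
            )
        if self.refractory < 0:
            raise ValueError(f"{self.name}: refractory must be >= 0")
        if self.leak_rate <= 0:
            raise ValueError(f"{self.name}: leak_rate must be > 0")
        if not 0 < self.compartment_coupling <= 1:
            raise ValueError(f"{self.name}: compartment_coupling must be in (0, 1]")


@dataclass(frozen=True)
class SynapseSpec:
    """One afferent line onto a cell (slot ``synapse_id`` in 1..16)."""

    synapse_id: int
    kind: SynapseKind
    weight: float
    weight_max: float = 2.0
    plastic: bool = False
    psp_rise: float = 2.0
    psp_decay: float = 10.0

    def __post_init__(self) -> None:
        if not 1 <= self.synapse_id <= N_SYNAPSES:
            raise ValueError(f"synapse_id {self.synapse_id} outside 1..{N_SYNAPSES}")
        if self.weight < 0 or self.weight > self.weight_max:
            raise ValueError(
                f"weight {self.weight} outside [0, {self.weight_max}]"
            )
        if self.psp_rise <= 0 or self.psp_decay <= self.psp_rise:
            raise ValueError("require 0 < psp_rise < psp_decay")
        if self.kind is SynapseKind.GABA and self.sign > 0:
            raise AssertionError("unreachable: GABA is inhibitory by construction")
        if self.plastic and self.sign < 0:
            raise ValueError("plastic synapses must be excitatory")

    @property
    def sign(self) -> int:
        return -1 if self.kind is SynapseKind.GABA else 1

    @property
    def compartment(self) -> int:
        return SLOT_COMPARTMENT[self.synapse_id - 1]


@dataclass(frozen=True)
class PSPEvent:
    """A postsynaptic potential scheduled by a presynaptic spike."""

    onset: float
    amplitude: float  # signed; mV scale of the local PSP peak
    psp_rise: float
    psp_decay: float


def deliver_spike(spec: SynapseSpec, t: float) -> PSPEvent:
    """Turn a presynaptic spike at time ``t`` into a PSP event.

    Amplitude is linear in the current weight and carries the synapse sign, so
    simultaneous events superpose additively on the membrane.
    """
    if t < 0:
        raise ValueError("spike time must be >= 0")
    return PSPEvent(
        onset=t,
        amplitude=spec.sign * spec.weight,
        psp_rise=spec.psp_rise,
        psp_decay=spec.psp_decay,
    )


def _kernel_norm(tau_r: np.ndarray, tau_d: np.ndarray) -> np.ndarray:
    """Normalisation so the continuous double-exponential peaks at 1."""
    ratio = tau_r / tau_d
    tp = (tau_r * tau_d) / (tau_d - tau_r) * np.log(tau_d / tau_r)
    peak = np.exp(-tp / tau_d) - np.exp(-tp / tau_r)
    return 1.0 / peak


def psp_kernel_peak_time(tau_r: float, tau_d: float) -> float:
    """Time to peak of the double-exponential kernel, ms."""
    return (tau_r * tau_d) / (tau_d - tau_r) * float(np.log(tau_d / tau_r))


def _coupling_matrix() -> np.ndarray:
    """Neighbour-average mixing matrix A: (A @ V) = mean of tree neighbours."""
    adj = np.zeros((N_COMPARTMENTS, N_COMPARTMENTS))
    for child, parent in enumerate(COMPARTMENT_PARENT, start=1):
        adj[child, parent] = 1.0
        adj[parent, child] = 1.0
    deg = adj.sum(axis=1, keepdims=True)
    return adj / deg


_AVG = _coupling_matrix()


@dataclass
class CellState:
    """Full dynamic state of one cell (or, stacked, of an ensemble)."""

    compartment_potentials: np.ndarray
    synapse_weights: np.ndarray
    last_spike_time: float | None = None
    kernel_decay: np.ndarray = field(default=None)  # type: ignore[assignment]
    kernel_rise: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.compartment_potentials = np.asarray(
            self.compartment_potentials, dtype=float
        )
        self.synapse_weights = np.asarray(self.synapse_weights, dtype=float)
        if self.kernel_decay is None:
            self.kernel_decay = np.zeros(N_SYNAPSES)
        if self.kernel_rise is None:
            self.kernel_rise = np.zeros(N_SYNAPSES)

    def copy(self) -> "CellState":
        return CellState(
            self.compartment_potentials.copy(),
            self.synapse_weights.copy(),
            self.last_spike_time,
            self.kernel_decay.copy(),
            self.kernel_rise.copy(),
        )


class CellEnsemble:
    """Vectorised integrator for ``n`` cells sharing the update rule.

    Synaptic drive is injected at the synapse's compartment; compartments leak
    toward rest and diffuse along the dendritic tree every step.  NMDA-kind
    synapses are voltage gated: their current is scaled by a sigmoid of the
    local depolarisation around the unblock level.
    """

    def __init__(
        self,
        classes: Sequence[CellClass],
        synapses: Sequence[Sequence[SynapseSpec]],
        dt: float = 1.0,
        psp_gain: float = 1.0,
        nmda_unblock: float = 10.0,
        ltp_increment_frac: float = 0.05,
    ) -> None:
        if dt <= 0:
            raise ValueError("dt must be > 0")
        n = len(classes)
        if len(synapses) != n:
            raise ValueError("one synapse table per cell required")
        self.n = n
        self.dt = dt
        self.psp_gain = psp_gain
        self.nmda_unblock = nmda_unblock
        self.classes = list(classes)

        self.rest = np.array([c.resting_potential for c in classes])[:, None]
        self.threshold = np.array([c.threshold for c in classes])
        self.refractory = np.array([c.refractory for c in classes])
        leak = np.array([c.leak_rate for c in classes])[:, None]
        self.leak_decay = np.exp(-leak * dt)
        self.coupling = np.array([c.compartment_coupling for c in classes])[:, None]

        tau_r = np.full((n, N_SYNAPSES), 2.0)
        tau_d = np.full((n, N_SYNAPSES), 10.0)
        sign = np.ones((n, N_SYNAPSES))
        self.weight_max = np.full((n, N_SYNAPSES), np.inf)
        self.plastic = np.zeros((n, N_SYNAPSES), dtype=bool)
        self.is_nmda = np.zeros((n, N_SYNAPSES), dtype=bool)
        w0 = np.zeros((n, N_SYNAPSES))
        self.slot_defined = np.zeros((n, N_SYNAPSES), dtype=bool)
        for i, table in enumerate(synapses):
            for spec in table:
                j = spec.synapse_id - 1
                if self.slot_defined[i, j]:
                    raise ValueError(
                        f"cell {i}: synapse slot {spec.synapse_id} defined twice"
                    )
                self.slot_defined[i, j] = True
                tau_r[i, j] = spec.psp_rise
                tau_d[i, j] = spec.psp_decay
                sign[i, j] = spec.sign
                w0[i, j] = spec.weight
                self.weight_max[i, j] = spec.weight_max
                self.plastic[i, j] = spec.plastic
                self.is_nmda[i, j] = spec.kind is SynapseKind.NMDA

        self.decay_d = np.exp(-dt / tau_d)
        self.decay_r = np.exp(-dt / tau_r)
        self.norm = _kernel_norm(tau_r, tau_d) * sign
        self.slot_comp = np.array(SLOT_COMPARTMENT)
        # scatter matrix synapse-slot -> compartment
        self.scatter = np.zeros((N_SYNAPSES, N_COMPARTMENTS))
        for s, c in enumerate(SLOT_COMPARTMENT):
            self.scatter[s, c] = 1.0

        self.ltp_increment = ltp_increment_frac * np.where(
            np.isfinite(self.weight_max), self.weight_max, 0.0
        )

        # dynamic state
        self.V = np.broadcast_to(self.rest, (n, N_COMPARTMENTS)).copy()
        self.a = np.zeros((n, N_SYNAPSES))  # decay component
        self.b = np.zeros((n, N_SYNAPSES))  # rise component
        self.w = w0
        self.last_spike = np.full(n, -np.inf)

    # -- event delivery -------------------------------------------------
    def deliver(
        self,
        cell_idx: np.ndarray,
        slot_idx: np.ndarray,
        scale: np.ndarray | None = None,
    ) -> None:
        """Deliver presynaptic spikes to (cell, slot) pairs and apply LTP.

        LTP: a plastic synapse whose local compartment is depolarised past the
        NMDA-unblock level at spike arrival gains a fixed weight increment,
        clipped at ``weight_max``.  Weights never decrease.
        """
        if len(cell_idx) == 0:
            return
        if not self.slot_defined[cell_idx, slot_idx].all():
            bad = ~self.slot_defined[cell_idx, slot_idx]
            raise KeyError(
                f"undefined synapse slot(s) "
                f"{list(zip(cell_idx[bad], slot_idx[bad] + 1))}"
            )
        local_v = self.V[cell_idx, self.slot_comp[slot_idx]]
        gate = self.plastic[cell_idx, slot_idx] & (
            local_v >= self.rest[cell_idx, 0] + self.nmda_unblock
        )
        if gate.any():
            ci, si = cell_idx[gate], slot_idx[gate]
            self.w[ci, si] = np.minimum(
                self.w[ci, si] + self.ltp_increment[ci, si],
                self.weight_max[ci, si],
            )
        wts = self.w[cell_idx, slot_idx]
        if scale is not None:
            wts = wts * scale
        np.add.at(self.a, (cell_idx, slot_idx), wts)
        np.add.at(self.b, (cell_idx, slot_idx), wts)

    # -- one time step ---------------------------------------------------
    def step(self, t: float) -> np.ndarray:
        """Advance one dt (events must have been delivered first).

        Returns a boolean spike vector of length ``n``.
        """
        self.a *= self.decay_d
        self.b *= self.decay_r
        drive = self.norm * (self.a - self.b)
        if self.is_nmda.any():
            local_v = self.V[:, self.slot_comp]
            gate = 1.0 / (
                1.0
                + np.exp(-(local_v - (self.rest + self.nmda_unblock)) / 2.0)
            )
            drive = np.where(self.is_nmda, drive * gate, drive)
        # leak toward rest
        self.V = self.rest + (self.V - self.rest) * self.leak_decay
        # tree diffusion toward the neighbour average
        self.V += self.coupling * (self.V @ _AVG.T - self.V)
        # synaptic injection
        self.V += self.psp_gain * (drive @ self.scatter)
        if not np.isfinite(self.V).all():
            raise FloatingPointError("non-finite membrane potential")
        soma = self.V[:, 0]
        spikes = (soma >= self.threshold) & (t - self.last_spike >= self.refractory)
        if spikes.any():
            self.V[spikes, 0] = self.rest[spikes, 0]
            self.last_spike[spikes] = t
        return spikes


def _single_cell_ensemble(
    cls: CellClass, synapses: Sequence[SynapseSpec], state: CellState, dt: float
) -> CellEnsemble:
    ens = CellEnsemble([cls], [synapses], dt=dt)
    ens.V[0] = state.compartment_potentials
    ens.w[0] = state.synapse_weights
    ens.a[0] = state.kernel_decay
    ens.b[0] = state.kernel_rise
    ens.last_spike[0] = (
        -np.inf if state.last_spike_time is None else state.last_spike_time
    )
    return ens


def step_cell(
    state: CellState,
    cls: CellClass,
    synapses: Sequence[SynapseSpec],
    incoming_spikes: Iterable[int],
    t: float,
    dt: float = 1.0,
) -> tuple[CellState, bool]:
    """Advance one cell by one time step.

    ``incoming_spikes`` holds 1-based synapse ids receiving a presynaptic
    spike in this step.  Returns the new state and whether the cell fired.
    """
    if not np.isfinite(state.compartment_potentials).all():
        raise FloatingPointError("invalid state: non-finite potentials")
    ens = _single_cell_ensemble(cls, synapses, state, dt)
    ids = np.asarray(sorted(set(incoming_spikes)), dtype=int)
    if ids.size:
        if ids.min() < 1 or ids.max() > N_SYNAPSES:
            raise KeyError(f"synapse id outside 1..{N_SYNAPSES}: {ids}")
        ens.deliver(np.zeros(len(ids), dtype=int), ids - 1)
    spiked = bool(ens.step(t)[0])
    new = CellState(
        ens.V[0].copy(),
        ens.w[0].copy(),
        None if np.isneginf(ens.last_spike[0]) else float(ens.last_spike[0]),
        ens.a[0].copy(),
        ens.b[0].copy(),
    )
    return new, spiked


def ltp_update(
    state: CellState,
    spec: SynapseSpec,
    pre_spike: bool,
    t: float,
    nmda_unblock: float = 10.0,
    resting_potential: float = -70.0,
    increment_frac: float = 0.05,
) -> CellState:
    """Apply the NMDA-gated LTP rule to one synapse; weights never decrease."""
    if not spec.plastic:
        raise ValueError(f"ltp_update on non-plastic synapse {spec.synapse_id}")
    if not pre_spike:
        return state
    local_v = state.compartment_potentials[spec.compartment]
    if local_v < resting_potential + nmda_unblock:
        return state
    new = state.copy()
    j = spec.synapse_id - 1
    new.synapse_weights[j] = min(
        new.synapse_weights[j] + increment_frac * spec.weight_max, spec.weight_max
    )
    return new
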