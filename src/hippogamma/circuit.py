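"""The 21-cell DG-CA3-CA1 microcircuit and its staged synaptic deletions.

Cell inventory (7 per region):

* DG:  granule cells G1-G4, basket cells B5-B6, mossy cell MC
* CA3: pyramidal cells P5-P8, basket cells B3-B4, O-LM cell OLM2
* CA1: pyramidal cells P1-P4, basket cells B1-B2, O-LM cell OLM1

External afferents are the entorhinal perforant-path lines ``Ex1..Ex9``
(onto DG granule cells, CA3 pyramidal cells and DG/CA3 basket cells) and the
medial septum-diagonal band GABAergic lines ``T4..T9`` (onto interneurons
only).  Pathway structure: granule -> CA3 (mossy fibre), CA3 -> CA1
(Schaffer collateral), mossy cell reciprocal with granule/basket cells,
basket cells inhibiting the principal cells of their own region
perisomatically, O-LM cells inhibiting distal dendrites.

Disease-like degeneration is modelled purely as deactivation of perforant
path synapses in the DG-CA3 microcircuits, applied as a prefix of a fixed
deletion order (never touching CA1 or the Schaffer collaterals).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .cell_model import (
    CellClass,
    CellClassName,
    SynapseKind,
    SynapseSpec,
    N_EXCITATORY,
    N_INHIBITORY,
    N_SYNAPSES,
)

__all__ = [
    "REGIONS",
    "CELL_REGION",
    "CELL_NAMES",
    "PRINCIPAL_CELLS",
    "EC2_LINES",
    "MSDB_LINES",
    "EXTERNAL_LINES",
    "CellLabel",
    "Edge",
    "Circuit",
    "ConfigurationError",
    "default_config",
    "build_circuit",
    "apply_ad_deletion",
    "summarize_circuit",
    "DEFAULT_AD_STAGE",
]


class ConfigurationError(ValueError):
    """A circuit configuration violates a structural invariant."""


REGIONS = ("DG", "CA3", "CA1")

CELL_REGION: dict[str, str] = {
    **{c: "DG" for c in ("G1", "G2", "G3", "G4", "B5", "B6", "MC")},
    **{c: "CA3" for c in ("P5", "P6", "P7", "P8", "B3", "B4", "OLM2")},
    **{c: "CA1" for c in ("P1", "P2", "P3", "P4", "B1", "B2", "OLM1")},
}
CELL_NAMES = tuple(CELL_REGION)

PRINCIPAL_CELLS: dict[str, tuple[str, ...]] = {
    "DG": ("G1", "G2", "G3", "G4"),
    "CA3": ("P5", "P6", "P7", "P8"),
    "CA1": ("P1", "P2", "P3", "P4"),
}

EC2_LINES = tuple(f"Ex{i}" for i in range(1, 10))
#: perforant-path lines silent under the control protocol
SILENT_EC2_LINES = ("Ex8", "Ex9")
MSDB_LINES = tuple(f"T{i}" for i in range(4, 10))
EXTERNAL_LINES = EC2_LINES + MSDB_LINES

_CLASS_OF: dict[str, CellClassName] = {}
for _c in CELL_NAMES:
    if _c.startswith("G"):
        _CLASS_OF[_c] = CellClassName.granule
    elif _c.startswith("P"):
        _CLASS_OF[_c] = CellClassName.pyramidal
    elif _c.startswith("B"):
        _CLASS_OF[_c] = CellClassName.basket
    elif _c.startswith("OLM"):
        _CLASS_OF[_c] = CellClassName.olm
    else:
        _CLASS_OF[_c] = CellClassName.mossy

_INTERNEURONS = tuple(
    c for c, k in _CLASS_OF.items() if k in (CellClassName.basket, CellClassName.olm)
)


@dataclass(frozen=True)
class CellLabel:
    region: str
    name: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ConfigurationError(f"unknown region {self.region!r}")
        if CELL_REGION.get(self.name) != self.region:
            raise ConfigurationError(
                f"cell {self.name!r} does not belong to region {self.region!r}"
            )

    @classmethod
    def of(cls, name: str) -> "CellLabel":
        return cls(CELL_REGION[name], name)


@dataclass
class Edge:
    """A directed synaptic line terminating on slot ``synapse.synapse_id``."""

    source: str  # cell name or external line
    target: str
    synapse: SynapseSpec
    active: bool = True

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ConfigurationError(f"self-edge on {self.target}")
        if self.target not in CELL_REGION:
            raise ConfigurationError(f"unknown target cell {self.target!r}")
        if self.source not in CELL_REGION and self.source not in EXTERNAL_LINES:
            raise ConfigurationError(f"unknown source {self.source!r}")


@dataclass
class Circuit:
    cells: dict[str, CellClass]
    edges: list[Edge]
    lesion_stage: int = 0
    deletion_order: list[tuple[str, str]] = field(default_factory=list)

    @property
    def labels(self) -> list[CellLabel]:
        return [CellLabel.of(c) for c in self.cells]

    def afferents(self, cell: str) -> list[Edge]:
        return [e for e in self.edges if e.target == cell]

    def active_edges(self) -> list[Edge]:
        return [e for e in self.edges if e.active]

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "lesion_stage": self.lesion_stage,
            "cells": {
                name: {
                    "class": cls.name.value,
                    "resting_potential": cls.resting_potential,
                    "threshold": cls.threshold,
                    "refractory": cls.refractory,
                    "leak_rate": cls.leak_rate,
                    "compartment_coupling": cls.compartment_coupling,
                }
                for name, cls in self.cells.items()
            },
            "edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "slot": e.synapse.synapse_id,
                    "kind": e.synapse.kind.value,
                    "weight": e.synapse.weight,
                    "weight_max": e.synapse.weight_max,
                    "plastic": e.synapse.plastic,
                    "psp_rise": e.synapse.psp_rise,
                    "psp_decay": e.synapse.psp_decay,
                    "active": e.active,
                }
                for e in self.edges
            ],
            "deletion_order": [list(p) for p in self.deletion_order],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "Circuit":
        cells = {
            name: CellClass(
                name=CellClassName(spec["class"]),
                resting_potential=spec["resting_potential"],
                threshold=spec["threshold"],
                refractory=spec["refractory"],
                leak_rate=spec["leak_rate"],
                compartment_coupling=spec["compartment_coupling"],
            )
            for name, spec in data["cells"].items()
        }
        edges = [
            Edge(
                source=e["source"],
                target=e["target"],
                synapse=SynapseSpec(
                    synapse_id=e["slot"],
                    kind=SynapseKind(e["kind"]),
                    weight=e["weight"],
                    weight_max=e["weight_max"],
                    plastic=e["plastic"],
                    psp_rise=e["psp_rise"],
                    psp_decay=e["psp_decay"],
                ),
                active=e["active"],
            )
            for e in data["edges"]
        ]
        circ = cls(
            cells=cells,
            edges=edges,
            lesion_stage=data.get("lesion_stage", 0),
            deletion_order=[tuple(p) for p in data.get("deletion_order", [])],
        )
        _validate(circ)
        return circ

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "Circuit":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# default configuration
# ---------------------------------------------------------------------------

#: Integration parameters per cell; CA3 pyramidal cells recover faster than
#: CA1 ones, granule cells are the slowest principal class, which sets the
#: characteristic intra-burst inter-spike interval of each region.
DEFAULT_CLASS_PARAMS: dict[str, dict] = {
    "granule": dict(threshold=-62.0, refractory=14.0, leak_rate=0.25,
                    compartment_coupling=0.6),
    "pyramidal_ca3": dict(threshold=-62.0, refractory=7.0, leak_rate=0.25,
                          compartment_coupling=0.6),
    "pyramidal_ca1": dict(threshold=-62.0, refractory=9.5, leak_rate=0.25,
                          compartment_coupling=0.6),
    "basket": dict(threshold=-64.0, refractory=7.0, leak_rate=0.25,
                   compartment_coupling=0.7),
    "olm": dict(threshold=-58.0, refractory=10.0, leak_rate=0.25,
                compartment_coupling=0.6),
    "mossy": dict(threshold=-62.0, refractory=10.0, leak_rate=0.25,
                  compartment_coupling=0.6),
}

#: Projection weights (local PSP peak, mV) — the main calibration knobs.
DEFAULT_WEIGHTS: dict[str, float] = {
    "ec2_granule": 15.0,
    "ec2_ca3pyr": 16.0,
    "ec2_basket": 14.0,
    "mossy_fiber": 9.0,       # granule -> CA3 pyramidal
    "mossy_fiber_decay": 5.0,  # ms
    "recurrent_ca3": 1.2,
    "schaffer": 3.5,          # CA3 -> CA1 pyramidal (x13 slots)
    "schaffer_decay": 5.0,     # ms; short tail so CA1 bursts track CA3 bursts
    "mc_granule": 2.0,        # mossy cell -> granule (slow NMDA)
    "granule_mc": 4.0,
    "mc_ca3pyr": 1.0,
    "mc_basket": 1.0,
    "granule_basket": 3.0,
    "pyr_basket": 4.0,
    "pyr_basket_ca1": 2.5,
    "pyr_olm": 3.0,
    "basket_principal": 17.0,  # GABA, perisomatic
    "basket_principal_decay": 6.0,  # ms, faster than the generic GABA kernel
    "olm_principal": 2.0,      # GABA, distal dendrite
    "basket_mc": 4.0,
    "msdb_interneuron": 30.0,  # GABA, theta gating of interneurons
    "msdb_decay": 8.0,         # ms; sharp gating edges
    "weight_max_factor": 2.0,  # weight_max = factor * initial weight
}

#: Deletion stage defining the degenerated ("pathological") circuit:
#: perforant-path lines Ex1-Ex4 off on every granule and CA3 pyramidal cell.
DEFAULT_AD_STAGE = 32

_KERNELS = {
    SynapseKind.AMPA: (2.0, 10.0),
    SynapseKind.NMDA: (5.0, 50.0),
    SynapseKind.GABA: (2.0, 20.0),
}


def _mk_syn(slot: int, kind: SynapseKind, weight: float, wmax_factor: float,
            plastic: bool = False, decay: float | None = None) -> SynapseSpec:
    rise, kdecay = _KERNELS[kind]
    decay = kdecay if decay is None else decay
    return SynapseSpec(
        synapse_id=slot,
        kind=kind,
        weight=weight,
        weight_max=weight * wmax_factor if weight > 0 else 1.0,
        plastic=plastic,
        psp_rise=rise,
        psp_decay=decay,
    )


def default_config(
    class_params: Mapping[str, Mapping] | None = None,
    weights: Mapping[str, float] | None = None,
) -> dict:
    """Build the default circuit configuration as a plain dictionary.

    ``class_params`` / ``weights`` override entries of
    :data:`DEFAULT_CLASS_PARAMS` / :data:`DEFAULT_WEIGHTS`.
    """
    cp = {k: dict(v) for k, v in DEFAULT_CLASS_PARAMS.items()}
    for k, v in (class_params or {}).items():
        cp[k].update(v)
    w = dict(DEFAULT_WEIGHTS)
    w.update(weights or {})
    wf = w["weight_max_factor"]

    def cell_block(name: str) -> dict:
        kind = _CLASS_OF[name]
        if kind is CellClassName.pyramidal:
            key = "pyramidal_ca3" if CELL_REGION[name] == "CA3" else "pyramidal_ca1"
        else:
            key = kind.value
        return {"class": kind.value, "resting_potential": -70.0, **cp[key]}

    cells = {name: cell_block(name) for name in CELL_NAMES}

    A, N, G = SynapseKind.AMPA, SynapseKind.NMDA, SynapseKind.GABA
    edges: list[dict] = []

    def add(source: str, target: str, slot: int, kind: SynapseKind,
            weight: float, plastic: bool = False, decay: float | None = None) -> None:
        spec = _mk_syn(slot, kind, weight, wf, plastic, decay)
        edges.append(
            {
                "source": source,
                "target": target,
                "slot": slot,
                "kind": kind.value,
                "weight": spec.weight,
                "weight_max": spec.weight_max,
                "plastic": spec.plastic,
                "psp_rise": spec.psp_rise,
                "psp_decay": spec.psp_decay,
                "active": True,
            }
        )

    granules = PRINCIPAL_CELLS["DG"]
    ca3pyr = PRINCIPAL_CELLS["CA3"]
    ca1pyr = PRINCIPAL_CELLS["CA1"]

    for g in granules:
        for i, line in enumerate(EC2_LINES, start=1):  # slots 1..9
            add(line, g, i, A, w["ec2_granule"], plastic=True)
        for slot in (10, 11, 12, 13):
            add("MC", g, slot, N, w["mc_granule"])
        gd = w["basket_principal_decay"]
        add("B5", g, 14, G, w["basket_principal"], decay=gd)
        add("B6", g, 15, G, w["basket_principal"], decay=gd)
        add("B6", g, 16, G, w["basket_principal"] / 2, decay=gd)

    for p in ca3pyr:
        # mossy fibres contact proximal dendrites, perforant path distal ones
        for slot, g in zip((1, 2, 3, 4), granules):
            add(g, p, slot, A, w["mossy_fiber"], plastic=True,
                decay=w["mossy_fiber_decay"])
        for i in range(1, 6):  # perforant path Ex1..Ex5
            add(EC2_LINES[i - 1], p, 4 + i, A, w["ec2_ca3pyr"], plastic=True)
        others = [q for q in ca3pyr if q != p]
        for slot, q in zip((10, 11, 12), others):
            add(q, p, slot, A, w["recurrent_ca3"], plastic=True)
        add("MC", p, 13, A, w["mc_ca3pyr"])
        gd = w["basket_principal_decay"]
        add("B3", p, 14, G, w["basket_principal"], decay=gd)
        add("B4", p, 15, G, w["basket_principal"], decay=gd)
        add("OLM2", p, 16, G, w["olm_principal"], decay=gd)

    for i, p in enumerate(ca1pyr):
        for slot in range(1, 13):  # Schaffer collaterals, x3 per CA3 cell
            add(ca3pyr[(slot - 1) % 4], p, slot, A, w["schaffer"], plastic=True,
                decay=w["schaffer_decay"])
        add(ca3pyr[i], p, 13, A, w["schaffer"], plastic=True,
            decay=w["schaffer_decay"])
        gd = w["basket_principal_decay"]
        add("B1", p, 14, G, w["basket_principal"], decay=gd)
        add("B2", p, 15, G, w["basket_principal"], decay=gd)
        add("OLM1", p, 16, G, w["olm_principal"], decay=gd)

    msdb_of = {"B1": "T4", "B2": "T5", "B3": "T6", "B4": "T7",
               "B5": "T8", "B6": "T9", "OLM1": "T4", "OLM2": "T6"}

    for b in ("B5", "B6"):
        for i in range(1, 8):
            add(EC2_LINES[i - 1], b, i, A, w["ec2_basket"])
        for slot, g in zip((8, 9, 10, 11), granules):
            add(g, b, slot, A, w["granule_basket"])
        add("MC", b, 12, A, w["mc_basket"])
        add("MC", b, 13, A, w["mc_basket"])
        for slot in (14, 15, 16):
            add(msdb_of[b], b, slot, G, w["msdb_interneuron"], decay=w["msdb_decay"])

    for b in ("B3", "B4"):
        for i in range(1, 8):
            add(EC2_LINES[i - 1], b, i, A, w["ec2_basket"])
        for slot, p in zip((8, 9, 10, 11), ca3pyr):
            add(p, b, slot, A, w["pyr_basket"])
        for slot, g in zip((12, 13), granules[:2]):
            add(g, b, slot, A, w["granule_basket"])
        for slot in (14, 15, 16):
            add(msdb_of[b], b, slot, G, w["msdb_interneuron"], decay=w["msdb_decay"])

    for b in ("B1", "B2"):
        for slot, p in zip((1, 2, 3, 4), ca3pyr):
            add(p, b, slot, A, w["pyr_basket_ca1"])
        for slot, p in zip((5, 6, 7, 8), ca1pyr):
            add(p, b, slot, A, w["pyr_basket_ca1"])
        for slot, p in zip((9, 10, 11, 12), ca3pyr):
            add(p, b, slot, A, w["pyr_basket_ca1"] / 2)
        add("P5", b, 13, A, w["pyr_basket_ca1"] / 2)
        for slot in (14, 15, 16):
            add(msdb_of[b], b, slot, G, w["msdb_interneuron"], decay=w["msdb_decay"])

    for olm, pyrs in (("OLM1", ca1pyr), ("OLM2", ca3pyr)):
        for slot in range(1, 13):
            add(pyrs[(slot - 1) % 4], olm, slot, A, w["pyr_olm"], plastic=True)
        add(pyrs[0], olm, 13, A, w["pyr_olm"] / 2, plastic=True)
        for slot in (14, 15, 16):
            add(msdb_of[olm], olm, slot, G, w["msdb_interneuron"], decay=w["msdb_decay"])

    for slot in range(1, 13):
        add(granules[(slot - 1) % 4], "MC", slot, A, w["granule_mc"])
    add("G1", "MC", 13, A, w["granule_mc"] / 2)
    add("B5", "MC", 14, G, w["basket_mc"])
    add("B6", "MC", 15, G, w["basket_mc"])
    add("B6", "MC", 16, G, w["basket_mc"] / 2)

    # fixed deletion order: per perforant-path line, granule targets then CA3
    # pyramidal targets; all interneuron EC2 afferents last.
    deletion_order: list[list[str]] = []
    for i, line in enumerate(EC2_LINES, start=1):
        deletion_order.extend([line, g] for g in granules)
        if i <= 5:
            deletion_order.extend([line, p] for p in ca3pyr)
    for i, line in enumerate(EC2_LINES, start=1):
        if i <= 7:
            deletion_order.extend([line, b] for b in ("B5", "B6", "B3", "B4"))

    return {
        "lesion_stage": 0,
        "cells": cells,
        "edges": edges,
        "deletion_order": deletion_order,
    }


# ---------------------------------------------------------------------------
# validation and operations
# ---------------------------------------------------------------------------

def _validate(circ: Circuit) -> None:
    if set(circ.cells) != set(CELL_NAMES):
        missing = set(CELL_NAMES) - set(circ.cells)
        extra = set(circ.cells) - set(CELL_NAMES)
        raise ConfigurationError(f"cell inventory mismatch: missing={missing}, extra={extra}")
    seen: set[tuple[str, int]] = set()
    for e in circ.edges:
        key = (e.target, e.synapse.synapse_id)
        if key in seen:
            raise ConfigurationError(
                f"duplicate afferent on {e.target} slot {e.synapse.synapse_id}"
            )
        seen.add(key)
        if e.source in EC2_LINES and CELL_REGION[e.target] == "CA1":
            raise ConfigurationError(
                f"perforant-path line {e.source} may not target CA1 cell {e.target}"
            )
        if e.source in MSDB_LINES and e.target not in _INTERNEURONS:
            raise ConfigurationError(
                f"MS-DB line {e.source} must target an interneuron, not {e.target}"
            )
    for cell in CELL_NAMES:
        if circ.cells[cell].name is CellClassName.mossy:
            continue
        aff = circ.afferents(cell)
        n_exc = sum(1 for e in aff if e.synapse.sign > 0)
        n_inh = sum(1 for e in aff if e.synapse.sign < 0)
        if n_exc != N_EXCITATORY or n_inh != N_INHIBITORY:
            raise ConfigurationError(
                f"{cell}: expected {N_EXCITATORY} excitatory + {N_INHIBITORY} "
                f"inhibitory afferents, found {n_exc}+{n_inh}"
            )
    for e in circ.edges:
        if e.synapse.plastic:
            kind = circ.cells[e.target].name
            if kind not in (CellClassName.granule, CellClassName.pyramidal,
                            CellClassName.olm):
                raise ConfigurationError(
                    f"plastic synapse on {e.target} ({kind.value}); plasticity is "
                    "restricted to granule, pyramidal and O-LM cells"
                )


def build_circuit(params: Mapping | None = None) -> Circuit:
    """Construct and validate a circuit; ``params=None`` uses the defaults."""
    data = params if params is not None else default_config()
    circ = Circuit.from_dict(data)
    if circ.lesion_stage != 0:
        raise ConfigurationError("build_circuit expects an unlesioned configuration")
    if any(not e.active for e in circ.edges):
        raise ConfigurationError("build_circuit expects all edges active")
    return circ


def apply_ad_deletion(circuit: Circuit, stage: int) -> Circuit:
    """Deactivate the first ``stage`` perforant-path edges of the deletion order.

    Returns a new circuit; the input is not mutated.  Only DG-CA3 perforant
    path synapses are ever touched.
    """
    order = circuit.deletion_order
    if not 0 <= stage <= len(order):
        raise ValueError(f"stage {stage} outside 0..{len(order)}")
    doomed = set(map(tuple, order[:stage]))
    new = copy.deepcopy(circuit)
    hit = set()
    for e in new.edges:
        key = (e.source, e.target)
        if key in doomed:
            e.active = False
            hit.add(key)
    missing = doomed - hit
    if missing:
        raise ConfigurationError(f"deletion order names unknown edges: {missing}")
    new.lesion_stage = stage
    return new


def summarize_circuit(circuit: Circuit) -> pd.DataFrame:
    """Per-region table of cell and afferent-edge counts."""
    rows = []
    for region in REGIONS:
        cells = [c for c in CELL_NAMES if CELL_REGION[c] == region]
        aff = [e for e in circuit.edges if CELL_REGION[e.target] == region]
        act = [e for e in aff if e.active]
        rows.append(
            {
                "region": region,
                "n_cells": len(cells),
                "n_edges": len(aff),
                "n_active_edges": len(act),
                "n_active_ec2_edges": sum(1 for e in act if e.source in EC2_LINES),
            }
        )
    return pd.DataFrame(rows)
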