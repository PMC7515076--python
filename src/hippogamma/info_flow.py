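"""Mutual information and transfer entropy between discretised spike trains.

Spike trains are binarised into ``bin_width`` ms bins (symbol 1 when the bin
holds at least one spike).  Both measures use plug-in (maximum likelihood)
estimators on the joint symbol histograms, in bits; transfer entropy follows
the Schreiber definition with source/target history lengths ``l``/``k``
(default 1):

    TE(X -> Y) = sum p(y_{t+1}, y_t^(k), x_t^(l))
                 log2 [ p(y_{t+1} | y_t^(k), x_t^(l)) / p(y_{t+1} | y_t^(k)) ]

The plug-in bias for a table with ``m`` cells on ``n`` samples is of order
``(m - 1) / (2 n ln 2)`` bits (Miller-Madow); :func:`plugin_bias_bound`
exposes it so tests and reports can reason about estimator tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .circuit import PRINCIPAL_CELLS
from .engine import SpikeRecording
from .protocols import SpikeTrain

__all__ = [
    "SymbolSeries",
    "FlowMatrix",
    "discretize",
    "entropy",
    "mutual_information",
    "transfer_entropy",
    "plugin_bias_bound",
    "shuffled_transfer_entropy",
    "flow_matrices",
    "DEFAULT_BIN_WIDTH",
]

DEFAULT_BIN_WIDTH = 10.0


@dataclass(frozen=True)
class SymbolSeries:
    """Discrete symbol sequence for one unit."""

    unit_id: str
    symbols: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        s = np.asarray(self.symbols, dtype=np.int64)
        object.__setattr__(self, "symbols", s)
        if s.size and s.min() < 0:
            raise ValueError("symbols must be non-negative integers")

    def __len__(self) -> int:
        return int(self.symbols.size)

    @property
    def alphabet_size(self) -> int:
        return int(self.symbols.max()) + 1 if len(self) else 0


def discretize(
    train: SpikeTrain, duration: float | None = None, bin_width: float = DEFAULT_BIN_WIDTH
) -> SymbolSeries:
    """Binary symbol series: 1 iff the bin ``[k*w, (k+1)*w)`` holds a spike."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    duration = duration if duration is not None else train.duration
    n_bins = int(np.ceil(duration / bin_width))
    sym = np.zeros(n_bins, dtype=np.int64)
    if len(train):
        k = np.floor(train.times / bin_width).astype(int)
        k = k[(k >= 0) & (k < n_bins)]
        sym[k] = 1
    return SymbolSeries(train.unit_id, sym, bin_width)


def _check_equal_length(*series: SymbolSeries) -> int:
    lengths = {len(s) for s in series}
    if len(lengths) != 1:
        raise ValueError(f"symbol series lengths differ: {sorted(lengths)}")
    return lengths.pop()


def entropy(x: SymbolSeries) -> float:
    """Plug-in Shannon entropy H(X) in bits."""
    counts = np.bincount(x.symbols)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _joint_entropy(cols: Sequence[np.ndarray]) -> float:
    stacked = np.stack(cols, axis=1)
    _, counts = np.unique(stacked, axis=0, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def mutual_information(x: SymbolSeries, y: SymbolSeries) -> float:
    """Plug-in mutual information I(X;Y) in bits (symmetric, >= 0)."""
    _check_equal_length(x, y)
    return entropy(x) + entropy(y) - _joint_entropy([x.symbols, y.symbols])


def _history(sym: np.ndarray, order: int, upto: int) -> np.ndarray:
    """Encode the ``order``-symbol history ending at each index < upto."""
    base = int(sym.max()) + 1 if sym.size else 1
    out = np.zeros(upto, dtype=np.int64)
    for j in range(order):
        out = out * base + sym[order - 1 - j : order - 1 - j + upto]
    return out


def transfer_entropy(
    source: SymbolSeries, target: SymbolSeries, k: int = 1, l: int = 1
) -> float:
    """Schreiber transfer entropy TE(source -> target) in bits.

    Degenerate (constant) targets give exactly 0.
    """
    n = _check_equal_length(source, target)
    if k < 1 or l < 1:
        raise ValueError("history lengths k, l must be >= 1")
    h = max(k, l)
    if n <= h:
        raise ValueError("series shorter than history length")
    m = n - h
    y_next = target.symbols[h : h + m]
    y_hist = _history(target.symbols[h - k :], k, m)
    x_hist = _history(source.symbols[h - l :], l, m)
    # TE = H(y+|y) - H(y+|y,x) expressed via joint entropies
    te = (
        _joint_entropy([y_next, y_hist])
        - _joint_entropy([y_hist])
        - _joint_entropy([y_next, y_hist, x_hist])
        + _joint_entropy([y_hist, x_hist])
    )
    return float(te)


def plugin_bias_bound(n: int, n_cells: int) -> float:
    """Miller-Madow first-order bias of a plug-in entropy, bits."""
    return (n_cells - 1) / (2 * n * np.log(2))


def shuffled_transfer_entropy(
    source: SymbolSeries,
    target: SymbolSeries,
    k: int = 1,
    l: int = 1,
    n_shuffles: int = 20,
    seed: int = 0,
) -> float:
    """Mean TE after time-shuffling the source (estimator noise floor)."""
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_shuffles):
        perm = SymbolSeries(
            source.unit_id, rng.permutation(source.symbols), source.bin_width
        )
        vals.append(transfer_entropy(perm, target, k=k, l=l))
    return float(np.mean(vals))


@dataclass
class FlowMatrix:
    """Run-averaged information-flow matrix between two cell groups."""

    measure: str  # "TE" or "MI"
    sources: tuple[str, ...]
    targets: tuple[str, ...]
    values: pd.DataFrame
    settings: dict

    def to_long(self) -> pd.DataFrame:
        out = self.values.stack().rename("bits").reset_index()
        out.columns = ["source", "target", "bits"]
        out.insert(0, "measure", self.measure)
        return out


def flow_matrices(
    recordings: Sequence[SpikeRecording],
    bin_width: float = DEFAULT_BIN_WIDTH,
    k: int = 1,
    l: int = 1,
) -> dict[str, FlowMatrix]:
    """TE matrices along DG->CA3 and CA3->CA1 plus all-pairs principal MI.

    Entries are averaged over runs; the MI matrix diagonal holds the per-cell
    entropies.
    """
    if not recordings:
        raise ValueError("no recordings")
    durations = {r.duration for r in recordings}
    if len(durations) != 1:
        raise ValueError("recordings must share duration")
    dg = PRINCIPAL_CELLS["DG"]
    ca3 = PRINCIPAL_CELLS["CA3"]
    ca1 = PRINCIPAL_CELLS["CA1"]
    all_principal = dg + ca3 + ca1

    te_blocks = {"TE_DG_CA3": (dg, ca3), "TE_CA3_CA1": (ca3, ca1)}
    te_acc = {name: np.zeros((len(s), len(t))) for name, (s, t) in te_blocks.items()}
    mi_acc = np.zeros((len(all_principal), len(all_principal)))

    for rec in recordings:
        sym = {
            c: discretize(rec.spikes[c], rec.duration, bin_width)
            for c in all_principal
        }
        for name, (srcs, tgts) in te_blocks.items():
            for a, s in enumerate(srcs):
                for b, t in enumerate(tgts):
                    te_acc[name][a, b] += transfer_entropy(sym[s], sym[t], k=k, l=l)
        for a, s in enumerate(all_principal):
            for b, t in enumerate(all_principal):
                if b < a:
                    continue
                v = entropy(sym[s]) if a == b else mutual_information(sym[s], sym[t])
                mi_acc[a, b] += v
                if a != b:
                    mi_acc[b, a] += v

    n = len(recordings)
    settings = {"bin_width_ms": bin_width, "k": k, "l": l, "n_runs": n,
                "estimator": "plug-in, base 2"}
    out = {}
    for name, (srcs, tgts) in te_blocks.items():
        out[name] = FlowMatrix(
            "TE", tuple(srcs), tuple(tgts),
            pd.DataFrame(te_acc[name] / n, index=list(srcs), columns=list(tgts)),
            settings,
        )
    out["MI_all"] = FlowMatrix(
        "MI", tuple(all_principal), tuple(all_principal),
        pd.DataFrame(mi_acc / n, index=list(all_principal),
                     columns=list(all_principal)),
        settings,
    )
    return out
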