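"""Burst detection and the four neuronal outcome measures.

Per cell and run: total number of spikes, mean spikes per burst, mean burst
duration (first-to-last spike of a burst) and mean inter-burst interval (gap
between the end of one burst and the start of the next).  A burst is a
maximal run of at least two spikes whose consecutive inter-spike intervals do
not exceed ``max_isi`` (default 15 ms: the protocol's intra-burst interval is
10 ms while the theta gap is an order of magnitude longer).  Isolated spikes
count toward the spike total but belong to no burst.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .circuit import CELL_REGION, PRINCIPAL_CELLS
from .engine import SpikeRecording
from .protocols import SpikeTrain

__all__ = [
    "Burst",
    "DEFAULT_MAX_ISI",
    "REGION_GROUPS",
    "detect_bursts",
    "compute_metrics",
    "aggregate_metrics",
]

DEFAULT_MAX_ISI = 15.0

#: Region groupings reported by the analysis: single regions plus the pooled
#: CA3-CA1 and whole-circuit groupings, each averaging over principal cells.
REGION_GROUPS: dict[str, tuple[str, ...]] = {
    "DG": PRINCIPAL_CELLS["DG"],
    "CA3": PRINCIPAL_CELLS["CA3"],
    "CA1": PRINCIPAL_CELLS["CA1"],
    "CA3-CA1": PRINCIPAL_CELLS["CA3"] + PRINCIPAL_CELLS["CA1"],
    "DG-CA3-CA1": PRINCIPAL_CELLS["DG"]
    + PRINCIPAL_CELLS["CA3"]
    + PRINCIPAL_CELLS["CA1"],
}


@dataclass(frozen=True)
class Burst:
    start: float
    end: float
    n_spikes: int

    def __post_init__(self) -> None:
        if self.end < self.start or self.n_spikes < 2:
            raise ValueError("burst must span >= 2 spikes with end >= start")

    @property
    def duration(self) -> float:
        return self.end - self.start


def detect_bursts(train: SpikeTrain | np.ndarray, max_isi: float = DEFAULT_MAX_ISI) -> list[Burst]:
    """Maximal runs of >= 2 spikes with consecutive ISIs <= ``max_isi``."""
    if max_isi <= 0:
        raise ValueError("max_isi must be > 0")
    times = train.times if isinstance(train, SpikeTrain) else np.asarray(train, float)
    if times.size < 2:
        return []
    breaks = np.nonzero(np.diff(times) > max_isi)[0]
    bounds = np.concatenate([[0], breaks + 1, [times.size]])
    bursts = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi - lo >= 2:
            bursts.append(Burst(times[lo], times[hi - 1], int(hi - lo)))
    return bursts


def _cell_row(train: SpikeTrain, max_isi: float) -> dict:
    bursts = detect_bursts(train, max_isi)
    row = {
        "n_spikes": len(train),
        "n_bursts": len(bursts),
        "mean_spikes_per_burst": math.nan,
        "mean_burst_duration_ms": math.nan,
        "mean_inter_burst_interval_ms": math.nan,
    }
    if bursts:
        row["mean_spikes_per_burst"] = float(np.mean([b.n_spikes for b in bursts]))
        row["mean_burst_duration_ms"] = float(np.mean([b.duration for b in bursts]))
    if len(bursts) >= 2:
        gaps = [nb.start - b.end for b, nb in zip(bursts[:-1], bursts[1:])]
        row["mean_inter_burst_interval_ms"] = float(np.mean(gaps))
    return row


def compute_metrics(
    recording: SpikeRecording,
    cells: Sequence[str] | None = None,
    max_isi: float = DEFAULT_MAX_ISI,
) -> pd.DataFrame:
    """Tidy per-cell metric rows for one recording.

    Undefined metrics (no bursts, or fewer than two bursts for the
    inter-burst interval) are NaN, never zero.
    """
    cells = tuple(cells) if cells is not None else REGION_GROUPS["DG-CA3-CA1"]
    rows = []
    for c in cells:
        row = {
            "condition": recording.condition.name,
            "run": recording.run_index,
            "cell": c,
            "region": CELL_REGION[c],
        }
        row.update(_cell_row(recording.spikes[c], max_isi))
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_metrics(
    rows: pd.DataFrame, groups: dict[str, tuple[str, ...]] | None = None
) -> pd.DataFrame:
    """Unweighted mean over (cells x runs) per condition and region group."""
    groups = groups or REGION_GROUPS
    metrics = [
        "n_spikes",
        "mean_spikes_per_burst",
        "mean_burst_duration_ms",
        "mean_inter_burst_interval_ms",
    ]
    out = []
    for gname, cells in groups.items():
        sub = rows[rows["cell"].isin(cells)]
        for cond, grp in sub.groupby("condition", sort=False):
            rec = {"condition": cond, "region_group": gname,
                   "n_obs": len(grp)}
            for m in metrics:
                rec[f"{m}_mean"] = grp[m].mean()
                rec[f"{m}_sd"] = grp[m].std(ddof=1)
            out.append(rec)
    return pd.DataFrame(out)
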