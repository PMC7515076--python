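"""End-to-end analysis pipeline over batches of recordings.

Ties the stages together: spike/burst metrics, delay-embedding measures on
the per-cell firing-rate series, information-flow matrices, and the group
statistics, with one pinned set of estimator settings
(:class:`AnalysisSettings`) recorded next to every output table.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .circuit import CELL_REGION
from .engine import ALL_PRINCIPAL, SpikeRecording
from .info_flow import flow_matrices
from .nonlinear import (
    EmbeddingSpec,
    correlation_dimension,
    false_nearest_neighbors,
    max_lyapunov_jacobian,
    radius_for_rate,
    recurrence_matrix,
    rqa_measures,
    select_delay,
    series_entropy,
)
from .spike_metrics import REGION_GROUPS, aggregate_metrics, compute_metrics

__all__ = [
    "AnalysisSettings",
    "rate_series",
    "nonlinear_cell_measures",
    "nonlinear_table",
    "aggregate_nonlinear",
    "metrics_table",
    "analyze_batch",
]


@dataclass(frozen=True)
class AnalysisSettings:
    """Pinned estimator settings for the nonlinear / information stages.

    The analysis series is the smoothed instantaneous firing rate of each
    principal cell (spike counts in ``rate_bin_ms`` bins convolved with a
    Gaussian of ``rate_smooth_sd`` bins); embeddings use the auto-MI delay
    and the FNN dimension; the Lyapunov exponent is the local-Jacobian (QR)
    estimate per bin; recurrence analysis fixes the radius at a
    ``recurrence_rate_target`` recurrence rate.
    """

    rate_bin_ms: float = 5.0
    rate_smooth_sd: float = 2.0
    delay_max_lag: int = 30
    fnn_max_dim: int = 6
    lyapunov_evolve: int = 2
    recurrence_rate_target: float = 0.02
    rqa_max_points: int = 1200
    info_bin_ms: float = 10.0


DEFAULT_SETTINGS = AnalysisSettings()


def rate_series(
    rec: SpikeRecording, cell: str, settings: AnalysisSettings = DEFAULT_SETTINGS
) -> np.ndarray:
    """Smoothed firing-rate series (spikes per bin) of one cell."""
    n = int(round(rec.duration / settings.rate_bin_ms))
    hist, _ = np.histogram(
        rec.spikes[cell].times, bins=n, range=(0.0, rec.duration)
    )
    return gaussian_filter1d(hist.astype(float), settings.rate_smooth_sd)


def nonlinear_cell_measures(
    x: np.ndarray, settings: AnalysisSettings = DEFAULT_SETTINGS
) -> dict:
    """Embedding choice plus the dynamical measures for one scalar series.

    Undefined measures (flat series, degenerate fits) come back as NaN with
    a reason in ``flags``.
    """
    out = {
        "delay": np.nan, "dimension": np.nan, "lyapunov": np.nan,
        "rqa_entropy_bits": np.nan, "determinism": np.nan,
        "correlation_dimension": np.nan, "series_entropy_bits": np.nan,
        "flags": "",
    }
    if np.ptp(x) == 0:
        out["flags"] = "flat-series"
        return out
    out["series_entropy_bits"] = series_entropy(x)
    try:
        delay = select_delay(x, max_lag=settings.delay_max_lag)
        dim, saturated = false_nearest_neighbors(
            x, delay, max_dim=settings.fnn_max_dim
        )
    except ValueError as err:
        out["flags"] = f"embedding-failed:{err}"
        return out
    spec = EmbeddingSpec(delay, dim)
    out["delay"] = delay
    out["dimension"] = dim
    flags = ["fnn-saturated"] if saturated else []
    lam = max_lyapunov_jacobian(x, spec, evolve=settings.lyapunov_evolve)
    if math.isnan(lam):
        flags.append("lyapunov-degenerate")
    out["lyapunov"] = lam
    # recurrence analysis on a bounded subsample
    stride = max(1, int(np.ceil(len(x) / settings.rqa_max_points)))
    xs = x[::stride]
    sub_spec = EmbeddingSpec(max(1, delay // stride), dim)
    try:
        radius = radius_for_rate(xs, sub_spec, settings.recurrence_rate_target)
        rqa = rqa_measures(
            recurrence_matrix(xs, sub_spec, radius),
            theiler=sub_spec.theiler,
        )
        out["rqa_entropy_bits"] = rqa.entropy_bits
        out["determinism"] = rqa.determinism
        flags.extend(rqa.flags)
    except ValueError as err:
        flags.append(f"rqa-failed:{err}")
    out["correlation_dimension"] = correlation_dimension(xs, sub_spec)
    out["flags"] = ";".join(flags)
    return out


def nonlinear_table(
    recordings: Sequence[SpikeRecording],
    cells: Sequence[str] = ALL_PRINCIPAL,
    settings: AnalysisSettings = DEFAULT_SETTINGS,
) -> pd.DataFrame:
    """Tidy per-(run, cell) table of the nonlinear measures."""
    rows = []
    for rec in recordings:
        for cell in cells:
            row = {
                "condition": rec.condition.name,
                "run": rec.run_index,
                "cell": cell,
                "region": CELL_REGION[cell],
            }
            row.update(nonlinear_cell_measures(rate_series(rec, cell, settings),
                                               settings))
            rows.append(row)
    return pd.DataFrame(rows)


def aggregate_nonlinear(rows: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD of each nonlinear measure per condition and region group."""
    measures = ["lyapunov", "rqa_entropy_bits", "determinism",
                "correlation_dimension", "series_entropy_bits"]
    out = []
    for gname, cells in REGION_GROUPS.items():
        sub = rows[rows["cell"].isin(cells)]
        for cond, grp in sub.groupby("condition", sort=False):
            rec = {"condition": cond, "region_group": gname, "n_obs": len(grp)}
            for m in measures:
                rec[f"{m}_mean"] = grp[m].mean()
                rec[f"{m}_sd"] = grp[m].std(ddof=1)
            out.append(rec)
    return pd.DataFrame(out)


def metrics_table(recordings: Sequence[SpikeRecording]) -> pd.DataFrame:
    """Per-(run, cell) burst-metric rows for a batch."""
    return pd.concat(
        [compute_metrics(rec) for rec in recordings], ignore_index=True
    )


def analyze_batch(
    recordings: Sequence[SpikeRecording],
    settings: AnalysisSettings = DEFAULT_SETTINGS,
    with_flow: bool = True,
) -> dict:
    """Full per-condition analysis: metrics, nonlinear measures, info flow."""
    result = {
        "settings": asdict(settings),
        "metrics": metrics_table(recordings),
        "nonlinear": nonlinear_table(recordings, settings=settings),
    }
    result["metrics_summary"] = aggregate_metrics(result["metrics"])
    result["nonlinear_summary"] = aggregate_nonlinear(result["nonlinear"])
    if with_flow:
        result["flow"] = flow_matrices(recordings,
                                       bin_width=settings.info_bin_ms)
    return result
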