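"""Surrogate generators with analytically known ground truth.

Every analysis stage can be tested against these without the simulator:
Poisson and theta-burst spike trains, directionally coupled binary processes
whose transfer entropy is computed by exact enumeration of the joint
distribution, chaotic/periodic scalar maps with known Lyapunov exponents, and
a synthetic five-condition metric table with stated effect sizes for the
statistics stage.  Ground-truth values are returned with the data so that
tests never hard-code constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .info_flow import SymbolSeries
from .protocols import SpikeTrain

__all__ = [
    "gen_poisson_train",
    "gen_coupled_binary",
    "gen_map_series",
    "gen_ad_like_dataset",
    "CoupledBinary",
    "MapSeries",
]


def gen_poisson_train(
    rate: float, duration: float, seed: int = 0, unit_id: str = "poisson"
) -> SpikeTrain:
    """Homogeneous Poisson train; expected count = rate * duration / 1000."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    if rate == 0 or duration <= 0:
        return SpikeTrain(unit_id, np.empty(0), max(duration, 0.0))
    n = rng.poisson(rate * duration / 1000.0)
    times = np.unique(rng.uniform(0.0, duration, size=n))
    return SpikeTrain(unit_id, times, duration)


@dataclass(frozen=True)
class CoupledBinary:
    source: SymbolSeries
    target: SymbolSeries
    coupling: float
    lag: int
    analytic_te_bits: float
    analytic_mi_bits: float
    #: per-sample SD of the pointwise log-likelihood ratio; the sampling SE
    #: of the plug-in TE estimate is ~ this / sqrt(n)
    te_pointwise_sd: float


def _exact_te_from_joint(joint: np.ndarray) -> tuple[float, float]:
    """TE(x->y) with k=l=1 and the pointwise log-ratio SD, from the exact
    joint p(x_t, y_t, y_{t+1})."""
    p = joint / joint.sum()
    te = second = 0.0
    p_y = p.sum(axis=0)          # p(y_t, y_next)
    p_yhist = p_y.sum(axis=1)    # p(y_t)
    p_xy = p.sum(axis=2)         # p(x_t, y_t)
    for x in range(2):
        for y in range(2):
            for yn in range(2):
                pj = p[x, y, yn]
                if pj == 0:
                    continue
                cond_full = pj / p_xy[x, y]
                cond_hist = p_y[y, yn] / p_yhist[y]
                term = np.log2(cond_full / cond_hist)
                te += pj * term
                second += pj * term**2
    return float(te), float(np.sqrt(max(second - te**2, 0.0)))


def gen_coupled_binary(
    n: int, coupling: float, lag: int = 1, seed: int = 0
) -> CoupledBinary:
    """Driver-follower binary pair with exactly known TE and MI.

    The source is an i.i.d. fair coin; ``lag`` steps later the target copies
    it with probability ``coupling`` and otherwise draws a fresh fair coin.
    The analytic TE/MI are computed by enumerating the exact joint
    distribution of ``(x_t, y_t, y_{t+lag})`` (no closed-form constants are
    hard-coded).
    """
    if not 0 <= coupling <= 1:
        raise ValueError("coupling must be in [0, 1]")
    if lag < 1 or n <= lag:
        raise ValueError("need lag >= 1 and n > lag")
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=n)
    y = np.empty(n, dtype=np.int64)
    y[:lag] = rng.integers(0, 2, size=lag)
    copy = rng.random(n - lag) < coupling
    noise = rng.integers(0, 2, size=n - lag)
    y[lag:] = np.where(copy, x[:-lag], noise)

    # exact joint p(x_t, y_t, y_{t+1}) for lag=1 dynamics: y_t independent of
    # x_t, y_{t+1} = x_t w.p. c else fair.
    c = coupling
    joint = np.zeros((2, 2, 2))
    for xv in range(2):
        for yv in range(2):
            for ynv in range(2):
                p_yn = c * (1.0 if ynv == xv else 0.0) + (1 - c) * 0.5
                joint[xv, yv, ynv] = 0.25 * p_yn
    te, te_sd = _exact_te_from_joint(joint)
    # MI(x_t; y_{t+lag}) from the exact pair marginal
    pair = joint.sum(axis=1)
    mi = 0.0
    for xv in range(2):
        for ynv in range(2):
            pj = pair[xv, ynv]
            if pj > 0:
                mi += pj * np.log2(pj / (pair[xv].sum() * pair[:, ynv].sum()))
    return CoupledBinary(
        SymbolSeries("driver", x, 1.0),
        SymbolSeries("follower", y, 1.0),
        coupling,
        lag,
        te,
        float(mi),
        te_sd,
    )


@dataclass(frozen=True)
class MapSeries:
    series: np.ndarray
    kind: str
    lyapunov_true: float
    d2_true: float


def gen_map_series(
    kind: str,
    n: int,
    seed: int = 0,
    r: float = 4.0,
    period: float = 19.7,
    burn_in: int = 100,
) -> MapSeries:
    """Scalar series with known dynamical invariants.

    ``logistic``: x <- r x (1 - x).  The true Lyapunov exponent is computed
    as the average log derivative along the generated orbit (Jacobian
    product), not assumed.  ``sine``: a periodic signal, lambda <= 0, D2 ~ 1;
    the default period is incommensurate with the unit sampling grid so the
    orbit fills its closed curve densely instead of revisiting a handful of
    exact duplicate points.
    """
    if n < 1000:
        raise ValueError("need n >= 1000")
    rng = np.random.default_rng(seed)
    if kind == "logistic":
        if not 0 < r <= 4:
            raise ValueError(f"logistic parameter r={r} diverges outside (0, 4]")
        x = rng.uniform(0.05, 0.95)
        out = np.empty(n + burn_in)
        for i in range(n + burn_in):
            x = r * x * (1.0 - x)
            out[i] = x
        series = out[burn_in:]
        with np.errstate(divide="ignore"):
            lyap = float(np.mean(np.log(np.abs(r * (1.0 - 2.0 * series)))))
        return MapSeries(series, kind, lyap, 1.0)
    if kind == "sine":
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n)
        series = np.sin(2 * np.pi * t / period + phase)
        return MapSeries(series, kind, 0.0, 1.0)
    raise ValueError(f"unknown map kind {kind!r}")


def gen_ad_like_dataset(
    group_means: Mapping[str, float],
    group_sds: Mapping[str, float],
    n_per_group: int = 30,
    metric: str = "n_spikes",
    region: str = "DG-CA3-CA1",
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian per-group metric rows emulating a five-condition comparison."""
    if set(group_means) != set(group_sds):
        raise ValueError("group_means and group_sds must share keys")
    rng = np.random.default_rng(seed)
    rows = []
    for cond in group_means:
        vals = rng.normal(group_means[cond], group_sds[cond], size=n_per_group)
        for i, v in enumerate(vals):
            rows.append(
                {"condition": cond, "run": i, "cell": "synthetic",
                 "region": region, metric: v}
            )
    return pd.DataFrame(rows)
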