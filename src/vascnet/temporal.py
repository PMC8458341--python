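"""Time-course analysis of per-frame network metrics.

Replicate assays (one metric time series per video) are aggregated to
mean ± SEM per time point; metric trends over the 48 h assay are
summarised by an exponential fit y(t) = a·exp(b·t) (unweighted nonlinear
least squares, initialised from the log-linear regression).  Circular
layouts place vertices uniformly on the unit circle for chord plots of
network growth.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .graph import VascularGraph
from .metrics import NetworkMetrics, compute_metrics

__all__ = [
    "MetricTimeSeries",
    "TrendFit",
    "aggregate_replicates",
    "fit_exponential",
    "build_series",
    "circular_layout",
]

METRIC_COLUMNS = [
    "n_vertices", "n_edges", "mean_clustering", "char_path_length", "sigma",
    "c_random", "l_random", "mean_edge_length", "mean_edge_thickness",
    "lcc_fraction",
]


@dataclasses.dataclass
class MetricTimeSeries:
    """Per-replicate sequence of NetworkMetrics over time."""

    replicate_id: str
    times: Sequence[float]
    metrics: Sequence[NetworkMetrics]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.metrics):
            raise ValueError("times and metrics must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, m in zip(self.times, self.metrics):
            row = {"replicate_id": self.replicate_id, "time_h": t}
            row.update({c: getattr(m, c) for c in METRIC_COLUMNS})
            rows.append(row)
        return pd.DataFrame(rows)


@dataclasses.dataclass
class TrendFit:
    """Exponential trend y(t) = a·exp(b·t) for one metric."""

    metric_name: str
    a: float
    b: float  # per hour
    rss: float
    n_points: int
    degenerate: bool = False

    def predict(self, t) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(t, dtype=float))


def aggregate_replicates(series_list: Sequence[MetricTimeSeries],
                         metric_name: str) -> pd.DataFrame:
    """Per-time-point mean and SEM (sd/√r) of one metric over replicates.

    All series must share a common time grid.  Undefined (NaN) values are
    excluded pairwise; a single defined replicate reports SEM 0 (with a
    warning); no defined replicate at a time point reports NaN.
    """
    if not series_list:
        raise ValueError("need at least one replicate series")
    if metric_name not in METRIC_COLUMNS:
        raise KeyError(f"unknown metric {metric_name!r}")
    times = series_list[0].times
    for s in series_list[1:]:
        if len(s.times) != len(times) or not np.allclose(s.times, times):
            raise ValueError("replicates must share a common time grid")

    values = np.array([[getattr(m, metric_name) for m in s.metrics]
                       for s in series_list], dtype=float)
    out = []
    warned = False
    for j, t in enumerate(times):
        col = values[:, j]
        defined = col[np.isfinite(col)]
        r = len(defined)
        if r == 0:
            out.append((t, float("nan"), float("nan"), 0))
            continue
        mean = float(defined.mean())
        if r == 1:
            if not warned:
                warnings.warn("single defined replicate: SEM reported as 0",
                              stacklevel=2)
                warned = True
            sem = 0.0
        else:
            sem = float(defined.std(ddof=1) / math.sqrt(r))
        out.append((t, mean, sem, r))
    return pd.DataFrame(out, columns=["time_h", "mean", "sem", "n"])


def fit_exponential(times, values, metric_name: str = "") -> TrendFit:
    """Least-squares fit of y = a·exp(b·t).

    Initialised from the log-linear regression when all values are
    positive, otherwise from (mean, 0).  Constant series are flagged
    degenerate with b = 0 and a = the constant.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(t) < 3:
        raise ValueError("need at least 3 finite points to fit")
    if np.ptp(y) < 1e-12:
        return TrendFit(metric_name, a=float(y.mean()), b=0.0, rss=0.0,
                        n_points=len(t), degenerate=True)
    if (y > 0).all():
        slope, intercept = np.polyfit(t, np.log(y), 1)
        p0 = (float(np.exp(intercept)), float(slope))
    else:
        p0 = (float(np.mean(np.abs(y))) or 1.0, 0.0)
    popt, _ = curve_fit(lambda tt, a, b: a * np.exp(b * tt), t, y, p0=p0,
                        maxfev=20000)
    resid = y - popt[0] * np.exp(popt[1] * t)
    return TrendFit(metric_name, a=float(popt[0]), b=float(popt[1]),
                    rss=float(np.dot(resid, resid)), n_points=len(t))


def build_series(entries, *, replicate_id: str = "rep0", n_random: int = 20,
                 seed: int = 0) -> MetricTimeSeries:
    """Assemble a MetricTimeSeries from per-frame graphs.

    ``entries`` is a sequence of ``(time_h, VascularGraph)`` pairs or of
    ``(time_h, path-to-GraphML)`` pairs; frames are sorted by time and
    each frame's random-ensemble seed is derived from ``seed`` and the
    frame's position in time order, so input order does not matter.
    """
    loaded = []
    for t, item in entries:
        if isinstance(item, VascularGraph):
            loaded.append((float(t), item))
        else:
            try:
                loaded.append((float(t), VascularGraph.from_graphml(item)))
            except FileNotFoundError as exc:
                raise FileNotFoundError(
                    f"missing graph file for frame at t={t} h: {item}") from exc
    loaded.sort(key=lambda p: p[0])
    frame_seeds = np.random.SeedSequence(seed).generate_state(
        max(len(loaded), 1)) % (2 ** 31)
    times = [t for t, _ in loaded]
    mets = [compute_metrics(g, n_random=n_random, seed=int(frame_seeds[i]))
            for i, (_, g) in enumerate(loaded)]
    return MetricTimeSeries(replicate_id=replicate_id, times=times, metrics=mets)


def circular_layout(graph):
    """Place vertices uniformly on the unit circle ordered by vertex id.

    Returns ``(positions, chords)`` where positions maps vertex id ->
    (x, y) and chords is a list of ``(u, v, length)`` tuples (length NaN
    for abstract graphs), suitable for colour-mapped chord plots.
    """
    g = graph.g if isinstance(graph, VascularGraph) else graph
    nodes = sorted(g.nodes)
    if not nodes:
        raise ValueError("need at least one vertex")
    n = len(nodes)
    positions = {v: (math.cos(2 * math.pi * i / n), math.sin(2 * math.pi * i / n))
                 for i, v in enumerate(nodes)}
    chords = [(u, v, float(d.get("length", float("nan"))))
              for u, v, d in g.edges(data=True)]
    return positions, chords
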