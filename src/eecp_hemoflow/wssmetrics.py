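"""Wall-shear-derived hemodynamic indices and study-style summaries.

Per wall point, from the WSS vector time series tau(t) over one cardiac
cycle T:

    AWSS  = (1/T) int_0^T |tau| dt                  (Pa)
    OSI   = 1/2 (1 - |int_0^T tau dt| / int_0^T |tau| dt)
    WSSG  = |grad |tau||  in the wall tangent plane  (Pa/m)
    AWSSG = (1/T) int_0^T WSSG dt
    RRT   = 1 / ((1 - 2 OSI) * AWSS)                (1/Pa)

OSI lies in [0, 1/2] by the triangle inequality: 0 for unidirectional
shear, 1/2 for zero-mean fully reversing shear.  Time quadrature is the
composite trapezoid with periodic closure, which on uniform samples of a
periodic function reduces to the sample mean.  The spatial gradient uses
exact per-triangle linear (P1) reconstruction on surface meshes — so
linear fields on flat walls are differentiated exactly — or central
differences on structured wall polylines.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .flow import WallShearField
from .mesh import SurfaceMesh

__all__ = [
    "MetricField",
    "awss",
    "osi",
    "wssg_instant",
    "awssg",
    "rrt",
    "compute_metric_field",
    "summarize",
    "comparison_report",
    "percent_change",
    "mesh_independence",
]


def _check_uniform(t: np.ndarray, period: float) -> float:
    dt = np.diff(t)
    if len(t) < 2 or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise ValueError("time samples must be uniform over one period")
    if not np.isclose(t[0], 0.0) or not np.isclose(t[-1] + dt[0], period, rtol=1e-6):
        raise ValueError("samples must span exactly one period, starting at t=0")
    return float(dt[0])


def _cycle_mean(values: np.ndarray, t: np.ndarray, period: float) -> np.ndarray:
    """(1/T) int_0^T f dt by periodic trapezoid = sample mean on uniform grids."""
    _check_uniform(t, period)
    return values.mean(axis=-1)


def awss(series: WallShearField) -> np.ndarray:
    """Time-averaged WSS magnitude per wall point (Pa)."""
    return _cycle_mean(series.magnitudes(), series.t, series.period)


def osi(series: WallShearField, zero_flag: float = 1e-300) -> tuple[np.ndarray, np.ndarray]:
    """Oscillatory shear index per point, with a data-quality flag.

    Returns ``(osi, flagged)``; identically zero series get OSI = 0 (no
    flow, no oscillation) and ``flagged=True``.
    """
    _check_uniform(series.t, series.period)
    mean_vec = series.tau.mean(axis=1)  # (n_pts, 3)
    num = np.linalg.norm(mean_vec, axis=1)
    den = series.magnitudes().mean(axis=1)
    flagged = den <= zero_flag
    out = np.zeros(series.n_points)
    ok = ~flagged
    out[ok] = 0.5 * (1.0 - num[ok] / den[ok])
    return np.clip(out, 0.0, 0.5), flagged


def _triangle_gradients(mesh: SurfaceMesh, values: np.ndarray) -> np.ndarray:
    """Per-face |grad f| via the P1 metric-tensor formula (frame free)."""
    tri = mesh.faces
    p0, p1, p2 = (mesh.vertices[tri[:, k]] for k in range(3))
    e1, e2 = p1 - p0, p2 - p0
    df1 = values[tri[:, 1]] - values[tri[:, 0]]
    df2 = values[tri[:, 2]] - values[tri[:, 0]]
    g11 = np.einsum("ij,ij->i", e1, e1)
    g12 = np.einsum("ij,ij->i", e1, e2)
    g22 = np.einsum("ij,ij->i", e2, e2)
    det = g11 * g22 - g12**2
    bad = det <= 1e-300
    det = np.where(bad, 1.0, det)
    a = (g22 * df1 - g12 * df2) / det
    b = (g11 * df2 - g12 * df1) / det
    grad = a[:, None] * e1 + b[:, None] * e2
    mag = np.linalg.norm(grad, axis=1)
    mag[bad] = 0.0
    return mag


def wssg_instant(values: np.ndarray, geometry) -> np.ndarray:
    """Spatial WSS gradient magnitude per point at one instant (Pa/m).

    ``geometry`` is a :class:`SurfaceMesh` (tangent-plane P1 gradient,
    area-weighted onto vertices) or an (n, 3) array of ordered polyline
    points on a structured wall line (central differences in arclength).
    """
    values = np.asarray(values, dtype=float)
    if isinstance(geometry, SurfaceMesh):
        if len(values) != len(geometry.vertices):
            raise ValueError("one value per mesh vertex required")
        face_mag = _triangle_gradients(geometry, values)
        areas = geometry.as_trimesh().area_faces
        num = np.zeros(len(values))
        den = np.zeros(len(values))
        for k in range(3):
            np.add.at(num, geometry.faces[:, k], face_mag * areas)
            np.add.at(den, geometry.faces[:, k], areas)
        if np.any(den == 0):
            raise ValueError("mesh contains isolated points (no incident faces)")
        return num / den
    pts = np.asarray(geometry, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points for a gradient on a wall line")
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    if np.any(np.diff(s) <= 0):
        raise ValueError("wall line contains coincident (isolated) points")
    return np.abs(np.gradient(values, s))


def awssg(series: WallShearField, geometry) -> np.ndarray:
    """Cycle-averaged WSSG per point (Pa/m)."""
    mags = series.magnitudes()  # (n_pts, n_t)
    _check_uniform(series.t, series.period)
    inst = np.stack(
        [wssg_instant(mags[:, k], geometry) for k in range(mags.shape[1])], axis=1
    )
    return inst.mean(axis=1)


def rrt(osi_value, awss_value) -> np.ndarray:
    """Relative residence time surrogate 1/((1-2 OSI) AWSS).

    Singular points (OSI -> 1/2 or AWSS -> 0) are flagged as +inf, never
    NaN.
    """
    o = np.atleast_1d(np.asarray(osi_value, dtype=float))
    a = np.atleast_1d(np.asarray(awss_value, dtype=float))
    denom = (1.0 - 2.0 * o) * a
    out = np.full(np.broadcast(o, a).shape, np.inf)
    ok = denom > 1e-12
    out[ok] = 1.0 / denom[ok]
    return out if np.ndim(osi_value) or np.ndim(awss_value) else float(out[0])


@dataclass
class MetricField:
    """Per-wall-point index fields for one flow state."""

    awss: np.ndarray
    osi: np.ndarray
    rrt: np.ndarray
    awssg: np.ndarray | None = None
    osi_flagged: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.awss < 0):
            raise ValueError("AWSS must be non-negative")
        if np.any((self.osi < 0) | (self.osi > 0.5)):
            raise ValueError("OSI must lie in [0, 0.5]")


def compute_metric_field(series: WallShearField, geometry=None) -> MetricField:
    """All indices from a wall shear series (AWSSG only when geometry given)."""
    a = awss(series)
    o, flagged = osi(series)
    g = awssg(series, geometry) if geometry is not None else None
    return MetricField(awss=a, osi=o, rrt=rrt(o, a), awssg=g, osi_flagged=flagged)


def summarize(
    metric: MetricField, area_weights: np.ndarray | None = None
) -> pd.DataFrame:
    """Max/min/mean table over wall points, one column per index.

    ``area_weights`` switches the mean from the unweighted point mean to
    an area-weighted mean.  Flagged-infinite RRT points are excluded from
    the RRT statistics.
    """
    cols = {"AWSS (Pa)": metric.awss, "OSI": metric.osi}
    if metric.awssg is not None:
        cols["AWSSG (Pa/m)"] = metric.awssg
    finite = np.isfinite(metric.rrt)
    cols["RRT (1/Pa)"] = metric.rrt[finite]
    if len(cols["RRT (1/Pa)"]) == 0:
        raise ValueError("all RRT values are singular")
    rows = {}
    for name, arr in cols.items():
        if area_weights is not None and name != "RRT (1/Pa)":
            mean = float(np.average(arr, weights=area_weights))
        else:
            w = area_weights[finite] if (area_weights is not None) else None
            mean = float(np.average(arr, weights=w)) if name == "RRT (1/Pa)" else float(
                arr.mean()
            )
        rows[name] = {"Max": float(arr.max()), "Min": float(arr.min()), "Mean": mean}
    return pd.DataFrame(rows).loc[["Max", "Min", "Mean"]]


def percent_change(pre: float, during: float) -> float:
    """(during - pre)/pre * 100, rounded half-up to one decimal."""
    if pre == 0:
        raise ValueError("percent change undefined for a zero reference value")
    raw = (during - pre) / pre * 100.0
    return float(Decimal(repr(raw)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def comparison_report(pre: pd.DataFrame, during: pd.DataFrame) -> pd.DataFrame:
    """Pre/during summary tables merged with percent changes per statistic."""
    rows = []
    for col in pre.columns:
        if col not in during.columns:
            continue
        for stat in pre.index:
            a, b = float(pre.loc[stat, col]), float(during.loc[stat, col])
            rows.append(
                {
                    "metric": col,
                    "statistic": stat,
                    "pre": a,
                    "during": b,
                    "percent_change": percent_change(a, b) if a != 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def mesh_independence(
    results: list[tuple[int, float]], threshold: float = 0.01
) -> tuple[pd.DataFrame, bool]:
    """Grid-convergence table from (mesh_size, mean AWSS) pairs.

    Returns the table of successive and cumulative relative changes and a
    verdict: mesh-independent when the final successive change is below
    ``threshold`` (default 1%).
    """
    if len(results) < 2:
        raise ValueError("need at least two mesh results")
    sizes = [s for s, _ in results]
    if len(set(sizes)) != len(sizes):
        raise ValueError("duplicate mesh sizes")
    if sizes != sorted(sizes):
        raise ValueError("results must be sorted by mesh size")
    vals = np.array([v for _, v in results], dtype=float)
    succ = np.abs(np.diff(vals)) / np.abs(vals[:-1])
    cum = np.abs(vals - vals[0]) / np.abs(vals[0])
    df = pd.DataFrame(
        {
            "mesh_size": sizes,
            "mean_awss": vals,
            "successive_change": np.concatenate([[np.nan], succ]),
            "cumulative_change": cum,
        }
    )
    return df, bool(succ[-1] < threshold)
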