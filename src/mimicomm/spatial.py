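"""End-point spatial statistics for cell-mimic communities.

The central quantity is the *local density* n/A of a population around a
receiver: the number of mimics of that population whose centres lie within
radius r of the receiver centre, divided by the circle area pi*(r/1000)^2
in mm^2.  Receiver activation is then related to neighbourhood composition
by per-sample Pearson correlations, averaged across samples, scanned over a
grid of radii to locate the most informative spatial scale; fold changes
relative to sender-free controls feed a LOESS-smoothed response surface
over the (trigger density, STAR density) plane.

Samples are pandas DataFrames in the package's mimic-record schema
(``mimic_id, x_mm, y_mm, diameter_um, label, load, t0, t15, ...``); the
last ``t`` column is the end point unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DensityRecord",
    "CorrelationScan",
    "DEFAULT_RADIUS_GRID",
    "local_density",
    "density_table",
    "pearson",
    "radius_scan",
    "fold_change",
    "loess_surface",
    "positional_independence",
    "timepoint_columns",
    "endpoint_column",
]

#: default neighbourhood radius grid in um
DEFAULT_RADIUS_GRID = np.arange(200.0, 1201.0, 100.0)

#: minimum receivers for a sample to enter averaged correlations
MIN_RECEIVERS = 5


def timepoint_columns(df: pd.DataFrame) -> list[str]:
    """Columns holding intensity frames, ordered by time (``t0, t15, ...``)."""
    cols = [c for c in df.columns if c.startswith("t") and c[1:].isdigit()]
    return sorted(cols, key=lambda c: int(c[1:]))


def endpoint_column(df: pd.DataFrame) -> str:
    cols = timepoint_columns(df)
    if not cols:
        raise ValueError("no timepoint columns (t<min>) found")
    return cols[-1]


@dataclass
class DensityRecord:
    """Local neighbourhood composition around one receiver."""

    receiver_id: int
    radius_um: float
    counts: dict  # population -> n
    area_mm2: float
    densities: dict  # population -> n / A (mm^-2)


def _positions(df: pd.DataFrame) -> np.ndarray:
    return df[["x_mm", "y_mm"]].to_numpy(dtype=float)


def local_density(
    receiver: pd.Series | Sequence[float],
    all_records: pd.DataFrame,
    r: float,
    population: str,
) -> float:
    """Local density (mm^-2) of ``population`` within radius ``r`` um.

    Counts members whose centre lies within Euclidean distance r of the
    receiver centre; the receiver itself is excluded when counting
    receivers.  No edge correction: the area is always pi*(r/1000)^2,
    matching the plain n/A definition.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    if isinstance(receiver, pd.Series):
        cx, cy = float(receiver["x_mm"]), float(receiver["y_mm"])
        rid = receiver.get("mimic_id", None)
    else:
        cx, cy = float(receiver[0]), float(receiver[1])
        rid = None
    members = all_records[all_records["label"] == population]
    if rid is not None and population == "receiver":
        members = members[members["mimic_id"] != rid]
    p = _positions(members)
    r_mm = r / 1000.0
    n = int(np.sum((p[:, 0] - cx) ** 2 + (p[:, 1] - cy) ** 2 <= r_mm**2)) if len(p) else 0
    area = np.pi * r_mm**2
    return n / area


def density_table(
    sample: pd.DataFrame,
    r: float,
    populations: Sequence[str] = ("star_sender", "trigger_sender", "receiver"),
    edge_correction: bool = False,
    droplet_radius: float | None = None,
) -> pd.DataFrame:
    """Vectorised local densities around every receiver of a sample.

    Returns one row per receiver with columns ``density_<population>``.
    With ``edge_correction=True`` the area is the intersection of the
    neighbourhood circle with the droplet (requires ``droplet_radius`` in
    mm); off by default, matching the plain n/A convention.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    recv = sample[sample["label"] == "receiver"]
    out = recv[["mimic_id", "x_mm", "y_mm"]].copy().reset_index(drop=True)
    r_mm = r / 1000.0
    rp = _positions(recv)
    area = np.full(len(recv), np.pi * r_mm**2)
    if edge_correction:
        if droplet_radius is None:
            raise ValueError("edge correction requires droplet_radius")
        area = _disc_intersection_area(
            np.sqrt((rp**2).sum(axis=1)), r_mm, droplet_radius
        )
    for pop in populations:
        members = sample[sample["label"] == pop]
        mp = _positions(members)
        if len(mp) == 0:
            n = np.zeros(len(recv))
        else:
            d2 = ((rp[:, None, :] - mp[None, :, :]) ** 2).sum(axis=-1)
            n = (d2 <= r_mm**2).sum(axis=1).astype(float)
            if pop == "receiver":
                n -= 1.0  # the receiver itself always matches
        out[f"density_{pop}"] = n / area
    return out


def _disc_intersection_area(d: np.ndarray, r: float, R: float) -> np.ndarray:
    """Area of intersection of a circle radius r centred d from the origin
    with the droplet disc of radius R (standard lens formula)."""
    d = np.asarray(d, dtype=float)
    full = np.pi * r**2
    out = np.where(d + r <= R, full, 0.0)
    mask = (d + r > R) & (d < r + R)
    dm = d[mask]
    a1 = r**2 * np.arccos(np.clip((dm**2 + r**2 - R**2) / (2 * dm * r), -1, 1))
    a2 = R**2 * np.arccos(np.clip((dm**2 + R**2 - r**2) / (2 * dm * R), -1, 1))
    a3 = 0.5 * np.sqrt(
        np.maximum((-dm + r + R) * (dm + r - R) * (dm - r + R) * (dm + r + R), 0.0)
    )
    out[mask] = a1 + a2 - a3
    return out


def pearson(x, y) -> float:
    """Product-moment correlation; NaN flags degenerate (zero-variance) input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt((xd**2).sum())
    sy = np.sqrt((yd**2).sum())
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float((xd * yd).sum() / (sx * sy))


@dataclass
class CorrelationScan:
    """Sample-averaged correlation between activation and local density vs radius."""

    radii: np.ndarray  # um
    per_sample: dict  # population -> (n_samples, n_radii) array (NaN where excluded)
    mean_r: dict  # population -> (n_radii,) mean over valid samples
    argmax_um: dict  # population -> radius of max mean r
    joint_argmax_um: float  # argmax of mean of STAR- and trigger-density rows

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"radius_um": self.radii})
        for pop, v in self.mean_r.items():
            df[f"mean_r_{pop}"] = v
        return df


def radius_scan(
    samples: Iterable[pd.DataFrame],
    radii: np.ndarray = DEFAULT_RADIUS_GRID,
    populations: Sequence[str] = ("star_sender", "trigger_sender", "receiver"),
    value_column: str | None = None,
    min_receivers: int = MIN_RECEIVERS,
) -> CorrelationScan:
    """Scan neighbourhood radii for the scale most correlated with activation.

    For every sample and radius, computes the Pearson r between each
    receiver's end point intensity and its local density of each population,
    then averages r across samples.  A sample enters the average for a
    population only if it has at least ``min_receivers`` receivers, at least
    one member of that population, and non-degenerate variance on both
    sides.  The joint argmax is taken on the mean of the STAR- and
    trigger-sender curves (the radius most informative about sender
    neighbourhoods overall).
    """
    samples = list(samples)
    radii = np.asarray(radii, dtype=float)
    if not samples:
        raise ValueError("need at least one sample")
    per = {pop: np.full((len(samples), len(radii)), np.nan) for pop in populations}
    for si, sample in enumerate(samples):
        recv = sample[sample["label"] == "receiver"]
        if len(recv) < min_receivers:
            continue
        col = value_column or endpoint_column(sample)
        vals = recv[col].to_numpy(dtype=float)
        for ri, r in enumerate(radii):
            dens = density_table(sample, r, populations)
            for pop in populations:
                if (sample["label"] == pop).sum() < (2 if pop == "receiver" else 1):
                    continue
                d = dens[f"density_{pop}"].to_numpy()
                if np.std(d) == 0 or np.std(vals) == 0:
                    continue
                per[pop][si, ri] = pearson(vals, d)
    mean_r = {}
    argmax = {}
    for pop in populations:
        with np.errstate(invalid="ignore"):
            m = np.nanmean(per[pop], axis=0)
        mean_r[pop] = m
        argmax[pop] = float(radii[np.nanargmax(m)]) if np.any(np.isfinite(m)) else float("nan")
    if all(np.all(np.isnan(per[pop])) for pop in populations):
        raise ValueError("all samples degenerate; no correlations computable")
    sender_pops = [p for p in ("star_sender", "trigger_sender") if p in mean_r]
    joint = np.nanmean(np.vstack([mean_r[p] for p in sender_pops]), axis=0)
    joint_argmax = float(radii[np.nanargmax(joint)])
    return CorrelationScan(radii, per, mean_r, argmax, joint_argmax)


def fold_change(
    receiver_intensities,
    baseline_samples: Iterable[pd.DataFrame],
    value_column: str | None = None,
) -> np.ndarray:
    """Fold activation relative to sender-free controls.

    Each intensity is divided by the mean end point receiver intensity
    pooled over all baseline (no-sender) samples.
    """
    baseline_samples = list(baseline_samples)
    pooled = []
    for s in baseline_samples:
        recv = s[s["label"] == "receiver"]
        col = value_column or endpoint_column(s)
        pooled.append(recv[col].to_numpy(dtype=float))
    if not pooled or sum(len(p) for p in pooled) == 0:
        raise ValueError("baseline set is empty")
    base = float(np.concatenate(pooled).mean())
    if base == 0.0:
        raise ValueError("baseline mean intensity is zero")
    return np.asarray(receiver_intensities, dtype=float) / base


def loess_surface(
    star_density,
    trigger_density,
    fold,
    grid: int | tuple = 25,
    span: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """LOESS-smoothed fold-change surface over the density plane.

    Locally linear regression with tricube weights: for each grid node the
    ``span`` fraction of nearest data points (in standardised density
    coordinates) is fitted by weighted least squares and the fit evaluated
    at the node.

    Returns ``(star_grid, trigger_grid, surface)`` with surface shape
    (len(trigger_grid), len(star_grid)) -- trigger on rows, STAR on columns.
    """
    S = np.asarray(star_density, dtype=float)
    T = np.asarray(trigger_density, dtype=float)
    z = np.asarray(fold, dtype=float)
    if not (len(S) == len(T) == len(z)):
        raise ValueError("inputs must have equal length")
    if len(S) < 30:
        raise ValueError("need at least 30 points for a stable surface")
    if not (0.0 < span <= 1.0):
        raise ValueError("span must be in (0, 1]")
    X = np.column_stack([S, T])
    scale = X.std(axis=0)
    if np.any(scale == 0):
        raise ValueError("degenerate (collinear/constant) density inputs")
    Xs = X / scale
    if isinstance(grid, int):
        sg = np.linspace(S.min(), S.max(), grid)
        tg = np.linspace(T.min(), T.max(), grid)
    else:
        sg, tg = (np.asarray(g, dtype=float) for g in grid)
    k = max(int(np.ceil(span * len(z))), 8)
    surface = np.empty((len(tg), len(sg)))
    for i, tv in enumerate(tg):
        for j, sv in enumerate(sg):
            q = np.array([sv, tv]) / scale
            d = np.sqrt(((Xs - q) ** 2).sum(axis=1))
            idx = np.argpartition(d, k - 1)[:k]
            dmax = d[idx].max()
            if dmax == 0:
                surface[i, j] = z[idx].mean()
                continue
            w = (1.0 - (d[idx] / dmax) ** 3) ** 3
            A = np.column_stack([np.ones(k), Xs[idx]])
            W = w[:, None]
            beta, *_ = np.linalg.lstsq(A * W, z[idx] * w, rcond=None)
            surface[i, j] = beta[0] + beta[1] * q[0] + beta[2] * q[1]
    return sg, tg, surface


def positional_independence(
    sample: pd.DataFrame, value_column: str | None = None
) -> tuple[float, float]:
    """Pearson r of receiver end point intensity vs x and vs y coordinate.

    A null check: with no positional covariate in the experiment, both
    should be small.  Returns ``(r_x, r_y)``; NaN flags degenerate variance.
    """
    recv = sample[sample["label"] == "receiver"]
    if len(recv) < 10:
        raise ValueError("need at least 10 receivers")
    col = value_column or endpoint_column(sample)
    v = recv[col].to_numpy(dtype=float)
    return (
        pearson(recv["x_mm"].to_numpy(dtype=float), v),
        pearson(recv["y_mm"].to_numpy(dtype=float), v),
    )
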