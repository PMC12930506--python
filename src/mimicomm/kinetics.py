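"""Time-lapse analysis: correlation kinetics, activation onsets, kymographs.

Operates on the same mimic-record DataFrames as :mod:`mimicomm.spatial`,
using every ``t<min>`` column rather than only the end point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .spatial import density_table, pearson, timepoint_columns

__all__ = [
    "Kymograph",
    "correlation_timecourse",
    "activation_onset",
    "kymograph",
]


def _common_timepoints(samples: Sequence[pd.DataFrame]) -> list[str]:
    cols = set(timepoint_columns(samples[0]))
    for s in samples[1:]:
        cols &= set(timepoint_columns(s))
    if not cols:
        raise ValueError("samples share no timepoint columns")
    out = sorted(cols, key=lambda c: int(c[1:]))
    if any(len(timepoint_columns(s)) != len(out) for s in samples):
        warnings.warn("samples have unequal timepoints; aligned by intersection")
    return out


def correlation_timecourse(
    timelapse_samples: Iterable[pd.DataFrame],
    r_fixed: float = 600.0,
    populations: Sequence[str] = ("star_sender", "trigger_sender", "receiver"),
    min_receivers: int = 5,
) -> pd.DataFrame:
    """Mean Pearson r between receiver intensity and local density over time.

    For each sample and frame, correlates every receiver's intensity with
    its local density of each population at the fixed radius ``r_fixed``
    (um, default 600), then averages r across samples.  Returns a tidy
    DataFrame with columns ``time_min`` and ``mean_r_<population>``.
    """
    samples = list(timelapse_samples)
    if not samples:
        raise ValueError("need at least one sample")
    cols = _common_timepoints(samples)
    times = np.array([int(c[1:]) for c in cols], dtype=float)
    acc = {pop: np.full((len(samples), len(cols)), np.nan) for pop in populations}
    for si, sample in enumerate(samples):
        recv = sample[sample["label"] == "receiver"]
        if len(recv) < min_receivers:
            continue
        dens = density_table(sample, r_fixed, populations)
        for ti, col in enumerate(cols):
            vals = recv[col].to_numpy(dtype=float)
            if np.std(vals) == 0:
                continue
            for pop in populations:
                d = dens[f"density_{pop}"].to_numpy()
                if np.std(d) == 0:
                    continue
                acc[pop][si, ti] = pearson(vals, d)
    out = pd.DataFrame({"time_min": times})
    for pop in populations:
        with np.errstate(invalid="ignore"):
            out[f"mean_r_{pop}"] = np.nanmean(acc[pop], axis=0)
    return out


def activation_onset(
    trace,
    threshold_fraction: float = 0.25,
    timepoints=None,
    n_baseline: int = 2,
) -> float | None:
    """Time at which a trace first exceeds a fraction of its final rise.

    The baseline is the mean of the first ``n_baseline`` frames; the onset
    is the first time the baseline-subtracted trace crosses
    ``threshold_fraction`` of its final (baseline-subtracted) value,
    linearly interpolated between frames.  Returns ``None`` for traces that
    never rise above baseline.  Affine-equivariant: rescaling or shifting
    intensities leaves the onset unchanged.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must be in (0, 1)")
    y = np.asarray(trace, dtype=float)
    t = (
        np.asarray(timepoints, dtype=float)
        if timepoints is not None
        else np.arange(len(y), dtype=float)
    )
    if len(y) != len(t):
        raise ValueError("trace and timepoints must align")
    base = y[: max(1, n_baseline)].mean()
    final = y[-1] - base
    if final <= 0:
        return None
    level = base + threshold_fraction * final
    above = y >= level
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    # linear interpolation between frames i-1 and i
    f = (level - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + f * (t[i] - t[i - 1]))


@dataclass
class Kymograph:
    """Distance x time intensity matrix for radial propagation analysis."""

    distances_mm: np.ndarray  # (n_rows,) distance of each row from the centre
    timepoints_min: np.ndarray  # (n_t,)
    intensity: np.ndarray  # (n_rows, n_t)

    def __post_init__(self) -> None:
        if self.intensity.shape != (len(self.distances_mm), len(self.timepoints_min)):
            raise ValueError("matrix shape must match axes")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.intensity,
            columns=[f"t{int(round(t))}" for t in self.timepoints_min],
        )
        df.insert(0, "distance_mm", self.distances_mm)
        return df


def kymograph(
    sample: pd.DataFrame,
    n_receivers: int = 15,
    center: tuple | None = None,
    binned: bool = False,
) -> Kymograph:
    """Radial intensity profile of receiver activation over time.

    Receivers are sorted by distance from ``center`` (default: centroid of
    the sender populations).  By default the rows are ``n_receivers``
    receivers sampled evenly along the distance ordering, each group of
    neighbouring receivers averaged into its row; with ``binned=True`` the
    rows are fixed-width distance bins instead.
    """
    cols = timepoint_columns(sample)
    times = np.array([int(c[1:]) for c in cols], dtype=float)
    recv = sample[sample["label"] == "receiver"]
    if len(recv) == 0:
        raise ValueError("sample has no receivers")
    if center is None:
        senders = sample[sample["label"] != "receiver"]
        if len(senders) == 0:
            raise ValueError("no senders to define a centre; pass center explicitly")
        center = (senders["x_mm"].mean(), senders["y_mm"].mean())
    d = np.sqrt(
        (recv["x_mm"].to_numpy() - center[0]) ** 2
        + (recv["y_mm"].to_numpy() - center[1]) ** 2
    )
    mat = recv[cols].to_numpy(dtype=float)
    order = np.argsort(d)
    d, mat = d[order], mat[order]
    if n_receivers > len(recv):
        warnings.warn(
            f"requested {n_receivers} receivers but sample has {len(recv)}; using all"
        )
        n_receivers = len(recv)
    if binned:
        edges = np.linspace(d.min(), d.max() + 1e-12, n_receivers + 1)
        idx = np.digitize(d, edges) - 1
    else:
        # equal-count groups along the distance ordering
        idx = np.minimum((np.arange(len(d)) * n_receivers) // len(d), n_receivers - 1)
    rows, dists = [], []
    for g in range(n_receivers):
        m = idx == g
        if not m.any():
            continue
        rows.append(mat[m].mean(axis=0))
        dists.append(d[m].mean())
    return Kymograph(np.asarray(dists), times, np.vstack(rows))
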