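"""Synthetic communities of cell mimics and their simulated activation.

A sample is a thin, sandwiched TXTL droplet (a few microlitres between a
gas-permeable membrane and a cover glass) in which 60--80 um porous polymer
compartments settle at random positions.  Three populations are mixed:
receivers (AND-gate reporter plus tetO capture array), STAR senders and
trigger senders; a fourth ``dual_sender`` type carrying both activator
templates is used for the centrally arranged layouts.

This module generates layouts (random or central-patch), simulates each
receiver's reporter accumulation by driving the AND gate with the local
transient RNA concentration fields, and renders the result into synthetic
multi-channel microscopy images with ground truth attached.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .signal_model import (
    GateParams,
    RnaSpecies,
    STAR_DEFAULTS,
    TRIGGER_DEFAULTS,
    TransientKernel,
    SOURCE_CLIP_MM,
    activation_factor,
    mature_trace,
)

__all__ = [
    "LABELS",
    "SampleLayout",
    "MimicTimecourse",
    "NoiseModel",
    "sample_random_layout",
    "arrange_central_senders",
    "simulate_sample",
    "render_images",
    "DEFAULT_TIMEPOINTS",
]

LABELS = ("receiver", "star_sender", "trigger_sender", "dual_sender")

#: acquisition grid: one frame every 15 min over a 5 h reaction
DEFAULT_TIMEPOINTS = np.arange(0.0, 301.0, 15.0)


@dataclass
class SampleLayout:
    """Positions, labels, sizes and DNA loads of one simulated sample."""

    droplet_radius: float  # mm
    positions: np.ndarray  # (n, 2) mm, droplet-centered
    labels: np.ndarray  # (n,) strings from LABELS
    diameters: np.ndarray  # (n,) um
    dna_loads: np.ndarray  # (n,) relative load, lognormal around 1
    seed: int | None = None
    autofluorescence: np.ndarray | None = None  # (n,) constant offset, a.u.

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.labels = np.asarray(self.labels, dtype=object)
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.dna_loads = np.asarray(self.dna_loads, dtype=float)
        n = len(self.positions)
        if self.autofluorescence is None:
            self.autofluorescence = np.zeros(n)
        self.autofluorescence = np.asarray(self.autofluorescence, dtype=float)
        if len(self.autofluorescence) != n:
            raise ValueError("autofluorescence must have one value per mimic")
        if not (len(self.labels) == len(self.diameters) == len(self.dna_loads) == n):
            raise ValueError("layout arrays must have equal length")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels: {bad}")

    def __len__(self) -> int:
        return len(self.positions)

    def mask(self, label: str) -> np.ndarray:
        return self.labels == label

    def counts(self) -> dict:
        return {lab: int(np.sum(self.labels == lab)) for lab in LABELS}

    def senders_of(self, species_name: str) -> np.ndarray:
        """Boolean mask of mimics emitting the given species (dual included)."""
        if species_name == "STAR":
            return self.mask("star_sender") | self.mask("dual_sender")
        if species_name == "trigger":
            return self.mask("trigger_sender") | self.mask("dual_sender")
        raise ValueError(f"unknown species {species_name!r}")

    def emission_loads(self, species_name: str) -> np.ndarray:
        """Per-emitting-sender load; dual senders split their load between species."""
        m = self.senders_of(species_name)
        w = self.dna_loads[m].copy()
        w[self.labels[m] == "dual_sender"] *= 0.5
        return w

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mimic_id": np.arange(len(self)),
                "x_mm": self.positions[:, 0],
                "y_mm": self.positions[:, 1],
                "diameter_um": self.diameters,
                "label": self.labels,
                "load": self.dna_loads,
            }
        )


@dataclass
class MimicTimecourse:
    """Reporter intensity trace of one mimic (cumulative, non-decreasing)."""

    mimic_id: int
    timepoints: np.ndarray  # min
    intensity: np.ndarray  # a.u.


def _pack_circles(
    n: int,
    rng: np.random.Generator,
    radial_sampler,
    diameters_um: np.ndarray,
    max_tries: int = 20000,
) -> np.ndarray:
    """Place ``n`` non-overlapping circles by rejection sampling.

    ``radial_sampler(rng, size)`` draws candidate positions (mm).  Raises if
    the packing stalls, naming the achievable count.
    """
    placed = np.empty((n, 2))
    radii_mm = diameters_um / 2000.0
    k, tries = 0, 0
    while k < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n} non-overlapping mimics; achieved {k} "
                f"after {max_tries} attempts -- reduce counts or enlarge droplet"
            )
        cand = radial_sampler(rng, 1)[0]
        if k > 0:
            d = np.sqrt(((placed[:k] - cand) ** 2).sum(axis=1))
            min_sep = radii_mm[:k] + radii_mm[k]
            if np.any(d < min_sep):
                tries += 1
                continue
        placed[k] = cand
        k += 1
        tries += 1
    return placed


def _uniform_disc(radius: float, margin: float):
    def sampler(rng: np.random.Generator, size: int) -> np.ndarray:
        r = (radius - margin) * np.sqrt(rng.uniform(size=size))
        th = rng.uniform(0, 2 * np.pi, size=size)
        return np.column_stack([r * np.cos(th), r * np.sin(th)])

    return sampler


def _uniform_annulus(r_in: float, r_out: float):
    def sampler(rng: np.random.Generator, size: int) -> np.ndarray:
        r = np.sqrt(rng.uniform(r_in**2, r_out**2, size=size))
        th = rng.uniform(0, 2 * np.pi, size=size)
        return np.column_stack([r * np.cos(th), r * np.sin(th)])

    return sampler


def _draw_diameters(rng: np.random.Generator, n: int, diameter_range=(60.0, 80.0)):
    return rng.uniform(*diameter_range, size=n)


def _draw_loads(rng: np.random.Generator, n: int, cv: float = 0.35):
    # lognormal with mean 1 and the requested coefficient of variation
    sigma2 = np.log(1.0 + cv**2)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=n)


#: per-mimic shell autofluorescence (a.u.): polymer shells fluoresce weakly
#: and unevenly in the sfGFP channel, a constant offset per mimic
AUTOFL_MEAN = 30.0
AUTOFL_SD = 15.0


def _draw_autofluorescence(rng: np.random.Generator, n: int, sd: float = AUTOFL_SD):
    return np.clip(rng.normal(AUTOFL_MEAN, sd, size=n), 0.0, None)


def sample_random_layout(
    counts: dict | Sequence[int],
    droplet_radius: float = 1.5,
    seed: int | None = None,
    diameter_range: tuple = (60.0, 80.0),
    load_cv: float = 0.35,
    autofl_sd: float = AUTOFL_SD,
    max_tries: int = 200000,
) -> SampleLayout:
    """Place mimics uniformly at random in the droplet, without overlap.

    Parameters
    ----------
    counts : dict or sequence
        Either ``{"receiver": n_r, "star_sender": n_s, ...}`` or a sequence
        ``(n_receiver, n_star, n_trigger[, n_dual])``.
    droplet_radius : float
        Droplet radius in mm (default 1.5, a ~5 uL sandwiched droplet).
    load_cv : float
        Coefficient of variation of the per-mimic lognormal DNA load.
    """
    if not isinstance(counts, dict):
        vals = list(counts) + [0] * (4 - len(counts))
        counts = dict(zip(LABELS, vals))
    counts = {lab: int(counts.get(lab, 0)) for lab in LABELS}
    n = sum(counts.values())
    rng = np.random.default_rng(seed)
    diameters = _draw_diameters(rng, n, diameter_range)
    margin = diameters.max() / 2000.0 if n else 0.0
    positions = _pack_circles(
        n, rng, _uniform_disc(droplet_radius, margin), diameters, max_tries
    )
    labels = np.concatenate(
        [np.full(counts[lab], lab, dtype=object) for lab in LABELS]
    )
    rng.shuffle(labels)
    loads = _draw_loads(rng, n, load_cv)
    autofl = _draw_autofluorescence(rng, n, autofl_sd)
    return SampleLayout(droplet_radius, positions, labels, diameters, loads, seed, autofl)


def arrange_central_senders(
    n_senders: int = 30,
    n_receivers: int = 100,
    droplet_radius: float = 2.1,
    patch_radius: float = 0.5,
    seed: int | None = None,
    diameter_range: tuple = (60.0, 80.0),
    load_cv: float = 0.35,
    autofl_sd: float = AUTOFL_SD,
    max_tries: int = 200000,
) -> SampleLayout:
    """Central patch of dual senders surrounded by a ring of receivers.

    Mirrors the spatially arranged propagation experiment: senders carrying
    both activator templates confined to a central patch, receivers spread
    through the surrounding annulus out to the droplet edge (~2.1 mm at the
    default droplet radius).
    """
    if patch_radius >= droplet_radius:
        raise ValueError("patch_radius must be smaller than droplet_radius")
    rng = np.random.default_rng(seed)
    n = n_senders + n_receivers
    diameters = _draw_diameters(rng, n, diameter_range)
    margin = diameters.max() / 2000.0 if n else 0.0
    sender_pos = _pack_circles(
        n_senders, rng, _uniform_disc(patch_radius, 0.0), diameters[:n_senders], max_tries
    )
    recv_pos = _pack_circles(
        n_receivers,
        rng,
        _uniform_annulus(patch_radius + margin, droplet_radius - margin),
        diameters[n_senders:],
        max_tries,
    )
    positions = np.vstack([sender_pos, recv_pos]) if n else np.empty((0, 2))
    labels = np.concatenate(
        [
            np.full(n_senders, "dual_sender", dtype=object),
            np.full(n_receivers, "receiver", dtype=object),
        ]
    )
    loads = _draw_loads(rng, n, load_cv)
    autofl = _draw_autofluorescence(rng, n, autofl_sd)
    return SampleLayout(droplet_radius, positions, labels, diameters, loads, seed, autofl)


def _local_levels(
    layout: SampleLayout,
    species: RnaSpecies,
    query_idx: np.ndarray,
    t_grid: np.ndarray,
) -> np.ndarray:
    """Concentration of one species at each query mimic over the time grid.

    Uses a dense log-r lookup of the transient point-source kernel, then
    superposes sender contributions weighted by emission load.  Shape
    (n_query, n_t).
    """
    m = layout.senders_of(species.name)
    nq = len(query_idx)
    if not m.any() or nq == 0:
        return np.zeros((nq, len(t_grid)))
    src = layout.positions[m]
    w = layout.emission_loads(species.name)
    q = layout.positions[query_idx]
    r = np.sqrt(((q[:, None, :] - src[None, :, :]) ** 2).sum(axis=-1))
    r = np.maximum(r, SOURCE_CLIP_MM)
    log_r, table = TransientKernel(species).table(
        t_grid, r_max=max(6.0, 2.5 * layout.droplet_radius)
    )
    lr = np.log(r)
    out = np.empty((nq, len(t_grid)))
    for j in range(len(t_grid)):
        out[:, j] = np.interp(lr, log_r, table[j]).reshape(nq, -1) @ w
    return out


def simulate_sample(
    layout: SampleLayout,
    gate: GateParams | None = None,
    species: tuple = (STAR_DEFAULTS, TRIGGER_DEFAULTS),
    timepoints: np.ndarray = DEFAULT_TIMEPOINTS,
    internal_dt: float = 5.0,
    escape_fraction: float = 0.1,
    tau_mix: float = 120.0,
    tau_leak: float = 180.0,
) -> list[MimicTimecourse]:
    """Simulate reporter accumulation in every mimic of a layout.

    Each receiver integrates the AND-gate synthesis rate driven by its local
    STAR and trigger concentrations,

        dG/dt = load * beta * [h(S, T) - h(0, 0)] * exp(-t / tau_res),

    plus its own load-scaled basal leak (leak transcripts come from the
    receiver's reporter template, so leak scales with DNA load and builds up
    slowly over ``tau_leak``), plus a background shared by every mimic:
    a fraction ``escape_fraction`` of all reporter synthesis escapes into
    the medium (reporter mRNA and protein are not confined to the producing
    mimic) and re-enters mimics after a first-order mixing lag ``tau_mix``
    (min).  The double integration makes the shared term flat early and
    rising late, reproducing the flat-then-rising baseline of
    sender-omitted controls.  Senders carry no reporter template and show
    only the shared background.  Fully deterministic given the layout.

    Returns one :class:`MimicTimecourse` per mimic, sampled on ``timepoints``
    (min), integrating internally at ``internal_dt``.
    """
    gate = gate or GateParams()
    star_sp, trig_sp = species
    timepoints = np.asarray(timepoints, dtype=float)
    t_grid = np.arange(0.0, timepoints.max() + 0.5 * internal_dt, internal_dt)

    recv_idx = np.flatnonzero(layout.mask("receiver"))
    S = _local_levels(layout, star_sp, recv_idx, t_grid)
    T = _local_levels(layout, trig_sp, recv_idx, t_grid)

    decay = np.exp(-t_grid / gate.tau_res)
    basal = gate.alpha_term * gate.alpha_toe

    # leak synthesis builds up slowly (tau_leak): double read-through /
    # leak-translation events accumulate over hours, so control traces stay
    # flat early and rise late, unlike signal-activated synthesis
    basal_rate = gate.beta * basal * (1.0 - np.exp(-t_grid / tau_leak)) * decay
    h = activation_factor(S, T, gate)
    excess_rate = gate.beta * (h - basal) * decay[None, :]
    excess_rate = layout.dna_loads[recv_idx, None] * excess_rate

    # shared medium pool: a fraction of all synthesis escapes into a
    # well-mixed pool with first-order mixing time tau_mix; the pool's
    # capture rate is the exponential-kernel convolution of the droplet-mean
    # synthesis rate, and what is captured matures like any other reporter
    n_total = max(len(layout), 1)
    own_basal = layout.dna_loads[recv_idx, None] * basal_rate[None, :]
    mean_rate = (excess_rate.sum(axis=0) + own_basal.sum(axis=0)) / n_total
    wts = np.full(len(t_grid), internal_dt)
    wts[0] = 0.5 * internal_dt
    expker = np.tril(
        np.exp(-np.maximum(t_grid[:, None] - t_grid[None, :], 0.0) / tau_mix)
    )
    capture_rate = (escape_fraction / tau_mix) * ((expker * wts[None, :]) @ mean_rate)
    background = mature_trace(capture_rate, t_grid, gate.tau_mat)

    traces = np.tile(background, (len(layout), 1))
    traces += layout.autofluorescence[:, None]
    own_rate = own_basal + excess_rate
    traces[recv_idx] += mature_trace(own_rate, t_grid, gate.tau_mat)

    # sample onto the acquisition grid
    out = []
    for i in range(len(layout)):
        vals = np.interp(timepoints, t_grid, traces[i])
        out.append(MimicTimecourse(i, timepoints.copy(), vals))
    return out


def timecourses_to_frame(
    layout: SampleLayout, courses: Iterable[MimicTimecourse]
) -> pd.DataFrame:
    """Tidy per-mimic table: layout columns plus one ``t<min>`` column per frame."""
    df = layout.to_dataframe()
    courses = list(courses)
    if courses:
        tp = courses[0].timepoints
        mat = np.vstack([c.intensity for c in courses])
        for j, t in enumerate(tp):
            df[f"t{int(round(t))}"] = mat[:, j]
    return df


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: Poisson shot noise at ``gain`` photons/count + Gaussian read noise."""

    read_sigma: float = 5.0
    gain: float = 0.5
    enabled: bool = True

    def apply(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if not self.enabled:
            return img
        shot = rng.poisson(np.maximum(img, 0.0) * self.gain) / self.gain
        return shot + rng.normal(0.0, self.read_sigma, size=img.shape)


# rendering levels (a.u., camera offset included)
_BF_BACKGROUND = 1000.0
_BF_RING = 300.0
_DYE_LEVEL = 2000.0
_CHANNEL_OFFSET = 100.0


def render_images(
    layout: SampleLayout,
    intensities: np.ndarray | None = None,
    pixel_size: float = 4.0,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    margin_mm: float = 0.1,
) -> dict:
    """Render a layout into synthetic multi-channel microscopy frames.

    Channels mirror the acquisition scheme: ``brightfield`` (dark ring at
    each mimic boundary), ``cy5`` (trigger-sender membrane dye), ``mcherry``
    (STAR-sender membrane dye) and ``sfgfp`` (reporter concentrated in the
    condensed clay nucleus, rendered as a disc of half the mimic diameter).
    Dual senders are stained in both dye channels.

    Parameters
    ----------
    intensities : array, optional
        Per-mimic sfGFP values, shape (n,) for a single frame or (n, T) for
        a stack; defaults to zeros.
    pixel_size : float
        um per pixel (default 4).

    Returns
    -------
    dict mapping channel name to float array of shape (H, W) or (T, H, W).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)

    half = layout.droplet_radius + margin_mm
    npx = int(np.ceil(2 * half * 1000.0 / pixel_size))
    n = len(layout)
    if intensities is None:
        intensities = np.zeros((n, 1))
    intensities = np.asarray(intensities, dtype=float)
    single = intensities.ndim == 1
    if single:
        intensities = intensities[:, None]
    if intensities.shape[0] != n:
        raise ValueError("intensities must have one row per mimic")
    n_t = intensities.shape[1]

    # pixel centre coordinates in mm (origin top-left, x right, y down)
    def to_px(mm: np.ndarray) -> np.ndarray:
        return (mm + half) * 1000.0 / pixel_size

    cx = to_px(layout.positions[:, 0])
    cy = to_px(layout.positions[:, 1])
    rad_px = layout.diameters / 2.0 / pixel_size
    if n and (np.any(cx + rad_px > npx) or np.any(cx - rad_px < 0)):
        raise ValueError("field of view too small for the droplet layout")

    bf = np.full((npx, npx), _BF_BACKGROUND)
    cy5 = np.full((npx, npx), _CHANNEL_OFFSET)
    mch = np.full((npx, npx), _CHANNEL_OFFSET)
    sf_base = np.full((npx, npx), _CHANNEL_OFFSET)
    # per-mimic nucleus pixel masks for the sfGFP stack
    nucleus_masks = []

    for i in range(n):
        r = rad_px[i]
        x0, x1 = int(max(0, cx[i] - r - 3)), int(min(npx, cx[i] + r + 4))
        y0, y1 = int(max(0, cy[i] - r - 3)), int(min(npx, cy[i] + r + 4))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.sqrt((xx + 0.5 - cx[i]) ** 2 + (yy + 0.5 - cy[i]) ** 2)
        ring = (d >= r - 1.5) & (d <= r + 0.5)
        inside = d < r - 1.5
        bf[yy[ring], xx[ring]] = _BF_RING
        bf[yy[inside], xx[inside]] = 0.92 * _BF_BACKGROUND
        membrane = (d >= 0.75 * r) & (d <= r)
        lab = layout.labels[i]
        if lab in ("trigger_sender", "dual_sender"):
            cy5[yy[membrane], xx[membrane]] += _DYE_LEVEL
        if lab in ("star_sender", "dual_sender"):
            mch[yy[membrane], xx[membrane]] += _DYE_LEVEL
        nucleus = d <= 0.5 * r
        nucleus_masks.append((yy[nucleus], xx[nucleus]))

    out = {}
    for name, base in (("brightfield", bf), ("cy5", cy5), ("mcherry", mch)):
        stack = np.stack([noise.apply(base, rng) for _ in range(n_t)])
        out[name] = stack

    sf_stack = np.empty((n_t, npx, npx))
    for t in range(n_t):
        frame = sf_base.copy()
        for i, (yy, xx) in enumerate(nucleus_masks):
            frame[yy, xx] += intensities[i, t]
        sf_stack[t] = noise.apply(frame, rng)
    out["sfgfp"] = sf_stack

    if single:
        out = {k: v[0] for k, v in out.items()}
    return out
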