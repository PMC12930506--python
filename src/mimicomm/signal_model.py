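"""Mechanistic model of the distributed RNA AND gate.

Two small regulatory RNAs act as diffusible signals between cell mimics
suspended in a shared cell-free transcription--translation (TXTL) medium:

* a STAR (Small Transcription Activating RNA) that suppresses formation of
  an intrinsic terminator, enabling transcriptional read-through, and
* a trigger RNA that opens a toehold switch sequestering the ribosome
  binding site, enabling translation.

A reporter (TetR-sfGFP) is produced efficiently only when both signals are
present; each regulatory layer leaks independently, with terminator
read-through (trigger-only condition) leaking far more than the toehold
switch (STAR-only condition).

This module provides

* :class:`GateParams` / :class:`RnaSpecies` -- the kinetic and transport
  parameter containers shared by the whole package,
* :func:`activation_factor` -- the leaky dual-Hill AND-gate response,
* :func:`simulate_bulk` -- well-mixed TXTL kinetics with resource decay,
* :func:`steady_state_field` / :func:`transient_field` -- superposed 2-D
  diffusion--decay point-source concentration fields around senders,
* :func:`signaling_length` -- the characteristic signal range sqrt(D*tau).

Concentration "field units" are nM-equivalents: the bulk simulator and the
spatial fields feed the same Hill functions, so K_S and K_T carry the same
units in both settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import k0

__all__ = [
    "GateParams",
    "RnaSpecies",
    "STAR_DEFAULTS",
    "TRIGGER_DEFAULTS",
    "activation_factor",
    "simulate_bulk",
    "steady_state_field",
    "transient_field",
    "signaling_length",
    "TransientKernel",
]

#: radius (mm) below which the point-source singularity is clipped;
#: one mimic radius (35 um), i.e. concentrations are evaluated no closer
#: than the mimic surface.
SOURCE_CLIP_MM = 0.035


@dataclass(frozen=True)
class GateParams:
    """Kinetic parameters of the leaky AND gate.

    Attributes
    ----------
    beta : float
        Maximal reporter synthesis rate (intensity units / min) with both
        activators saturating.
    alpha_term : float
        Terminator read-through fraction without STAR (dimensionless).
    alpha_toe : float
        Toehold leak fraction without trigger (dimensionless).  Must be
        smaller than ``alpha_term``: the trigger-only condition leaks more
        than the STAR-only condition.
    K_S, K_T : float
        Half-activation concentrations (field units, nM-equivalent).
    n_S, n_T : float
        Hill coefficients (>= 1).
    tau_RNA : float
        RNA lifetime in TXTL (min).
    tau_res : float
        TXTL resource lifetime (min); synthesis capacity decays as
        exp(-t / tau_res), producing the characteristic plateau.
    k_tx : float
        Bulk transcription rate constant (field units / (nM template * min)).
    tau_mat : float
        Reporter maturation-and-capture lag (min): synthesised TetR-sfGFP
        becomes visible at the nucleus with first-order delay, giving the
        sigmoidal early phase of the observed traces.
    """

    beta: float = 10.0
    alpha_term: float = 0.286
    alpha_toe: float = 0.03
    K_S: float = 10.0
    K_T: float = 10.0
    n_S: float = 2.0
    n_T: float = 2.0
    tau_RNA: float = 17.0
    tau_res: float = 120.0
    k_tx: float = 1.0
    tau_mat: float = 45.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_toe < self.alpha_term < 1.0):
            raise ValueError(
                "leak ordering violated: need 0 < alpha_toe < alpha_term < 1, "
                f"got alpha_toe={self.alpha_toe}, alpha_term={self.alpha_term}"
            )
        for name in ("beta", "K_S", "K_T", "tau_RNA", "tau_res", "k_tx", "tau_mat"):
            if getattr(self, name) < 0 or (
                name in ("K_S", "K_T", "tau_RNA", "tau_res") and getattr(self, name) == 0
            ):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_S < 1 or self.n_T < 1:
            raise ValueError("Hill coefficients must be >= 1")

    def replace(self, **kw) -> "GateParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class RnaSpecies:
    """Transport parameters of one diffusing RNA signal.

    ``Q`` is the emission rate of a sender with unit DNA load, in field
    units * mm^2 / s; the default normalisation puts the steady-state
    concentration of a single unit-load sender at 2.5x the half-activation
    constant K when evaluated one signaling length away, so a sender
    strongly activates its own neighbourhood out to ~lambda.
    """

    name: str
    D: float  # mm^2/s
    tau: float = 1020.0  # s (~17 min)
    Q: float | None = None
    onset_delay: float = 15.0  # min

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"diffusion coefficient must be > 0, got {self.D}")
        if self.tau <= 0:
            raise ValueError(f"lifetime must be > 0, got {self.tau}")
        if self.Q is None:
            # c(lambda) = Q * K0(1) / (2 pi D) == 25 field units (2.5 K)
            object.__setattr__(self, "Q", 25.0 * 2.0 * np.pi * self.D / k0(1.0))
        if self.Q < 0:
            raise ValueError("emission rate must be >= 0")

    def replace(self, **kw) -> "RnaSpecies":
        return replace(self, **kw)


#: predicted diffusion coefficients: 8.48e-7 cm^2/s (STAR), 6.49e-7 cm^2/s
#: (trigger), converted to mm^2/s; RNA lifetime ~17 min in TXTL.
STAR_DEFAULTS = RnaSpecies(name="STAR", D=8.48e-5)
TRIGGER_DEFAULTS = RnaSpecies(name="trigger", D=6.49e-5)


def _hill(x, K: float, n: float):
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        xn = np.power(x, n)
    return xn / (K**n + xn)


def activation_factor(star_level, trigger_level, params: GateParams | None = None):
    """Dimensionless AND-gate response h_S(S) * h_T(T) in [a_term*a_toe, 1].

    Each layer is a leaky Hill function,
    ``h_S = alpha_term + (1 - alpha_term) * S^n / (K_S^n + S^n)`` and
    analogously for the trigger with ``alpha_toe``.  Monotone non-decreasing
    in both arguments; accepts scalars or arrays (broadcast).
    """
    params = params or GateParams()
    S = np.asarray(star_level, dtype=float)
    T = np.asarray(trigger_level, dtype=float)
    if np.any(S < 0) or np.any(T < 0):
        raise ValueError("RNA levels must be non-negative")
    h_S = params.alpha_term + (1.0 - params.alpha_term) * _hill(S, params.K_S, params.n_S)
    h_T = params.alpha_toe + (1.0 - params.alpha_toe) * _hill(T, params.K_T, params.n_T)
    out = h_S * h_T
    return float(out) if out.ndim == 0 else out


def _bulk_rna_level(template_nM: float, t_min: np.ndarray, params: GateParams) -> np.ndarray:
    """RNA level in a well-mixed reaction with decaying synthesis capacity.

    dS/dt = k_tx * template * exp(-t/tau_res) - S / tau_RNA, S(0) = 0.
    Closed form (a = 1/tau_res, b = 1/tau_RNA):
    S(t) = k_tx*template * (exp(-a t) - exp(-b t)) / (b - a).
    """
    a = 1.0 / params.tau_res
    b = 1.0 / params.tau_RNA
    t = np.asarray(t_min, dtype=float)
    if abs(b - a) < 1e-12:
        return params.k_tx * template_nM * t * np.exp(-a * t)
    return params.k_tx * template_nM * (np.exp(-a * t) - np.exp(-b * t)) / (b - a)


def simulate_bulk(
    template_concs: dict,
    params: GateParams | None = None,
    t_end: float = 300.0,
    dt: float = 1.0,
):
    """Simulate a well-mixed (bulk) TXTL AND-gate reaction.

    Parameters
    ----------
    template_concs : dict
        Template plasmid concentrations in nM with keys ``STAR``,
        ``trigger`` and ``reporter`` (missing keys default to 0).
    params : GateParams, optional
    t_end, dt : float
        Duration and output step in minutes.

    Returns
    -------
    (t, reporter) : tuple of ndarray
        Time grid (min) and the cumulative reporter intensity trace (a.u.),
        non-negative and non-decreasing, plateauing as TXTL resources decay.
    """
    params = params or GateParams()
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    conc = {k: float(template_concs.get(k, 0.0)) for k in ("STAR", "trigger", "reporter")}
    for k, v in conc.items():
        if v < 0:
            raise ValueError(f"negative template concentration for {k}")

    t = np.arange(0.0, t_end + 0.5 * dt, dt)
    S = _bulk_rna_level(conc["STAR"], t, params)
    T = _bulk_rna_level(conc["trigger"], t, params)
    # reporter template scales synthesis linearly (2 nM reference)
    rate = (
        params.beta
        * (conc["reporter"] / 2.0)
        * activation_factor(S, T, params)
        * np.exp(-t / params.tau_res)
    )
    return t, mature_trace(rate, t, params.tau_mat)


def mature_trace(rate: np.ndarray, t: np.ndarray, tau_mat: float) -> np.ndarray:
    """Observed reporter from a synthesis-rate trace.

    Convolves the synthesis rate with the first-order maturation/capture
    response ``1 - exp(-dt / tau_mat)``: the cumulative synthesis becomes
    visible with a lag, giving non-negative, non-decreasing observed traces.
    ``rate`` may be (n_t,) or (n, n_t) on the uniform grid ``t``.
    """
    t = np.asarray(t, dtype=float)
    dt = t[1] - t[0] if len(t) > 1 else 1.0
    lag = 1.0 - np.exp(-np.maximum(t[:, None] - t[None, :], 0.0) / tau_mat)
    lag = np.tril(lag)
    w = np.full(len(t), dt)
    w[0] = 0.5 * dt
    out = np.asarray(rate, dtype=float) @ (lag * w[None, :]).T
    return out


def signaling_length(species: RnaSpecies) -> float:
    """Characteristic signal range lambda = sqrt(D * tau) in mm.

    The 2-D steady-state concentration around a constant point source decays
    as K0(r / lambda); beyond a few lambda a sender is effectively silent.
    ``D = 0`` is rejected by the :class:`RnaSpecies` constructor, so the
    degenerate case cannot arise here.
    """
    return float(np.sqrt(species.D * species.tau))


def _clipped_distances(sources: np.ndarray, queries: np.ndarray) -> np.ndarray:
    """Pairwise distances (n_query, n_source) in mm, clipped at the mimic surface."""
    d = np.sqrt(
        ((queries[:, None, :] - sources[None, :, :]) ** 2).sum(axis=-1)
    )
    return np.maximum(d, SOURCE_CLIP_MM)


def _as_sources(sender_positions, loads=None):
    pos = np.atleast_2d(np.asarray(sender_positions, dtype=float))
    if pos.size == 0:
        pos = pos.reshape(0, 2)
    if pos.shape[-1] != 2:
        raise ValueError("sender positions must be (n, 2) in mm")
    if loads is None:
        loads = np.ones(pos.shape[0])
    loads = np.asarray(loads, dtype=float)
    if loads.shape != (pos.shape[0],):
        raise ValueError("loads must match sender count")
    return pos, loads


def steady_state_field(
    sender_positions,
    species: RnaSpecies,
    query_points,
    loads=None,
) -> np.ndarray:
    """Steady-state concentration of one RNA species at the query points.

    Superposition of 2-D diffusion--decay point-source solutions: each sender
    of load w contributes ``w * Q / (2 pi D) * K0(r / lambda)``, the droplet
    being treated as a thin film.  Distances are clipped at one mimic radius
    (35 um) so the logarithmic singularity is never evaluated.
    """
    sources, loads = _as_sources(sender_positions, loads)
    queries = np.atleast_2d(np.asarray(query_points, dtype=float))
    if sources.shape[0] == 0:
        return np.zeros(queries.shape[0])
    lam = signaling_length(species)
    r = _clipped_distances(sources, queries)
    contrib = (species.Q / (2.0 * np.pi * species.D)) * k0(r / lam)
    return contrib @ loads


class TransientKernel:
    """Time-dependent point-source response F(r, t) for one species.

    ``F(r, t)`` is the concentration at distance r (mm) from a unit-load
    sender that starts emitting at ``onset_delay`` and emits at constant
    rate Q thereafter, while the RNA decays with lifetime tau:

        F(r, t) = Q * integral_0^{t - t0} exp(-r^2/(4 D s) - s/tau)
                                          / (4 pi D s) ds

    The integral is evaluated by Gauss--Legendre quadrature after the
    substitution s = exp(u), which resolves the many-decade support of the
    integrand; as t -> infinity it converges to the K0 steady state.
    ``table()`` returns a dense log-r lookup for fast superposition over
    many sender--receiver pairs.
    """

    def __init__(self, species: RnaSpecies, n_nodes: int = 80, s_min: float = 1e-3):
        self.species = species
        self.n_nodes = n_nodes
        self.s_min = s_min
        self._u, self._w = leggauss(n_nodes)

    def __call__(self, r, t_min) -> np.ndarray:
        """Evaluate F at distances ``r`` (mm, array) and scalar time ``t_min``."""
        sp = self.species
        te = (float(t_min) - sp.onset_delay) * 60.0  # emission duration, s
        r = np.maximum(np.asarray(r, dtype=float), SOURCE_CLIP_MM)
        if te <= self.s_min:
            return np.zeros_like(r)
        lo, hi = np.log(self.s_min), np.log(te)
        u = 0.5 * (hi - lo) * self._u + 0.5 * (hi + lo)
        w = 0.5 * (hi - lo) * self._w
        s = np.exp(u)  # (n_nodes,)
        integrand = np.exp(-r[..., None] ** 2 / (4.0 * sp.D * s) - s / sp.tau)
        return sp.Q / (4.0 * np.pi * sp.D) * (integrand @ w)

    def table(self, t_grid_min, r_max: float = 6.0, n_r: int = 1024):
        """Precompute F on a log-spaced r grid for each time in ``t_grid_min``.

        Returns ``(log_r, values)`` where values has shape (n_t, n_r);
        interpolate with :func:`numpy.interp` on log distance.
        """
        r = np.geomspace(SOURCE_CLIP_MM, r_max, n_r)
        vals = np.stack([self(r, t) for t in np.asarray(t_grid_min, dtype=float)])
        return np.log(r), vals


def transient_field(
    sender_positions,
    species: RnaSpecies,
    query_points,
    t: float,
    loads=None,
) -> np.ndarray:
    """Concentration field at time ``t`` (min) after reaction start.

    Senders begin emitting at ``species.onset_delay``; for ``t`` at or below
    the delay the field is identically zero, and for ``t >> tau`` it
    converges to :func:`steady_state_field`.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    sources, loads = _as_sources(sender_positions, loads)
    queries = np.atleast_2d(np.asarray(query_points, dtype=float))
    if sources.shape[0] == 0 or t <= species.onset_delay:
        return np.zeros(queries.shape[0])
    r = _clipped_distances(sources, queries)
    return TransientKernel(species)(r, t) @ loads
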