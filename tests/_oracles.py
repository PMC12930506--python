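"""Independent numerical oracles used by the test suite.

These deliberately avoid the implementation paths they check: the PDE
oracles are finite-volume solvers of the radial diffusion--decay equation,
the density oracle is a plain O(N^2) loop, and the reporter-trace oracle
integrates the synthesis model with scipy adaptive quadrature.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.linalg import solve_banded


def fd_steady_state(D, tau, Q, r_eval, r_max=2.5, n=1000, a_src=0.02):
    """Steady state of du/dt = D lap(u) - u/tau + s in 2-D radial symmetry.

    Finite-volume discretisation on cell centres r_j = (j+1/2) dr with a
    source of total strength Q spread over a disc of radius ``a_src``;
    u(r_max) = 0.  Returns the solution interpolated at ``r_eval``.
    """
    dr = r_max / n
    r_c = (np.arange(n) + 0.5) * dr
    r_f = np.arange(1, n) * dr  # interior faces
    # banded system: -D * div(grad) + 1/tau
    ab = np.zeros((3, n))
    for j in range(n):
        lo = D * r_f[j - 1] / (r_c[j] * dr * dr) if j > 0 else 0.0
        hi = D * r_f[j] / (r_c[j] * dr * dr) if j < n - 1 else D * r_f[-1] / (r_c[j] * dr * dr)
        ab[1, j] = lo + hi + 1.0 / tau
        if j > 0:
            ab[0, j] = -D * r_f[j - 1] / (r_c[j - 1] * dr * dr)  # superdiag col j
        if j < n - 1:
            ab[2, j] = -D * r_f[j] / (r_c[j + 1] * dr * dr)  # subdiag col j
    src = _normalized_source(Q, r_c, dr, a_src)
    u = solve_banded((1, 1), ab, src)
    return np.interp(r_eval, r_c, u)


def _normalized_source(Q, r_c, dr, a_src):
    """Uniform disc source scaled so the discrete cell sum emits exactly Q."""
    ind = (r_c < a_src).astype(float)
    total = (ind * 2.0 * np.pi * r_c * dr).sum()
    return ind * Q / total


def fd_transient(D, tau, Q, r_eval, t_eval_s, r_max=2.5, n=800, dt=5.0, a_src=0.02):
    """Crank--Nicolson time stepping of the same radial problem from u = 0.

    The source switches on at t = 0 and emits at constant rate Q.  Returns
    an array of shape (len(t_eval_s), len(r_eval)).
    """
    dr = r_max / n
    r_c = (np.arange(n) + 0.5) * dr
    r_f = np.arange(1, n) * dr
    main = np.zeros(n)
    lower = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    for j in range(n):
        lo = D * r_f[j - 1] / (r_c[j] * dr * dr) if j > 0 else 0.0
        hi = D * r_f[j] / (r_c[j] * dr * dr) if j < n - 1 else D * r_f[-1] / (r_c[j] * dr * dr)
        main[j] = -(lo + hi) - 1.0 / tau
        if j > 0:
            lower[j - 1] = lo
        if j < n - 1:
            upper[j] = hi
    src = _normalized_source(Q, r_c, dr, a_src)

    # (I - dt/2 A) u_new = (I + dt/2 A) u_old + dt * src
    abL = np.zeros((3, n))
    abL[0, 1:] = -0.5 * dt * upper
    abL[1, :] = 1.0 - 0.5 * dt * main
    abL[2, :-1] = -0.5 * dt * lower

    def apply_R(u):
        out = (1.0 + 0.5 * dt * main) * u
        out[:-1] += 0.5 * dt * upper * u[1:]
        out[1:] += 0.5 * dt * lower * u[:-1]
        return out

    u = np.zeros(n)
    targets = np.asarray(t_eval_s, dtype=float)
    # snap evaluation times onto the stepping grid (dt chosen to divide them)
    steps = np.round(targets / dt).astype(int)
    out = np.empty((len(targets), len(np.atleast_1d(r_eval))))
    order = np.argsort(steps)
    k = 0
    for s in range(int(steps.max()) + 1):
        while k < len(order) and steps[order[k]] == s:
            out[order[k]] = np.interp(r_eval, r_c, u)
            k += 1
        u = solve_banded((1, 1), abL, apply_R(u) + dt * src)
    return out


def brute_force_density(receiver_xy, member_xy, r_um, exclude_self=False):
    """O(N^2) local density count, one loop pair at a time."""
    rx, ry = receiver_xy
    r_mm = r_um / 1000.0
    n = 0
    for (mx, my) in member_xy:
        d = ((mx - rx) ** 2 + (my - ry) ** 2) ** 0.5
        if d <= r_mm:
            n += 1
    if exclude_self:
        n -= 1
    return n / (np.pi * r_mm**2)


def quad_reporter_trace(
    sender_xy, receiver_xy, species, gate, load, t_end_min, tau_leak=180.0
):
    """Reporter intensity of one receiver near one STAR sender at ``t_end_min``.

    Adaptive-quadrature evaluation of the same model the simulator
    implements: the transient point-source concentration drives the gate,
    synthesis decays with resources, and the product is convolved with the
    maturation response.  No shared-medium background term (the caller
    compares against a simulation with escape_fraction = 0).
    """
    r = np.hypot(sender_xy[0] - receiver_xy[0], sender_xy[1] - receiver_xy[1])
    r = max(r, 0.035)

    def conc(t_min):
        te = (t_min - species.onset_delay) * 60.0
        if te <= 0:
            return 0.0
        val, _ = quad(
            lambda s: np.exp(-r**2 / (4.0 * species.D * s) - s / species.tau)
            / (4.0 * np.pi * species.D * s),
            1e-6,
            te,
            limit=400,
        )
        return species.Q * val

    basal = gate.alpha_term * gate.alpha_toe

    def h(t_min):
        S = conc(t_min)
        h_S = gate.alpha_term + (1 - gate.alpha_term) * S**gate.n_S / (
            gate.K_S**gate.n_S + S**gate.n_S
        )
        return h_S * gate.alpha_toe  # trigger absent: h_T = alpha_toe

    def rate(t_min):
        own = gate.beta * (h(t_min) - basal)
        leak = gate.beta * basal * (1.0 - np.exp(-t_min / tau_leak))
        return load * (own + leak) * np.exp(-t_min / gate.tau_res)

    val, _ = quad(
        lambda s: rate(s) * (1.0 - np.exp(-(t_end_min - s) / gate.tau_mat)),
        0.0,
        t_end_min,
        limit=300,
    )
    return val
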