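"""Deterministic (mean-field) chemical rate equations of ring assembly.

Factorizing the two-point correlators of the master equation and exploiting
the relabelling symmetry between species reduces the heterogeneous system to
a single Becker-Doering-type ladder for the per-species concentrations
``c_l = <n_l^s>/V``::

    dc_0/dt = -alpha c_0
    dc_1/dt =  alpha c_0 - 2 c_1 sum_{l=1}^{L-1} nu_l c_l
                         + sum_{l=2}^{Lnuc-1} l delta_l c_l
    dc_2/dt =  nu_1 c_1^2 - 2 nu_2 c_1 c_2          - delta_2 c_2 [2 < Lnuc]
    dc_l/dt =  2 nu_{l-1} c_1 c_{l-1} - 2 nu_l c_1 c_l
                                                    - delta_l c_l [l < Lnuc]
    dc_L/dt =  2 nu_{L-1} c_1 c_{L-1}

with ``nu_l = mu_l`` below the nucleation size and ``nu`` above, and yield
``cL * L / C``.  The deterministic yield depends on the activation rate only
through the dimensionless combination ``alpha/(nu C)`` (master-curve
collapse), and is independent of the number of species ``S``; the full
species-resolved mean-field system is provided as a verification mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .core_types import AssemblyConfig, validate_config

__all__ = ["ConcentrationProfile", "ODEResult", "rhs", "integrate_ode",
           "integrate_full_heterogeneous"]

#: steady-state detection tolerance: stop once c0 + c1 < EPS_STEADY * C
EPS_STEADY = 1e-9


@dataclass
class ConcentrationProfile:
    """Concentrations per species-equivalent at one instant: ``c[0]`` and
    ``c[1]`` are the inactive/active monomer pools, ``c[l]`` for
    ``2 <= l < L`` the polymer ladder, ``c[L]`` the completed rings."""

    c: np.ndarray
    t: float

    def mass(self, L: int) -> float:
        w = np.arange(L + 1, dtype=float)
        w[0] = 1.0
        return float(w @ self.c)


def _growth_rates(config: AssemblyConfig) -> np.ndarray:
    nu_l = np.full(config.L, config.nu)
    nu_l[0] = 0.0
    for l in range(1, config.Lnuc):
        nu_l[l] = config.mu_vec[l - 1]
    return nu_l


def rhs(c: np.ndarray, config: AssemblyConfig, nu_l: np.ndarray | None = None) -> np.ndarray:
    """Time derivative of the concentration vector ``[c0, c1, c2..cL]``.

    Conserves mass identically: ``d/dt (c0 + c1 + sum l*c_l + L*cL) = 0``.
    """
    L, Lnuc = config.L, config.Lnuc
    if nu_l is None:
        nu_l = _growth_rates(config)
    alpha = 0.0 if config.all_active else config.alpha
    c0, c1 = c[0], c[1]
    dc = np.zeros_like(c)
    dc[0] = -alpha * c0
    # loss of active monomers to dimerization (2 per event) and growth
    total_binding = nu_l[1] * c1 + (nu_l[2:L] * c[2:L]).sum() if L > 2 else nu_l[1] * c1
    dc[1] = alpha * c0 - 2.0 * c1 * total_binding
    for l in range(2, Lnuc):
        dc[1] += l * config.delta_vec[l - 2] * c[l]
    if L == 2:
        dc[2] = nu_l[1] * c1 * c1
        return dc
    dc[2] = nu_l[1] * c1 * c1 - 2.0 * nu_l[2] * c1 * c[2]
    if Lnuc > 2:
        dc[2] -= config.delta_vec[0] * c[2]
    for l in range(3, L):
        dc[l] = 2.0 * c1 * (nu_l[l - 1] * c[l - 1] - nu_l[l] * c[l])
        if l < Lnuc:
            dc[l] -= config.delta_vec[l - 2] * c[l]
    dc[L] = 2.0 * nu_l[L - 1] * c1 * c[L - 1]
    return dc


@dataclass
class ODEResult:
    """Deterministic trajectory: concentration ladder and yield over time."""

    t: np.ndarray
    c: np.ndarray              # shape (n_t, L + 1)
    yield_series: np.ndarray
    final_yield: float
    steady: bool
    config: AssemblyConfig

    def profile_at(self, t: float) -> ConcentrationProfile:
        idx = int(np.searchsorted(self.t, t))
        idx = min(idx, len(self.t) - 1)
        return ConcentrationProfile(self.c[idx], float(self.t[idx]))


def integrate_ode(config: AssemblyConfig, t_final="auto", snapshot_times=None,
                  rtol: float = 1e-9, atol: float = 1e-13) -> ODEResult:
    """Integrate the reduced mean-field ladder to its steady state.

    ``t_final="auto"`` doubles the horizon geometrically until the free
    monomer pools fall below ``EPS_STEADY * C`` (after which nothing moves);
    a numeric ``t_final`` integrates exactly that far.  ``snapshot_times``
    are merged into the output grid so polymer-size "wave" profiles can be
    read off at matched times.
    """
    config = validate_config(config)
    L, C = config.L, config.C
    nu_l = _growth_rates(config)
    c0 = np.zeros(L + 1)
    if config.all_active:
        c0[1] = C
    else:
        c0[0] = C

    def f(t, y):
        return rhs(y, config, nu_l)

    def steady_event(t, y):
        return y[0] + y[1] - EPS_STEADY * C

    steady_event.terminal = True
    steady_event.direction = -1

    rate_scale = max(config.nu * C, (0.0 if config.all_active else config.alpha), 1e-30)
    if t_final == "auto":
        horizon = 100.0 / rate_scale
        if not config.all_active and config.alpha > 0:
            horizon = max(horizon, 30.0 / config.alpha)
        cap = 1e18 / rate_scale
    else:
        horizon = float(t_final)
        cap = horizon

    ts, cs = [], []
    t_start, y_start = 0.0, c0
    steady = False
    snap = (np.asarray(snapshot_times, dtype=float)
            if snapshot_times is not None else None)
    while True:
        sol = solve_ivp(f, (t_start, horizon), y_start, method="LSODA",
                        rtol=rtol, atol=atol, events=steady_event,
                        dense_output=True)
        if not sol.success:
            raise RuntimeError(f"mean-field integration failed: {sol.message}")
        ts.append(sol.t)
        cs.append(sol.y.T)
        if snap is not None:
            # merge requested snapshot times into the natural output grid
            t_hi = sol.t_events[0][0] if sol.t_events[0].size else sol.t[-1]
            extra = snap[(snap >= sol.t[0]) & (snap <= t_hi)]
            if extra.size:
                ts.append(extra)
                cs.append(sol.sol(extra).T)
        if sol.t_events[0].size > 0:
            tev = sol.t_events[0][0]
            ts.append(np.array([tev]))
            cs.append(sol.y_events[0])
            steady = True
            break
        t_start = sol.t[-1]
        y_start = sol.y[:, -1]
        if horizon >= cap or t_final != "auto":
            break
        horizon = min(horizon * 10.0, cap)

    t = np.concatenate(ts)
    c = np.vstack(cs)
    order = np.argsort(t, kind="stable")
    t, c = t[order], c[order]
    yields = c[:, L] * L / C
    return ODEResult(t=t, c=c, yield_series=yields,
                     final_yield=float(yields[-1]), steady=steady, config=config)


def integrate_full_heterogeneous(config: AssemblyConfig, t_final="auto",
                                 rtol: float = 1e-9, atol: float = 1e-13) -> ODEResult:
    """Species-resolved mean-field system (verification mode).

    Integrates all ``S*(L+1)`` coupled equations without assuming the
    relabelling symmetry; by that symmetry the result must coincide with
    :func:`integrate_ode` for any ``S``, which the tests exploit as an
    S-independence check.  Returns the species-averaged ladder.
    """
    config = validate_config(config)
    S, L, C = config.S, config.L, config.C
    nu_l = _growth_rates(config)
    alpha = 0.0 if config.all_active else config.alpha
    Lnuc = config.Lnuc

    # state layout: x0[s], x1[s], xl[l-2, s] for 2 <= l < L, xL (total rings / S)
    def unpack(y):
        x0 = y[:S]
        x1 = y[S:2 * S]
        xl = y[2 * S:2 * S + (L - 2) * S].reshape(L - 2, S)
        xL = y[-1]
        return x0, x1, xl, xL

    def f(t, y):
        x0, x1, xl, xL = unpack(y)
        d0 = -alpha * x0
        d1 = alpha * x0
        dl = np.zeros_like(xl)
        # dimerization: monomer s + monomer s+1 -> dimer with left end s
        dim = nu_l[1] * x1 * np.roll(x1, -1)
        d1 -= dim + np.roll(dim, 1)
        if L > 2:
            dl[0] += dim
        else:
            return np.concatenate([d0, d1, dl.ravel(), [dim.sum() / S]])
        dLr = 0.0
        for l in range(2, L):
            row = xl[l - 2]
            # right attachment consumes monomer species s+l; left s-1
            gr_r = nu_l[l] * row * np.roll(x1, -l)
            gr_l = nu_l[l] * row * np.roll(x1, 1)
            d1 -= np.roll(gr_r, l) + np.roll(gr_l, -1)
            dl[l - 2] -= gr_r + gr_l
            if l + 1 < L:
                dl[l - 1] += gr_r          # left end unchanged
                dl[l - 1] += np.roll(gr_l, -1)  # new left end s-1
            else:
                dLr += gr_r.sum() + gr_l.sum()
            if l < Lnuc:
                dec = config.delta_vec[l - 2] * row
                dl[l - 2] -= dec
                for k in range(l):
                    d1 += np.roll(dec, k)  # monomer species s+k regains dec[s]
        return np.concatenate([d0, d1, dl.ravel(), [dLr / S]])

    y0 = np.zeros(2 * S + (L - 2) * S + 1)
    if config.all_active:
        y0[S:2 * S] = C
    else:
        y0[:S] = C

    def steady_event(t, y):
        return y[:2 * S].sum() / S - EPS_STEADY * C

    steady_event.terminal = True
    steady_event.direction = -1

    rate_scale = max(config.nu * C, alpha, 1e-30)
    horizon = 100.0 / rate_scale
    if alpha > 0:
        horizon = max(horizon, 30.0 / alpha)
    cap = 1e18 / rate_scale if t_final == "auto" else float(t_final)
    if t_final != "auto":
        horizon = cap

    ts, cs = [], []
    t_start, y_start = 0.0, y0
    steady = False
    while True:
        sol = solve_ivp(f, (t_start, horizon), y_start, method="LSODA",
                        rtol=rtol, atol=atol, events=steady_event)
        if not sol.success:
            raise RuntimeError(f"heterogeneous mean-field integration failed: {sol.message}")
        ts.append(sol.t)
        cs.append(sol.y.T)
        if sol.t_events[0].size > 0:
            steady = True
            break
        t_start, y_start = sol.t[-1], sol.y[:, -1]
        if horizon >= cap:
            break
        horizon = min(horizon * 10.0, cap)

    t = np.concatenate(ts)
    y = np.vstack(cs)
    # species-averaged ladder in the reduced layout
    c = np.zeros((len(t), L + 1))
    c[:, 0] = y[:, :S].mean(axis=1)
    c[:, 1] = y[:, S:2 * S].mean(axis=1)
    for l in range(2, L):
        c[:, l] = y[:, 2 * S + (l - 2) * S: 2 * S + (l - 1) * S].mean(axis=1)
    c[:, L] = y[:, -1]
    yields = c[:, L] * L / C
    return ODEResult(t=t, c=c, yield_series=yields,
                     final_yield=float(yields[-1]), steady=steady, config=config)
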