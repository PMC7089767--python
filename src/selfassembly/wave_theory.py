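"""Effective wave description and closed-form yield thresholds.

For ``Lnuc = 2`` the polymer ladder behaves as an advection-diffusion wave
in size space ``x in [2, L]``::

    dc/dt = -2 nu A dc/dx + nu A d2c/dx2

with drift ``2 nu A(t)`` and diffusion ``nu A(t)`` set by the instantaneous
active-monomer concentration, a Robin influx boundary
``2 nu A c(2) - nu A dc/dx(2) = mu A**2`` (dimer formation) and an absorbing
boundary ``c(L) = 0`` (ring completion).  Yield sets in once the travelled
distance reaches the far boundary, which reduces the whole problem to the
integral ``g(omega, eta) = int_0^inf A dtau`` of the dimensionless
two-component system::

    dA/dtau = omega e**(-omega tau) - 2 eta A**2 - 2 A B
    dB/dtau = eta A**2

where ``A, B`` are the active-monomer and total-polymer concentrations in
units of ``C``, ``tau = nu C t``, ``omega = alpha/(nu C)`` and
``eta = mu/nu``.  In the slow-nucleation limits the integral has closed
forms whose insertion into the onset condition yields the threshold rates

    alpha_th = P_alpha * (nu/mu) * nu C / (L - sqrt(L))**3,
    mu_th    = P_mu * nu / (L - sqrt(L))**2,

with ``P_alpha = [Gamma(1/2)*Gamma(2/3)/Gamma(7/6)]**3 / 3 ~ 5.77`` and
``P_mu = pi**2/2 ~ 4.93``.  (``P_alpha`` follows from the activation-limit
quadrature ``g = a*(omega*eta)**(-1/3)`` with ``a = 3**(2/3)*sqrt(pi)*
Gamma(2/3)/(6*Gamma(7/6))``: under quasi-steady state ``A = omega*
exp(-omega*tau)/(2B)`` one finds ``B**3 = (3*eta*omega/8)*(1-exp(-2*omega*
tau))`` and ``g = (8/(3*eta*omega))**(1/3) * B(1/2, 2/3)/4`` with the Euler
beta function, whence ``P_alpha = 8*a**3``.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.special import gamma as _gamma

from .core_types import AssemblyConfig, validate_config

__all__ = [
    "P_ALPHA", "P_MU", "wave_amplitude_coefficient", "ReducedResult",
    "integrate_reduced", "asymptotic_g", "OnsetResult", "onset_condition",
    "threshold_distance", "threshold_alpha", "threshold_mu", "onset_omega",
    "PDEResult", "pde_wave",
]

#: coefficient a in the activation-limit travelled distance 2*a*(omega*eta)^(-1/3)
wave_amplitude_coefficient = (3 ** (2 / 3) * math.sqrt(math.pi) * _gamma(2 / 3)
                              / (6 * _gamma(7 / 6)))

#: proportionality constant of the activation-rate threshold, 8*a**3 ~ 5.77
P_ALPHA = (math.sqrt(math.pi) * _gamma(2 / 3) / _gamma(7 / 6)) ** 3 / 3

#: proportionality constant of the dimerization-rate threshold, 4*(pi/(2*sqrt(2)))**2
P_MU = math.pi ** 2 / 2

#: the g-integral tail is cut once A drops below this and extrapolated
#: exponentially from the local decay rate
A_TAIL = 1e-12


@dataclass
class ReducedResult:
    """Solution of the dimensionless two-component system."""

    tau: np.ndarray
    A: np.ndarray
    B: np.ndarray
    g: float              # converged quadrature of A, including the tail
    omega: float
    eta: float
    scenario: str

    @property
    def travelled_distance(self) -> float:
        """Advective distance of the wave in size space, ``2*g``."""
        return 2.0 * self.g


def integrate_reduced(omega: float, eta: float = 1.0,
                      scenario: str = "activation",
                      rtol: float = 1e-10, atol: float = 1e-14) -> ReducedResult:
    """Integrate the reduced (A, B) system and the quadrature ``g``.

    ``scenario="activation"`` keeps the activation source ``omega *
    exp(-omega tau)`` with ``A(0) = 0`` (finite ``omega``; ``eta < 1`` gives
    the mixed scenario).  ``scenario="dimerization"`` drops the source and
    starts from ``A(0) = 1, B(0) = 0`` (all monomers active).  Integration
    runs until ``A < A_TAIL``; the remaining exponential tail ``A/k`` with
    ``k = 2*eta*A + 2*B`` is added to ``g``.
    """
    if scenario not in ("activation", "dimerization"):
        raise ValueError("scenario must be 'activation' or 'dimerization'")
    act = scenario == "activation"
    if act and omega <= 0:
        raise ValueError("activation scenario requires omega > 0")
    if eta < 0:
        raise ValueError("eta must be non-negative")

    def f(tau, y):
        A, B, G = y
        src = omega * math.exp(-omega * tau) if act else 0.0
        return [src - 2 * eta * A * A - 2 * A * B, eta * A * A, A]

    def tail_event(tau, y):
        return y[0] - A_TAIL

    tail_event.terminal = True
    tail_event.direction = -1

    y0 = [0.0, 0.0, 0.0] if act else [1.0, 0.0, 0.0]
    horizon = 100.0 / omega if act else 100.0 / max(math.sqrt(2 * eta), 1e-12)
    taus, ys = [], []
    t_start = 0.0
    converged = False
    for _ in range(60):
        sol = solve_ivp(f, (t_start, horizon), y0, method="LSODA",
                        rtol=rtol, atol=atol, events=tail_event)
        if not sol.success:
            raise RuntimeError(f"reduced-system integration failed: {sol.message}")
        taus.append(sol.t)
        ys.append(sol.y.T)
        if sol.t_events[0].size:
            taus.append(sol.t_events[0])
            ys.append(sol.y_events[0])
            converged = True
            break
        t_start = sol.t[-1]
        y0 = sol.y[:, -1]
        horizon *= 10.0
    if not converged:
        raise RuntimeError("g-integral tail did not converge")
    tau = np.concatenate(taus)
    y = np.vstack(ys)
    A_end, B_end, G_end = y[-1]
    k = 2 * eta * A_end + 2 * B_end
    g = float(G_end + (A_end / k if k > 0 else 0.0))
    return ReducedResult(tau=tau, A=y[:, 0], B=y[:, 1], g=g,
                         omega=omega if act else math.inf, eta=eta,
                         scenario=scenario)


def asymptotic_g(omega: float, eta: float, scenario: str = "activation") -> float:
    """Closed-form slow-nucleation limits of ``g``.

    Activation (``omega << 1``): ``2 g = 2 a (omega*eta)**(-1/3)`` with
    ``a = 3**(2/3) pi Gamma(2/3) / (6 Gamma(7/6))``.
    Dimerization (``eta << 1``): ``2 g = (pi / sqrt(2)) * eta**(-1/2)``.
    """
    if scenario == "activation":
        return wave_amplitude_coefficient * (omega * eta) ** (-1 / 3)
    if scenario == "dimerization":
        return math.pi / (2 * math.sqrt(2)) * eta ** (-1 / 2)
    raise ValueError("scenario must be 'activation' or 'dimerization'")


def threshold_distance(L: int, exact: bool = True) -> float:
    """Distance the wave must travel for yield onset.

    The exact requirement (advection plus diffusive broadening covering
    ``L - 2``) is ``(sqrt(1 + 4(L-2)) - 1)**2 / 4``; for large ``L`` this
    approaches ``L - sqrt(L)``.
    """
    if L < 3:
        raise ValueError("threshold distance needs L >= 3")
    if exact:
        return 0.25 * (math.sqrt(1.0 + 4.0 * (L - 2)) - 1.0) ** 2
    return L - math.sqrt(L)


@dataclass
class OnsetResult:
    """Outcome of the wave-arrival criterion for nonzero yield."""

    reached: bool
    distance: float            # 2 * nu * g
    threshold_exact: float     # (sqrt(1+4(L-2))-1)^2 / 4
    threshold_approx: float    # L - sqrt(L)
    margin: float              # distance - threshold_exact
    rel_gap: float             # |exact - approx| / exact


def onset_condition(g: float, nu: float, L: int) -> OnsetResult:
    """Check whether the size-distribution wave reaches the target size.

    Nonzero deterministic yield requires ``2 nu g`` to exceed the threshold
    distance.  (With ``g`` from :func:`integrate_reduced`, which uses units
    ``nu C = 1``, pass ``nu = 1``.)
    """
    if g < 0:
        raise ValueError("g must be non-negative")
    d = 2.0 * nu * g
    exact = threshold_distance(L, exact=True)
    approx = threshold_distance(L, exact=False)
    return OnsetResult(reached=d >= exact, distance=d, threshold_exact=exact,
                       threshold_approx=approx, margin=d - exact,
                       rel_gap=abs(exact - approx) / exact)


def threshold_alpha(L: int, C: float = 1.0, nu: float = 1.0,
                    mu: float | None = None) -> float:
    """Activation-rate threshold ``P_alpha (nu/mu) nu C / (L - sqrt(L))**3``.

    Below this rate the deterministic wave reaches size ``L`` and nonzero
    yield is produced; scales linearly with the concentration ``C`` and is
    enhanced by slow dimerization (``mu < nu``)."""
    if L < 3 or nu <= 0 or C <= 0:
        raise ValueError("need L >= 3 and positive rates")
    mu = nu if mu is None else mu
    if mu <= 0:
        raise ValueError("mu must be positive")
    return P_ALPHA * (nu / mu) * nu * C / (L - math.sqrt(L)) ** 3


def threshold_mu(L: int, nu: float = 1.0) -> float:
    """Dimerization-rate threshold ``P_mu nu / (L - sqrt(L))**2``
    (independent of the concentration ``C``)."""
    if L < 3 or nu <= 0:
        raise ValueError("need L >= 3 and positive nu")
    return P_MU * nu / (L - math.sqrt(L)) ** 2


def onset_omega(L: int, eta: float = 1.0, exact_distance: bool = True,
                bracket=(1e-10, 10.0)) -> float:
    """Numerically invert the onset condition for the activation scenario.

    Returns the dimensionless activation rate ``omega = alpha/(nu C)`` at
    which ``2 g(omega, eta)`` equals the threshold distance; ``g`` decreases
    monotonically with ``omega``, so the root is unique."""
    d_th = threshold_distance(L, exact=exact_distance)

    def f(log_om):
        return 2.0 * integrate_reduced(math.exp(log_om), eta).g - d_th

    lo, hi = math.log(bracket[0]), math.log(bracket[1])
    return math.exp(brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))


@dataclass
class PDEResult:
    """Finite-volume solution of the size-space advection-diffusion wave."""

    x: np.ndarray                  # cell centres in [2, L]
    times: np.ndarray
    profiles: np.ndarray           # shape (n_times, n_cells)
    influx_cum: np.ndarray         # integral of mu A^2 up to each time
    outflux_cum: np.ndarray        # mass absorbed at x = L up to each time
    advective_distance: np.ndarray  # 2 nu int_0^t A dt'

    def centre_of_mass(self, k: int) -> float:
        p = self.profiles[k]
        m = p.sum()
        return float((self.x * p).sum() / m) if m > 0 else math.nan


def pde_wave(config: AssemblyConfig | None, times, dx: float = 0.25,
             A_of_t=None, initial=None, nu: float | None = None,
             mu: float | None = None, L: int | None = None,
             cfl: float = 0.4) -> PDEResult:
    """Solve the advection-diffusion wave ``dc/dt = -2 nu A c_x + nu A c_xx``.

    The active-monomer history ``A(t)`` is taken from the mean-field ladder
    of ``config`` (its ``c_1``) unless ``A_of_t`` is supplied directly.
    Upwind advection and central diffusion on a uniform finite-volume grid;
    the time step honours both CFL limits with the coefficients frozen per
    step.  ``initial`` seeds a starting profile (defaults to empty);
    ``mu = 0`` switches off the influx boundary, leaving pure transport of
    the initial profile -- handy for checking the advective displacement
    against ``2 nu int A dt``.
    """
    if config is not None:
        config = validate_config(config)
        if config.Lnuc != 2:
            raise ValueError("the wave description assumes Lnuc = 2")
        L = config.L
        nu = config.nu
        mu = config.mu_vec[0] if mu is None else mu
        if A_of_t is None:
            from .mean_field_ode import integrate_ode
            ode = integrate_ode(config)
            tgrid, c1 = ode.t, ode.c[:, 1]

            def A_of_t(t):  # noqa: F811 - deliberate closure
                return float(np.interp(t, tgrid, c1))
    if A_of_t is None or L is None or nu is None:
        raise ValueError("need either config or (A_of_t, L, nu, mu)")
    mu = 0.0 if mu is None else mu

    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted")
    M = max(int(round((L - 2) / dx)), 4)
    dx = (L - 2) / M
    x = 2.0 + (np.arange(M) + 0.5) * dx
    c = np.zeros(M)
    if initial is not None:
        c[:] = np.asarray(initial, dtype=float)

    profiles = np.zeros((len(times), M))
    influx = np.zeros(len(times))
    outflux = np.zeros(len(times))
    dadv = np.zeros(len(times))
    t = 0.0
    cum_in = cum_out = cum_adv = 0.0
    for k, t_target in enumerate(times):
        t_span_floor = max(times[-1], 1e-12) / 4096.0
        while t < t_target:
            A = max(A_of_t(t), 0.0)
            if A * nu <= 1e-300:
                # nothing moves while A = 0, but A may switch on inside the
                # interval: probe forward in small bounded steps
                t += min(t_target - t, t_span_floor)
                continue
            dt = cfl * min(dx / (2 * nu * A), dx * dx / (2 * nu * A))
            dt = min(dt, t_target - t)
            adv = 2 * nu * A
            dif = nu * A
            # fluxes at the M+1 cell faces
            J = np.empty(M + 1)
            J[0] = mu * A * A
            J[1:M] = adv * c[:-1] - dif * (c[1:] - c[:-1]) / dx
            J[M] = adv * c[-1] + dif * c[-1] / dx  # absorbing: ghost value 0
            c += dt / dx * (J[:-1] - J[1:])
            np.maximum(c, 0.0, out=c)
            cum_in += mu * A * A * dt
            cum_out += J[M] * dt
            cum_adv += adv * dt
            t += dt
        profiles[k] = c
        influx[k] = cum_in
        outflux[k] = cum_out
        dadv[k] = cum_adv
    return PDEResult(x=x, times=times, profiles=profiles, influx_cum=influx,
                     outflux_cum=outflux, advective_distance=dadv)
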