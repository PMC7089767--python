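"""Parameter sweeps over the simulators and theory.

Reproduces the headline phenomenology from parameters alone: yield-vs-rate
curves (stochastic mean +- std against the deterministic line), the
saturation yield ``y_max`` of the small-activation-rate plateau, the
``y_max(N, L)`` phase diagram of the stochastic yield catastrophe, and the
power-law scaling of the particle-number threshold for nonzero yield.

The ``alpha -> 0`` limit is operationalized by the decade-halving rule:
the activation rate is decreased by factors of ten until the ensemble-mean
yield changes by less than ``tol`` (default 0.01) between consecutive
decades; the last mean is reported as ``y_max``.  "Nonzero yield" in the
stochastic threshold search needs an operational cutoff, which the model
definition does not supply: here at least one completed structure in at
least ``frac`` (default 5%) of the runs; the fit reports the exponent for a
range of cutoffs so its sensitivity is visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_types import AssemblyConfig, EnsembleSummary, validate_config
from .mean_field_ode import integrate_ode
from .ring_gillespie import run_ensemble, run_ssa, spawn_seeds
from .variant_models import run_ssa_pp, run_ssa_square
from .wave_theory import threshold_alpha

__all__ = ["SweepResult", "runner_for", "yield_curve", "estimate_ymax",
           "phase_diagram", "threshold_N_nonzero_yield",
           "fit_powerlaw", "fit_threshold_exponent"]


def runner_for(config: AssemblyConfig):
    """Trajectory runner matching ``config.variant``."""
    return {"ring": run_ssa,
            "ring_polymer_polymer": run_ssa_pp,
            "square": run_ssa_square}[config.variant]


@dataclass
class SweepResult:
    """Tidy grid of ensemble summaries, one row per evaluated cell."""

    rows: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def add(self, summary: EnsembleSummary | None, **cell):
        row = dict(cell)
        if summary is not None:
            row.update(mean_yield=summary.mean_yield, std_yield=summary.std_yield,
                       stderr=summary.stderr, n_runs=summary.n_realizations,
                       seed_root=summary.seed_root)
        self.rows.append(row)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def yield_curve(config_base: AssemblyConfig, param: str, grid, n_runs: int,
                seed_root: int = 0, include_ode: bool = True,
                **runner_kwargs) -> SweepResult:
    """Stochastic mean +- std (and deterministic yield) along a rate grid.

    ``param`` is ``"alpha"`` or ``"mu"``; every grid point gets an
    independently spawned seed block so the sweep is reproducible from
    ``seed_root`` alone.
    """
    if param not in ("alpha", "mu"):
        raise ValueError("param must be 'alpha' or 'mu'")
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be sorted ascending")
    config_base = validate_config(config_base)
    result = SweepResult(metadata={"param": param, "variant": config_base.variant,
                                   "seed_root": seed_root, "n_runs": n_runs})
    runner = runner_for(config_base)
    cell_seeds = spawn_seeds(seed_root, len(grid))
    for value, cell_seed in zip(grid, cell_seeds):
        cfg = replace(config_base, **{param: float(value)})
        summary = run_ensemble(cfg, n_runs, int(cell_seed), runner=runner,
                               **runner_kwargs)
        ode_yield = math.nan
        if include_ode and cfg.variant == "ring":
            ode_yield = integrate_ode(cfg).final_yield
        result.add(summary, **{param: float(value)}, ode_yield=ode_yield)
    return result


def estimate_ymax(config: AssemblyConfig, n_runs: int, seed_root: int = 0,
                  alpha_start: float | None = None, tol: float = 0.01,
                  max_decades: int = 10, screen_runs: int | None = None,
                  **runner_kwargs):
    """Saturation yield of the small-activation-rate plateau.

    Starting from ``alpha_start`` (default: one decade below the
    deterministic threshold ``alpha_th``), the activation rate is lowered by
    decades until the ensemble mean changes by less than ``tol``; the plateau
    is then re-evaluated with the full ``n_runs`` ensemble.  ``screen_runs``
    (default ``n_runs``) controls the ensemble size used during the decade
    scan.  Returns ``(y_max, diagnostics)``.
    """
    config = validate_config(config)
    if config.all_active:
        raise ValueError("the saturation plateau is defined for finite alpha")
    runner = runner_for(config)
    if alpha_start is None:
        mu1 = float(config.mu_vec[0])
        alpha_start = 0.1 * threshold_alpha(config.L, config.C, config.nu, mu1)
    screen_runs = n_runs if screen_runs is None else screen_runs

    alphas, means = [], []
    alpha = float(alpha_start)
    seeds = spawn_seeds(seed_root, max_decades + 1)
    prev = None
    for d in range(max_decades):
        cfg = replace(config, alpha=alpha)
        m = run_ensemble(cfg, screen_runs, int(seeds[d]), runner=runner,
                         **runner_kwargs).mean_yield
        alphas.append(alpha)
        means.append(m)
        if prev is not None and abs(m - prev) < tol:
            break
        prev = m
        alpha /= 10.0
    final_alpha = alphas[-1]
    if screen_runs != n_runs:
        cfg = replace(config, alpha=final_alpha)
        summary = run_ensemble(cfg, n_runs, int(seeds[max_decades]),
                               runner=runner, **runner_kwargs)
        ymax = summary.mean_yield
    else:
        summary = None
        ymax = means[-1]
    diag = {"alphas": alphas, "means": means, "alpha_plateau": final_alpha,
            "plateaued": len(means) > 1 and abs(means[-1] - means[-2]) < tol,
            "summary": summary}
    return ymax, diag


def phase_diagram(L_grid, N_grid, n_runs: int, seed_root: int = 0,
                  alpha="auto", tol: float = 0.01) -> SweepResult:
    """Saturation yield ``y_max`` over an ``(N, L)`` grid for the fully
    heterogeneous system ``S = L`` in the small-activation-rate limit.

    ``alpha="auto"`` applies the decade-halving rule per cell; a numeric
    ``alpha`` (interpreted as a fraction of each cell's ``alpha_th``) uses a
    single deep-plateau evaluation, which is much cheaper on large grids.
    """
    result = SweepResult(metadata={"seed_root": seed_root, "n_runs": n_runs,
                                   "alpha": alpha})
    cells = [(int(L), int(N)) for L in L_grid for N in N_grid]
    seeds = spawn_seeds(seed_root, len(cells))
    for (L, N), cell_seed in zip(cells, seeds):
        cfg = AssemblyConfig(S=L, L=L, N=N)
        if alpha == "auto":
            ymax, diag = estimate_ymax(cfg, n_runs, int(cell_seed), tol=tol)
            result.add(diag["summary"], L=L, N=N, y_max=ymax,
                       alpha_plateau=diag["alpha_plateau"])
        else:
            a = float(alpha) * threshold_alpha(L)
            summary = run_ensemble(replace(cfg, alpha=a), n_runs, int(cell_seed))
            result.add(summary, L=L, N=N, y_max=summary.mean_yield, alpha_plateau=a)
    return result


def threshold_N_nonzero_yield(L: int, n_runs: int = 64, frac: float = 0.05,
                              seed_root: int = 0, alpha_factor: float = 1e-3,
                              N_max: int = 1_000_000):
    """Smallest particle number with nonzero yield at ``S = L``, ``alpha -> 0``.

    A particle number "produces yield" when at least one complete ring forms
    in at least ``frac`` of ``n_runs`` seeded runs; the simulations use
    ``alpha = alpha_factor * alpha_th(L)``, deep inside the stochastic
    plateau.  Geometric bracketing doubles ``N`` until success, then integer
    bisection localizes the threshold.  Returns ``(N_th, cache)`` where
    ``cache`` maps each evaluated ``N`` to its success fraction (reusable for
    other cutoffs).
    """
    alpha = alpha_factor * threshold_alpha(L)
    cache: dict[int, float] = {}

    def success_frac(N: int) -> float:
        if N not in cache:
            cfg = AssemblyConfig(S=L, L=L, N=N, alpha=alpha)
            seeds = spawn_seeds(seed_root * 1_000_003 + N, n_runs)
            hits = 0
            for s in seeds:
                hits += run_ssa(cfg, int(s)).final_yield > 0
            cache[N] = hits / n_runs
        return cache[N]

    N = 1
    while success_frac(N) < frac:
        N *= 2
        if N > N_max:
            raise RuntimeError(f"no nonzero yield up to N={N_max} for L={L}")
    lo, hi = N // 2, N  # success_frac(lo) < frac <= success_frac(hi)
    if lo == 0:
        return 1, cache
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if success_frac(mid) >= frac:
            hi = mid
        else:
            lo = mid
    return hi, cache


def fit_powerlaw(L_values, N_values):
    """Least-squares slope of ``log N`` vs ``log L`` with its standard error.

    Returns ``(slope, stderr)``; the slope is invariant under rescaling of
    ``N`` by a constant (a pure offset in log space).
    """
    x = np.log(np.asarray(L_values, dtype=float))
    y = np.log(np.asarray(N_values, dtype=float))
    if len(x) < 3:
        raise ValueError("need at least 3 points for a slope with error")
    A = np.vstack([x, np.ones_like(x)]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    dof = len(x) - 2
    s2 = float(res[0]) / dof if res.size else 0.0
    cov = s2 * np.linalg.inv(A.T @ A)
    return float(coef[0]), float(math.sqrt(max(cov[0, 0], 0.0)))


def fit_threshold_exponent(L_grid, n_runs: int = 64, seed_root: int = 0,
                           frac: float = 0.05, extra_fracs=(0.02, 0.1),
                           alpha_factor: float = 1e-3):
    """Power-law exponent of the nonzero-yield threshold, ``N_th ~ L**xi``.

    Runs the threshold search for every ``L`` in ``L_grid`` and fits the
    log-log slope.  The cached per-``N`` success fractions are re-thresholded
    at ``extra_fracs`` to report the cutoff sensitivity without extra
    simulation (bisection holes are filled conservatively).  Returns a dict
    with ``xi``, ``xi_stderr``, ``N_th`` and ``sensitivity``.
    """
    L_grid = [int(L) for L in L_grid]
    if len(L_grid) < 4:
        raise ValueError("need at least 4 target sizes for the exponent fit")
    N_th, caches = [], []
    for L in L_grid:
        nth, cache = threshold_N_nonzero_yield(
            L, n_runs=n_runs, frac=frac, seed_root=seed_root,
            alpha_factor=alpha_factor)
        N_th.append(nth)
        caches.append(cache)
    xi, err = fit_powerlaw(L_grid, N_th)

    sensitivity = {}
    for f in extra_fracs:
        alt = []
        for cache in caches:
            Ns = sorted(cache)
            above = [N for N in Ns if cache[N] >= f]
            alt.append(above[0] if above else max(Ns))
        try:
            xi_f, _ = fit_powerlaw(L_grid, alt)
        except (ValueError, FloatingPointError):
            xi_f = math.nan
        sensitivity[f] = xi_f
    return {"xi": xi, "xi_stderr": err, "L": L_grid, "N_th": N_th,
            "sensitivity": sensitivity}
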