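"""Exact stochastic simulation of the heterogeneous ring model.

The master equation is simulated with Gillespie's algorithm: waiting times
are exponential in the total propensity and the next reaction is chosen with
probability proportional to its propensity.  The reaction channels are

* activation of an inactive monomer of species ``s`` at ``alpha * n0[s]``,
* dimerization of active monomers of consecutive species at
  ``(mu_1/V) * n1[s] * n1[s+1]`` (``(mu_1/V) * n1 * (n1-1)`` for ``S = 1``,
  so that the mean-field gain is ``mu_1 * c1**2``),
* attachment of an active monomer to the right end (species ``s + l``) or
  left end (species ``s - 1``) of a polymer ``(s, l)`` at
  ``(rate_l/V) * n1 * n_l``, with ``rate_l = mu_l`` below the nucleation size
  and ``nu`` above; attachment to a polymer of length ``L - 1`` closes a
  ring, the absorbing state,
* decay of a sub-nucleation polymer at ``delta_l * n_l``, returning its
  monomers to the active pools.

:func:`run_ssa` uses the compiled kernel in :mod:`selfassembly._kernels`;
:func:`propensities` and :func:`reference_ssa` are a deliberately simple
pure-Python enumeration of the same chemistry, kept as an independent oracle
for the kernel's bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .core_types import (
    AssemblyConfig,
    EnsembleSummary,
    RingState,
    Trajectory,
    validate_config,
    yield_of,
)

__all__ = [
    "ReactionChannel",
    "propensities",
    "apply_channel",
    "run_ssa",
    "run_ensemble",
    "reference_ssa",
    "spawn_seeds",
]


@dataclass
class ReactionChannel:
    """One reaction channel of the chemical network.

    ``kind`` is one of ``activation``, ``dimerization``, ``attach_left``,
    ``attach_right``, ``decay``, ``ring_closure`` (attachment that completes
    a ring), or ``join``/``join_closure`` (polymer-polymer variant).
    ``(s, l)`` index the structure acted on; ``(s2, l2)`` the partner where
    applicable.
    """

    kind: str
    s: int = -1
    l: int = 0
    s2: int = -1
    l2: int = 0
    propensity: float = 0.0


def propensities(state: RingState, config: AssemblyConfig) -> list[ReactionChannel]:
    """Enumerate all channels with positive propensity for the ring model.

    At a final state (for ``Lnuc = 2``: no monomers left that could move)
    the list is empty and the simulation is absorbed.
    """
    S, L, V = config.S, config.L, config.V
    n0, n1, npoly = state.n_inactive, state.n_active, state.n_poly
    channels: list[ReactionChannel] = []
    if not config.all_active:
        for s in range(S):
            if n0[s] > 0 and config.alpha > 0:
                channels.append(ReactionChannel("activation", s=s,
                                                propensity=config.alpha * n0[s]))
    mu1 = config.mu_vec[0]
    for s in range(S):
        if S == 1:
            p = mu1 / V * n1[0] * (n1[0] - 1)
        else:
            p = mu1 / V * n1[s] * n1[(s + 1) % S]
        if p > 0:
            kind = "ring_closure" if L == 2 else "dimerization"
            channels.append(ReactionChannel(kind, s=s, s2=(s + 1) % S, propensity=p))
    for l in range(2, L):
        rate = config.rate_of_size(l)
        for s in range(S):
            if npoly[l, s] == 0:
                continue
            kind = "ring_closure" if l + 1 == L else None
            m_r = (s + l) % S
            p = rate / V * n1[m_r] * npoly[l, s]
            if p > 0:
                channels.append(ReactionChannel(kind or "attach_right", s=s, l=l,
                                                s2=m_r, propensity=p))
            m_l = (s - 1) % S
            p = rate / V * n1[m_l] * npoly[l, s]
            if p > 0:
                channels.append(ReactionChannel(kind or "attach_left", s=s, l=l,
                                                s2=m_l, propensity=p))
            if l < config.Lnuc:
                p = config.delta_vec[l - 2] * npoly[l, s]
                if p > 0:
                    channels.append(ReactionChannel("decay", s=s, l=l, propensity=p))
    return channels


def apply_channel(state: RingState, ch: ReactionChannel, config: AssemblyConfig) -> None:
    """Execute one reaction, mutating ``state`` (used by the reference SSA)."""
    S, L = config.S, config.L
    if ch.kind == "activation":
        state.n_inactive[ch.s] -= 1
        state.n_active[ch.s] += 1
    elif ch.kind == "dimerization" or (ch.kind == "ring_closure" and L == 2 and ch.l == 0):
        state.n_active[ch.s] -= 1
        state.n_active[ch.s2] -= 1
        if L == 2:
            state.n_rings += 1
        else:
            state.n_poly[2, ch.s] += 1
    elif ch.kind in ("attach_right", "attach_left") or ch.kind == "ring_closure":
        right = ch.kind != "attach_left"
        if ch.kind == "ring_closure":
            right = ch.s2 == (ch.s + ch.l) % S
        m = (ch.s + ch.l) % S if right else (ch.s - 1) % S
        state.n_active[m] -= 1
        state.n_poly[ch.l, ch.s] -= 1
        if ch.l + 1 == L:
            state.n_rings += 1
        else:
            state.n_poly[ch.l + 1, ch.s if right else m] += 1
    elif ch.kind == "decay":
        state.n_poly[ch.l, ch.s] -= 1
        for k in range(ch.l):
            state.n_active[(ch.s + k) % S] += 1
    else:
        raise ValueError(f"unknown channel kind {ch.kind!r}")


def _default_max_events(config: AssemblyConfig) -> int:
    # for Lnuc = 2 every trajectory ends within 2*S*N events; decay above
    # that can recycle monomers, so leave generous headroom
    base = 2 * config.S * config.N + 10
    if config.Lnuc > 2:
        base = max(2_000_000, 400 * config.S * config.N)
    return base


def _default_plateau_window(config: AssemblyConfig) -> int:
    return max(20_000, 40 * config.S * config.N)


def run_ssa(config: AssemblyConfig, seed: int, max_events: int | None = None,
            snapshot_times=None, check_mass: bool = False,
            plateau_window: int | None = None) -> Trajectory:
    """Run one exact SSA trajectory of the monomer-attachment ring model.

    Identical ``(config, seed)`` give bit-identical trajectories.  The run
    terminates when the total propensity is exactly zero (final state), when
    ``max_events`` is exhausted, or -- for ``Lnuc > 2``, where decay and
    re-nucleation can cycle indefinitely -- when the yield has not changed
    over ``plateau_window`` events after the inactive pool is empty
    ("plateau" termination, reported in ``Trajectory.termination``).
    """
    config = validate_config(config)
    if config.variant != "ring":
        raise ValueError("run_ssa handles variant='ring'; use variant_models for others")
    snap = np.asarray([] if snapshot_times is None else snapshot_times, dtype=float)
    me = _default_max_events(config) if max_events is None else int(max_events)
    pw = _default_plateau_window(config) if plateau_window is None else int(plateau_window)
    alpha = 0.0 if config.all_active else float(config.alpha)
    out = _kernels.ring_ssa_kernel(
        config.S, config.L, config.Lnuc, config.N, alpha, config.all_active,
        config.mu_vec, config.delta_vec, float(config.nu), float(config.V),
        int(seed) & 0x7FFFFFFF, me, pw, snap, check_mass, 4096,
    )
    return _package(out, config, seed, snap)


def _package(out, config, seed, snap) -> Trajectory:
    term, t, n_rings, n_events, yield_times, n_yield, snaps, max_poly = out[:8]
    if term == _kernels.TERM_MASS_ERROR:
        raise AssertionError("mass conservation violated in SSA kernel")
    term_name = {_kernels.TERM_ABSORBED: "absorbed",
                 _kernels.TERM_PLATEAU: "plateau",
                 _kernels.TERM_MAX_EVENTS: "max_events"}[term]
    maxn = config.max_structures
    times = np.asarray(yield_times[:n_yield])
    series = (np.arange(1, n_yield + 1)) / maxn
    return Trajectory(
        times=times,
        yield_series=series,
        final_yield=n_rings / maxn,
        seed=int(seed),
        t_final=float(t),
        n_events=int(n_events),
        termination=term_name,
        snapshot_times=snap if len(snap) else None,
        size_distribution_snapshots=np.asarray(snaps) if len(snap) else None,
        max_polymer_count=int(max_poly),
    )


def spawn_seeds(seed_root: int, n: int) -> np.ndarray:
    """Derive ``n`` independent, reproducible run seeds from one root seed
    (NumPy SeedSequence spawning; values fit in 31 bits)."""
    ss = np.random.SeedSequence(seed_root)
    return np.array([int(c.generate_state(1)[0]) & 0x7FFFFFFF for c in ss.spawn(n)],
                    dtype=np.int64)


def run_ensemble(config: AssemblyConfig, n_runs: int, seed_root: int,
                 runner=run_ssa, **kwargs) -> EnsembleSummary:
    """Average the final yield over ``n_runs`` independent trajectories.

    Seeds are spawned reproducibly from ``seed_root``; ``runner`` may be any
    of the variant ``run_ssa`` functions.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    config = validate_config(config)
    seeds = spawn_seeds(seed_root, n_runs)
    yields = np.empty(n_runs)
    for i, s in enumerate(seeds):
        try:
            yields[i] = runner(config, int(s), **kwargs).final_yield
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(f"ensemble run {i} (seed {int(s)}) failed") from exc
    return EnsembleSummary.from_yields(yields, config, seed_root=seed_root)


def reference_ssa(config: AssemblyConfig, seed: int,
                  max_events: int = 100_000) -> Trajectory:
    """Pure-Python SSA via full channel re-enumeration (debug oracle).

    Asserts integer mass conservation and yield monotonicity after every
    event; intended for small systems only.
    """
    config = validate_config(config)
    rng = np.random.default_rng(seed)
    state = RingState.initial(config)
    mass0 = state.total_mass(config.L)
    times, series = [], []
    prev_yield = 0.0
    n_events = 0
    term = "max_events"
    while n_events < max_events:
        chans = propensities(state, config)
        atot = sum(c.propensity for c in chans)
        if atot == 0.0:
            term = "absorbed"
            break
        state.t += rng.exponential(1.0 / atot)
        r = rng.random() * atot
        for ch in chans:
            if r < ch.propensity:
                break
            r -= ch.propensity
        apply_channel(state, ch, config)
        n_events += 1
        assert state.total_mass(config.L) == mass0, "mass conservation violated"
        y = yield_of(state, config)
        assert y >= prev_yield - 1e-15, "yield decreased"
        if y > prev_yield:
            times.append(state.t)
            series.append(y)
        prev_yield = y
    return Trajectory(
        times=np.asarray(times),
        yield_series=np.asarray(series),
        final_yield=prev_yield,
        seed=int(seed),
        t_final=state.t,
        n_events=n_events,
        termination=term,
    )
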