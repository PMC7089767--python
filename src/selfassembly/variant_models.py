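"""Robustness-check variants: polymer-polymer ring assembly and 2D squares.

Polymer-polymer variant
-----------------------
On top of the monomer channels of :mod:`selfassembly.ring_gillespie`, two
structures ``(s1, l1)`` and ``(s2, l2)`` join at rate ``nu/V`` (independent
of both sizes, the worst case for yield) when they fit, i.e. the left end of
the second periodically continues the right end of the first
(``s2 = s1 + l1 mod S``) and their combined length does not exceed ``L``.
Structures with overlapping parts can never fit.  A combined length of
exactly ``L`` closes a ring directly -- a length-``L`` open chain is never
instantiated.  In that case both junctions of the pair match simultaneously;
by default each junction contributes ``nu/V`` ("rate nu per binding site"),
giving ``2*nu/V`` per fitting unordered pair, and ``closure_double_junction=
False`` selects the single-junction convention ``nu/V``.

Square variant
--------------
``S = L`` species sit on a ``sqrt(S) x sqrt(S)`` grid, one species per
position.  Active monomers at grid-adjacent positions dimerize at ``nu/V``;
a monomer whose position is missing from a cluster and has ``b >= 1``
occupied neighbours attaches at ``b*nu/V``.  All polymers are stable
(``Lnuc = 2``), clusters never merge, and the completed grid is absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .core_types import (
    AssemblyConfig,
    RingState,
    SquareState,
    Trajectory,
    validate_config,
    yield_of,
)
from .ring_gillespie import (
    ReactionChannel,
    _default_max_events,
    _default_plateau_window,
    _package,
    apply_channel,
    propensities,
)

__all__ = [
    "PolymerPair",
    "propensities_pp",
    "propensities_square",
    "run_ssa_pp",
    "run_ssa_square",
    "reference_ssa_pp",
    "reference_ssa_square",
]


@dataclass(frozen=True)
class PolymerPair:
    """An ordered, fitting pair of ring fragments.

    The pair fits when ``s2 = s1 + l1 (mod S)``; the junction count is 2
    exactly when the combined length equals ``L`` (both ends match at once
    and the join closes the ring).
    """

    s1: int
    l1: int
    s2: int
    l2: int

    def fits(self, config: AssemblyConfig) -> bool:
        return (self.l1 + self.l2 <= config.L
                and (self.s1 + self.l1) % config.S == self.s2 % config.S)

    def junctions(self, config: AssemblyConfig) -> int:
        return 2 if self.l1 + self.l2 == config.L else 1


def propensities_pp(state: RingState, config: AssemblyConfig,
                    closure_double_junction: bool = True) -> list[ReactionChannel]:
    """All monomer-attachment channels plus polymer-polymer joining channels.

    Joining channels are enumerated over ordered fitting pairs of polymers
    (``l1, l2 >= 2``); self-pairs use ``n*(n-1)`` combinatorics.  Channels
    that close a ring are tagged ``join_closure``.
    """
    channels = propensities(state, config)
    S, L, V = config.S, config.L, config.V
    npoly = state.n_poly
    gv = config.nu / V
    cf = 1.0 if closure_double_junction else 0.5
    for l1 in range(2, L - 1):
        for s1 in range(S):
            m1 = npoly[l1, s1]
            if m1 == 0:
                continue
            s2 = (s1 + l1) % S
            for l2 in range(2, L - l1 + 1):
                m2 = npoly[l2, s2]
                if s2 == s1 and l2 == l1:
                    m2 -= 1
                if m2 <= 0:
                    continue
                closing = l1 + l2 == L
                p = gv * m1 * m2 * (cf if closing else 1.0)
                channels.append(ReactionChannel(
                    "join_closure" if closing else "join",
                    s=s1, l=l1, s2=s2, l2=l2, propensity=p))
    return channels


def _apply_pp(state: RingState, ch: ReactionChannel, config: AssemblyConfig) -> None:
    if ch.kind in ("join", "join_closure"):
        state.n_poly[ch.l, ch.s] -= 1
        state.n_poly[ch.l2, ch.s2] -= 1
        if ch.l + ch.l2 == config.L:
            state.n_rings += 1
        else:
            state.n_poly[ch.l + ch.l2, ch.s] += 1
    else:
        apply_channel(state, ch, config)


def run_ssa_pp(config: AssemblyConfig, seed: int, max_events: int | None = None,
               snapshot_times=None, check_mass: bool = False,
               plateau_window: int | None = None, pp_enabled: bool = True,
               closure_double_junction: bool = True) -> Trajectory:
    """One exact SSA trajectory of the polymer-polymer ring variant.

    With ``pp_enabled=False`` the joining channels are dropped and the
    reaction law reduces to the plain ring model (useful as a cross-check).
    """
    config = validate_config(config)
    if config.variant not in ("ring", "ring_polymer_polymer"):
        raise ValueError("run_ssa_pp requires a ring variant")
    snap = np.asarray([] if snapshot_times is None else snapshot_times, dtype=float)
    me = _default_max_events(config) if max_events is None else int(max_events)
    pw = _default_plateau_window(config) if plateau_window is None else int(plateau_window)
    alpha = 0.0 if config.all_active else float(config.alpha)
    out = _kernels.ring_pp_ssa_kernel(
        config.S, config.L, config.Lnuc, config.N, alpha, config.all_active,
        config.mu_vec, config.delta_vec, float(config.nu), float(config.V),
        int(seed) & 0x7FFFFFFF, me, pw, snap, check_mass,
        pp_enabled, 1.0 if closure_double_junction else 0.5,
    )
    return _package(out, config, seed, snap)


def propensities_square(state: SquareState, config: AssemblyConfig) -> list[ReactionChannel]:
    """Channels of the square model.

    ``join`` channels are not part of this model (no cluster-cluster
    binding).  Attachment channels carry the cluster index in ``s`` and the
    grid position in ``s2``; their propensity is ``b*nu/V*n1[p]`` with ``b``
    the number of contacts.
    """
    G = config.grid_side
    S, V = config.S, config.V
    gv = config.nu / V
    n0, n1 = state.n_inactive, state.n_active
    channels: list[ReactionChannel] = []
    if not config.all_active and config.alpha > 0:
        for p in range(S):
            if n0[p] > 0:
                channels.append(ReactionChannel("activation", s=p,
                                                propensity=config.alpha * n0[p]))

    def neighbours(p):
        i, j = divmod(p, G)
        if i > 0:
            yield p - G
        if i < G - 1:
            yield p + G
        if j > 0:
            yield p - 1
        if j < G - 1:
            yield p + 1

    for p in range(S):
        for q in neighbours(p):
            if q > p and n1[p] > 0 and n1[q] > 0:
                channels.append(ReactionChannel("dimerization", s=p, s2=q,
                                                propensity=gv * n1[p] * n1[q]))
    for i, cl in enumerate(state.clusters):
        for p in range(S):
            if p in cl or n1[p] == 0:
                continue
            b = sum(1 for q in neighbours(p) if q in cl)
            if b > 0:
                kind = "ring_closure" if len(cl) + 1 == S else "attach_right"
                channels.append(ReactionChannel(kind, s=i, s2=p, l=b,
                                                propensity=b * gv * n1[p]))
    return channels


def _apply_square(state: SquareState, ch: ReactionChannel, config: AssemblyConfig) -> None:
    if ch.kind == "activation":
        state.n_inactive[ch.s] -= 1
        state.n_active[ch.s] += 1
    elif ch.kind == "dimerization":
        state.n_active[ch.s] -= 1
        state.n_active[ch.s2] -= 1
        state.clusters.append(frozenset((ch.s, ch.s2)))
    else:  # attachment (possibly completing the square)
        state.n_active[ch.s2] -= 1
        cl = state.clusters[ch.s] | {ch.s2}
        if len(cl) == config.S:
            del state.clusters[ch.s]
            state.n_squares += 1
        else:
            state.clusters[ch.s] = cl


def run_ssa_square(config: AssemblyConfig, seed: int, max_events: int | None = None,
                   snapshot_times=None, check_mass: bool = False) -> Trajectory:
    """One exact SSA trajectory of the square model (always terminates at a
    propensity-zero final state since all bonds are irreversible)."""
    config = validate_config(config)
    if config.variant != "square":
        raise ValueError("run_ssa_square requires variant='square'")
    snap = np.asarray([] if snapshot_times is None else snapshot_times, dtype=float)
    me = (2 * config.S * config.N + 10) if max_events is None else int(max_events)
    alpha = 0.0 if config.all_active else float(config.alpha)
    out = _kernels.square_ssa_kernel(
        config.grid_side, config.N, alpha, config.all_active, float(config.nu),
        float(config.V), int(seed) & 0x7FFFFFFF, me, snap, check_mass,
    )
    return _package(out, config, seed, snap)


def _reference_loop(config, seed, max_events, state, prop_fn, apply_fn, mass_fn):
    rng = np.random.default_rng(seed)
    mass0 = mass_fn(state)
    prev_yield = 0.0
    times, series = [], []
    n_events = 0
    term = "max_events"
    while n_events < max_events:
        chans = prop_fn(state, config)
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
        apply_fn(state, ch, config)
        n_events += 1
        assert mass_fn(state) == mass0, "mass conservation violated"
        y = yield_of(state, config)
        assert y >= prev_yield - 1e-15, "yield decreased"
        if y > prev_yield:
            times.append(state.t)
            series.append(y)
        prev_yield = y
    return Trajectory(times=np.asarray(times), yield_series=np.asarray(series),
                      final_yield=prev_yield, seed=int(seed), t_final=state.t,
                      n_events=n_events, termination=term)


def reference_ssa_pp(config: AssemblyConfig, seed: int, max_events: int = 100_000,
                     closure_double_junction: bool = True) -> Trajectory:
    """Pure-Python polymer-polymer SSA with per-event invariant checks."""
    config = validate_config(config)
    state = RingState.initial(config)

    def prop(st, cfg):
        return propensities_pp(st, cfg, closure_double_junction)

    return _reference_loop(config, seed, max_events, state, prop, _apply_pp,
                           lambda st: st.total_mass(config.L))


def reference_ssa_square(config: AssemblyConfig, seed: int,
                         max_events: int = 100_000) -> Trajectory:
    """Pure-Python square SSA with per-event invariant checks."""
    config = validate_config(config)
    state = SquareState.initial(config)
    return _reference_loop(config, seed, max_events, state, propensities_square,
                           _apply_square, lambda st: st.total_mass(config.S))
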