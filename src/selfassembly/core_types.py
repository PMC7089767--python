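"""Shared data model for heterogeneous self-assembly kinetics.

The system assembles closed target structures (rings of circumference ``L``,
or fully heterogeneous ``sqrt(S) x sqrt(S)`` squares) from ``S`` monomer
species, ``N`` particles of each species, in a reaction volume ``V = N / C``.
Monomers start inactive and are activated at a per-capita rate ``alpha``;
active monomers of periodically consecutive species bind.  Structures below a
critical nucleation size ``Lnuc`` grow at (size-dependent) rates ``mu_l`` and
decay at rates ``delta_l``; at and above ``Lnuc`` growth is irreversible at
rate ``nu`` per binding site.  Completed targets are absorbing.

Unit conventions: by default ``nu = 1`` and ``C = 1`` set the time and
concentration scales, so activation rates are naturally read as the
dimensionless ratio ``alpha / (nu * C)``.  Stochastic propensities use the
volume factor ``V = N / C`` to convert concentration-based rate constants
into per-pair event rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "AssemblyConfig",
    "RingState",
    "SquareState",
    "Trajectory",
    "EnsembleSummary",
    "validate_config",
    "yield_of",
]

#: Sentinel accepted for ``alpha`` meaning every monomer starts active
#: (the dimerization scenario, alpha -> infinity).
ALPHA_INF = math.inf

_RING_VARIANTS = ("ring", "ring_polymer_polymer")
_VARIANTS = _RING_VARIANTS + ("square",)


@dataclass(frozen=True)
class AssemblyConfig:
    """Complete parameter set for one assembly model.

    Parameters
    ----------
    S : int
        Number of distinct monomer species (>= 1).
    L : int
        Target size: ring circumference, or total number of positions of the
        square.  For ring variants ``L`` must be an integer multiple of ``S``.
    Lnuc : int
        Critical nucleation size, ``2 <= Lnuc <= L``.  Structures of size
        ``l < Lnuc`` bind reversibly; larger ones are stable.
    N : int
        Particles per species.
    C : float
        Initial concentration per species; the reaction volume is ``V = N/C``.
    alpha : float
        Per-capita activation rate.  ``math.inf`` (or the string ``"inf"`` in
        config files) selects the dimerization scenario in which all monomers
        start active.
    mu : float or sequence, optional
        Sub-nucleation attachment rates ``mu_l`` for ``l = 1 .. Lnuc-1``
        (``mu_1`` is the dimerization rate).  A scalar is broadcast; the
        default is ``nu`` (the activation scenario, all binding rates equal).
    delta : float or sequence, optional
        Decay rates ``delta_l`` for ``2 <= l < Lnuc``.  Scalar broadcast;
        default ``nu`` when ``Lnuc > 2`` (reversible pre-nuclei decay on the
        growth time scale), irrelevant and empty for ``Lnuc = 2``.
    nu : float
        Growth rate per binding site above the nucleation size.
    variant : str
        ``"ring"`` (monomer attachment only), ``"ring_polymer_polymer"``
        (additionally lets fitting polymers join), or ``"square"``.
    """

    S: int
    L: int
    Lnuc: int = 2
    N: int = 100
    C: float = 1.0
    alpha: float = 1e-4
    mu: float | Sequence[float] | None = None
    delta: float | Sequence[float] | None = None
    nu: float = 1.0
    variant: str = "ring"
    # normalized vectors, filled in by validate_config
    mu_vec: np.ndarray | None = field(default=None, repr=False, compare=False)
    delta_vec: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def V(self) -> float:
        """Reaction volume ``N / C``."""
        return self.N / self.C

    @property
    def all_active(self) -> bool:
        """True in the dimerization scenario (alpha -> infinity)."""
        return math.isinf(self.alpha)

    @property
    def max_structures(self) -> float:
        """Maximal number of complete targets, ``N*S/L`` for rings, ``N`` for squares."""
        if self.variant == "square":
            return float(self.N)
        return self.N * self.S / self.L

    @property
    def grid_side(self) -> int:
        """Side length of the square grid (square variant only)."""
        return int(round(math.sqrt(self.S)))

    def rate_of_size(self, l: int) -> float:
        """Attachment rate constant for growth of a structure of size ``l``:
        ``mu_l`` below the nucleation size, ``nu`` at or above it."""
        if l < self.Lnuc:
            return float(self.mu_vec[l - 1])
        return self.nu

    def to_dict(self) -> dict:
        """JSON/YAML-serializable snapshot (round-trips through validate_config)."""
        d = {
            "S": self.S,
            "L": self.L,
            "Lnuc": self.Lnuc,
            "N": self.N,
            "C": self.C,
            "alpha": "inf" if self.all_active else self.alpha,
            "nu": self.nu,
            "variant": self.variant,
        }
        if self.mu_vec is not None:
            d["mu"] = [float(x) for x in self.mu_vec]
        elif self.mu is not None:
            d["mu"] = self.mu
        if self.delta_vec is not None and len(self.delta_vec):
            d["delta"] = [float(x) for x in self.delta_vec]
        elif self.delta is not None:
            d["delta"] = self.delta
        return d


class ConfigError(ValueError):
    """Raised for an invalid or inconsistent parameter combination."""


def _broadcast(value, length, default, name):
    if value is None:
        value = default
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.full(length, float(arr[0]))
    if arr.size != length:
        raise ConfigError(
            f"{name} must be a scalar or have length {length}, got {arr.size}"
        )
    if np.any(arr < 0):
        raise ConfigError(f"{name} rates must be non-negative")
    return arr


def validate_config(config: AssemblyConfig) -> AssemblyConfig:
    """Check invariants and return a normalized copy of ``config``.

    Normalization broadcasts ``mu``/``delta`` to vectors (``mu_vec`` has one
    entry per sub-nucleation size ``l = 1 .. Lnuc-1``; ``delta_vec`` one per
    ``l = 2 .. Lnuc-1``) and parses the ``"inf"`` activation sentinel.

    Raises
    ------
    ConfigError
        If ``L mod S != 0`` for a ring variant, ``Lnuc`` is out of range,
        any rate is negative, ``nu < mu_l``, or a square configuration does
        not have ``S == L`` equal to a perfect square.
    """
    c = config
    alpha = c.alpha
    if isinstance(alpha, str):
        alpha = math.inf if alpha.lower() in ("inf", "infinity") else float(alpha)
    if c.variant not in _VARIANTS:
        raise ConfigError(f"unknown variant {c.variant!r}; choose from {_VARIANTS}")
    if c.S < 1 or c.L < 2 or c.N < 1:
        raise ConfigError("require S >= 1, L >= 2, N >= 1")
    if not (2 <= c.Lnuc <= c.L):
        raise ConfigError(f"Lnuc must satisfy 2 <= Lnuc <= L, got Lnuc={c.Lnuc}, L={c.L}")
    if c.C <= 0:
        raise ConfigError("C must be positive")
    if alpha < 0:
        raise ConfigError("alpha must be non-negative")
    if c.nu < 0:
        raise ConfigError("nu must be non-negative")
    if c.variant in _RING_VARIANTS:
        if c.L % c.S != 0:
            raise ConfigError(
                f"ring size L={c.L} must be an integer multiple of the number "
                f"of species S={c.S}"
            )
    else:  # square
        side = int(round(math.sqrt(c.S)))
        if side * side != c.S:
            raise ConfigError(f"square variant needs a perfect-square S, got S={c.S}")
        if c.S != c.L:
            raise ConfigError(f"square variant needs S == L, got S={c.S}, L={c.L}")
        if c.Lnuc != 2:
            raise ConfigError("square variant is defined for Lnuc = 2 only")

    mu_vec = _broadcast(c.mu, c.Lnuc - 1, c.nu, "mu")
    n_delta = max(c.Lnuc - 2, 0)
    delta_vec = _broadcast(c.delta, n_delta, c.nu, "delta") if n_delta else np.zeros(0)
    if np.any(mu_vec > c.nu):
        raise ConfigError("growth above the nucleation size must be at least as "
                          "fast as below: nu >= mu_l for all l")
    return replace(c, alpha=alpha, mu_vec=mu_vec, delta_vec=delta_vec)


@dataclass
class RingState:
    """Species-resolved occupation numbers of the ring model.

    ``n_poly[l, s]`` counts polymers of length ``l`` (rows ``2 .. L-1``)
    whose left-end monomer has species ``s``; a polymer is fully specified by
    this pair because binding is sequential on a periodic alphabet.  Rows 0
    and 1 of ``n_poly`` are unused (monomer pools are separate).
    """

    n_inactive: np.ndarray  # shape (S,)
    n_active: np.ndarray    # shape (S,)
    n_poly: np.ndarray      # shape (L, S), rows 2..L-1 used
    n_rings: int = 0
    t: float = 0.0

    @classmethod
    def initial(cls, config: AssemblyConfig) -> "RingState":
        S, L, N = config.S, config.L, config.N
        if config.all_active:
            n0 = np.zeros(S, dtype=np.int64)
            n1 = np.full(S, N, dtype=np.int64)
        else:
            n0 = np.full(S, N, dtype=np.int64)
            n1 = np.zeros(S, dtype=np.int64)
        return cls(n0, n1, np.zeros((L, S), dtype=np.int64))

    def total_mass(self, L: int) -> int:
        """Monomer-equivalents in the system; conserved and equal to S*N."""
        lengths = np.arange(self.n_poly.shape[0])
        return int(
            self.n_inactive.sum()
            + self.n_active.sum()
            + (lengths[:, None] * self.n_poly).sum()
            + L * self.n_rings
        )


@dataclass
class SquareState:
    """State of the square model: per-position monomer pools plus a multiset
    of connected clusters (each a frozenset of grid positions, size >= 2)."""

    n_inactive: np.ndarray
    n_active: np.ndarray
    clusters: list  # list of frozenset[int], positions indexed row-major
    n_squares: int = 0
    t: float = 0.0

    @classmethod
    def initial(cls, config: AssemblyConfig) -> "SquareState":
        S, N = config.S, config.N
        if config.all_active:
            n0 = np.zeros(S, dtype=np.int64)
            n1 = np.full(S, N, dtype=np.int64)
        else:
            n0 = np.full(S, N, dtype=np.int64)
            n1 = np.zeros(S, dtype=np.int64)
        return cls(n0, n1, [])

    def total_mass(self, S: int) -> int:
        return int(
            self.n_inactive.sum()
            + self.n_active.sum()
            + sum(len(c) for c in self.clusters)
            + S * self.n_squares
        )


@dataclass
class Trajectory:
    """One stochastic realization: the yield time series and optional
    polymer-size snapshots."""

    times: np.ndarray                 # times at which yield increased (plus t_final)
    yield_series: np.ndarray          # yield after each of those times
    final_yield: float
    seed: int
    t_final: float = 0.0
    n_events: int = 0
    termination: str = "absorbed"     # "absorbed" | "plateau" | "max_events"
    snapshot_times: np.ndarray | None = None
    size_distribution_snapshots: np.ndarray | None = None  # (n_snap, L+2) counts
    max_polymer_count: int = 0        # peak of the total polymer number over time


@dataclass
class EnsembleSummary:
    """Mean and spread of the final yield over independent realizations."""

    mean_yield: float
    std_yield: float
    n_realizations: int
    final_yields: np.ndarray
    config: dict
    seed_root: int | None = None

    @classmethod
    def from_yields(cls, yields, config: AssemblyConfig, seed_root=None):
        y = np.asarray(yields, dtype=float)
        return cls(
            mean_yield=float(y.mean()),
            std_yield=float(y.std(ddof=0)),
            n_realizations=len(y),
            final_yields=y,
            config=config.to_dict(),
            seed_root=seed_root,
        )

    @property
    def stderr(self) -> float:
        """Monte-Carlo standard error of the ensemble mean."""
        n = self.n_realizations
        return float(self.final_yields.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0


def yield_of(state: RingState | SquareState, config: AssemblyConfig) -> float:
    """Assembly yield: completed targets relative to the maximal number.

    For rings this is ``n_rings / (N*S/L)``; for squares ``n_squares / N``.
    Complete structures are absorbing, so along any trajectory this quantity
    is non-decreasing and lies in [0, 1].
    """
    if isinstance(state, SquareState):
        return state.n_squares / config.N
    return state.n_rings / config.max_structures
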