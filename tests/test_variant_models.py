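import math

import numpy as np
import pytest

from selfassembly.core_types import AssemblyConfig, RingState, SquareState, validate_config
from selfassembly.ring_gillespie import propensities, run_ensemble, run_ssa
from selfassembly.variant_models import (
    PolymerPair,
    propensities_pp,
    propensities_square,
    reference_ssa_pp,
    reference_ssa_square,
    run_ssa_pp,
    run_ssa_square,
)


def _pp_cfg(**kw):
    kw.setdefault("variant", "ring_polymer_polymer")
    return validate_config(AssemblyConfig(**kw))


class TestPolymerPairs:
    def test_fitting_pair_with_full_length_closes_the_ring(self):
        cfg = _pp_cfg(S=4, L=4, N=2)
        pair = PolymerPair(s1=1, l1=2, s2=3, l2=2)
        assert pair.fits(cfg)
        assert pair.junctions(cfg) == 2  # both ends match simultaneously

    def test_overlapping_fragments_cannot_bind(self):
        cfg = _pp_cfg(S=4, L=4, N=2)
        assert not PolymerPair(s1=1, l1=2, s2=2, l2=2).fits(cfg)

    def test_combined_length_beyond_target_cannot_bind(self):
        cfg = _pp_cfg(S=4, L=8, N=2)
        assert PolymerPair(s1=0, l1=5, s2=1, l2=3).fits(cfg)
        assert not PolymerPair(s1=0, l1=6, s2=2, l2=3).fits(cfg)


class TestPolymerPolymerChannels:
    def _state(self, cfg, polymers):
        state = RingState.initial(cfg)
        state.n_inactive[:] = 0
        for (l, s, n) in polymers:
            state.n_poly[l, s] = n
        return state

    def test_closure_pair_appears_once_per_junction(self):
        # fragments (1,2) and (3,2) in S = L = 4 tile the full ring; with
        # the double-junction convention the ordered enumeration yields two
        # closing channels of nu/V each, i.e. 2 nu/V per pair
        cfg = _pp_cfg(S=4, L=4, N=2)
        state = self._state(cfg, [(2, 1, 1), (2, 3, 1)])
        close = [c for c in propensities_pp(state, cfg) if c.kind == "join_closure"]
        assert len(close) == 2
        assert sum(c.propensity for c in close) == pytest.approx(2 * cfg.nu / cfg.V)
        close1 = [c for c in propensities_pp(state, cfg, closure_double_junction=False)
                  if c.kind == "join_closure"]
        assert sum(c.propensity for c in close1) == pytest.approx(cfg.nu / cfg.V)

    def test_overlapping_fragments_have_no_joining_channel(self):
        cfg = _pp_cfg(S=4, L=4, N=2)
        state = self._state(cfg, [(2, 1, 1), (2, 2, 1)])
        assert [c for c in propensities_pp(state, cfg)
                if c.kind.startswith("join")] == []

    def test_self_pairs_use_n_times_n_minus_one(self):
        # S = 2, L = 8: two (s=0, l=2) fragments fit each other (0+2 = 0 mod 2)
        cfg = _pp_cfg(S=2, L=8, N=4)
        state = self._state(cfg, [(2, 0, 3)])
        joins = [c for c in propensities_pp(state, cfg)
                 if c.kind == "join" and c.s == 0 and c.l == 2 and c.l2 == 2]
        assert len(joins) == 1
        assert joins[0].propensity == pytest.approx(cfg.nu / cfg.V * 3 * 2)

    def test_disabling_joins_recovers_the_base_channel_set(self):
        cfg = _pp_cfg(S=4, L=8, N=5, alpha=0.2)
        state = self._state(cfg, [(2, 0, 2), (3, 2, 1), (6, 1, 1)])
        state.n_active[:] = [2, 0, 1, 3]
        state.n_inactive[:] = 1
        base = propensities(state, cfg)
        pp = [c for c in propensities_pp(state, cfg)
              if not c.kind.startswith("join")]
        assert [(c.kind, c.s, c.l, c.propensity) for c in base] == \
               [(c.kind, c.s, c.l, c.propensity) for c in pp]

    def test_disabled_joins_match_base_kernel_statistics(self):
        cfg = AssemblyConfig(S=4, L=8, N=6, alpha=1e-2)
        base = run_ensemble(cfg, 400, 21, runner=run_ssa)
        off = run_ensemble(cfg, 400, 22, runner=run_ssa_pp, pp_enabled=False)
        se = math.sqrt(base.stderr ** 2 + off.stderr ** 2)
        assert abs(base.mean_yield - off.mean_yield) < 4 * max(se, 1e-3)


class TestPolymerPolymerRuns:
    def test_single_copy_per_species_always_completes(self):
        # with N = 1 the fragments tile the ring and can always merge
        for alpha in (1e-3, 1.0, 1e3):
            cfg = AssemblyConfig(S=8, L=8, N=1, alpha=alpha,
                                 variant="ring_polymer_polymer")
            for seed in range(12):
                assert run_ssa_pp(cfg, seed, check_mass=True).final_yield == 1.0

    def test_joining_rescues_yield_at_high_activation_for_small_N(self):
        # at high alpha the monomer-only model nucleates itself to death;
        # polymer joining can still merge the fragments
        cfg = AssemblyConfig(S=12, L=12, N=2, alpha=100.0)
        mono = run_ensemble(cfg, 150, 31, runner=run_ssa)
        pp = run_ensemble(
            AssemblyConfig(S=12, L=12, N=2, alpha=100.0,
                           variant="ring_polymer_polymer"),
            150, 31, runner=run_ssa_pp)
        assert pp.mean_yield > mono.mean_yield + 0.2

    def test_kernel_matches_reference_enumeration(self):
        cfg = AssemblyConfig(S=4, L=8, N=6, alpha=1e-2,
                             variant="ring_polymer_polymer")
        yk = np.array([run_ssa_pp(cfg, s, check_mass=True).final_yield
                       for s in range(600)])
        yr = np.array([reference_ssa_pp(cfg, s).final_yield for s in range(250)])
        se = math.sqrt(yk.var() / len(yk) + yr.var() / len(yr))
        assert abs(yk.mean() - yr.mean()) < 4 * max(se, 1e-3)


class TestSquareChannels:
    def _cfg(self, **kw):
        kw.setdefault("variant", "square")
        return validate_config(AssemblyConfig(**kw))

    def test_contact_count_sets_attachment_rate(self):
        # 2x2 grid, cluster occupying three cells: the missing corner has
        # two occupied neighbours, so the rate is 2 nu/V per active monomer
        cfg = self._cfg(S=4, L=4, N=3)
        state = SquareState.initial(cfg)
        state.n_inactive[:] = 0
        state.n_active[:] = [0, 0, 2, 0]
        state.clusters = [frozenset({0, 1, 3})]
        chans = propensities_square(state, cfg)
        assert len(chans) == 1
        ch = chans[0]
        assert ch.kind == "ring_closure" and ch.l == 2
        assert ch.propensity == pytest.approx(2 * cfg.nu / cfg.V * 2)

    def test_dimerization_only_between_grid_neighbours(self):
        cfg = self._cfg(S=9, L=9, N=1)
        state = SquareState.initial(cfg)
        state.n_inactive[:] = 0
        state.n_active[[0, 8]] = 1  # opposite corners: never adjacent
        assert propensities_square(state, cfg) == []
        state.n_active[[0, 1]] = 1
        kinds = {c.kind for c in propensities_square(state, cfg)}
        assert "dimerization" in kinds

    def test_mass_conserved_through_cluster_growth(self):
        cfg = AssemblyConfig(S=9, L=9, N=4, alpha=0.05, variant="square")
        for seed in range(5):
            tr = run_ssa_square(cfg, seed, check_mass=True)
            assert tr.termination == "absorbed"
        tr = reference_ssa_square(cfg, 1)  # asserts mass per event internally
        assert 0.0 <= tr.final_yield <= 1.0

    def test_kernel_matches_reference_enumeration(self):
        cfg = AssemblyConfig(S=9, L=9, N=5, alpha=1e-2, variant="square")
        yk = np.array([run_ssa_square(cfg, s).final_yield for s in range(500)])
        yr = np.array([reference_ssa_square(cfg, s).final_yield for s in range(200)])
        se = math.sqrt(yk.var() / len(yk) + yr.var() / len(yr))
        assert abs(yk.mean() - yr.mean()) < 4 * max(se, 1e-3)


class TestSquareYieldCatastrophe:
    def test_saturation_below_one_and_decreasing_with_N(self):
        # small-activation-rate plateau of the square model: imperfect and
        # worse for fewer particles
        means = {}
        for N in (10, 100):
            cfg = AssemblyConfig(S=16, L=16, N=N, alpha=1e-7, variant="square")
            means[N] = run_ensemble(cfg, 150, 40 + N, runner=run_ssa_square).mean_yield
        assert means[100] < 0.995
        assert means[10] < means[100] - 0.1
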