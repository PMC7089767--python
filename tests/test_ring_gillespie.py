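import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from selfassembly.core_types import AssemblyConfig, RingState, validate_config
from selfassembly.mean_field_ode import integrate_ode
from selfassembly.ring_gillespie import (
    propensities,
    reference_ssa,
    run_ensemble,
    run_ssa,
)
from selfassembly.wave_theory import threshold_alpha


def _state_with(cfg, active=None, polymers=()):
    state = RingState.initial(cfg)
    if active is not None:
        state.n_active[:] = active
        state.n_inactive[:] = 0
    for (l, s, n) in polymers:
        state.n_poly[l, s] = n
    return state


class TestPropensities:
    def test_dimer_has_one_formation_but_two_growth_channels(self):
        # a specific dimer forms via a single reaction pathway but can grow
        # at either end
        cfg = validate_config(AssemblyConfig(S=4, L=8, N=5, alpha=0.1))
        state = _state_with(cfg, active=1, polymers=[(2, 0, 1)])
        chans = propensities(state, cfg)
        dim = [c for c in chans if c.kind == "dimerization" and c.s == 1]
        grow = [c for c in chans if c.kind.startswith("attach") and c.l == 2]
        assert len(dim) == 1
        assert {c.kind for c in grow} == {"attach_right", "attach_left"}

    def test_homogeneous_growth_counts_both_ends(self):
        # S = 1: total growth propensity of an l >= Lnuc polymer is
        # 2 (nu/V) n1 n_l, the factor 2 of the mean-field gain term
        cfg = validate_config(AssemblyConfig(S=1, L=6, N=10, alpha=0.1))
        state = _state_with(cfg, active=3, polymers=[(3, 0, 2)])
        grow = [c for c in propensities(state, cfg) if c.l == 3]
        assert sum(c.propensity for c in grow) == pytest.approx(
            2 * cfg.nu / cfg.V * 3 * 2)

    def test_homogeneous_dimerization_uses_pair_combinatorics(self):
        cfg = validate_config(AssemblyConfig(S=1, L=6, N=10, alpha=0.1))
        state = _state_with(cfg, active=4)
        dim = [c for c in propensities(state, cfg) if c.kind == "dimerization"]
        assert sum(c.propensity for c in dim) == pytest.approx(
            cfg.mu_vec[0] / cfg.V * 4 * 3)

    def test_exhausted_state_has_zero_total_propensity(self):
        cfg = validate_config(AssemblyConfig(S=3, L=6, N=2, alpha=0.1))
        state = RingState.initial(cfg)
        state.n_inactive[:] = 0   # nothing to activate, nothing active
        assert propensities(state, cfg) == []

    def test_decay_channels_only_below_nucleation_size(self):
        cfg = validate_config(AssemblyConfig(S=2, L=8, Lnuc=4, N=5, alpha=0.1,
                                             mu=0.5, delta=0.25))
        state = _state_with(cfg, active=0, polymers=[(2, 0, 3), (3, 1, 2), (4, 0, 1)])
        dec = [(c.l, c.propensity) for c in propensities(state, cfg)
               if c.kind == "decay"]
        assert dec == [(2, pytest.approx(0.25 * 3)), (3, pytest.approx(0.25 * 2))]


class TestRunSSA:
    def test_two_monomers_form_the_only_possible_ring(self):
        # S = L = 2, N = 1, all active: the unique path is dimerization
        # straight into the closed ring
        cfg = AssemblyConfig(S=2, L=2, N=1, alpha=math.inf)
        for seed in range(5):
            tr = run_ssa(cfg, seed, check_mass=True)
            assert tr.final_yield == 1.0
            assert tr.termination == "absorbed"
            assert tr.n_events == 1

    def test_identical_seed_gives_identical_trajectory(self):
        cfg = AssemblyConfig(S=4, L=8, N=10, alpha=1e-2)
        a = run_ssa(cfg, 123)
        b = run_ssa(cfg, 123)
        assert a.final_yield == b.final_yield
        assert a.t_final == b.t_final
        np.testing.assert_array_equal(a.times, b.times)

    def test_mass_conserved_at_every_event(self):
        # the kernel re-counts monomer equivalents after each event in
        # check_mass mode and aborts on any violation
        for cfg in [AssemblyConfig(S=6, L=12, N=8, alpha=1e-2),
                    AssemblyConfig(S=3, L=12, Lnuc=4, N=6, alpha=1e-2, delta=1.0),
                    AssemblyConfig(S=1, L=8, N=30, alpha=math.inf, mu=1e-3)]:
            tr = run_ssa(cfg, 7, check_mass=True)
            assert 0.0 <= tr.final_yield <= 1.0

    def test_yield_series_monotone_and_bounded(self):
        cfg = AssemblyConfig(S=4, L=8, N=20, alpha=1e-3)
        tr = run_ssa(cfg, 11)
        assert np.all(np.diff(tr.yield_series) > 0)
        assert np.all(np.diff(tr.times) >= 0)
        assert 0.0 <= tr.final_yield <= 1.0

    def test_kernel_matches_reference_enumeration(self):
        # same reaction law, independent implementations: ensemble means
        # must agree within Monte-Carlo error
        cfg = AssemblyConfig(S=4, L=8, N=6, alpha=1e-2)
        yk = np.array([run_ssa(cfg, s).final_yield for s in range(600)])
        yr = np.array([reference_ssa(cfg, s).final_yield for s in range(300)])
        se = math.sqrt(yk.var() / len(yk) + yr.var() / len(yr))
        assert abs(yk.mean() - yr.mean()) < 4 * se

    def test_snapshot_histograms_conserve_mass(self):
        cfg = AssemblyConfig(S=6, L=12, N=10, alpha=1e-2)
        tr = run_ssa(cfg, 3, snapshot_times=[1.0, 50.0, 1e9])
        snaps = tr.size_distribution_snapshots
        L = cfg.L
        lengths = np.arange(L + 1)
        lengths[0] = 1  # column 0 = inactive monomers, column 1 = active
        weights = np.ones(L + 1)
        weights[2:L] = np.arange(2, L)
        weights[L] = L
        for row in snaps:
            assert row @ weights == cfg.S * cfg.N


class TestEnsemble:
    def test_single_run_has_zero_std(self):
        cfg = AssemblyConfig(S=2, L=4, N=5, alpha=1e-2)
        summary = run_ensemble(cfg, 1, 0)
        assert summary.std_yield == 0.0
        assert summary.n_realizations == 1

    def test_ensemble_reproducible_from_seed_root(self):
        cfg = AssemblyConfig(S=4, L=8, N=6, alpha=1e-2)
        a = run_ensemble(cfg, 16, 99)
        b = run_ensemble(cfg, 16, 99)
        np.testing.assert_array_equal(a.final_yields, b.final_yields)

    def test_homogeneous_limit_reaches_perfect_yield(self):
        # S = 1 with slow activation: a single wave of growth consumes all
        # monomers into complete rings (N a multiple of L so the particle
        # budget divides into whole rings)
        cfg = AssemblyConfig(S=1, L=60, N=120, alpha=1e-7)
        summary = run_ensemble(cfg, 64, 5)
        assert summary.mean_yield > 0.98

    def test_dimerization_scenario_robust_at_small_N(self):
        # all monomers active, mu far below the threshold: yield ~ 1 even
        # for N = 10 in the fully heterogeneous system
        cfg = AssemblyConfig(S=60, L=60, N=10, alpha=math.inf, mu=1e-5)
        summary = run_ensemble(cfg, 128, 6)
        assert summary.mean_yield > 0.98


class TestAgainstMeanField:
    def test_deviation_from_ode_decreases_with_particle_number(self):
        # mean-field is exact as N -> infinity; the finite-N deficit at
        # fixed rates must shrink monotonically over two decades of N
        L = 30
        alpha = 0.5 * threshold_alpha(L)
        ode = integrate_ode(AssemblyConfig(S=L, L=L, N=1000, alpha=alpha)).final_yield
        devs = []
        for N, runs in ((100, 64), (1000, 24), (10000, 8)):
            cfg = AssemblyConfig(S=L, L=L, N=N, alpha=alpha)
            devs.append(abs(run_ensemble(cfg, runs, 13).mean_yield - ode))
        assert devs[0] > devs[1] > devs[2]

    def test_homogeneous_ssa_matches_ode_within_three_se(self):
        # without species fluctuations (S = 1) the rate equations describe
        # the stochastic mean accurately already at N = 1e4
        cfg = AssemblyConfig(S=1, L=60, N=10000, alpha=0.5 * threshold_alpha(60))
        summary = run_ensemble(cfg, 16, 17)
        ode = integrate_ode(cfg).final_yield
        assert abs(summary.mean_yield - ode) < 3 * max(summary.stderr, 1e-4)

    def test_stochastic_nucleation_excess_over_deterministic(self):
        # in the slow-activation limit demographic fluctuations inflate the
        # number of nucleated structures far beyond the mean-field wave
        cfg = AssemblyConfig(S=40, L=40, N=100, alpha=1e-7)
        peaks = [run_ssa(cfg, s).max_polymer_count for s in range(16)]
        ode = integrate_ode(cfg)
        det_peak = ode.c[:, 2:cfg.L].sum(axis=1).max() * cfg.V * cfg.S
        assert np.mean(peaks) > 2 * det_peak

    def test_stochastic_yield_collapse_under_concentration_rescaling(self):
        # rescaling (C, alpha) -> (10C, 10 alpha) multiplies every propensity
        # by ten: the embedded jump chain is identical, so equal seeds give
        # bit-identical final yields
        c1 = AssemblyConfig(S=12, L=12, N=50, C=1.0, alpha=0.01)
        c2 = AssemblyConfig(S=12, L=12, N=50, C=10.0, alpha=0.1)
        y1 = [run_ssa(c1, s).final_yield for s in range(10)]
        y2 = [run_ssa(c2, s).final_yield for s in range(10)]
        assert y1 == y2


@given(
    S=st.integers(1, 4),
    L_mult=st.integers(1, 3),
    N=st.integers(1, 4),
    Lnuc_off=st.integers(0, 2),
    scenario=st.sampled_from(["activation", "dimerization"]),
)
def test_reference_ssa_invariants_hold_for_random_small_systems(
        S, L_mult, N, Lnuc_off, scenario):
    """Mass conservation and yield monotonicity hold event-by-event for any
    parameter combination (asserted inside the reference SSA)."""
    L = max(S * L_mult, 2 * S) if S > 1 else max(2, 2 * L_mult)
    Lnuc = min(2 + Lnuc_off, L)
    alpha = math.inf if scenario == "dimerization" else 0.05
    cfg = AssemblyConfig(S=S, L=L, N=N, Lnuc=Lnuc, alpha=alpha,
                         mu=0.5, delta=0.5)
    tr = reference_ssa(cfg, seed=2, max_events=3000)
    assert 0.0 <= tr.final_yield <= 1.0
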