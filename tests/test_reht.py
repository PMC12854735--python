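"""REHT controller: hybrid enthalpy, swap statistics, detailed balance."""

import numpy as np
import pytest

from remass import constants as C
from remass.engine import EngineConfig, Integrator
from remass.ladder import Condition, Ladder, build_ladder
from remass.reht import hybrid_enthalpy, run_reht, swap_delta
from remass.topology import Atom, BondTerm, EnergyBreakdown, SystemState, Topology


def _cond(m, T, T_solv, dt=1.0, sps=10):
    return Condition(index=m, T=T, T_solv=T_solv, dt=dt, steps_per_swap=sps)


class TestHybridEnthalpy:
    def test_no_solvent_tempering_reduces_to_potential_plus_pv(self):
        e = EnergyBreakdown(E_p=3.0, E_ps=-7.0, E_s=-100.0, PV=2.5)
        c = _cond(1, 400.0, 400.0)
        assert hybrid_enthalpy(e, c) == pytest.approx(3.0 - 7.0 - 100.0 + 2.5)

    def test_hand_evaluated_value(self):
        e = EnergyBreakdown(E_p=10.0, E_ps=-20.0, E_s=-500.0, PV=0.0)
        c = _cond(1, 430.0, 350.0)
        assert hybrid_enthalpy(e, c) == pytest.approx(10.0 + (430.0 / 350.0) * (-520.0),
                                                      rel=1e-12)
        assert hybrid_enthalpy(e, c) == pytest.approx(-628.857, abs=5e-4)

    def test_linearity_in_energies(self):
        c = _cond(1, 430.0, 350.0)
        e1 = EnergyBreakdown(E_p=4.0, E_ps=-8.0, E_s=-50.0, PV=1.0)
        e2 = EnergyBreakdown(E_p=12.0, E_ps=-24.0, E_s=-150.0, PV=1.0)
        assert (hybrid_enthalpy(e2, c) - 1.0) == pytest.approx(
            3.0 * (hybrid_enthalpy(e1, c) - 1.0), rel=1e-12)


class TestSwapDelta:
    def test_identical_configurations_give_zero(self):
        assert swap_delta(5.0, 5.0, 7.0, 7.0, 1.2, 1.0) == 0.0

    def test_antisymmetry(self, rng):
        for _ in range(20):
            h = rng.normal(size=4)
            b = rng.uniform(1.0, 2.0, size=2)
            d1 = swap_delta(h[0], h[1], h[2], h[3], b[0], b[1])
            d2 = swap_delta(h[1], h[0], h[3], h[2], b[0], b[1])
            assert d1 == pytest.approx(-d2, rel=1e-12, abs=1e-12)

    def test_reduction_to_standard_temperature_re(self, rng):
        """With beta' = beta the exponent collapses to (b_m - b_m1)(E' - E)."""
        for _ in range(50):
            ep, eps, es, pv = rng.normal(scale=50.0, size=4)
            ep2, eps2, es2 = rng.normal(scale=50.0, size=3)
            cm = _cond(0, 310.0, 310.0)
            cm1 = _cond(1, 350.0, 350.0)
            e_r = EnergyBreakdown(ep, eps, es, pv)
            e_rp = EnergyBreakdown(ep2, eps2, es2, pv)
            d = swap_delta(hybrid_enthalpy(e_r, cm), hybrid_enthalpy(e_rp, cm),
                           hybrid_enthalpy(e_r, cm1), hybrid_enthalpy(e_rp, cm1),
                           cm.beta, cm1.beta)
            etot_r = ep + eps + es + pv
            etot_rp = ep2 + eps2 + es2 + pv
            expected = (cm.beta - cm1.beta) * (etot_rp - etot_r)
            assert d == pytest.approx(expected, rel=1e-10, abs=1e-10)


class TestTwoReplicaChain:
    """Exact enumeration of the swap Markov chain on stub energies.

    Each replica occupies one of two discrete states with known energies;
    within-condition dynamics is an exact Gibbs resample, swaps use the
    package's Metropolis exponent.  The empirical acceptance and the
    stationary distribution must match the analytic chain.
    """

    E = np.array([0.0, 1.2])        # kcal/mol, two-state system
    T0, T1 = 310.0, 430.0

    def _boltzmann(self, T):
        w = np.exp(-self.E / (C.KB * T))
        return w / w.sum()

    def _omega(self, s0, s1):
        b0 = 1.0 / (C.KB * self.T0)
        b1 = 1.0 / (C.KB * self.T1)
        # replica r (state s0) at condition 0, replica r' (state s1) at 1;
        # the stub enthalpy of a state is its energy under either condition
        d = swap_delta(self.E[s0], self.E[s1], self.E[s0], self.E[s1], b0, b1)
        return min(1.0, np.exp(-d))

    def test_empirical_acceptance_matches_analytic(self, rng):
        p0, p1 = self._boltzmann(self.T0), self._boltzmann(self.T1)
        n = 10000
        s0 = rng.choice(2, size=n, p=p0)
        s1 = rng.choice(2, size=n, p=p1)
        omega = np.array([self._omega(a, b) for a, b in zip(s0, s1)])
        accepted = rng.random(n) < omega
        expected = sum(p0[a] * p1[b] * self._omega(a, b)
                       for a in range(2) for b in range(2))
        se = np.sqrt(expected * (1 - expected) / n) + omega.std() / np.sqrt(n)
        assert accepted.mean() == pytest.approx(expected, abs=2.5 * se + 1e-3)

    def test_stationary_distribution_is_product_boltzmann(self):
        """Gibbs-within-condition + Metropolis swap leaves the product
        of Boltzmann distributions invariant (exact transition matrix)."""
        p0, p1 = self._boltzmann(self.T0), self._boltzmann(self.T1)
        # joint states (s0, s1); one round = Gibbs resample then swap attempt
        pi = np.array([p0[a] * p1[b] for a in range(2) for b in range(2)])
        P = np.zeros((4, 4))
        for a in range(2):
            for b in range(2):
                k = 2 * a + b
                # Gibbs resample lands anywhere with product probability,
                # then the swap exchanges the pair with prob omega
                for a2 in range(2):
                    for b2 in range(2):
                        k2 = 2 * a2 + b2
                        w = p0[a2] * p1[b2]
                        om = self._omega(a2, b2)
                        P[k, 2 * b2 + a2] += w * om
                        P[k, k2] += w * (1.0 - om)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(pi @ P, pi, atol=1e-12)


def _harmonic_probe_system():
    """Stiff-ish dimer whose bond length is the probe coordinate."""
    atoms = [Atom("A", "C", 12.0, 0.0), Atom("B", "C", 12.0, 0.0, molecule_id=1)]
    top = Topology(atoms=atoms, bonds=[BondTerm(0, 1, 80.0, 1.5)])
    st = SystemState(coords=np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]]),
                     velocities=None)
    return top, st


class TestRunReht:
    def test_single_condition_is_plain_md(self):
        top, st = _harmonic_probe_system()
        lad = Ladder(conditions=(_cond(0, 310.0, 310.0, dt=1.0, sps=20),))
        cfg = EngineConfig(T=310.0, dt=1.0, gamma=5.0, seed=0)
        res = run_reht(top, [st], lad, cfg, n_swap_rounds=5, seed=3)
        assert res.log.attempts == []
        assert len(res.condition_records[0]) > 0

    def test_replica_condition_mapping_stays_permutation(self):
        top, st = _harmonic_probe_system()
        lad = build_ladder(4, 310.0, 430.0, Tmax_solv=430.0, dt0=1.0,
                           swap_interval_ps=0.02)
        cfg = EngineConfig(T=310.0, dt=1.0, gamma=5.0, seed=0)
        res = run_reht(top, [st.copy() for _ in range(4)], lad, cfg,
                       n_swap_rounds=40, seed=5)
        assert not res.failed
        assert res.log.check_permutation(4)
        assert len(res.log.attempts) > 0

    def test_condition0_marginal_matches_single_t_reference(self):
        """Bond-length distribution demultiplexed at the base condition is
        statistically indistinguishable from a long plain run at T0."""
        from scipy.stats import ks_2samp

        top, st = _harmonic_probe_system()
        lad = build_ladder(4, 310.0, 430.0, Tmax_solv=430.0, dt0=1.0,
                           swap_interval_ps=0.05)
        cfg = EngineConfig(T=310.0, dt=1.0, gamma=20.0, seed=0)
        res = run_reht(top, [st.copy() for _ in range(4)], lad, cfg,
                       n_swap_rounds=150, seed=8, record_interval=10)
        assert not res.failed
        rates = [res.log.acceptance_rate(m) for m in range(3)]
        assert all(r > 0.3 for r in rates)   # well-overlapping toy ladder

        def bond_lengths(recs, skip):
            return np.array([np.linalg.norm(r.state.coords[0] - r.state.coords[1])
                             for r in recs[skip:]])

        reht_sample = bond_lengths(res.condition_records[0], 100)

        st2 = st.copy()
        rng = np.random.default_rng(77)
        recs = Integrator(top, cfg, rng=rng).run(st2, 15000, record_interval=10)
        ref_sample = bond_lengths(recs, 100)
        stat, p = ks_2samp(reht_sample[::4], ref_sample[::4])
        assert p > 0.01

    def test_failure_identifies_replica_and_condition(self):
        top, st = _harmonic_probe_system()
        top.bonds[0] = BondTerm(0, 1, 3000.0, 1.5)   # stiff: unstable at 6 fs
        lad = Ladder(conditions=(
            _cond(0, 310.0, 310.0, dt=6.0, sps=200),
            _cond(1, 430.0, 430.0, dt=6.0, sps=200)))
        cfg = EngineConfig(T=310.0, dt=6.0, gamma=0.0, seed=0)
        res = run_reht(top, [st.copy(), st.copy()], lad, cfg,
                       n_swap_rounds=3, seed=1)
        assert res.failed
        replica, dt, T = res.failure_info
        assert dt == 6.0 and T in (310.0, 430.0)
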