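"""Analysis probes: MBD, PMF/states, hydration, RMSD, equilibration."""

import math

import numpy as np
import pytest

from remass import constants as C
from remass.analysis import (
    REFERENCE_STATES,
    StateDefinition,
    define_states,
    fit_equilibration,
    hydrogen_bonds,
    instantaneous_temperature,
    kabsch_rmsd,
    mbd_reference,
    mbd_rmsd,
    pmf,
    rdf,
    rmsd_distribution,
    scaled_times,
    solvation_count,
    state_populations,
)
from remass.fixtures import place_ideal_gas, sample_angles, sample_relaxation


class TestMBD:
    def test_mean_is_half_ndof_kt(self):
        ref = mbd_reference(174, 310.0)
        assert ref.mean == pytest.approx(87 * C.KB * 310.0, rel=1e-12)

    def test_ndof_2_is_exponential(self):
        ref = mbd_reference(2, 310.0)
        e = np.linspace(0.01, 3.0, 50)
        expected = np.exp(-e / (C.KB * 310.0)) / (C.KB * 310.0)
        np.testing.assert_allclose(ref.pdf(e), expected, rtol=1e-10)

    def test_self_consistency_rmsd_small(self, rng):
        ref = mbd_reference(50, 310.0)
        samples = ref.rvs(100000, rng)
        # binomial noise floor of a 200-bin density histogram
        floor = np.sqrt(ref.pdf(ref.mean) / (len(samples) * ref.mean * 4 / 200))
        assert mbd_rmsd(samples, ref) < 3 * floor

    def test_rmsd_decreases_with_sample_size(self, rng):
        ref = mbd_reference(30, 310.0)
        r = [mbd_rmsd(ref.rvs(n, rng), ref) for n in (1000, 100000)]
        assert r[1] < r[0]

    def test_empty_samples_raise(self):
        with pytest.raises(ValueError):
            mbd_rmsd([], mbd_reference(6, 310.0))


class TestInstantaneousTemperature:
    def test_zero_velocities(self):
        assert instantaneous_temperature(np.zeros((5, 3)), np.ones(5), 15) == 0.0

    def test_linearity_in_mass(self, rng):
        v = rng.normal(size=(8, 3)) * 0.01
        m = np.full(8, 12.0)
        t1 = instantaneous_temperature(v, m, 24)
        t2 = instantaneous_temperature(v, 2 * m, 24)
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_sampling_mean_matches_draw_temperature(self, rng):
        n, m = 2000, np.full(60, 18.0)
        sigma = np.sqrt(C.KB * 310.0 * C.KE_CONV / m)
        ts = [instantaneous_temperature(
            rng.normal(size=(60, 3)) * sigma[:, None], m, 180) for _ in range(n)]
        assert np.mean(ts) == pytest.approx(310.0, abs=1.0)


class TestPmf:
    def test_uniform_angles_give_flat_pmf(self, rng):
        prof = pmf(rng.uniform(-180, 180, size=400000), T=310.0)
        assert prof.P.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.nanmax(prof.G[np.isfinite(prof.G)]) < 0.05
        assert prof.G.min() == 0.0

    def test_inverse_boltzmann_recovers_two_well_landscape(self):
        angles, density = sample_angles(1_000_000, seed=5)
        prof = pmf(angles, T=310.0)
        g_true = density.free_energy(prof.centers, T=310.0)
        mask = np.isfinite(prof.G) & (prof.G <= 5.0)
        g_fit = prof.G[mask] - prof.G[mask].min()
        g_ref = g_true[mask] - g_true[mask].min()
        rms = np.sqrt(np.mean((g_fit - g_ref) ** 2))
        assert rms < 0.1

    def test_two_well_states_are_disjoint_and_complete(self):
        angles, density = sample_angles(200_000, seed=3)
        prof = pmf(angles, T=310.0)
        states = define_states(prof, depth=0.5)
        assert len(states) == 2
        pops = state_populations(angles, states)
        both = sum(pops.values())
        assert both < 1.0 + 1e-12
        # no overlap: indicator sums never exceed 1
        inds = np.array([s.contains(angles) for s in states])
        assert int(inds.sum(axis=0).max()) <= 1
        # populations + gap occupancy account for every sample
        gap = 1.0 - both
        in_any = inds.any(axis=0).mean()
        assert in_any + gap == pytest.approx(1.0, abs=1e-12)
        # deepest well (weight 0.7) is recovered as the dominant state;
        # the 0.5 kcal/mol depth cut trims basin tails, so state occupancy
        # is below the full well weight but the ordering must hold
        assert max(pops.values()) > 2.0 * min(pops.values())
        assert 0.4 < max(pops.values()) < 0.7

    def test_reference_state_boundaries(self):
        phi1 = StateDefinition("Phi1", REFERENCE_STATES["Phi1"])
        assert phi1.contains([-60.0, 179.0]).all()
        assert not phi1.contains([0.0, 100.0]).any()
        phi2 = StateDefinition("Phi2", REFERENCE_STATES["Phi2"])
        assert phi2.contains([60.0]).all()
        assert not phi2.contains([23.9, 108.1]).any()


class TestHydrogenBonds:
    def _frame(self, r_da, angle_deg):
        """D at origin, H at (1,0,0), A placed to give angle DHA = angle_deg.

        The ray H->A makes angle (180 - angle_deg) with +x, so that the angle
        between H->D and H->A is angle_deg; s is solved so |D-A| = r_da.
        """
        d = np.array([0.0, 0.0, 0.0])
        h = np.array([1.0, 0.0, 0.0])
        theta = math.radians(180.0 - angle_deg)
        direction = np.array([math.cos(theta), math.sin(theta), 0.0])
        for s in np.linspace(0.1, 6.0, 6000):
            a = h + s * direction
            if abs(np.linalg.norm(a - d) - r_da) < 1e-3:
                return np.array([d, h, a])
        raise AssertionError("could not construct geometry")

    def test_ideal_collinear_geometry_counts(self):
        x = self._frame(3.0, 180.0)
        assert hydrogen_bonds(x, [0], [1], [2]) == 1

    def test_angle_just_below_threshold_rejected(self):
        x = self._frame(3.0, 149.0)
        assert hydrogen_bonds(x, [0], [1], [2]) == 0
        x2 = self._frame(3.0, 151.0)
        assert hydrogen_bonds(x2, [0], [1], [2]) == 1

    def test_distance_boundary_is_strict(self):
        d = np.array([0.0, 0.0, 0.0])
        h = np.array([1.0, 0.0, 0.0])
        a = np.array([4.0, 0.0, 0.0])
        assert hydrogen_bonds(np.array([d, h, a]), [0], [1], [2]) == 0
        a2 = np.array([3.999, 0.0, 0.0])
        assert hydrogen_bonds(np.array([d, h, a2]), [0], [1], [2]) == 1


class TestRdfAndShell:
    def test_ideal_gas_rdf_is_unity(self):
        box = 20.0
        frames = [place_ideal_gas(400, box, seed=s) for s in range(30)]
        refs = np.arange(50)
        targets = np.arange(50, 400)
        r, g = rdf(frames, refs, targets, box, dr=0.5)
        sel = r > 2.0
        assert np.abs(g[sel] - 1.0).max() < 0.15
        assert np.mean(g[sel]) == pytest.approx(1.0, abs=0.02)

    def test_rmax_validation(self):
        with pytest.raises(ValueError):
            rdf([np.zeros((4, 3))], [0], [1, 2, 3], 10.0, r_max=8.0)

    def test_solvation_count_thresholds(self):
        solute = np.array([[0.0, 0.0, 0.0]])
        for r, expected in ((3.70, 1), (3.80, 0)):
            coords = np.vstack([solute, [[r, 0.0, 0.0]]])
            assert solvation_count(coords, [0], [1], box_edge=50.0) == expected
        assert solvation_count(solute, [0], [], box_edge=50.0) == 0

    def test_each_water_counted_once(self):
        solute = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]])
        water_o = np.array([[2.0, 0.0, 0.0]])   # close to both heavy atoms
        coords = np.vstack([solute, water_o])
        assert solvation_count(coords, [0, 1], [2], box_edge=50.0) == 1


class TestKabsch:
    def test_identical_structures(self, rng):
        a = rng.normal(size=(10, 3))
        assert kabsch_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        a = rng.normal(size=(10, 3))
        rot = Rotation.random(random_state=4).as_matrix()
        b = a @ rot.T + np.array([3.0, -1.0, 2.0])
        assert kabsch_rmsd(a, b) == pytest.approx(0.0, abs=1e-10)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(25):
            a = rng.normal(size=(5, 3))
            b = rng.normal(size=(5, 3))
            assert kabsch_rmsd(a, b) == pytest.approx(
                _quaternion_rmsd(a, b), abs=1e-10)

    def test_pseudometric_properties(self, rng):
        a, b, c = (rng.normal(size=(7, 3)) for _ in range(3))
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a), abs=1e-10)
        assert kabsch_rmsd(a, c) <= kabsch_rmsd(a, b) + kabsch_rmsd(b, c) + 1e-10

    def test_distribution_over_frames(self, rng):
        frames = [rng.normal(size=(6, 3)) for _ in range(8)]
        vals, centers, hist, mean = rmsd_distribution(frames, stride=1)
        assert len(vals) == 8 * 7 // 2
        assert mean == pytest.approx(vals.mean())


def _quaternion_rmsd(a, b):
    """Independent quaternion (Horn) superposition RMSD."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    m = ac.T @ bc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(key).max()
    e0 = np.sum(ac ** 2) + np.sum(bc ** 2)
    return math.sqrt(max(e0 - 2.0 * lam, 0.0) / a.shape[0])


class TestEquilibration:
    def test_table_of_scaled_times(self):
        # tau / sigma and the long-range-interaction corrections
        assert scaled_times(136.4, 4.0, 1.2) == (4.0, 34.1, 40.9)
        assert scaled_times(101.2, 4.0, 1.2)[1:] == (25.3, 30.4)
        assert scaled_times(80.9, 2.0, 1.13)[2] == 45.7
        assert scaled_times(63.6, 2.0, 1.13)[2] == 35.9

    def test_identity_scalings(self):
        sigma, ts, tsc = scaled_times(100.0, 1.0, 1.0)
        assert (sigma, ts, tsc) == (1.0, 100.0, 100.0)

    def test_parameter_recovery_from_synthetic_relaxation(self):
        # occupancy over 300 trajectories recorded every 0.25 ps for 10 tau2
        t = np.linspace(0.0, 1200.0, 4801)
        truth = dict(a0=0.94, a1=0.5, a2=0.2, tau1=30.0, tau2=120.0)
        p = sample_relaxation(**truth, t=t, n_traj=300, seed=9)
        fit = fit_equilibration(t, p, P_eq=0.94, dt_s=1.0)
        assert fit.converged
        taus = sorted([fit.tau1, fit.tau2])
        assert taus[0] == pytest.approx(30.0, rel=0.10)
        assert taus[1] == pytest.approx(120.0, rel=0.10)

    def test_tau_is_95_percent_crossing(self):
        t = np.linspace(0.0, 500.0, 401)
        p = 0.9 - 0.4 * np.exp(-t / 50.0) - 0.1 * np.exp(-t / 10.0)
        fit = fit_equilibration(t, p, P_eq=0.9, dt_s=2.0, slowdown=1.2)
        # analytic crossing of 0.855 for the noiseless curve
        crossing = t[np.argmax(p >= 0.95 * 0.9)]
        assert fit.tau == pytest.approx(crossing, abs=2.0)
        assert fit.tau_sigma == pytest.approx(round(fit.tau / 2.0, 1), abs=0.1)
        assert fit.tau_sigma_cor == pytest.approx(round(fit.tau_sigma * 1.2, 1), abs=0.1)

    def test_short_series_raises(self):
        with pytest.raises(ValueError):
            fit_equilibration([0, 1], [0.1, 0.2])
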