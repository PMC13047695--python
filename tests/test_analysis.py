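import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cgnmr import analysis, fixtures
from cgnmr.analysis import (
    HelixBundleSpec,
    contact_lifetimes,
    contact_lifetimes_from_series,
    dihedral_rmsd,
    free_energy_profile,
    msd_diffusion,
    pseudo_ramachandran,
    radial_profile,
    representative_structure,
    rmsd_coords,
    rmsf,
    s_matrix,
    stationarity_test,
    tau_omega,
    twist_angle,
    wrap_degrees,
)
from cgnmr.engine import KB
from cgnmr.errors import DegenerateInputError


class TestRMSD:
    def test_self_is_zero(self, peptide):
        out = rmsd_coords(peptide.coords[None], peptide.coords)
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_zero_after_alignment(self, peptide, rng):
        R = Rotation.random(random_state=1).as_matrix()
        moved = peptide.coords @ R.T + rng.normal(size=3)
        out = rmsd_coords(moved[None], peptide.coords)
        assert out[0] == pytest.approx(0.0, abs=1e-9)

    def test_uniform_displacement_pre_alignment(self, peptide):
        moved = peptide.coords + np.array([0.1, 0.0, 0.0])
        out = rmsd_coords(moved[None], peptide.coords, align=False)
        assert out[0] == pytest.approx(0.1, abs=1e-12)

    def test_small_selection_rejected(self, peptide):
        with pytest.raises(ValueError):
            rmsd_coords(peptide.coords[None], peptide.coords,
                        selection=[0, 1])


class TestRMSF:
    def test_static_trajectory_zero(self, peptide):
        frames = np.repeat(peptide.coords[None], 5, axis=0)
        np.testing.assert_allclose(rmsf(frames), 0.0, atol=1e-12)

    def test_two_frame_oscillation(self):
        # anchor triangle + a bead oscillating ±d: fluctuation = d
        base = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0],
                         [0, 0, 0.0]])
        d = 0.05
        f1, f2 = base.copy(), base.copy()
        f1[3, 2] = d
        f2[3, 2] = -d
        out = rmsf(np.stack([f1, f2]), selection=[0, 1, 2, 3],
                   align_selection=[0, 1, 2])
        assert out[3] == pytest.approx(d, abs=1e-9)

    def test_matches_two_pass_variance_oracle(self, peptide, rng):
        frames = peptide.coords + 0.01 * rng.normal(
            size=(6, *peptide.coords.shape))
        out = rmsf(frames)
        aligned = analysis.align_frames(frames, frames[0])
        mean = aligned.mean(axis=0)
        expected = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2),
                                   axis=0))
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_single_frame_rejected(self, peptide):
        with pytest.raises(DegenerateInputError):
            rmsf(peptide.coords[None])


class TestDihedralRMSD:
    def test_identical_zero(self, peptide):
        out = dihedral_rmsd(peptide, peptide.coords[None], peptide.coords)
        assert out[0] == pytest.approx(0.0, abs=1e-9)

    def test_wrapping(self):
        assert wrap_degrees(350.0) == pytest.approx(-10.0)
        assert wrap_degrees(-350.0) == pytest.approx(10.0)
        assert wrap_degrees(180.0) == pytest.approx(180.0)

    def test_periodicity_invariance(self, peptide, rng):
        frames = peptide.coords + 0.02 * rng.normal(
            size=(3, *peptide.coords.shape))
        a = dihedral_rmsd(peptide, frames, peptide.coords)
        angles, _ = analysis.backbone_dihedrals(peptide, frames)
        ref, _ = analysis.backbone_dihedrals(peptide,
                                             peptide.coords[None])
        diff = wrap_degrees(angles - ref[0] + 360.0)
        b = np.sqrt(np.mean(diff ** 2, axis=1))
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_matches_per_angle_loop_oracle(self, peptide, rng):
        frames = peptide.coords + 0.02 * rng.normal(
            size=(2, *peptide.coords.shape))
        out = dihedral_rmsd(peptide, frames, peptide.coords)
        angles, owners = analysis.backbone_dihedrals(peptide, frames)
        ref, _ = analysis.backbone_dihedrals(peptide, peptide.coords[None])
        for k in range(2):
            sq = [wrap_degrees(angles[k, c] - ref[0, c]) ** 2
                  for c in range(len(owners))]
            assert out[k] == pytest.approx(np.sqrt(np.mean(sq)), abs=1e-9)


class TestPseudoRamachandran:
    def test_single_frame_single_point(self, peptide):
        out = pseudo_ramachandran(peptide, peptide.coords[None])
        for samples in out.values():
            assert samples.shape == (1, 2)

    def test_terminal_residues_excluded(self, peptide):
        out = pseudo_ramachandran(peptide, peptide.coords[None])
        assert 0 not in out
        assert peptide.n_residues - 1 not in out

    def test_sample_count(self, peptide, rng):
        frames = peptide.coords + 0.01 * rng.normal(
            size=(4, *peptide.coords.shape))
        out = pseudo_ramachandran(peptide, frames)
        total = sum(v.shape[0] for v in out.values())
        assert total == 4 * len(out)


class TestSMatrix:
    def _ensemble(self, rng, n_frames=4, n=5, offset=0.0):
        return offset + rng.uniform(0, 1, size=(n_frames, n, 3))

    def test_identical_ensembles_zero(self, rng):
        ens = self._ensemble(rng)
        sm = s_matrix(ens, ens.copy())
        np.testing.assert_allclose(sm.values, 0.0, atol=1e-12)

    def test_disjoint_supports_two(self, rng):
        a = self._ensemble(rng)
        b = a * 10.0                   # pair distances shifted out of a's bins
        sm = s_matrix(a, b, bin_range=(0.0, 20.0))
        off_diag = sm.values[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off_diag, 2.0, atol=1e-12)

    def test_symmetric_zero_diagonal_bounded(self, rng):
        sm = s_matrix(self._ensemble(rng), self._ensemble(rng))
        np.testing.assert_allclose(sm.values, sm.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(sm.values), 0.0)
        assert np.all(sm.values >= 0) and np.all(sm.values <= 2)

    def test_hand_binned_toy(self):
        # two beads; ensemble A distances {0.15, 0.25}, B distances {0.15}
        a = np.zeros((2, 2, 3))
        a[0, 1, 0] = 0.15
        a[1, 1, 0] = 0.25
        b = np.zeros((1, 2, 3))
        b[0, 1, 0] = 0.15
        sm = s_matrix(a, b, bin_width=0.1, bin_range=(0.0, 0.5))
        # A: [0.5, 0.5] in bins 1 and 2; B: [1, 0] → L1 = 0.5 + 0.5 = 1.0
        assert sm.values[0, 1] == pytest.approx(1.0)

    def test_out_of_range_data_rejected(self, rng):
        with pytest.raises(ValueError):
            s_matrix(self._ensemble(rng), self._ensemble(rng),
                     bin_range=(0.0, 0.1))

    def test_mixture_monotonicity(self, rng):
        a = self._ensemble(rng, n_frames=8)
        b = self._ensemble(rng, n_frames=8, offset=0.5)
        mix = np.concatenate([a, b])
        s_ab = s_matrix(a, b, bin_range=(0, 5)).values
        s_amix = s_matrix(a, mix, bin_range=(0, 5)).values
        assert np.all(s_amix <= s_ab + 1e-9)


class TestTauOmega:
    def _frames(self, vectors, starts=None):
        # one frame; helix i runs from starts[i] to starts[i]+vectors[i]
        n = len(vectors)
        starts = np.zeros((n, 3)) if starts is None else np.asarray(starts)
        frame = np.zeros((1, 2 * n, 3))
        for i, (s, v) in enumerate(zip(starts, vectors)):
            frame[0, 2 * i] = s
            frame[0, 2 * i + 1] = s + v
        helices = [(2 * i, 2 * i + 1) for i in range(n)]
        return frame, helices

    def test_parallel_to_normal_tau_zero(self):
        frame, helices = self._frames([[0, 0, 1.0]] * 3,
                                      starts=np.eye(3))
        spec = HelixBundleSpec(helices, b0=[0, 0, 1.0])
        tau, _ = tau_omega(frame, spec)
        assert tau[0] == pytest.approx(0.0, abs=1e-9)

    def test_single_helix_omega_printed_convention(self):
        # bundle axis = start − end is antiparallel to the helix vector
        frame, helices = self._frames([[0, 0, 1.0]])
        spec = HelixBundleSpec(helices, b0=[0, 0, 1.0])
        _, omega = tau_omega(frame, spec)
        assert omega[0] == pytest.approx(180.0)

    def test_symmetric_cone_tau_equals_half_angle(self):
        phi = 25.0
        vectors = []
        for azimuth in np.linspace(0, 2 * np.pi, 6, endpoint=False):
            s, c = np.sin(np.deg2rad(phi)), np.cos(np.deg2rad(phi))
            vectors.append([s * np.cos(azimuth), s * np.sin(azimuth), c])
        frame, helices = self._frames(vectors, starts=np.random.RandomState(0)
                                      .rand(6, 3))
        spec = HelixBundleSpec(helices, b0=[0, 0, 1.0])
        tau, _ = tau_omega(frame, spec)
        assert tau[0] == pytest.approx(phi, abs=1e-9)

    def test_zero_length_helix_rejected(self):
        with pytest.raises(ValueError):
            HelixBundleSpec([(0, 0)], b0=[0, 0, 1])


class TestFreeEnergy:
    def test_density_ratio_e_gives_kbt(self):
        # two bins populated 1:e give ΔF exactly k_B·T... construct via
        # explicit densities: n and round(n·e) samples
        n1, n2 = 1000, int(round(1000 * np.e))
        samples = np.concatenate([np.full(n1, 0.25), np.full(n2, 0.75)])
        prof = free_energy_profile(samples, bins=[0.0, 0.5, 1.0], n_bootstrap=2)
        dF = prof.free_energy[0] - prof.free_energy[1]
        expected = KB * 300.0 * np.log(n2 / n1)
        assert dF == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(KB * 300.0, rel=2e-4)

    def test_single_occupied_bin_zero(self):
        prof = free_energy_profile(np.full(50, 0.5), bins=[0.0, 1.0])
        assert prof.free_energy[0] == pytest.approx(0.0)

    def test_degenerate_bootstrap_sigma_zero(self):
        prof = free_energy_profile(np.full(50, 0.5), bins=[0.0, 1.0],
                                   n_bootstrap=50)
        assert prof.sigma[0] == pytest.approx(0.0, abs=1e-15)

    def test_empty_bin_masked_not_inf(self):
        prof = free_energy_profile(np.full(10, 0.25),
                                   bins=[0.0, 0.5, 1.0])
        assert np.isnan(prof.free_energy[1])
        assert np.isfinite(prof.free_energy[0])

    def test_normalization_invariance_of_differences(self, rng):
        samples = rng.normal(0.5, 0.1, size=2000)
        bins = np.linspace(0, 1, 11)
        p1 = free_energy_profile(samples, bins, n_bootstrap=2)
        p2 = free_energy_profile(np.repeat(samples, 2), bins, n_bootstrap=2)
        d1 = p1.free_energy - np.nanmin(p1.free_energy)
        d2 = p2.free_energy - np.nanmin(p2.free_energy)
        np.testing.assert_allclose(d1, d2, atol=1e-12, equal_nan=True)


class TestContactLifetimes:
    def test_hand_traced_hysteresis(self):
        events = contact_lifetimes_from_series(
            [1.2, 0.7, 0.9, 1.1], frame_spacing=10.0)
        assert list(events.lifetimes) == [20.0]
        assert events.censored == 0

    def test_never_below_r0_no_contacts(self):
        events = contact_lifetimes_from_series(
            [0.9, 0.85, 0.95], frame_spacing=10.0)
        assert len(events.lifetimes) == 0

    def test_constant_contact_censored(self):
        events = contact_lifetimes_from_series(
            [0.7, 0.7, 0.7], frame_spacing=10.0)
        assert len(events.lifetimes) == 0
        assert events.censored == 1
        assert np.isnan(events.mean_lifetime())

    def test_trajectory_wrapper_matches_series(self):
        traj = fixtures.scripted_trajectory([1.2, 0.7, 0.9, 1.1],
                                            frame_spacing=10.0)
        events = contact_lifetimes(traj, [([0], [1])])
        assert list(events[0].lifetimes) == [20.0]


class TestMSDDiffusion:
    def test_static_bead_zero_d(self):
        traj = fixtures.brownian_trajectory(1, 200, D=0.0, seed=0)
        out = msd_diffusion(traj, selection=[4], core_selection=[0, 1, 2, 3])
        assert out.D[0] == pytest.approx(0.0, abs=1e-12)

    def test_brownian_recovery(self):
        D_true = 1e-3
        estimates = []
        for seed in range(3):
            traj = fixtures.brownian_trajectory(20, 4000, D=D_true,
                                                seed=seed)
            out = msd_diffusion(traj, selection=np.arange(4, 24),
                                core_selection=[0, 1, 2, 3])
            estimates.append(out.D.mean())
        assert np.mean(estimates) == pytest.approx(D_true, rel=0.15)

    def test_ballistic_flagged_superdiffusive(self):
        n_frames = 120
        frames = np.zeros((n_frames, 5, 3))
        frames[:, :4] = np.random.RandomState(0).rand(4, 3)
        frames[:, 4, 0] = 0.05 * np.arange(n_frames)   # constant drift
        traj = fixtures.scripted_trajectory(
            displacement_script=frames, frame_spacing=10.0)
        out = msd_diffusion(traj, selection=[4], core_selection=[0, 1, 2, 3])
        assert out.pearson_r[0] > 0.97
        assert out.superdiffusive[0]

    def test_short_trajectory_rejected(self):
        traj = fixtures.brownian_trajectory(2, 30, D=1e-3, seed=0)
        with pytest.raises(DegenerateInputError):
            msd_diffusion(traj, [4], [0, 1, 2, 3])


class TestRadialProfile:
    def test_uniform_slab_flat_profile(self, rng):
        n = 40000
        r = np.sqrt(rng.uniform(0.0, 1.0, n)) * 2.0
        phi = rng.uniform(0, 2 * np.pi, n)
        z = rng.uniform(0.0, 1.0, n)
        frame = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])[None]
        c = radial_profile(frame, np.arange(n), [(0.0, 0.0)], 0.0, 1.0,
                           np.linspace(0.5, 2.0, 6), excluded_fraction=0.0)
        assert np.std(c) / np.mean(c) < 0.05

    def test_empty_shell_zero(self):
        frame = np.zeros((1, 3, 3))
        c = radial_profile(frame, [0, 1, 2], [(5.0, 5.0)], -1.0, 1.0,
                           [0.0, 0.5, 1.0])
        np.testing.assert_allclose(c, 0.0)

    def test_doubling_slab_halves_density(self, rng):
        frame = rng.uniform(0, 1, size=(1, 500, 3))
        args = (np.arange(500), [(0.5, 0.5)])
        c1 = radial_profile(frame, *args, 0.0, 1.0, [0.0, 1.0], 0.0)
        c2 = radial_profile(frame, *args, -0.5, 1.5, [0.0, 1.0], 0.0)
        np.testing.assert_allclose(c2, c1 / 2.0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            radial_profile(np.zeros((1, 1, 3)), [0], [(0, 0)], 0, 1,
                           [0, 1], excluded_fraction=1.0)


class TestTwist:
    def _layers(self, n_layers, rotation_per_layer=0.0, rise=0.5):
        # rotation axis passes through the 'b' reference-bead column, so
        # the inter-layer dihedral equals the rotation exactly
        frames = np.zeros((1, 2 * n_layers, 3))
        base = np.array([[1.0, 0.0], [0.0, 0.0]])
        layer_beads = []
        for i in range(n_layers):
            phi = np.deg2rad(rotation_per_layer * i)
            R = np.array([[np.cos(phi), -np.sin(phi)],
                          [np.sin(phi), np.cos(phi)]])
            xy = base @ R.T
            frames[0, 2 * i, :2] = xy[0]
            frames[0, 2 * i + 1, :2] = xy[1]
            frames[0, 2 * i:2 * i + 2, 2] = i * rise
            layer_beads.append((2 * i, 2 * i + 1))
        return frames, layer_beads

    def test_translated_layers_zero_twist(self):
        frames, layers = self._layers(4)
        assert twist_angle(frames, layers)[0] == pytest.approx(0.0, abs=1e-9)

    def test_rotated_layers_twist_equals_phi(self):
        frames, layers = self._layers(4, rotation_per_layer=15.0)
        assert abs(twist_angle(frames, layers)[0]) == pytest.approx(
            15.0, abs=1e-9)

    def test_mean_matches_per_interface_oracle(self):
        frames, layers = self._layers(5, rotation_per_layer=10.0)
        from cgnmr.geometry import dihedral
        per_interface = []
        for i in range(4):
            a, b = layers[i]
            c, d = layers[i + 1]
            per_interface.append(np.rad2deg(dihedral(
                frames[0, a], frames[0, b], frames[0, d], frames[0, c])))
        assert twist_angle(frames, layers)[0] == pytest.approx(
            np.mean(per_interface))

    def test_missing_layer_skipped_with_warning(self):
        frames, layers = self._layers(4, rotation_per_layer=5.0)
        layers[1] = None
        with pytest.warns(UserWarning):
            out = twist_angle(frames, layers)
        assert np.isfinite(out[0])


class TestStationarity:
    def test_white_noise_rejects_unit_root(self, rng):
        stat, p = stationarity_test(rng.normal(size=500))
        assert p < 0.05

    def test_random_walk_fails_to_reject(self, rng):
        walk = np.cumsum(rng.normal(size=500))
        _, p = stationarity_test(walk)
        assert p > 0.05

    def test_short_series_rejected(self):
        with pytest.raises(DegenerateInputError):
            stationarity_test(np.arange(10))

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateInputError):
            stationarity_test(np.full(50, 1.0))


class TestRepresentative:
    def test_identical_frames_lowest_index(self, peptide):
        frames = np.repeat(peptide.coords[None], 4, axis=0)
        assert representative_structure(frames) == 0

    def test_central_frame_of_cluster(self, peptide, rng):
        spread = 0.3 * rng.normal(size=(9, *peptide.coords.shape))
        spread[4] = 0.0                # frame 4 sits at the cluster center
        frames = peptide.coords + spread - spread.mean(axis=0)
        assert representative_structure(frames) == 4

    def test_invariant_to_frame_order(self, peptide, rng):
        frames = peptide.coords + 0.1 * rng.normal(
            size=(7, *peptide.coords.shape))
        k1 = representative_structure(frames)
        perm = np.array([3, 1, 4, 0, 6, 2, 5])
        k2 = representative_structure(frames[perm])
        assert perm[k2] == k1
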