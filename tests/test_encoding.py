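"""Operator-correctness tests: NUFFT accuracy against a brute-force DFT,
adjoint dot-product identities, and dense-matrix equivalence of the full
encoding operator on a small instance."""

import numpy as np
import pytest

from lrmcperf.encoding import (GOLDEN_ANGLE_DEG, CoilMaps, EncodingOperator,
                               GriddedNufft, TrajectorySpec, apply_coils,
                               combine_coils, radial_trajectory, ramp_dcf)
from lrmcperf.motion import MotionFieldSeries, warp_matrix
from lrmcperf.subspace import TemporalSubspace


def direct_dft(image, coords):
    """Double-loop nonuniform DFT oracle (origin at floor(N/2))."""
    n = np.arange(image.shape[0]) - image.shape[0] // 2
    out = np.empty(len(coords), dtype=complex)
    for i, (ky, kx) in enumerate(coords):
        phase = np.exp(-2j * np.pi * (ky * n[:, None] + kx * n[None, :]))
        out[i] = (image * phase).sum()
    return out


@pytest.fixture(scope="module")
def random_instance(  ):
    rng = np.random.default_rng(0)
    img = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
    coords = rng.uniform(-0.5, 0.4999, size=(100, 2))
    return img, coords


class TestNufft:
    def test_matches_direct_dft(self, random_instance):
        img, coords = random_instance
        nu = GriddedNufft(16, coords)
        ref = direct_dft(img, coords)
        err = np.abs(nu.forward(img) - ref).max() / np.abs(ref).max()
        assert err < 1e-6

    def test_zero_image_maps_to_zero(self, random_instance):
        _, coords = random_instance
        assert np.all(GriddedNufft(16, coords).forward(np.zeros((16, 16))) == 0)

    def test_center_impulse_has_unit_magnitude(self, random_instance):
        _, coords = random_instance
        imp = np.zeros((16, 16), dtype=complex)
        imp[8, 8] = 1.0
        mags = np.abs(GriddedNufft(16, coords).forward(imp))
        assert np.allclose(mags, 1.0, atol=1e-6)

    def test_adjoint_dot_product(self, random_instance):
        img, coords = random_instance
        rng = np.random.default_rng(5)
        nu = GriddedNufft(16, coords)
        y = rng.normal(size=100) + 1j * rng.normal(size=100)
        lhs = np.vdot(y, nu.forward(img))
        rhs = np.vdot(nu.adjoint(y), img)
        assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_zero_samples_map_to_zero_image(self, random_instance):
        _, coords = random_instance
        assert np.all(GriddedNufft(16, coords).adjoint(np.zeros(100)) == 0)

    def test_out_of_range_coordinates_rejected(self):
        bad = np.array([[0.7, 0.0]])
        with pytest.raises(ValueError):
            GriddedNufft(16, bad)

    def test_gridded_point_object_peaks_at_object_pixel(self):
        # dense radial set, point object off-center; density-compensated
        # adjoint must peak at the object pixel
        n = 32
        traj = radial_trajectory(1, 51, 64)
        img = np.zeros((n, n), dtype=complex)
        img[20, 13] = 1.0
        nu = GriddedNufft(n, traj.frame_coords(0))
        k = nu.forward(img)
        recon = nu.adjoint(k, dcf=ramp_dcf(traj).ravel())
        peak = np.unravel_index(np.abs(recon).argmax(), recon.shape)
        assert peak == (20, 13)


class TestTrajectory:
    def test_coordinates_within_half_cycle(self):
        traj = radial_trajectory(4, 13, 64)
        assert np.abs(traj.coordinates).max() <= 0.5

    def test_golden_angle_increment_across_frames(self):
        traj = radial_trajectory(3, 5, 16)
        # spoke m (global index) lies at angle m * GA; check via coordinates
        c = traj.coordinates[1, 0]  # frame 1, spoke 0 -> global index 5
        ang = np.rad2deg(np.arctan2(c[-1, 0], c[-1, 1]))  # outermost sample
        expected = (5 * GOLDEN_ANGLE_DEG) % 360
        assert np.isclose(ang % 180, expected % 180, atol=1e-6) or \
            np.isclose((ang + 180) % 180, expected % 180, atol=1e-6)

    def test_kspace_shape_validation(self, desk_phantom):
        traj = radial_trajectory(2, 3, 8)
        from lrmcperf.encoding import RadialKSpace
        with pytest.raises(ValueError):
            RadialKSpace(np.zeros((2, 1, 3, 9), dtype=complex), traj)


class TestCoils:
    def test_single_unit_coil_is_identity(self, rng):
        maps = CoilMaps(np.ones((1, 8, 8), dtype=complex))
        img = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        assert np.allclose(apply_coils(img, maps)[0], img)
        assert np.allclose(combine_coils(apply_coils(img, maps), maps), img)

    def test_adjoint_identity(self, rng):
        maps = CoilMaps(rng.normal(size=(3, 8, 8)) + 1j * rng.normal(size=(3, 8, 8)))
        x = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        y = rng.normal(size=(3, 8, 8)) + 1j * rng.normal(size=(3, 8, 8))
        lhs = np.vdot(y, apply_coils(x, maps))
        rhs = np.vdot(combine_coils(y, maps), x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-12

    def test_normal_operator_is_sum_of_squared_magnitudes(self, rng):
        maps = CoilMaps(rng.normal(size=(3, 8, 8)) + 1j * rng.normal(size=(3, 8, 8)))
        x = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        chc = combine_coils(apply_coils(x, maps), maps)
        assert np.allclose(chc, (np.abs(maps.maps) ** 2).sum(axis=0) * x)


def _small_operator(rng, n=8, n_frames=2, rank=2):
    traj = radial_trajectory(n_frames, 3, 2 * n)
    maps = CoilMaps((rng.normal(size=(1, n, n)) + 1j * rng.normal(size=(1, n, n))))
    fields = 1.5 * rng.normal(size=(n_frames, 2, n, n))
    motion = MotionFieldSeries(fields, -fields)
    q, _ = np.linalg.qr(rng.normal(size=(n_frames, rank)))
    sub = TemporalSubspace(q, np.ones(n_frames), 1.0)
    return EncodingOperator(traj, maps, motion=motion, subspace=sub), traj, maps, motion, sub


class TestFullOperator:
    def test_adjoint_dot_product(self, rng):
        op, traj, maps, _, sub = _small_operator(rng)
        y = rng.normal(size=(sub.rank, 8, 8)) + 1j * rng.normal(size=(sub.rank, 8, 8))
        k = rng.normal(size=(traj.n_frames, 1, 3, 16)) + 1j * rng.normal(size=(traj.n_frames, 1, 3, 16))
        lhs = np.vdot(k, op.forward(y))
        rhs = np.vdot(op.adjoint(k), y)
        assert abs(lhs - rhs) / abs(lhs) < 1e-5

    def test_linearity(self, rng):
        op, _, _, _, sub = _small_operator(rng)
        x = rng.normal(size=(sub.rank, 8, 8)) + 1j * rng.normal(size=(sub.rank, 8, 8))
        y = rng.normal(size=(sub.rank, 8, 8)) + 1j * rng.normal(size=(sub.rank, 8, 8))
        lhs = op.forward(2.0 * x + 0.5j * y)
        rhs = 2.0 * op.forward(x) + 0.5j * op.forward(y)
        assert np.abs(lhs - rhs).max() < 1e-8 * np.abs(rhs).max()

    def test_zero_kspace_gives_zero_stack(self, rng):
        op, traj, _, _, _ = _small_operator(rng)
        out = op.adjoint(np.zeros((traj.n_frames, 1, 3, 16), dtype=complex))
        assert np.all(out == 0)

    def test_matches_dense_matrix_composition(self, rng):
        """Column-by-column assembly of E equals the product of dense DFT,
        coil, warp and temporal-basis matrices (8x8, 2 frames, 1 coil)."""
        op, traj, maps, motion, sub = _small_operator(rng)
        n, r = 8, sub.rank
        n_samp = 3 * 16

        # dense oracle: per frame  A_t F_t C W_t  (pixel space), stacked
        grid = np.arange(n) - n // 2
        dense_rows = []
        for t in range(traj.n_frames):
            coords = traj.frame_coords(t)
            F = np.exp(-2j * np.pi * (coords[:, :1] * grid[None, :])).reshape(n_samp, n, 1) \
                * np.exp(-2j * np.pi * (coords[:, 1:] * grid[None, :])).reshape(n_samp, 1, n)
            F = F.reshape(n_samp, n * n)
            C = np.diag(maps.maps[0].ravel())
            W = warp_matrix(motion.forward[t]).toarray()
            dense_rows.append(F @ C @ W)
        E_frames = np.zeros((traj.n_frames * n_samp, traj.n_frames * n * n), dtype=complex)
        for t, block in enumerate(dense_rows):
            E_frames[t * n_samp:(t + 1) * n_samp, t * n * n:(t + 1) * n * n] = block
        U_kron = np.kron(sub.Ur, np.eye(n * n))
        E_dense = E_frames @ U_kron

        # operator columns
        for j in range(0, r * n * n, 17):  # sparse subset of columns
            e = np.zeros(r * n * n, dtype=complex)
            e[j] = 1.0
            col = op.forward(e.reshape(r, n, n)).ravel()
            assert np.abs(col - E_dense[:, j]).max() < 1e-8 * max(1.0, np.abs(E_dense[:, j]).max())

    def test_generative_model_consistency(self, desk_phantom):
        """With the exact temporal basis, true motion and coils, the forward
        model reproduces the noiseless acquisition."""
        from lrmcperf.phantom import sample_kspace
        from lrmcperf.subspace import estimate_subspace
        ph = desk_phantom
        k0 = sample_kspace(ph, noise_fraction=0.0)
        sub = estimate_subspace(ph.reference_series, fixed_rank=6)
        op = EncodingOperator(k0.traj, ph.coil_maps, motion=ph.motion_fields,
                              subspace=sub)
        pred = op.forward(sub.project(ph.reference_series))
        resid = np.linalg.norm(pred - k0.data) / np.linalg.norm(k0.data)
        assert resid < 1e-3
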