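"""Forward diffraction simulation and the enumeration oracle."""

import numpy as np
import pytest

import padfkit as pk


class TestHexagonModel:
    def test_pair_distance_multiset(self, hexagon):
        pos = hexagon.positions
        dists = []
        for i in range(6):
            for j in range(6):
                if i != j:
                    dists.append(np.linalg.norm(pos[i] - pos[j]))
        dists = np.sort(dists)
        expected = np.sort([15.0] * 12 + [15.0 * np.sqrt(3)] * 12 + [30.0] * 6)
        assert np.allclose(dists, expected, rtol=1e-9)

    def test_circumradius_equals_side(self, hexagon):
        assert np.allclose(np.linalg.norm(hexagon.positions, axis=1), 15.0)

    def test_centroid_at_origin(self, hexagon):
        assert np.allclose(hexagon.positions.mean(axis=0), 0.0, atol=1e-12)

    def test_invalid_distance_rejected(self):
        with pytest.raises(ValueError):
            pk.make_hexagon(0.0)


class TestRandomRotations:
    def test_deterministic_under_seed(self):
        a = pk.random_rotations(5, np.random.default_rng(42))
        b = pk.random_rotations(5, np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_proper_orthogonal(self, rng):
        R = pk.random_rotations(50, rng)
        eye = np.einsum("nij,nkj->nik", R, R)
        assert np.allclose(eye, np.eye(3), atol=1e-12)
        assert np.allclose(np.linalg.det(R), 1.0, atol=1e-12)

    def test_orientation_average_is_isotropic(self, rng):
        # Monte-Carlo uniformity: the mean rotated z-axis vanishes
        R = pk.random_rotations(10_000, rng)
        mean_z = (R @ np.array([0.0, 0.0, 1.0])).mean(axis=0)
        assert np.linalg.norm(mean_z) < 0.05


class TestSimulatePattern:
    def test_single_atom_gives_unit_intensity_everywhere(self, small_geom):
        model = pk.StructureModel(np.zeros((1, 3)), [1.0], [0.0])
        I = pk.simulate_pattern(model, np.eye(3), small_geom)
        assert np.allclose(I, 1.0, rtol=1e-12)

    def test_translation_invariance_of_intensity(self, small_geom, hexagon):
        I0 = pk.simulate_pattern(hexagon, np.eye(3), small_geom)
        shifted = pk.StructureModel(
            hexagon.positions + np.array([3.0, -2.0, 1.5]), hexagon.f0, hexagon.b
        )
        I1 = pk.simulate_pattern(shifted, np.eye(3), small_geom)
        assert np.max(np.abs(I1 - I0)) < 1e-9 * I0.max()

    def test_two_atom_fringe_period(self):
        # two point atoms 10 nm apart along x: fringes at q_x = k/d
        d = 10.0
        g = pk.DetectorGeometry.for_edge_q(128, 1.28)
        model = pk.StructureModel(
            [[-d / 2, 0, 0], [d / 2, 0, 0]], [1.0, 1.0], [0.0, 0.0]
        )
        I = pk.simulate_pattern(model, np.eye(3), g)
        qx = g.ewald_qvectors()[:, 64, 0]  # central column, phi = 0 axis
        row = I[:, 64]
        # maxima of 2 + 2cos(2 pi qx d) sit at qx = k/d
        interior = np.arange(1, 127)
        is_max = (row[interior] > row[interior - 1]) & (row[interior] > row[interior + 1])
        peaks_qx = qx[interior][is_max]
        peaks_qx = peaks_qx[peaks_qx > 0.01]
        k = np.round(peaks_qx * d)
        assert np.allclose(peaks_qx, k / d, atol=0.15 / d)

    def test_solid_angle_attenuates_edges(self, small_geom, hexagon):
        plain = pk.simulate_pattern(hexagon, np.eye(3), small_geom)
        att = pk.simulate_pattern(hexagon, np.eye(3), small_geom, solid_angle=True)
        ratio = att / np.where(plain > 0, plain, 1.0)
        assert ratio[0, 0] < ratio[32, 32] <= 1.0 + 1e-12

    def test_poisson_noise_reproducible_and_negative_count_fatal(self, small_geom, hexagon):
        a = pk.simulate_pattern(hexagon, np.eye(3), small_geom, photons=1e4,
                                rng=np.random.default_rng(5))
        b = pk.simulate_pattern(hexagon, np.eye(3), small_geom, photons=1e4,
                                rng=np.random.default_rng(5))
        assert np.array_equal(a, b)
        assert np.all(a >= 0) and a.sum() > 0
        with pytest.raises(ValueError):
            pk.simulate_pattern(hexagon, np.eye(3), small_geom, photons=-1)


class TestSimulateDataset:
    def test_reproducible_under_seed(self, small_geom, hexagon):
        a = pk.simulate_dataset(hexagon, small_geom, 2, seed=3)
        b = pk.simulate_dataset(hexagon, small_geom, 2, seed=3)
        for pa, pb in zip(a.patterns, b.patterns):
            assert np.array_equal(pa, pb)
        assert np.array_equal(a.rotations, b.rotations)

    def test_intensities_non_negative(self, hex_midscale):
        for p in hex_midscale["dataset"].patterns[:20]:
            assert np.all(p >= 0)

    def test_ensemble_mean_ring_flattens_as_n_grows(self, hex_midscale):
        # rotational averaging: residual theta structure of the mean polar
        # pattern decays like 1/sqrt(n) toward isotropy
        q_grid = hex_midscale["polar"][0].q_grid
        sel = (q_grid > 0.2 * q_grid[-1]) & (q_grid < 0.9 * q_grid[-1])

        def flatness(n):
            mean_polar = np.mean(
                [p.values for p in hex_midscale["polar"][:n]], axis=0
            )[sel]
            return np.median(mean_polar.std(axis=1) / mean_polar.mean(axis=1))

        f100, f400 = flatness(100), flatness(400)
        assert f100 < 0.2
        assert f400 < 0.7 * f100  # consistent with 1/sqrt(n) (ideal: 0.5)

    def test_friedel_symmetry_in_flat_ewald_regime(self):
        # where the Ewald offset 2 q_z is negligible against 1/(object size),
        # rings are centrosymmetric: I(q, theta) ~ I(q, theta + pi)
        geom = pk.DetectorGeometry.for_edge_q(64, 0.04)  # low-q detector
        ds = pk.simulate_dataset(pk.make_hexagon(15.0), geom, 1, seed=5)
        pol = pk.to_polar(ds.patterns[0], geom, 16, 180)
        rows = np.where((pol.q_grid > 0.008) & (pol.q_grid <= 0.025))[0]
        assert len(rows) >= 4
        for k in rows:
            ring = pol.values[k]
            flipped = np.roll(ring, pol.ntheta // 2)
            assert np.max(np.abs(ring - flipped)) < 0.01 * ring.max()

    def test_write_produces_files_and_manifest(self, tmp_path, small_geom, hexagon):
        ds = pk.simulate_dataset(hexagon, small_geom, 3, seed=0)
        paths = ds.write(tmp_path, tag="sim")
        assert len(paths) == 3 and all(p.exists() for p in paths)
        assert (tmp_path / "sim_manifest.json").exists()
        assert np.array_equal(np.load(paths[1]), ds.patterns[1])


class TestModelPadfOracle:
    def test_hexagon_diagonal_support(self, hexagon):
        # bins centred on multiples of 0.5 nm so exact distances avoid edges
        r_edges = np.arange(0.25, 35.0, 0.5)
        th_edges = np.arange(0.0, 181.0, 2.0)
        hist = pk.model_padf_oracle(hexagon, r_edges, th_edges)
        diag = hist[np.arange(len(r_edges) - 1), np.arange(len(r_edges) - 1), :]
        occupied = np.where(diag.sum(axis=1) > 0)[0]
        centres = 0.5 * (r_edges[:-1] + r_edges[1:])[occupied]
        assert np.allclose(np.sort(centres), [15.0, 26.0, 30.0], atol=0.3)

    def test_two_atom_model_all_weight_at_0_and_180(self):
        model = pk.StructureModel([[0, 0, 0], [7, 0, 0]], [1, 1], [0, 0])
        r_edges = np.arange(0.0, 10.0, 1.0)
        th_edges = np.arange(0.0, 181.0, 1.0)
        hist = pk.model_padf_oracle(model, r_edges, th_edges)
        ang = hist.sum(axis=(0, 1))
        nz = np.where(ang > 0)[0]
        assert set(nz) <= {0, 179}
        assert hist.sum() == 4  # 2 ordered pairs, squared

    def test_hexagon_ideal_peak_ratios(self, hexagon):
        # counts at the principal (r, r, 120 deg) peaks: 48 : 48 : 12
        r_edges = np.arange(0.25, 35.0, 0.5)
        th_edges = np.arange(-0.5, 181.0, 1.0)  # bins centred on whole degrees
        hist = pk.model_padf_oracle(hexagon, r_edges, th_edges)
        centres = 0.5 * (r_edges[:-1] + r_edges[1:])

        def peak(rval, tlo, thi):
            i = np.argmin(np.abs(centres - rval))
            sel = hist[i, i, (th_edges[:-1] >= tlo) & (th_edges[:-1] < thi)]
            return sel.max()

        A = peak(15.0, 100, 140)
        B = peak(15 * np.sqrt(3), 100, 140)
        C = peak(30.0, 100, 140)
        assert B / A == pytest.approx(1.0)
        assert C / A == pytest.approx(0.25)
        assert peak(15.0, 40, 80) == A  # 60 and 120 degree peaks are equal

    def test_oracle_symmetries_for_centrosymmetric_model(self, hexagon):
        r_edges = np.arange(0.0, 35.0, 1.0)
        # angular bins centred on even degrees so the 180 - theta mirror is exact
        th_edges = np.arange(-1.0, 182.0, 2.0)
        hist = pk.model_padf_oracle(hexagon, r_edges, th_edges)
        assert np.allclose(hist, np.swapaxes(hist, 0, 1))
        assert np.allclose(hist, hist[:, :, ::-1])  # theta -> 180 - theta
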