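"""Legendre inversion, discrete spherical Bessel transforms and reassembly."""

import numpy as np
import pytest
from scipy.special import spherical_jn

import padfkit as pk
from padfkit.padf import sbt_forward_matrix, sbt_matrix
from tests.conftest import random_polar_set


class TestLegendreArgument:
    def test_flat_ewald_limit_reduces_to_cos_theta(self):
        th = np.linspace(0, 2 * np.pi, 37)
        cospsi = pk.legendre_argument(1.0, 1.0, th, wavelength=1e-6)
        assert np.allclose(cospsi, np.cos(th), atol=1e-6)

    def test_equal_q_zero_separation_gives_one(self):
        assert pk.legendre_argument(0.9, 0.9, 0.0, 0.1) == pytest.approx(1.0, abs=1e-14)

    def test_matches_ewald_vector_dot_product(self, rng):
        # geometric oracle: build the two Ewald-sphere vectors explicitly
        lam = 0.1

        def qvec(q, phi):
            ths = 2 * np.arcsin(q * lam / 2)
            return np.array(
                [np.sin(ths) * np.cos(phi), np.sin(ths) * np.sin(phi),
                 np.cos(ths) - 1.0]
            ) / lam

        for _ in range(100):
            q, qp = rng.uniform(0.05, 1.28, 2)
            dphi = rng.uniform(0, 2 * np.pi)
            v1, v2 = qvec(q, 0.0), qvec(qp, dphi)
            expected = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            got = pk.legendre_argument(q, qp, dphi, lam)
            assert abs(got - expected) < 1e-10

    def test_beyond_backscattering_fatal(self):
        with pytest.raises(ValueError):
            pk.legendre_argument(25.0, 1.0, 0.0, 0.1)


def planted_bl_volume(nq=16, nth=90, lmax=8, lam=0.05, qmax=1.0, seed=0):
    rng = np.random.default_rng(seed)
    ls = np.arange(0, lmax + 2, 2)
    data = rng.standard_normal((len(ls), nq, nq))
    data = 0.5 * (data + np.swapaxes(data, 1, 2))  # Bl(q,q') symmetric
    blq = pk.BlMatrixSetQ(
        data=data, ls=ls, wavelength=lam, sampling="uniform",
        q_grid=np.linspace(0, qmax, nq),
    )
    return blq, pk.synthesize_correlation(blq, nth)


class TestExtractBl:
    def test_flat_correlation_is_pure_l0(self):
        C = pk.CorrelationVolume(np.ones((6, 6, 90)), qmax=1.0)
        Cw = pk.apply_sintheta_weight(C)
        bl = pk.extract_bl(Cw, l_max=8, wavelength=0.05)
        assert np.allclose(bl.data[0], 1.0, atol=1e-9)
        assert np.max(np.abs(bl.data[1:])) < 1e-9

    def test_round_trip_recovers_planted_even_orders(self):
        blq, C = planted_bl_volume()
        rec = pk.extract_bl(C, l_max=8, wavelength=0.05)
        assert np.max(np.abs(rec.data - blq.data)) < 1e-6

    def test_result_independent_of_conditioning_exponent(self):
        blq, _ = planted_bl_volume(nq=8, seed=3)
        raw = pk.synthesize_correlation(blq, 90, conditioned=False)
        outs = []
        for expo in (0.5, 1.0, 2.0):
            outs.append(
                pk.extract_bl(
                    pk.apply_sintheta_weight(raw, expo), 8, 0.05
                ).data
            )
        assert np.max(np.abs(outs[0] - outs[1])) < 1e-8
        assert np.max(np.abs(outs[0] - outs[2])) < 1e-8

    def test_bl_matrices_symmetric(self):
        pats = random_polar_set(4, 8, 90, seed=6)
        C = pk.apply_sintheta_weight(pk.dataset_correlation(pats))
        bl = pk.extract_bl(C, 8, 0.05)
        assert np.allclose(bl.data, np.swapaxes(bl.data, 1, 2), rtol=1e-9, atol=1e-12)

    def test_unconditioned_volume_refused_unless_overridden(self):
        C = pk.CorrelationVolume(np.ones((4, 4, 36)), qmax=1.0)
        with pytest.raises(ValueError, match="sin"):
            pk.extract_bl(C, 4, 0.05)
        bl = pk.extract_bl(C, 4, 0.05, allow_unconditioned=True)
        assert bl.data.shape == (3, 4, 4)

    def test_odd_lmax_fatal(self):
        C = pk.apply_sintheta_weight(pk.CorrelationVolume(np.ones((4, 4, 36)), qmax=1.0))
        with pytest.raises(ValueError):
            pk.extract_bl(C, 7, 0.05)

    def test_theta_zero_masked_volume_still_inverts(self):
        blq, C = planted_bl_volume(nq=8, nth=180, seed=9)
        Cm = pk.theta_zero_mask(C, 4.0)
        rec = pk.extract_bl(Cm, 8, 0.05)
        assert np.max(np.abs(rec.data - blq.data)) < 1e-6


class TestResampleBl:
    def test_j0_zeros_are_uniform(self):
        z = pk.jl_zeros(0, 10)
        assert np.allclose(z, np.arange(1, 11) * np.pi, atol=1e-10)

    def test_jl_zeros_interlace_and_are_zeros(self):
        for l in (1, 2, 8, 32):
            z = pk.jl_zeros(l, 12)
            assert np.all(np.diff(z) > 0)
            assert np.max(np.abs(spherical_jn(l, z))) < 1e-10

    def test_identity_when_grids_coincide(self):
        nq = 17
        rng = np.random.default_rng(0)
        data = rng.standard_normal((1, nq, nq))
        blq = pk.BlMatrixSetQ(data=data, ls=np.array([0]), wavelength=0.1,
                              q_grid=np.linspace(0, 1.0, nq))
        out = pk.resample_bl(blq, nr=nq - 1)
        assert np.array_equal(out.data[0], data[0, 1:, 1:])

    def test_smooth_function_interpolates_accurately(self):
        nq = 64
        qs = np.linspace(0, 1.0, nq)
        f = lambda qa, qb: np.exp(-((qa - 0.4) ** 2 + (qb - 0.5) ** 2) / 0.02)
        QA, QB = np.meshgrid(qs, qs, indexing="ij")
        blq = pk.BlMatrixSetQ(
            data=np.stack([f(QA, QB), f(QA, QB)]), ls=np.array([0, 2]),
            wavelength=0.1, q_grid=qs,
        )
        out = pk.resample_bl(blq, nr=40, rmax=25.0)
        ql = out.q_grids[1]
        inside = ql <= 1.0
        QA2, QB2 = np.meshgrid(ql[inside], ql[inside], indexing="ij")
        expected = f(QA2, QB2)
        err = np.abs(out.data[1][np.ix_(inside, inside)] - expected)
        assert err.max() < 1e-3 * expected.max()

    def test_out_of_range_samples_are_zero(self):
        nq = 16
        blq = pk.BlMatrixSetQ(
            data=np.ones((1, nq, nq)), ls=np.array([2]), wavelength=0.1,
            q_grid=np.linspace(0, 1.0, nq),
        )
        out = pk.resample_bl(blq, nr=30, rmax=10.0)  # grid extends past qmax
        ql = out.q_grids[0]
        outside = ql > 1.0
        assert outside.any()
        assert np.all(out.data[0][outside, :] == 0)

    def test_invalid_rmax_fatal(self):
        blq = pk.BlMatrixSetQ(
            data=np.ones((1, 4, 4)), ls=np.array([0]), wavelength=0.1,
            q_grid=np.linspace(0, 1, 4),
        )
        with pytest.raises(ValueError):
            pk.resample_bl(blq, nr=4, rmax=-1.0)


class TestSphericalBesselTransform:
    def test_zero_input_gives_zero_output(self):
        blq = pk.BlMatrixSetQ(
            data=np.zeros((1, 8, 8)), ls=np.array([0]), wavelength=0.1,
            sampling="bessel", q_grids=[pk.jl_zeros(0, 8) / (2 * np.pi * 5.0)],
            rmax=5.0,
        )
        blr = pk.sbt_bl(blq)
        assert np.all(blr.data == 0)

    @pytest.mark.parametrize("l", [0, 2, 6])
    def test_forward_then_inverse_recovers_band_limited_function(self, l):
        N, R = 64, 10.0
        z = pk.jl_zeros(l, N + 1)
        rng = np.random.default_rng(l)
        coeff = rng.standard_normal(8)

        def f(r):
            return sum(c * spherical_jn(l, z[m] * r / R) for m, c in enumerate(coeff))

        nodes = z[:N] * R / z[N]  # forward sampling radii
        fhat = sbt_forward_matrix(l, N, R) @ f(nodes)
        back = sbt_matrix(l, N, R, nodes) @ fhat
        assert np.max(np.abs(back - f(nodes))) < 1e-6 * np.max(np.abs(f(nodes)))

    def test_single_shell_peaks_at_shell_radius(self):
        # Bl built from a single spherical shell at r0 localizes at (r0, r0)
        N, R, r0 = 48, 12.0, 5.0
        z = pk.jl_zeros(0, N)
        qs = z / (2 * np.pi * R)
        shell = spherical_jn(0, 2 * np.pi * qs * r0)
        data = np.outer(shell, shell)[None, :, :]
        blq = pk.BlMatrixSetQ(data=data, ls=np.array([0]), wavelength=0.1,
                              sampling="bessel", q_grids=[qs], rmax=R)
        blr = pk.sbt_bl(blq)
        i = np.unravel_index(np.argmax(np.abs(blr.data[0])), blr.data[0].shape)
        dr = blr.r_grid[1] - blr.r_grid[0]
        assert abs(blr.r_grid[i[0]] - r0) <= dr
        assert abs(blr.r_grid[i[1]] - r0) <= dr

    def test_uniform_grid_input_refused(self):
        blq = pk.BlMatrixSetQ(
            data=np.ones((1, 4, 4)), ls=np.array([0]), wavelength=0.1,
            q_grid=np.linspace(0, 1, 4),
        )
        with pytest.raises(ValueError, match="resample"):
            pk.sbt_bl(blq)


class TestAssemblePadf:
    def _blr(self, data, ls, rmax=10.0):
        nr = data.shape[1]
        return pk.BlMatrixSetR(
            data=data, ls=np.asarray(ls),
            r_grid=np.arange(1, nr + 1) * rmax / nr, rmax=rmax,
        )

    def test_pure_l0_is_theta_flat_before_scaling(self):
        blr = self._blr(np.ones((1, 6, 6)), [0])
        padf = pk.assemble_padf(blr, ntheta=91, sintheta_exponent=0.0,
                                radial_weight=False)
        assert np.max(padf.values.std(axis=2)) < 1e-12

    def test_missing_order_fatal(self):
        blr = self._blr(np.ones((2, 4, 4)), [0, 4])  # l=2 missing
        with pytest.raises(ValueError, match="every even order"):
            pk.assemble_padf(blr)

    def test_exchange_symmetry_in_r(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((3, 8, 8))
        data = 0.5 * (data + np.swapaxes(data, 1, 2))
        padf = pk.assemble_padf(self._blr(data, [0, 2, 4]))
        assert np.allclose(padf.values, np.swapaxes(padf.values, 0, 1), atol=1e-12)

    def test_scaling_record_and_unreliable_band(self):
        blr = self._blr(np.ones((1, 4, 4)), [0])
        padf = pk.assemble_padf(blr, absolute=(0.1, 1e6))
        assert padf.scaling["radial_weight"] is True
        assert padf.scaling["sintheta_exponent"] == 1.0
        assert padf.scaling["absolute"] == {"rho0": 0.1, "n_incident": 1e6}
        blr32 = self._blr(np.ones((17, 4, 4)) * 0, np.arange(0, 34, 2))
        padf32 = pk.assemble_padf(blr32)
        assert padf32.unreliable_theta_deg == pytest.approx(5.625)

    def test_angular_peaks_merge_below_resolution_and_resolve_above(self):
        from scipy.special import eval_legendre

        ls = np.arange(0, 34, 2)

        def kernel_volume(angles_deg):
            data = np.zeros((len(ls), 2, 2))
            for ang in angles_deg:
                x = np.cos(np.radians(ang))
                data[:, 0, 0] += eval_legendre(ls, x)
            return self._blr(data, ls)

        def angular_maxima(angles_deg):
            padf = pk.assemble_padf(kernel_volume(angles_deg), ntheta=181,
                                    sintheta_exponent=0.0, radial_weight=False)
            prof = padf.values[0, 0, :]
            interior = np.arange(1, 180)
            is_max = (prof[interior] >= prof[interior - 1]) & (
                prof[interior] > prof[interior + 1]
            ) & (prof[interior] > 0.5 * prof.max())
            return padf.theta_deg[interior][is_max]

        merged = angular_maxima([87.0, 93.0])  # separation well below 360/32
        assert len(merged) == 1 and merged[0] == pytest.approx(90.0, abs=1.0)
        resolved = angular_maxima([60.0, 120.0])  # separation >> 2 * 360/32
        assert len(resolved) == 2
        assert np.allclose(np.sort(resolved), [60.0, 120.0], atol=1.5)


class TestEndToEndLinearity:
    def test_intensity_scaling_propagates_quadratically(self):
        geom = pk.DetectorGeometry.for_edge_q(32, 1.28)
        model = pk.make_hexagon(15.0)
        ds = pk.simulate_dataset(model, geom, 3, seed=4)
        s = 3.0

        def pipeline(scale):
            polar = [pk.to_polar(scale * p, geom, 16, 90) for p in ds.patterns]
            C = pk.apply_sintheta_weight(pk.dataset_correlation(polar))
            padf, _, _ = pk.correlation_to_padf(C, geom.wavelength, l_max=8)
            return padf.values

        base = pipeline(1.0)
        scaled = pipeline(s)
        assert np.max(np.abs(scaled - s**2 * base)) < 1e-9 * np.max(np.abs(base))
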