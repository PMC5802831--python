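import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdcorr import tensor_math as tm

# ---------------------------------------------------------------------------
# independent oracle: explicit matrix construction by rotation
# M = R diag(l_perp, l_perp, l_par) R^T  with  R = Rz(phi) @ Ry(theta)


def rotation(theta, phi):
    ct, stn = math.cos(theta), math.sin(theta)
    cp, sp = math.cos(phi), math.sin(phi)
    ry = np.array([[ct, 0, stn], [0, 1, 0], [-stn, 0, ct]])
    rz = np.array([[cp, -sp, 0], [sp, cp, 0], [0, 0, 1]])
    return rz @ ry


def explicit_matrix(iso, delta, theta, phi):
    lam_par = iso * (1 + 2 * delta)
    lam_perp = iso * (1 - delta)
    r = rotation(theta, phi)
    return r @ np.diag([lam_perp, lam_perp, lam_par]) @ r.T


finite_angles = st.floats(0, math.pi, allow_nan=False)
deltas = st.floats(-0.5, 1.0, allow_nan=False)


class TestAxisymmetricTensor:
    def test_eigenvalue_properties(self):
        t = tm.AxisymmetricTensor(2.0, 0.5, 0.3, 0.4)
        assert t.lambda_par == pytest.approx(2.0 * 2.0)
        assert t.lambda_perp == pytest.approx(2.0 * 0.5)

    @pytest.mark.parametrize("iso,delta", [(-1.0, 0.0), (1.0, 1.5), (1.0, -0.6)])
    def test_invalid_parameters_rejected(self, iso, delta):
        with pytest.raises(ValueError):
            tm.AxisymmetricTensor(iso, delta)


class TestToMatrix:
    def test_spherical_is_scaled_identity(self):
        m = tm.to_matrix(tm.AxisymmetricTensor(3.0, 0.0, 1.1, 2.2))
        np.testing.assert_allclose(m, 3.0 * np.eye(3), atol=1e-15)

    def test_stick_along_z(self):
        m = tm.to_matrix(tm.AxisymmetricTensor(2.0, 1.0, 0.0, 0.0))
        np.testing.assert_allclose(m, np.diag([0.0, 0.0, 6.0]), atol=1e-14)

    def test_eigendecomposition_matches_parameterization(self):
        # derived: eigendecompose the built matrix, invert back
        iso, delta, theta, phi = 1e-9, 0.5, math.pi / 3, math.pi / 4
        m = tm.to_matrix(tm.AxisymmetricTensor(iso, delta, theta, phi))
        vals, vecs = np.linalg.eigh(m)
        assert vals[-1] == pytest.approx(2e-9, rel=1e-12)       # lambda_par
        np.testing.assert_allclose(vals[:2], 0.5e-9, rtol=1e-12)  # lambda_perp
        axis = vecs[:, -1]
        expected = np.array(
            [
                math.cos(phi) * math.sin(theta),
                math.sin(phi) * math.sin(theta),
                math.cos(theta),
            ]
        )
        assert abs(abs(axis @ expected) - 1.0) < 1e-12  # up to sign

    @given(
        iso=st.floats(1e-12, 1e-8),
        delta=deltas,
        theta=finite_angles,
        phi=st.floats(0, 2 * math.pi - 1e-9),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_explicit_rotation_oracle(self, iso, delta, theta, phi):
        built = tm.to_matrix(tm.AxisymmetricTensor(iso, delta, theta, phi))
        oracle = explicit_matrix(iso, delta, theta, phi)
        np.testing.assert_allclose(built, oracle, atol=1e-12 * iso + 1e-30)

    def test_trace_and_psd(self, rng):
        for _ in range(100):
            t = tm.AxisymmetricTensor(
                rng.uniform(0, 2),
                rng.uniform(-0.5, 1),
                rng.uniform(0, math.pi),
                rng.uniform(0, 2 * math.pi),
            )
            m = tm.to_matrix(t)
            np.testing.assert_allclose(m, m.T)
            assert np.trace(m) == pytest.approx(3 * t.iso, abs=1e-12)
            assert np.linalg.eigvalsh(m).min() >= -1e-12


class TestEigenvaluesToIsoDelta:
    @pytest.mark.parametrize(
        "lpar,lperp,iso,delta",
        [(1, 1, 1, 0), (3, 0, 1, 1), (0, 1.5, 1, -0.5)],
    )
    def test_canonical_shapes(self, lpar, lperp, iso, delta):
        assert tm.eigenvalues_to_iso_delta(lpar, lperp) == pytest.approx((iso, delta))

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            tm.eigenvalues_to_iso_delta(0.0, 0.0)
        with pytest.raises(ValueError):
            tm.eigenvalues_to_iso_delta(-1.0, 1.0)

    @given(iso=st.floats(1e-3, 1e3), delta=deltas)
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, iso, delta):
        t = tm.AxisymmetricTensor(iso, delta)
        iso2, delta2 = tm.eigenvalues_to_iso_delta(t.lambda_par, t.lambda_perp)
        assert iso2 == pytest.approx(iso, rel=1e-12)
        assert delta2 == pytest.approx(delta, abs=1e-12)


class TestP2:
    @pytest.mark.parametrize(
        "x,expected", [(1.0, 1.0), (0.0, -0.5), (1 / math.sqrt(3), 0.0)]
    )
    def test_values(self, x, expected):
        assert tm.p2(x) == pytest.approx(expected, abs=1e-15)


class TestContract:
    def test_spherical_b_ignores_anisotropy(self, rng):
        b = tm.AxisymmetricTensor(1e9 / 3, 0.0, 0.7, 0.3)
        for _ in range(20):
            d = tm.AxisymmetricTensor(
                1e-9, rng.uniform(-0.5, 1), rng.uniform(0, math.pi), rng.uniform(0, 2 * math.pi)
            )
            assert tm.contract(b, d) == pytest.approx(1e9 * 1e-9, rel=1e-12)

    def test_parallel_sticks(self):
        b = tm.AxisymmetricTensor(1e9 / 3, 1.0, 0.4, 1.2)
        d = tm.AxisymmetricTensor(1e-9, 1.0, 0.4, 1.2)
        assert tm.contract(b, d) == pytest.approx(3.0 * 1e9 * 1e-9, rel=1e-12)

    def test_matches_matrix_double_contraction(self, rng):
        for _ in range(500):
            b = tm.AxisymmetricTensor(
                rng.uniform(1e8, 1e11) / 3,
                rng.uniform(-0.5, 1),
                rng.uniform(0, math.pi),
                rng.uniform(0, 2 * math.pi),
            )
            d = tm.AxisymmetricTensor(
                rng.uniform(1e-12, 1e-8),
                rng.uniform(-0.5, 1),
                rng.uniform(0, math.pi),
                rng.uniform(0, 2 * math.pi),
            )
            oracle = float(
                np.sum(
                    explicit_matrix(b.iso, b.delta, b.theta, b.phi)
                    * explicit_matrix(d.iso, d.delta, d.theta, d.phi)
                )
            )
            assert tm.contract(b, d) == pytest.approx(oracle, rel=1e-10, abs=1e-20)


class TestZetaBdelta:
    def test_linear_at_zero(self):
        assert tm.bdelta_from_zeta(0.0) == pytest.approx(1.0)

    def test_planar_at_ninety(self):
        assert tm.bdelta_from_zeta(math.pi / 2) == pytest.approx(-0.5)

    def test_magic_angle(self):
        assert math.degrees(tm.zeta_from_bdelta(0.0)) == pytest.approx(54.7356, abs=1e-3)

    def test_inverse_out_of_range(self):
        with pytest.raises(ValueError):
            tm.zeta_from_bdelta(1.5)

    @given(zeta=st.floats(0, math.pi / 2))
    @settings(max_examples=300, deadline=None)
    def test_round_trip(self, zeta):
        assert tm.zeta_from_bdelta(tm.bdelta_from_zeta(zeta)) == pytest.approx(
            zeta, abs=1e-9
        )

    def test_monotone_decreasing(self):
        z = np.linspace(0, math.pi / 2, 200)
        bd = [tm.bdelta_from_zeta(x) for x in z]
        assert np.all(np.diff(bd) < 0)


class TestRatioDelta:
    @pytest.mark.parametrize("delta,ratio", [(0.0, 1.0), (-0.5, 0.0)])
    def test_limits(self, delta, ratio):
        assert tm.ratio_from_delta(delta) == pytest.approx(ratio)

    def test_ratio_100(self):
        # derived: solve (1 + 2x)/(1 - x) = 100  =>  x = 99/102
        assert tm.delta_from_ratio(100.0) == pytest.approx(99.0 / 102.0, rel=1e-14)
        assert tm.ratio_from_delta(99.0 / 102.0) == pytest.approx(100.0, rel=1e-12)

    def test_stick_limit_raises(self):
        with pytest.raises(ValueError):
            tm.ratio_from_delta(1.0)

    def test_infinite_ratio_clamps(self):
        assert tm.delta_from_ratio(math.inf) == pytest.approx(1.0 - 1e-9)
        assert tm.delta_from_ratio(math.inf, eps=1e-6) == pytest.approx(1.0 - 1e-6)

    @given(delta=st.floats(-0.5, 0.999999))
    @settings(max_examples=200, deadline=None)
    def test_mutual_inverse(self, delta):
        assert tm.delta_from_ratio(tm.ratio_from_delta(delta)) == pytest.approx(
            delta, abs=1e-9
        )


class TestRotationalInvariance:
    def test_joint_rotation_leaves_contract_unchanged(self, rng):
        from scipy.spatial.transform import Rotation

        b = tm.AxisymmetricTensor(2e9 / 3, 0.8, 0.9, 1.1)
        d = tm.AxisymmetricTensor(3e-9, -0.3, 2.1, 4.0)
        ref = tm.contract(b, d)
        for rot in Rotation.random(1000, rng=rng):
            tb = _rotated(b, rot)
            td = _rotated(d, rot)
            assert tm.contract(tb, td) == pytest.approx(ref, rel=1e-10)


def _rotated(t, rot):
    axis = rot.apply(t.axis)
    theta = math.acos(np.clip(axis[2], -1, 1))
    phi = math.atan2(axis[1], axis[0]) % (2 * math.pi)
    return tm.AxisymmetricTensor(t.iso, t.delta, theta, phi)


class TestCanonicalizeAxis:
    def test_antipodal_pairs_map_together(self, rng):
        for _ in range(100):
            theta = rng.uniform(0, math.pi)
            phi = rng.uniform(0, 2 * math.pi)
            t1, p1 = tm.canonicalize_axis(theta, phi)
            t2, p2 = tm.canonicalize_axis(math.pi - theta, (phi + math.pi) % (2 * math.pi))
            assert t1 <= math.pi / 2 + 1e-12
            assert t1 == pytest.approx(t2, abs=1e-12)
            # azimuths agree unless the axis is in the equatorial plane
            if abs(theta - math.pi / 2) > 1e-9:
                assert p1 == pytest.approx(p2, abs=1e-9)
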