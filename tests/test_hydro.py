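"""Diffusion-tensor construction: self terms, RPY pair blocks, orientational
averages, divergence drift, Cholesky factors and condition numbers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bdhi.hydro import (
    BeadModel,
    DecompositionError,
    FullDiffusionTensor,
    assemble_tensor,
    condition_number,
    count_apply_DF_multiplications,
    count_cholesky_multiplications,
    expand_oa_tensor,
    oa_divergence,
    oa_pair_coefficient,
    oa_pair_coefficient_derivative,
    rpy_pair_block,
    sqrt_factor,
    stokes_einstein_self,
)
from bdhi.units import KB_KCAL_MOL_K, CP_TO_INTERNAL, HydroEnvironment

from conftest import numeric_divergence, random_nonoverlapping_beads, sphere_average_block

A = 5.3  # default protein bead radius, Å


class TestStokesEinstein:
    def test_inverse_radius_scaling(self, env):
        assert stokes_einstein_self(2 * A, env) == pytest.approx(
            0.5 * stokes_einstein_self(A, env), rel=1e-14
        )

    def test_matches_independent_rederivation(self):
        # recompute kBT/(6πηa) from first principles in SI units
        a_m = A * 1e-10
        kb_si = 1.380649e-23
        temp = 310.0
        eta_si = 1.1e-3  # Pa s
        d_si = kb_si * temp / (6.0 * np.pi * eta_si * a_m)  # m²/s
        d_internal_expected = d_si * 1e20 / 1e12  # Å²/ps
        env = HydroEnvironment(temperature=temp, viscosity_cp=1.1)
        # rel 1e-5 absorbs the conventional truncation of kB in kcal/mol/K
        assert stokes_einstein_self(A, env) == pytest.approx(
            d_internal_expected, rel=1e-5
        )
        # and the exact internal-unit formula
        expected = (KB_KCAL_MOL_K * temp) / (
            6.0 * np.pi * 1.1 * CP_TO_INTERNAL * A
        )
        assert stokes_einstein_self(A, env) == pytest.approx(expected, rel=1e-12)

    def test_default_protein_value_on_diagonal(self, env):
        d_self = stokes_einstein_self(A, env)
        model = random_nonoverlapping_beads(4, A, np.random.default_rng(7))
        entries = assemble_tensor(model, env, "full-rpy").entries
        for i in range(4):
            block = entries[3 * i : 3 * i + 3, 3 * i : 3 * i + 3]
            np.testing.assert_allclose(block, d_self * np.eye(3), rtol=1e-14)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_invalid_radius_rejected(self, bad, env):
        with pytest.raises(ValueError):
            stokes_einstein_self(bad, env)

    def test_invalid_environment_rejected(self):
        with pytest.raises(ValueError):
            HydroEnvironment(temperature=-10)
        with pytest.raises(ValueError):
            HydroEnvironment(viscosity_cp=0.0)


class TestRpyPairBlock:
    def test_zero_separation_reduces_to_self_term(self, env):
        block = rpy_pair_block(np.zeros(3), A, env)
        np.testing.assert_allclose(
            block, stokes_einstein_self(A, env) * np.eye(3), rtol=1e-14
        )

    def test_branches_agree_at_touching_distance(self, env, rng):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        below = rpy_pair_block((2 * A - 1e-9) * u, A, env)
        above = rpy_pair_block((2 * A + 1e-9) * u, A, env)
        np.testing.assert_allclose(below, above, rtol=1e-8)
        exact_lo = rpy_pair_block((2 * A) * u, A, env)
        # evaluate the overlap formula exactly at r = 2a via a tiny offset
        np.testing.assert_allclose(below, exact_lo, rtol=1e-9)

    def test_axis_aligned_block_is_diagonal(self, env):
        block = rpy_pair_block(np.array([4 * A, 0, 0]), A, env)
        assert block[0, 1] == block[0, 2] == block[1, 2] == 0.0
        assert block[1, 1] == pytest.approx(block[2, 2], rel=1e-14)
        assert block[0, 0] > block[1, 1] > 0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        r=st.floats(0.1, 60.0),
        ct=st.floats(-1.0, 1.0),
        phi=st.floats(0.0, 2 * np.pi),
    )
    def test_block_symmetric_any_orientation(self, r, ct, phi):
        env = HydroEnvironment()
        stheta = np.sqrt(1 - ct * ct)
        sep = r * np.array([stheta * np.cos(phi), stheta * np.sin(phi), ct])
        block = rpy_pair_block(sep, A, env)
        np.testing.assert_allclose(block, block.T, atol=1e-18)


class TestOrientationalAverage:
    def test_isotropic_average_weights(self):
        # <x²/r²> over orientations is exactly 1/3 and <xy/r²> is 0
        nodes, weights = np.polynomial.legendre.leggauss(24)
        phis = (np.arange(48) + 0.5) * 2 * np.pi / 48
        xx = xy = wsum = 0.0
        for ct, w in zip(nodes, weights):
            stheta = np.sqrt(1 - ct * ct)
            for phi in phis:
                ux, uy = stheta * np.cos(phi), stheta * np.sin(phi)
                xx += w * ux * ux
                xy += w * ux * uy
                wsum += w
        assert xx / wsum == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert abs(xy / wsum) < 1e-14

    def test_zero_distance_equals_self_term(self, env):
        assert oa_pair_coefficient(0.0, A, env) == pytest.approx(
            stokes_einstein_self(A, env), rel=1e-14
        )

    @pytest.mark.parametrize("r", [1.0, 5.0, 2 * A - 0.5, 2 * A, 2 * A + 0.5, 30.0, 80.0])
    def test_matches_quadrature_average_of_full_block(self, r, env):
        avg = sphere_average_block(r, A, env)
        d_rr = oa_pair_coefficient(r, A, env)
        np.testing.assert_allclose(np.diag(avg), d_rr * np.ones(3), rtol=1e-9)
        off = avg - np.diag(np.diag(avg))
        assert np.max(np.abs(off)) < 1e-10 * d_rr

    def test_continuity_at_touching_distance(self, env):
        lo = oa_pair_coefficient(2 * A - 1e-9, A, env)
        hi = oa_pair_coefficient(2 * A + 1e-9, A, env)
        assert lo == pytest.approx(hi, rel=1e-8)

    def test_derivative_negative_and_continuous(self, env):
        rs = np.array([0.5, A, 2 * A - 1e-9, 2 * A + 1e-9, 4 * A, 10 * A])
        d = oa_pair_coefficient_derivative(rs, A, env)
        assert np.all(d < 0)
        assert d[2] == pytest.approx(d[3], rel=1e-7)
        # derivative matches finite differences of the coefficient
        for r in (3.0, 9.0, 15.0, 40.0):
            h = 1e-6
            fd = (
                oa_pair_coefficient(r + h, A, env) - oa_pair_coefficient(r - h, A, env)
            ) / (2 * h)
            assert oa_pair_coefficient_derivative(r, A, env) == pytest.approx(fd, rel=1e-6)


class TestAssemble:
    def test_single_bead_shapes(self, env):
        model = BeadModel(np.zeros((1, 3)), A)
        full = assemble_tensor(model, env, "full-rpy")
        oa = assemble_tensor(model, env, "oa-rpy")
        assert full.entries.shape == (3, 3)
        assert oa.entries.shape == (1, 1)
        assert oa.entries[0, 0] == pytest.approx(stokes_einstein_self(A, env))

    def test_two_bead_rotation_average_equals_oa(self, env):
        from scipy.stats import special_ortho_group

        pos = np.array([[0.0, 0, 0], [14.0, 5.0, -3.0]])
        oa3n = expand_oa_tensor(assemble_tensor(BeadModel(pos, A), env, "oa-rpy")).entries
        rots = special_ortho_group.rvs(3, size=4000, random_state=5)
        acc = np.zeros((6, 6))
        for rot in rots:
            acc += assemble_tensor(BeadModel(pos @ rot.T, A), env, "full-rpy").entries
        acc /= len(rots)
        scale = np.max(np.abs(oa3n))
        assert np.max(np.abs(acc - oa3n)) / scale < 0.02  # Monte-Carlo tolerance

    def test_positive_definite_on_random_clusters(self, env, rng):
        for _ in range(10):
            n = int(rng.integers(2, 21))
            model = random_nonoverlapping_beads(n, A, rng)
            for kind in ("full-rpy", "oa-rpy"):
                vals = np.linalg.eigvalsh(assemble_tensor(model, env, kind).entries)
                assert vals[0] > 0

    def test_unequal_radii_rejected(self):
        with pytest.raises(ValueError, match="share one hydrodynamic radius"):
            BeadModel(np.zeros((2, 3)), np.array([5.3, 5.5]))


class TestSqrtFactor:
    def test_identity_factor(self):
        fac = sqrt_factor(FullDiffusionTensor(entries=np.eye(6)))
        np.testing.assert_allclose(fac.factor, np.eye(6))

    def test_diagonal_factor_is_elementwise_sqrt(self):
        diag = np.diag([4.0, 9.0, 16.0])
        fac = sqrt_factor(FullDiffusionTensor(entries=diag))
        np.testing.assert_allclose(fac.factor, np.sqrt(diag))

    def test_reconstruction(self, env, rng):
        model = random_nonoverlapping_beads(2, A, rng)
        tensor = assemble_tensor(model, env, "full-rpy")
        fac = sqrt_factor(tensor).factor
        err = np.linalg.norm(fac @ fac.T - tensor.entries) / np.linalg.norm(tensor.entries)
        assert err < 1e-12
        assert np.allclose(fac, np.tril(fac))

    def test_non_spd_raises_with_minor(self):
        bad = np.diag([1.0, -1.0, 1.0])
        with pytest.raises(DecompositionError, match="minor"):
            sqrt_factor(FullDiffusionTensor(entries=bad))


class TestDivergence:
    def test_single_bead_zero(self, env):
        field = oa_divergence(BeadModel(np.zeros((1, 3)), A), env)
        np.testing.assert_array_equal(field.drift, 0.0)

    def test_pair_contributions_antisymmetric_and_collinear(self, env):
        sep = np.array([9.0, 7.0, -4.0])  # r > 2a
        model = BeadModel(np.stack([np.zeros(3), sep]), A)
        drift = oa_divergence(model, env).drift
        np.testing.assert_allclose(drift[0], -drift[1], rtol=1e-14)
        cross = np.cross(drift[0], sep)
        assert np.linalg.norm(cross) < 1e-12 * np.linalg.norm(drift[0]) * np.linalg.norm(sep)

    def test_far_field_drift_pushes_beads_apart(self, env):
        sep = np.array([3 * A, 0.0, 0.0])
        model = BeadModel(np.stack([np.zeros(3), sep]), A)
        drift = oa_divergence(model, env).drift
        assert drift[0, 0] < 0  # bead at origin pushed toward -x
        assert drift[1, 0] > 0

    def test_analytic_matches_finite_difference(self, env, rng):
        model = random_nonoverlapping_beads(5, A, rng)
        analytic = oa_divergence(model, env).drift
        numeric = numeric_divergence(model.positions, A, env, "oa-rpy")
        np.testing.assert_allclose(analytic, numeric, rtol=1e-6, atol=1e-12)

    def test_overlapping_pair_also_matches_oracle(self, env):
        pos = np.array([[0.0, 0, 0], [3.8, 0, 0], [1.5, 3.0, 0.5]])  # r < 2a pairs
        model = BeadModel(pos, A)
        analytic = oa_divergence(model, env).drift
        numeric = numeric_divergence(pos, A, env, "oa-rpy")
        np.testing.assert_allclose(analytic, numeric, rtol=1e-6, atol=1e-12)

    def test_full_rpy_divergence_identically_zero(self, env, rng):
        model = random_nonoverlapping_beads(4, A, rng)
        numeric = numeric_divergence(model.positions, A, env, "full-rpy")
        scale = stokes_einstein_self(A, env) / A
        assert np.max(np.abs(numeric)) < 1e-6 * scale


class TestConditionNumber:
    def test_identity_is_one(self):
        assert condition_number(FullDiffusionTensor(entries=np.eye(9))) == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self, env, rng):
        model = random_nonoverlapping_beads(8, A, rng)
        tensor = assemble_tensor(model, env, "full-rpy")
        vals = np.linalg.eigvalsh(tensor.entries)
        assert condition_number(tensor) == pytest.approx(vals[-1] / vals[0], rel=1e-10)

    def test_oa_condition_below_full_on_clusters(self, env, rng):
        for _ in range(5):
            model = random_nonoverlapping_beads(int(rng.integers(5, 25)), A, rng)
            c_full = condition_number(assemble_tensor(model, env, "full-rpy"))
            c_oa = condition_number(assemble_tensor(model, env, "oa-rpy"))
            assert c_oa <= c_full


class TestOperationCounts:
    def test_apply_df_multiplication_counts(self):
        n = 50
        assert count_apply_DF_multiplications(n, "full-rpy") == 9 * n * n
        assert count_apply_DF_multiplications(n, "oa-rpy") == 3 * n * n

    def test_cholesky_count_ratio_near_27(self):
        n = 60
        ratio = count_cholesky_multiplications(n, "full-rpy") / count_cholesky_multiplications(n, "oa-rpy")
        assert ratio == pytest.approx(27.0, rel=0.05)
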