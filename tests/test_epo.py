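"""EPO correction: difference matrix, projection algebra, Wilk's lambda and
factor selection."""

import numpy as np
import pytest

from moistspec import (
    SpectraSet,
    apply_epo,
    difference_matrix,
    fit_epo,
    select_factors,
    wilks_lambda,
)
from moistspec.epo import DifferenceMatrix
from moistspec.exceptions import ExcessFactorsError, GridMismatchError, MissingSampleError

from .oracles import wilks_lambda_1d

P_DIM = 40
GRID = np.linspace(1000, 2000, P_DIM)


def _spectra(values, ids=None):
    values = np.atleast_2d(values)
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    return SpectraSet(ids=ids, grid=GRID, values=values, yunit="absorbance")


def _unit(seed=0):
    v = np.random.default_rng(seed).normal(size=P_DIM)
    return v / np.linalg.norm(v)


class TestDifferenceMatrix:
    def test_equal_sets_give_zero(self, rng):
        vals = rng.normal(size=(5, P_DIM))
        ids = [f"s{i}" for i in range(5)]
        D = difference_matrix(_spectra(vals, ids), _spectra(vals.copy(), ids), ids)
        assert np.allclose(D.values, 0.0)

    def test_rank_one_construction(self, rng):
        dry = rng.normal(size=(6, P_DIM))
        ids = [f"s{i}" for i in range(6)]
        c = np.arange(1.0, 7.0)
        v = _unit(1)
        moist = dry + c[:, None] * v
        D = difference_matrix(_spectra(moist, ids), _spectra(dry, ids), ids)
        assert np.allclose(D.values, c[:, None] * v, atol=1e-12)

    def test_matches_subtraction_oracle_and_ordering(self, rng):
        dry = rng.normal(size=(4, P_DIM))
        moist = rng.normal(size=(4, P_DIM)) * 0.1 + dry
        ids = ["a", "b", "c", "d"]
        order = ["c", "a"]
        D = difference_matrix(_spectra(moist, ids), _spectra(dry, ids), order)
        assert np.allclose(D.values[0], moist[2] - dry[2], atol=1e-14)
        assert np.allclose(D.values[1], moist[0] - dry[0], atol=1e-14)

    def test_errors(self, rng):
        vals = rng.normal(size=(3, P_DIM))
        ids = ["a", "b", "c"]
        other = SpectraSet(ids=ids, grid=GRID + 1, values=vals, yunit="absorbance")
        with pytest.raises(GridMismatchError):
            difference_matrix(_spectra(vals, ids), other, ids)
        with pytest.raises(MissingSampleError):
            difference_matrix(_spectra(vals, ids), _spectra(vals, ids), ["z"])


class TestProjectionAlgebra:
    def test_zero_factors_is_identity(self, rng):
        D = DifferenceMatrix(rng.normal(size=(5, P_DIM)), GRID, "moist_minus_sieved")
        model = fit_epo(D, 0)
        assert np.array_equal(model.P, np.eye(P_DIM))

    def test_rank_one_unwanted_subspace(self):
        v = _unit(2)
        c = np.linspace(0.5, 2.0, 5)
        D = DifferenceMatrix(c[:, None] * v, GRID, "moist_minus_sieved")
        model = fit_epo(D, 1)
        assert np.allclose(model.Q, np.outer(v, v), atol=1e-10)

    @pytest.mark.parametrize("g", range(0, 11))
    def test_projector_identities(self, rng, g):
        D = DifferenceMatrix(rng.normal(size=(12, P_DIM)), GRID, "moist_minus_fine")
        model = fit_epo(D, g)
        P = model.P
        Q = model.Q
        assert np.allclose(P @ P, P, atol=1e-10)
        assert np.allclose(Q @ Q, Q, atol=1e-10)
        assert np.allclose(P, P.T, atol=1e-10)
        assert np.trace(P) == pytest.approx(P_DIM - g, abs=1e-8)

    def test_training_residual_monotone_to_zero(self, rng):
        Dv = rng.normal(size=(8, P_DIM))
        D = DifferenceMatrix(Dv, GRID, "moist_minus_sieved")
        norms = []
        for g in range(0, 9):
            model = fit_epo(D, g)
            norms.append(np.linalg.norm(Dv @ model.P) / np.linalg.norm(Dv))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-8  # g = rank(D) kills the training differences

    def test_excess_factors_rejected(self):
        v = _unit(3)
        D = DifferenceMatrix(np.vstack([v, 2 * v, 3 * v]), GRID, "moist_minus_sieved")
        with pytest.raises(ExcessFactorsError):
            fit_epo(D, 2)  # numerical rank is 1
        with pytest.raises(ExcessFactorsError):
            fit_epo(D, 4)  # exceeds min(rows, cols)


class TestApplyEpo:
    def test_zero_factor_model_is_identity(self, rng):
        D = DifferenceMatrix(rng.normal(size=(5, P_DIM)), GRID, "moist_minus_sieved")
        spectra = _spectra(rng.normal(size=(3, P_DIM)))
        out = apply_epo(spectra, fit_epo(D, 0))
        assert np.array_equal(out.values, spectra.values)

    def test_spectra_inside_unwanted_subspace_are_annihilated(self, rng):
        v = _unit(4)
        D = DifferenceMatrix(np.outer([1.0, 2.0], v), GRID, "moist_minus_sieved")
        model = fit_epo(D, 1)
        spectra = _spectra(np.outer([3.0, -1.0, 0.5], v))
        out = apply_epo(spectra, model)
        assert np.allclose(out.values, 0.0, atol=1e-10)

    def test_rank_one_distortion_fully_corrected(self, rng):
        dry = rng.normal(size=(8, P_DIM))
        ids = [f"s{i}" for i in range(8)]
        v = _unit(5)
        moist = dry + np.linspace(1, 3, 8)[:, None] * v
        D = difference_matrix(_spectra(moist, ids), _spectra(dry, ids), ids)
        model = fit_epo(D, 1)
        cm = apply_epo(_spectra(moist, ids), model)
        cd = apply_epo(_spectra(dry, ids), model)
        assert np.allclose(cm.values, cd.values, atol=1e-8)

    def test_grid_mismatch_rejected(self, rng):
        D = DifferenceMatrix(rng.normal(size=(4, P_DIM)), GRID, "moist_minus_sieved")
        model = fit_epo(D, 1)
        wrong = SpectraSet(
            ids=["a"], grid=GRID + 5, values=rng.normal(size=(1, P_DIM)),
            yunit="absorbance",
        )
        with pytest.raises(GridMismatchError):
            apply_epo(wrong, model)


class TestWilksLambda:
    def test_identical_groups_are_indistinguishable(self, rng):
        grp = rng.normal(size=(6, P_DIM))
        assert wilks_lambda(grp, grp.copy(), 3) == pytest.approx(1.0, abs=1e-9)

    def test_large_offset_separates_groups(self, rng):
        a = rng.normal(size=(8, P_DIM))
        b = a + 50.0 * _unit(6)
        assert wilks_lambda(a, b, 3) < 0.01

    def test_one_dimensional_closed_form(self, rng):
        a = rng.normal(size=(10, P_DIM))
        b = rng.normal(size=(10, P_DIM)) + 0.5 * _unit(7)
        # oracle: project pooled-centred data on the first PC by hand
        pooled = np.vstack([a, b])
        centred = pooled - pooled.mean(axis=0)
        U, s, _ = np.linalg.svd(centred, full_matrices=False)
        scores = U[:, 0] * s[0]
        assert wilks_lambda(a, b, 1) == pytest.approx(
            wilks_lambda_1d(scores[:10], scores[10:]), abs=1e-10
        )

    def test_label_exchange_symmetry(self, rng):
        a = rng.normal(size=(7, P_DIM))
        b = rng.normal(size=(9, P_DIM)) + 0.3
        assert wilks_lambda(a, b, 4) == pytest.approx(wilks_lambda(b, a, 4), abs=1e-12)

    def test_group_size_floor(self, rng):
        with pytest.raises(ValueError):
            wilks_lambda(rng.normal(size=(1, P_DIM)), rng.normal(size=(5, P_DIM)), 2)


class TestSelectFactors:
    def test_rank_one_distortion_selects_one_factor(self, rng):
        dry = rng.normal(size=(10, P_DIM))
        ids = [f"s{i}" for i in range(10)]
        moist = dry + np.linspace(1, 4, 10)[:, None] * _unit(8)
        model = select_factors(_spectra(moist, ids), _spectra(dry, ids), ids, g_max=6)
        assert model.g == 1
        assert model.lambda_trace[1] > model.lambda_trace[0]

    def test_rank_three_distortion_needs_three_factors(self, rng):
        dry = rng.normal(size=(12, P_DIM))
        ids = [f"s{i}" for i in range(12)]
        basis = np.linalg.qr(rng.normal(size=(P_DIM, 3)))[0]
        coeffs = rng.normal(size=(12, 3)) * 3.0
        moist = dry + coeffs @ basis.T
        model = select_factors(_spectra(moist, ids), _spectra(dry, ids), ids, g_max=6)
        assert 3 <= model.g <= 6
        assert model.lambda_trace[3] > model.lambda_trace[2]

    def test_no_distortion_selects_zero_by_tie_rule(self, rng):
        dry = rng.normal(size=(8, P_DIM))
        ids = [f"s{i}" for i in range(8)]
        model = select_factors(_spectra(dry.copy(), ids), _spectra(dry, ids), ids, g_max=5)
        assert model.g == 0
        assert all(lam == pytest.approx(1.0, abs=1e-6) for lam in model.lambda_trace.values())
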