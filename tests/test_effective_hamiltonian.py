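"""Tests of the effective-Hamiltonian construction and coupling fits."""

import logging

import numpy as np
import pytest

from spincouple.csf_spaces import SystemSpec
from spincouple.effective_hamiltonian import (EffHamResult, build_heff,
                                              extract_effective_hamiltonian,
                                              fit_params,
                                              project_and_orthonormalize,
                                              sparsity_measures)
from spincouple.spin_models import (ModelParams, model_in_coupled_basis,
                                    synthesize_fixture)
from spincouple.su2_algebra import HalfInt

TRIMER = ["3/2"] * 3
BLOCKS = (1, 3, 5, 7, 9)


def model_blocks_as_results(params, scheme="local", blocks=BLOCKS):
    """Exact model blocks dressed as numerical effective Hamiltonians."""
    out = []
    for ts in blocks:
        blk = model_in_coupled_basis(TRIMER, params, scheme, HalfInt(twice=ts))
        out.append(EffHamResult(blk.basis_labels, blk.matrix,
                                np.linalg.eigvalsh(blk.matrix),
                                np.ones(blk.dim)))
    return out


def pipeline_blocks(params, mixing, seed, scheme="local"):
    out = []
    for ts in BLOCKS:
        spec = SystemSpec.equal_chain(3, 3, HalfInt(twice=ts))
        energies, civec, _ = synthesize_fixture(spec, params, mixing=mixing,
                                                seed=seed)
        out.append(extract_effective_hamiltonian(civec, energies, spec,
                                                 scheme))
    return out


class TestProjection:
    def test_identity_on_model_space_vectors(self):
        U0 = np.linalg.qr(np.random.default_rng(0).standard_normal((4, 4)))[0]
        U, retained = project_and_orthonormalize(U0)
        assert np.allclose(U, U0, atol=1e-12)
        assert np.allclose(retained, 1.0)

    def test_lowdin_preserves_symmetric_mixture(self):
        """S^(-1/2) orthonormalization is the closest orthonormal set to
        the projections; it must not reorder or rotate an already
        symmetric pair."""
        P = np.array([[1.0, 0.3], [0.3, 1.0]])
        P /= np.linalg.norm(P, axis=0)
        U, _ = project_and_orthonormalize(P)
        assert np.allclose(U, U.T)  # symmetric inputs -> symmetric output
        assert np.max(np.abs(U.T @ U - np.eye(2))) < 1e-12

    def test_singular_overlap_names_roots(self):
        P = np.zeros((3, 3))
        P[:, 0] = [1, 0, 0]
        P[:, 1] = [1, 1e-12, 0]   # numerically parallel to root 0
        P[:, 2] = [0, 0, 1]
        with pytest.raises(ValueError, match="singular overlap"):
            project_and_orthonormalize(P)

    def test_root_count_must_match_dimension(self):
        with pytest.raises(ValueError, match="as many roots"):
            project_and_orthonormalize(np.ones((3, 2)))

    def test_low_retained_norm_is_flagged(self, caplog):
        """A projection keeping only ~78% of a root's norm is processed
        and reported, not rejected."""
        P = np.diag([np.sqrt(0.78), 1.0, 1.0])
        with caplog.at_level(logging.WARNING,
                             logger="spincouple.effective_hamiltonian"):
            U, retained = project_and_orthonormalize(P)
        assert retained[0] == pytest.approx(0.78)
        assert any("low retained norm" in r.message for r in caplog.records)
        assert np.max(np.abs(U.T @ U - np.eye(3))) < 1e-12


class TestBuildHeff:
    def test_spectral_identity(self, rng):
        E = np.array([-50.0, -10.0, 3.0, 40.0])
        U = np.linalg.qr(rng.standard_normal((4, 4)))[0]
        res = build_heff(U, E, [f"b{i}" for i in range(4)])
        assert np.allclose(np.linalg.eigvalsh(res.matrix), np.sort(E),
                           atol=1e-10)

    def test_model_eigenvectors_return_model_matrix(self, cubane_params):
        blk = model_in_coupled_basis(TRIMER, cubane_params, "local", "3/2")
        evals, evecs = np.linalg.eigh(blk.matrix)
        res = build_heff(evecs, evals, blk.basis_labels)
        assert np.max(np.abs(res.matrix - blk.matrix)) < 1e-10

    def test_invariance_under_root_rephasing(self, rng):
        E = np.array([1.0, 2.0, 5.0])
        U = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        flipped = U * np.array([1, -1, 1])
        a = build_heff(U, E, ["x", "y", "z"]).matrix
        b = build_heff(flipped, E, ["x", "y", "z"]).matrix
        assert np.max(np.abs(a - b)) < 1e-12

    def test_invariance_under_degenerate_mixing(self, rng):
        """Rotating within a degenerate pair leaves H_eff unchanged."""
        E = np.array([2.0, 7.0, 7.0])
        U = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        theta = 0.6
        R = np.eye(3)
        R[1:, 1:] = [[np.cos(theta), -np.sin(theta)],
                     [np.sin(theta), np.cos(theta)]]
        a = build_heff(U, E, ["x", "y", "z"]).matrix
        b = build_heff(U @ R, E, ["x", "y", "z"]).matrix
        assert np.max(np.abs(a - b)) < 1e-12

    def test_non_orthonormal_input_rejected(self):
        with pytest.raises(ValueError, match="not orthonormal"):
            build_heff(np.array([[1.0, 0.5], [0.0, 1.0]]), np.array([1., 2.]),
                       ["x", "y"])


class TestFit:
    def test_exact_recovery_from_model_blocks(self, cubane_params):
        fit = fit_params(model_blocks_as_results(cubane_params), TRIMER)
        assert fit.params.J[0, 1] == pytest.approx(-6.6, abs=1e-9)
        assert fit.params.J[0, 2] == pytest.approx(-27.7, abs=1e-9)
        assert fit.params.J[1, 2] == pytest.approx(-20.0, abs=1e-9)
        assert fit.params.b == pytest.approx(-0.01, abs=1e-9)
        assert np.max(np.abs(fit.params.K)) < 1e-9
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert all(np.linalg.norm(r) < 1e-9 for r in fit.residuals)

    def test_nested_bilinear_fit_agrees_on_heisenberg_data(self, cubane_params):
        """On K = 0 data, the 3-parameter and 6-parameter fits agree."""
        blocks = model_blocks_as_results(cubane_params)
        full = fit_params(blocks, TRIMER)
        restricted = fit_params(blocks, TRIMER, free=["J12", "J13", "J23"])
        for (i, j) in ((0, 1), (0, 2), (1, 2)):
            assert restricted.params.J[i, j] == pytest.approx(
                full.params.J[i, j], abs=1e-8)

    def test_biquadratic_recovery(self, rng):
        params = ModelParams.from_pairs(
            3, {(0, 1): -10.0, (0, 2): 15.0, (1, 2): 5.0},
            {(0, 1): 0.5, (0, 2): -0.4, (1, 2): 0.2}, b=1.3)
        fit = fit_params(model_blocks_as_results(params), TRIMER)
        assert np.max(np.abs(fit.params.J - params.J)) < 1e-8
        assert np.max(np.abs(fit.params.K - params.K)) < 1e-8

    def test_asymmetric_exchange_distinguished(self):
        """J13 != J23 shows up as a nonzero difference in the fit, the
        3J-vs-2J discrimination."""
        params = ModelParams.from_pairs(3, {(0, 1): -3.5, (0, 2): -22.2,
                                            (1, 2): -3.7})
        fit = fit_params(model_blocks_as_results(params), TRIMER,
                         free=["J12", "J13", "J23"])
        j3m = fit.params.J[0, 2] - fit.params.J[1, 2]
        assert j3m == pytest.approx(-22.2 + 3.7, abs=1e-8)

    def test_rank_deficient_design_reported(self, cubane_params):
        """A single one-dimensional block cannot fix seven parameters."""
        blocks = model_blocks_as_results(cubane_params, blocks=(9,))
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_params(blocks, TRIMER)

    def test_unknown_parameter_name_rejected(self, cubane_params):
        with pytest.raises(ValueError, match="unknown parameter"):
            fit_params(model_blocks_as_results(cubane_params), TRIMER,
                       free=["J14"])


class TestEndToEnd:
    def test_unmixed_pipeline_recovers_exactly(self, cubane_params):
        fit = fit_params(pipeline_blocks(cubane_params, 0.0, seed=1), TRIMER)
        assert np.max(np.abs(fit.params.J - cubane_params.J)) < 1e-8
        assert fit.params.b == pytest.approx(-0.01, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_tree_scheme_pipeline(self):
        """Four-site pipeline through the binary-tree model basis."""
        params = ModelParams.from_pairs(
            4, {(0, 1): 30.0, (2, 3): 30.0, (0, 2): 20.0, (0, 3): 20.0,
                (1, 2): 20.0, (1, 3): 20.0})
        spec = SystemSpec.equal_chain(4, 2, 2)
        energies, civec, _ = synthesize_fixture(spec, params, mixing=0.0,
                                                seed=2)
        res = extract_effective_hamiltonian(civec, energies, spec, "tree")
        ref = model_in_coupled_basis(["1"] * 4, params, "tree", 2)
        assert res.basis_labels == ref.basis_labels
        assert np.max(np.abs(res.matrix - ref.matrix)) < 1e-8

    def test_mixed_pipeline_recovery_within_tolerance(self, cubane_params):
        """t/gap = 0.01: couplings recovered to a few percent."""
        fit = fit_params(pipeline_blocks(cubane_params, 100.0, seed=3), TRIMER)
        rel = np.abs((fit.params.J - cubane_params.J)[np.triu_indices(3, 1)]
                     / cubane_params.J[np.triu_indices(3, 1)])
        assert np.median(rel) < 0.05

    def test_strong_mixing_low_norm_scenario_completes(self, caplog):
        """A fixture pushed toward ~78% retained norm still extracts,
        with the low norm flagged."""
        params = ModelParams.from_pairs(3, {(0, 1): -6.6, (0, 2): -27.7,
                                            (1, 2): -20.0})
        spec = SystemSpec.equal_chain(3, 3, "3/2")
        energies, civec, retained = synthesize_fixture(
            spec, params, non_hund_gap=1.0e4, mixing=4.7e3, seed=6)
        assert np.min(retained) < 0.9
        with caplog.at_level(logging.WARNING,
                             logger="spincouple.effective_hamiltonian"):
            res = extract_effective_hamiltonian(civec, energies, spec, "local")
        assert any("low retained norm" in r.message for r in caplog.records)
        assert np.allclose(np.linalg.eigvalsh(res.matrix), np.sort(energies),
                           atol=1e-8)


class TestSparsity:
    def test_single_csf(self):
        assert sparsity_measures(np.array([1.0])) == (1.0, 1.0)

    @pytest.mark.parametrize("d", [2, 4, 9])
    def test_uniform_spread(self, d):
        l1, ipr = sparsity_measures(np.full(d, 1.0 / np.sqrt(d)))
        assert l1 == pytest.approx(np.sqrt(d), abs=1e-12)
        assert ipr == pytest.approx(1.0 / d, abs=1e-12)

    def test_dominant_pair_regime(self):
        """Weights 0.68/0.30/0.02 give IPR ~ 0.55, L1 ~ 1.46 — the
        magnitude regime of a two-configuration state."""
        c = np.sqrt([0.68, 0.30, 0.02])
        l1, ipr = sparsity_measures(c)
        assert l1 == pytest.approx(np.sqrt(0.68) + np.sqrt(0.30)
                                   + np.sqrt(0.02), abs=1e-12)
        assert ipr == pytest.approx(0.68 ** 2 + 0.30 ** 2 + 0.02 ** 2,
                                    abs=1e-12)
        assert 0.5 < ipr < 0.6 and 1.3 < l1 < 1.6

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="not normalized"):
            sparsity_measures(np.array([1.0, 0.5]))
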