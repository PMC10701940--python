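"""Curve resolution: fnnls vs enumeration, SIMPLISMA, ALS, quantitation."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from chemocal import (
    McrConfig,
    default_library,
    fnnls,
    quantify_from_profiles,
    run_mcr_als,
    simplisma_init,
    simulate_dataset,
)
from chemocal.mcr import ComponentCollapseWarning
from chemocal.simulate import library_matrix


def brute_force_nnls(Z, b):
    """Oracle: enumerate all active sets, solve each, take the feasible best."""
    n = Z.shape[1]
    best_x, best_obj = np.zeros(n), np.sum(b**2)
    for mask in itertools.product([0, 1], repeat=n):
        idx = [i for i in range(n) if mask[i]]
        if not idx:
            continue
        x = np.zeros(n)
        sol, *_ = np.linalg.lstsq(Z[:, idx], b, rcond=None)
        if np.any(sol < 0):
            continue
        x[idx] = sol
        obj = np.sum((Z @ x - b) ** 2)
        if obj < best_obj - 1e-12:
            best_obj, best_x = obj, x
    return best_x


class TestFnnls:
    def test_identity_projection(self):
        x = fnnls(np.eye(3), np.array([1.0, -2.0, 3.0]))
        assert np.allclose(x, [1.0, 0.0, 3.0])

    def test_interior_optimum_equals_ols(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(8, 3))
        x_true = np.array([1.0, 2.0, 0.5])
        b = Z @ x_true
        assert np.allclose(fnnls(Z, b), x_true, atol=1e-10)

    def test_matches_active_set_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(150):
            n = rng.integers(2, 5)
            Z = rng.normal(size=(4, n))
            b = rng.normal(size=4)
            x = fnnls(Z, b)
            x_ref = brute_force_nnls(Z, b)
            assert np.all(x >= 0)
            assert np.sum((Z @ x - b) ** 2) <= np.sum((Z @ x_ref - b) ** 2) + 1e-9

    def test_matches_scipy_reference(self):
        from scipy.optimize import nnls as scipy_nnls

        rng = np.random.default_rng(7)
        for _ in range(50):
            Z = rng.normal(size=(10, 6))
            b = rng.normal(size=10)
            assert np.allclose(fnnls(Z, b), scipy_nnls(Z, b)[0], atol=1e-8)

    def test_kkt_conditions(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(12, 5))
        b = rng.normal(size=12)
        x = fnnls(Z, b)
        w = Z.T @ (b - Z @ x)
        assert np.all(w[x > 0] <= 1e-8) and np.all(np.abs(w[x > 1e-12]) <= 1e-8)
        assert np.all(w[x == 0] <= 1e-8)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            fnnls(np.array([[np.nan]]), np.array([1.0]))


class TestSimplisma:
    def test_exclusive_wavelengths_selected(self):
        # two components, each with a channel where only it absorbs
        c = np.array([[1.0, 0.2], [0.5, 1.0], [0.2, 0.6], [0.8, 0.9]])
        s = np.array([
            [1.0, 0.0],   # channel 0: exclusive to component 1
            [0.0, 1.0],   # channel 1: exclusive to component 2
            [0.5, 0.5],
            [0.3, 0.7],
        ])
        A = c @ s.T
        res = simplisma_init(A, 2)
        assert set(res.wavelength_indices) == {0, 1}

    def test_single_component_picks_max_purity(self):
        rng = np.random.default_rng(0)
        A = np.abs(rng.normal(size=(10, 30))) + 0.1
        res = simplisma_init(A, 1)
        mu, sd = A.mean(axis=0), A.std(axis=0)
        alpha = 0.05 * mu.max()
        assert res.wavelength_indices[0] == int(np.argmax(sd / (mu + alpha)))

    def test_constant_matrix_degenerate(self):
        with pytest.raises(ValueError):
            simplisma_init(np.ones((5, 8)), 2)
        with pytest.raises(ValueError):
            simplisma_init(np.zeros((5, 8)), 2)


@pytest.fixture(scope="module")
def clean_decomposition(clean_spectra):
    A = clean_spectra.absorbance
    init = simplisma_init(A, 6)
    return run_mcr_als(A, init.S0)


class TestAls:
    def test_true_init_gives_perfect_fit(self, clean_spectra):
        S_true = library_matrix(default_library())
        decomp = run_mcr_als(clean_spectra.absorbance, S_true)
        assert decomp.lof_percent <= 1e-6
        assert decomp.r2_percent >= 100 - 1e-8

    def test_simplisma_init_resolves_pure_spectra(self, clean_decomposition):
        # alignment oracle: best-congruence assignment of resolved to true
        S_true = library_matrix(default_library())
        Sn = S_true / np.linalg.norm(S_true, axis=0)
        En = clean_decomposition.S / np.linalg.norm(clean_decomposition.S, axis=0)
        cc = np.abs(Sn.T @ En)
        rows, cols = linear_sum_assignment(-cc)
        assert cc[rows, cols].min() >= 0.999

    def test_rank_one_matches_truncated_svd(self):
        rng = np.random.default_rng(2)
        A = np.outer(np.abs(rng.normal(size=9)) + 0.1, np.abs(rng.normal(size=40)) + 0.1)
        init = simplisma_init(A, 1)
        decomp = run_mcr_als(A, init.S0, McrConfig(n_components=1))
        U, s, Vt = np.linalg.svd(A)
        A1 = s[0] * np.outer(U[:, 0], Vt[0])
        assert np.max(np.abs(decomp.C @ decomp.S.T - A1)) <= 1e-8

    def test_lof_r2_identity(self, clean_decomposition, noisy_spectra):
        for decomp in (clean_decomposition, run_mcr_als(
            noisy_spectra.absorbance, simplisma_init(noisy_spectra.absorbance, 6).S0
        )):
            assert decomp.r2_percent == pytest.approx(
                100 * (1 - (decomp.lof_percent / 100) ** 2), abs=1e-9
            )

    def test_profiles_nonnegative_and_spectra_normalized(self, clean_decomposition):
        assert np.all(clean_decomposition.C >= 0)
        assert np.all(clean_decomposition.S >= 0)
        norms = np.linalg.norm(clean_decomposition.S, axis=0)
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_lof_monotone_non_increasing(self, clean_spectra):
        A = clean_spectra.absorbance
        S = simplisma_init(A, 6).S0.copy()
        lofs = []
        for _ in range(15):
            decomp = run_mcr_als(A, S, McrConfig(max_iterations=1))
            lofs.append(decomp.lof_percent)
            S = decomp.S
        assert np.all(np.diff(lofs) <= 1e-10)

    def test_component_collapse_warns(self):
        A = np.outer(np.linspace(1, 2, 6), np.ones(10))
        S0 = np.column_stack([np.ones(10), np.zeros(10)])
        with pytest.warns(ComponentCollapseWarning):
            decomp = run_mcr_als(A, S0, McrConfig(n_components=2))
        assert decomp.collapsed

    def test_bad_shapes_rejected(self, clean_spectra):
        with pytest.raises(ValueError):
            run_mcr_als(clean_spectra.absorbance, np.ones((10, 6)))
        with pytest.raises(ValueError):
            McrConfig(convergence_tol=0)


class TestQuantification:
    def test_noise_free_predictions_exact_with_true_init(self, design, clean_spectra):
        S_true = library_matrix(default_library())
        decomp = run_mcr_als(clean_spectra.absorbance, S_true)
        cal_rows = [i - 1 for i in sorted(design.calibration_ids)]
        quant = quantify_from_profiles(decomp, cal_rows, design.calibration)
        assert np.max(np.abs(quant.predictions - design.validation)) <= 1e-6

    def test_alignment_invariant_to_permutation(self, design, clean_decomposition):
        import dataclasses

        cal_rows = [i - 1 for i in sorted(design.calibration_ids)]
        base = quantify_from_profiles(clean_decomposition, cal_rows, design.calibration)
        perm = np.array([3, 1, 5, 0, 2, 4])
        shuffled = dataclasses.replace(
            clean_decomposition,
            C=clean_decomposition.C[:, perm],
            S=clean_decomposition.S[:, perm],
        )
        again = quantify_from_profiles(shuffled, cal_rows, design.calibration)
        assert np.allclose(again.predictions, base.predictions, atol=1e-12)

    def test_scale_invariance(self, design, clean_decomposition):
        import dataclasses

        cal_rows = [i - 1 for i in sorted(design.calibration_ids)]
        base = quantify_from_profiles(clean_decomposition, cal_rows, design.calibration)
        scale = np.array([2.0, 0.5, 1.5, 3.0, 0.25, 1.0])
        rescaled = dataclasses.replace(
            clean_decomposition,
            C=clean_decomposition.C * scale,
            S=clean_decomposition.S / scale,
        )
        again = quantify_from_profiles(rescaled, cal_rows, design.calibration)
        assert np.allclose(again.predictions, base.predictions, atol=1e-9)

    def test_self_prediction_recovery_100(self, design, clean_spectra):
        # resolve calibration rows only and predict them back through the lines
        S_true = library_matrix(default_library())
        cal_rows = [i - 1 for i in sorted(design.calibration_ids)]
        A = clean_spectra.absorbance[cal_rows]
        decomp = run_mcr_als(A, S_true)
        quant = quantify_from_profiles(decomp, range(len(cal_rows) - 1), design.calibration[:-1])
        assert np.allclose(quant.predictions, design.calibration[-1:], atol=1e-6)

    def test_ambiguous_alignment_rejected(self, design, clean_decomposition):
        import dataclasses

        cal_rows = [i - 1 for i in sorted(design.calibration_ids)]
        # duplicate one resolved column so two analytes match one component
        C = clean_decomposition.C.copy()
        C[:, 1] = C[:, 0]
        S = clean_decomposition.S.copy()
        S[:, 1] = S[:, 0]
        broken = dataclasses.replace(clean_decomposition, C=C, S=S)
        with pytest.raises(ValueError, match="mbiguous"):
            quantify_from_profiles(broken, cal_rows, design.calibration)
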