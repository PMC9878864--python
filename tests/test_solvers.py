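"""Abundance solvers: exactness, constraints, monotonicity, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import specunmix as su
from specunmix.endmembers import EndmemberSet
from specunmix.solvers import ElmmParams, GelmmParams, UnmixError, elmm, fclsu, gelmm

from conftest import as_pixels, random_endmembers


def brute_force_simplex_objective(S, x, step=2e-3):
    """Independent oracle: dense simplex grid then SLSQP polish."""
    from scipy.optimize import minimize

    k = S.shape[1]
    assert k == 3
    g = np.arange(0.0, 1.0 + step / 2, step)
    a1, a2 = np.meshgrid(g, g)
    keep = a1 + a2 <= 1 + 1e-12
    a = np.stack([a1[keep], a2[keep], 1.0 - a1[keep] - a2[keep]], axis=1)
    obj = 0.5 * np.sum((a @ S.T - x) ** 2, axis=1)
    i = int(np.argmin(obj))
    res = minimize(
        lambda v: 0.5 * np.sum((S @ v - x) ** 2),
        a[i],
        bounds=[(0, 1)] * k,
        constraints=({"type": "eq", "fun": lambda v: v.sum() - 1},),
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 300},
    )
    return min(obj[i], float(res.fun))


class TestFclsu:
    def test_consistent_two_member_system(self):
        S = EndmemberSet(np.array([[1.0, 0], [0, 1], [0, 0]]), ["a", "b"],
                         [1.0, 2, 3])
        A = fclsu(as_pixels([[0.3], [0.7], [0.0]]), S)
        np.testing.assert_allclose(A.A.ravel(), [0.3, 0.7], atol=1e-12)

    def test_orthogonal_pixel_splits_by_symmetry(self):
        S = EndmemberSet(np.array([[1.0, 0], [0, 1], [0, 0]]), ["a", "b"],
                         [1.0, 2, 3])
        A = fclsu(as_pixels([[0.0], [0.0], [1.0]]), S)
        np.testing.assert_allclose(A.A.ravel(), [0.5, 0.5], atol=1e-12)

    def test_matches_brute_force_oracle(self):
        """Objective equals the grid+polish oracle on random C=4, k=3 systems."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            ems = random_endmembers(rng, 4, 3)
            x = rng.random(4)
            a = fclsu(as_pixels(x[:, None]), ems).A[:, 0]
            mine = 0.5 * np.sum((ems.S @ a - x) ** 2)
            oracle = brute_force_simplex_objective(ems.S, x)
            assert mine <= oracle + 1e-6
            assert abs(mine - oracle) < 1e-6

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 6), st.integers(3, 12))
    def test_constraints_hold_on_fuzz_inputs(self, seed, k, c):
        if k > c:
            k = c
        rng = np.random.default_rng(seed)
        ems = random_endmembers(rng, c, k)
        F = rng.random((c, 30))
        A = fclsu(as_pixels(F), ems).A
        assert A.min() >= 0.0
        np.testing.assert_allclose(A.sum(axis=0), 1.0, atol=1e-6)

    def test_zero_pixels_get_zero_columns(self):
        ems = random_endmembers(np.random.default_rng(0), 4, 2)
        F = np.zeros((4, 3))
        F[:, 1] = 0.5
        A = fclsu(as_pixels(F), ems).A
        assert np.all(A[:, 0] == 0) and np.all(A[:, 2] == 0)
        assert A[:, 1].sum() == pytest.approx(1.0)

    def test_rank_deficient_endmembers_rejected(self):
        S = np.column_stack([np.ones(4), np.ones(4)])
        ems = EndmemberSet(S + np.array([[0, 1e-18]] * 4).reshape(4, 2) * 0,
                           ["a", "b"], np.arange(4.0))
        with pytest.raises(UnmixError, match="rank deficient"):
            fclsu(as_pixels(np.random.default_rng(0).random((4, 5))), ems)

    def test_independent_of_pixel_order(self):
        rng = np.random.default_rng(5)
        ems = random_endmembers(rng, 6, 3)
        F = rng.random((6, 50))
        perm = rng.permutation(50)
        A1 = fclsu(as_pixels(F), ems).A
        A2 = fclsu(as_pixels(F[:, perm]), ems).A
        np.testing.assert_allclose(A1[:, perm], A2, atol=1e-12)


class TestElmm:
    def test_reduces_to_fclsu_when_data_is_unscaled(self):
        rng = np.random.default_rng(0)
        ems = random_endmembers(rng, 16, 4)
        A = rng.dirichlet(np.ones(4), size=300).T
        X = ems.S @ A
        r = elmm(as_pixels(X), ems, ElmmParams(lambda_psi=0.0))
        base = fclsu(as_pixels(X), ems)
        assert np.abs(r.abundances.A - base.A).max() < 1e-6
        assert np.abs(r.psi - 1.0).max() < 1e-6

    def test_single_member_scale_identifiable(self):
        rng = np.random.default_rng(1)
        s = np.abs(rng.normal(size=(8, 1))) + 0.2
        ems = EndmemberSet(s, ["m"], np.arange(8.0))
        r = elmm(as_pixels(0.5 * ems.S), ems, ElmmParams(lambda_psi=0.0))
        assert r.abundances.A[0, 0] == pytest.approx(1.0)
        assert r.psi[0, 0] == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_recovers_per_pixel_scalings_on_pure_mosaic(self, seed):
        """Noise-free psi ~ U(0.8, 1.2) on single-endmember pixels: RMSE < 1e-3."""
        rng = np.random.default_rng(seed)
        ems = random_endmembers(rng, 32, 5)
        n = 1000
        assign = rng.integers(0, 5, size=n)
        psi_true = rng.uniform(0.8, 1.2, size=n)
        X = ems.S[:, assign] * psi_true
        r = elmm(as_pixels(X), ems, ElmmParams(lambda_psi=0.0))
        err = r.psi[assign, np.arange(n)] - psi_true
        assert np.sqrt(np.mean(err**2)) < 1e-3

    def test_objective_monotone_and_beats_fclsu_residual(self):
        rng = np.random.default_rng(2)
        ems = random_endmembers(rng, 16, 4)
        A = rng.dirichlet(np.ones(4), size=400).T
        psi = rng.uniform(0.8, 1.2, size=A.shape)
        X = ems.S @ (psi * A) + rng.normal(0, 0.005, size=(16, 400))
        X = np.clip(X, 0, None)
        r = elmm(as_pixels(X), ems, ElmmParams(lambda_psi=0.0))
        assert np.all(np.diff(r.objective_trace) <= 1e-10)
        base = fclsu(as_pixels(X), ems)
        res_f = 0.5 * np.sum((ems.S @ base.A - X) ** 2)
        assert r.objective_trace[-1] <= res_f + 1e-9


class TestGelmm:
    def test_huge_unit_penalty_collapses_to_fclsu(self):
        rng = np.random.default_rng(0)
        ems = random_endmembers(rng, 16, 4)
        A = rng.dirichlet(np.ones(4), size=200).T
        X = np.clip(ems.S @ A + rng.normal(0, 0.01, (16, 200)), 0, None)
        r = gelmm(as_pixels(X), ems,
                  GelmmParams(lambda_unit=1e9, lambda_smooth=0.0, max_iter=20))
        base = fclsu(as_pixels(X), ems)
        assert np.abs(r.abundances.A - base.A).max() < 1e-4

    def test_single_member_band_profile_recovered(self):
        rng = np.random.default_rng(1)
        s = np.abs(rng.normal(size=(8, 1))) + 0.2
        ems = EndmemberSet(s, ["m"], np.arange(8.0))
        c = 0.5 + rng.random(8)
        x = ems.S[:, 0] * c
        r = gelmm(as_pixels(x[:, None]), ems,
                  GelmmParams(lambda_smooth=0.0, lambda_unit=0.0))
        assert r.abundances.A[0, 0] == pytest.approx(1.0)
        assert np.corrcoef(r.Psi[0, :, 0], c)[0, 1] > 0.999

    def test_step_attenuation_profile_recovered(self):
        """One endmember dimmed x0.5 in red bands: recovered profile tracks it."""
        grid = np.linspace(410, 700, 32)
        panel = su.make_panel(grid=grid)
        labels = [l for l in panel.spectra if l != "background"]
        scene = su.make_pure_mosaic_scene((1, 32, 40), labels, seed=1)
        stack, truth = su.render(
            panel, scene,
            variability={"kind": "gelmm_step", "label": "Opal690",
                         "factor": 0.5, "above_nm": 650},
            seed=2,
        )
        pix = su.normalize_stack(stack)
        res = gelmm(pix, truth.endmembers, GelmmParams())
        j = truth.labels.index("Opal690")
        present = truth.A[j] > 0
        prof = res.Psi[present, :, j].mean(axis=0)
        r = np.corrcoef(prof, truth.Psi_profiles["Opal690"])[0, 1]
        assert r > 0.95
        assert np.all(np.diff(res.objective_trace) <= 1e-10)


class TestReconstruction:
    def test_pure_pixel_maps_to_saturation(self):
        ems = random_endmembers(np.random.default_rng(0), 6, 2)
        x = ems.S[:, 0]
        pix = as_pixels(np.column_stack([x, np.zeros(6)]), dtype=np.uint8)
        amap = fclsu(pix, ems)
        out = su.reconstruct_channels(amap, ems, pix)
        assert out.channels["m0"].ravel()[0] == 255  # dtype_max * unit peak
        assert out.channels["m1"].ravel()[0] == 0
        assert np.all(out.channels["m0"].ravel()[1] == 0)  # zero pixel

    def test_noise_free_scene_roundtrips_to_dice_one(self, panel):
        scene = su.make_scene((2, 40, 40), seed=3)
        stack, truth = su.render(panel, scene, seed=4)
        pix = su.normalize_stack(stack)
        amap = fclsu(pix, truth.endmembers)
        for j, label in enumerate(truth.labels[:-1]):
            d = su.dice(amap.A[j] >= 0.1, truth.A[j] >= 0.1)
            assert d == 1.0, label

    def test_unknown_label_rejected(self):
        ems = random_endmembers(np.random.default_rng(0), 6, 2)
        pix = as_pixels(np.random.default_rng(1).random((6, 4)))
        amap = fclsu(pix, ems)
        amap.labels = ["m0", "nope"]
        with pytest.raises(ValueError):
            su.reconstruct_channels(amap, ems, pix)
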