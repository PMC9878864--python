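"""Vertex component analysis and fingerprint matching."""

from itertools import permutations

import numpy as np
import pytest

import specunmix as su
from specunmix.endmembers import (
    EndmemberError,
    EndmemberSet,
    VcaParams,
    extract_fingerprints,
    fingerprint_rmse,
    match_endmembers,
    spectral_angle,
    vca,
)

from conftest import random_endmembers


def max_matched_angle(S_est, S_true):
    k = S_true.shape[1]
    return max(
        min(spectral_angle(S_est[:, i], S_true[:, j]) for i in range(S_est.shape[1]))
        for j in range(k)
    )


class TestVca:
    def test_one_hot_pure_pixels_recovered_exactly(self):
        """Repeated one-hot spectra are the simplex vertices themselves."""
        truth = np.eye(8)[:, :3]
        F = np.repeat(truth, 100, axis=1)
        ems = vca(F, VcaParams(k=3, seed=0))
        assert max_matched_angle(ems.S, truth) == 0.0
        assert ems.source_pixel_indices is not None

    def test_dirichlet_mixtures_with_pure_pixels(self):
        """Injected pure pixels in 2000 Dirichlet mixtures are found to < 1e-6 rad."""
        rng = np.random.default_rng(0)
        C, k = 32, 5
        S = np.abs(rng.normal(size=(C, k))) + 0.1
        S /= S.max(axis=0)
        A = rng.dirichlet(np.ones(k), size=2000).T
        A[:, :k] = np.eye(k)
        ems = vca(S @ A, VcaParams(k=k, seed=0))
        assert max_matched_angle(ems.S, S) < 1e-6

    def test_two_cluster_selection_matches_max_volume_pair(self):
        """k=2 picks one pixel per cluster, like the brute-force max-volume pair."""
        rng = np.random.default_rng(3)
        s1 = np.array([1.0, 0.2, 0.1, 0.05])
        s2 = np.array([0.05, 0.1, 0.3, 1.0])
        n = 40
        F = np.column_stack(
            [s1 + rng.normal(0, 0.01, 4) for _ in range(n // 2)]
            + [s2 + rng.normal(0, 0.01, 4) for _ in range(n // 2)]
        )
        F = np.abs(F)
        ems = vca(F, VcaParams(k=2, seed=0))
        # oracle: exhaustive pair with maximal simplex volume (pair distance)
        best = max(
            ((i, j) for i in range(n) for j in range(i + 1, n)),
            key=lambda ij: np.linalg.norm(F[:, ij[0]] - F[:, ij[1]]),
        )
        assert {best[0] < n // 2, best[1] < n // 2} == {True, False}
        got = set(int(i) >= n // 2 for i in ems.source_pixel_indices)
        assert got == {True, False}

    def test_invariant_to_pixel_shuffling(self):
        rng = np.random.default_rng(1)
        S = np.abs(rng.normal(size=(16, 4))) + 0.1
        A = rng.dirichlet(np.ones(4), size=500).T
        A[:, :4] = np.eye(4)
        F = S @ A
        perm = rng.permutation(F.shape[1])
        e1 = vca(F, VcaParams(k=4, seed=5))
        e2 = vca(F[:, perm], VcaParams(k=4, seed=5))
        spectra1 = sorted(map(tuple, np.round(e1.S.T, 12)))
        spectra2 = sorted(map(tuple, np.round(e2.S.T, 12)))
        assert spectra1 == spectra2

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        F = np.abs(rng.normal(size=(8, 200))) + 0.01
        i1 = vca(F, VcaParams(k=3, seed=11)).source_pixel_indices
        i2 = vca(F, VcaParams(k=3, seed=11)).source_pixel_indices
        assert np.array_equal(i1, i2)

    def test_both_projection_paths_recover_pure_pixels(self):
        """The high- and low-SNR reductions both keep exact vertices noise-free."""
        rng = np.random.default_rng(4)
        S = np.abs(rng.normal(size=(16, 4))) + 0.1
        S /= S.max(axis=0)
        A = rng.dirichlet(np.ones(4), size=400).T
        A[:, :4] = np.eye(4)
        F = S @ A
        for snr in (1e3, -1e3):  # force each path
            ems = vca(F, VcaParams(k=4, seed=0, snr_db_override=snr))
            assert max_matched_angle(ems.S, S) < 1e-6, snr

    def test_k_larger_than_bands_rejected(self):
        with pytest.raises(EndmemberError, match="exceeds|exceed"):
            vca(np.random.default_rng(0).random((4, 50)), VcaParams(k=5))

    def test_too_few_distinct_spectra_rejected(self):
        F = np.repeat(np.array([[1.0], [0.5]]), 30, axis=1)
        with pytest.raises(EndmemberError, match="distinct"):
            vca(F, VcaParams(k=2, seed=0))

    def test_unit_max_columns_and_k_bound(self):
        ems = random_endmembers(np.random.default_rng(0), 8, 3)
        assert np.allclose(ems.S.max(axis=0), 1.0)
        with pytest.raises(EndmemberError, match="under-determined"):
            EndmemberSet(np.ones((2, 3)), ["a", "b", "c"], [1.0, 2.0])


class TestMatching:
    def test_identity_assignment(self, panel):
        t = panel.as_table()
        ems = EndmemberSet.from_table(t)
        out = match_endmembers(ems, t)
        assert out.labels == t.labels
        assert all(abs(c - 1) < 1e-12 for c in out.match_report["correlations"].values())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_permutation_recovered_exactly(self, panel, seed):
        """Optimal assignment equals exhaustive search over all k! pairings."""
        t = panel.as_table()
        R = t.as_matrix()
        labels = t.labels
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(labels))
        ems = EndmemberSet(R[:, perm], [f"x{i}" for i in range(len(perm))],
                           t.wavelengths)
        out = match_endmembers(ems, t)
        assert out.labels == [labels[j] for j in perm]

        def corr(a, b):
            a = a - a.mean()
            b = b - b.mean()
            return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

        k = min(6, len(labels))
        sub = ems.S[:, :k]
        best = max(permutations(range(len(labels)), k),
                   key=lambda p: sum(corr(sub[:, i], R[:, p[i]]) for i in range(k)))
        assert [labels[j] for j in best] == out.labels[:k]

    def test_uncorrelated_column_flagged_unassigned(self, panel):
        t = panel.as_table()
        rng = np.random.default_rng(0)
        weird = np.abs(rng.normal(size=t.wavelengths.size)) * np.cos(
            np.arange(t.wavelengths.size) * 2.3
        ) ** 2 + 0.01
        S = np.column_stack([t.columns["DAPI"], weird / weird.max()])
        ems = EndmemberSet(S, ["a", "b"], t.wavelengths)
        out = match_endmembers(ems, t)
        assert out.labels[0] == "DAPI"
        assert out.labels[1].startswith("unassigned")
        assert out.match_report["unmatched"]

    def test_wavelength_grid_mismatch_rejected(self, panel):
        t = panel.as_table()
        ems = EndmemberSet.from_table(t)
        ems.wavelengths = ems.wavelengths + 1.0
        with pytest.raises(EndmemberError, match="grids"):
            match_endmembers(ems, t)


class TestFingerprintRmse:
    def test_closed_forms(self):
        a = np.linspace(0.1, 1.0, 32)
        assert fingerprint_rmse(a, a) == 0.0
        assert fingerprint_rmse(a, a - 0.05) == pytest.approx(0.05, abs=1e-12)
        with pytest.raises(EndmemberError, match="mismatch"):
            fingerprint_rmse(a, a[:-1])


class TestExtractionWorkflows:
    def test_single_positive_labels_fluorophore_and_background(self, panel):
        noise = su.NoiseModel(target_snr_db=40.0)
        stacks = [
            (su.make_single_positive(l, panel, shape=(2, 48, 48), noise=noise, seed=i)[0], l)
            for i, l in enumerate(["Opal570", "Opal620"])
        ]
        ems = extract_fingerprints(stacks, mode="single_positive", params=VcaParams(seed=0))
        assert ems.labels == ["Opal570", "Opal620", "background"]
        for l in ("Opal570", "Opal620"):
            assert fingerprint_rmse(ems.column(l), panel.spectra[l]) < 0.05

    def test_multiplex_without_reference_is_an_error(self, panel):
        scene = su.make_scene((1, 32, 32), seed=0)
        stack, _ = su.render(panel, scene, seed=1)
        with pytest.raises(EndmemberError, match="expected reference"):
            extract_fingerprints([(stack, "multiplex")], mode="multiplex",
                                 params=VcaParams(k=7, seed=0))
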