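import numpy as np
import pytest
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from dazvlsm.inference import (
    PermutationConfig,
    TfceParams,
    bh_fdr,
    bh_fdr_reject,
    bonferroni,
    permutation_correct,
    tfce,
)
from dazvlsm.vlsm import LesionMatrix, t_to_z, voxelwise_glm
from dazvlsm.volumes import GridSpec


def _lesion_matrix(rng, n=20, m=25, min_count=3):
    grid = GridSpec.default((8, 8, 8))
    vox = rng.choice(512, size=m, replace=False)
    voxel_index = np.stack(np.unravel_index(vox, (8, 8, 8)), axis=1)
    while True:
        L = (rng.random((n, m)) < 0.4).astype(np.uint8)
        if (L.sum(axis=0) >= min_count).all() and (L.sum(axis=0) <= n - min_count).all():
            break
    return LesionMatrix(patients=[f"p{i}" for i in range(n)], voxel_index=voxel_index,
                        L=L, min_overlap=1, grid=grid)


class TestBonferroni:
    def test_threshold_is_alpha_over_m(self, rng):
        lm = _lesion_matrix(rng, m=10)
        sm = voxelwise_glm(lm, rng.normal(size=20))
        res = bonferroni(sm, alpha=0.05)
        assert res.critical_value == pytest.approx(0.05 / sm.n_tested)
        expected = np.nan_to_num(sm.p_one_sided, nan=1.0) < 0.05 / sm.n_tested
        np.testing.assert_array_equal(res.rejected, expected)

    def test_large_m_threshold_quotient(self, rng):
        lm = _lesion_matrix(rng, m=5)
        sm = voxelwise_glm(lm, rng.normal(size=20))
        res = bonferroni(sm, alpha=0.05, m=193228)
        assert res.critical_value == pytest.approx(0.05 / 193228)

    def test_all_p_one_rejects_nothing(self, rng):
        lm = _lesion_matrix(rng, m=5)
        sm = voxelwise_glm(lm, rng.normal(size=20))
        sm.p_one_sided[:] = 1.0
        assert bonferroni(sm).n_significant == 0


class TestBhFdr:
    def test_worked_step_up_example(self):
        reject, crit = bh_fdr_reject(np.array([0.01, 0.02, 0.04, 0.50]), alpha=0.05)
        np.testing.assert_array_equal(reject, [True, True, False, False])
        assert crit == pytest.approx(0.02)

    def test_single_p_reduces_to_plain_threshold(self):
        reject, _ = bh_fdr_reject(np.array([0.04]), alpha=0.05)
        assert reject[0]

    def test_all_p_one_rejects_nothing(self):
        reject, crit = bh_fdr_reject(np.ones(10), alpha=0.05)
        assert not reject.any() and crit == 0.0

    def test_against_exhaustive_step_up_oracle(self, rng):
        """Enumerate every k explicitly and reject the k* smallest."""
        for _ in range(50):
            m = int(rng.integers(1, 40))
            p = rng.random(m) ** rng.uniform(0.5, 3)
            reject, _ = bh_fdr_reject(p, alpha=0.05)
            ranked = np.sort(p)
            k_star = max([k for k in range(1, m + 1) if ranked[k - 1] <= 0.05 * k / m],
                         default=0)
            assert reject.sum() == k_star
            if k_star:
                assert p[reject].max() <= ranked[k_star - 1]

    def test_matches_statsmodels(self, rng):
        for _ in range(20):
            p = rng.random(int(rng.integers(2, 100)))
            reject, _ = bh_fdr_reject(p, alpha=0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            np.testing.assert_array_equal(reject, ref)

    def test_bonferroni_rejections_subset_of_fdr(self, rng):
        """Step-up threshold >= alpha/m at every rank, so Bonferroni ⊆ FDR."""
        lm = _lesion_matrix(rng, n=30, m=40)
        for _ in range(20):
            y = rng.normal(size=30) + 0.5 * lm.L[:, 0]
            sm = voxelwise_glm(lm, y)
            bon = bonferroni(sm)
            fdr = bh_fdr(sm)
            assert np.all(fdr.rejected[bon.rejected])


def exact_tfce(zmap, params: TfceParams):
    """Piecewise-constant integration oracle: integrate e(h)^E * h^H
    exactly between consecutive distinct supra-threshold heights."""
    z = np.clip(np.asarray(zmap, dtype=float), 0, None)
    out = np.zeros_like(z)
    heights = np.unique(z[z > 0])
    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[params.connectivity])
    lo = 0.0
    for h in heights:
        supra = z >= h
        labels, _ = ndimage.label(supra, structure=structure)
        sizes = np.bincount(labels.ravel())
        seg = (h ** (params.H + 1) - lo ** (params.H + 1)) / (params.H + 1)
        out[supra] += sizes[labels[supra]] ** params.E * seg
        lo = h
    return out


class TestTfce:
    def test_all_zero_map(self):
        assert tfce(np.zeros((4, 4, 4))).sum() == 0

    def test_line_toy_map(self):
        """Heights [0,2,2,0] at dh=1: h=1 gives sqrt(2), h=2 gives 4*sqrt(2)."""
        z = np.array([0, 2, 2, 0], dtype=float).reshape(4, 1, 1)
        scores = tfce(z, TfceParams(dh=1.0))
        np.testing.assert_allclose(scores[1, 0, 0], 5 * np.sqrt(2), rtol=1e-12)
        np.testing.assert_allclose(scores[2, 0, 0], 5 * np.sqrt(2), rtol=1e-12)

    def test_isolated_voxel_toy(self):
        """Single voxel of height 3 at dh=1: 1 + 4 + 9 = 14."""
        z = np.zeros((3, 3, 3))
        z[1, 1, 1] = 3.0
        scores = tfce(z, TfceParams(dh=1.0))
        assert scores[1, 1, 1] == pytest.approx(14.0)

    def test_matches_exact_oracle_at_distinct_heights(self, rng):
        """With dh aligned to integer heights, sums agree with the exact
        piecewise integral computed only over those heights."""
        z = rng.integers(0, 4, size=(8, 8, 8)).astype(float)
        params = TfceParams(dh=1.0)
        approx = tfce(z, params)
        # at integer heights the right-Riemann sum integrates h^H over each
        # unit interval as h^H * 1; compare against the oracle's own sum
        oracle = np.zeros_like(z)
        structure = ndimage.generate_binary_structure(3, 3)
        for h in (1.0, 2.0, 3.0):
            supra = z >= h
            labels, _ = ndimage.label(supra, structure=structure)
            sizes = np.bincount(labels.ravel())
            oracle[supra] += sizes[labels[supra]] ** 0.5 * h**2
        np.testing.assert_allclose(approx, oracle, rtol=1e-12)

    def test_monotone_in_voxel_height(self, rng):
        z = rng.random((6, 6, 6)) * 3
        params = TfceParams(dh=0.05)
        base = tfce(z, params)
        z2 = z.copy()
        idx = tuple(rng.integers(0, 6, 3))
        z2[idx] += 1.0
        bumped = tfce(z2, params)
        assert (bumped >= base - 1e-9).all()

    def test_step_refinement_converges(self, rng):
        """Halving dh changes scores by < 2% on a random smooth map
        (Riemann-sum convergence; checked at the map maximum and at
        voxels carrying at least half the peak enhancement — voxels whose
        z barely clears a single step have scores of order dh and no
        meaningful relative error)."""
        for _ in range(3):
            z = ndimage.gaussian_filter(rng.normal(size=(12, 12, 12)), 2.0)
            z = np.clip(z, 0, None) * 10
            zmax = z.max()
            s1 = tfce(z, TfceParams(dh=zmax / 100))
            s2 = tfce(z, TfceParams(dh=zmax / 200))
            assert abs(s1.max() - s2.max()) / s2.max() < 0.02
            mask = s2 > 0.5 * s2.max()
            rel = np.abs(s1[mask] - s2[mask]) / s2[mask]
            assert rel.max() < 0.02

    def test_negative_values_clamped(self):
        z = np.full((3, 3, 3), -5.0)
        assert tfce(z).sum() == 0

    def test_bad_dh_rejected(self):
        with pytest.raises(ValueError):
            TfceParams(dh=-1.0)


class TestPermutation:
    def test_same_seed_reproduces_null_and_mask(self, rng):
        lm = _lesion_matrix(rng)
        y = rng.integers(0, 2, 20).astype(float)
        y[:2] = [0, 1]
        cfg = PermutationConfig(n_permutations=50, seed=7)
        r1 = permutation_correct(lm, y, cfg)
        r2 = permutation_correct(lm, y, cfg)
        np.testing.assert_array_equal(r1.null_max, r2.null_max)
        np.testing.assert_array_equal(r1.rejected, r2.rejected)

    def test_corrected_p_lower_bound(self, rng):
        """A peak never exceeded by the null gets p = 1/(B+1)."""
        lm = _lesion_matrix(rng)
        y = rng.integers(0, 2, 20).astype(float)
        y[:2] = [0, 1]
        cfg = PermutationConfig(n_permutations=24, seed=3)
        res = permutation_correct(lm, y, cfg)
        assert res.p_corrected.min() >= 1.0 / 25
        assert res.p_corrected.max() <= 1.0

    def test_null_max_matches_naive_oracle(self, rng):
        """Brute-force loop with scipy's two-sample t reproduces null_max."""
        lm = _lesion_matrix(rng, n=14, m=12)
        y = rng.normal(size=14)
        B, seed = 30, 11
        res = permutation_correct(lm, y, PermutationConfig(n_permutations=B, seed=seed))
        oracle_rng = np.random.default_rng(seed)
        df = 12
        expect = []
        for _ in range(B):
            yp = oracle_rng.permutation(y)
            ts = []
            for v in range(lm.n_voxels):
                col = lm.L[:, v].astype(bool)
                ts.append(stats.ttest_ind(yp[col], yp[~col], equal_var=True).statistic)
            _, zmax = t_to_z(np.array([max(ts)]), df)
            expect.append(zmax[0])
        np.testing.assert_allclose(res.null_max, expect, rtol=1e-10)

    def test_maxtfce_statistic_runs_and_is_reproducible(self, rng):
        lm = _lesion_matrix(rng, n=16, m=20)
        y = rng.integers(0, 2, 16).astype(float)
        y[:2] = [0, 1]
        cfg = PermutationConfig(n_permutations=20, seed=5, statistic="maxTFCE")
        r1 = permutation_correct(lm, y, cfg, TfceParams(dh=0.2))
        r2 = permutation_correct(lm, y, cfg, TfceParams(dh=0.2))
        np.testing.assert_array_equal(r1.null_max, r2.null_max)
        assert r1.method == "tfce-perm"

    def test_degenerate_voxels_never_significant(self, rng):
        lm = _lesion_matrix(rng)
        lm.L[:, 0] = 1  # constant column
        y = rng.integers(0, 2, 20).astype(float)
        y[:2] = [0, 1]
        res = permutation_correct(lm, y, PermutationConfig(n_permutations=20, seed=1))
        assert not res.rejected[0]
        assert res.p_corrected[0] == 1.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PermutationConfig(n_permutations=0)
        with pytest.raises(ValueError):
            PermutationConfig(statistic="maxFoo")
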