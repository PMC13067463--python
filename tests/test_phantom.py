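import hashlib
import json

import numpy as np
import pytest
from scipy import ndimage
import statsmodels.api as sm_api

from dazvlsm import phantom as ph
from dazvlsm.spatial import extract_daz
from dazvlsm.volumes import validate_cohort_grid


class TestGeometry:
    def test_shell_closure(self, space):
        """Every brain-boundary voxel has a dural voxel in its 26-neighborhood."""
        brain = space.brain.data.astype(bool)
        interior = ndimage.binary_erosion(brain, ndimage.generate_binary_structure(3, 1))
        boundary = brain & ~interior
        dura_halo = ndimage.binary_dilation(
            space.dura.domain, ndimage.generate_binary_structure(3, 3)
        )
        assert dura_halo[boundary].all()

    def test_falx_within_one_voxel_of_midline(self, space):
        falx = np.argwhere(space.dura.data == 2)
        world_x = space.grid.voxel_to_world(falx.astype(float))
        world_x = np.atleast_2d(world_x)[:, 0]
        assert np.abs(world_x).max() <= 1.0

    def test_compartments_partition_dural_domain(self, space):
        comp = space.compartment_map
        assert (comp > 0).sum() == space.dura.domain.sum()
        assert not (comp > 0)[~space.dura.domain].any()
        total = sum(len(space.compartment_voxels(n)) for n in ph.COMPARTMENTS)
        assert total == int(space.dura.domain.sum())

    def test_brain_and_dura_disjoint(self, space):
        assert not (space.brain.data.astype(bool) & space.dura.domain).any()

    def test_too_large_brain_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            ph.build_phantom_space(grid_size=(32, 32, 32), brain_axes=(25, 27, 22))


class TestGrowTumor:
    def test_contains_attachment_and_bounded_by_ball(self, space, rng):
        cand = np.argwhere(space.dura.domain)
        for _ in range(5):
            p = tuple(cand[rng.integers(len(cand))])
            r = float(rng.uniform(3, 10))
            tumor = ph.grow_tumor(space, p, r)
            assert tumor.data[p] == 1
            # exact lattice-ball oracle: voxel count cannot exceed the number
            # of lattice points within radius r of the attachment's position
            k = int(np.ceil(r)) + 1
            offs = np.arange(-k, k + 1)
            oi, oj, ok = np.meshgrid(offs, offs, offs, indexing="ij")
            lattice_ball = (oi**2 + oj**2 + ok**2 <= r**2).sum()
            assert tumor.n_voxels <= lattice_ball

    def test_single_voxel_for_subvoxel_radius(self, space):
        cand = np.argwhere(space.dura.domain)
        p = tuple(cand[0])
        assert ph.grow_tumor(space, p, 0.4).n_voxels == 1

    def test_connected(self, space, rng):
        cand = np.argwhere(space.dura.domain)
        p = tuple(cand[rng.integers(len(cand))])
        tumor = ph.grow_tumor(space, p, 9.0)
        _, n = ndimage.label(tumor.data, ndimage.generate_binary_structure(3, 3))
        assert n == 1

    def test_daz_of_grown_tumor_contains_attachment(self, space, rng):
        """Cross-module construction oracle: attachment survives the literal
        (dilation 0) dural intersection."""
        cand = np.argwhere(space.dura.domain)
        for _ in range(5):
            p = tuple(cand[rng.integers(len(cand))])
            tumor = ph.grow_tumor(space, p, 5.0)
            res = extract_daz(tumor, space.dura, dilation_voxels=0)
            assert res.attached and res.daz.data[p] == 1

    def test_off_dura_attachment_rejected(self, space):
        with pytest.raises(ValueError, match="dural"):
            ph.grow_tumor(space, (40, 32, 32), 5.0)  # interior voxel


class TestOutcomes:
    def test_null_prevalence_matches_p0(self, space):
        spec = ph.PhantomCohortSpec(n_patients=400, p0=0.3, p1=0.3, seed=5)
        rng = np.random.default_rng(spec.seed)
        hot = np.zeros(400)
        vols = np.full(400, 1.2)
        y = ph.simulate_outcomes(hot, vols, spec, rng)
        # 99.9% binomial interval around 0.3 at n=400
        assert abs(y.mean() - 0.3) < 3.3 * np.sqrt(0.3 * 0.7 / 400)

    def test_fixed_seed_reproducible(self, space):
        spec = ph.PhantomCohortSpec(n_patients=50, p0=0.2, p1=0.7,
                                    hot_region="falx", seed=9)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(spec.seed)
            hot = np.arange(50) < 20
            out.append(ph.simulate_outcomes(hot, np.full(50, 1.0), spec, rng))
        np.testing.assert_array_equal(out[0], out[1])

    def test_extreme_volume_effect_clamps_with_warning(self):
        spec = ph.PhantomCohortSpec(n_patients=10, p0=0.5, p1=0.5, volume_effect=50.0)
        rng = np.random.default_rng(0)
        vols = np.linspace(0.1, 5.0, 10)
        with pytest.warns(UserWarning, match="clamp"):
            y = ph.simulate_outcomes(np.zeros(10), vols, spec, rng)
        assert set(np.unique(y)) <= {0, 1}

    def test_logistic_fit_recovers_implanted_log_odds(self, space):
        """With p0=0.1, p1=0.6 and n=200, a logistic fit of endpoint on
        hot-region membership recovers the implanted log-odds difference
        within its 95% Wald interval in >= 90% of 20 replicates."""
        implanted = np.log(0.6 / 0.4) - np.log(0.1 / 0.9)
        hits = 0
        for seed in range(20):
            spec = ph.preset_spec("hotspot", n_patients=200, seed=seed)
            rng = np.random.default_rng(seed)
            att = ph.sample_attachments(space, spec, rng)
            hot = np.array([ph.in_hot_region(space, a, spec.hot_region) for a in att])
            y = ph.simulate_outcomes(hot, np.full(200, 1.2), spec, rng)
            fit = sm_api.Logit(y, sm_api.add_constant(hot.astype(float))).fit(disp=0)
            beta, se = fit.params[1], fit.bse[1]
            hits += abs(beta - implanted) <= 1.96 * se
        assert hits >= 18

    def test_attachment_frequencies_respect_weights(self, space):
        """Compartment frequencies match sampling weights within a
        multinomial confidence band at n = 500."""
        weights = (("falx", 0.5), ("convexity_right", 0.3), ("tentorium", 0.2))
        spec = ph.PhantomCohortSpec(n_patients=500, attachment_weights=weights, seed=3)
        rng = np.random.default_rng(spec.seed)
        att = ph.sample_attachments(space, spec, rng)
        comps = [space.compartment_of(a) for a in att]
        for name, w in weights:
            freq = np.mean([c == name for c in comps])
            assert abs(freq - w) < 3.3 * np.sqrt(w * (1 - w) / 500)


class TestGenerateCohort:
    def test_volume_law_calibration(self, space):
        """Empirical mean tumor volume within 15% of the lognormal target
        at n = 200."""
        spec = ph.PhantomCohortSpec(n_patients=200, seed=11)
        masks, table, _ = ph.generate_cohort(space, spec)
        mean_ml = table["volume_ml"].mean()
        assert abs(mean_ml - spec.mean_volume_ml) / spec.mean_volume_ml < 0.15

    def test_byte_identical_rerun(self, space, tmp_path):
        spec = ph.PhantomCohortSpec(n_patients=10, seed=21)
        digests = []
        for sub in ("a", "b"):
            d = tmp_path / sub
            ph.generate_cohort(space, spec, out_dir=d)
            files = sorted(p.name for p in d.iterdir())
            digests.append({f: hashlib.sha256((d / f).read_bytes()).hexdigest() for f in files})
        assert digests[0] == digests[1]

    def test_masks_share_grid_and_truth_is_consistent(self, space, tmp_path):
        spec = ph.preset_spec("hotspot", n_patients=12, seed=4)
        masks, table, truth = ph.generate_cohort(space, spec, out_dir=tmp_path)
        validate_cohort_grid(masks)
        assert len(truth["patients"]) == 12
        reloaded = json.loads((tmp_path / "truth.json").read_text())
        assert reloaded["spec"]["p1"] == 0.6
        # truth record regenerates each mask deterministically
        for i in (0, 5, 11):
            rec = truth["patients"][i]
            m = ph.grow_tumor(space, rec["attachment_ijk"], rec["radius_mm"])
            np.testing.assert_array_equal(m.data, masks[i].data)
            assert rec["endpoint"] == int(table["endpoint"][i])

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            ph.preset_spec("nope")
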