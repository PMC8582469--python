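"""HU conversion, plan simulation, cDVH, isodose and map comparison."""

import numpy as np
import pytest

import brachymc as bm
from brachymc.clinical import HuMaterialMap, Profile
from brachymc.scoring import DoseMap


class TestHuConversion:
    def test_uniform_zero_all_soft_tissue(self):
        hu = np.zeros((4, 4, 4))
        ph = bm.hu_to_phantom(hu, HuMaterialMap.default(), (1, 1, 1))
        assert ph.materials[int(ph.material_ids[0, 0, 0])] == "soft_tissue"
        assert np.all(ph.material_ids == ph.material_ids[0, 0, 0])

    def test_boundary_goes_to_upper_interval(self):
        m = HuMaterialMap.default()
        hu = np.array([[[-600.0, 100.0, 300.0, 299.999]]])
        ph = bm.hu_to_phantom(hu, m, (1, 1, 1))
        names = [ph.materials[i] for i in ph.material_ids.ravel()]
        assert names == ["soft_tissue", "prostate", "cortical_bone",
                         "prostate"]

    def test_prostate_confined_to_mask(self):
        hu = np.full((2, 2, 2), 150.0)
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 0] = True
        ph = bm.hu_to_phantom(hu, HuMaterialMap.default(), (1, 1, 1),
                              prostate_mask=mask)
        names = np.array(ph.materials)[ph.material_ids]
        assert names[0, 0, 0] == "prostate"
        assert np.all(names.ravel()[1:] == "soft_tissue")

    def test_out_of_span_clamped(self):
        hu = np.array([[[-3000.0, 5000.0]]])
        ph = bm.hu_to_phantom(hu, HuMaterialMap.default(), (1, 1, 1))
        names = [ph.materials[i] for i in ph.material_ids.ravel()]
        assert names == ["lung", "cortical_bone"]

    def test_empty_raster_rejected(self):
        with pytest.raises(ValueError):
            bm.hu_to_phantom(np.zeros((0,)), HuMaterialMap.default(),
                             (1, 1, 1))

    def test_noncontiguous_ranges_rejected(self):
        from brachymc.clinical import HuRange
        with pytest.raises(ValueError):
            HuMaterialMap(ranges=(
                HuRange(-1050, -600, "lung", 0.26),
                HuRange(-500, 4000, "soft_tissue", 1.06)))

    def test_pelvis_fixture_fractions_match_construction(self):
        """Material voxel fractions equal the fixture's own bookkeeping."""
        phantom, organs, hu = bm.make_pelvis_phantom(dims=(64, 64, 24))
        m = HuMaterialMap.default()
        ids = m.lookup(np.clip(hu, -1050, 3999.999))
        # prostate interval outside the mask demotes to soft tissue
        names = np.array(m.materials)[ids]
        got = np.array(phantom.materials)[phantom.material_ids]
        assert np.mean(got == "cortical_bone") == pytest.approx(
            np.mean(names == "cortical_bone"))
        assert np.sum(got == "prostate") <= np.sum(names == "prostate")
        assert np.mean(got == "lung") == pytest.approx(
            np.mean(hu < -600.0))


def _filled_map(vals, n_hist=4, noise=0.0, seed=0):
    vals = np.asarray(vals, float)
    m = DoseMap(np.zeros(3), np.ones(3), vals.shape)
    rng = np.random.default_rng(seed)
    for h in range(n_hist):
        contrib = vals.copy()     # value property averages over histories
        if noise:
            contrib = contrib * (1 + noise * rng.standard_normal(vals.shape))
        for flat, v in enumerate(contrib.ravel()):
            if v != 0:
                m._score(flat, v, h)
    m._flush()
    m.n_histories = n_hist
    return m


class TestCdvh:
    def test_uniform_dose_step_function(self):
        vals = np.zeros((4, 4, 4))
        mask = np.zeros((4, 4, 4), bool)
        mask[:2] = True
        vals[mask] = 2.0
        m = _filled_map(vals)
        c = bm.compute_cdvh(m, mask, edges=[0.0, 1.0, 2.0, 2.5])
        assert list(c.volume_fraction) == [100.0, 100.0, 100.0, 0.0]

    def test_matches_bruteforce_sort_count(self, rng):
        vals = rng.random((5, 5, 5))
        mask = rng.random((5, 5, 5)) < 0.6
        m = _filled_map(vals)
        edges = np.linspace(0, 1.1, 23)
        c = bm.compute_cdvh(m, mask, edges=edges)
        sel = m.value[mask]
        brute = [100.0 * np.sum(np.sort(sel) >= d) / sel.size
                 for d in edges]
        brute[0] = 100.0
        assert np.allclose(c.volume_fraction, brute)

    def test_monotone_and_starts_at_100(self, rng):
        vals = rng.random((6, 6, 6))
        m = _filled_map(vals)
        c = bm.compute_cdvh(m, np.ones((6, 6, 6), bool))
        assert c.volume_fraction[0] == 100.0
        assert np.all(np.diff(c.volume_fraction) <= 1e-12)

    def test_empty_mask_rejected(self):
        m = _filled_map(np.ones((2, 2, 2)))
        with pytest.raises(ValueError):
            bm.compute_cdvh(m, np.zeros((2, 2, 2), bool))

    def test_grid_mismatch_rejected(self):
        m = _filled_map(np.ones((2, 2, 2)))
        with pytest.raises(ValueError):
            bm.compute_cdvh(m, np.ones((3, 3, 3), bool))


class TestIsodose:
    def test_nesting_and_labels(self, rng):
        m = _filled_map(rng.random((6, 6, 6)) * 2.0)
        masks, labels = bm.isodose_masks(m, prescription=1.0)
        assert np.all(masks[150.0] <= masks[100.0])
        assert np.all(masks[100.0] <= masks[50.0])
        assert labels.max() <= 3

    def test_strict_inequality_at_exactly_100(self):
        m = _filled_map(np.full((3, 3, 3), 1.0))
        masks, _ = bm.isodose_masks(m, prescription=1.0)
        assert masks[50.0].all()
        assert not masks[100.0].any()
        assert not masks[150.0].any()

    def test_counts_match_bruteforce(self, rng):
        vals = rng.random((5, 5, 5))
        m = _filled_map(vals)
        masks, _ = bm.isodose_masks(m, prescription=0.5)
        for t, mask in masks.items():
            assert mask.sum() == np.sum(m.value > t / 100.0 * 0.5)

    def test_monotone_rebinning_invariance(self, rng):
        """Isodose masks depend only on the ordering of dose vs threshold:
        any strictly monotone rescaling of map + prescription together
        leaves the masks unchanged."""
        vals = rng.random((4, 4, 4))
        m1 = _filled_map(vals)
        m2 = _filled_map(vals * 7.5)
        a, _ = bm.isodose_masks(m1, prescription=0.6)
        b, _ = bm.isodose_masks(m2, prescription=0.6 * 7.5)
        for t in a:
            assert np.array_equal(a[t], b[t])

    def test_nonpositive_prescription_rejected(self):
        with pytest.raises(ValueError):
            bm.isodose_masks(_filled_map(np.ones((2, 2, 2))), 0.0)


class TestCompareMaps:
    def test_identical_maps_zero(self, rng):
        vals = rng.random((6, 4, 4)) + 0.5
        a = _filled_map(vals, noise=0.01, seed=1)
        prof = Profile(axis=0, fixed=(2, 2))
        cmp_ = bm.compare_maps(a, a, prof, sigma_gate_percent=50.0)
        assert cmp_.average_percent == 0.0
        assert cmp_.maximum_percent == 0.0

    def test_ratio_closed_form(self, rng):
        """b = 1.1 a gives 100 * 0.1/1.05 = 9.5238% everywhere."""
        vals = rng.random((6, 4, 4)) + 0.5
        a = _filled_map(vals, noise=0.0, seed=1)
        b = _filled_map(vals * 1.1, noise=0.0, seed=2)
        cmp_ = bm.compare_maps(a, b, Profile(axis=0, fixed=(2, 2)),
                               sigma_gate_percent=50.0)
        assert cmp_.average_percent == pytest.approx(100 * 0.1 / 1.05,
                                                     rel=1e-9)
        assert cmp_.average_percent <= cmp_.maximum_percent + 1e-12

    def test_sigma_gate_excludes_noisy_points(self, rng):
        vals = np.ones((6, 4, 4))
        a = _filled_map(vals, noise=0.3, seed=3)
        b = _filled_map(vals, noise=0.3, seed=4)
        strict = bm.compare_maps(a, b, Profile(axis=0, fixed=(1, 1)),
                                 sigma_gate_percent=0.001)
        assert strict.n_compared == 0

    def test_grid_mismatch_rejected(self):
        a = _filled_map(np.ones((2, 2, 2)))
        b = DoseMap(np.zeros(3), np.ones(3), (3, 3, 3))
        with pytest.raises(ValueError):
            bm.compare_maps(a, b, Profile(axis=0, fixed=(0, 0)))


@pytest.fixture(scope="module")
def small_plan_run():
    phantom, organs, _ = bm.make_pelvis_phantom(dims=(64, 64, 24))
    plan = bm.TreatmentPlan(
        entries=[e for e in bm.make_plan_67().entries[:5]])
    phsp = bm.generate_phsp(bm.build_seed("AmershamOncoseed6711"),
                            20_000, rng=9)
    store = {"AmershamOncoseed6711": phsp}
    return phantom, organs, plan, store


class TestPlanSimulation:
    def test_sk_linearity(self, small_plan_run):
        """Doubling every seed's S_K doubles every voxel dose exactly."""
        phantom, _, plan, store = small_plan_run
        cfg = bm.SimConfig(n_histories=20_000, rng_seed=42)
        d1, _ = bm.simulate_plan_mc(plan, phantom, cfg, store)
        plan2 = bm.TreatmentPlan(entries=[
            bm.PlanEntry(e.seed_id, e.pose, e.s_k * 2.0)
            for e in plan.entries])
        d2, _ = bm.simulate_plan_mc(plan2, phantom, cfg, store)
        assert np.allclose(d2._sum, 2.0 * d1._sum, rtol=1e-12)

    def test_missing_phsp_names_seed(self, small_plan_run):
        phantom, _, plan, _ = small_plan_run
        with pytest.raises(KeyError, match="AmershamOncoseed6711"):
            bm.simulate_plan_mc(plan, phantom,
                                bm.SimConfig(n_histories=100, rng_seed=0),
                                {})

    def test_history_allocation_proportional(self, small_plan_run):
        phantom, _, plan, store = small_plan_run
        uneven = bm.TreatmentPlan(entries=[
            bm.PlanEntry(e.seed_id, e.pose, sk)
            for e, sk in zip(plan.entries, (1.0, 1.0, 2.0, 4.0, 8.0))])
        _, info = bm.simulate_plan_mc(
            uneven, phantom, bm.SimConfig(n_histories=16_000, rng_seed=1),
            store)
        assert info["histories_per_seed"] == [1000, 1000, 2000, 4000, 8000]

    def test_replay_matches_direct_simulation(self, seed_6711):
        """A 1-seed plan in all-water agrees with direct seed-in-water
        simulation within combined 3 sigma (near-source, low-noise region).
        Both runs use identical physics (no in-seed fluorescence)."""
        box = bm.make_water_box(half_extent_mm=(12, 12, 12), spacing_mm=1.5)
        n = 120_000
        direct = bm.transport_through_seed(
            seed_6711, n, np.random.default_rng(5), fluorescence=False)
        m_direct = box.new_map()
        bm.run_voxel_phantom(direct, box, bm.SimConfig(rng_seed=6),
                             tle_map=m_direct)
        phsp = bm.generate_phsp(seed_6711, 30_000, rng=7)
        e, p, d, w, h = bm.replay_source(phsp, bm.Pose(), n,
                                         np.random.default_rng(8))
        m_replay = box.new_map()
        bm.run_voxel_phantom((e, p / 10.0, d, w, h), box,
                             bm.SimConfig(rng_seed=9), tle_map=m_replay)
        # compare where both are statistically solid
        scale = direct.n / direct.n_primary   # records per primary
        va = m_direct.value * (n / direct.n)  # per escaping photon
        vb = m_replay.value
        ra = bm.estimate_uncertainty(m_direct)
        rb = bm.estimate_uncertainty(m_replay)
        ok = (np.nan_to_num(ra, nan=1) < 0.05) & (np.nan_to_num(rb, nan=1)
                                                  < 0.05)
        assert ok.sum() > 100
        # replay maps carry a finite-record source term on top of the
        # per-history variance
        rb_tot = rb[ok] * np.sqrt(1.0 + n / phsp.n_records)
        z = np.abs(va[ok] - vb[ok]) / np.hypot(ra[ok] * va[ok],
                                               rb_tot * vb[ok])
        assert np.mean(z < 3.0) > 0.97
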