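import numpy as np
import pytest

from hubvuln.parcellation import tessellate
from hubvuln.simulate import (
    GroundTruth,
    Scenario,
    band_limited_noise,
    make_ground_truth,
    make_mask,
    simulate_behaviour,
    simulate_bold,
    simulate_expression,
    simulate_motion,
    simulate_region_signals,
)
from hubvuln.study import expected_strengths, simulate_study


@pytest.fixture(scope="module")
def setup():
    sc = Scenario(n_regions=20, n_subjects_per_group=3, n_timepoints=128)
    grid = make_mask((14, 14, 14), seed=1)
    parc = tessellate(grid, sc.n_regions, seed=1)
    gt = make_ground_truth(parc, sc, seed=1)
    return sc, grid, parc, gt


class TestScenario:
    def test_invariants(self):
        with pytest.raises(ValueError):
            Scenario(n_timepoints=32)
        with pytest.raises(ValueError):
            Scenario(repetition_time=0.0)
        with pytest.raises(ValueError):
            Scenario(n_donors=3, single_hemisphere_donors=4)


class TestGroundTruth:
    def test_invariants_enforced(self, setup):
        _, _, _, gt = setup
        with pytest.raises(ValueError, match="nonempty"):
            GroundTruth(
                hub_region_ids=set(),
                expression_strength_corr=0.3,
                attenuation_map={"PD": np.zeros(3)},
                fluency_slope=1.0,
                seeds={"s": 0},
                loadings=np.zeros((3, 2)),
                noise_sd=1.0,
                expected_strength=np.zeros(3),
                expression_profiles={},
                class_of_region=np.zeros(3, dtype=int),
                class_labels=["a"],
            )
        with pytest.raises(ValueError, match="outside"):
            GroundTruth(
                hub_region_ids={1},
                expression_strength_corr=0.3,
                attenuation_map={"PD": np.array([1.5])},
                fluency_slope=1.0,
                seeds={"s": 0},
                loadings=np.zeros((1, 1)),
                noise_sd=1.0,
                expected_strength=np.zeros(1),
                expression_profiles={},
                class_of_region=np.zeros(1, dtype=int),
                class_labels=["a"],
            )

    def test_round_trip_dict(self, setup):
        _, _, _, gt = setup
        gt2 = GroundTruth.from_dict(gt.to_dict())
        assert gt2.hub_region_ids == gt.hub_region_ids
        assert np.array_equal(gt2.loadings, gt.loadings)
        for g in gt.attenuation_map:
            assert np.array_equal(gt2.attenuation_map[g], gt.attenuation_map[g])

    def test_regeneration_is_exact(self, setup):
        sc, _, parc, gt = setup
        gt2 = make_ground_truth(parc, sc, seed=1)
        assert np.array_equal(gt.loadings, gt2.loadings)
        assert gt.hub_region_ids == gt2.hub_region_ids
        sig1 = simulate_region_signals(gt, sc, "PD", seed=4)
        sig2 = simulate_region_signals(GroundTruth.from_dict(gt.to_dict()), sc, "PD", seed=4)
        assert np.array_equal(sig1, sig2)

    def test_planted_hubs_have_top_covariance_row_sums(self, setup):
        sc, _, parc, gt = setup
        cov = gt.loadings @ gt.loadings.T + gt.noise_sd**2 * np.eye(len(parc.region_ids))
        rowsum = cov.sum(axis=1) - np.diag(cov)
        cut = np.quantile(rowsum, 0.9)
        hub_idx = np.isin(parc.region_ids, sorted(gt.hub_region_ids))
        assert np.all(rowsum[hub_idx] >= cut)


class TestBandLimitedNoise:
    def test_energy_confined_to_band(self, rng):
        x = band_limited_noise(512, 4, rng, level=2)
        F = np.abs(np.fft.rfft(x, axis=0)) ** 2
        f = np.fft.rfftfreq(512)
        inband = (f > 0.125) & (f <= 0.25)
        assert F[inband].sum() / F.sum() > 0.999

    def test_unit_variance(self, rng):
        x = band_limited_noise(256, 5, rng)
        assert np.allclose(x.std(axis=0), 1.0)


class TestRegionSignals:
    def test_unknown_group_errors(self, setup):
        sc, _, _, gt = setup
        with pytest.raises(ValueError, match="unknown group"):
            simulate_region_signals(gt, sc, "HD", seed=0)

    def test_deterministic(self, setup):
        sc, _, _, gt = setup
        a = simulate_region_signals(gt, sc, "control", seed=5)
        b = simulate_region_signals(gt, sc, "control", seed=5)
        assert np.array_equal(a, b)

    def test_attenuation_reduces_covariance(self, setup):
        sc, _, _, gt = setup
        e_ctrl = expected_strengths(gt, "control")
        e_psp = expected_strengths(gt, "PSP")
        assert np.all(e_psp <= e_ctrl + 1e-12)
        assert e_psp.sum() < e_ctrl.sum()


class TestSimulateBold:
    def test_deterministic(self, setup):
        sc, _, parc, gt = setup
        v1, t1 = simulate_bold(parc, sc, "control", gt, seed=2)
        v2, t2 = simulate_bold(parc, sc, "control", gt, seed=2)
        assert np.array_equal(v1, v2)
        assert np.array_equal(t1.translations, t2.translations)

    def test_shape_and_masking(self, setup):
        sc, grid, parc, gt = setup
        vol, _ = simulate_bold(parc, sc, "control", gt, seed=2)
        assert vol.shape == grid.dims + (sc.n_timepoints,)
        assert np.all(vol[~grid.mask] == 0)
        assert vol[grid.mask].std() > 0


class TestSimulateMotion:
    def test_spikes_raise_fd(self):
        from hubvuln.qc_motion import framewise_displacement

        calm = simulate_motion(200, 2.0, seed=0, spike_rate=0.0)
        spiky = simulate_motion(200, 2.0, seed=0, spike_rate=0.1, spike_mm=6.0)
        assert framewise_displacement(spiky).max() > 5.0
        assert framewise_displacement(calm).max() < 1.0


class TestSimulateExpression:
    def test_hemisphere_counts(self, setup):
        # 6 donors with 4 single-hemisphere: exactly 2 have both labels
        sc, _, parc, gt = setup
        samples, _ = simulate_expression(parc, sc, gt, seed=3)
        both = [
            d
            for d, blk in samples.groupby("donor_id")
            if {"L", "R"}.issubset(set(blk["hemisphere"]))
        ]
        assert len(both) == sc.n_donors - sc.single_hemisphere_donors == 2

    def test_noiseless_donors_identical_after_normalization(self, setup):
        from hubvuln.expression_map import normalize_within_donor

        sc, _, parc, gt = setup
        sc0 = Scenario(
            n_regions=sc.n_regions,
            n_timepoints=128,
            expression_noise_sd=0.0,
            single_hemisphere_donors=0,
            add_qc_fail_probe=False,
        )
        samples, probes = simulate_expression(
            parc, sc0, gt, seed=3, donor_offset_sd=0.0, probe_offset_sd=0.0
        )
        norm = normalize_within_donor(samples, probes)
        pivots = {
            d: blk.groupby("structure_label")["MAPT_p0"].mean()
            for d, blk in norm.groupby("donor_id")
        }
        ref = list(pivots.values())[0]
        for other in pivots.values():
            assert np.allclose(ref.sort_index(), other.sort_index(), atol=1e-9)

    def test_planted_correlation_with_strength(self):
        sc = Scenario(n_regions=100, n_timepoints=128, expression_noise_sd=0.01)
        grid = make_mask((22, 22, 22), seed=11)
        parc = tessellate(grid, 100, seed=11)
        gt = make_ground_truth(parc, sc, seed=11, expression_strength_corr=0.3)
        prof = gt.expression_profiles[sc.genes[0]]
        r = np.corrcoef(prof, gt.expected_strength)[0, 1]
        assert abs(r - 0.3) < 0.1

    def test_probe_table_structure(self, setup):
        sc, _, parc, gt = setup
        _, probes = simulate_expression(parc, sc, gt, seed=3)
        for gene in sc.genes:
            block = probes[probes["gene"] == gene]
            assert block["qc_pass"].sum() == sc.n_probes_per_gene
            assert (~block["qc_pass"]).sum() == 1


class TestSimulateBehaviour:
    def test_zero_slope_zero_noise_hits_intercepts(self, setup):
        _, _, _, gt = setup
        gt2 = GroundTruth.from_dict(gt.to_dict())
        gt2.fluency_slope = 0.0
        gt2.fluency_noise_sd = 0.0
        groups = np.array(["control", "PD", "PSP"] * 4, dtype=object)
        out = simulate_behaviour(np.ones(12), groups, gt2, seed=0)
        means = out.groupby("group")["fluency"].mean()
        assert means["control"] == pytest.approx(40.3)
        assert means["PD"] == pytest.approx(34.3)
        assert means["PSP"] == pytest.approx(14.1)

    def test_slope_recovered_by_least_squares(self, setup):
        _, _, _, gt = setup
        gt2 = GroundTruth.from_dict(gt.to_dict())
        gt2.fluency_noise_sd = 1e-9
        rng = np.random.default_rng(0)
        s = rng.normal(10, 3, size=200)
        groups = np.array(["PD"] * 200, dtype=object)
        out = simulate_behaviour(s, groups, gt2, seed=1)
        slope = np.polyfit(s, out["fluency"], 1)[0]
        assert slope == pytest.approx(gt2.fluency_slope, abs=1e-6)

    def test_updrs_independent_of_hub_strength(self, setup):
        _, _, _, gt = setup
        rng = np.random.default_rng(1)
        s = rng.normal(10, 3, size=500)
        out = simulate_behaviour(s, np.array(["PD"] * 500, dtype=object), gt, seed=2)
        assert abs(np.corrcoef(s, out["updrs"])[0, 1]) < 0.15


class TestStudyDeterminism:
    def test_same_seed_same_study(self):
        sc = Scenario(n_regions=15, n_subjects_per_group=2, n_timepoints=96)
        a = simulate_study(sc, seed=5, mask_shape=(14, 14, 14))
        b = simulate_study(sc, seed=5, mask_shape=(14, 14, 14))
        assert np.array_equal(a.parcellation.labels, b.parcellation.labels)
        for sid in a.signals:
            assert np.array_equal(a.signals[sid], b.signals[sid])
        assert a.subjects.equals(b.subjects)
        assert a.samples.equals(b.samples)
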