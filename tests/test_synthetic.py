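"""Tests of the synthetic cohort generator and its planted structure."""

import numpy as np
import pytest

from hippomediate import preprocess as pp
from hippomediate.connectivity import fisher_z, rsfc_map, seed_timeseries
from hippomediate.synthetic import (
    AAQ_MARGINAL,
    CohortSpec,
    default_regions,
    gen_behavior,
    gen_cohort,
    gen_motion,
    gen_paths_dataset,
)


def _quick_spec(**kw):
    kw.setdefault("n_subjects", 8)
    kw.setdefault("n_volumes", 60)
    return CohortSpec(**kw)


class TestDeterminism:
    def test_behavior_identical_across_calls(self):
        spec = _quick_spec(rng_seed=7)
        assert gen_behavior(spec).equals(gen_behavior(spec))

    def test_motion_and_volumes_bit_identical(self):
        spec = _quick_spec(rng_seed=7)
        co1, co2 = gen_cohort(spec), gen_cohort(spec)
        np.testing.assert_array_equal(gen_motion(spec, 3).values, gen_motion(spec, 3).values)
        np.testing.assert_array_equal(co1.volume(2).data, co2.volume(2).data)
        assert co1.behavior.equals(co2.behavior)

    def test_different_seeds_differ(self):
        a = gen_behavior(_quick_spec(rng_seed=1))
        b = gen_behavior(_quick_spec(rng_seed=2))
        assert not a["aaq"].equals(b["aaq"])


class TestBehavior:
    def test_acceptance_marginals_match_cohort_table(self):
        table = gen_behavior(CohortSpec(n_subjects=2000, rng_seed=3))
        assert table["aaq"].mean() == pytest.approx(AAQ_MARGINAL[0], abs=1.0)
        assert table["aaq"].std() == pytest.approx(AAQ_MARGINAL[1], abs=1.0)
        assert table["age"].between(18, 65).all()
        assert set(table["sex"].unique()) <= {0, 1}

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="subjects"):
            CohortSpec(n_subjects=3)


class TestMotion:
    def test_no_spikes_keeps_fd_low(self):
        spec = _quick_spec(spike_prob=0.0, rng_seed=5)
        for i in range(spec.n_subjects):
            fd = pp.compute_fd(gen_motion(spec, i))
            assert fd.max() < 0.5

    def test_every_spiked_volume_exceeds_threshold(self):
        spec = CohortSpec(n_subjects=8, n_volumes=10, spike_prob=1.0, rng_seed=5)
        fd = pp.compute_fd(gen_motion(spec, 0))
        assert (fd > 0.5).sum() >= 9

    def test_zero_noise_amplitude_gives_constant_trace(self):
        spec = _quick_spec(motion_noise=0.0, spike_prob=0.0)
        m = gen_motion(spec, 1)
        np.testing.assert_array_equal(m.values, 0.0)
        np.testing.assert_array_equal(pp.compute_fd(m), 0.0)

    def test_high_motion_subjects_exceed_mean_fd(self):
        spec = CohortSpec(n_subjects=10, n_volumes=100, high_motion_subjects=(2, 7), rng_seed=9)
        for i in (2, 7):
            fd = pp.compute_fd(gen_motion(spec, i))
            assert fd.mean() > 0.5
        fd_quiet = pp.compute_fd(gen_motion(spec, 0))
        assert fd_quiet.mean() < 0.5


class TestRegions:
    def test_default_regions_disjoint_and_in_brain(self):
        regions = default_regions((20, 20, 10))
        for name in ("seed", "target", "noise"):
            assert regions[name].any()
            assert not (regions[name] & ~regions["brain"]).any()
        assert not (regions["seed"] & regions["target"]).any()
        assert not (regions["seed"] & regions["noise"]).any()
        assert not (regions["target"] & regions["noise"]).any()

    def test_overlapping_regions_rejected(self):
        regions = default_regions((20, 20, 10))
        with pytest.raises(ValueError, match="overlap"):
            CohortSpec(seed_region=regions["seed"], target_region=regions["seed"])

    def test_label_volume_codes(self):
        labels = _quick_spec().label_volume()
        assert set(np.unique(labels)) <= {0, 1, 2, 3, 10, 20}
        for code in (1, 2, 3, 10, 20):
            assert (labels == code).any()


class TestPlantedStructure:
    def _zmaps_no_cleanup(self, spec):
        """Fast z-maps straight from raw volumes (no nuisance chain)."""
        co = gen_cohort(spec)
        mask = spec.brain_mask & ~spec.seed_region
        Z = []
        for i in range(spec.n_subjects):
            vol = co.volume(i)
            ts = seed_timeseries(vol, spec.seed_region)
            Z.append(fisher_z(rsfc_map(vol, ts, mask)))
        return co, np.array(Z), mask

    def test_null_planting_uncorrelated_with_x(self):
        spec = CohortSpec(n_subjects=200, n_volumes=100, a_true=0.0, rng_seed=21)
        co, Z, mask = self._zmaps_no_cleanup(spec)
        x = co.truth["x_std"]
        xs = (x - x.mean()) / x.std()
        target_z = Z[:, co.truth["target_region"]]
        r = (xs @ (target_z - target_z.mean(0))) / len(x) / target_z.std(0)
        assert np.abs(r).max() < 0.15

    def test_background_voxels_independent_of_x(self):
        spec = CohortSpec(n_subjects=200, n_volumes=100, rng_seed=22)
        co, Z, mask = self._zmaps_no_cleanup(spec)
        bg = mask & ~co.truth["support_region"]
        idx = np.argwhere(bg)[::13]  # subsample for speed
        x = co.truth["x_std"]
        xs = (x - x.mean()) / x.std()
        vals = Z[:, idx[:, 0], idx[:, 1], idx[:, 2]]
        r = (xs @ (vals - vals.mean(0))) / len(x) / vals.std(0)
        assert np.abs(r).mean() < 0.1

    def test_recovered_slope_monotone_in_a_true(self):
        slopes = []
        for a in (0.0, 0.35, 0.7):
            est = []
            for rep in range(2):
                spec = CohortSpec(n_subjects=60, n_volumes=100, a_true=a, rng_seed=100 + rep)
                co, Z, _ = self._zmaps_no_cleanup(spec)
                x = co.truth["x_std"]
                xc = x - x.mean()
                tz = Z[:, co.truth["target_region"]]
                est.append(((xc @ (tz - tz.mean(0))) / (xc @ xc)).mean())
            slopes.append(np.mean(est))
        assert slopes[0] < slopes[1] < slopes[2]

    def test_outcome_built_from_structural_model(self):
        spec = CohortSpec(n_subjects=500, rng_seed=31)
        co = gen_cohort(spec)
        t = co.truth
        # regressing y_std on the planted mediator and x recovers b and c'
        X = np.column_stack([t["m_latent"] - t["z0"], t["x_std"], t["cov_std"], np.ones(500)])
        coef, *_ = np.linalg.lstsq(X, t["y_std"], rcond=None)
        assert coef[0] == pytest.approx(spec.b_true, abs=0.08)
        assert coef[1] == pytest.approx(spec.c_prime_true, abs=0.08)
        # caps column is the affine image of y_std
        np.testing.assert_allclose(
            co.behavior["caps"], np.round(25.27 + 11.0 * t["y_std"], 2), atol=1e-9
        )

    def test_implied_total_correlation_matches_defaults(self):
        # default c' was chosen so corr(x, y) = c' + a b = -0.81
        spec = CohortSpec(n_subjects=4000, rng_seed=41)
        co = gen_cohort(spec)
        r = np.corrcoef(co.truth["x_std"], co.truth["y_std"])[0, 1]
        assert r == pytest.approx(spec.c_prime_true + spec.a_true * spec.b_true, abs=0.05)


def test_paths_dataset_marginals():
    x, m, y, cov = gen_paths_dataset(5000, 0.65, 0.45, 0.3074, n_covariates=0, rng_seed=1)
    assert np.corrcoef(x, m)[0, 1] == pytest.approx(0.65, abs=0.03)
    assert np.corrcoef(m, y)[0, 1] == pytest.approx(0.65, abs=0.03)
    assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.60, abs=0.03)
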