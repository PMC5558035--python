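import numpy as np
import pytest
import scipy.stats as sps

from connfrag.community import (
    affiliation_index,
    consensus_affiliation,
    detect_communities,
)
from connfrag.io import Connectome
from connfrag.simulate import (
    SyntheticConfig,
    apply_lesion,
    generate_behavior,
    generate_cohort,
    generate_damage_profile,
    generate_hemisphere,
    generate_planted_pair_cohort,
    make_parcellation,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"w_in": 0.5, "w_out": 0.6},
            {"n_regions_per_hemisphere": 6, "n_modules_healthy": 4},
            {"lesion_extent_range": (0.5, 0.2)},
            {"damage_severity_range": (-0.1, 0.5)},
            {"behavior_noise_sd": -1.0},
            {"complete_destruction_prob": 1.5},
            {"fi_n_runs": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)


class TestGenerateHemisphere:
    def test_deterministic_given_seed(self):
        cfg = SyntheticConfig()
        c1, t1 = generate_hemisphere(cfg, rng=np.random.default_rng(1))
        c2, t2 = generate_hemisphere(cfg, rng=np.random.default_rng(1))
        np.testing.assert_array_equal(c1.weights, c2.weights)
        np.testing.assert_array_equal(t1.labels, t2.labels)

    def test_output_satisfies_connectome_invariants(self):
        cfg = SyntheticConfig()
        c, truth = generate_hemisphere(cfg, rng=0)
        w = c.weights
        assert w.shape == (57, 57)
        np.testing.assert_array_equal(w, w.T)
        assert (np.diag(w) == 0).all()
        assert (w >= 0).all()
        assert truth.n_modules == 4

    def test_disconnected_blocks_recovered_every_run(self):
        """With w_out = 0 the planted blocks are disconnected components:
        the unique optimum, so every stochastic run recovers them."""
        cfg = SyntheticConfig(
            n_regions_per_hemisphere=24,
            w_out=0.0,
            density_within=0.9,
            rich_club_size=0,
        )
        c, truth = generate_hemisphere(cfg, rng=5)
        rng = np.random.default_rng(6)
        for _ in range(20):
            p = detect_communities(c, rng=rng)
            np.testing.assert_array_equal(p.labels, truth.labels)

    def test_within_block_weight_sampling_distribution(self):
        """Mean within-block weight over many draws sits within 3 SE of
        w_in (truncation at 0 shifts it far less than the SE band)."""
        cfg = SyntheticConfig(
            n_regions_per_hemisphere=12,
            n_modules_healthy=2,
            w_in=1.0,
            w_out=0.3,
            weight_noise_cv=0.4,
            density_within=1.0,
            density_between=1.0,
            rich_club_size=0,
        )
        rng = np.random.default_rng(7)
        vals = []
        truth = None
        for _ in range(40):
            c, truth = generate_hemisphere(cfg, rng=rng)
            same = truth.labels[:, None] == truth.labels[None, :]
            iu = np.triu_indices(12, k=1)
            vals.extend(c.weights[iu][same[iu]])
        vals = np.asarray(vals)
        assert len(vals) >= 1000
        se = cfg.w_in * cfg.weight_noise_cv / np.sqrt(len(vals))
        assert abs(vals.mean() - cfg.w_in) < 3 * se + 0.01


class TestDamageProfile:
    def test_zero_extent_means_no_damage(self):
        cfg = SyntheticConfig(lesion_extent_range=(0.0, 0.0))
        assert generate_damage_profile(cfg, rng=0) == {}

    def test_full_extent_full_severity(self):
        cfg = SyntheticConfig(
            lesion_extent_range=(1.0, 1.0),
            damage_severity_range=(1.0, 1.0),
            complete_destruction_prob=0.0,
        )
        dmg = generate_damage_profile(cfg, rng=1)
        assert len(dmg) == 57
        assert all(v == 1.0 for v in dmg.values())

    def test_damaged_window_is_contiguous(self):
        cfg = SyntheticConfig()
        rng = np.random.default_rng(2)
        ids = tuple(f"L{i + 1:03d}" for i in range(57))
        for _ in range(50):
            dmg = generate_damage_profile(cfg, rng)
            idx = sorted(ids.index(r) for r in dmg)
            if idx:
                assert idx == list(range(idx[0], idx[0] + len(idx)))

    def test_expected_damaged_count_matches_extent_midpoint(self):
        cfg = SyntheticConfig(lesion_extent_range=(0.2, 0.6))
        rng = np.random.default_rng(3)
        counts = [len(generate_damage_profile(cfg, rng)) for _ in range(1000)]
        expected = 0.4 * 57
        # extent is U(0.2, 0.6): sd of the count ~ 57 * 0.4/sqrt(12)
        se = 57 * 0.4 / np.sqrt(12) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se + 0.5


class TestApplyLesion:
    def test_no_damage_is_identity(self, two_cliques):
        out = apply_lesion(two_cliques, {})
        np.testing.assert_array_equal(out.weights, two_cliques.weights)

    def test_full_damage_isolates_region(self, two_cliques):
        out = apply_lesion(two_cliques, {"a": 1.0})
        assert out.weights[0].sum() == 0.0
        assert out.weights[:, 0].sum() == 0.0
        # remaining clique untouched
        np.testing.assert_array_equal(out.weights[4:, 4:], two_cliques.weights[4:, 4:])

    def test_attenuation_is_monotone_and_multiplicative(self, two_cliques):
        out = apply_lesion(two_cliques, {"a": 0.5, "b": 0.2})
        assert (out.weights <= two_cliques.weights + 1e-15).all()
        assert out.weights[0, 1] == pytest.approx(1.0 * 0.5 * 0.8)
        np.testing.assert_array_equal(out.weights, out.weights.T)

    def test_out_of_range_damage_rejected(self, two_cliques):
        with pytest.raises(ValueError):
            apply_lesion(two_cliques, {"a": 1.2})


class TestGenerateBehavior:
    def test_no_noise_no_effect_is_constant(self):
        cfg = SyntheticConfig(
            behavior_beta_fi=0.0, behavior_noise_sd=0.0, behavior_beta0=80.0
        )
        df = generate_behavior(np.zeros(10), cfg, rng=0)
        assert (df["wab_aq"] == 80.0).all()

    def test_scores_clipped_to_scale(self):
        cfg = SyntheticConfig(
            behavior_beta0=120.0, behavior_beta_fi=0.0, behavior_noise_sd=0.0
        )
        df = generate_behavior(np.zeros(5), cfg, rng=0)
        assert (df["wab_aq"] == 100.0).all()

    def test_score_fi_correlation_matches_attenuation_formula(self):
        """With standardized FI, r(score, fi) = beta / sqrt(beta^2 + sd^2)
        when no clipping occurs (beta0 centred mid-scale)."""
        cfg = SyntheticConfig(
            behavior_beta0=50.0, behavior_beta_fi=-10.0, behavior_noise_sd=10.0
        )
        rng = np.random.default_rng(4)
        fi_z = rng.normal(0, 1, 1000)
        df = generate_behavior(fi_z, cfg, rng=rng)
        expected = -10.0 / np.sqrt(10.0**2 + 10.0**2)
        got = np.corrcoef(df["wab_aq"], fi_z)[0, 1]
        assert got == pytest.approx(expected, abs=0.1)

    def test_subscores_positively_intercorrelated(self):
        cfg = SyntheticConfig(behavior_beta0=50.0, behavior_beta_fi=0.0)
        rng = np.random.default_rng(5)
        df = generate_behavior(np.zeros(500), cfg, rng=rng)
        corr = df[["comprehension", "fluency", "naming", "repetition"]].corr()
        off_diag = corr.to_numpy()[~np.eye(4, dtype=bool)]
        assert (off_diag > 0.5).all()


class TestGenerateCohort:
    def test_deterministic(self, small_cfg, small_cohort):
        again = generate_cohort(small_cfg)
        for a, b in zip(small_cohort.subjects, again.subjects):
            assert a.wab_aq == b.wab_aq
            np.testing.assert_array_equal(a.connectome.weights, b.connectome.weights)

    def test_structure_and_invariants(self, small_cfg, small_cohort):
        assert len(small_cohort) == small_cfg.n_subjects
        parc = small_cohort.parcellation
        n = small_cfg.n_regions_per_hemisphere
        assert len(parc) == 2 * n
        for s in small_cohort.subjects:
            # right hemisphere never damaged
            right_ids = {r.region_id for r in parc.regions if r.hemisphere == "R"}
            assert not right_ids & set(s.damage)
            assert 0 <= s.grey_damage_total <= 1
            assert 0 <= s.white_damage_total <= 1
        gt = small_cohort.ground_truth
        assert gt["network_ground_truth"] is True
        assert set(gt["subjects"]) == set(small_cohort.subject_ids)

    def test_zero_lesion_cohort_fi_centred_and_symmetric(self):
        """With no lesions the hemispheres are exchangeable: FI median near
        zero and C_L, C_R indistinguishable (two-sample KS over pooled
        seeds)."""
        cls, crs, fis = [], [], []
        for seed in (0, 1, 2):
            cfg = SyntheticConfig(
                n_subjects=30, lesion_extent_range=(0.0, 0.0), seed=seed
            )
            cohort = generate_cohort(cfg, network_ground_truth=True)
            for g in cohort.ground_truth["subjects"].values():
                cls.append(g["c_left"])
                crs.append(g["c_right"])
                fis.append(g["fi"])
        assert abs(np.median(fis)) < 0.05
        assert sps.ks_2samp(cls, crs).pvalue > 0.01

    def test_network_ground_truth_skipped_when_not_needed(self):
        cfg = SyntheticConfig(n_subjects=3, behavior_beta_fi=0.0, seed=1)
        cohort = generate_cohort(cfg)
        assert cohort.ground_truth["network_ground_truth"] is False
        assert "fi" not in next(iter(cohort.ground_truth["subjects"].values()))


class TestPlantedPairCohort:
    def test_dyad_structure_and_ground_truth(self):
        cfg = SyntheticConfig(
            n_subjects=20, n_regions_per_hemisphere=14, n_modules_healthy=3,
            rich_club_size=0, seed=9,
        )
        cohort = generate_planted_pair_cohort(cfg, pair_effect=20.0, noise_sd=5.0)
        i, j = cohort.ground_truth["planted_pair"]
        parc = cohort.parcellation
        ii, jj = parc.index(i), parc.index(j)
        co = cohort.ground_truth["co_assigned"]
        for s in cohort.subjects:
            w = s.connectome.weights
            pair_w = w[ii, jj]
            if co[s.subject_id]:
                assert pair_w > 0
            else:
                assert pair_w == 0.0
                assert w[ii].sum() == 0.0  # severed dyad members are isolated
        # co-assigned subjects score higher on average
        scores_in = [s.wab_aq for s in cohort.subjects if co[s.subject_id]]
        scores_out = [s.wab_aq for s in cohort.subjects if not co[s.subject_id]]
        assert np.mean(scores_in) > np.mean(scores_out)


class TestLesionMonotonicity:
    def test_progressive_destruction_raises_q_and_lowers_c(self):
        """Destroying progressively more of one planted module's members
        (the generator's lesion mechanism at full severity) never lowers
        the median best-Q and strictly lowers the median affiliation
        index, over 20 seeds."""
        cfg = SyntheticConfig()
        fracs = [0.0, 0.25, 0.5, 0.75, 1.0]
        q_med, c_med = [], []
        qs = {f: [] for f in fracs}
        cs = {f: [] for f in fracs}
        for s in range(20):
            c, truth = generate_hemisphere(cfg, rng=np.random.default_rng([71, s]))
            members = [
                c.region_ids[i] for i in np.flatnonzero(truth.labels == 0)
            ]
            for f in fracs:
                k = int(round(f * len(members)))
                lesioned = apply_lesion(c, {rid: 1.0 for rid in members[:k]})
                aff = consensus_affiliation(
                    lesioned, n_runs=16, rng=np.random.default_rng([72, s])
                )
                qs[f].append(aff.Q_best)
                cs[f].append(affiliation_index(aff))
        q_med = [np.median(qs[f]) for f in fracs]
        c_med = [np.median(cs[f]) for f in fracs]
        tol = 5e-3  # consensus Monte-Carlo noise on a median of 20
        assert all(b >= a - tol for a, b in zip(q_med, q_med[1:]))
        assert all(b < a for a, b in zip(c_med, c_med[1:]))
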