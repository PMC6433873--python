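"""Temporal ranking, MI estimator, subset distances and sample PCA."""

import numpy as np
import pandas as pd
import pytest

from abatime.core_io import PipelineConfig
from abatime.dynamics import (
    association_profile,
    mutual_information,
    profile_distance,
    sample_pca,
    select_contributing_genes,
    subset_distance_curve,
    temporal_response_rank,
)
from abatime.synthdata import (
    SimConfig,
    generate_timecourse,
    planted_dynamics_config,
    responsive_genes,
)
from helpers import build_matrix, random_matrix


class TestTemporalRank:
    def test_flat_profile_ranks_last(self):
        tps = (30, 60, 180)
        profiles = np.array([
            [8.0, 8.0, 8.0],   # flat → variance 0 → last
            [8.0, 10.0, 8.0],
            [8.0, 8.0, 10.0],
        ])
        groups = {}
        for cond in ("control", "treated"):
            for j, tp in enumerate(tps):
                col = profiles[:, j] if cond == "treated" else np.full(3, 8.0)
                groups[(cond, tp)] = np.column_stack([col] * 3)
        m = build_matrix(groups, gene_ids=["flat", "mid", "late"])
        ranked = temporal_response_rank(m)
        assert ranked[-1] == "flat"

    def test_late_response_outranks_flat_sustained(self):
        # noise-free: late_up profile (0,0,2) has temporal variance, the
        # sustained (2,2,2) profile is flat after stimulation → ranks below
        tps = (30, 60, 180)
        groups = {}
        treated = {"sustained": (10, 10, 10), "late": (8, 8, 10)}
        for cond in ("control", "treated"):
            for j, tp in enumerate(tps):
                if cond == "treated":
                    col = np.array([treated["sustained"][j], treated["late"][j]],
                                   dtype=float)
                else:
                    col = np.full(2, 8.0)
                groups[(cond, tp)] = np.column_stack([col] * 3)
        m = build_matrix(groups, gene_ids=["sustained", "late"])
        assert temporal_response_rank(m) == ["late", "sustained"]
        # the treated-minus-control variant sees both
        var_rank = temporal_response_rank(m, contrast_control=True)
        assert set(var_rank) == {"late", "sustained"}

    def test_planted_responders_rank_in_top_decile(self):
        matrix, truth = generate_timecourse(planted_dynamics_config(seed=2))
        ranked = temporal_response_rank(matrix)
        resp = responsive_genes(truth)
        positions = [i for i, g in enumerate(ranked) if g in resp]
        assert np.median(positions) < 0.1 * len(ranked)


class TestMutualInformation:
    def test_identity_equals_marginal_entropy(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1000)  # 1000 divisible by 10 bins
        mi = mutual_information(x, x, bins=10)
        assert mi == pytest.approx(np.log(10), rel=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=500), rng.normal(size=500)
        assert mutual_information(x, y, 8) == pytest.approx(
            mutual_information(y, x, 8), abs=1e-12
        )

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=10000), rng.normal(size=10000)
        # plug-in bias ≈ (bins−1)²/(2n) ≈ 0.004 ⇒ well below 0.02
        assert mutual_information(x, y, 10) < 0.02

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=400), rng.normal(size=400)
        base = mutual_information(x, y, 8)
        assert mutual_information(np.exp(x), y ** 3, 8) == pytest.approx(
            base, abs=1e-12
        )

    def test_constant_vector_degenerate(self):
        with pytest.warns(UserWarning, match="constant"):
            assert mutual_information(np.ones(100), np.arange(100.0), 5) == 0.0

    def test_non_negative(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x, y = rng.normal(size=64), rng.normal(size=64)
            assert mutual_information(x, y, 8) >= 0.0


class TestAssociationProfile:
    def test_whole_set_profile_is_reference(self, default_sim):
        matrix, _ = default_sim
        ref = association_profile(matrix, matrix.gene_ids, bins=12)
        again = association_profile(matrix, list(matrix.gene_ids), bins=12)
        np.testing.assert_array_equal(ref.pc_values, again.pc_values)
        np.testing.assert_array_equal(ref.mi_values, again.mi_values)
        assert profile_distance(again, ref) == 0.0

    def test_order_invariance_within_subset(self, default_sim):
        matrix, _ = default_sim
        subset = list(matrix.gene_ids[:100])
        a = association_profile(matrix, subset, bins=8)
        b = association_profile(matrix, subset[::-1], bins=8)
        np.testing.assert_array_equal(a.pc_values, b.pc_values)
        np.testing.assert_array_equal(a.mi_values, b.mi_values)

    def test_identical_groups_perfect_association(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(200, 3))
        groups = {("control", 30): vals, ("control", 60): vals,
                  ("treated", 30): rng.normal(size=(200, 3)),
                  ("treated", 60): rng.normal(size=(200, 3))}
        m = build_matrix(groups)
        prof = association_profile(m, m.gene_ids, bins=10)
        idx = prof.pair_labels.index(("control:30", "control:60"))
        assert prof.pc_values[idx] == pytest.approx(1.0)
        assert prof.mi_values[idx] == pytest.approx(np.log(10), rel=1e-9)

    def test_pc_matches_direct_formula(self):
        rng = np.random.default_rng(6)
        m = random_matrix(rng, 150, tps=(30, 60), reps=2)
        prof = association_profile(m, m.gene_ids, bins=8)
        means = m.group_means()
        for (a, b), pc in zip(prof.pair_labels, prof.pc_values):
            x, y = means[a].to_numpy(), means[b].to_numpy()
            xc, yc = x - x.mean(), y - y.mean()
            expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            assert pc == pytest.approx(expected, abs=1e-12)

    def test_subset_smaller_than_bins_rejected(self, default_sim):
        matrix, _ = default_sim
        with pytest.raises(ValueError, match="bins"):
            association_profile(matrix, matrix.gene_ids[:5], bins=10)


class TestDistanceCurve:
    def test_whole_transcriptome_window_distance_zero(self):
        matrix, _ = generate_timecourse(
            planted_dynamics_config(seed=3, n_genes=200)
        )
        cfg = PipelineConfig(subset_min=50, subset_max=500)
        curve = subset_distance_curve(matrix, cfg, sizes=[200])
        assert len(curve) == 1
        assert curve["distance"].iloc[0] == 0.0

    def test_deterministic_for_fixed_input(self):
        matrix, _ = generate_timecourse(
            planted_dynamics_config(seed=4, n_genes=300)
        )
        cfg = PipelineConfig()
        c1 = subset_distance_curve(matrix, cfg, sizes=[50, 100])
        c2 = subset_distance_curve(matrix, cfg, sizes=[50, 100])
        pd.testing.assert_frame_equal(c1, c2)

    def test_responder_windows_closer_to_global_change(self):
        # when responders dominate the concerted change, null-only windows
        # sit farther from the whole-transcriptome profile (5 seeds)
        for seed in range(5):
            matrix, truth = generate_timecourse(planted_dynamics_config(seed))
            ranked = temporal_response_rank(matrix)
            ref = association_profile(matrix, matrix.gene_ids, bins=10)
            d_resp = profile_distance(
                association_profile(matrix, ranked[:100], bins=10), ref
            )
            d_null = np.mean([
                profile_distance(
                    association_profile(matrix, ranked[s:s + 100], bins=10), ref
                )
                for s in (300, 500, 700, 900)
            ])
            assert d_resp < d_null


class TestSelection:
    def test_boundary_quantile_yields_empty(self):
        empty_curve = pd.DataFrame(
            columns=["start_rank", "size", "distance", "fitted_distance"]
        )
        sel = select_contributing_genes(
            empty_curve, [f"g{i}" for i in range(100)], rank_quantile=0.999
        )
        assert sel == set()

    def test_monotone_in_quantiles(self):
        matrix, _ = generate_timecourse(
            planted_dynamics_config(seed=5, n_genes=400)
        )
        ranked = temporal_response_rank(matrix)
        curve = subset_distance_curve(matrix, PipelineConfig(), sizes=[50, 100])
        tight = select_contributing_genes(curve, ranked, 0.95, 0.1)
        loose = select_contributing_genes(curve, ranked, 0.85, 0.4)
        assert tight <= loose

    def test_recovery_of_planted_responders(self):
        # > 80% of planted responders recovered at default quantiles
        for seed in range(5):
            matrix, truth = generate_timecourse(planted_dynamics_config(seed))
            ranked = temporal_response_rank(matrix)
            curve = subset_distance_curve(matrix, PipelineConfig())
            selected = select_contributing_genes(curve, ranked)
            resp = responsive_genes(truth)
            recovery = len(selected & resp) / len(resp)
            assert recovery > 0.8


class TestSamplePca:
    def test_duplicated_samples_have_identical_scores(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(100, 2))
        m = build_matrix({("control", 30): vals, ("treated", 30): vals})
        res = sample_pca(m)
        s = res.scores
        np.testing.assert_allclose(
            s.loc["control_t30_r1"], s.loc["treated_t30_r1"], atol=1e-9
        )

    def test_variance_fractions_non_increasing_and_bounded(self, default_sim):
        matrix, _ = default_sim
        res = sample_pca(matrix)
        evr = res.explained_variance_ratio
        assert (np.diff(evr) <= 1e-12).all()
        assert (evr >= 0).all() and evr.sum() <= 1 + 1e-9

    def test_reconstruction_with_all_components(self):
        rng = np.random.default_rng(8)
        m = random_matrix(rng, 60, tps=(30, 60), reps=2)
        X = m.values.to_numpy().T
        Xc = X - X.mean(axis=0)
        res = sample_pca(m, n_components=X.shape[0] - 1)
        from sklearn.decomposition import PCA

        pca = PCA(n_components=X.shape[0] - 1, svd_solver="full").fit(Xc)
        recon = res.scores.to_numpy() @ pca.components_
        np.testing.assert_allclose(recon, Xc, atol=1e-8)

    def test_first_component_separates_conditions(self):
        from sklearn.metrics import silhouette_score

        for seed in range(20):
            matrix, _ = generate_timecourse(
                SimConfig(n_genes=400, seed=seed)
            )
            res = sample_pca(matrix)
            labels = [s.condition for s in matrix.samples]
            score = silhouette_score(
                res.scores[["PC1"]].to_numpy(), labels
            )
            assert score > 0
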