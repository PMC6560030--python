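"""Pairwise SVM training, decision values, AUC generalization, exclusion."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from futurestate.decode import (PAIR_SCHEME, crossphase_performance,
                                decision_values, exclusion_check,
                                generalization_auc, train_pairwise)
from futurestate.simulate import SimTruth, VoxelPatternSet, simulate_patterns


def _localizer_set(truth, n_per_cat=12, noise=0.0, seed=0, flip=False):
    rng = np.random.default_rng(seed)
    rows, X = [], []
    sign = -1.0 if flip else 1.0
    for mb in (1, 2, 3):
        for cat in ("face", "scene", "object"):
            for _ in range(n_per_cat):
                rows.append({"miniblock": mb, "category": cat})
                X.append(sign * truth.category_templates[cat]
                         + rng.normal(0, noise, truth.n_voxels))
    return VoxelPatternSet(np.array(X), pd.DataFrame(rows))


def _learning_set(truth, cats, noise=0.0, seed=0, state="S1"):
    rng = np.random.default_rng(seed)
    X = [truth.category_templates[c] + rng.normal(0, noise, truth.n_voxels)
         for c in cats]
    ev = pd.DataFrame({"state": state, "onscreen_category": cats})
    return VoxelPatternSet(np.array(X), ev)


class TestTraining:
    def test_pair_scheme_fixed(self, truth):
        clfs = train_pairwise(_localizer_set(truth))
        assert {c: clfs[c].contrast_category for c in clfs} == PAIR_SCHEME

    def test_orthogonal_noiseless_templates_train_perfectly(self, truth):
        clfs = train_pairwise(_localizer_set(truth))
        for cat, clf in clfs.items():
            own = clf.margins(truth.category_templates[cat][None, :])
            other = clf.margins(truth.category_templates[clf.contrast_category][None, :])
            assert own > 0 > other

    def test_imbalanced_miniblock_balanced_by_discard(self, truth):
        loc = _localizer_set(truth, n_per_cat=12)
        drop = loc.events[(loc.events.miniblock == 1)
                          & (loc.events.category == "scene")].index[:3]
        keep = ~loc.events.index.isin(drop)
        loc = VoxelPatternSet(loc.betas[keep], loc.events[keep].reset_index(drop=True))
        clfs = train_pairwise(loc, seed=0)
        # face-vs-scene training: mini-block 1 now has 12 faces vs 9 scenes,
        # so 9 faces are kept there; 12 in the other two mini-blocks
        assert clfs["face"].n_train_per_class == 9 + 12 + 12

    def test_missing_class_rejected(self, truth):
        loc = _localizer_set(truth)
        only_faces = loc.events["category"] == "face"
        loc = VoxelPatternSet(loc.betas[only_faces.to_numpy()],
                              loc.events[only_faces].reset_index(drop=True))
        with pytest.raises(ValueError):
            train_pairwise(loc)

    def test_noise_only_localizer_decodes_at_chance(self, truth):
        # Monte-Carlo: train on pure noise, test generalization AUC on
        # fresh noise patterns; mean must sit at chance
        aucs = []
        for s in range(60):
            rng = np.random.default_rng(s)
            loc = VoxelPatternSet(
                rng.normal(size=(72, truth.n_voxels)),
                pd.DataFrame({"miniblock": np.repeat([1, 2, 3], 24),
                              "category": list("fso" * 24)}).assign(
                    category=lambda d: d["category"].map(
                        {"f": "face", "s": "scene", "o": "object"})))
            clfs = train_pairwise(loc, seed=s)
            test = VoxelPatternSet(
                rng.normal(size=(30, truth.n_voxels)),
                pd.DataFrame({"state": "S1",
                              "onscreen_category": ["face", "scene", "object"] * 10}))
            dv = decision_values(clfs, test)
            res = generalization_auc(dv, clfs, scale=False)
            aucs.extend(v for v in res.values() if np.isfinite(v))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)


class TestDecisionValues:
    def test_boundary_pattern_maps_to_half(self, truth):
        clfs = train_pairwise(_localizer_set(truth))
        clf = clfs["face"]
        # construct a pattern with margin exactly zero
        w = clf.weights
        x = -clf.intercept * w / (w @ w)
        assert clf.decision_values(x[None, :])[0] == pytest.approx(0.5, abs=1e-10)

    def test_value_increases_with_target_amplitude(self, truth):
        clfs = train_pairwise(_localizer_set(truth))
        clf = clfs["scene"]
        amps = np.linspace(0, 2, 9)
        pats = np.array([a * truth.category_templates["scene"] for a in amps])
        vals = clf.decision_values(pats)
        assert np.all(np.diff(vals) > 0)

    def test_rank_order_identical_for_margin_and_value(self, truth, pattern_sets):
        clfs = train_pairwise(pattern_sets[0])
        dv = decision_values(clfs, pattern_sets[1])
        for cat in clfs:
            rho = spearmanr(dv[f"margin_{cat}"], dv[f"dv_{cat}"]).statistic
            assert rho == pytest.approx(1.0)

    def test_values_bounded(self, pattern_sets):
        clfs = train_pairwise(pattern_sets[0])
        dv = decision_values(clfs, pattern_sets[1])
        for cat in clfs:
            assert dv[f"dv_{cat}"].between(0, 1).all()

    def test_dimension_mismatch_rejected(self, truth, pattern_sets):
        clfs = train_pairwise(pattern_sets[0])
        bad = VoxelPatternSet(np.zeros((4, truth.n_voxels + 1)),
                              pd.DataFrame({"state": ["S1"] * 4,
                                            "onscreen_category": ["face"] * 4}))
        with pytest.raises(ValueError):
            decision_values(clfs, bad)

    def test_rotation_invariance_of_decision_values(self, truth):
        # rotating voxel space consistently for training and test leaves
        # margins (hence decision values) unchanged
        rng = np.random.default_rng(2)
        Q, _ = np.linalg.qr(rng.standard_normal((truth.n_voxels, truth.n_voxels)))
        loc = _localizer_set(truth, noise=0.3, seed=5)
        test = _learning_set(truth, ["face", "scene", "object"] * 4,
                             noise=0.3, seed=6)
        clfs = train_pairwise(loc, seed=1)
        dv = decision_values(clfs, test)
        loc_r = VoxelPatternSet(loc.betas @ Q.T, loc.events)
        test_r = VoxelPatternSet(test.betas @ Q.T, test.events)
        clfs_r = train_pairwise(loc_r, seed=1)
        dv_r = decision_values(clfs_r, test_r)
        for cat in clfs:
            np.testing.assert_allclose(dv[f"dv_{cat}"], dv_r[f"dv_{cat}"],
                                       atol=1e-6)


class TestGeneralizationAuc:
    def test_perfect_separation_scores_fifty(self, truth):
        clfs = train_pairwise(_localizer_set(truth))
        test = _learning_set(truth, ["face", "scene"] * 8)
        dv = decision_values(clfs, test)
        res = generalization_auc(dv, clfs)
        assert res["face"] == pytest.approx(50.0)
        assert res["scene"] == pytest.approx(50.0)

    def test_label_permutation_centers_on_zero(self, truth):
        clfs = train_pairwise(_localizer_set(truth))
        test = _learning_set(truth, ["face", "scene"] * 10, noise=1.0, seed=3)
        dv = decision_values(clfs, test)
        rng = np.random.default_rng(4)
        perm_means = []
        for _ in range(1000):
            shuffled = dv.copy()
            shuffled["onscreen_category"] = rng.permutation(
                dv["onscreen_category"].to_numpy())
            perm_means.append(generalization_auc(shuffled, clfs)["face"])
        assert np.mean(perm_means) == pytest.approx(0.0, abs=1.0)

    def test_single_class_flagged_nan(self, truth):
        clfs = train_pairwise(_localizer_set(truth))
        test = _learning_set(truth, ["face"] * 6)
        dv = decision_values(clfs, test)
        assert np.isnan(generalization_auc(dv, clfs)["face"])

    def test_antisymmetric_under_pair_swap(self, truth):
        # face-vs-scene AUC-chance equals the negative of scene's when
        # computed on the same two-class events with swapped roles
        clfs = train_pairwise(_localizer_set(truth, noise=0.5, seed=8), seed=8)
        test = _learning_set(truth, ["face", "scene"] * 10, noise=1.2, seed=9)
        dv = decision_values(clfs, test)
        from sklearn.metrics import roc_auc_score
        rel = dv[dv["onscreen_category"].isin(["face", "scene"])]
        y = (rel["onscreen_category"] == "face").astype(int)
        a1 = roc_auc_score(y, rel["dv_face"])
        a2 = roc_auc_score(1 - y, rel["dv_face"])   # roles swapped
        assert (a1 - 0.5) == pytest.approx(-(a2 - 0.5))


class TestExclusion:
    def test_strong_signal_all_valid(self, participant_result):
        assert all(participant_result.validity.values())
        assert participant_result.included

    def test_sign_flipped_patterns_excluded(self, truth):
        clfs = train_pairwise(_localizer_set(truth, noise=0.3, seed=1), seed=1)
        # anti-learned world: learning patterns carry the *negated* templates
        rng = np.random.default_rng(2)
        cats = ["face", "scene", "object"] * 8
        X = np.array([-truth.category_templates[c]
                      + rng.normal(0, 0.3, truth.n_voxels) for c in cats])
        test = VoxelPatternSet(X, pd.DataFrame({"state": "S1",
                                                "onscreen_category": cats}))
        dv = decision_values(clfs, test)
        valid, included = exclusion_check(crossphase_performance(dv, clfs))
        assert not any(valid.values())
        assert not included

    def test_noise_cohort_excluded_near_half_per_category(self, truth):
        # at chance the generalization coefficient is positive about half
        # the time, so each category is flagged invalid at ~50%
        flags = {c: 0 for c in PAIR_SCHEME}
        n = 100
        for s in range(n):
            rng = np.random.default_rng(1000 + s)
            loc = _localizer_set(truth, n_per_cat=8, noise=3.0, seed=s)
            clfs = train_pairwise(loc, seed=s)
            cats = ["face", "scene", "object"] * 8
            test = VoxelPatternSet(rng.normal(size=(24, truth.n_voxels)),
                                   pd.DataFrame({"state": "S1",
                                                 "onscreen_category": cats}))
            dv = decision_values(clfs, test)
            valid, _ = exclusion_check(crossphase_performance(dv, clfs))
            for c, v in valid.items():
                flags[c] += (not v)
        for c, k in flags.items():
            assert 30 <= k <= 70    # binomial(100, .5) within ~4 sd
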