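"""Synthetic-data generators: determinism, planted structure, trajectories."""

import numpy as np
import pytest
from scipy import stats as sps

import semcoh as sc


class TestTopicsAndCorpus:
    def test_disjoint_topics_share_no_tokens(self):
        spec = sc.TopicModelSpec(n_topics=2, vocab_per_topic=30,
                                 shared_vocab=0, seed=1)
        topics = sc.build_topics(spec)
        docs, doc_topics = sc.gen_corpus(topics, n_docs=10, doc_length=50,
                                         seed=2)
        for i, di in enumerate(docs):
            for j, dj in enumerate(docs):
                if doc_topics[i] != doc_topics[j]:
                    assert not set(di) & set(dj)

    def test_same_seed_reproduces_corpus(self, small_topics):
        c1, t1 = sc.gen_corpus(small_topics, n_docs=20, doc_length=40, seed=9)
        c2, t2 = sc.gen_corpus(small_topics, n_docs=20, doc_length=40, seed=9)
        assert c1 == c2 and t1 == t2

    def test_topic_distributions_are_proper(self, study_topics):
        sums = study_topics.topic_dists.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        assert np.all(study_topics.topic_dists >= 0)

    def test_token_frequencies_match_topic_distribution(self):
        spec = sc.TopicModelSpec(n_topics=3, vocab_per_topic=40,
                                 shared_vocab=0,
                                 topic_word_concentration=5.0, seed=7)
        topics = sc.build_topics(spec)
        rng = np.random.default_rng(0)
        n = 10_000
        tokens = topics.sample_tokens(0, n, rng)
        index = {w: i for i, w in enumerate(topics.vocabulary)}
        counts = np.zeros(len(topics.vocabulary))
        for t in tokens:
            counts[index[t]] += 1
        p = topics.topic_dists[0]
        support = p > 0
        # merge low-expectation cells to keep the chi-square valid
        expected = p[support] * n
        observed = counts[support]
        keep = expected >= 5
        if (~keep).any():
            observed = np.append(observed[keep], observed[~keep].sum())
            expected = np.append(expected[keep], expected[~keep].sum())
        stat, pval = sps.chisquare(observed, expected)
        assert pval > 0.01


class TestDriftResponses:
    def test_zero_drift_constant_trajectory(self, study_topics):
        tokens, traj = sc.gen_response(
            sc.DriftSpec(prompt_topic=4, drift_prob=0.0, target_length=100,
                         seed=3),
            study_topics,
        )
        assert len(tokens) == 100
        assert set(traj) == {4}

    def test_same_seed_reproduces_response(self, study_topics):
        spec = sc.DriftSpec(prompt_topic=2, drift_prob=0.5,
                            switch_style="abrupt", target_length=80, seed=13)
        r1 = sc.gen_response(spec, study_topics)
        r2 = sc.gen_response(spec, study_topics)
        assert r1 == r2

    def test_full_abrupt_drift_reaches_uniform_occupancy(self, study_topics):
        """With drift probability 1 and uniform jumps the topic chain's
        stationary distribution is uniform: the long-run on-topic fraction
        approaches 1/n_topics."""
        spec = sc.DriftSpec(prompt_topic=0, drift_prob=1.0,
                            switch_style="abrupt", target_length=8000,
                            seed=21)
        _, traj = sc.gen_response(spec, study_topics)
        frac = np.mean(np.asarray(traj[20:]) == 0)
        assert frac == pytest.approx(1 / study_topics.n_topics, abs=0.03)

    def test_smooth_drift_moves_to_adjacent_topics(self, study_topics):
        spec = sc.DriftSpec(prompt_topic=5, drift_prob=1.0,
                            switch_style="smooth", target_length=400,
                            transition_len=40, seed=17)
        _, traj = sc.gen_response(spec, study_topics)
        steps = np.abs(np.diff(np.asarray(traj)))
        K = study_topics.n_topics
        assert set(steps) <= {0, 1, K - 1}  # ring-adjacent moves only

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            sc.DriftSpec(drift_prob=1.5)
        with pytest.raises(ValueError):
            sc.DriftSpec(switch_style="sideways")
        with pytest.raises(ValueError):
            sc.DriftSpec(target_length=0)


class TestNorms:
    def test_seed_repeatable(self):
        n1, _ = sc.gen_norms(50, seed=3)
        n2, _ = sc.gen_norms(50, seed=3)
        assert n1.equals(n2)

    def test_zero_noise_gives_rank_four(self):
        norms, truth = sc.gen_norms(300, noise_sd=0.0, seed=5)
        X = norms[["frequency", "concreteness", "aoa", "semantic_diversity",
                   "phonemic_length"]].to_numpy()
        Xc = X - X.mean(axis=0)
        assert np.linalg.matrix_rank(Xc, tol=1e-8) == 4

    def test_planted_correlation_structure(self):
        norms, truth = sc.gen_norms(4000, noise_sd=0.3, seed=11)
        L = np.asarray(truth["loadings"])
        # implied correlation between frequency and concreteness
        cov = L @ L.T + 0.3**2 * np.eye(5)
        implied = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
        observed = np.corrcoef(norms["frequency"],
                               norms["concreteness"])[0, 1]
        assert observed == pytest.approx(implied, abs=0.05)


class TestAccuracyTrials:
    def test_intercept_only_mean_accuracy(self):
        trials, _ = sc.gen_accuracy(
            effects={"intercept": 1.5}, sd_participant=0.0, sd_item=0.0,
            n_participants=20, n_items=60, seed=2,
        )
        expected = 1 / (1 + np.exp(-1.5))
        assert trials["correct"].mean() == pytest.approx(expected, abs=0.04)

    def test_seed_repeatable_and_balanced(self):
        t1, _ = sc.gen_accuracy(seed=4)
        t2, _ = sc.gen_accuracy(seed=4)
        assert t1.equals(t2)
        cells = t1.groupby(["task", "demand"])["item"].nunique()
        assert set(cells) == {15}  # 60 items over 4 cells

    def test_planted_group_effect_visible_marginally(self):
        trials, _ = sc.gen_accuracy(
            effects={"intercept": 0.0, "group": 2.0},
            sd_participant=0.2, sd_item=0.2, seed=6,
        )
        acc = trials.groupby("group")["correct"].mean()
        assert acc["patient"] - acc["control"] > 0.2


class TestLmmGenerator:
    def test_structure_and_determinism(self):
        d1 = sc.gen_lmm_data(seed=2)
        d2 = sc.gen_lmm_data(seed=2)
        assert d1.equals(d2)
        assert d1["participant"].nunique() == 19
        assert d1["prompt"].nunique() == 6
        assert set(d1["group"]) == {"control", "patient"}

    def test_planted_group_gap(self):
        gaps = []
        for seed in range(30):
            d = sc.gen_lmm_data(group_effect=-0.14, seed=seed)
            means = d.groupby("group")["value"].mean()
            gaps.append(means["patient"] - means["control"])
        assert np.mean(gaps) == pytest.approx(-0.14, abs=0.02)


class TestStudy:
    def test_study_is_deterministic_and_complete(self):
        s1 = sc.make_study(seed=5, n_controls=3, n_patients=2, n_prompts=2,
                           n_docs=40, doc_length=60)
        s2 = sc.make_study(seed=5, n_controls=3, n_patients=2, n_prompts=2,
                           n_docs=40, doc_length=60)
        assert s1.metadata.equals(s2.metadata)
        assert [t.raw_tokens for t in s1.transcripts] == \
            [t.raw_tokens for t in s2.transcripts]
        assert s1.norms.equals(s2.norms)
        assert s1.trials.equals(s2.trials)
        # ground truth emitted alongside the data
        assert set(s1.ground_truth) >= {"speakers", "accuracy", "norms"}

    def test_annotation_rates_near_targets(self):
        study = sc.make_study(seed=8, n_controls=4, n_patients=3,
                              n_prompts=3, n_docs=40, doc_length=60)
        from semcoh.transcripts import pooled_removed_fraction
        ctrl = [t for t in study.transcripts if t.group == "control"]
        pat = [t for t in study.transcripts if t.group == "patient"]
        assert float(pooled_removed_fraction(ctrl)) == pytest.approx(
            0.016, abs=0.006)
        assert float(pooled_removed_fraction(pat)) == pytest.approx(
            0.09, abs=0.02)
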