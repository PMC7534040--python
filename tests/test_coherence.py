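"""Moving-window coherence: windows, composites, GC, LC, aggregation."""

import numpy as np
import pytest

import semcoh as sc
from semcoh.pipeline import group_summary

# Per-patient global coherence values for a semantic-aphasia case series
# (used for exact aggregation arithmetic).
SA_GC = [0.46, 0.40, 0.34, 0.36, 0.19, 0.37, 0.33]


def brute_force_windows(tokens, space, w):
    """Independent oracle: recompute each window slice from scratch."""
    return [
        sc.passage_vector(space, tokens[p:p + w])
        for p in range(len(tokens) - w + 1)
    ]


class TestMakeWindows:
    def test_window_count(self, identity_space):
        tokens = ["apple"] * 25
        assert len(sc.make_windows(tokens, identity_space, w=20)) == 6

    def test_single_window_equals_whole_passage(self, identity_space):
        tokens = ["apple", "banana"] * 10
        ws = sc.make_windows(tokens, identity_space, w=20)
        assert len(ws) == 1
        np.testing.assert_allclose(
            ws.vectors[0].values,
            sc.passage_vector(identity_space, tokens).values,
        )

    def test_matches_brute_force_slices(self, study_topics, study_space):
        rng = np.random.default_rng(21)
        for _ in range(10):
            spec = sc.DriftSpec(
                prompt_topic=int(rng.integers(20)),
                drift_prob=float(rng.uniform(0, 1)),
                switch_style=("smooth", "abrupt")[int(rng.integers(2))],
                target_length=int(rng.integers(45, 150)),
                function_word_rate=0.3,
                seed=int(rng.integers(2**31)),
            )
            tokens, _ = sc.gen_response(spec, study_topics)
            ws = sc.make_windows(tokens, study_space, w=20)
            oracle = brute_force_windows(tokens, study_space, 20)
            assert len(ws) == len(oracle)
            for got, want in zip(ws.vectors, oracle):
                np.testing.assert_allclose(got.values, want.values,
                                           atol=1e-10)
                assert got.n_contributing_tokens == \
                    want.n_contributing_tokens

    def test_too_short_raises(self, identity_space):
        with pytest.raises(ValueError):
            sc.make_windows(["apple"] * 5, identity_space, w=20)


class TestComposite:
    def test_single_contributor_is_parallel(self, small_space):
        tokens = small_space.vocabulary[:30]
        comp = sc.build_composite([tokens], small_space)
        pv = sc.passage_vector(small_space, tokens)
        assert sc.cosine(pv, comp.values) == pytest.approx(1.0)
        assert comp.n_contributors == 1

    def test_order_invariant(self, small_space):
        responses = [small_space.vocabulary[i:i + 25] for i in (0, 30, 60)]
        c1 = sc.build_composite(responses, small_space)
        c2 = sc.build_composite(responses[::-1], small_space)
        np.testing.assert_allclose(c1.values, c2.values, atol=1e-12)

    def test_identical_multisets_parallel_to_either(self, small_space):
        a = small_space.vocabulary[:20]
        b = a[::-1]
        comp = sc.build_composite([a, b], small_space)
        assert sc.cosine(
            comp.values, sc.passage_vector(small_space, a).values
        ) == pytest.approx(1.0)

    def test_no_contributors_raises(self, small_space):
        with pytest.raises(ValueError, match="composite"):
            sc.build_composite([["zzz_not_a_word"]], small_space, "p0")


class TestGlobalLocalCoherence:
    def test_gc_one_when_parallel_to_composite(self, identity_space):
        tokens = ["apple"] * 30
        ws = sc.make_windows(tokens, identity_space, w=10)
        comp = sc.CompositeVector("p", identity_space.vector("apple"), 1)
        gc, trace = sc.global_coherence(ws, comp)
        assert gc == pytest.approx(1.0)
        assert len(trace) == 21

    def test_gc_zero_for_orthogonal_topic(self, identity_space):
        tokens = ["apple"] * 30
        ws = sc.make_windows(tokens, identity_space, w=10)
        comp = sc.CompositeVector("p", identity_space.vector("cherry"), 1)
        gc, _ = sc.global_coherence(ws, comp)
        assert gc == pytest.approx(0.0)

    def test_lc_one_for_homogeneous_text(self, identity_space):
        ws = sc.make_windows(["banana"] * 40, identity_space, w=20)
        lc, trace = sc.local_coherence(ws)
        assert lc == pytest.approx(1.0)
        assert len(trace) == 1

    def test_lc_zero_for_orthogonal_halves(self, identity_space):
        tokens = ["apple"] * 20 + ["cherry"] * 20
        ws = sc.make_windows(tokens, identity_space, w=20)
        lc, trace = sc.local_coherence(ws)
        # the first/last comparison pairs two disjoint pure-topic windows
        assert trace[0] == pytest.approx(0.0)
        assert trace[-1] == pytest.approx(0.0)

    def test_lc_disjoint_matches_brute_force(self, study_topics, study_space):
        tokens, _ = sc.gen_response(
            sc.DriftSpec(prompt_topic=3, drift_prob=0.5,
                         switch_style="abrupt", target_length=90, seed=77),
            study_topics,
        )
        ws = sc.make_windows(tokens, study_space, w=20)
        lc, trace = sc.local_coherence(ws, style="disjoint")
        oracle = brute_force_windows(tokens, study_space, 20)
        expected = [
            sc.cosine(oracle[p], oracle[p - 20])
            for p in range(20, len(oracle))
        ]
        np.testing.assert_allclose(trace, expected, atol=1e-10)
        assert lc == pytest.approx(np.mean(expected))

    def test_overlapping_style_nearly_one(self, study_topics, study_space):
        tokens, _ = sc.gen_response(
            sc.DriftSpec(prompt_topic=0, drift_prob=0.0, target_length=60,
                         seed=5),
            study_topics,
        )
        ws = sc.make_windows(tokens, study_space, w=20)
        lc_overlap, _ = sc.local_coherence(ws, style="overlapping")
        lc_disjoint, _ = sc.local_coherence(ws, style="disjoint")
        assert lc_overlap > lc_disjoint
        assert lc_overlap > 0.98  # 19/20 shared tokens

    def test_scale_invariance(self, small_topics, small_space):
        tokens, _ = sc.gen_response(
            sc.DriftSpec(prompt_topic=1, drift_prob=0.3, target_length=60,
                         seed=9),
            small_topics,
        )
        comp_tokens = [small_space.vocabulary[:30]]
        scaled = sc.SemanticSpace(
            vocabulary=list(small_space.vocabulary),
            vectors=small_space.vectors * 7.3,
            weighting=small_space.weighting,
            d=small_space.d,
        )
        r1 = sc.score_response(tokens, small_space,
                               sc.build_composite(comp_tokens, small_space))
        r2 = sc.score_response(tokens, scaled,
                               sc.build_composite(comp_tokens, scaled))
        assert r1.gc == pytest.approx(r2.gc, abs=1e-10)
        assert r1.lc == pytest.approx(r2.lc, abs=1e-10)

    def test_undefined_values_stay_missing(self, identity_space):
        # no in-vocabulary token anywhere: GC/LC undefined, not zero
        r = sc.score_response(["zzz"] * 40, identity_space,
                              sc.CompositeVector("p", np.ones(4), 1))
        assert r.gc is None
        assert r.lc is None
        assert r.n_windows_gc == 0


class TestAggregation:
    def test_participant_mean_single_response(self):
        r = sc.CoherenceResult("p1", "q1", 0.42, 0.3, 10, 5, 50)
        agg = sc.aggregate_participant([r])
        assert agg.loc["p1", "gc"] == pytest.approx(0.42)

    def test_case_series_group_mean_and_sd(self):
        results = [
            sc.CoherenceResult(f"SA{i+1}", "q", gc, None, 10, 0, 80)
            for i, gc in enumerate(SA_GC)
        ]
        agg = sc.aggregate_participant(results).reset_index()
        agg["group"] = "patient"
        summary = group_summary(agg[["group", "gc"]])
        assert round(float(summary["gc_mean"].iloc[0]), 2) == 0.35
        assert round(float(summary["gc_sd"].iloc[0]), 2) == 0.08

    def test_response_means_unweighted_over_prompts(self):
        results = [
            sc.CoherenceResult("p", "q1", 0.2, 0.1, 5, 2, 40),
            sc.CoherenceResult("p", "q2", 0.6, 0.5, 50, 30, 200),
        ]
        agg = sc.aggregate_participant(results)
        assert agg.loc["p", "gc"] == pytest.approx(0.4)
        assert agg.loc["p", "lc"] == pytest.approx(0.3)
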