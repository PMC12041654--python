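"""Shared-ion extraction, deduplication, unique-ion screening, top-N cards."""

import numpy as np
import pytest

import idcard as ic
from idcard.card_builder import SharedIonSet
from idcard.errors import ConfigurationError, EmptyCardError, IdCardWarning

from conftest import brute_force_pairs, small_generator_config


def table(sample_id, ions, origin="A"):
    return ic.FeatureTable.from_ions(sample_id, ions, origin=origin)


def shared_set(label, ions):
    return SharedIonSet(label, [ic.IonFeature(*i) for i in ions])


class TestExtractSharedIons:
    def test_anchor_and_mean_intensity_rule(self, tol):
        a = table("a", [(5.00, 300.10, 1.0e4)])
        b = table("b", [(5.03, 300.12, 2.0e4)])
        shared = ic.extract_shared_ions([a, b], tol)
        assert len(shared) == 1
        assert shared.ions[0] == ic.IonFeature(5.00, 300.10, 1.5e4)

    def test_identical_batches_yield_full_anchor_list(self, tol):
        ions = [(5.0, 300.0, 1e4), (10.0, 500.0, 2e4), (15.0, 900.0, 3e4)]
        shared = ic.extract_shared_ions([table("a", ions), table("b", ions)], tol)
        assert shared.ions == [ic.IonFeature(*i) for i in ions]

    def test_disjoint_batches_give_empty_set_with_warning(self, tol):
        a = table("a", [(5.0, 300.0, 1.0)])
        b = table("b", [(5.0, 700.0, 1.0)])
        with pytest.warns(IdCardWarning, match="no shared ions"):
            shared = ic.extract_shared_ions([a, b], tol)
        assert len(shared) == 0

    def test_fewer_than_two_batches_rejected(self, tol):
        with pytest.raises(ConfigurationError):
            ic.extract_shared_ions([table("a", [(5.0, 300.0, 1.0)])], tol)

    def test_closest_match_feeds_mean_when_several_candidates(self, tol):
        a = table("a", [(5.00, 300.10, 1.0e4)])
        # two candidates in batch b; the closer m/z (300.11) supplies intensity
        b = table("b", [(5.00, 300.11, 4.0e4), (5.00, 300.14, 8.0e4)])
        shared = ic.extract_shared_ions([a, b], tol)
        assert shared.ions[0].intensity == pytest.approx(2.5e4)

    def test_batch_support_records_all_matches(self, tol):
        a = table("a", [(5.00, 300.10, 1.0e4)])
        b = table("b", [(5.00, 300.11, 4.0e4), (5.00, 300.14, 8.0e4)])
        shared = ic.extract_shared_ions([a, b], tol)
        ids = [sid for sid, _ in shared.batch_support[0]]
        assert ids == ["a", "b", "b"]

    def test_matches_all_batch_intersection_oracle(self, rng, tol):
        # 6 jittered batches over a planted panel + per-batch extras
        panel_mz = np.arange(200.0, 320.0, 0.5)
        panel_rt = rng.uniform(2, 25, len(panel_mz))
        batches = []
        for k in range(6):
            keep = rng.random(len(panel_mz)) > 0.2
            mz = panel_mz[keep] + rng.normal(0, 0.01, keep.sum())
            rt = panel_rt[keep] + rng.normal(0, 0.01, keep.sum())
            extra_mz = rng.uniform(400, 1500, 30)
            extra_rt = rng.uniform(2, 25, 30)
            batches.append(
                ic.FeatureTable(
                    f"b{k}",
                    np.concatenate([rt, extra_rt]),
                    np.concatenate([mz, extra_mz]),
                    np.ones(keep.sum() + 30),
                    origin="A",
                )
            )
        shared = ic.extract_shared_ions(batches, tol)
        anchor = batches[0]
        expected = set(range(anchor.n_ions))
        for other in batches[1:]:
            hit = {
                i for i, _ in brute_force_pairs(anchor.rt, anchor.mz, other.rt, other.mz, tol)
            }
            expected &= hit
        got = {int(np.flatnonzero(anchor.rt == ion.rt)[0]) for ion in shared.ions}
        assert got == expected

    def test_quorum_relaxes_the_all_batch_rule(self, tol):
        a = table("a", [(5.0, 300.0, 1e4), (10.0, 500.0, 1e4)])
        b = table("b", [(5.0, 300.0, 2e4), (10.0, 500.0, 2e4)])
        c = table("c", [(5.0, 300.0, 3e4)])  # second ion missing here
        strict = ic.extract_shared_ions([a, b, c], tol)
        assert [i.mz for i in strict.ions] == [300.0]
        quorum = ic.extract_shared_ions([a, b, c], tol, quorum=2)
        assert [i.mz for i in quorum.ions] == [300.0, 500.0]


class TestDedupSimilarIons:
    def test_strongest_of_cluster_kept(self, tol):
        s = shared_set("A", [(5.00, 300.10, 9e4), (5.02, 300.12, 1e4)])
        out = ic.dedup_similar_ions(s, tol)
        assert out.ions == [ic.IonFeature(5.00, 300.10, 9e4)]

    def test_non_matching_set_unchanged(self, tol):
        s = shared_set("A", [(5.0, 300.0, 1.0), (5.0, 400.0, 2.0), (20.0, 300.0, 3.0)])
        assert ic.dedup_similar_ions(s, tol).ions == s.ions

    def test_output_pairwise_non_matching(self, rng, tol):
        # clustered ions: several per 0.03-Da clump
        centers = np.arange(300.0, 360.0, 0.5)
        mz = np.concatenate([c + rng.uniform(-0.015, 0.015, 4) for c in centers])
        rt = np.concatenate([np.full(4, r) for r in rng.uniform(2, 25, len(centers))])
        s = SharedIonSet("A", [
            ic.IonFeature(r, m, i) for r, m, i in zip(rt, mz, rng.uniform(1, 9, len(mz)))
        ])
        out = ic.dedup_similar_ions(s, tol)
        for i, a in enumerate(out.ions):
            for b in out.ions[i + 1:]:
                assert not ic.ions_match(a, b, tol)
        # greedy by intensity: every kept ion is its clump's strongest survivor
        assert len(out) == len(centers)


class TestScreening:
    def test_unique_vs_shared_removes_cross_matches(self, tol):
        own = shared_set("A", [(5.00, 300.10, 1.0), (8.00, 500.25, 2.0)])
        other = shared_set("B", [(5.02, 300.13, 9.0)])
        out = ic.screen_unique_vs_shared(own, [other], tol)
        assert out.ions == [ic.IonFeature(8.00, 500.25, 2.0)]

    def test_disjoint_contrast_keeps_everything(self, tol):
        own = shared_set("A", [(5.0, 300.0, 1.0)])
        other = shared_set("B", [(15.0, 900.0, 1.0)])
        assert ic.screen_unique_vs_shared(own, [other], tol).ions == own.ions
        assert ic.screen_unique_vs_raw(own, [], tol).ions == own.ions

    def test_raw_screening_stricter_than_shared_screening(self, tol):
        # a weak contrast ion absent from the contrast shared set still
        # eliminates the card candidate under raw screening
        own = shared_set("A", [(5.0, 300.0, 5e4)])
        contrast_batches = [
            table("x1", [(5.01, 300.01, 50.0), (20.0, 900.0, 1e5)], origin="B"),
            table("x2", [(20.0, 900.0, 1e5)], origin="B"),
        ]
        contrast_shared = ic.extract_shared_ions(contrast_batches, tol)
        assert ic.screen_unique_vs_shared(own, [contrast_shared], tol).ions == own.ions
        assert ic.screen_unique_vs_raw(own, contrast_batches, tol).ions == []

    def test_raw_screened_set_is_subset_of_shared_screened_set(self, small_corpus, tol):
        corpus = small_corpus
        groups = {}
        for t in corpus.batches:
            groups.setdefault(t.origin, []).append(t)
        pre = {
            o: [ic.preprocess(t, corpus.blanks, tol) for t in ts] for o, ts in groups.items()
        }
        shared = {
            o: ic.dedup_similar_ions(ic.extract_shared_ions(ts, tol), tol)
            for o, ts in pre.items()
        }
        for origin in groups:
            others_shared = [shared[o] for o in groups if o != origin]
            others_raw = [t for o in groups if o != origin for t in pre[o]]
            a = ic.screen_unique_vs_shared(shared[origin], others_shared, tol)
            b = ic.screen_unique_vs_raw(shared[origin], others_raw, tol)
            assert set(b.ions) <= set(a.ions)


class TestSelectTopN:
    def test_top_two_of_three(self, tol):
        s = shared_set("A", [(5.0, 300.0, 5e4), (6.0, 400.0, 3e4), (7.0, 500.0, 1e4)])
        card = ic.select_top_n(s, 2, tolerance=tol)
        assert [i.intensity for i in card.ions] == [5e4, 3e4]

    def test_small_set_warns_and_keeps_actual_size(self, tol):
        s = shared_set("A", [(5.0, 300.0, 1.0)])
        with pytest.warns(IdCardWarning, match="only 1 ions"):
            card = ic.select_top_n(s, 100, tolerance=tol)
        assert card.size == 1 and card.top_n == 100

    def test_ties_broken_by_mz_then_rt(self, tol):
        s = shared_set("A", [(9.0, 500.0, 2e4), (5.0, 300.0, 2e4), (3.0, 300.0, 2e4)])
        card = ic.select_top_n(s, 3, tolerance=tol)
        assert [(i.rt, i.mz) for i in card.ions] == [(3.0, 300.0), (5.0, 300.0), (9.0, 500.0)]

    def test_empty_set_fails_loudly(self, tol):
        with pytest.raises(EmptyCardError):
            ic.select_top_n(shared_set("A", []), 10, tolerance=tol)


class TestBuildCards:
    def test_origin_with_single_batch_named_in_error(self, tol):
        corpus = [
            table("a1", [(5.0, 300.0, 1.0)], origin="A"),
            table("a2", [(5.0, 300.0, 1.0)], origin="A"),
            table("b1", [(5.0, 700.0, 1.0)], origin="B"),
        ]
        with pytest.raises(ConfigurationError, match="'B'"):
            ic.build_cards(corpus, None, tol, n=10)

    def test_planted_unique_panels_recovered_exactly_when_noiseless(self, tol):
        cfg = small_generator_config(dropout_rate=0.0, detection_floor=0.0,
                                     rt_jitter_sd=0.005, mz_jitter_sd=0.005)
        corpus = ic.generate_corpus(cfg)
        cards = ic.build_cards(corpus.batches, corpus.blanks, tol,
                               n=cfg.unique_panel_size)
        for origin, card in cards.items():
            rt, mz, _ = card.arrays()
            assert card.size == cfg.unique_panel_size
            assert ic.GroundTruth.in_unique_panel(
                corpus.truth, origin, rt, mz, tol.delta_rt, tol.delta_mz
            ).all()

    def test_duplicate_batch_leaves_cards_unchanged(self, tol):
        ions_a = [(5.0, 300.0, 1e4), (10.0, 480.0, 2e4)]
        ions_b = [(5.0, 700.0, 1e4), (10.0, 900.0, 2e4)]
        corpus = [
            table("a1", ions_a, "A"), table("a2", ions_a, "A"),
            table("b1", ions_b, "B"), table("b2", ions_b, "B"),
        ]
        cards1 = ic.build_cards(corpus, None, tol, n=10)
        cards2 = ic.build_cards(corpus + [table("a3", ions_a, "A")], None, tol, n=10)
        assert cards1["A"].ions == cards2["A"].ions
        assert cards1["B"].ions == cards2["B"].ions

    def test_non_anchor_batch_order_does_not_matter(self, small_corpus, tol):
        corpus = small_corpus.batches
        reordered = []
        for origin in ("origin-1", "origin-2", "origin-3"):
            group = [t for t in corpus if t.origin == origin]
            reordered += [group[0]] + group[1:][::-1]
        cards1 = ic.build_cards(corpus, small_corpus.blanks, tol, n=30)
        cards2 = ic.build_cards(reordered, small_corpus.blanks, tol, n=30)
        for o in cards1:
            assert cards1[o].ions == cards2[o].ions

    def test_card_exclusivity_vs_other_shared_sets(self, small_corpus, tol):
        corpus = small_corpus
        groups = {}
        for t in corpus.batches:
            groups.setdefault(t.origin, []).append(t)
        shared = {
            o: ic.dedup_similar_ions(
                ic.extract_shared_ions(
                    [ic.preprocess(t, corpus.blanks, tol) for t in ts], tol
                ),
                tol,
            )
            for o, ts in groups.items()
        }
        cards = ic.build_cards(corpus.batches, corpus.blanks, tol, n=30)
        for origin, card in cards.items():
            for other, sset in shared.items():
                if other == origin:
                    continue
                for a in card.ions:
                    for b in sset.ions:
                        assert not ic.ions_match(a, b, tol)

    def test_shared_yield_non_decreasing_in_mz_tolerance(self, small_corpus):
        corpus = small_corpus
        group = [t for t in corpus.batches if t.origin == "origin-1"]
        counts = []
        for dmz in (0.0, 0.005, 0.01, 0.05):
            tol = ic.ToleranceSpec(0.05, dmz)
            pre = [ic.preprocess(t, corpus.blanks, tol) for t in group]
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", IdCardWarning)
                counts.append(len(ic.extract_shared_ions(pre, tol)))
        assert counts == sorted(counts)
        assert counts[0] < counts[-1]  # harsh window loses the shared panel

    def test_rebuild_is_deterministic(self, small_corpus, tol, tmp_path):
        corpus = small_corpus
        for trial in range(2):
            cards = ic.build_cards(corpus.batches, corpus.blanks, tol, n=30)
            ic.write_card(cards["origin-1"], tmp_path / f"c{trial}.json")
        assert (tmp_path / "c0.json").read_bytes() == (tmp_path / "c1.json").read_bytes()
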