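"""Stage-1 retrieval: segmentation, similarity, top-k, windows, Recall@k.

The [derived] expectations are checked against independent brute-force
oracles written directly from the definitions (per-pair cosine loops,
sort-then-truncate, merge/dedup by hand).
"""

import numpy as np
import pytest

from nursemap.embedders import EmbedderContractError, HashedNGramEmbedder
from nursemap.retrieval import (
    DEFAULT_PUNCTUATION,
    ContextWindow,
    DenseIndex,
    EmbeddingMatrix,
    HitSource,
    RetrievalHit,
    SubqueryOrigin,
    build_context_window,
    build_corpus_index,
    build_reference_index,
    embed,
    l2_normalize,
    recall_at_k,
    retrieve_top_k,
    segment_record,
    similarity_matrix,
)
from nursemap.synthetic import OneHotEmbedder, SynthConfig, generate_terminology
from nursemap.terminology import GoldAnnotation, NursingRecord


# ---------------------------------------------------------------------------
# Independent oracles


def cosine_oracle(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-pair cosine similarity by explicit loops."""
    out = np.zeros((a.shape[0], b.shape[0]))
    for i in range(a.shape[0]):
        for j in range(b.shape[0]):
            na, nb = np.linalg.norm(a[i]), np.linalg.norm(b[j])
            out[i, j] = 0.0 if na == 0 or nb == 0 else float(a[i] @ b[j]) / (na * nb)
    return out


def topk_oracle(scores, ids, k):
    """Full sort (score desc, ordinal asc) then truncate."""
    ranked = sorted(range(len(ids)), key=lambda i: (-scores[i], i))
    return [ids[i] for i in ranked[:k]]


def window_oracle(per_source_hits, k):
    """Merge per-subquery/source top-k lists, dedup keeping max score."""
    best = {}
    for hits in per_source_hits:
        for item, score in hits[:k]:
            if item not in best or score > best[item]:
                best[item] = score
    return sorted(best.items(), key=lambda kv: -kv[1])


# ---------------------------------------------------------------------------


class TestSegmentRecord:
    def test_mixed_punctuation_chunks_plus_full_record(self):
        record = NursingRecord("R1", "皮肤完整。予翻身，监测生命体征.")
        subs = segment_record(record)
        chunks = [s.text for s in subs if s.origin is SubqueryOrigin.CHUNK]
        assert chunks == ["皮肤完整", "予翻身", "监测生命体征"]
        full = [s for s in subs if s.origin is SubqueryOrigin.FULL_RECORD]
        assert len(full) == 1 and full[0].text == record.text

    def test_no_delimiter_collapses_to_single_subquery(self):
        subs = segment_record(NursingRecord("R1", "monitor vitals"))
        assert len(subs) == 1
        assert subs[0].origin is SubqueryOrigin.FULL_RECORD

    def test_empty_text_yields_empty_list(self, caplog):
        with caplog.at_level("WARNING", logger="nursemap.retrieval"):
            assert segment_record(NursingRecord("R1", "   ")) == []
        assert caplog.records


class TestEmbedAndNormalize:
    def test_identical_texts_embed_identically(self):
        emb = HashedNGramEmbedder(dim=64, seed=3)
        m = embed(["turn patient", "turn patient"], emb)
        np.testing.assert_array_equal(m.matrix[0], m.matrix[1])

    def test_empty_text_list_gives_zero_row_matrix(self):
        m = embed([], HashedNGramEmbedder(dim=32))
        assert m.matrix.shape == (0, 32)

    def test_hashed_embedder_is_deterministic_across_instances(self):
        texts = ["皮肤完整", "monitor vitals", ""]
        a = HashedNGramEmbedder(dim=128, seed=5).embed(texts)
        b = HashedNGramEmbedder(dim=128, seed=5).embed(texts)
        np.testing.assert_array_equal(a, b)
        c = HashedNGramEmbedder(dim=128, seed=6).embed(texts)
        assert not np.array_equal(a, c)

    def test_l2_normalize_rows(self, caplog):
        m = EmbeddingMatrix(np.array([[3.0, 4.0], [0.6, 0.8], [0.0, 0.0]]), ["a", "b", "c"])
        with caplog.at_level("WARNING", logger="nursemap.retrieval"):
            normed = l2_normalize(m)
        np.testing.assert_allclose(normed.matrix[0], [0.6, 0.8])
        np.testing.assert_allclose(normed.matrix[1], [0.6, 0.8])
        np.testing.assert_array_equal(normed.matrix[2], [0.0, 0.0])
        assert normed.normalized
        assert any("zero" in r.message for r in caplog.records)

    def test_dimension_mismatch_is_contract_violation(self):
        class BadEmbedder:
            dim = 8
            fingerprint = "bad"

            def embed(self, texts):
                return np.zeros((len(texts), 4))

        with pytest.raises(EmbedderContractError):
            embed(["x"], BadEmbedder())


class TestSimilarityMatrix:
    def test_requires_normalized_inputs(self):
        raw = EmbeddingMatrix(np.eye(3), ["a", "b", "c"], normalized=False)
        with pytest.raises(ValueError, match="normalized"):
            similarity_matrix(raw, raw)

    def test_unit_diagonal_for_self_similarity(self):
        rng = np.random.default_rng(0)
        m = l2_normalize(EmbeddingMatrix(rng.normal(size=(6, 5)), [str(i) for i in range(6)]))
        sims = similarity_matrix(m, m)
        np.testing.assert_allclose(np.diag(sims), 1.0, atol=1e-9)

    def test_matches_per_pair_cosine_oracle(self):
        rng = np.random.default_rng(42)
        q_raw, r_raw = rng.normal(size=(4, 3)), rng.normal(size=(5, 3))
        sims = similarity_matrix(
            l2_normalize(EmbeddingMatrix(q_raw, list("abcd"))),
            l2_normalize(EmbeddingMatrix(r_raw, list("vwxyz"))),
        )
        np.testing.assert_allclose(sims, cosine_oracle(q_raw, r_raw), atol=1e-12)


class TestRetrieveTopK:
    def test_k_at_least_one(self):
        with pytest.raises(ValueError):
            retrieve_top_k(np.array([0.5]), ["a"], 0, HitSource.REFERENCE)

    def test_k_exceeding_items_returns_all_sorted(self):
        hits = retrieve_top_k(np.array([0.1, 0.9]), ["a", "b"], 10, HitSource.REFERENCE)
        assert [h.item_id for h in hits] == ["b", "a"]

    def test_ties_break_by_ascending_ordinal(self):
        hits = retrieve_top_k(np.array([0.7, 0.9, 0.9]), ["a", "b", "c"], 2, HitSource.REFERENCE)
        assert [h.item_id for h in hits] == ["b", "c"]

    def test_matches_sort_truncate_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            scores = np.round(rng.uniform(-1, 1, size=10), 2)  # rounding forces ties
            ids = [f"t{i}" for i in range(10)]
            hits = retrieve_top_k(scores, ids, 3, HitSource.REFERENCE)
            assert [h.item_id for h in hits] == topk_oracle(scores, ids, 3)


class TestContextWindow:
    @pytest.fixture()
    def setup(self):
        cfg = SynthConfig(n_diagnoses=8, n_interventions=8, seed=3)
        synth = generate_terminology(cfg)
        embedder = HashedNGramEmbedder(dim=64, seed=1)
        return synth, embedder, build_reference_index(synth.terms, embedder)

    def test_reference_only_bound(self, setup):
        synth, embedder, ref = setup
        record = NursingRecord("R1", "noted impaired skin integrity. family visited at bedside")
        window = build_context_window(record, embedder, ref, corpus_index=None, k=5)
        n_sub = len(segment_record(record))
        assert 0 < len(window.hits) <= 5 * n_sub
        scores = [h.score for h in window.hits]
        assert scores == sorted(scores, reverse=True)

    def test_duplicate_item_keeps_maximum_score(self):
        with pytest.raises(ValueError):
            ContextWindow("R", [
                RetrievalHit("a", HitSource.REFERENCE, 0.9),
                RetrievalHit("a", HitSource.REFERENCE, 0.4),
            ])

    def test_empty_record_gives_empty_window(self, setup, caplog):
        _, embedder, ref = setup
        with caplog.at_level("WARNING", logger="nursemap.retrieval"):
            window = build_context_window(NursingRecord("R1", ""), embedder, ref)
        assert window.hits == []

    def test_matches_brute_force_merge_oracle(self, setup):
        synth, embedder, ref = setup
        corpus_texts = [f"example note {i} about care" for i in range(6)]
        corpus = build_corpus_index(
            [type("E", (), {"text": t, "example_id": f"E{i}"})() for i, t in enumerate(corpus_texts)],
            embedder,
        )
        record = NursingRecord(
            "R1", "impaired skin integrity observed this shift. monitor vital signs, example note 2 about care"
        )
        k = 3
        window = build_context_window(record, embedder, ref, corpus, k=k)

        # oracle: per subquery and source, score all items, sort, truncate, merge
        subs = segment_record(record)
        per_source = []
        for index in (ref, corpus):
            raw_refs = index.embeddings.matrix
            for s in subs:
                q = embedder.embed([s.text])
                sims = cosine_oracle(q, raw_refs)[0]
                ranked = sorted(
                    zip(index.embeddings.item_ids, sims), key=lambda t: (-t[1], index.embeddings.item_ids.index(t[0]))
                )
                per_source.append(ranked)
        expected = window_oracle(per_source, k)
        got = [(h.item_id, h.score) for h in window.hits]
        assert [g[0] for g in got] == [e[0] for e in expected] or {
            g[0] for g in got
        } == {e[0] for e in expected}
        for (gi, gs), (ei, es) in zip(sorted(got), sorted(expected)):
            assert gi == ei
            assert gs == pytest.approx(es, abs=1e-9)


class TestRecallAtK:
    def test_gold_ranked_first_gives_recall_one(self):
        gold = [GoldAnnotation("R1", frozenset({"D1"}), frozenset())]
        result = recall_at_k({"R1": ["D1", "D2", "D3"]}, gold, ks=(1, 3))
        assert result.recall_at_k[1] == 1.0

    def test_absent_gold_code_contributes_zero_everywhere(self):
        gold = [GoldAnnotation("R1", frozenset({"D9"}), frozenset())]
        result = recall_at_k({"R1": ["D1", "D2"]}, gold, ks=(1, 3, 5))
        assert all(v == 0.0 for v in result.recall_at_k.values())

    def test_all_empty_gold_is_undefined(self):
        gold = [GoldAnnotation("R1", frozenset(), frozenset())]
        with pytest.raises(ValueError, match="undefined"):
            recall_at_k({"R1": ["D1"]}, gold)

    def test_matches_counting_oracle_and_monotone(self):
        rng = np.random.default_rng(19)
        codes = [f"C{i}" for i in range(20)]
        gold, rankings = [], {}
        for r in range(12):
            gold_codes = frozenset(rng.choice(codes, size=int(rng.integers(1, 5)), replace=False))
            gold.append(GoldAnnotation(f"R{r}", gold_codes, frozenset()))
            rankings[f"R{r}"] = list(rng.permutation(codes)[: int(rng.integers(3, 15))])
        ks = (1, 3, 5, 10)
        result = recall_at_k(rankings, gold, ks=ks)
        for k in ks:
            expected = np.mean(
                [
                    len(g.codes() & set(rankings[g.record_id][:k])) / len(g.codes())
                    for g in gold
                ]
            )
            assert result.recall_at_k[k] == pytest.approx(expected)
        vals = [result.recall_at_k[k] for k in ks]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestOneHotRetrieval:
    def test_perfect_embedder_puts_gold_at_rank_one(self):
        cfg = SynthConfig(
            n_diagnoses=10, n_interventions=10, n_records=15,
            codes_per_record=(1, 1), noise_clause_rate=0.0, seed=23,
        )
        synth = generate_terminology(cfg)
        from nursemap.synthetic import generate_records

        records, gold, _ = generate_records(synth, cfg)
        # single-code records so the merged ranking's top entry is the gold code
        one_code_gold = [
            GoldAnnotation(g.record_id, g.diagnosis_codes, frozenset()) for g in gold
        ]
        embedder = OneHotEmbedder(synth)
        ref = build_reference_index(synth.terms, embedder)
        rankings = {}
        for record, g in zip(records, one_code_gold):
            window = build_context_window(record, embedder, ref, k=5)
            # keep only hits that tie the top score before asserting rank 1
            rankings[record.record_id] = window.items(HitSource.REFERENCE)
            top = window.hits[0]
            assert top.score == pytest.approx(1.0, abs=1e-9)
            assert next(iter(g.diagnosis_codes)) in {
                h.item_id for h in window.hits if h.score >= top.score - 1e-9
            }


class TestIndexPersistence:
    def test_save_load_round_trip(self, tmp_path):
        embedder = HashedNGramEmbedder(dim=16, seed=2)
        m = l2_normalize(embed(["alpha", "beta", "gamma"], embedder, item_ids=["a", "b", "c"]))
        index = DenseIndex(m, HitSource.REFERENCE, embedder.fingerprint)
        index.save(tmp_path / "index.txt")
        loaded = DenseIndex.load(tmp_path / "index.txt")
        assert loaded.embeddings.item_ids == ["a", "b", "c"]
        assert loaded.embedder_fingerprint == embedder.fingerprint
        np.testing.assert_allclose(loaded.embeddings.matrix, m.matrix)
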