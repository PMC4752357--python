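"""Semantic-search tests: lexicon construction, indexing fidelity,
keyword-vs-semantic retrieval, and the synthetic corpus generator."""

import pytest

from muscle_logic import (
    ConfigurationError,
    CorpusSpec,
    CorpusSpecError,
    Document,
    LexiconBuildError,
    SearchQuery,
    build_lexicon,
    compare_engines,
    generate_corpus,
    index_corpus,
    read_corpus_jsonl,
    search,
    write_corpus_jsonl,
)
from muscle_logic.model import Curie, Ontology, OntologyClass
from muscle_logic.search import phrase_tokens, split_sentences, tokenize


@pytest.fixture(scope="module")
def tm_lexicon(fixture_onto, fixture_sat):
    tm = fixture_onto.resolve_label("trigeminal muscle")
    return build_lexicon(fixture_onto, fixture_sat, tm)


@pytest.fixture(scope="module")
def lp_lexicon(fixture_onto, fixture_sat):
    lp = fixture_onto.resolve_label("lateral pterygoid muscle")
    return build_lexicon(fixture_onto, fixture_sat, lp)


class TestBuildLexicon:
    def test_trigeminal_category_contains_its_member_muscles(
        self, fixture_onto, tm_lexicon
    ):
        assert phrase_tokens("temporalis muscle") in tm_lexicon.phrases
        assert phrase_tokens("masseter muscle") in tm_lexicon.phrases
        assert len(tm_lexicon.members) == 20

    def test_synonyms_are_lexicon_phrases(self, lp_lexicon):
        assert set(lp_lexicon.phrase_text.values()) == {
            "lateral pterygoid muscle",
            "external pterygoid muscle",
        }

    def test_leaf_class_without_synonyms_gives_single_phrase(
        self, fixture_onto, fixture_sat
    ):
        buc = fixture_onto.resolve_label("buccinator muscle")
        lex = build_lexicon(fixture_onto, fixture_sat, buc)
        assert list(lex.phrase_text.values()) == ["buccinator muscle"]

    def test_colliding_phrases_are_a_build_error(self, fixture_sat):
        onto = Ontology()
        root = Curie("T", "0")
        onto.add_class(OntologyClass(root, "root thing"))
        onto.add_class(OntologyClass(Curie("T", "1"), "left thing", synonyms=("shared name",)))
        onto.add_class(OntologyClass(Curie("T", "2"), "right thing", synonyms=("shared name",)))
        from muscle_logic import SubClassOf, Named, classify

        onto.axioms = [
            SubClassOf(Named(Curie("T", "1")), Named(root)),
            SubClassOf(Named(Curie("T", "2")), Named(root)),
        ]
        onto.validate()
        with pytest.raises(LexiconBuildError, match="shared name"):
            build_lexicon(onto, classify(onto), root)


class TestIndexing:
    def test_synonym_mention_is_tagged_with_the_canonical_class(
        self, fixture_onto, lp_lexicon
    ):
        doc = Document("d1", "A note", "The external pterygoid was not active. The external pterygoid muscle fired late.")
        index = index_corpus([doc], [lp_lexicon])
        tags = [t for s in index.sentences["d1"] for t in s.tags]
        assert len(tags) == 1  # only the full phrase matches (no stemming)
        assert tags[0].member == fixture_onto.resolve_label("lateral pterygoid muscle")
        assert tags[0].phrase == "external pterygoid muscle"

    def test_document_without_phrases_gets_zero_tags(self, tm_lexicon):
        doc = Document("d1", "Plain", "Nothing anatomical happens here at all.")
        index = index_corpus([doc], [tm_lexicon])
        assert all(not s.tags for s in index.sentences["d1"])

    def test_empty_corpus_gives_empty_index_not_an_error(self, tm_lexicon):
        index = index_corpus([], [tm_lexicon])
        assert index.documents == {}
        assert search(index, SearchQuery(categories=(tm_lexicon.category,))) == []

    def test_longest_match_wins(self, fixture_onto, fixture_sat, tm_lexicon):
        doc = Document("d1", "t", "The superficial masseter muscle contracted.")
        index = index_corpus([doc], [tm_lexicon])
        tags = [t for s in index.sentences["d1"] for t in s.tags]
        assert [t.phrase for t in tags] == ["superficial masseter muscle"]

    def test_tag_spans_recover_their_phrases(self, fixture_onto, fixture_sat, tm_lexicon):
        """Lossless indexing: re-extracting every tag span from the raw
        sentence text yields exactly the lexicon phrase, across a large
        generated corpus."""
        tm = tm_lexicon.category
        docs = generate_corpus(
            CorpusSpec(target_category=tm, n_relevant=150, n_distractor=150, seed=5),
            tm_lexicon,
        )
        index = index_corpus(docs, [tm_lexicon])
        checked = 0
        for sents in index.sentences.values():
            for sent in sents:
                for tag in sent.tags:
                    span_text = sent.text[tag.char_start : tag.char_end]
                    assert phrase_tokens(span_text) == phrase_tokens(tag.phrase)
                    checked += 1
        assert checked >= 150  # every relevant document mentions a member


class TestSearch:
    def test_semantic_query_finds_member_mention_keyword_query_does_not(
        self, fixture_onto, tm_lexicon
    ):
        """A document that says only 'temporalis muscle' and 'mastication'
        answers the semantic category query but not the literal phrase
        query — the scenario keyword engines fail on."""
        doc = Document(
            "herring-2011",
            "Mastication and the postorbital ligament",
            "Dynamic strain was recorded while the temporalis muscle was active. "
            "Strain increased during mastication in every subject.",
        )
        index = index_corpus([doc], [tm_lexicon])
        semantic = search(
            index,
            SearchQuery(
                categories=(tm_lexicon.category,),
                keywords=("mastication",),
                scope="document",
                mode="semantic",
            ),
        )
        keyword = search(
            index,
            SearchQuery(
                keywords=("muscle innervated by the trigeminal nerve", "mastication"),
                scope="document",
                mode="keyword",
            ),
        )
        assert [h.doc_id for h in semantic] == ["herring-2011"]
        assert keyword == []

    def test_sentence_scope_requires_cooccurrence_in_one_sentence(self, tm_lexicon):
        doc = Document(
            "split",
            "t",
            "The masseter muscle was recorded. Mastication was observed separately.",
        )
        index = index_corpus([doc], [tm_lexicon])
        q = dict(categories=(tm_lexicon.category,), keywords=("mastication",))
        assert search(index, SearchQuery(scope="document", **q)) != []
        assert search(index, SearchQuery(scope="sentence", **q)) == []

    def test_category_without_lexicon_is_a_configuration_error(self, tm_lexicon):
        doc = Document("d", "t", "Some text.")
        index = index_corpus([doc], [tm_lexicon])
        with pytest.raises(ConfigurationError):
            search(index, SearchQuery(categories=(Curie("X", "1"),), mode="semantic"))

    def test_ranking_by_match_count_then_doc_id(self, tm_lexicon):
        one = Document("b-one", "t", "The masseter muscle was active.")
        two = Document(
            "a-two",
            "t",
            "The masseter muscle fired. The temporalis muscle fired too.",
        )
        tie = Document("a-tie", "t", "The masseter muscle was active.")
        index = index_corpus([one, two, tie], [tm_lexicon])
        hits = search(index, SearchQuery(categories=(tm_lexicon.category,)))
        assert [h.doc_id for h in hits] == ["a-two", "a-tie", "b-one"]


class TestGenerateCorpus:
    def test_zero_relevant_documents_all_unlabeled(self, tm_lexicon):
        docs = generate_corpus(
            CorpusSpec(target_category=tm_lexicon.category, n_relevant=0, n_distractor=5, seed=1),
            tm_lexicon,
        )
        assert len(docs) == 5
        assert all(doc.truth_labels == frozenset() for doc in docs)

    def test_same_seed_reproduces_the_corpus_exactly(self, tm_lexicon):
        spec = CorpusSpec(target_category=tm_lexicon.category, n_relevant=20, n_distractor=20, seed=9)
        assert generate_corpus(spec, tm_lexicon) == generate_corpus(spec, tm_lexicon)

    def test_synonym_probability_without_synonyms_is_a_spec_error(
        self, fixture_onto, fixture_sat
    ):
        buc = fixture_onto.resolve_label("buccinator muscle")
        lex = build_lexicon(fixture_onto, fixture_sat, buc)
        with pytest.raises(CorpusSpecError, match="synonym"):
            generate_corpus(
                CorpusSpec(target_category=buc, n_relevant=5, synonym_probability=0.5, seed=1),
                lex,
            )

    def test_synonym_usage_tracks_the_requested_probability(self, lp_lexicon):
        spec = CorpusSpec(
            target_category=lp_lexicon.category,
            n_relevant=50,
            n_distractor=0,
            synonym_probability=0.5,
            seed=1,
        )
        docs = generate_corpus(spec, lp_lexicon)
        used_synonym = sum("external pterygoid muscle" in d.body for d in docs)
        # Binomial(50, 0.5): a count outside [10, 40] has probability < 1e-4
        assert 10 <= used_synonym <= 40

    def test_jsonl_io_round_trips(self, tm_lexicon, tmp_path):
        docs = generate_corpus(
            CorpusSpec(target_category=tm_lexicon.category, n_relevant=5, n_distractor=5, seed=3),
            tm_lexicon,
        )
        path = tmp_path / "corpus.jsonl"
        write_corpus_jsonl(docs, path)
        assert read_corpus_jsonl(path) == docs


class TestCompareEngines:
    def _indexed(self, lexicon, synonym_probability, seed=1, n=60):
        spec = CorpusSpec(
            target_category=lexicon.category,
            n_relevant=n,
            n_distractor=n,
            synonym_probability=synonym_probability,
            seed=seed,
        )
        docs = generate_corpus(spec, lexicon)
        return index_corpus(docs, [lexicon]), docs

    def test_all_label_mentions_give_both_engines_full_recall(self, lp_lexicon):
        index, _ = self._indexed(lp_lexicon, synonym_probability=0.0)
        (report,) = compare_engines(
            index, [SearchQuery(categories=(lp_lexicon.category,), scope="document")]
        )
        assert report.keyword_recall == 1.0
        assert report.semantic_recall == 1.0

    def test_all_synonym_mentions_defeat_the_keyword_engine(self, lp_lexicon):
        index, _ = self._indexed(lp_lexicon, synonym_probability=1.0)
        (report,) = compare_engines(
            index, [SearchQuery(categories=(lp_lexicon.category,), scope="document")]
        )
        assert report.keyword_recall == 0.0
        assert report.semantic_recall == 1.0

    def test_semantic_matches_contain_keyword_matches(self, lp_lexicon):
        """Dominance: for a query whose keyword phrase is the category's
        label, the semantic match set is a superset of the keyword set."""
        index, _ = self._indexed(lp_lexicon, synonym_probability=0.5)
        base = SearchQuery(categories=(lp_lexicon.category,), scope="document")
        kw = {h.doc_id for h in search(index, SearchQuery(**{**base.__dict__, "mode": "keyword"}))}
        sem = {h.doc_id for h in search(index, base)}
        assert kw <= sem
        (report,) = compare_engines(index, [base])
        assert report.semantic_recall == 1.0
        assert report.semantic_recall >= report.keyword_recall

    def test_missing_truth_labels_are_a_configuration_error(self, tm_lexicon):
        doc = Document("d", "t", "The masseter muscle was active.")
        index = index_corpus([doc], [tm_lexicon])
        with pytest.raises(ConfigurationError, match="truth labels"):
            compare_engines(index, [SearchQuery(categories=(tm_lexicon.category,))])


class TestTokenization:
    def test_sentence_split_is_deterministic_and_simple(self):
        text = "First sentence here. Second one follows! Third? Yes."
        assert split_sentences(text) == [
            "First sentence here.",
            "Second one follows!",
            "Third?",
            "Yes.",
        ]

    def test_tokenizer_keeps_intra_word_hyphens(self):
        toks = [t for t, _, _ in tokenize("Fine-wire EMG, recorded in-vivo.")]
        assert toks == ["fine-wire", "emg", "recorded", "in-vivo"]
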