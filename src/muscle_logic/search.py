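"""Ontology-expanded (Textpresso-style) search over a plain-text corpus.

A *category* is an ontology class together with all classes the reasoner
places below it; its *lexicon* is the bag of labels and synonyms of those
classes. Documents are split into sentences, tokenized, and tagged
wherever a lexicon phrase occurs (case-folded, longest match wins).
A semantic query then matches a document that mentions *any* member of
the category by *any* of its names — which is precisely what a literal
keyword engine cannot do: it does not "know" that the temporalis muscle
is one of the muscles innervated by the trigeminal nerve, or that the
external pterygoid is the lateral pterygoid.

The synthetic corpus generator emulates abstracts that mention a target
category through a randomly chosen label or synonym, plus distractor
documents that contain the individual query words without naming any
relevant structure; generated documents carry ground-truth labels so
keyword and semantic retrieval can be scored against each other.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConfigurationError, CorpusSpecError, LexiconBuildError
from .model import Curie, Ontology, normalize_text
from .reasoner import Saturation

__all__ = [
    "Document",
    "Lexicon",
    "CorpusIndex",
    "SearchQuery",
    "SearchHit",
    "CorpusSpec",
    "QueryComparison",
    "build_lexicon",
    "index_corpus",
    "search",
    "generate_corpus",
    "compare_engines",
    "read_corpus_jsonl",
    "write_corpus_jsonl",
]


@dataclass(frozen=True)
class Document:
    doc_id: str
    title: str
    body: str
    truth_labels: frozenset[Curie] | None = None

    def __post_init__(self) -> None:
        if not self.body:
            raise ValueError(f"document {self.doc_id!r} has an empty body")


# --------------------------------------------------------------------------
# Tokenization and sentence splitting (deterministic, no ML)

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:-[A-Za-z0-9]+)*")
_SENT_RE = re.compile(r"(?<=[.!?])\s+(?=[A-Z‘'\"(])")


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Case-folded tokens with character spans; punctuation is dropped
    except intra-word hyphens."""
    return [
        (m.group().casefold(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)
    ]


def split_sentences(text: str) -> list[str]:
    """Split on sentence punctuation followed by whitespace and an
    uppercase/opening character. Deterministic by construction."""
    return [s for s in _SENT_RE.split(text) if s.strip()]


def phrase_tokens(phrase: str) -> tuple[str, ...]:
    return tuple(tok for tok, _, _ in tokenize(phrase))


# --------------------------------------------------------------------------
# Lexicon


@dataclass(frozen=True)
class Lexicon:
    """Phrase -> class map for one category (a class and its subtree)."""

    category: Curie
    category_label: str
    members: frozenset[Curie]
    phrases: dict[tuple[str, ...], Curie]  # token-tuple -> member class
    phrase_text: dict[tuple[str, ...], str]  # token-tuple -> original phrase
    labels: dict[Curie, str]  # member class -> its label
    synonyms: dict[Curie, tuple[str, ...]]  # member class -> its synonyms

    def phrases_of(self, member: Curie) -> tuple[str, ...]:
        return tuple(
            sorted(t for k, t in self.phrase_text.items() if self.phrases[k] == member)
        )


def build_lexicon(
    ontology: Ontology, saturation: Saturation, category: Curie
) -> Lexicon:
    """Collect labels and synonyms of a category class and all classes the
    saturation places below it. Phrases are stored case-folded with
    longest-match priority; a phrase claimed by two classes is a build
    error."""
    if category not in ontology.classes:
        raise ConfigurationError(f"category {category} is not a declared class")
    members = {category} | set(saturation.descendants_of(category))
    phrases: dict[tuple[str, ...], Curie] = {}
    phrase_text: dict[tuple[str, ...], str] = {}
    labels: dict[Curie, str] = {}
    synonyms: dict[Curie, tuple[str, ...]] = {}
    collisions: list[str] = []
    for member in sorted(members, key=str):
        cls = ontology.classes[member]
        labels[member] = cls.label
        synonyms[member] = cls.synonyms
        for phrase in (cls.label, *cls.synonyms):
            key = phrase_tokens(phrase)
            if not key:
                continue
            if key in phrases and phrases[key] != member:
                collisions.append(
                    f"{phrase!r} maps to both {phrases[key]} and {member}"
                )
                continue
            phrases[key] = member
            phrase_text[key] = phrase
    if collisions:
        raise LexiconBuildError("; ".join(collisions))
    return Lexicon(
        category=category,
        category_label=ontology.classes[category].label,
        members=frozenset(members),
        phrases=phrases,
        phrase_text=phrase_text,
        labels=labels,
        synonyms=synonyms,
    )


# --------------------------------------------------------------------------
# Index


@dataclass(frozen=True)
class Tag:
    category: Curie  # lexicon root
    member: Curie  # the class the matched phrase names
    start_token: int
    end_token: int  # exclusive
    char_start: int
    char_end: int
    phrase: str


@dataclass
class IndexedSentence:
    text: str
    tokens: list[str]
    token_spans: list[tuple[int, int]]
    tags: list[Tag] = field(default_factory=list)


@dataclass
class CorpusIndex:
    """Sentence-level index: token sequences plus category tags.

    Sentence 0 of each document is its title; body sentences follow.
    """

    documents: dict[str, Document]
    sentences: dict[str, list[IndexedSentence]]
    lexicons: dict[Curie, Lexicon]

    def doc_ids(self) -> list[str]:
        return list(self.documents)


def _tag_sentence(
    sentence: IndexedSentence, lexicons: dict[Curie, Lexicon], max_len: int
) -> None:
    tokens = sentence.tokens
    i = 0
    while i < len(tokens):
        matched = None
        for length in range(min(max_len, len(tokens) - i), 0, -1):
            key = tuple(tokens[i : i + length])
            for root, lex in lexicons.items():
                if key in lex.phrases:
                    matched = (root, lex.phrases[key], length, lex.phrase_text[key])
                    break
            if matched:
                break
        if matched:
            root, member, length, phrase = matched
            sentence.tags.append(
                Tag(
                    category=root,
                    member=member,
                    start_token=i,
                    end_token=i + length,
                    char_start=sentence.token_spans[i][0],
                    char_end=sentence.token_spans[i + length - 1][1],
                    phrase=phrase,
                )
            )
            i += length  # longest match wins; no overlapping tags
        else:
            i += 1


def index_corpus(
    documents: Sequence[Document], lexicons: Sequence[Lexicon]
) -> CorpusIndex:
    """Index a corpus: deterministic sentence split, case-folded
    longest-match phrase tagging. Lexicons must not claim the same phrase
    for different classes (merge them beforehand)."""
    by_root: dict[Curie, Lexicon] = {}
    seen_phrases: dict[tuple[str, ...], Curie] = {}
    for lex in lexicons:
        if lex.category in by_root:
            raise ConfigurationError(f"duplicate lexicon for category {lex.category}")
        for key, member in lex.phrases.items():
            if key in seen_phrases and seen_phrases[key] != member:
                raise ConfigurationError(
                    f"phrase {' '.join(key)!r} is claimed by two lexicons"
                )
            seen_phrases[key] = member
        by_root[lex.category] = lex
    max_len = max((len(k) for k in seen_phrases), default=1)

    docs: dict[str, Document] = {}
    sentences: dict[str, list[IndexedSentence]] = {}
    for doc in documents:
        if doc.doc_id in docs:
            raise ConfigurationError(f"duplicate doc_id {doc.doc_id!r}")
        docs[doc.doc_id] = doc
        sents: list[IndexedSentence] = []
        for text in [doc.title, *split_sentences(doc.body)]:
            toks = tokenize(text)
            sent = IndexedSentence(
                text=text,
                tokens=[t for t, _, _ in toks],
                token_spans=[(s, e) for _, s, e in toks],
            )
            _tag_sentence(sent, by_root, max_len)
            sents.append(sent)
        sentences[doc.doc_id] = sents
    return CorpusIndex(documents=docs, sentences=sentences, lexicons=by_root)


# --------------------------------------------------------------------------
# Search


@dataclass(frozen=True)
class SearchQuery:
    """Keywords are matched as literal token phrases; categories through
    their lexicons (semantic mode) or their bare label phrase (keyword
    mode — what a literal engine would do with the same question)."""

    keywords: tuple[str, ...] = ()
    categories: tuple[Curie, ...] = ()
    scope: str = "sentence"  # or "document"
    mode: str = "semantic"  # or "keyword"

    def __post_init__(self) -> None:
        if not self.keywords and not self.categories:
            raise ValueError("a query needs at least one keyword or category")
        if self.scope not in ("sentence", "document"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.mode not in ("semantic", "keyword"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class SearchHit:
    doc_id: str
    score: int
    matched_sentences: tuple[int, ...]
    matched_phrases: tuple[str, ...]


def _contains_subseq(tokens: Sequence[str], needle: tuple[str, ...]) -> bool:
    n = len(needle)
    return any(tuple(tokens[i : i + n]) == needle for i in range(len(tokens) - n + 1))


def search(index: CorpusIndex, query: SearchQuery) -> list[SearchHit]:
    """Run a query; ranking is by match count, ties broken by doc_id."""
    for cat in query.categories:
        if query.mode == "semantic" and cat not in index.lexicons:
            raise ConfigurationError(
                f"category {cat} queried without its lexicon in the index"
            )

    # an "item" is one required query element; each sentence either
    # satisfies it or not
    keyword_items = [phrase_tokens(k) for k in query.keywords]
    category_items: list[Curie] = []
    if query.mode == "semantic":
        category_items = list(query.categories)
    else:
        for cat in query.categories:
            if cat in index.lexicons:
                label = index.lexicons[cat].category_label
            else:
                label = str(cat)
            keyword_items.append(phrase_tokens(label))

    hits: list[SearchHit] = []
    for doc_id, sents in index.sentences.items():

        def sentence_matches(sent: IndexedSentence, kw, cats) -> tuple[bool, list[str]]:
            phrases = []
            for needle in kw:
                if not _contains_subseq(sent.tokens, needle):
                    return False, []
                phrases.append(" ".join(needle))
            for cat in cats:
                tag = next((t for t in sent.tags if t.category == cat), None)
                if tag is None:
                    return False, []
                phrases.append(tag.phrase)
            return True, phrases

        matched_sents: list[int] = []
        matched_phrases: list[str] = []
        if query.scope == "sentence":
            for i, sent in enumerate(sents):
                ok, phrases = sentence_matches(sent, keyword_items, category_items)
                if ok:
                    matched_sents.append(i)
                    matched_phrases.extend(phrases)
            score = len(matched_sents)
            if not matched_sents:
                continue
        else:  # document scope: each item anywhere in the document
            per_item_sents: list[set[int]] = []
            ok_doc = True
            for needle in keyword_items:
                found = {
                    i for i, s in enumerate(sents) if _contains_subseq(s.tokens, needle)
                }
                if not found:
                    ok_doc = False
                    break
                per_item_sents.append(found)
                matched_phrases.append(" ".join(needle))
            if ok_doc:
                for cat in category_items:
                    found = set()
                    for i, s in enumerate(sents):
                        for t in s.tags:
                            if t.category == cat:
                                found.add(i)
                                matched_phrases.append(t.phrase)
                    if not found:
                        ok_doc = False
                        break
                    per_item_sents.append(found)
            if not ok_doc:
                continue
            matched_sents = sorted(set().union(*per_item_sents))
            score = len(matched_sents)
        hits.append(
            SearchHit(
                doc_id=doc_id,
                score=score,
                matched_sentences=tuple(matched_sents),
                matched_phrases=tuple(dict.fromkeys(matched_phrases)),
            )
        )
    hits.sort(key=lambda h: (-h.score, h.doc_id))
    return hits


# --------------------------------------------------------------------------
# Synthetic corpus generation


@dataclass(frozen=True)
class CorpusSpec:
    """Conditions for a generated corpus.

    ``n_relevant`` documents mention a member of ``target_category`` by a
    lexicon phrase (a synonym with probability ``synonym_probability``,
    the label otherwise) together with a topical keyword;
    ``n_distractor`` documents contain the query's individual words in
    non-matching arrangements and no lexicon phrase at all.
    """

    target_category: Curie
    n_relevant: int = 50
    n_distractor: int = 50
    synonym_probability: float = 0.5
    topic_keyword: str = "mastication"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_relevant < 0 or self.n_distractor < 0:
            raise ValueError("document counts must be non-negative")
        if not 0.0 <= self.synonym_probability <= 1.0:
            raise ValueError("synonym_probability must be within [0, 1]")


_RELEVANT_TEMPLATES = (
    "Electromyographic activity of the {phrase} was recorded during {topic}. "
    "Burst timing in the {phrase} tracked gape cycle phase. "
    "These recordings extend the comparative record of feeding physiology.",
    "We measured strain and activity in the {phrase} of adult specimens. "
    "During {topic} the {phrase} showed biphasic recruitment. "
    "Species differences were small but consistent.",
    "The {phrase} was exposed and implanted with fine-wire electrodes. "
    "Activity during {topic} preceded jaw closing in every trial. "
    "Results are discussed in a comparative framework.",
)

_DISTRACTOR_TEMPLATES = (
    "The graft attached well to the mandible surface in all animals. "
    "No muscle recordings were collected, and {topic} was not observed. "
    "Healing of the nerve conduit was uneventful.",
    "We review imaging of the trigeminal ganglion after nerve injury. "
    "Jaw kinematics during {topic} were excluded from analysis. "
    "A single muscle biopsy informed the histology only.",
    "Sensory fibers of the trigeminal and facial systems were traced. "
    "The prosthesis attached to the mandible required no revision. "
    "Swallowing rather than {topic} was the behavior of interest.",
)


def generate_corpus(
    spec: CorpusSpec,
    lexicon: Lexicon | None = None,
) -> list[Document]:
    """Generate a seed-deterministic labeled corpus.

    If no lexicon is supplied, one is built for ``spec.target_category``
    over the bundled fixture ontology. Raises
    :class:`~muscle_logic.errors.CorpusSpecError` if synonyms are
    requested but no member of the category has one.
    """
    if lexicon is None:
        from .fixture import build_fixture
        from .reasoner import classify

        onto = build_fixture()
        lexicon = build_lexicon(onto, classify(onto), spec.target_category)
    if lexicon.category != spec.target_category:
        raise CorpusSpecError(
            f"lexicon is for {lexicon.category}, spec targets {spec.target_category}"
        )

    label_of = lexicon.labels
    synonyms_of = lexicon.synonyms

    rng = random.Random(spec.seed)
    members = sorted(label_of, key=str)
    with_synonyms = [m for m in members if synonyms_of[m]]
    if spec.synonym_probability > 0 and spec.n_relevant > 0 and not with_synonyms:
        raise CorpusSpecError(
            f"synonym_probability={spec.synonym_probability} requested but no "
            f"member of {lexicon.category} has a synonym"
        )

    docs: list[Document] = []
    for i in range(spec.n_relevant):
        use_synonym = rng.random() < spec.synonym_probability
        pool = with_synonyms if use_synonym else members
        member = pool[rng.randrange(len(pool))]
        if use_synonym:
            syns = synonyms_of[member]
            phrase = syns[rng.randrange(len(syns))]
        else:
            phrase = label_of[member]
        template = _RELEVANT_TEMPLATES[rng.randrange(len(_RELEVANT_TEMPLATES))]
        body = template.format(phrase=phrase, topic=spec.topic_keyword)
        docs.append(
            Document(
                doc_id=f"rel-{i:04d}",
                title=f"Feeding muscle study {i}",
                body=body,
                truth_labels=frozenset({member}),
            )
        )
    for i in range(spec.n_distractor):
        template = _DISTRACTOR_TEMPLATES[rng.randrange(len(_DISTRACTOR_TEMPLATES))]
        body = template.format(topic=spec.topic_keyword)
        docs.append(
            Document(
                doc_id=f"dis-{i:04d}",
                title=f"Clinical note {i}",
                body=body,
                truth_labels=frozenset(),
            )
        )

    # construction guarantee: distractors never contain a lexicon phrase
    for doc in docs:
        if doc.truth_labels:
            continue
        for text in (doc.title, *split_sentences(doc.body)):
            toks = [t for t, _, _ in tokenize(text)]
            for key in lexicon.phrases:
                if _contains_subseq(toks, key):
                    raise CorpusSpecError(
                        f"distractor template produced lexicon phrase {' '.join(key)!r}"
                    )
    return docs


# --------------------------------------------------------------------------
# Engine comparison


@dataclass(frozen=True)
class QueryComparison:
    query: SearchQuery
    relevant: int
    keyword_hits: int
    keyword_true_positives: int
    semantic_hits: int
    semantic_true_positives: int

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return num / den if den else 1.0

    @property
    def keyword_recall(self) -> float:
        return self._ratio(self.keyword_true_positives, self.relevant)

    @property
    def semantic_recall(self) -> float:
        return self._ratio(self.semantic_true_positives, self.relevant)

    @property
    def keyword_precision(self) -> float:
        return self._ratio(self.keyword_true_positives, self.keyword_hits)

    @property
    def semantic_precision(self) -> float:
        return self._ratio(self.semantic_true_positives, self.semantic_hits)


def compare_engines(
    index: CorpusIndex, queries: Iterable[SearchQuery]
) -> list[QueryComparison]:
    """Score keyword vs semantic retrieval against generator ground truth.

    Each query is run in both modes; a retrieved document counts as a true
    positive if its truth labels intersect the members of any queried
    category. All indexed documents must carry truth labels.
    """
    for doc in index.documents.values():
        if doc.truth_labels is None:
            raise ConfigurationError(
                f"document {doc.doc_id!r} has no truth labels; "
                "compare_engines needs a generated corpus"
            )
    out: list[QueryComparison] = []
    for query in queries:
        members: set[Curie] = set()
        for cat in query.categories:
            if cat in index.lexicons:
                members |= index.lexicons[cat].members
            else:
                members.add(cat)
        relevant = {
            d.doc_id for d in index.documents.values() if d.truth_labels & members
        }
        kw_query = SearchQuery(
            keywords=query.keywords,
            categories=query.categories,
            scope=query.scope,
            mode="keyword",
        )
        sem_query = SearchQuery(
            keywords=query.keywords,
            categories=query.categories,
            scope=query.scope,
            mode="semantic",
        )
        kw_ids = {h.doc_id for h in search(index, kw_query)}
        sem_ids = {h.doc_id for h in search(index, sem_query)}
        out.append(
            QueryComparison(
                query=query,
                relevant=len(relevant),
                keyword_hits=len(kw_ids),
                keyword_true_positives=len(kw_ids & relevant),
                semantic_hits=len(sem_ids),
                semantic_true_positives=len(sem_ids & relevant),
            )
        )
    return out


# --------------------------------------------------------------------------
# JSON-lines corpus I/O


def write_corpus_jsonl(documents: Sequence[Document], path: str | Path) -> None:
    lines = []
    for doc in documents:
        record = {
            "doc_id": doc.doc_id,
            "title": doc.title,
            "body": doc.body,
        }
        if doc.truth_labels is not None:
            record["truth_labels"] = sorted(str(c) for c in doc.truth_labels)
        lines.append(json.dumps(record, ensure_ascii=False))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_corpus_jsonl(path: str | Path) -> list[Document]:
    docs = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        record = json.loads(line)
        truth = record.get("truth_labels")
        docs.append(
            Document(
                doc_id=record["doc_id"],
                title=record.get("title", ""),
                body=record["body"],
                truth_labels=(
                    frozenset(Curie.parse(c) for c in truth) if truth is not None else None
                ),
            )
        )
    return docs
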