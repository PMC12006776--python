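"""Normalization of review text into token streams.

The preparation chain runs in a fixed order:

    clean -> expand abbreviations -> tokenize + lemmatize
          -> stop-word removal -> domain-term removal

Order matters: short forms are expanded before noise-word removal so that
"yr" becomes "year" and is then dropped with the other calendar words, and
stop words are removed after tokenization so that expansions which produce
stop words ("i'm" -> "i am") are swept up.  Rerunning the chain on its own
output is a no-op from the tokenize stage onward.

The word "not" is deliberately kept despite being a standard stop word: in
reviews describing complaints and side effects, negation carries meaning
("not worth it", "not happy").
"""

from __future__ import annotations

import html
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# cleaning

_QUOTE_MAP = {
    "‘": "'", "’": "'", "‚": "'", "‛": "'",
    "“": '"', "”": '"', "„": '"',
    "–": "-", "—": "-", "−": "-",
    " ": " ", "…": "...",
}


def clean_text(text: str) -> str:
    """Decode HTML entities, normalize typographic punctuation to ASCII,
    strip control characters and collapse whitespace.

    The raw source corpus stores apostrophes as numeric character references
    (``I&#039;m``) and contains stray control characters; both are repaired
    here.  Returns the empty string for text that is nothing but noise
    (callers flag such documents).
    """
    out = html.unescape(text)
    # double-escaped entities ("&amp;#039;") appear in scraped data
    if "&" in out:
        out = html.unescape(out)
    for src, dst in _QUOTE_MAP.items():
        out = out.replace(src, dst)
    out = "".join(" " if unicodedata.category(ch) == "Cc" else ch for ch in out)
    return re.sub(r"\s+", " ", out).strip()


# ---------------------------------------------------------------------------
# abbreviation expansion

@dataclass
class AbbreviationCatalog:
    """Ordered mapping of short form -> long form.

    Keys are matched case-insensitively as whole tokens.  Short forms with
    several possible readings (e.g. "he's") carry their most common
    expansion.
    """

    entries: Mapping[str, str]
    _pattern: re.Pattern = field(init=False, repr=False)
    _lookup: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._lookup = {k.lower(): v for k, v in self.entries.items()}
        if len(self._lookup) < len(dict(self.entries)):
            raise ValueError("abbreviation catalog keys collide case-insensitively")
        # longest-first so "he's" wins over any prefix entry
        keys = sorted(self._lookup, key=len, reverse=True)
        alternation = "|".join(re.escape(k) for k in keys)
        self._pattern = re.compile(
            rf"(?<![A-Za-z0-9'])(?:{alternation})(?![A-Za-z0-9'])",
            re.IGNORECASE,
        )

    def __len__(self) -> int:
        return len(self._lookup)

    def expand(self, text: str) -> str:
        return self._pattern.sub(lambda m: self._lookup[m.group(0).lower()], text)


def expand_abbreviations(text: str, catalog: AbbreviationCatalog) -> str:
    """Replace every whole-token catalog short form by its long form."""
    return catalog.expand(text)


# ---------------------------------------------------------------------------
# tokenization and lemmatization

#: Irregular plurals and -ves forms the suffix rules cannot reach.
_LEMMA_EXCEPTIONS = {
    "women": "woman", "men": "man", "children": "child", "feet": "foot",
    "teeth": "tooth", "mice": "mouse", "geese": "goose",
    "lives": "life", "wives": "wife", "knives": "knife", "leaves": "leaf",
    "halves": "half", "shelves": "shelf",
}

#: Words ending in s that are not plurals (kept verbatim).
_NOT_PLURAL = frozenset({
    "news", "species", "series", "always", "perhaps", "yes", "plus",
    "menses", "os", "is", "was", "its", "this", "does", "goes",
    "clothes", "thanks", "diabetes", "herpes",
})


def lemmatize(token: str) -> str:
    """Reduce a lower-case token to its dictionary base form.

    A rule-based English noun lemmatizer: plural suffixes are stripped,
    everything else (including inflected verbs such as "started" or
    "taking") passes through unchanged, matching a noun-default
    dictionary lemmatizer on this domain's vocabulary.
    """
    if token in _LEMMA_EXCEPTIONS:
        return _LEMMA_EXCEPTIONS[token]
    if token in _NOT_PLURAL or len(token) <= 3 or not token.endswith("s"):
        return token
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith(("sses", "shes", "ches", "xes", "zes")):
        return token[:-2]
    if token.endswith(("ss", "us", "is")):
        return token
    return token[:-1]


@dataclass(frozen=True)
class TokenStream:
    """An ordered list of prepared tokens for one document."""

    doc_id: str
    tokens: tuple[str, ...]


_WORD_RE = re.compile(r"[a-z]+")


def tokenize_lemmatize(
    text: str,
    doc_id: str = "",
    stopwords: frozenset[str] = frozenset(),
) -> TokenStream:
    """Lower-case, keep alphabetic tokens of length >= 2, lemmatize.

    Tokens already on the stop list are left unlemmatized (they are dropped
    at the next stage; lemmatizing them could only move them off the list).
    """
    toks = []
    for raw in _WORD_RE.findall(text.lower()):
        if len(raw) < 2 and raw != "not":
            continue
        toks.append(raw if raw in stopwords else lemmatize(raw))
    return TokenStream(doc_id=doc_id, tokens=tuple(toks))


def remove_stopwords(stream: TokenStream, stoplist: frozenset[str]) -> TokenStream:
    """Drop stop-list tokens; "not" is always retained."""
    kept = tuple(t for t in stream.tokens if t == "not" or t not in stoplist)
    return TokenStream(doc_id=stream.doc_id, tokens=kept)


def remove_domain_terms(
    stream: TokenStream,
    product_terms: frozenset[str],
    noise_terms: frozenset[str],
) -> TokenStream:
    """Drop product/method names and the high-frequency calendar noise words,
    so extracted topics are product- and method-agnostic."""
    drop = product_terms | noise_terms
    kept = tuple(t for t in stream.tokens if t not in drop)
    return TokenStream(doc_id=stream.doc_id, tokens=kept)


# ---------------------------------------------------------------------------
# the full chain

@dataclass
class PrepConfig:
    """Word lists and catalogs driving the preparation chain."""

    abbreviations: AbbreviationCatalog
    stopwords: frozenset[str]
    product_terms: frozenset[str]
    noise_terms: frozenset[str]

    @classmethod
    def default(cls) -> "PrepConfig":
        from . import resources
        catalog = resources.default_method_catalog()
        return cls(
            abbreviations=resources.default_abbreviations(),
            stopwords=resources.default_stopwords(),
            product_terms=catalog.product_name_tokens()
            | resources.default_method_terms(),
            noise_terms=resources.default_noise_terms(),
        )


def prepare_document(text: str, doc_id: str, config: PrepConfig,
                     stop_stage: str = "domain") -> TokenStream:
    """Run the chain on one document.

    *stop_stage* controls where to stop: ``"stopwords"`` returns the stream
    after stop-word removal (the stage at which corpus word frequencies are
    tabulated), ``"domain"`` (default) runs the full chain.
    """
    cleaned = clean_text(text)
    expanded = expand_abbreviations(cleaned, config.abbreviations)
    stream = tokenize_lemmatize(expanded, doc_id=doc_id,
                                stopwords=config.stopwords)
    stream = remove_stopwords(stream, config.stopwords)
    if stop_stage == "stopwords":
        return stream
    return remove_domain_terms(stream, config.product_terms, config.noise_terms)


def prepare_corpus(
    docs: Iterable[tuple[str, str]],
    config: PrepConfig | None = None,
    stop_stage: str = "domain",
) -> tuple[list[TokenStream], list[str]]:
    """Prepare ``(doc_id, text)`` pairs; returns streams and the ids of
    documents that came out empty (flagged, not silently dropped)."""
    config = config if config is not None else PrepConfig.default()
    streams: list[TokenStream] = []
    empty: list[str] = []
    for doc_id, text in docs:
        stream = prepare_document(text, doc_id, config, stop_stage=stop_stage)
        if not stream.tokens:
            empty.append(doc_id)
        streams.append(stream)
    if empty:
        logger.warning("%d document(s) empty after preparation", len(empty))
    return streams, empty


def corpus_word_frequency(streams: Sequence[TokenStream]) -> pd.DataFrame:
    """Ranked token counts with corpus shares.

    Returns a frame with columns ``word``, ``count``, ``share`` sorted by
    descending count, ties alphabetical; shares sum to 1 over the whole
    vocabulary.
    """
    counts: dict[str, int] = {}
    for s in streams:
        for t in s.tokens:
            counts[t] = counts.get(t, 0) + 1
    total = sum(counts.values())
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {"word": [w for w, _ in rows],
         "count": [c for _, c in rows],
         "share": [c / total if total else 0.0 for _, c in rows]}
    )


def write_token_streams(streams: Sequence[TokenStream], tokens_path,
                        index_path) -> None:
    """Serialize streams as one whitespace-joined document per line, with a
    parallel doc-id index file."""
    with open(tokens_path, "w", encoding="utf-8") as fh:
        for s in streams:
            fh.write(" ".join(s.tokens) + "\n")
    with open(index_path, "w", encoding="utf-8") as fh:
        for s in streams:
            fh.write(s.doc_id + "\n")


def read_token_streams(tokens_path, index_path) -> list[TokenStream]:
    with open(index_path, "r", encoding="utf-8") as fh:
        ids = [ln.rstrip("\n") for ln in fh]
    out: list[TokenStream] = []
    with open(tokens_path, "r", encoding="utf-8") as fh:
        for doc_id, line in zip(ids, fh):
            toks = tuple(line.split())
            out.append(TokenStream(doc_id=doc_id, tokens=toks))
    if len(out) != len(ids):
        raise ValueError("token and index files have different lengths")
    return out
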