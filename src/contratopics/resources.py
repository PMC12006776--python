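"""Loaders for the catalogs and word lists shipped with the package.

Everything here is plain-text data under ``contratopics/data`` so that users
can copy, edit and point the pipeline at their own versions.  The shipped
files are starting points: the product->method catalog in particular covers
the brands named in published analyses of the Drugs.com corpus but makes no
claim of covering all 167 products reviewed there.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

from .ingest import MethodCatalog
from .textprep import AbbreviationCatalog

_DATA = resources.files("contratopics") / "data"


def _read_lines(path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8") if isinstance(path, (str, Path)) else path.read_text(encoding="utf-8")
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def default_stopwords() -> frozenset[str]:
    """The shipped English stop list (standard list snapshot, minus "not").

    Apostrophe-stripped variants ("dont", "shes", ...) are added because
    tokenization removes non-alphabetic characters before stop-word removal.
    """
    words = _read_lines(_DATA / "stopwords_en.txt")
    out = set(words)
    for w in words:
        stripped = "".join(ch for ch in w if ch.isalpha())
        if stripped:
            out.add(stripped)
    out.discard("not")
    return frozenset(out)


def default_noise_terms() -> frozenset[str]:
    """High-frequency corpus words carrying no side-effect signal."""
    return frozenset(_read_lines(_DATA / "noise_terms.txt"))


def default_method_terms() -> frozenset[str]:
    """Generic contraceptive-method words (iud, pill, ...) removed from text."""
    return frozenset(_read_lines(_DATA / "method_terms.txt"))


def default_method_catalog() -> MethodCatalog:
    """The shipped product -> contraceptive-method catalog."""
    with (_DATA / "method_catalog.csv").open("r", encoding="utf-8") as fh:
        entries = list(csv.DictReader(fh))
    with (_DATA / "ambiguous_generics.csv").open("r", encoding="utf-8") as fh:
        ambiguous = [row["drug_name"] for row in csv.DictReader(fh)]
    return MethodCatalog.from_rows(entries, ambiguous_generics=ambiguous)


def load_method_catalog(catalog_csv, ambiguous_csv=None) -> MethodCatalog:
    """Load a user-supplied catalog (columns drug_name, method, is_brand)."""
    with open(catalog_csv, "r", encoding="utf-8") as fh:
        entries = list(csv.DictReader(fh))
    ambiguous: list[str] = []
    if ambiguous_csv is not None:
        with open(ambiguous_csv, "r", encoding="utf-8") as fh:
            ambiguous = [row["drug_name"] for row in csv.DictReader(fh)]
    return MethodCatalog.from_rows(entries, ambiguous_generics=ambiguous)


def default_abbreviations() -> AbbreviationCatalog:
    """The shipped abbreviation/short-form catalog (>110 entries)."""
    with (_DATA / "abbreviations.csv").open("r", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    return AbbreviationCatalog({r["short_form"]: r["long_form"] for r in rows})


def load_abbreviations(path) -> AbbreviationCatalog:
    with open(path, "r", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    return AbbreviationCatalog({r["short_form"]: r["long_form"] for r in rows})


def default_topic_lexicons() -> dict[str, list[str]]:
    """Themed word lists used by the synthetic generator, keyed by topic name."""
    lex: dict[str, list[str]] = {}
    with (_DATA / "topic_lexicons.csv").open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            lex.setdefault(row["topic"], []).append(row["word"])
    return lex


def default_background_lexicon() -> list[str]:
    return _read_lines(_DATA / "background_lexicon.txt")


def default_positive_lexicon() -> list[str]:
    return _read_lines(_DATA / "positive_lexicon.txt")
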