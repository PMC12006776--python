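"""Reading and cleansing contraceptive drug-review tables.

The input is the tab-separated dialect used by the Drugs.com review corpus in
the UCI Machine Learning Repository: a header row, a free-text ``review``
field that is double-quoted (embedded quotes doubled, embedded tabs and
newlines kept inside the quotes), and columns

    uniqueID  drugName  condition  review  rating  date  usefulCount

Cleansing follows four stages, each of which records its removals in a
:class:`RunLog` so that input and output row counts always reconcile:

1. keep only rows whose condition matches a target label (case-insensitive),
2. collapse duplicate reviews (same normalized text, rating and date) that
   arise from a product being listed under both its brand and generic name,
   keeping the brand-name record,
3. drop reviews of generic names that cannot be tied to one contraceptive
   method (e.g. bare "levonorgestrel", which may be a hormonal IUD or
   emergency contraception),
4. label every remaining review with one of eleven contraceptive methods,
   drop the two methods with negligible review counts (emergency
   contraception, spermicides), and flag ratings of 5 or lower as
   unfavorable.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: The nine contraceptive-method labels retained for analysis.
RETAINED_METHODS = (
    "COCP",
    "POP",
    "OCP-91-day",
    "implant",
    "hormonal IUD",
    "copper IUD",
    "vaginal ring",
    "shot",
    "patch",
)

#: Methods with too few reviews to analyze; dropped during categorization.
EXCLUDED_METHODS = frozenset({"emergency contraception", "spermicide"})

ALL_METHODS = tuple(RETAINED_METHODS) + tuple(sorted(EXCLUDED_METHODS))

#: Threshold on the 1-10 rating scale at or below which a review is
#: unfavorable.  Deliberately wide: scores of 4-5 are neutral-to-negative but
#: still tend to describe unpleasant experiences.
UNFAVORABLE_MAX_RATING = 5


@dataclass(frozen=True)
class TableDialect:
    """Column names and delimiter of an input review table."""

    delimiter: str = "\t"
    record_id: str = "uniqueID"
    drug_name: str = "drugName"
    condition: str = "condition"
    text: str = "review"
    rating: str = "rating"
    date: str = "date"
    useful_count: str = "usefulCount"

    @property
    def required_columns(self) -> tuple[str, ...]:
        return (
            self.record_id,
            self.drug_name,
            self.condition,
            self.text,
            self.rating,
            self.date,
            self.useful_count,
        )


UCI_DIALECT = TableDialect()


@dataclass(frozen=True)
class RawReview:
    """One row of an input review table."""

    record_id: str
    drug_name: str
    condition: str
    text: str
    rating: int
    date: str
    useful_count: int


@dataclass(frozen=True)
class Review(RawReview):
    """A cleansed review carrying its method label and unfavorable flag."""

    method: str = ""
    unfavorable: bool = False


@dataclass
class MethodCatalog:
    """Maps product names to contraceptive methods.

    ``entries`` is keyed by lower-cased drug name; each value is a
    ``(method, is_brand)`` pair.  ``ambiguous_generics`` lists generic names
    that cannot be tied to a single method and are dropped outright.
    """

    entries: dict[str, tuple[str, bool]]
    ambiguous_generics: frozenset[str] = frozenset()
    excluded_methods: frozenset[str] = EXCLUDED_METHODS

    def __post_init__(self) -> None:
        bad = {m for m, _ in self.entries.values()} - set(ALL_METHODS)
        if bad:
            raise ValueError(f"unknown method labels in catalog: {sorted(bad)}")
        if not self.excluded_methods <= EXCLUDED_METHODS:
            raise ValueError("excluded_methods must be a subset of "
                             f"{sorted(EXCLUDED_METHODS)}")

    @classmethod
    def from_rows(
        cls,
        rows: Iterable[Mapping[str, str]],
        ambiguous_generics: Iterable[str] = (),
    ) -> "MethodCatalog":
        entries = {
            row["drug_name"].strip().lower():
                (row["method"].strip(), str(row["is_brand"]).strip() in ("1", "true", "True"))
            for row in rows
        }
        return cls(entries=entries,
                   ambiguous_generics=frozenset(g.strip().lower() for g in ambiguous_generics))

    def lookup(self, drug_name: str) -> tuple[str, bool] | None:
        return self.entries.get(drug_name.strip().lower())

    def is_brand(self, drug_name: str) -> bool:
        entry = self.lookup(drug_name)
        return bool(entry and entry[1])

    def product_name_tokens(self) -> frozenset[str]:
        """All alphabetic tokens occurring in catalog drug names (lower-cased)."""
        toks: set[str] = set()
        for name in self.entries:
            toks.update(re.findall(r"[a-z]+", name))
        return frozenset(toks)


class RunLog:
    """Counts and removal records accumulated across pipeline stages."""

    def __init__(self) -> None:
        self.counts: dict[str, int] = {}
        self.records: dict[str, list] = {}

    def count(self, key: str, n: int = 1) -> None:
        self.counts[key] = self.counts.get(key, 0) + n

    def record(self, key: str, item) -> None:
        self.records.setdefault(key, []).append(item)
        self.count(key)

    def as_dict(self) -> dict:
        return {"counts": dict(self.counts),
                "records": {k: list(v) for k, v in self.records.items()}}

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.as_dict(), fh, indent=2, sort_keys=True)


def _parse_rating(value: str) -> int | None:
    try:
        x = float(value)
    except (TypeError, ValueError):
        return None
    if not x.is_integer():
        return None
    r = int(x)
    return r if 1 <= r <= 10 else None


def read_raw_reviews(
    path,
    dialect: TableDialect = UCI_DIALECT,
    log: RunLog | None = None,
) -> list[RawReview]:
    """Parse a review table into :class:`RawReview` records.

    Quoted text fields containing delimiters and newlines are parsed intact.
    Rows with an unparseable or out-of-range rating, or with empty review
    text, are rejected and reported with their line numbers.

    Raises
    ------
    ValueError
        If a required column is missing from the header.
    """
    log = log if log is not None else RunLog()
    out: list[RawReview] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter, quotechar='"',
                            doublequote=True)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, no header row") from None
        missing = [c for c in dialect.required_columns if c not in header]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        idx = {c: header.index(c) for c in dialect.required_columns}

        for row in reader:
            line_no = reader.line_num
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) < len(header):
                logger.warning("line %d: %d fields, expected %d - row rejected",
                               line_no, len(row), len(header))
                log.record("rows_malformed", line_no)
                continue
            rating = _parse_rating(row[idx[dialect.rating]])
            if rating is None:
                logger.warning("line %d: unparseable rating %r - row rejected",
                               line_no, row[idx[dialect.rating]])
                log.record("rows_bad_rating", line_no)
                continue
            text = row[idx[dialect.text]]
            if not text.strip():
                log.record("rows_empty_text", line_no)
                continue
            try:
                useful = int(float(row[idx[dialect.useful_count]]))
            except ValueError:
                useful = 0
            out.append(RawReview(
                record_id=row[idx[dialect.record_id]],
                drug_name=row[idx[dialect.drug_name]],
                condition=row[idx[dialect.condition]],
                text=text,
                rating=rating,
                date=row[idx[dialect.date]],
                useful_count=useful,
            ))
    log.count("rows_parsed", len(out))
    return out


def filter_condition(
    reviews: Sequence[RawReview],
    condition_label: str,
    log: RunLog | None = None,
) -> list[RawReview]:
    """Keep reviews whose condition equals *condition_label* (case-insensitive,
    whitespace-trimmed)."""
    if not condition_label.strip():
        raise ValueError("condition_label must be nonempty")
    target = condition_label.strip().lower()
    kept = [r for r in reviews if r.condition.strip().lower() == target]
    if log is not None:
        log.count("condition_removed", len(reviews) - len(kept))
        log.count("condition_kept", len(kept))
    if reviews and not kept:
        logger.warning("no reviews match condition %r", condition_label)
    return kept


def _dup_key(r: RawReview) -> tuple[str, int, str]:
    text = re.sub(r"\s+", " ", r.text.strip().lower())
    return (text, r.rating, r.date)


def deduplicate(
    reviews: Sequence[RawReview],
    catalog: MethodCatalog | None = None,
    log: RunLog | None = None,
) -> list[RawReview]:
    """Collapse duplicate listings of the same review.

    Duplicates share normalized text, rating and date (the signature of one
    review posted under both a brand and its generic name).  Among duplicates
    the brand-name record is kept - brand names carry more detail, since
    products sharing an active ingredient differ in dose and schedule.
    Output order follows the first occurrence of each key.
    """
    groups: dict[tuple, list[RawReview]] = {}
    order: list[tuple] = []
    for r in reviews:
        key = _dup_key(r)
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(r)

    out: list[RawReview] = []
    for key in order:
        group = groups[key]
        survivor = group[0]
        if len(group) > 1 and catalog is not None:
            branded = [g for g in group if catalog.is_brand(g.drug_name)]
            if branded:
                survivor = branded[0]
        out.append(survivor)
    if log is not None:
        log.count("duplicates_removed", len(reviews) - len(out))
        log.count("unique_reviews", len(out))
    return out


def drop_ambiguous_generics(
    reviews: Sequence[RawReview],
    catalog: MethodCatalog,
    log: RunLog | None = None,
) -> list[RawReview]:
    """Remove reviews filed under a generic name that maps to more than one
    contraceptive method; removals are counted in the run log."""
    out: list[RawReview] = []
    for r in reviews:
        if r.drug_name.strip().lower() in catalog.ambiguous_generics:
            if log is not None:
                log.record("ambiguous_generic_removed", r.record_id)
            logger.info("dropping ambiguous generic %r (record %s)",
                        r.drug_name, r.record_id)
        else:
            out.append(r)
    return out


def categorize_and_prune(
    reviews: Sequence[RawReview],
    catalog: MethodCatalog,
    log: RunLog | None = None,
) -> list[Review]:
    """Label each review with its contraceptive method and unfavorable flag.

    Reviews of excluded methods (emergency contraception, spermicides) are
    dropped; reviews whose drug name is absent from the catalog are routed to
    the run log's ``unmapped`` report and the run continues.
    """
    out: list[Review] = []
    for r in reviews:
        entry = catalog.lookup(r.drug_name)
        if entry is None:
            if log is not None:
                log.record("unmapped", {"record_id": r.record_id,
                                        "drug_name": r.drug_name})
            logger.warning("drug %r not in catalog (record %s)",
                           r.drug_name, r.record_id)
            continue
        method, _ = entry
        if method in catalog.excluded_methods:
            if log is not None:
                log.record("excluded_method_removed", r.record_id)
            continue
        out.append(Review(
            **{f: getattr(r, f) for f in (
                "record_id", "drug_name", "condition", "text",
                "rating", "date", "useful_count")},
            method=method,
            unfavorable=r.rating <= UNFAVORABLE_MAX_RATING,
        ))
    if log is not None:
        log.count("categorized", len(out))
        log.count("unfavorable", sum(r.unfavorable for r in out))
    return out


def ingest_corpus(
    path,
    catalog: MethodCatalog,
    condition_label: str = "birth control",
    dialect: TableDialect = UCI_DIALECT,
    log: RunLog | None = None,
) -> tuple[list[Review], RunLog]:
    """Run the full cleansing chain on one or more input tables.

    *path* may be a single path or a sequence of paths (e.g. the train and
    test splits of the source corpus, which are analyzed jointly).
    """
    log = log if log is not None else RunLog()
    paths = [path] if isinstance(path, (str, bytes)) or hasattr(path, "__fspath__") else list(path)
    raw: list[RawReview] = []
    for p in paths:
        raw.extend(read_raw_reviews(p, dialect=dialect, log=log))
    log.count("rows_input_total", len(raw))
    filtered = filter_condition(raw, condition_label, log=log)
    unique = deduplicate(filtered, catalog=catalog, log=log)
    unambiguous = drop_ambiguous_generics(unique, catalog, log=log)
    corpus = categorize_and_prune(unambiguous, catalog, log=log)
    return corpus, log


def write_corpus(reviews: Sequence[Review], path,
                 dialect: TableDialect = UCI_DIALECT) -> None:
    """Write a cleansed corpus as TSV with added method/unfavorable columns."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter, quotechar='"',
                            doublequote=True, quoting=csv.QUOTE_MINIMAL,
                            lineterminator="\n")
        writer.writerow(list(dialect.required_columns) + ["method", "unfavorable"])
        for r in reviews:
            writer.writerow([r.record_id, r.drug_name, r.condition, r.text,
                             r.rating, r.date, r.useful_count, r.method,
                             int(r.unfavorable)])


def read_corpus(path, dialect: TableDialect = UCI_DIALECT) -> list[Review]:
    """Reload a corpus written by :func:`write_corpus`."""
    out: list[Review] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter, quotechar='"',
                                doublequote=True)
        for row in reader:
            out.append(Review(
                record_id=row[dialect.record_id],
                drug_name=row[dialect.drug_name],
                condition=row[dialect.condition],
                text=row[dialect.text],
                rating=int(row[dialect.rating]),
                date=row[dialect.date],
                useful_count=int(row[dialect.useful_count]),
                method=row["method"],
                unfavorable=bool(int(row["unfavorable"])),
            ))
    return out
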