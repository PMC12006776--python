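"""Descriptive statistics linking ratings, contraceptive methods and topics.

These are deliberately descriptive: the source data are self-selected online
reviews, so no significance testing or confounder adjustment is attempted.
The quantities computed here are

* the rating histogram over the 1-10 scale, with its mean and population SD,
* per-method review counts, rating mean/SD and unfavorable shares,
* the distribution of dominant topics within each method's unfavorable
  reviews, optionally *scaled* by the method's unfavorable rate to give the
  corpus-wide prevalence of a complaint, and
* per-topic summaries of the 1-5 ratings of unfavorable reviews.

Percentages mirror printed-table conventions: rounding is half away from
zero at the table's precision (e.g. 234/800 unfavorable prints as 29.3%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .ingest import RETAINED_METHODS, Review
from .topics import UNASSIGNED

logger = logging.getLogger(__name__)


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round with ties going away from zero (printed-table convention),
    unlike Python's builtin banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RatingHistogram:
    """Counts of each rating value 1..10."""

    counts: dict[int, int]

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(range(1, 11))
        if bad:
            raise ValueError(f"ratings outside 1..10: {sorted(bad)}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative counts")
        self.counts = {r: int(self.counts.get(r, 0)) for r in range(1, 11)}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def shares(self) -> dict[int, float]:
        t = self.total
        return {r: (c / t if t else 0.0) for r, c in self.counts.items()}

    def n_unfavorable(self, threshold: int = 5) -> int:
        return sum(c for r, c in self.counts.items() if r <= threshold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rating": list(self.counts),
                             "count": list(self.counts.values()),
                             "share": list(self.shares().values())})


def rating_histogram(reviews: Sequence[Review]) -> RatingHistogram:
    """Exact rating counts over a corpus."""
    counts: dict[int, int] = {}
    for r in reviews:
        counts[r.rating] = counts.get(r.rating, 0) + 1
    return RatingHistogram(counts=counts)


def histogram_mean_sd(hist: RatingHistogram) -> tuple[float, float]:
    """Mean and population standard deviation of the binned ratings."""
    total = hist.total
    if total == 0:
        raise ValueError("empty histogram has no mean")
    ratings = np.array(list(hist.counts), dtype=float)
    counts = np.array(list(hist.counts.values()), dtype=float)
    mean = float(ratings @ counts / total)
    var = float(counts @ (ratings - mean) ** 2 / total)
    return mean, float(np.sqrt(var))


def method_summary(reviews: Sequence[Review]) -> pd.DataFrame:
    """Per-method counts, rating mean/SD and unfavorable shares.

    Indexed by method, ordered by descending review count.  SDs are
    population SDs, matching the descriptive use of these tables.
    """
    df = pd.DataFrame({
        "method": [r.method for r in reviews],
        "rating": [r.rating for r in reviews],
        "unfavorable": [r.unfavorable for r in reviews],
    })
    total = len(df)
    rows = []
    for method, grp in df.groupby("method"):
        n = len(grp)
        rows.append({
            "method": method,
            "n_reviews": n,
            "share_of_corpus": n / total,
            "mean_rating": float(grp["rating"].mean()),
            "sd_rating": float(grp["rating"].std(ddof=0)),
            "n_unfavorable": int(grp["unfavorable"].sum()),
            "unfavorable_share": float(grp["unfavorable"].mean()),
        })
    out = pd.DataFrame(rows).sort_values("n_reviews", ascending=False)
    return out.set_index("method")


def topic_share_by_method(
    unfavorable_reviews: Sequence[Review],
    labels: Sequence[int],
    topic_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Dominant-topic shares within each method's unfavorable reviews.

    Rows are methods, columns topics; each row sums to 1.  Unassigned
    documents are excluded and reported; a method with no unfavorable
    reviews yields a row of NaN with a warning.
    """
    if len(unfavorable_reviews) != len(labels):
        raise ValueError("reviews and labels differ in length")
    labels = np.asarray(labels)
    assigned = labels != UNASSIGNED
    if (~assigned).any():
        logger.warning("excluding %d unassigned document(s) from topic shares",
                       int((~assigned).sum()))
    methods = [r.method for r, a in zip(unfavorable_reviews, assigned) if a]
    lab = labels[assigned]
    k = int(lab.max()) + 1 if lab.size else 0
    cols = list(topic_names) if topic_names is not None else list(range(k))
    present = sorted({r.method for r in unfavorable_reviews},
                     key=lambda m: RETAINED_METHODS.index(m)
                     if m in RETAINED_METHODS else len(RETAINED_METHODS))
    table = pd.DataFrame(0.0, index=present, columns=cols)
    counts = pd.DataFrame(0, index=present, columns=cols)
    for m, t in zip(methods, lab):
        counts.loc[m, cols[t]] += 1
    for m in present:
        n = counts.loc[m].sum()
        if n == 0:
            logger.warning("method %r has no assigned unfavorable reviews", m)
            table.loc[m] = np.nan
        else:
            table.loc[m] = counts.loc[m] / n
    return table


def scaled_topic_share(share: float, unfavorable_rate: float) -> float:
    """Corpus-wide prevalence of a complaint: its share among a method's
    unfavorable reviews times that method's unfavorable rate.

    Additive over disjoint topic sets *before* scaling, so a sum of shares
    may be passed directly.
    """
    if not 0.0 <= share <= 1.0:
        raise ValueError(f"share {share} outside [0, 1]")
    if not 0.0 <= unfavorable_rate <= 1.0:
        raise ValueError(f"unfavorable_rate {unfavorable_rate} outside [0, 1]")
    return share * unfavorable_rate


def topic_rating_summary(
    unfavorable_reviews: Sequence[Review],
    labels: Sequence[int],
    topic_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-dominant-topic summaries of the (1-5) ratings of unfavorable
    reviews: n, quartiles (linear interpolation), mean and population SD."""
    if len(unfavorable_reviews) != len(labels):
        raise ValueError("reviews and labels differ in length")
    labels = np.asarray(labels)
    ratings = np.array([r.rating for r in unfavorable_reviews], dtype=float)
    k = int(labels[labels != UNASSIGNED].max()) + 1 if (labels != UNASSIGNED).any() else 0
    names = list(topic_names) if topic_names is not None else list(range(k))
    rows = []
    for t in range(k):
        vals = ratings[labels == t]
        if vals.size == 0:
            logger.warning("topic %s has no members", names[t])
            rows.append({"topic": names[t], "n": 0, "q1": np.nan,
                         "median": np.nan, "q3": np.nan, "mean": np.nan,
                         "sd": np.nan})
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75], method="linear")
        rows.append({"topic": names[t], "n": int(vals.size),
                     "q1": float(q1), "median": float(med), "q3": float(q3),
                     "mean": float(vals.mean()),
                     "sd": float(vals.std(ddof=0))})
    return pd.DataFrame(rows).set_index("topic")


def bundle_report(
    hist: RatingHistogram,
    methods: pd.DataFrame,
    shares: pd.DataFrame,
    scaled: pd.DataFrame | None,
    topic_ratings: pd.DataFrame,
) -> dict:
    """Assemble the single JSON-serializable report covering all four
    research questions (overall ratings, topics, per-method shares,
    topic-rating association)."""
    mean, sd = histogram_mean_sd(hist)
    out = {
        "ratings": {
            "histogram": {str(r): c for r, c in hist.counts.items()},
            "total": hist.total,
            "mean": mean,
            "sd": sd,
            "n_unfavorable": hist.n_unfavorable(),
            "unfavorable_share": hist.n_unfavorable() / hist.total if hist.total else 0.0,
        },
        "methods": methods.reset_index().to_dict(orient="records"),
        "topic_shares_by_method": shares.to_dict(orient="index"),
        "topic_rating_summary": topic_ratings.reset_index().to_dict(orient="records"),
    }
    if scaled is not None:
        out["scaled_topic_shares_by_method"] = scaled.to_dict(orient="index")
    return out


def scaled_share_table(shares: pd.DataFrame,
                       methods: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`scaled_topic_share` to every cell of a share table using
    each method's unfavorable rate."""
    out = shares.copy()
    for m in out.index:
        rate = float(methods.loc[m, "unfavorable_share"])
        out.loc[m] = [scaled_topic_share(s, rate) if not np.isnan(s) else np.nan
                      for s in shares.loc[m]]
    return out
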