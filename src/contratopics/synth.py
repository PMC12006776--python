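"""Synthetic review corpora with planted topic structure.

The generator emulates the statistical shape of a contraceptive-review
corpus so the whole pipeline can be exercised without the study data:

* every review gets a planted primary topic drawn from its method's
  topic-prevalence weights, and a generative component (favorable or
  unfavorable, mixed at ``unfavorable_mix``);
* unfavorable reviews draw a ``separation`` fraction of their tokens from
  the planted topic's lexicon and the rest from background vocabulary and
  other topics; favorable reviews draw from a positive lexicon instead;
* ratings come from the component: unfavorable reviews from a per-topic
  left-skewed distribution on 1..5 whose means span roughly 2.3-2.9,
  favorable reviews from a high distribution on 6..10 - echoing the
  U-shaped, topic-dependent rating structure seen in real review corpora;
* the surface text carries stop-word fillers, occasional contractions
  (including HTML-entity-mangled apostrophes) and plural forms, so the
  cleaning, expansion and lemmatization stages all have work to do.

Documents are bags of words dressed up as sentences - there is no grammar,
which is sufficient for a bag-of-words pipeline and is the main way these
corpora are easier than real ones.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

#: Canonical order of the shipped topic lexicons; a k-topic corpus uses the
#: first k.
TOPIC_ORDER = (
    "weight_gain",
    "skin_problems",
    "loss_of_libido",
    "mental_health",
    "menstrual_irregularities",
    "cramps_pain",
    "continuous_bleeding",
    "multiple_cause",
)

#: Per-method prevalence over the 8 canonical topics (rows sum to 1),
#: echoing the observed pattern: IUD complaints concentrate on cramps/pain,
#: implant and shot complaints on continuous bleeding, POP and 91-day-cycle
#: pills on menstrual irregularities, rings/patches on the mixed topic.
METHOD_TOPIC_WEIGHTS: dict[str, tuple[float, ...]] = {
    "COCP":         (0.10, 0.19, 0.10, 0.12, 0.12, 0.08, 0.08, 0.21),
    "implant":      (0.12, 0.08, 0.10, 0.12, 0.14, 0.09, 0.21, 0.14),
    "hormonal IUD": (0.07, 0.08, 0.08, 0.08, 0.12, 0.42, 0.08, 0.07),
    "copper IUD":   (0.08, 0.08, 0.08, 0.08, 0.14, 0.38, 0.09, 0.07),
    "vaginal ring": (0.06, 0.08, 0.25, 0.08, 0.06, 0.06, 0.05, 0.36),
    "shot":         (0.14, 0.06, 0.08, 0.10, 0.17, 0.08, 0.19, 0.18),
    "patch":        (0.10, 0.18, 0.08, 0.10, 0.08, 0.06, 0.04, 0.36),
    "POP":          (0.12, 0.08, 0.08, 0.12, 0.21, 0.08, 0.17, 0.14),
    "OCP-91-day":   (0.08, 0.10, 0.06, 0.08, 0.24, 0.08, 0.24, 0.12),
}

#: Relative review volume per method (normalized at use).
METHOD_VOLUME: dict[str, float] = {
    "COCP": 0.441, "implant": 0.225, "hormonal IUD": 0.147,
    "vaginal ring": 0.042, "copper IUD": 0.041, "shot": 0.033,
    "patch": 0.026, "POP": 0.022, "OCP-91-day": 0.021,
}

#: Stop-word fillers woven between content tokens.
_FILLERS = ("i", "the", "my", "and", "it", "was", "is", "a", "to", "so",
            "of", "on", "in", "that", "this", "have", "had", "been", "me")

#: Contractions occasionally inserted verbatim; each expands to stop words
#: only, and one carries the numeric-entity apostrophe seen in scraped text.
_CONTRACTIONS = ("I'm", "I've", "it's", "that's", "I&#039;m")

#: Favorable-component rating distribution on 6..10 (mean 8.76).
_FAVORABLE_P = (0.08, 0.10, 0.18, 0.26, 0.38)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    ``separation`` is the probability mass a document's content tokens draw
    from its planted topic's lexicon; the remainder is split 70/30 between
    background vocabulary and other topics' lexicons.  Unfavorable rating
    means are spaced over ``unfavorable_mean_range`` across topics via a
    mixture of a point mass at 1 and a uniform on 1..5.
    """

    n_reviews: int = 500
    k_topics: int = 4
    separation: float = 0.9
    doc_length: float = 40.0
    unfavorable_mix: float = 0.43
    unfavorable_mean_range: tuple[float, float] = (2.3, 2.9)
    methods: Mapping[str, float] = dc_field(
        default_factory=lambda: dict(METHOD_VOLUME))
    method_topic_weights: Mapping[str, Sequence[float]] = dc_field(
        default_factory=lambda: {m: w for m, w in METHOD_TOPIC_WEIGHTS.items()})
    filler_rate: float = 0.25
    plural_rate: float = 0.08
    contraction_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.separation <= 1.0:
            raise ValueError("separation must be in (0, 1]")
        if not 0.0 <= self.unfavorable_mix <= 1.0:
            raise ValueError("unfavorable_mix must be in [0, 1]")
        if self.n_reviews < 1:
            raise ValueError("n_reviews must be positive")
        if not 1 <= self.k_topics <= len(TOPIC_ORDER):
            raise ValueError(f"k_topics must be in 1..{len(TOPIC_ORDER)}")

    @property
    def topic_names(self) -> tuple[str, ...]:
        return TOPIC_ORDER[: self.k_topics]


def _unfavorable_rating_p(mean: float) -> np.ndarray:
    """Distribution on 1..5 as a mixture of a point mass at 1 and a uniform,
    with the requested mean (left-skewed, first quartile at 1)."""
    lam = (3.0 - mean) / 2.0
    if not 0.0 <= lam < 1.0:
        raise ValueError(f"unfavorable mean {mean} outside achievable (1, 3]")
    p = np.full(5, (1.0 - lam) / 5.0)
    p[0] += lam
    return p


def _pluralizable(word: str) -> bool:
    return (len(word) > 3
            and not word.endswith(("s", "x", "z", "y", "ch", "sh"))
            and word[-1].isalpha())


def _render(tokens: list[str], rng: np.random.Generator,
            cfg: GeneratorConfig) -> str:
    """Dress a bag of content tokens up as review text."""
    words: list[str] = []
    for tok in tokens:
        if rng.random() < cfg.filler_rate:
            words.append(str(rng.choice(_FILLERS)))
        if cfg.plural_rate and _pluralizable(tok) and rng.random() < cfg.plural_rate:
            tok = tok + "s"
        words.append(tok)
    if cfg.contraction_rate and rng.random() < cfg.contraction_rate and words:
        pos = int(rng.integers(0, len(words) + 1))
        words.insert(pos, str(rng.choice(_CONTRACTIONS)))
    # sentence breaks every 9-14 words
    out: list[str] = []
    i = 0
    while i < len(words):
        n = int(rng.integers(9, 15))
        sentence = words[i:i + n]
        sentence[0] = sentence[0][:1].upper() + sentence[0][1:]
        out.append(" ".join(sentence) + ".")
        i += n
    return " ".join(out)


_MONTHS = ("January", "February", "March", "April", "May", "June", "July",
           "August", "September", "October", "November", "December")


def generate_corpus(
    config: GeneratorConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a review table in the UCI TSV schema plus its ground truth.

    Returns ``(reviews, truth)``: *reviews* has columns uniqueID, drugName,
    condition, review, rating, date, usefulCount (condition is always
    "Birth Control"); *truth* has one row per review with the planted topic,
    method and generative component, joinable on record_id.  Deterministic
    given ``config.seed``.
    """
    from . import resources

    cfg = config if config is not None else GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)

    lexicons = resources.default_topic_lexicons()
    missing = [t for t in cfg.topic_names if t not in lexicons]
    if missing:
        raise ValueError(f"no lexicon for topic(s) {missing}")
    topic_words = [lexicons[t] for t in cfg.topic_names]
    background = resources.default_background_lexicon()
    positive = resources.default_positive_lexicon()

    catalog = resources.default_method_catalog()
    brands_by_method: dict[str, list[str]] = {}
    for name, (method, is_brand) in sorted(catalog.entries.items()):
        if is_brand:
            brands_by_method.setdefault(method, []).append(name.title())

    methods = sorted(cfg.methods)
    volume = np.array([cfg.methods[m] for m in methods], dtype=float)
    volume /= volume.sum()
    topic_p = {}
    for m in methods:
        w = np.asarray(cfg.method_topic_weights[m], dtype=float)[: cfg.k_topics]
        if w.sum() <= 0:
            raise ValueError(f"method {m} has no mass on the first "
                             f"{cfg.k_topics} topics")
        topic_p[m] = w / w.sum()

    lo, hi = cfg.unfavorable_mean_range
    means = np.linspace(lo, hi, cfg.k_topics) if cfg.k_topics > 1 else np.array([(lo + hi) / 2])
    unfav_p = [_unfavorable_rating_p(mu) for mu in means]

    reviews, truth = [], []
    for i in range(cfg.n_reviews):
        record_id = str(10_000 + i)
        m = methods[int(rng.choice(len(methods), p=volume))]
        t = int(rng.choice(cfg.k_topics, p=topic_p[m]))
        unfav = bool(rng.random() < cfg.unfavorable_mix)

        length = max(8, int(rng.poisson(cfg.doc_length)))
        tokens: list[str] = []
        for _ in range(length):
            u = rng.random()
            if unfav:
                if u < cfg.separation:
                    pool = topic_words[t]
                elif u < cfg.separation + (1 - cfg.separation) * 0.7 or cfg.k_topics == 1:
                    pool = background
                else:
                    other = int(rng.choice([j for j in range(cfg.k_topics) if j != t]))
                    pool = topic_words[other]
            else:
                pool = positive if u < cfg.separation else background
            tokens.append(str(rng.choice(pool)))
        text = _render(tokens, rng, cfg)

        if unfav:
            rating = 1 + int(rng.choice(5, p=unfav_p[t]))
        else:
            rating = 6 + int(rng.choice(5, p=np.asarray(_FAVORABLE_P)))

        date = f"{_MONTHS[int(rng.integers(0, 12))]} {int(rng.integers(1, 29))}, {int(rng.integers(2009, 2018))}"
        brands = brands_by_method.get(m)
        if not brands:
            raise ValueError(f"shipped catalog has no brand for method {m!r}")
        drug = brands[int(rng.integers(0, len(brands)))]

        reviews.append({
            "uniqueID": record_id, "drugName": drug,
            "condition": "Birth Control", "review": text,
            "rating": rating, "date": date,
            "usefulCount": int(rng.poisson(10)),
        })
        truth.append({
            "record_id": record_id, "topic": cfg.topic_names[t],
            "method": m, "component": "unfavorable" if unfav else "favorable",
        })
    return pd.DataFrame(reviews), pd.DataFrame(truth)


def write_corpus_tsv(reviews: pd.DataFrame, path) -> None:
    """Write the generated table in the UCI dialect (tab-separated, review
    field quoted with embedded quotes doubled)."""
    reviews.to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_MINIMAL,
                   lineterminator="\n")


def write_truth_csv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False, lineterminator="\n")


def simulate_to_dir(config: GeneratorConfig, out_dir) -> tuple[Path, Path]:
    """Generate and serialize one corpus; returns the two file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reviews, truth = generate_corpus(config)
    rp, tp = out / "reviews.tsv", out / "truth.csv"
    write_corpus_tsv(reviews, rp)
    write_truth_csv(truth, tp)
    return rp, tp


def evaluate_recovery(
    labels: Mapping[str, int] | pd.Series,
    truth: pd.DataFrame,
) -> float:
    """Permutation-matched accuracy of fitted dominant-topic labels against
    the planted topics.

    *labels* maps record_id -> fitted topic index (unassigned documents may
    carry a negative sentinel and can never match).  The best one-to-one
    matching of fitted indices to planted topics is found by solving the
    assignment problem on the confusion matrix; accuracy is the matched
    fraction.
    """
    labels = pd.Series(labels)
    truth = truth.set_index("record_id") if "record_id" in truth.columns else truth
    if len(labels) != len(truth) or not labels.index.isin(truth.index).all():
        raise ValueError("labels and truth must align exactly on record_id")
    planted = truth.loc[labels.index, "topic"]
    topic_names = sorted(planted.unique())
    fitted = sorted(int(x) for x in labels.unique() if int(x) >= 0)
    if not fitted:
        return 0.0
    C = np.zeros((len(topic_names), len(fitted)))
    f_idx = {f: j for j, f in enumerate(fitted)}
    t_idx = {t: i for i, t in enumerate(topic_names)}
    for rec, lab in labels.items():
        if int(lab) >= 0:
            C[t_idx[planted.loc[rec]], f_idx[int(lab)]] += 1
    rows, cols = linear_sum_assignment(-C)
    return float(C[rows, cols].sum() / len(labels))
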