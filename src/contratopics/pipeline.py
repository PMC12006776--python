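"""End-to-end orchestration: ingest -> prep -> vectorize -> fit -> stats.

A run is driven by a :class:`RunConfig` (usually loaded from YAML), writes
every intermediate artifact into one output directory, and finishes with a
single ``summary.json``.  The run directory is self-contained provenance:
the echoed config plus the logs and outputs suffice to re-execute the
identical run, and stage-by-stage record counts in the run log reconcile
exactly (input = output + enumerated removals).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import resources
from .ingest import Review, RunLog, ingest_corpus, write_corpus
from .stats import (bundle_report, histogram_mean_sd, method_summary,
                    rating_histogram, scaled_share_table,
                    topic_rating_summary, topic_share_by_method)
from .synth import GeneratorConfig, evaluate_recovery, simulate_to_dir
from .textprep import PrepConfig, corpus_word_frequency, prepare_corpus, write_token_streams
from .topics import build_tfidf, dominant_topic, fit_nmf, select_model, top_terms

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


@dataclass
class RunConfig:
    """All parameters of one pipeline run."""

    output_dir: str = "run"
    # input: either paths to review tables, or a synthetic scenario
    review_paths: list[str] = field(default_factory=list)
    simulate: dict | None = None
    condition_label: str = "Birth Control"
    # catalogs (None = the shipped defaults)
    catalog_csv: str | None = None
    ambiguous_csv: str | None = None
    abbreviations_csv: str | None = None
    # modeling
    fit_on: str = "unfavorable"
    min_df: int = 5
    max_df: float = 0.95
    k: int | None = 8
    k_min: int = 3
    k_max: int = 13
    seeds: list[int] = field(default_factory=lambda: [0, 1, 2, 3, 4])
    max_iter: int = 500
    tol: float = 1e-5
    top_n: int = 10
    selection_criterion: str = "coherence"
    make_figures: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_catalogs(config: RunConfig):
    if config.catalog_csv is not None:
        p = Path(config.catalog_csv)
        if not p.exists():
            raise FileNotFoundError(f"catalog file not found: {p}")
        catalog = resources.load_method_catalog(p, config.ambiguous_csv)
    else:
        catalog = resources.default_method_catalog()
    prep = PrepConfig.default()
    if config.abbreviations_csv is not None:
        ap = Path(config.abbreviations_csv)
        if not ap.exists():
            raise FileNotFoundError(f"abbreviation file not found: {ap}")
        prep.abbreviations = resources.load_abbreviations(ap)
    if config.catalog_csv is not None:
        prep.product_terms = (catalog.product_name_tokens()
                              | resources.default_method_terms())
    return catalog, prep


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the summary dict (also written to
    ``summary.json`` in the output directory)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True))
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("contratopics")
    root.addHandler(handler)
    try:
        return _run(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> dict:
    catalog, prep = _stage("load-catalogs")(_load_catalogs)(config)

    # --- input ------------------------------------------------------------
    truth = None
    paths: Sequence = config.review_paths
    if config.simulate is not None:
        gen = GeneratorConfig(**config.simulate)
        rp, tp = _stage("simulate")(simulate_to_dir)(gen, out / "synthetic")
        paths = [rp]
        truth = pd.read_csv(tp, dtype={"record_id": str})
    if not paths:
        raise PipelineError("stage 'input' failed: no review_paths and no "
                            "simulate block in the config")

    # --- ingest -----------------------------------------------------------
    log = RunLog()
    corpus, log = _stage("ingest")(ingest_corpus)(
        list(paths), catalog, condition_label=config.condition_label, log=log)
    if not corpus:
        raise PipelineError("stage 'ingest' failed: empty corpus")
    write_corpus(corpus, out / "corpus.tsv")

    # --- text preparation ---------------------------------------------------
    docs = [(r.record_id, r.text) for r in corpus]
    streams_stop, _ = _stage("prep")(prepare_corpus)(docs, prep,
                                                     stop_stage="stopwords")
    word_freq = corpus_word_frequency(streams_stop)
    word_freq.to_csv(out / "table1_word_frequency.csv", index=False)

    fit_reviews = ([r for r in corpus if r.unfavorable]
                   if config.fit_on == "unfavorable" else list(corpus))
    fit_docs = [(r.record_id, r.text) for r in fit_reviews]
    streams, empty_ids = _stage("prep")(prepare_corpus)(fit_docs, prep)
    write_token_streams(streams, out / "tokens.txt", out / "tokens_index.txt")

    # --- vectorize and factorize -------------------------------------------
    dtm = _stage("vectorize")(build_tfidf)(streams, min_df=config.min_df,
                                           max_df=config.max_df)
    dtm.save(out / "dtm")

    selection = None
    if config.k is None:
        selection = _stage("select")(select_model)(
            dtm, streams, k_grid=range(config.k_min, config.k_max + 1),
            seeds=config.seeds, top_n=config.top_n,
            max_iter=config.max_iter, tol=config.tol,
            criterion=config.selection_criterion)
        selection.to_frame().to_csv(out / "selection_report.csv", index=False)
        k = selection.chosen_k
    else:
        k = config.k
    fits = [_stage("fit")(fit_nmf)(dtm, k, seed=s, max_iter=config.max_iter,
                                   tol=config.tol) for s in config.seeds]
    model = min(fits, key=lambda m: m.objective_trace[-1])
    model.save(out / "model")

    labels = dominant_topic(model.W)
    terms = top_terms(model.H, dtm.term_index, n=config.top_n)

    # --- statistics ---------------------------------------------------------
    hist = rating_histogram(corpus)
    hist.to_frame().to_csv(out / "table2_rating_histogram.csv", index=False)
    methods_tbl = method_summary(corpus)
    methods_tbl.to_csv(out / "table3_method_summary.csv")

    unfav = [r for r in corpus if r.unfavorable]
    if config.fit_on == "unfavorable":
        unfav_labels = labels
        unfav_for_tables = fit_reviews
    else:  # restrict topic tables to the unfavorable subset
        keep = [i for i, r in enumerate(fit_reviews) if r.unfavorable]
        unfav_labels = labels[keep]
        unfav_for_tables = [fit_reviews[i] for i in keep]

    label_counts = pd.Series(unfav_labels)
    roster = pd.DataFrame({
        "topic": range(k),
        "top_terms": [" ".join(t) for t in terms],
        "n_dominant": [int((label_counts == t).sum()) for t in range(k)],
    })
    roster["share"] = roster["n_dominant"] / max(len(unfav_labels), 1)
    roster.to_csv(out / "table4_topic_roster.csv", index=False)

    shares = topic_share_by_method(unfav_for_tables, unfav_labels)
    shares.to_csv(out / "topic_shares_by_method.csv")
    scaled = scaled_share_table(shares, methods_tbl)
    scaled.to_csv(out / "topic_shares_scaled.csv")
    topic_ratings = topic_rating_summary(unfav_for_tables, unfav_labels)
    topic_ratings.to_csv(out / "topic_rating_summary.csv")

    report = bundle_report(hist, methods_tbl, shares, scaled, topic_ratings)

    recovery = None
    if truth is not None:
        fitted = pd.Series(unfav_labels,
                           index=[r.record_id for r in unfav_for_tables])
        recovery = evaluate_recovery(
            fitted, truth[truth["record_id"].isin(fitted.index)])

    if config.make_figures:
        _stage("figures")(_make_figures)(out, methods_tbl, shares,
                                         unfav_for_tables, unfav_labels)

    log.count("prep_empty_documents", len(empty_ids))
    log.to_json(out / "run_log.json")

    mean, sd = histogram_mean_sd(hist)
    summary = {
        "config": config.to_dict(),
        "counts": dict(log.counts),
        "corpus_size": len(corpus),
        "n_unfavorable": len(unfav),
        "k": k,
        "chosen_k": selection.chosen_k if selection is not None else None,
        "rating_mean": mean,
        "rating_sd": sd,
        "top_terms": [" ".join(t) for t in terms],
        "recovery_accuracy": recovery,
        "report": report,
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _make_figures(out: Path, methods_tbl: pd.DataFrame, shares: pd.DataFrame,
                  unfav_reviews: list[Review], labels) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(methods_tbl["mean_rating"], methods_tbl["sd_rating"])
    for m, row in methods_tbl.iterrows():
        ax.annotate(m, (row["mean_rating"], row["sd_rating"]), fontsize=7)
    ax.set_xlabel("mean rating")
    ax.set_ylabel("SD of rating")
    fig.tight_layout()
    fig.savefig(out / "fig2_method_scatter.png", dpi=120)
    plt.close(fig)

    ax = shares.plot.barh(stacked=True, figsize=(7, 5)).axes
    ax.set_xlabel("share of unfavorable reviews")
    ax.figure.tight_layout()
    ax.figure.savefig(out / "fig3_topic_shares.png", dpi=120)
    plt.close(ax.figure)

    labels = np.asarray(labels)
    k = int(labels[labels >= 0].max()) + 1 if (labels >= 0).any() else 0
    ratings = np.array([r.rating for r in unfav_reviews])
    groups = [ratings[labels == t] for t in range(k)]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot([g if g.size else [np.nan] for g in groups], vert=False,
               showmeans=True)
    ax.set_xlabel("rating")
    ax.set_ylabel("dominant topic")
    fig.tight_layout()
    fig.savefig(out / "fig4_topic_boxplots.png", dpi=120)
    plt.close(fig)
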