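"""End-to-end orchestration: corpus -> scores -> topics -> keyness -> regression.

Every stage writes flat CSVs with documented headers into the output
directory, a run log records per-stage row counts, and a manifest captures
input hashes, the resolved configuration, the seed and package versions.
Deterministic stages reproduce bitwise on rerun; the topic model reproduces
given the seed, which is expanded into per-stage substreams so stages never
share randomness.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from ._seeds import stage_seed
from .corpus_io import PreprocessConfig, build_dfm, load_corpus, tokenize
from .health_scoring import HealthLexicon, score_corpus, scores_to_frame, summarize_categories
from .keyness import group_by_hes, keyness_table
from .regression import COVARIATE_COLUMNS, fit_logistic, fit_ols_robust, listwise_complete
from .synthetic import (
    SyntheticCovariateSpec,
    SyntheticScoredCorpusSpec,
    gen_covariates,
    gen_scored_corpus,
)
from .topic_model import KeyATMSpec, KeywordTopicModel, load_keywords

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "simulate_bundle"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    corpus_dir: str
    metadata: str
    out_dir: str = "ndch_out"
    lexicon: str | None = None
    keywords: str | None = None
    covariates: str | None = None
    seed: int = 0
    topics: dict[str, Any] = field(default_factory=dict)
    keyness: dict[str, Any] = field(default_factory=dict)
    regression: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _log(lines: list[str], stage: str, message: str) -> None:
    lines.append(f"[{stage}] {message}")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run all stages; returns a mapping of output name -> written path.

    A missing covariate table skips the regression stage with a warning;
    any stage's hard error aborts with the stage name and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    written: dict[str, Path] = {}

    # ---- score ---------------------------------------------------------
    try:
        docs = load_corpus(config.corpus_dir, config.metadata)
        pre = PreprocessConfig()
        tokenized = [tokenize(d, pre) for d in docs]
        lexicon = (
            HealthLexicon.from_yaml(config.lexicon)
            if config.lexicon
            else HealthLexicon.default()
        )
        scores = score_corpus(tokenized, lexicon)
        scores_df = scores_to_frame(scores)
        _log(log, "score", f"{len(docs)} documents in, {len(scores_df)} score rows out")
    except Exception as err:
        raise PipelineError("score", err) from err

    # ---- topics --------------------------------------------------------
    try:
        tcfg = dict(config.topics)
        min_df = int(tcfg.pop("min_doc_frequency", 2))
        keywords = load_keywords(config.keywords)
        dfm = build_dfm(tokenized, ngram_order=1, min_doc_frequency=min_df)
        spec = KeyATMSpec(keyword_topics=keywords, **tcfg)
        fit = KeywordTopicModel(dfm, spec).fit(seed=stage_seed(config.seed, "topics"))
        htp = fit.htp("health")
        scores_df = scores_df.merge(
            htp.rename_axis("doc_id").reset_index(), on="doc_id", how="left"
        )
        fit.theta.rename_axis("doc_id").to_csv(out / "theta.csv")
        htp.rename_axis("doc_id").to_csv(out / "htp.csv")
        fit.top_words(20).to_csv(out / "top_words.csv", index=False)
        written["theta"] = out / "theta.csv"
        written["htp"] = out / "htp.csv"
        _log(log, "topics", f"{dfm.shape[0]} docs x {dfm.shape[1]} terms, "
             f"{spec.n_topics} topics, {len(htp)} HTP rows out")
    except Exception as err:
        raise PipelineError("topics", err) from err

    scores_df.to_csv(out / "scores.csv", index=False)
    written["scores"] = out / "scores.csv"
    summarize_categories(scores).rename_axis("category").to_csv(out / "category_proportions.csv")
    written["category_proportions"] = out / "category_proportions.csv"

    # ---- keyness -------------------------------------------------------
    try:
        kcfg = dict(config.keyness)
        low = tuple(kcfg.get("low", (0, 1)))
        high = tuple(kcfg.get("high", (2, 5)))
        statistic = kcfg.get("statistic", "chi2")
        bigram_dfm = build_dfm(
            tokenized, ngram_order=2,
            min_doc_frequency=int(kcfg.get("min_doc_frequency", 1)),
        )
        groups = group_by_hes(scores_df, low, high)
        ktable = keyness_table(bigram_dfm, groups, sort_by=statistic)
        ktable.to_csv(out / "keyness.csv", index=False)
        written["keyness"] = out / "keyness.csv"
        _log(log, "keyness", f"groups {len(groups.target_doc_ids)}/"
             f"{len(groups.reference_doc_ids)}, {len(ktable)} bigram rows out")
    except Exception as err:
        raise PipelineError("keyness", err) from err

    # ---- regression ----------------------------------------------------
    if config.covariates is None:
        warnings.warn("no covariate table configured; skipping regression stage",
                      stacklevel=2)
        _log(log, "regress", "skipped (no covariates)")
    else:
        try:
            records = pd.read_csv(config.covariates)
            outcomes = scores_df[["doc_id", "any_mention", "hes", "htp"]].copy()
            outcomes["any_mention"] = outcomes["any_mention"].astype(int)
            data, dropped = listwise_complete(records, outcomes)
            rcfg = dict(config.regression)
            hc = rcfg.get("hc_type", "HC1")
            results = [
                fit_logistic(data, "any_mention",
                             robust=bool(rcfg.get("robust_logistic", False))),
                fit_ols_robust(data, "hes", hc_type=hc),
                fit_ols_robust(data, "htp", hc_type=hc),
            ]
            frames = []
            for res in results:
                frame = res.to_frame().rename_axis("term").reset_index()
                frame.insert(0, "outcome", res.outcome)
                frame.insert(0, "model", res.model)
                frame["n_used"] = res.n_used
                frame["fit_stat"] = res.pseudo_r2 if res.pseudo_r2 is not None else res.r2
                frames.append(frame)
            pd.concat(frames).to_csv(out / "regression.csv", index=False)
            written["regression"] = out / "regression.csv"
            _log(log, "regress", f"{len(data)} complete rows "
                 f"({len(dropped)} dropped), 3 models out")
        except Exception as err:
            raise PipelineError("regress", err) from err

    # ---- manifest + log ------------------------------------------------
    inputs = {
        name: _sha256(Path(p))
        for name, p in (
            ("metadata", config.metadata),
            ("lexicon", config.lexicon),
            ("keywords", config.keywords),
            ("covariates", config.covariates),
        )
        if p is not None and Path(p).exists()
    }
    corpus_files = sorted(Path(config.corpus_dir).glob("*.txt"))
    inputs["corpus"] = hashlib.sha256(
        b"".join(_sha256(f).encode() for f in corpus_files)
    ).hexdigest()
    manifest = {
        "ndchealth_version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in vars(config).items()},
        "input_hashes": inputs,
        "outputs": {k: str(v) for k, v in written.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str), "utf-8")
    (out / "run.log").write_text("\n".join(log) + "\n", "utf-8")
    written["manifest"] = out / "manifest.json"
    written["log"] = out / "run.log"
    return written


def simulate_bundle(
    out_dir: str | Path,
    seed: int = 0,
    corpus_spec: SyntheticScoredCorpusSpec | None = None,
    covariate_spec: SyntheticCovariateSpec | None = None,
) -> dict[str, Path]:
    """Write a synthetic corpus bundle in the pipeline's input layout.

    Documents are relabelled with the synthetic iso3 codes so the covariate
    table joins the text-derived scores; the planted truth is written
    alongside for validation.
    """
    out = Path(out_dir)
    corpus_dir = out / "corpus"
    corpus_dir.mkdir(parents=True, exist_ok=True)
    corpus_spec = corpus_spec or SyntheticScoredCorpusSpec()
    covariate_spec = covariate_spec or SyntheticCovariateSpec(
        n_countries=corpus_spec.n_docs
    )
    if covariate_spec.n_countries != corpus_spec.n_docs:
        raise ValueError("covariate_spec.n_countries must equal corpus_spec.n_docs")

    docs, truth = gen_scored_corpus(corpus_spec, seed=stage_seed(seed, "simulate.corpus"))
    table, cov_truth = gen_covariates(covariate_spec, seed=stage_seed(seed, "simulate.covariates"))

    iso3 = table["iso3"].tolist()
    rename = {d.doc_id: iso3[i] for i, d in enumerate(docs)}
    meta_rows = []
    for doc in docs:
        doc_id = rename[doc.doc_id]
        (corpus_dir / f"{doc_id}.txt").write_text(doc.text, "utf-8")
        meta_rows.append({"doc_id": doc_id, "country_name": f"Country {doc_id}", "year": 2016})
    meta = pd.DataFrame(meta_rows)
    meta.to_csv(out / "metadata.csv", index=False)
    truth = truth.assign(doc_id=truth["doc_id"].map(rename))
    truth.to_csv(out / "truth.csv", index=False)
    table.drop(columns=["any_mention", "hes", "htp"]).to_csv(
        out / "covariates.csv", index=False
    )
    return {
        "corpus_dir": corpus_dir,
        "metadata": out / "metadata.csv",
        "covariates": out / "covariates.csv",
        "truth": out / "truth.csv",
    }
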