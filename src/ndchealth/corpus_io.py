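"""Corpus reading, tokenization and document-feature matrices.

A corpus is a directory of UTF-8 ``.txt`` files (one per country document)
plus a metadata CSV with columns ``doc_id,country_name,year``. Tokenization
is deterministic and English-centric: accents are ASCII-folded, text is
lowercased, intra-word hyphens/apostrophes are collapsed, tokens are
alphabetic strings, stopwords and short tokens are dropped, and bigrams are
formed from adjacent surviving tokens within a sentence. Sentences come from
a rule-based splitter on terminal punctuation with an abbreviation exception
list.
"""

from __future__ import annotations

import re
import unicodedata
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmwrite

__all__ = [
    "Document",
    "TokenizedDocument",
    "DocumentFeatureMatrix",
    "PreprocessConfig",
    "default_stopwords",
    "normalize_term",
    "load_corpus",
    "tokenize",
    "build_dfm",
    "write_dfm",
]

_WORD_RE = re.compile(r"[a-z]+")
_JOIN_RE = re.compile(r"(?<=\w)[-'’](?=\w)")
_SENT_END_RE = re.compile(r"(?<=[.!?])\s+")

#: Abbreviations whose trailing period must not end a sentence.
_ABBREVIATIONS = frozenset(
    {"e.g.", "i.e.", "etc.", "cf.", "vs.", "no.", "dr.", "mr.", "mrs.",
     "fig.", "art.", "para.", "approx.", "inc.", "ltd.", "st."}
)


def default_stopwords() -> frozenset[str]:
    """The fixed English stopword list shipped with the package."""
    text = resources.files("ndchealth.data").joinpath("stopwords_en.txt").read_text("utf-8")
    return frozenset(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def _ascii_fold(text: str) -> str:
    return unicodedata.normalize("NFKD", text).encode("ascii", "ignore").decode("ascii")


def normalize_term(term: str) -> str:
    """Normalize a lexicon term with the same rules applied to corpus text.

    Multiword terms come back space-joined (``"early-warning"`` ->
    ``"earlywarning"``, ``"heat stress"`` -> ``"heat stress"``).
    """
    folded = _JOIN_RE.sub("", _ascii_fold(term).lower())
    return " ".join(_WORD_RE.findall(folded))


@dataclass(frozen=True)
class Document:
    """One country's policy document."""

    doc_id: str
    text: str
    year: int | None = None
    country_name: str | None = None


@dataclass(frozen=True)
class PreprocessConfig:
    """Deterministic tokenization settings.

    ``min_token_len`` and the stopword list apply only to the filtered token
    stream used for feature matrices; sentence token lists keep every word so
    that phrase lexicons can match across function words.
    """

    stopwords: frozenset[str] = field(default_factory=default_stopwords)
    min_token_len: int = 2
    abbreviations: frozenset[str] = _ABBREVIATIONS


@dataclass
class TokenizedDocument:
    """Processed token streams for one document.

    ``sentences`` holds all-word (unfiltered) lowercase tokens per sentence;
    ``tokens`` and ``bigrams`` are the stopword-filtered streams, with bigrams
    formed only within sentences.
    """

    doc_id: str
    tokens: list[str]
    sentences: list[list[str]]
    bigrams: list[str]

    @property
    def is_empty(self) -> bool:
        return len(self.tokens) == 0


def load_corpus(directory: str | Path, metadata: str | Path | pd.DataFrame) -> list[Document]:
    """Read one :class:`Document` per metadata row from ``directory``.

    Raises ``FileNotFoundError`` naming every absent ``doc_id`` and
    ``ValueError`` on duplicate ids or empty files.
    """
    directory = Path(directory)
    meta = metadata if isinstance(metadata, pd.DataFrame) else pd.read_csv(metadata)
    if "doc_id" not in meta.columns:
        raise ValueError("metadata must have a 'doc_id' column")
    ids = meta["doc_id"].astype(str).tolist()
    dupes = sorted({d for d in ids if ids.count(d) > 1})
    if dupes:
        raise ValueError(f"duplicate doc_id in metadata: {dupes}")

    missing = [d for d in ids if not (directory / f"{d}.txt").exists()]
    if missing:
        raise FileNotFoundError(f"corpus files missing for doc_ids: {missing}")

    docs: list[Document] = []
    for _, row in meta.iterrows():
        doc_id = str(row["doc_id"])
        text = (directory / f"{doc_id}.txt").read_text("utf-8")
        if not text.strip():
            raise ValueError(f"document {doc_id!r} is empty")
        docs.append(
            Document(
                doc_id=doc_id,
                text=text,
                year=int(row["year"]) if "year" in meta.columns and pd.notna(row.get("year")) else None,
                country_name=row.get("country_name"),
            )
        )
    return docs


def split_sentences(text: str, abbreviations: frozenset[str] = _ABBREVIATIONS) -> list[str]:
    """Rule-based sentence splitting on terminal punctuation."""
    pieces = _SENT_END_RE.split(text.strip())
    sentences: list[str] = []
    buffer = ""
    for piece in pieces:
        buffer = f"{buffer} {piece}".strip() if buffer else piece
        last = buffer.rsplit(maxsplit=1)[-1].lower() if buffer.split() else ""
        if last in abbreviations:
            continue  # splitter fired on an abbreviation's period; rejoin
        if buffer:
            sentences.append(buffer)
            buffer = ""
    if buffer:
        sentences.append(buffer)
    return sentences


def tokenize(document: Document, config: PreprocessConfig | None = None) -> TokenizedDocument:
    """Tokenize a document deterministically under ``config``.

    Warns and flags the document (``is_empty``) when no token survives
    filtering.
    """
    config = config or PreprocessConfig()
    sentences: list[list[str]] = []
    tokens: list[str] = []
    bigrams: list[str] = []
    for sent in split_sentences(document.text, config.abbreviations):
        folded = _JOIN_RE.sub("", _ascii_fold(sent).lower())
        words = _WORD_RE.findall(folded)
        if not words:
            continue
        sentences.append(words)
        kept = [
            w for w in words
            if w not in config.stopwords and len(w) >= config.min_token_len
        ]
        tokens.extend(kept)
        bigrams.extend(f"{a}_{b}" for a, b in zip(kept, kept[1:]))
    if not tokens:
        warnings.warn(
            f"document {document.doc_id!r} has no tokens after filtering; "
            "it will be excluded from feature matrices",
            stacklevel=2,
        )
    return TokenizedDocument(document.doc_id, tokens, sentences, bigrams)


@dataclass
class DocumentFeatureMatrix:
    """Documents x features count matrix (unigrams or bigrams)."""

    doc_ids: list[str]
    features: list[str]
    counts: np.ndarray  # (D, V) non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.doc_ids), len(self.features)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.doc_ids, columns=self.features)

    def to_long(self) -> pd.DataFrame:
        """Long-format (doc_id, feature, count) table of non-zero cells."""
        rows, cols = np.nonzero(self.counts)
        return pd.DataFrame(
            {
                "doc_id": [self.doc_ids[r] for r in rows],
                "feature": [self.features[c] for c in cols],
                "count": self.counts[rows, cols],
            }
        )


def build_dfm(
    tokenized_docs: Sequence[TokenizedDocument],
    ngram_order: int = 1,
    min_doc_frequency: int = 1,
) -> DocumentFeatureMatrix:
    """Count unigram (``ngram_order=1``) or bigram (``2``) features.

    Features occurring in fewer than ``min_doc_frequency`` documents are
    dropped; empty documents are excluded with a warning.
    """
    if ngram_order not in (1, 2):
        raise ValueError("ngram_order must be 1 or 2")
    kept_docs = [d for d in tokenized_docs if not d.is_empty]
    if len(kept_docs) < len(tokenized_docs):
        dropped = [d.doc_id for d in tokenized_docs if d.is_empty]
        warnings.warn(f"excluding empty documents from DFM: {dropped}", stacklevel=2)
    if not kept_docs:
        raise ValueError("no non-empty documents to build a DFM from")

    streams = [d.tokens if ngram_order == 1 else d.bigrams for d in kept_docs]
    doc_freq: dict[str, int] = {}
    for stream in streams:
        for feat in set(stream):
            doc_freq[feat] = doc_freq.get(feat, 0) + 1
    features = sorted(f for f, df_ in doc_freq.items() if df_ >= min_doc_frequency)
    if not features:
        raise ValueError("all features removed by the min_doc_frequency filter")
    index = {f: j for j, f in enumerate(features)}

    counts = np.zeros((len(kept_docs), len(features)), dtype=np.int64)
    for i, stream in enumerate(streams):
        for feat in stream:
            j = index.get(feat)
            if j is not None:
                counts[i, j] += 1
    return DocumentFeatureMatrix([d.doc_id for d in kept_docs], features, counts)


def write_dfm(dfm: DocumentFeatureMatrix, out_dir: str | Path, stem: str = "dfm") -> None:
    """Export a DFM as Matrix Market + label files + long CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out_dir / f"{stem}.mtx"), sparse.csr_matrix(dfm.counts))
    (out_dir / f"{stem}.rows.txt").write_text("\n".join(dfm.doc_ids) + "\n", "utf-8")
    (out_dir / f"{stem}.cols.txt").write_text("\n".join(dfm.features) + "\n", "utf-8")
    dfm.to_long().to_csv(out_dir / f"{stem}.long.csv", index=False)
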