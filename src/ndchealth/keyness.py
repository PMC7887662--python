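"""Keyness: bigrams that statistically distinguish document groups.

Documents are split into a target group (low health engagement, HES 0–1) and
a reference group (HES 2–5). For each feature a 2x2 contingency table —
occurrences of the feature vs all other tokens, by group — yields Pearson's
chi-squared (no continuity correction) and Dunning's log-likelihood ratio G².
A feature's direction records which group over-represents it in relative
frequency. Features are ranked by either statistic; ties break
lexicographically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus_io import DocumentFeatureMatrix

__all__ = [
    "GroupedCorpus",
    "KeynessRow",
    "group_by_hes",
    "keyness_table",
    "top_terms",
]


@dataclass(frozen=True)
class GroupedCorpus:
    target_doc_ids: tuple[str, ...]
    reference_doc_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.target_doc_ids) & set(self.reference_doc_ids)
        if overlap:
            raise ValueError(f"groups must be disjoint; overlap: {sorted(overlap)}")
        if not self.target_doc_ids or not self.reference_doc_ids:
            raise ValueError("both groups must be non-empty")


@dataclass(frozen=True)
class KeynessRow:
    feature: str
    n_target: int
    n_reference: int
    total_target: int
    total_reference: int
    chi2: float
    g2: float
    direction: str  # "target" | "reference"


def group_by_hes(
    scores: pd.DataFrame | Sequence,
    low_range: tuple[int, int] = (0, 1),
    high_range: tuple[int, int] = (2, 5),
) -> GroupedCorpus:
    """Split documents into low-HES (target) and high-HES (reference) groups.

    ``scores`` is a frame with ``doc_id`` and ``hes`` columns (or a sequence
    of objects with those attributes). Ranges must be disjoint and together
    cover 0–5.
    """
    if not isinstance(scores, pd.DataFrame):
        scores = pd.DataFrame(
            {"doc_id": [s.doc_id for s in scores], "hes": [s.hes for s in scores]}
        )
    lo = set(range(low_range[0], low_range[1] + 1))
    hi = set(range(high_range[0], high_range[1] + 1))
    if lo & hi:
        raise ValueError("low and high HES ranges overlap")
    if lo | hi != set(range(6)):
        raise ValueError("HES ranges must together cover 0–5")
    target = tuple(scores.loc[scores["hes"].isin(lo), "doc_id"].astype(str))
    reference = tuple(scores.loc[scores["hes"].isin(hi), "doc_id"].astype(str))
    if not target:
        raise ValueError("target (low-HES) group is empty")
    if not reference:
        raise ValueError("reference (high-HES) group is empty")
    return GroupedCorpus(target, reference)


def _chi2_g2(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray):
    """Vectorised 2x2 chi-squared (no correction) and G² for tables
    [[a, b], [c, d]] = [[feature-in-target, other-in-target],
                        [feature-in-reference, other-in-reference]]."""
    a, b, c, d = (x.astype(np.float64) for x in (a, b, c, d))
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(den > 0, num / den, 0.0)

    # G² = 2 Σ O ln(O/E), with 0 ln 0 = 0
    g2 = np.zeros_like(chi2)
    for obs, row, col in ((a, a + b, a + c), (b, a + b, b + d),
                          (c, c + d, a + c), (d, c + d, b + d)):
        expected = row * col / n
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
        g2 += term
    g2 = np.maximum(2.0 * g2, 0.0)
    return chi2, g2


def keyness_table(
    dfm: DocumentFeatureMatrix,
    groups: GroupedCorpus,
    sort_by: str = "chi2",
) -> pd.DataFrame:
    """Per-feature keyness statistics for the target vs reference contrast.

    Returns a frame with columns ``feature, n_target, n_reference,
    total_target, total_reference, chi2, g2, direction`` sorted by
    ``sort_by`` descending (ties lexicographic on feature).
    """
    if sort_by not in ("chi2", "g2"):
        raise ValueError("sort_by must be 'chi2' or 'g2'")
    index = {d: i for i, d in enumerate(dfm.doc_ids)}
    missing = [d for d in (*groups.target_doc_ids, *groups.reference_doc_ids)
               if d not in index]
    if missing:
        raise ValueError(f"doc_ids absent from the DFM: {missing}")

    t_rows = [index[d] for d in groups.target_doc_ids]
    r_rows = [index[d] for d in groups.reference_doc_ids]
    n_t = dfm.counts[t_rows].sum(axis=0)
    n_r = dfm.counts[r_rows].sum(axis=0)
    total_t = int(n_t.sum())
    total_r = int(n_r.sum())
    if total_t == 0 or total_r == 0:
        raise ValueError("one group has zero total tokens")

    chi2, g2 = _chi2_g2(n_t, total_t - n_t, n_r, total_r - n_r)
    direction = np.where(
        n_t / total_t > n_r / total_r, "target", "reference"
    )
    table = pd.DataFrame(
        {
            "feature": dfm.features,
            "n_target": n_t,
            "n_reference": n_r,
            "total_target": total_t,
            "total_reference": total_r,
            "chi2": chi2,
            "g2": g2,
            "direction": direction,
        }
    )
    return (
        table.sort_values([sort_by, "feature"], ascending=[False, True])
        .reset_index(drop=True)
    )


def top_terms(
    table: pd.DataFrame, n: int, direction: str, statistic: str = "chi2"
) -> list[str]:
    """Top-``n`` features over-represented in ``direction``, by ``statistic``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if direction not in ("target", "reference"):
        raise ValueError("direction must be 'target' or 'reference'")
    if statistic not in ("chi2", "g2"):
        raise ValueError("statistic must be 'chi2' or 'g2'")
    sub = table.loc[
        (table["direction"] == direction) & (table[statistic] > 0)
    ].sort_values([statistic, "feature"], ascending=[False, True])
    if sub.empty:
        warnings.warn(f"no features over-represented in {direction!r}", stacklevel=2)
        return []
    if len(sub) < n:
        warnings.warn(
            f"only {len(sub)} features available for {direction!r} (requested {n})",
            stacklevel=2,
        )
    return sub["feature"].head(n).tolist()
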