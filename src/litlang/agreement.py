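"""Interrater agreement for ordinal 0-3 element scores.

The headline statistic is the quadratic weighted kappa

    kappa_qw = 1 - sum(W * O) / sum(W * E)

where O is the observed joint proportion matrix over the k=4 score
categories, E the chance-expected matrix (outer product of the two raters'
marginals), and W the quadratic penalty W[i,j] = (i - j)^2 / (k - 1)^2. A
one-point disagreement therefore costs 1/9 of the penalty a three-point
disagreement does. kappa_qw is 1 for perfect agreement, 0 for chance-level
agreement, and can be negative when raters agree less than chance would.

The category domain is fixed at {0, 1, 2, 3} — the rubric's scale — even when
some categories never occur in a given sample; inferring k from the observed
data would silently change the statistic.

Also provided: the per-transcript total absolute difference across the six
elements (0-18), and grouped median/IQR summaries of those differences for
error profiling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lexicon import ELEMENTS
from .scorers import MISLMicroScores

__all__ = [
    "CATEGORIES",
    "SCORE_COLUMNS",
    "ScoreTable",
    "KappaResult",
    "quadratic_weighted_kappa",
    "per_element_agreement",
    "total_absolute_difference",
    "table_total_differences",
    "error_by_group",
]

CATEGORIES: tuple[int, ...] = (0, 1, 2, 3)

#: Score CSV schema: identifier plus one column per element plus total.
SCORE_COLUMNS = (
    "id", "coord_conj", "subord_conj", "metaling_verb", "metacog_verb",
    "adverb", "enp", "total",
)
_ELEMENT_COLUMNS = SCORE_COLUMNS[1:7]


@dataclass(frozen=True)
class ScoreTable:
    """One rater's six-element scores for a corpus, one row per transcript."""

    rater_label: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("id", *_ELEMENT_COLUMNS)
                   if c not in self.frame.columns]
        if missing:
            raise ValueError(f"score table missing column(s): {missing}")
        if self.frame["id"].duplicated().any():
            dupes = self.frame.loc[self.frame["id"].duplicated(), "id"]
            raise ValueError(f"duplicate transcript ids: {list(dupes)[:5]}")
        vals = self.frame[list(_ELEMENT_COLUMNS)].to_numpy()
        if not np.isin(vals, CATEGORIES).all():
            raise ValueError("all element scores must be in {0,1,2,3}")

    @classmethod
    def from_rows(cls, rater_label: str, rows: list[dict]) -> "ScoreTable":
        return cls(rater_label, pd.DataFrame(rows))

    @classmethod
    def read_csv(cls, path, rater_label: str | None = None) -> "ScoreTable":
        frame = pd.read_csv(path)
        return cls(rater_label or str(path), frame)


@dataclass(frozen=True)
class KappaResult:
    """Observed/expected matrices and the quadratic weighted kappa."""

    element: str
    n: int
    observed: np.ndarray
    expected: np.ndarray
    weights: np.ndarray
    kappa_qw: float
    degenerate: bool = False


def _weight_matrix(k: int) -> np.ndarray:
    idx = np.arange(k)
    return (idx[:, None] - idx[None, :]) ** 2 / (k - 1) ** 2


def quadratic_weighted_kappa(
    a, b, categories: tuple[int, ...] = CATEGORIES, element: str = ""
) -> KappaResult:
    """Quadratic weighted kappa between two aligned score vectors.

    ``a`` and ``b`` must be the same length, with every entry in
    ``categories``. The category domain is used as given, observed or not.
    When both raters are constant and identical, chance disagreement is zero
    and the result is returned as kappa 1 with ``degenerate=True``.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("score vectors must be equal-length, nonempty, 1-D")
    cats = list(categories)
    if not (np.isin(a, cats).all() and np.isin(b, cats).all()):
        raise ValueError(f"scores outside category domain {cats}")
    k = len(cats)
    lookup = {c: i for i, c in enumerate(cats)}
    ai = np.array([lookup[v] for v in a])
    bi = np.array([lookup[v] for v in b])
    counts = np.zeros((k, k))
    np.add.at(counts, (ai, bi), 1.0)
    O = counts / counts.sum()
    E = np.outer(O.sum(axis=1), O.sum(axis=0))
    W = _weight_matrix(k)
    denom = float((W * E).sum())
    if denom == 0.0:
        return KappaResult(element, len(a), O, E, W, 1.0, degenerate=True)
    kappa = 1.0 - float((W * O).sum()) / denom
    return KappaResult(element, len(a), O, E, W, kappa)


def _aligned(pred: ScoreTable, ref: ScoreTable) -> pd.DataFrame:
    merged = pred.frame.merge(
        ref.frame, on="id", how="inner", suffixes=("_pred", "_ref")
    )
    n_pred, n_ref = len(pred.frame), len(ref.frame)
    if len(merged) == 0:
        raise ValueError(
            f"no transcript ids shared between {pred.rater_label!r} "
            f"and {ref.rater_label!r}"
        )
    if len(merged) < max(n_pred, n_ref):
        warnings.warn(
            f"id mismatch: {n_pred} vs {n_ref} rows, "
            f"{len(merged)} shared; agreement computed on the intersection",
            stacklevel=3,
        )
    return merged


def per_element_agreement(
    pred: ScoreTable, ref: ScoreTable
) -> list[KappaResult]:
    """Quadratic weighted kappa per element, aligned by transcript id."""
    merged = _aligned(pred, ref)
    results = []
    for col, element in zip(_ELEMENT_COLUMNS, ELEMENTS):
        results.append(
            quadratic_weighted_kappa(
                merged[f"{col}_pred"].to_numpy(),
                merged[f"{col}_ref"].to_numpy(),
                element=element,
            )
        )
    return results


def total_absolute_difference(
    x: MISLMicroScores, y: MISLMicroScores
) -> int:
    """Sum over the six elements of |x - y|; ranges 0-18 on the 0-3 scale."""
    if x.transcript_id != y.transcript_id:
        raise ValueError(
            f"transcript id mismatch: {x.transcript_id!r} vs "
            f"{y.transcript_id!r}"
        )
    xs, ys = x.by_element(), y.by_element()
    return sum(abs(xs[el] - ys[el]) for el in ELEMENTS)


def table_total_differences(
    pred: ScoreTable, ref: ScoreTable
) -> pd.DataFrame:
    """Per-transcript total absolute difference between two score tables."""
    merged = _aligned(pred, ref)
    diff = sum(
        (merged[f"{c}_pred"] - merged[f"{c}_ref"]).abs()
        for c in _ELEMENT_COLUMNS
    )
    return pd.DataFrame({"id": merged["id"], "total_diff": diff})


def error_by_group(diffs: list[tuple[str, float]]) -> pd.DataFrame:
    """Median and interquartile spread of total differences per group.

    ``diffs`` holds ``(group_label, total_difference)`` pairs, e.g. age bands
    against per-transcript error. Returns one row per group with n, median,
    q1, q3 and iqr, computed independently per group.
    """
    if not diffs:
        raise ValueError("no observations")
    frame = pd.DataFrame(diffs, columns=["group", "total_diff"])
    grouped = frame.groupby("group")["total_diff"]
    out = grouped.agg(
        n="count",
        median="median",
        q1=lambda s: s.quantile(0.25),
        q3=lambda s: s.quantile(0.75),
    ).reset_index()
    out["iqr"] = out["q3"] - out["q1"]
    return out
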