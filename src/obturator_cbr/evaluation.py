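"""Retrieval-quality evaluation: precision@k, summaries, rank correlation.

The protocol mirrors a held-out clinical assessment: for each test case the
system retrieves its top-k designs with their confidence scores, and an
external judgment (clinician relevance labels, supplied as data and never
computed here) marks each retrieved design correct or not.  From these the
module computes per-case precision@k curves with across-case medians,
min/max/median summary tables, and Spearman's rank correlation between the
mean top-k confidence and the number of correct designs per case.
"""

from __future__ import annotations

import json
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import BoundsError, ConstantInputError, EmptyInputError

__all__ = [
    "EvaluationSample",
    "PrecisionCurve",
    "CorrelationResult",
    "CorrelationReport",
    "precision_at_k",
    "precision_curve",
    "mean_top_confidence",
    "spearman",
    "summarize_confidences",
    "correlation_report",
    "load_labels",
    "write_labels",
    "samples_from_reports",
]


@dataclass(frozen=True)
class EvaluationSample:
    """One test case: ranked top-k confidences plus relevance labels."""

    test_id: str
    confidences: tuple[float, ...]
    relevant: tuple[bool, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "confidences", tuple(float(c) for c in self.confidences))
        object.__setattr__(self, "relevant", tuple(bool(r) for r in self.relevant))
        if len(self.confidences) != len(self.relevant):
            raise ValueError(
                f"{self.test_id}: {len(self.confidences)} confidences but "
                f"{len(self.relevant)} relevance labels")

    @property
    def correct_count(self) -> int:
        """Number of retrieved designs judged correct."""
        return int(sum(self.relevant))

    def __len__(self) -> int:
        return len(self.confidences)


def precision_at_k(sample: EvaluationSample, k: int) -> float:
    """Fraction of the first *k* retrieved designs judged relevant."""
    if not 1 <= k <= len(sample):
        raise BoundsError(
            f"{sample.test_id}: k={k} outside 1..{len(sample)} retrieved")
    return sum(sample.relevant[:k]) / k


def mean_top_confidence(sample: EvaluationSample, k: int) -> float:
    """Arithmetic mean of the first *k* confidence scores."""
    if not 1 <= k <= len(sample):
        raise BoundsError(
            f"{sample.test_id}: k={k} outside 1..{len(sample)} retrieved")
    return float(np.mean(sample.confidences[:k]))


@dataclass(frozen=True)
class PrecisionCurve:
    """Per-case precision@k for k=1..K plus the across-case median at each k."""

    k_values: tuple[int, ...]
    per_case: pd.DataFrame  # index: test_id, columns: k, NaN where k > retrieved
    median_precision: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        frame = self.per_case.T.copy()
        frame.insert(0, "median", list(self.median_precision))
        frame.index.name = "k"
        return frame

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, encoding="utf-8")
        return path


def precision_curve(samples: Sequence[EvaluationSample], K: int) -> PrecisionCurve:
    """Precision@k for k = 1..K across a set of evaluation samples.

    A sample with fewer than K retrieved designs contributes to the medians
    only up to its own length (truncation with a warning); the median at
    each k is taken over the samples that reach it.
    """
    if not samples:
        raise EmptyInputError("precision_curve needs at least one sample")
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    short = [s.test_id for s in samples if len(s) < K]
    if short:
        warnings.warn(
            f"{len(short)} sample(s) retrieved fewer than K={K} designs and "
            f"are truncated: {short}", stacklevel=2)
    k_values = tuple(range(1, K + 1))
    matrix = pd.DataFrame(
        {
            s.test_id: [
                precision_at_k(s, k) if k <= len(s) else np.nan for k in k_values
            ]
            for s in samples
        },
        index=list(k_values),
    ).T
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        medians = tuple(float(m) for m in np.nanmedian(matrix.to_numpy(), axis=0))
    return PrecisionCurve(k_values, matrix, medians)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman's rho with its p-value and sample size."""

    rho: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {"rho": self.rho, "p_value": self.p_value, "n": self.n}


def spearman(x: Sequence[float], y: Sequence[float], *,
             permutation: int | None = None,
             seed: int | None = None) -> CorrelationResult:
    """Spearman rank correlation between two equal-length samples.

    Ranks are assigned by the mid-rank (average-rank) convention and rho is
    the Pearson correlation of the ranks, which handles ties exactly.  The
    p-value uses the t-approximation with n-2 degrees of freedom; pass
    ``permutation=<resamples>`` (with a seed) for a permutation p-value
    instead, which is preferable at very small n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = len(x)
    if n < 3:
        raise EmptyInputError(f"need at least 3 paired observations, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError(
            "rank correlation is undefined for a constant input vector")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if permutation is None:
        p = float(res.pvalue)
    else:
        rng = np.random.default_rng(seed)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        observed = abs(rho)
        hits = 0
        for _ in range(permutation):
            perm = rng.permutation(ry)
            r = float(np.corrcoef(rx, perm)[0, 1])
            if abs(r) >= observed - 1e-12:
                hits += 1
        p = (hits + 1) / (permutation + 1)
    return CorrelationResult(rho, p, n)


def summarize_confidences(values: Sequence[float]) -> dict[str, float]:
    """Minimum, maximum and median of a non-empty sample.

    The median follows the mid-point convention: for even n it is the mean
    of the two central order statistics.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise EmptyInputError("summarize_confidences needs at least one value")
    return {
        "minimum": float(arr.min()),
        "maximum": float(arr.max()),
        "median": float(np.median(arr)),
    }


@dataclass(frozen=True)
class CorrelationReport:
    """Correlation of mean top-k confidence with correct-design counts."""

    correlation: CorrelationResult
    confidence_summary: dict[str, float]
    correct_count_summary: dict[str, float]
    k: int
    mean_confidences: tuple[float, ...]
    correct_counts: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "spearman": self.correlation.to_dict(),
            "mean_top_confidence": self.confidence_summary,
            "correct_designs_per_case": self.correct_count_summary,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def correlation_report(samples: Sequence[EvaluationSample],
                       k: int = 5) -> CorrelationReport:
    """Correlate per-case mean top-k confidence with correct-design counts.

    This is the headline association of the evaluation protocol: if the
    weighted keyword match is informative, test cases whose retrieved
    designs scored higher should also collect more clinician-approved
    designs among the top k.
    """
    if len(samples) < 3:
        raise EmptyInputError(
            f"correlation_report needs at least 3 samples, got {len(samples)}")
    means = tuple(mean_top_confidence(s, min(k, len(s))) for s in samples)
    counts = tuple(int(sum(s.relevant[:k])) for s in samples)
    corr = spearman(means, [float(c) for c in counts])
    return CorrelationReport(
        correlation=corr,
        confidence_summary=summarize_confidences(means),
        correct_count_summary=summarize_confidences([float(c) for c in counts]),
        k=k,
        mean_confidences=means,
        correct_counts=counts,
    )


# ---------------------------------------------------------------------------
# Label and report plumbing
# ---------------------------------------------------------------------------


def write_labels(samples: Sequence[EvaluationSample], path: str | Path) -> Path:
    """Write relevance labels as CSV columns test_id, rank, relevant(0/1)."""
    rows = [
        {"test_id": s.test_id, "rank": rank, "relevant": int(flag)}
        for s in samples
        for rank, flag in enumerate(s.relevant, start=1)
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=["test_id", "rank", "relevant"]).to_csv(
        path, index=False, encoding="utf-8")
    return path


def load_labels(path: str | Path) -> dict[str, list[bool]]:
    """Read a relevance-label CSV into rank-ordered label lists per test_id."""
    frame = pd.read_csv(path, dtype={"test_id": str, "rank": int, "relevant": int})
    for column in ("test_id", "rank", "relevant"):
        if column not in frame.columns:
            raise ValueError(f"{path}: missing column {column!r}")
    labels: dict[str, list[bool]] = {}
    for test_id, group in frame.groupby("test_id", sort=False):
        group = group.sort_values("rank")
        labels[str(test_id)] = [bool(v) for v in group["relevant"]]
    return labels


def samples_from_reports(
    confidences_by_id: Mapping[str, Sequence[float]],
    labels_by_id: Mapping[str, Sequence[bool]],
) -> list[EvaluationSample]:
    """Join retrieval confidences with relevance labels on test id."""
    missing = sorted(set(confidences_by_id) - set(labels_by_id))
    if missing:
        raise ValueError(f"no relevance labels for test id(s): {missing}")
    return [
        EvaluationSample(test_id, tuple(confs), tuple(labels_by_id[test_id]))
        for test_id, confs in confidences_by_id.items()
    ]
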