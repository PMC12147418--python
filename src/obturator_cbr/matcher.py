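"""Weighted keyword matching and top-k retrieval of stored designs.

The confidence score of a stored case against a query is the weighted
fraction of *comparable* attributes on which the two agree::

    confidence = sum(weight(k) for matching k) / sum(weight(k) for comparable k)

where the comparable set is the keys present in both records — keys a
skipped questionnaire branch legitimately left out of either side are
excluded from numerator and denominator alike.  The Aramany class is a hard
candidate filter, never a weighted attribute: only same-class cases are
scored.

Weights come in two kinds.  Ordinary keys carry a fixed weight (default 1,
overridable per class and key).  A few clinically secondary keys — the
remaining-molar count and whether both premolars are present — instead carry
a *share* weight: a fixed fraction (default 0.05) of the total comparable
weight.  A case agreeing with the query everywhere except the number of
remaining molars therefore scores exactly 1 - 0.05 = 0.95 on every branch of
the schema, while full agreement scores exactly 1.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from . import case_model as cm
from .errors import ClassMismatchError, ConfigError, UndefinedScoreError
from .questionnaire import QuerySpec

__all__ = [
    "WeightTable",
    "MatchResult",
    "RetrievalReport",
    "confidence",
    "shared_keywords",
    "retrieve",
    "flag_eligible",
    "DEFAULT_K",
    "DEFAULT_ELIGIBILITY_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Number of designs presented to the clinician by default.
DEFAULT_K = 5
#: A retrieved design is eligible for reuse when its confidence is strictly
#: above this similarity threshold.
DEFAULT_ELIGIBILITY_THRESHOLD = 0.90

#: Keys whose default weight is a fraction of the comparable total rather
#: than a fixed amount (see the module docstring).
_DEFAULT_SHARES: dict[str, float] = {
    key: 0.05
    for key in (
        cm.REMAINING_MOLAR_COUNT, cm.MOLAR_COUNT_R, cm.MOLAR_COUNT_L,
        cm.BOTH_PREMOLARS_PRESENT, cm.BOTH_PREMOLARS_R, cm.BOTH_PREMOLARS_L,
    )
}


@dataclass(frozen=True)
class WeightTable:
    """Attribute-importance weights used by the confidence score.

    ``overrides`` maps ``(aramany_class_value, key)`` to a fixed weight;
    any key not overridden and not in ``shares`` weighs ``default_weight``.
    ``shares`` maps a key to its fraction of the total comparable weight.
    """

    default_weight: float = 1.0
    overrides: Mapping[tuple[str, str], float] = field(default_factory=dict)
    shares: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_SHARES))

    def __post_init__(self) -> None:
        if not self.default_weight > 0:
            raise ConfigError("default_weight must be positive")
        for (cls, key), w in self.overrides.items():
            if not (w >= 0 and w == w and w != float("inf")):
                raise ConfigError(f"weight for ({cls}, {key}) must be finite and >= 0")
        for key, f in self.shares.items():
            if not 0 < f < 1:
                raise ConfigError(f"share for {key} must lie in (0, 1)")

    def fixed_weight(self, aramany_class: cm.AramanyClass, key: str) -> float:
        return self.overrides.get((aramany_class.value, key), self.default_weight)

    @classmethod
    def from_config(cls, path: str | Path) -> "WeightTable":
        """Load weights from a YAML (or JSON) mapping.

        Layout::

            default_weight: 1.0
            shares:
              remaining_molar_count: 0.05
            overrides:
              I:
                oronasal_connection: 2.0
        """
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        overrides = {
            (str(cls_value), str(key)): float(w)
            for cls_value, per_class in (raw.get("overrides") or {}).items()
            for key, w in per_class.items()
        }
        shares = {str(k): float(v) for k, v in (raw.get("shares") or {}).items()}
        return cls(
            default_weight=float(raw.get("default_weight", 1.0)),
            overrides=overrides,
            shares=shares if shares else dict(_DEFAULT_SHARES),
        )


@dataclass(frozen=True)
class MatchResult:
    """One retrieved case: its score, shared keywords and design images."""

    case_id: str
    confidence: float
    shared_keys: tuple[str, ...]
    rank: int
    media_paths: tuple[str, ...]
    eligible: bool | None = None

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "confidence": self.confidence,
            "shared_keys": list(self.shared_keys),
            "rank": self.rank,
            "media_paths": list(self.media_paths),
            "eligible": self.eligible,
        }


@dataclass(frozen=True)
class RetrievalReport:
    """The ranked outcome of one retrieval run."""

    query: QuerySpec
    results: tuple[MatchResult, ...]
    k: int

    @property
    def confidences(self) -> tuple[float, ...]:
        return tuple(r.confidence for r in self.results)

    def to_dict(self) -> dict:
        return {
            "query": {
                "aramany_class": self.query.aramany_class.value,
                "attributes": dict(self.query.attributes),
            },
            "k": self.k,
            "results": [r.to_dict() for r in self.results],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_dict(cls, payload: Mapping) -> "RetrievalReport":
        query = QuerySpec(
            cm.AramanyClass(payload["query"]["aramany_class"]),
            dict(payload["query"]["attributes"]),
        )
        results = tuple(
            MatchResult(
                case_id=r["case_id"],
                confidence=float(r["confidence"]),
                shared_keys=tuple(r["shared_keys"]),
                rank=int(r["rank"]),
                media_paths=tuple(r["media_paths"]),
                eligible=r.get("eligible"),
            )
            for r in payload["results"]
        )
        return cls(query, results, int(payload["k"]))

    @classmethod
    def from_json(cls, path: str | Path) -> "RetrievalReport":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    def to_table(self) -> str:
        """A human-readable rendering for terminal display."""
        lines = [f"Top {len(self.results)} matching Class "
                 f"{self.query.aramany_class.value} designs (k={self.k})"]
        if not self.results:
            lines.append("  (no stored case of this Aramany class)")
        for r in self.results:
            flag = ""
            if r.eligible is not None:
                flag = "  [eligible]" if r.eligible else "  [below threshold]"
            lines.append(
                f"  #{r.rank}  {r.case_id}  confidence={r.confidence:.3f}{flag}")
            lines.append(f"      shared: {', '.join(r.shared_keys) or '-'}")
            lines.append(f"      media:  {'; '.join(r.media_paths) or '-'}")
        return "\n".join(lines)


def _comparable_keys(query: QuerySpec, case: cm.CaseRecord) -> list[str]:
    schema = cm.schema_for_class(query.aramany_class)
    return [k for k in schema.keys
            if k in query.attributes and k in case.attributes]


def confidence(query: QuerySpec, case: cm.CaseRecord,
               weights: WeightTable | None = None) -> float:
    """Weighted keyword-match confidence of a stored case for a query.

    Both records must be of the same Aramany class (callers pre-filter;
    a mismatch is a contract violation, not a zero score).  The score is 1
    exactly when every comparable attribute agrees, 0 when none does, and
    a mismatch on a share-weighted key costs exactly that key's share.
    """
    if weights is None:
        weights = WeightTable()
    if query.aramany_class != case.aramany_class:
        raise ClassMismatchError(
            f"query is Class {query.aramany_class.value} but case "
            f"{case.case_id} is Class {case.aramany_class.value}")
    comparable = _comparable_keys(query, case)
    if not comparable:
        raise UndefinedScoreError(
            f"no comparable attribute between the query and case {case.case_id}")

    cls = query.aramany_class
    fixed_total = fixed_matched = 0.0
    share_total = share_matched = 0.0
    mismatch = False
    for key in comparable:
        matched = query.attributes[key] == case.attributes[key]
        mismatch |= not matched
        share = weights.shares.get(key)
        if share is not None:
            share_total += share
            if matched:
                share_matched += share
        else:
            w = weights.fixed_weight(cls, key)
            fixed_total += w
            if matched:
                fixed_matched += w
    if not mismatch:
        return 1.0
    if share_total >= 1.0:
        raise ConfigError(
            "share weights of the comparable keys sum to >= 1; "
            "no weight remains for the fixed-weight keys")
    if fixed_total == 0.0:
        # degenerate: only share-weighted keys are comparable
        return share_matched / share_total
    score = (1.0 - share_total) * (fixed_matched / fixed_total) + share_matched
    return min(max(score, 0.0), 1.0)


def shared_keywords(query: QuerySpec, case: cm.CaseRecord) -> tuple[str, ...]:
    """Comparable keys on which query and case agree, in schema order."""
    if query.aramany_class != case.aramany_class:
        raise ClassMismatchError(
            f"query is Class {query.aramany_class.value} but case "
            f"{case.case_id} is Class {case.aramany_class.value}")
    return tuple(
        k for k in _comparable_keys(query, case)
        if query.attributes[k] == case.attributes[k]
    )


def retrieve(query: QuerySpec, casebase: cm.CaseBase,
             weights: WeightTable | None = None,
             k: int = DEFAULT_K) -> RetrievalReport:
    """Score every same-class stored case and return the ranked top k.

    Results are sorted by descending confidence with ties broken by
    ascending case_id, so the output is independent of the case base's row
    order.  An empty candidate pool yields an empty report (with a logged
    notice), not an exception.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if weights is None:
        weights = WeightTable()
    candidates = casebase.of_class(query.aramany_class)
    if not candidates:
        logger.warning(
            "no stored case of Aramany class %s among %d cases; empty result",
            query.aramany_class.value, len(casebase))
        return RetrievalReport(query, (), k)
    scored = sorted(
        ((confidence(query, case, weights), case) for case in candidates),
        key=lambda pair: (-pair[0], pair[1].case_id),
    )
    results = tuple(
        MatchResult(
            case_id=case.case_id,
            confidence=score,
            shared_keys=shared_keywords(query, case),
            rank=rank,
            media_paths=case.media_paths,
        )
        for rank, (score, case) in enumerate(scored[:k], start=1)
    )
    return RetrievalReport(query, results, k)


def flag_eligible(report: RetrievalReport,
                  threshold: float = DEFAULT_ELIGIBILITY_THRESHOLD) -> RetrievalReport:
    """Mark each result eligible iff its confidence is strictly above *threshold*.

    The default 0.90 encodes the similarity floor a retrieved design must
    clear before clinicians consider it a candidate for the new case.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    return replace(
        report,
        results=tuple(
            replace(r, eligible=r.confidence > threshold) for r in report.results
        ),
    )
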