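"""Synthetic case bases, queries and relevance labels.

No clinical data ship with this package.  This module generates schema-valid
stand-ins with the structural features the matcher and evaluator rely on: a
case mix dominated by Aramany Class I and II defects (as hospital obturator
databases typically are), skip-logic-consistent attribute maps, queries at a
controlled distance from a source case, and relevance labels drawn from a
monotone confidence→relevance link.  Everything is deterministic given the
seed, down to byte-identical serialized output.

The generator draws attribute values independently within the schema's
constraints; it makes no attempt to model anatomical covariance between
attributes, and its relevance labels follow a logistic link rather than any
clinical judgment — conclusions drawn from synthetic runs are about the
retrieval machinery, not about real maxillectomy populations.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import case_model as cm
from .errors import ConfigError, GenerationError
from .evaluation import EvaluationSample
from .matcher import DEFAULT_K, WeightTable, retrieve
from .questionnaire import QuerySpec

__all__ = [
    "GeneratorConfig",
    "DEFAULT_CLASS_PROBABILITIES",
    "generate_casebase",
    "perturb_query",
    "generate_evaluation_set",
]

#: Default Aramany class mix: Classes I and II dominate, with central
#: (III), extensive (IV) and the rarer posterior/anterior bilateral defects
#: (V, VI) making up the remainder.
DEFAULT_CLASS_PROBABILITIES: dict[cm.AramanyClass, float] = {
    cm.AramanyClass.I: 0.35,
    cm.AramanyClass.II: 0.30,
    cm.AramanyClass.III: 0.07,
    cm.AramanyClass.IV: 0.10,
    cm.AramanyClass.V: 0.08,
    cm.AramanyClass.VI: 0.10,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic study.

    ``n_cases`` defaults to 209 stored cases and ``perturbation_count`` is
    the maximum number of attribute flips applied to a source case when
    drawing a test query (the actual count is uniform on
    ``0..perturbation_count``).  The relevance link is logistic:
    ``P(relevant) = sigmoid(intercept + slope * confidence)``.  Because
    synthetic attribute values are drawn independently, retrieved
    confidences concentrate around 0.3-0.65 (unlike a real database, where
    same-class cases resemble each other and confidences cluster near 1);
    the defaults (-5.5, 12) span exactly that realized range, rising from
    ~0.13 at confidence 0.3 to ~0.9 at confidence 0.65.  ``slope=0`` gives
    labels independent of confidence (a null link).
    """

    n_cases: int = 209
    class_probabilities: Mapping[cm.AramanyClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBABILITIES))
    seed: int = 0
    perturbation_count: int = 3
    relevance_intercept: float = -5.5
    relevance_slope: float = 12.0

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ConfigError("n_cases must be >= 0")
        if self.perturbation_count < 0:
            raise ConfigError("perturbation_count must be >= 0")
        probs = {cm.AramanyClass(k): float(v)
                 for k, v in self.class_probabilities.items()}
        if any(v < 0 for v in probs.values()):
            raise ConfigError("class probabilities must be non-negative")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ConfigError(
                f"class probabilities must sum to 1, got {sum(probs.values())}")
        object.__setattr__(self, "class_probabilities", probs)

    def relevance_probability(self, confidence: float) -> float:
        z = self.relevance_intercept + self.relevance_slope * confidence
        return 1.0 / (1.0 + math.exp(-z))


def _sample_attributes(aramany_class: cm.AramanyClass,
                       rng: np.random.Generator) -> dict[str, str]:
    """Walk the class schema and draw a value for every applicable key."""
    schema = cm.schema_for_class(aramany_class)
    answers: dict[str, str] = {}
    for item in schema.items:
        if item.applicable(answers):
            vocab = cm.vocabulary_for(aramany_class, item.key)
            answers[item.key] = str(vocab[rng.integers(len(vocab))])
    return answers


def _write_placeholder_png(path: Path) -> None:
    from PIL import Image

    path.parent.mkdir(parents=True, exist_ok=True)
    Image.new("L", (8, 8), color=200).save(path)


def generate_casebase(config: GeneratorConfig,
                      media_dir: str | Path | None = None) -> cm.CaseBase:
    """Generate ``config.n_cases`` schema-valid synthetic case records.

    Class membership is drawn from ``class_probabilities`` and every
    attribute map is produced by walking the class schema, so each record
    passes :func:`~obturator_cbr.case_model.validate_case` by construction.
    ``media_paths`` are placeholder image references; when *media_dir* is
    given, tiny grayscale PNG files are actually written there so the
    end-to-end "open the matched designs" path can be exercised.
    """
    rng = np.random.default_rng(config.seed)
    classes = list(config.class_probabilities)
    probs = np.array([config.class_probabilities[c] for c in classes])
    draws = rng.choice(len(classes), size=config.n_cases, p=probs)
    records = []
    for index, class_index in enumerate(draws):
        aramany_class = classes[int(class_index)]
        case_id = f"C{index + 1:04d}"
        attributes = _sample_attributes(aramany_class, rng)
        if media_dir is not None:
            media_path = Path(media_dir) / f"{case_id}_design.png"
            _write_placeholder_png(media_path)
            media = (str(media_path),)
        else:
            media = (f"media/{case_id}_design.png",)
        records.append(cm.CaseRecord(case_id, aramany_class, attributes, media))
    return cm.CaseBase(records)


def perturb_query(case: cm.CaseRecord, n_perturb: int,
                  seed: int) -> QuerySpec:
    """A query at a controlled distance from a stored case.

    Exactly ``n_perturb`` attributes are flipped to different in-vocabulary
    values, chosen so that the flip changes no skip-logic outcome (the
    applicable key set is preserved, keeping the query schema-valid).  Keys
    whose every alternative value would alter the skip logic are passed
    over and another key is tried.  With ``n_perturb=0`` the query is the
    case's own attribute map.

    For a fixed seed the flipped key sets are nested across increasing
    ``n_perturb``, so confidence against the source case is non-increasing
    in the perturbation count.
    """
    rng = np.random.default_rng(seed)
    attributes = dict(case.attributes)
    schema = cm.schema_for_class(case.aramany_class)
    keys = [k for k in schema.keys if k in attributes]
    if n_perturb > len(keys):
        raise GenerationError(
            f"cannot flip {n_perturb} of {len(keys)} applicable attributes")
    original_keys = set(attributes)
    order = [keys[i] for i in rng.permutation(len(keys))]
    flipped = 0
    for key in order:
        if flipped == n_perturb:
            break
        vocab = [v for v in cm.vocabulary_for(case.aramany_class, key)
                 if v != attributes[key]]
        candidates = [vocab[i] for i in rng.permutation(len(vocab))]
        for value in candidates:
            trial = dict(attributes)
            trial[key] = str(value)
            if set(schema.applicable_keys(trial)) == original_keys:
                attributes = trial
                flipped += 1
                break
    if flipped < n_perturb:
        raise GenerationError(
            f"only {flipped} of the requested {n_perturb} attribute flips "
            f"were feasible for case {case.case_id}")
    return QuerySpec(case.aramany_class, attributes)


def generate_evaluation_set(
    casebase: cm.CaseBase,
    n_tests: int,
    config: GeneratorConfig,
    *,
    k: int = DEFAULT_K,
    weights: WeightTable | None = None,
) -> tuple[list[EvaluationSample], pd.DataFrame]:
    """Simulate a held-out evaluation: queries, retrieval, relevance labels.

    ``n_tests`` source cases are sampled without replacement; each is
    perturbed into a test query (uniform 0..perturbation_count flips) and
    retrieval runs against the case base *with the source case removed*,
    emulating test cases that are not part of the stored database.  Each
    retrieved design then receives a Bernoulli relevance label with success
    probability ``config.relevance_probability(confidence)``.

    Returns the evaluation samples and a label table with columns
    test_id, rank, relevant — the same layout clinician judgments would be
    supplied in.
    """
    if len(casebase) == 0:
        raise GenerationError("cannot draw test queries from an empty case base")
    if n_tests < 3:
        raise ConfigError(f"n_tests must be >= 3, got {n_tests}")
    if n_tests > len(casebase):
        raise ConfigError(
            f"n_tests={n_tests} exceeds the {len(casebase)} stored cases")
    rng = np.random.default_rng([config.seed, 1])
    source_indices = rng.choice(len(casebase), size=n_tests, replace=False)
    samples: list[EvaluationSample] = []
    rows = []
    for i, source_index in enumerate(source_indices):
        source = casebase.cases[int(source_index)]
        n_perturb = int(rng.integers(0, config.perturbation_count + 1))
        child_seed = int(rng.integers(0, 2**31 - 1))
        # Sparse cases (e.g. an intact-arch Class III with no bounded
        # spaces) may not support the drawn number of feasible flips;
        # fall back to the largest count the case admits.
        while True:
            try:
                query = perturb_query(source, n_perturb, seed=child_seed)
                break
            except GenerationError:
                n_perturb -= 1
        pool = cm.CaseBase([c for c in casebase if c.case_id != source.case_id])
        report = retrieve(query, pool, weights, k=k)
        confidences = report.confidences
        labels = tuple(
            bool(rng.random() < config.relevance_probability(c))
            for c in confidences
        )
        test_id = f"T{i + 1:03d}"
        samples.append(EvaluationSample(test_id, confidences, labels))
        rows.extend(
            {"test_id": test_id, "rank": rank, "relevant": int(flag)}
            for rank, flag in enumerate(labels, start=1)
        )
    label_frame = pd.DataFrame(rows, columns=["test_id", "rank", "relevant"])
    return samples, label_frame
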