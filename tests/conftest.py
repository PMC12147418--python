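"""Shared fixtures, hypothesis strategies and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

import obturator_cbr.case_model as cm
from obturator_cbr import GeneratorConfig, generate_casebase
from obturator_cbr.synthetic import _sample_attributes

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


# ---------------------------------------------------------------------------
# Strategies for schema-valid records
# ---------------------------------------------------------------------------

ALL_CLASSES = tuple(cm.AramanyClass)


@st.composite
def attribute_maps(draw, aramany_class: cm.AramanyClass | None = None):
    """(class, attributes) drawn by walking the class schema front to back."""
    cls = aramany_class or draw(st.sampled_from(ALL_CLASSES))
    attrs: dict[str, str] = {}
    for item in cm.schema_for_class(cls).items:
        if item.applicable(attrs):
            attrs[item.key] = draw(
                st.sampled_from(cm.vocabulary_for(cls, item.key)))
    return cls, attrs


@st.composite
def case_records(draw, aramany_class: cm.AramanyClass | None = None):
    cls, attrs = draw(attribute_maps(aramany_class))
    case_id = draw(st.from_regex(r"C[0-9]{3}", fullmatch=True))
    media = draw(st.lists(
        st.from_regex(r"media/[A-Za-z0-9 _-]{1,12}\.png", fullmatch=True),
        min_size=1, max_size=3))
    return cm.CaseRecord(case_id, cls, attrs, tuple(media))


@st.composite
def case_bases(draw, max_size: int = 6):
    n = draw(st.integers(min_value=0, max_value=max_size))
    records = []
    for i in range(n):
        record = draw(case_records())
        records.append(cm.CaseRecord(
            f"C{i:04d}", record.aramany_class, record.attributes,
            record.media_paths))
    return cm.CaseBase(records)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def midranks(values) -> list[float]:
    """Average-rank assignment, written independently of scipy."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        average = (i + j) / 2 + 1  # ranks are 1-based
        for t in range(i, j + 1):
            ranks[order[t]] = average
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    """Pearson correlation of mid-ranks (exact under ties), brute force."""
    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den


def confidence_oracle(query, case, *, default_weight=1.0, shares=None) -> float:
    """Explicit-weight brute force: materialize each share key's weight as
    f * S / (1 - c*f) (S = fixed total, c = number of comparable share keys,
    all shares equal f) and take the plain weighted matched fraction."""
    if shares is None:
        from obturator_cbr.matcher import _DEFAULT_SHARES
        shares = _DEFAULT_SHARES
    schema = cm.schema_for_class(query.aramany_class)
    comparable = [k for k in schema.keys
                  if k in query.attributes and k in case.attributes]
    share_keys = [k for k in comparable if k in shares]
    fixed_keys = [k for k in comparable if k not in shares]
    S = default_weight * len(fixed_keys)
    weights = {k: default_weight for k in fixed_keys}
    if share_keys:
        fractions = [shares[k] for k in share_keys]
        F = sum(fractions)
        if S == 0:
            weights.update({k: shares[k] for k in share_keys})
        else:
            total = S / (1 - F)
            weights.update({k: shares[k] * total for k in share_keys})
    total = sum(weights.values())
    matched = sum(w for k, w in weights.items()
                  if query.attributes[k] == case.attributes[k])
    return matched / total


def random_casebase(rng: np.random.Generator, n: int,
                    aramany_class: cm.AramanyClass | None = None) -> cm.CaseBase:
    """A quick seeded case base for oracle sweeps (ids shuffled on purpose)."""
    classes = list(cm.AramanyClass)
    ids = [f"C{i:03d}" for i in rng.permutation(n)]
    records = []
    for i in range(n):
        cls = aramany_class or classes[int(rng.integers(len(classes)))]
        attrs = _sample_attributes(cls, rng)
        records.append(cm.CaseRecord(ids[i], cls, attrs, (f"m/{ids[i]}.png",)))
    return cm.CaseBase(records)


@pytest.fixture(scope="session")
def casebase_209() -> cm.CaseBase:
    """One default-configuration synthetic case base shared across tests."""
    return generate_casebase(GeneratorConfig(seed=11))
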