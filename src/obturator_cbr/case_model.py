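"""Case records, controlled vocabularies and per-class attribute schemas.

A stored maxillectomy case is a flat keyword record: a case ID, an Aramany
defect class, a map of categorical attributes describing the oral condition
(abutments, defect extension, bounded edentulous spaces, oronasal connection,
...), and paths to the images of the definitive obturator delivered for that
case.  Which attributes apply depends on the Aramany class and, through skip
logic, on earlier attribute values; :func:`schema_for_class` is the single
source of truth for that dependency structure, used by the questionnaire, the
matcher, the validator and the synthetic generator alike.

The on-disk representation is a UTF-8 CSV with a header row: one column per
attribute key plus ``case_id``, ``aramany_class`` and ``media_paths``
(semicolon-joined).  Cells for attributes that do not apply to a case are
left empty.  ``.xlsx`` workbooks with the same columns are accepted on input.
"""

from __future__ import annotations

import enum
import json
import warnings
from collections.abc import Callable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import CaseValidationError, IntegrityError, SchemaError, VocabularyError

__all__ = [
    "AramanyClass",
    "ToothRef",
    "CaseRecord",
    "CaseBase",
    "ClassSchema",
    "SchemaItem",
    "ValidationIssue",
    "schema_for_class",
    "vocabulary_for",
    "validate_attributes",
    "validate_case",
    "load_casebase",
    "save_casebase",
    "schema_to_json",
    "ALL_ATTRIBUTE_KEYS",
]


class AramanyClass(enum.Enum):
    """The six Aramany classes of partially edentulous maxillectomy defects.

    I: hemi-maxillectomy; II: unilateral defect sparing the premaxilla on the
    defect side; III: central palatal defect with intact dentition; IV: defect
    crossing the midline; V: bilateral defect posterior to the remaining
    abutments; VI: defect anterior to the remaining abutments.
    """

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    VI = "VI"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# ---------------------------------------------------------------------------
# Teeth (FDI notation, maxillary arch only)
# ---------------------------------------------------------------------------

#: FDI two-digit codes for the maxillary arch: quadrant 1 (upper right) and
#: quadrant 2 (upper left), positions 1 (central incisor) .. 8 (third molar).
TOOTH_CODES: tuple[str, ...] = tuple(
    f"{q}{p}" for q in (1, 2) for p in range(1, 9)
)

_TOOTH_TYPES = {1: "incisor", 2: "incisor", 3: "canine", 4: "premolar",
                5: "premolar", 6: "molar", 7: "molar", 8: "molar"}


@dataclass(frozen=True)
class ToothRef:
    """A maxillary tooth in FDI two-digit notation (11-18, 21-28)."""

    code: str

    def __post_init__(self) -> None:
        if self.code not in TOOTH_CODES:
            raise VocabularyError(
                f"{self.code!r} is not a maxillary FDI tooth code (11-18, 21-28)"
            )

    @property
    def quadrant(self) -> int:
        return int(self.code[0])

    @property
    def position(self) -> int:
        return int(self.code[1])

    @property
    def tooth_type(self) -> str:
        """incisor / canine / premolar / molar, derived from the position digit."""
        return _TOOTH_TYPES[self.position]

    @property
    def is_anterior(self) -> bool:
        """Incisors and canines (positions 1-3)."""
        return self.position <= 3

    @property
    def is_posterior(self) -> bool:
        return self.position >= 4


def tooth_type(code: str) -> str:
    return ToothRef(code).tooth_type


# ---------------------------------------------------------------------------
# Attribute keys and controlled vocabularies
# ---------------------------------------------------------------------------

ARAMANY_CLASS_KEY = "aramany_class"

NEAREST_ABUTMENT = "nearest_abutment"
LAST_TOOTH = "last_tooth"
DEFECT_EXTENSION = "defect_extension"
ABUTMENT_CONDITION = "abutment_condition"
BOUNDED_SPACE_COUNT = "bounded_space_count"
BOUNDED_SPACE_LOCATION = "bounded_space_location"
BOUNDED_SPACE_DISTRIBUTION = "bounded_space_distribution"
ORONASAL_CONNECTION = "oronasal_connection"
DEFECT_SIDE_REMAINING_TEETH = "defect_side_remaining_teeth"
ARCH_CLASSIFICATION = "arch_classification"
POSTERIOR_ABUTMENTS = "posterior_abutments"
BOTH_PREMOLARS_PRESENT = "both_premolars_present"
REMAINING_MOLAR_COUNT = "remaining_molar_count"

#: Side suffixes for Class VI, where the abutment questions are answered once
#: per side of the arch.  The right side is interviewed first.
RIGHT, LEFT = "_right", "_left"


def _sided(key: str) -> tuple[str, str]:
    return key + RIGHT, key + LEFT


NEAREST_ABUTMENT_R, NEAREST_ABUTMENT_L = _sided(NEAREST_ABUTMENT)
LAST_TOOTH_R, LAST_TOOTH_L = _sided(LAST_TOOTH)
BOTH_PREMOLARS_R, BOTH_PREMOLARS_L = _sided(BOTH_PREMOLARS_PRESENT)
MOLAR_COUNT_R, MOLAR_COUNT_L = _sided(REMAINING_MOLAR_COUNT)

#: Canonical column order for the flat case table (union over all classes).
ALL_ATTRIBUTE_KEYS: tuple[str, ...] = (
    NEAREST_ABUTMENT, NEAREST_ABUTMENT_R, NEAREST_ABUTMENT_L,
    LAST_TOOTH, LAST_TOOTH_R, LAST_TOOTH_L,
    DEFECT_EXTENSION,
    ABUTMENT_CONDITION,
    BOUNDED_SPACE_COUNT, BOUNDED_SPACE_LOCATION, BOUNDED_SPACE_DISTRIBUTION,
    ORONASAL_CONNECTION,
    DEFECT_SIDE_REMAINING_TEETH,
    ARCH_CLASSIFICATION, POSTERIOR_ABUTMENTS,
    BOTH_PREMOLARS_R, BOTH_PREMOLARS_L, BOTH_PREMOLARS_PRESENT,
    MOLAR_COUNT_R, MOLAR_COUNT_L, REMAINING_MOLAR_COUNT,
)

_BASE_VOCAB: dict[str, tuple[str, ...]] = {
    NEAREST_ABUTMENT: TOOTH_CODES,
    LAST_TOOTH: TOOTH_CODES,
    POSTERIOR_ABUTMENTS: TOOTH_CODES,
    ABUTMENT_CONDITION: (
        "healthy", "periodontally_compromised", "weak_lateral_incisor",
        "overdenture_root",
    ),
    BOUNDED_SPACE_COUNT: ("none", "single", "double", "triple", "multiple"),
    BOUNDED_SPACE_LOCATION: ("anterior", "posterior"),
    BOUNDED_SPACE_DISTRIBUTION: ("unilateral", "bilateral"),
    ORONASAL_CONNECTION: (
        "entire_defect", "partial_defect", "small_fistula",
        "surgically_reconstructed", "no_connection",
    ),
    DEFECT_SIDE_REMAINING_TEETH: ("posterior_only", "anterior_and_posterior"),
    ARCH_CLASSIFICATION: (
        "bilateral_distal_extension", "unilateral_distal_extension",
        "bounded_saddle", "intact_arch",
    ),
    BOTH_PREMOLARS_PRESENT: ("yes", "no"),
    REMAINING_MOLAR_COUNT: ("one", "two", "three", "four_or_more"),
}
# side-suffixed keys share the base key's vocabulary
for _k in (NEAREST_ABUTMENT, LAST_TOOTH, BOTH_PREMOLARS_PRESENT,
           REMAINING_MOLAR_COUNT):
    for _s in _sided(_k):
        _BASE_VOCAB[_s] = _BASE_VOCAB[_k]

#: defect_extension is the one key whose vocabulary depends on the class:
#: Class II records how many quadrants the defect involves, Class VI whether
#: it is limited to the anterior region or extends onto the hard palate.
_DEFECT_EXTENSION_VOCAB: dict[AramanyClass, tuple[str, ...]] = {
    AramanyClass.II: ("one_quadrant", "two_quadrants"),
    AramanyClass.VI: ("anterior_only", "extends_onto_hard_palate"),
}


def vocabulary_for(aramany_class: AramanyClass, key: str) -> tuple[str, ...]:
    """Controlled vocabulary for *key* in the context of *aramany_class*."""
    if key == ARAMANY_CLASS_KEY:
        return tuple(c.value for c in AramanyClass)
    if key == DEFECT_EXTENSION:
        try:
            return _DEFECT_EXTENSION_VOCAB[aramany_class]
        except KeyError:
            raise VocabularyError(
                f"defect_extension does not apply to Class {aramany_class.value}"
            ) from None
    try:
        return _BASE_VOCAB[key]
    except KeyError:
        raise VocabularyError(f"unknown attribute key {key!r}") from None


# ---------------------------------------------------------------------------
# Per-class schemas with conditional (skip-logic) predicates
# ---------------------------------------------------------------------------

Predicate = Callable[[Mapping[str, str]], bool]


@dataclass(frozen=True)
class SchemaItem:
    """One attribute slot of a class schema.

    ``condition`` is a predicate over the attributes answered *earlier* in
    schema order; ``None`` means the key is unconditionally required.
    ``condition_desc`` is a human-readable rendering used in JSON exports.
    """

    key: str
    condition: Predicate | None = None
    condition_desc: str | None = None

    def applicable(self, attributes: Mapping[str, str]) -> bool:
        return self.condition is None or self.condition(attributes)


@dataclass(frozen=True)
class ClassSchema:
    """The ordered attribute schema of one Aramany class."""

    aramany_class: AramanyClass
    items: tuple[SchemaItem, ...]

    @property
    def required_keys(self) -> tuple[str, ...]:
        return tuple(i.key for i in self.items if i.condition is None)

    @property
    def conditional_keys(self) -> tuple[SchemaItem, ...]:
        return tuple(i for i in self.items if i.condition is not None)

    @property
    def keys(self) -> tuple[str, ...]:
        return tuple(i.key for i in self.items)

    def applicable_keys(self, attributes: Mapping[str, str]) -> tuple[str, ...]:
        """Keys applicable under *attributes* (evaluated in schema order)."""
        return tuple(i.key for i in self.items if i.applicable(attributes))


def _has_spaces(a: Mapping[str, str]) -> bool:
    return a.get(BOUNDED_SPACE_COUNT, "none") != "none"


def _tooth_is(key: str, *types: str) -> Predicate:
    def pred(a: Mapping[str, str]) -> bool:
        code = a.get(key)
        return code in TOOTH_CODES and tooth_type(code) in types
    return pred


def _arch_is_distal_extension(a: Mapping[str, str]) -> bool:
    return a.get(ARCH_CLASSIFICATION) in (
        "bilateral_distal_extension", "unilateral_distal_extension"
    )


_SPACES_DESC = "bounded_space_count != none"


def _build_schemas() -> dict[AramanyClass, ClassSchema]:
    r = SchemaItem  # terse alias for the tables below

    def abutment_block(side: str = "") -> list[SchemaItem]:
        return [r(NEAREST_ABUTMENT + side), r(LAST_TOOTH + side)]

    def spaces_block(with_distribution: bool) -> list[SchemaItem]:
        items = [
            r(BOUNDED_SPACE_COUNT),
            r(BOUNDED_SPACE_LOCATION, _has_spaces, _SPACES_DESC),
        ]
        if with_distribution:
            items.append(r(BOUNDED_SPACE_DISTRIBUTION, _has_spaces, _SPACES_DESC))
        return items

    def retainer_followups(side: str = "") -> list[SchemaItem]:
        lt = LAST_TOOTH + side
        return [
            r(BOTH_PREMOLARS_PRESENT + side, _tooth_is(lt, "premolar"),
              f"{lt} is a premolar"),
            r(REMAINING_MOLAR_COUNT + side, _tooth_is(lt, "molar"),
              f"{lt} is a molar"),
        ]

    schemas: dict[AramanyClass, ClassSchema] = {}

    # Class I (hemi-maxillectomy) and IV (defect crossing the midline) keep
    # their remaining teeth on one side only, so bounded-space distribution
    # (unilateral/bilateral) never applies; defect extension is evident from
    # the class itself.
    for cls in (AramanyClass.I, AramanyClass.IV):
        schemas[cls] = ClassSchema(cls, tuple(
            abutment_block()
            + [r(ABUTMENT_CONDITION)]
            + spaces_block(with_distribution=False)
            + [r(ORONASAL_CONNECTION)]
            + retainer_followups()
        ))

    # Class II: unilateral posterior defect sparing the premaxilla.  The
    # defect may involve one or two quadrants; when the nearest abutment is a
    # premolar or molar the user further records whether any anterior teeth
    # remain on the defect side (skipped for an anterior nearest abutment).
    schemas[AramanyClass.II] = ClassSchema(AramanyClass.II, tuple(
        abutment_block()
        + [r(DEFECT_EXTENSION), r(ABUTMENT_CONDITION)]
        + spaces_block(with_distribution=True)
        + [r(ORONASAL_CONNECTION),
           r(DEFECT_SIDE_REMAINING_TEETH,
             _tooth_is(NEAREST_ABUTMENT, "premolar", "molar"),
             "nearest_abutment is a premolar or molar")]
        + retainer_followups()
    ))

    # Class III: central palatal defect with intact dentition; described via
    # the dental-arch classification (with the most posterior abutments for
    # distal-extension arches) rather than defect-bordering abutments.
    schemas[AramanyClass.III] = ClassSchema(AramanyClass.III, tuple(
        [r(ARCH_CLASSIFICATION),
         r(POSTERIOR_ABUTMENTS, _arch_is_distal_extension,
           "arch_classification is a distal extension")]
        + spaces_block(with_distribution=True)
        + [r(ORONASAL_CONNECTION)]
    ))

    # Class V: bilateral posterior defect behind the remaining abutments.
    schemas[AramanyClass.V] = ClassSchema(AramanyClass.V, tuple(
        abutment_block()
        + [r(ABUTMENT_CONDITION)]
        + spaces_block(with_distribution=True)
        + [r(ORONASAL_CONNECTION)]
        + retainer_followups()
    ))

    # Class VI: anterior defect; abutment questions are answered once per
    # side (right first), and the last-tooth follow-ups follow each side.
    schemas[AramanyClass.VI] = ClassSchema(AramanyClass.VI, tuple(
        abutment_block(RIGHT) + abutment_block(LEFT)
        + [r(DEFECT_EXTENSION), r(ABUTMENT_CONDITION)]
        + spaces_block(with_distribution=True)
        + [r(ORONASAL_CONNECTION)]
        + retainer_followups(RIGHT) + retainer_followups(LEFT)
    ))
    return schemas


_SCHEMAS = _build_schemas()


def schema_for_class(aramany_class: AramanyClass) -> ClassSchema:
    """Return the ordered attribute schema for an Aramany class.

    The schema drives the dynamic questionnaire, record validation and the
    comparable-key ordering of the matcher.  Conditional items reference only
    keys earlier in the order, so the schema can be walked front to back.
    """
    return _SCHEMAS[AramanyClass(aramany_class)]


def schema_to_json(aramany_class: AramanyClass) -> dict:
    """JSON-serializable description of a class schema (for documentation)."""
    schema = schema_for_class(aramany_class)
    return {
        "aramany_class": schema.aramany_class.value,
        "items": [
            {
                "key": item.key,
                "condition": item.condition_desc,
                "vocabulary": list(vocabulary_for(aramany_class, item.key)),
            }
            for item in schema.items
        ],
    }


# ---------------------------------------------------------------------------
# Records, validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationIssue:
    key: str
    reason: str
    kind: str  # missing_required | inapplicable_key | unknown_key | bad_value | no_media

    def __str__(self) -> str:
        return f"[{self.kind}] {self.key}: {self.reason}"


@dataclass(frozen=True)
class CaseRecord:
    """One stored maxillectomy case (keywords + design-image references)."""

    case_id: str
    aramany_class: AramanyClass
    attributes: Mapping[str, str]
    media_paths: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", dict(self.attributes))
        object.__setattr__(self, "media_paths", tuple(self.media_paths))


def validate_attributes(aramany_class: AramanyClass,
                        attributes: Mapping[str, str]) -> list[ValidationIssue]:
    """Check an attribute map against its class schema.

    Returns an empty list iff the map carries exactly the applicable keys
    (given the skip logic evaluated on the map itself) and every value is in
    its key's vocabulary.  Issues are data, not exceptions.
    """
    schema = schema_for_class(aramany_class)
    issues: list[ValidationIssue] = []
    applicable = set(schema.applicable_keys(attributes))
    schema_keys = set(schema.keys)
    for key in schema.keys:
        if key in applicable and key not in attributes:
            issues.append(ValidationIssue(key, "missing required key", "missing_required"))
        elif key not in applicable and key in attributes:
            issues.append(ValidationIssue(
                key, f"inapplicable key for Class {aramany_class.value}",
                "inapplicable_key"))
    for key, value in attributes.items():
        if key not in schema_keys:
            if key in ALL_ATTRIBUTE_KEYS:
                issues.append(ValidationIssue(
                    key,
                    f"inapplicable key for Class {aramany_class.value}",
                    "inapplicable_key"))
            else:
                issues.append(ValidationIssue(key, "unknown attribute key",
                                              "unknown_key"))
            continue
        try:
            vocab = vocabulary_for(aramany_class, key)
        except VocabularyError:
            vocab = ()
        if vocab and value not in vocab:
            issues.append(ValidationIssue(
                key, f"value {value!r} not in vocabulary {sorted(vocab)}",
                "bad_value"))
    return issues


def validate_case(record: CaseRecord) -> list[ValidationIssue]:
    """Validate a stored case: schema conformance plus non-empty media."""
    issues = validate_attributes(record.aramany_class, record.attributes)
    if not record.media_paths:
        issues.append(ValidationIssue(
            "media_paths", "a stored case must reference at least one design image",
            "no_media"))
    return issues


@dataclass
class CaseBase:
    """An ordered collection of case records with unique IDs."""

    cases: list[CaseRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for case in self.cases:
            if case.case_id in seen:
                raise IntegrityError(f"duplicate case_id {case.case_id!r}")
            seen.add(case.case_id)

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self) -> Iterator[CaseRecord]:
        return iter(self.cases)

    def __getitem__(self, case_id: str) -> CaseRecord:
        for case in self.cases:
            if case.case_id == case_id:
                return case
        raise KeyError(case_id)

    def of_class(self, aramany_class: AramanyClass) -> list[CaseRecord]:
        return [c for c in self.cases if c.aramany_class == aramany_class]


# ---------------------------------------------------------------------------
# Flat-table I/O
# ---------------------------------------------------------------------------

_FIXED_COLUMNS = ("case_id", ARAMANY_CLASS_KEY)
_MEDIA_COLUMN = "media_paths"
_MEDIA_SEP = ";"


def _row_to_record(row: Mapping[str, str], row_number: int) -> CaseRecord:
    case_id = str(row["case_id"]).strip()
    if not case_id:
        raise CaseValidationError(f"row {row_number}: empty case_id")
    try:
        cls = AramanyClass(str(row[ARAMANY_CLASS_KEY]).strip())
    except ValueError:
        raise CaseValidationError(
            f"row {row_number} (case {case_id}): aramany_class "
            f"{row[ARAMANY_CLASS_KEY]!r} is not one of "
            f"{[c.value for c in AramanyClass]}") from None
    attributes = {
        key: str(row[key]).strip()
        for key in ALL_ATTRIBUTE_KEYS
        if key in row and str(row[key]).strip() != ""
    }
    media_raw = str(row.get(_MEDIA_COLUMN, "")).strip()
    media = tuple(p for p in media_raw.split(_MEDIA_SEP) if p) if media_raw else ()
    return CaseRecord(case_id, cls, attributes, media)


def load_casebase(path: str | Path, *, strict: bool = True) -> CaseBase:
    """Load a case base from a CSV (or .xlsx) flat table.

    Parameters
    ----------
    path:
        The table file.  ``.xlsx`` is read with the same column layout;
        anything else is treated as CSV.
    strict:
        When true (default), any record failing :func:`validate_case` raises
        :class:`CaseValidationError` naming the row and keys.  When false,
        vocabulary and schema issues are reported as warnings instead —
        useful when triaging a legacy spreadsheet.

    Raises
    ------
    SchemaError
        if a required column (case_id, aramany_class, media_paths) is absent.
    IntegrityError
        if two rows share a case_id.
    CaseValidationError
        under ``strict`` for any vocabulary or schema violation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"case base not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        frame = pd.read_excel(path, dtype=str)
    else:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame = frame.fillna("")

    for column in (*_FIXED_COLUMNS, _MEDIA_COLUMN):
        if column not in frame.columns:
            raise SchemaError(f"{path}: missing required column {column!r}")
    unknown = [c for c in frame.columns
               if c not in (*_FIXED_COLUMNS, _MEDIA_COLUMN, *ALL_ATTRIBUTE_KEYS)]
    if unknown:
        warnings.warn(
            f"{path}: ignoring unknown columns {unknown}", stacklevel=2)

    records: list[CaseRecord] = []
    problems: list[str] = []
    all_issues: list[ValidationIssue] = []
    for i, row in enumerate(frame.to_dict(orient="records")):
        record = _row_to_record(row, i + 2)  # +2: header + 1-based rows
        issues = validate_case(record)
        if issues:
            all_issues.extend(issues)
            problems.append(
                f"row {i + 2} (case {record.case_id}): "
                + "; ".join(str(x) for x in issues))
        records.append(record)

    if problems:
        if strict:
            raise CaseValidationError(
                f"{path}: {len(problems)} invalid record(s)\n  "
                + "\n  ".join(problems), issues=all_issues)
        warnings.warn(f"{path}: {len(problems)} invalid record(s)", stacklevel=2)
    return CaseBase(records)


def save_casebase(casebase: CaseBase, path: str | Path) -> Path:
    """Write a case base as a UTF-8 CSV flat table; returns the path.

    ``save`` then :func:`load_casebase` reproduces every field exactly: cells
    are written as plain strings, inapplicable attributes as empty cells and
    media paths joined with ``;``.
    """
    path = Path(path)
    columns = [*_FIXED_COLUMNS, *ALL_ATTRIBUTE_KEYS, _MEDIA_COLUMN]
    rows = []
    for case in casebase:
        row = dict.fromkeys(columns, "")
        row["case_id"] = case.case_id
        row[ARAMANY_CLASS_KEY] = case.aramany_class.value
        row.update(case.attributes)
        row[_MEDIA_COLUMN] = _MEDIA_SEP.join(case.media_paths)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, index=False, encoding="utf-8")
    return path


def casebase_to_json(casebase: CaseBase) -> str:
    """A stable JSON rendering (used for byte-identity checks and debugging)."""
    payload = [
        {
            "case_id": c.case_id,
            "aramany_class": c.aramany_class.value,
            "attributes": dict(c.attributes),
            "media_paths": list(c.media_paths),
        }
        for c in casebase
    ]
    return json.dumps(payload, indent=2, sort_keys=True)
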