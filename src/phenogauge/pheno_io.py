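"""Reading and validation of phenopackets and ranked differential-diagnosis responses.

The GA4GH Phenopacket Schema v2 is the input standard for case data: one
document per patient carrying observed and excluded Human Phenotype Ontology
(HPO) terms, demographics, and the gold-standard (solved) diagnosis as an
OMIM/Orphanet/Mondo identifier. Method outputs — differential diagnoses —
arrive either as free text in which candidate diseases are enumerated one
per line (the typical LLM response), or as identifier lists, one CURIE per
line with an optional score column (the typical ranked output of a
phenotype-matching tool such as Exomiser).

Only the v2 JSON dialect is accepted; v1 documents are rejected with a
versioned error. Variant/genomic blocks inside phenopackets are ignored:
the benchmark is phenotype-only.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "DiseaseRef",
    "PhenotypeFeature",
    "CaseRecord",
    "Differential",
    "Cohort",
    "PhenopacketError",
    "PhenopacketParseError",
    "PhenopacketValidationError",
    "CohortEmptyError",
    "read_phenopacket",
    "read_cohort",
    "read_ranked_response",
    "case_record_to_dict",
    "case_record_from_dict",
    "write_cohort_manifest",
    "write_differentials_jsonl",
    "read_differentials_jsonl",
]

HP_CURIE = re.compile(r"^HP:\d{7}$")
CURIE = re.compile(r"^[A-Za-z][A-Za-z0-9]*:\S+$")

#: Disease-nomenclature prefixes accepted for gold diagnoses. The X-suffixed
#: prefixes are reserved for synthetic test identifiers so that accidental
#: mixing of simulated and real ontologies is detectable.
DISEASE_PREFIXES = frozenset(
    {"OMIM", "ORPHA", "MONDO", "OMIMX", "ORPHAX", "MONDOX"}
)

SEXES = ("male", "female", "other", "unknown")
_PPKT_SEX = {
    "MALE": "male",
    "FEMALE": "female",
    "OTHER_SEX": "other",
    "UNKNOWN_SEX": "unknown",
}


class PhenopacketError(ValueError):
    """Base class for phenopacket reading problems."""


class PhenopacketParseError(PhenopacketError):
    """The document is not well-formed JSON."""


class PhenopacketValidationError(PhenopacketError):
    """The document is JSON but violates the expected v2 structure.

    ``path`` names the missing or offending field.
    """

    def __init__(self, message: str, path: str):
        super().__init__(f"{message} (at {path!r})")
        self.path = path


class CohortEmptyError(PhenopacketError):
    """A cohort directory yielded no parseable phenopackets."""


@dataclass(frozen=True)
class DiseaseRef:
    """A disease identifier in one nomenclature, with its display label."""

    id: str
    label: str = ""

    def __post_init__(self) -> None:
        if not CURIE.match(self.id):
            raise ValueError(f"not a CURIE: {self.id!r}")
        if self.prefix not in DISEASE_PREFIXES:
            raise ValueError(
                f"unsupported disease nomenclature {self.prefix!r} in {self.id!r}"
            )

    @property
    def prefix(self) -> str:
        return self.id.split(":", 1)[0]


@dataclass(frozen=True)
class PhenotypeFeature:
    """One observed or excluded phenotypic abnormality (an HPO term)."""

    term_id: str
    label: str
    excluded: bool = False
    onset_age: str | None = None  # ISO-8601 duration, stored verbatim

    def __post_init__(self) -> None:
        if not HP_CURIE.match(self.term_id):
            raise ValueError(f"not an HP CURIE: {self.term_id!r}")


@dataclass
class CaseRecord:
    """Structured content of one phenopacket.

    ``age_at_last_exam`` and ``disease_onset`` are ISO-8601 durations kept
    verbatim (lossless); they are rendered to words only at prompt time.
    """

    case_id: str
    sex: str = "unknown"
    age_at_last_exam: str | None = None
    features: list[PhenotypeFeature] = field(default_factory=list)
    gold_diagnosis: DiseaseRef | None = None
    disease_onset: str | None = None
    source_publication: str | None = None

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")

    def observed(self) -> list[PhenotypeFeature]:
        return [f for f in self.features if not f.excluded]

    def excluded(self) -> list[PhenotypeFeature]:
        return [f for f in self.features if f.excluded]


@dataclass
class Differential:
    """An ordered differential diagnosis for one case from one method.

    ``items`` holds free-text candidate strings or :class:`DiseaseRef`
    objects (identifier mode). Position ``i`` is rank ``i + 1``. Duplicates
    are kept on input; de-duplication is an evaluation-time decision.
    """

    case_id: str
    method_id: str
    items: list = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass
class Cohort:
    """Result of reading a directory of phenopackets."""

    records: list[CaseRecord]
    failures: list[tuple[str, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# phenopacket reading


def _require(doc: dict, path: str):
    node = doc
    for part in path.split("."):
        if not isinstance(node, dict) or part not in node:
            raise PhenopacketValidationError("missing required field", path)
        node = node[part]
    return node


def _age_duration(node) -> str | None:
    if isinstance(node, dict):
        age = node.get("age")
        if isinstance(age, dict):
            return age.get("iso8601duration")
    return None


def _gold_from_doc(doc: dict) -> DiseaseRef:
    # Preferred location: the solved interpretation's diagnosis block.
    for interp in doc.get("interpretations", []):
        disease = interp.get("diagnosis", {}).get("disease")
        if disease and disease.get("id"):
            return DiseaseRef(disease["id"], disease.get("label", ""))
    for entry in doc.get("diseases", []):
        term = entry.get("term")
        if term and term.get("id"):
            return DiseaseRef(term["id"], term.get("label", ""))
    raise PhenopacketValidationError(
        "no gold diagnosis found", "interpretations[0].diagnosis.disease"
    )


def read_phenopacket(document: str) -> CaseRecord:
    """Parse a phenopacket v2 JSON document into a :class:`CaseRecord`.

    Observed and excluded features are separated; unknown schema fields are
    ignored; the gold diagnosis is taken from the interpretation block,
    falling back to the ``diseases`` list. v1 documents are rejected.
    """
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as exc:
        raise PhenopacketParseError(f"malformed JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise PhenopacketParseError("document root must be a JSON object")

    version = doc.get("metaData", {}).get("phenopacketSchemaVersion")
    if "phenotypes" in doc or (version is not None and not str(version).startswith("2")):
        raise PhenopacketValidationError(
            f"only phenopacket schema v2 is supported (got version {version!r})",
            "metaData.phenopacketSchemaVersion",
        )

    subject = _require(doc, "subject")
    case_id = doc.get("id") or subject.get("id")
    if not case_id:
        raise PhenopacketValidationError("missing case identifier", "id")

    sex = _PPKT_SEX.get(subject.get("sex", "UNKNOWN_SEX"), "unknown")
    last_exam = _age_duration(subject.get("timeAtLastEncounter"))

    features = []
    for pf in doc.get("phenotypicFeatures", []):
        term = pf.get("type", {})
        if not term.get("id"):
            raise PhenopacketValidationError(
                "phenotypic feature without a term id", "phenotypicFeatures[].type.id"
            )
        features.append(
            PhenotypeFeature(
                term_id=term["id"],
                label=term.get("label", ""),
                excluded=bool(pf.get("excluded", False)),
                onset_age=_age_duration(pf.get("onset")),
            )
        )

    gold = _gold_from_doc(doc)

    disease_onset = None
    for entry in doc.get("diseases", []):
        onset = _age_duration(entry.get("onset"))
        if onset:
            disease_onset = onset
            break

    source = None
    refs = doc.get("metaData", {}).get("externalReferences", [])
    if refs and isinstance(refs, list) and refs[0].get("id"):
        source = refs[0]["id"]

    return CaseRecord(
        case_id=case_id,
        sex=sex,
        age_at_last_exam=last_exam,
        features=features,
        gold_diagnosis=gold,
        disease_onset=disease_onset,
        source_publication=source,
    )


def read_cohort(directory: str | Path, pattern: str = "*.json") -> Cohort:
    """Read every phenopacket in ``directory``.

    Records are ordered lexicographically by ``case_id`` (independent of
    filesystem enumeration order); per-file failures are collected in
    ``Cohort.failures`` rather than silently dropped.
    """
    directory = Path(directory)
    records: list[CaseRecord] = []
    failures: list[tuple[str, str]] = []
    for path in sorted(directory.glob(pattern)):
        try:
            records.append(read_phenopacket(path.read_text()))
        except PhenopacketError as exc:
            failures.append((path.name, str(exc)))
    if not records:
        raise CohortEmptyError(
            f"no parseable phenopackets in {directory} "
            f"({len(failures)} failed file(s))"
        )
    records.sort(key=lambda r: r.case_id)
    seen: set[str] = set()
    for rec in records:
        if rec.case_id in seen:
            raise PhenopacketValidationError(
                f"duplicate case_id {rec.case_id!r} in cohort", "id"
            )
        seen.add(rec.case_id)
    return Cohort(records=records, failures=failures)


# ---------------------------------------------------------------------------
# ranked-response reading

_NUMBERED = re.compile(r"^\s*(?:rank\s+)?(\d+)\s*[.):\]]\s*(.*)$", re.IGNORECASE)
_BULLET = re.compile(r"^\s*[-*•]\s+(.*)$")


def _clean_item(text: str) -> str:
    return text.strip().rstrip(".,;:").strip()


def read_ranked_response(
    text: str,
    mode: str = "free_text",
    case_id: str = "",
    method_id: str = "",
) -> Differential:
    """Parse a ranked differential-diagnosis response.

    ``free_text`` mode extracts an ordered candidate list from numbered
    ("1.", "2)", "3:", "Rank 4:") or bulleted ("-", "*") lines, stripping
    enumeration markers and trailing punctuation. Non-matching, non-blank
    lines inside an otherwise-listed block are treated as continuations of
    the previous item (LLM outputs wrap lines). ``identifier_list`` mode
    parses one CURIE per line with an optional tab-separated score column.

    Unparseable text never raises: it yields an empty differential carrying
    a warning record.
    """
    diff = Differential(case_id=case_id, method_id=method_id)
    if mode not in ("free_text", "identifier_list"):
        raise ValueError(f"unknown mode {mode!r}")

    if mode == "identifier_list":
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            ident = line.split("\t", 1)[0].strip()
            try:
                diff.items.append(DiseaseRef(ident))
            except ValueError:
                diff.warnings.append(f"unparseable identifier line: {line!r}")
        if text.strip() and not diff.items:
            diff.warnings.append("no identifiers recognised in response")
        return diff

    in_block = False
    last_blank = True
    for line in text.splitlines():
        m = _NUMBERED.match(line) or _BULLET.match(line)
        if m:
            item = _clean_item(m.group(m.lastindex))
            if item:
                diff.items.append(item)
                in_block = True
            last_blank = False
            continue
        if not line.strip():
            last_blank = True
            continue
        if in_block and diff.items and not last_blank:
            # continuation of a wrapped item
            diff.items[-1] = _clean_item(diff.items[-1] + " " + line.strip())
        last_blank = False
    if text.strip() and not diff.items:
        diff.warnings.append("no list items recognised in response")
    return diff


# ---------------------------------------------------------------------------
# internal serial form and tabular artifacts


def case_record_to_dict(case: CaseRecord) -> dict:
    """Lossless internal serial form (JSON-compatible) of a CaseRecord."""
    return {
        "case_id": case.case_id,
        "sex": case.sex,
        "age_at_last_exam": case.age_at_last_exam,
        "disease_onset": case.disease_onset,
        "source_publication": case.source_publication,
        "gold_diagnosis": (
            {"id": case.gold_diagnosis.id, "label": case.gold_diagnosis.label}
            if case.gold_diagnosis
            else None
        ),
        "features": [
            {
                "term_id": f.term_id,
                "label": f.label,
                "excluded": f.excluded,
                "onset_age": f.onset_age,
            }
            for f in case.features
        ],
    }


def case_record_from_dict(data: dict) -> CaseRecord:
    gold = data.get("gold_diagnosis")
    return CaseRecord(
        case_id=data["case_id"],
        sex=data.get("sex", "unknown"),
        age_at_last_exam=data.get("age_at_last_exam"),
        disease_onset=data.get("disease_onset"),
        source_publication=data.get("source_publication"),
        gold_diagnosis=DiseaseRef(gold["id"], gold.get("label", "")) if gold else None,
        features=[
            PhenotypeFeature(
                term_id=f["term_id"],
                label=f["label"],
                excluded=f.get("excluded", False),
                onset_age=f.get("onset_age"),
            )
            for f in data.get("features", [])
        ],
    )


def write_cohort_manifest(cohort: Iterable[CaseRecord], path: str | Path) -> None:
    """Write the cohort manifest TSV: case_id, n_observed, n_excluded, gold_id."""
    import pandas as pd

    rows = [
        {
            "case_id": c.case_id,
            "n_observed": len(c.observed()),
            "n_excluded": len(c.excluded()),
            "gold_id": c.gold_diagnosis.id if c.gold_diagnosis else "",
        }
        for c in cohort
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_differentials_jsonl(
    diffs: Sequence[Differential], path: str | Path
) -> None:
    """One JSON object per case/method; identifier items serialised as CURIEs."""
    with open(path, "w") as fh:
        for d in diffs:
            items = [
                it.id if isinstance(it, DiseaseRef) else it for it in d.items
            ]
            fh.write(
                json.dumps(
                    {
                        "case_id": d.case_id,
                        "method_id": d.method_id,
                        "items": items,
                        "warnings": d.warnings,
                    }
                )
                + "\n"
            )


def read_differentials_jsonl(path: str | Path) -> list[Differential]:
    diffs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            diffs.append(
                Differential(
                    case_id=obj["case_id"],
                    method_id=obj["method_id"],
                    items=list(obj.get("items", [])),
                    warnings=list(obj.get("warnings", [])),
                )
            )
    return diffs
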