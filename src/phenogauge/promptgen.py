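"""Clinical-narrative prompt generation from structured case records.

A case's structured phenotype data is rendered into a deterministic
narrative: a task preamble requesting a ranked, numbered differential
diagnosis; a demographic sentence carrying sex, disease onset and age at
last examination; the observed findings, each HPO term label exactly once;
and, when any findings were explicitly ruled out, a single negated block.
When features carry distinct onset ages, observed findings are grouped into
separate lists per age.

The narrative carries term labels only — HPO identifiers never leak into
prompt text. Exact wording is a template parameter; the structure is the
contract.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .pheno_io import CaseRecord

__all__ = ["PromptTemplate", "Prompt", "AgeFormatError", "render_age", "generate_prompt"]


class AgeFormatError(ValueError):
    """The age string is not a supported ISO-8601 duration."""


_DURATION = re.compile(
    r"^P(?!$)(?:(?P<years>\d+)Y)?(?:(?P<months>\d+)M)?"
    r"(?:(?P<weeks>\d+)W)?(?:(?P<days>\d+)D)?$"
)


def render_age(duration: str) -> str:
    """Render an ISO-8601 duration as a human-readable age phrase.

    ``"P4Y2M"`` becomes ``"4-year, 2-month-old"``; zero components are
    suppressed; an all-zero duration (``"P0D"``) renders as ``"newborn"``.
    Time-of-day components are not ages and are rejected.
    """
    m = _DURATION.match(duration or "")
    if not m:
        raise AgeFormatError(f"not an ISO-8601 age duration: {duration!r}")
    parts = []
    for unit in ("years", "months", "weeks", "days"):
        raw = m.group(unit)
        if raw is not None and int(raw) > 0:
            parts.append(f"{int(raw)}-{unit[:-1]}")
    if not parts:
        return "newborn"
    return ", ".join(parts) + "-old"


@dataclass(frozen=True)
class PromptTemplate:
    """Wording of the narrative; every field is overridable from config."""

    preamble: str = (
        "You are an expert clinical geneticist performing a differential "
        "diagnosis. Based on the case description below, return a ranked "
        "list of candidate diagnoses, most likely first, as a numbered "
        "list with one disease name per line."
    )
    sex_phrases: dict = field(
        default_factory=lambda: {
            "male": "male",
            "female": "female",
            "other": "individual of other sex",
            "unknown": "individual",
        }
    )
    demographic_pattern: str = "The patient was a {age} {sex}."
    demographic_pattern_no_age: str = "The patient was a {sex}."
    onset_clause_pattern: str = (
        "The disease manifestations first appeared when the patient was {age}."
    )
    observed_section_header: str = (
        "The patient presented with the following clinical findings:"
    )
    excluded_section_header: str = (
        "The following findings were explicitly ruled out:"
    )
    age_section_pattern: str = (
        "At the examination when the patient was {age}, "
        "the following findings were observed:"
    )
    per_age_section: bool = True


@dataclass(frozen=True)
class Prompt:
    case_id: str
    text: str
    n_observed_terms: int
    n_excluded_terms: int


def _dedupe(labels):
    seen, out = set(), []
    for lbl in labels:
        if lbl and lbl not in seen:
            seen.add(lbl)
            out.append(lbl)
    return out


def _bullet_block(labels) -> str:
    return "\n".join(f"- {lbl}" for lbl in labels)


def generate_prompt(case: CaseRecord, template: PromptTemplate | None = None) -> Prompt:
    """Render a :class:`CaseRecord` into a clinical-narrative prompt.

    Rendering is deterministic: the same case and template always yield
    byte-identical text. Absent demographics are omitted from the sentence,
    never rendered as placeholders.
    """
    tpl = template or PromptTemplate()
    sex_phrase = tpl.sex_phrases.get(case.sex, tpl.sex_phrases["unknown"])

    sentences = []
    if case.age_at_last_exam:
        sentences.append(
            tpl.demographic_pattern.format(
                age=render_age(case.age_at_last_exam), sex=sex_phrase
            )
        )
    else:
        sentences.append(tpl.demographic_pattern_no_age.format(sex=sex_phrase))
    if case.disease_onset:
        sentences.append(
            tpl.onset_clause_pattern.format(age=render_age(case.disease_onset))
        )
    demographic = " ".join(sentences)

    blocks = [tpl.preamble, demographic]

    observed = case.observed()
    observed_labels = _dedupe(f.label for f in observed)
    onset_ages = {f.onset_age for f in observed if f.label}
    if observed_labels:
        if tpl.per_age_section and len(onset_ages) > 1:
            # group by onset age, ageless findings first, each label once
            emitted: set[str] = set()
            ageless = _dedupe(
                f.label for f in observed if f.onset_age is None
            )
            if ageless:
                blocks.append(
                    tpl.observed_section_header + "\n" + _bullet_block(ageless)
                )
                emitted.update(ageless)
            ages = sorted(
                {f.onset_age for f in observed if f.onset_age is not None}
            )
            for age in ages:
                labels = _dedupe(
                    f.label
                    for f in observed
                    if f.onset_age == age and f.label not in emitted
                )
                if labels:
                    blocks.append(
                        tpl.age_section_pattern.format(age=render_age(age))
                        + "\n"
                        + _bullet_block(labels)
                    )
                    emitted.update(labels)
        else:
            blocks.append(
                tpl.observed_section_header + "\n" + _bullet_block(observed_labels)
            )

    excluded_labels = _dedupe(f.label for f in case.excluded())
    if excluded_labels:
        blocks.append(
            tpl.excluded_section_header + "\n" + _bullet_block(excluded_labels)
        )

    return Prompt(
        case_id=case.case_id,
        text="\n\n".join(blocks),
        n_observed_terms=len(observed_labels),
        n_excluded_terms=len(excluded_labels),
    )
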