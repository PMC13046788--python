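"""Synthetic ontologies, cohorts and responders for offline benchmarking.

The generator emulates the structure of the real benchmark inputs at toy
scale: a two-level disease ontology in which clinical grouping terms have
genetic-subtype leaves (mirroring genetically heterogeneous diseases, where
a clinical diagnosis subsumes several precise genetic diagnoses), an
exact-match table pairing each leaf with an OMIM-style identifier, a small
phenotype DAG with three organ-system roots, and per-disease phenotype
profiles from which cases draw their observed terms plus noise.

Simulated responders emit ranked free-text differentials whose
rank-of-correct-diagnosis distribution is controlled exactly, so that every
pipeline stage — prompt rendering, list parsing, grounding, roll-up scoring,
Top-k metrics — can be exercised end to end with a known ground truth.

Synthetic identifiers use reserved prefixes (MONDOX:, OMIMX:) and a
reserved HP:9xxxxxx number range so that accidental mixing with real
ontologies is detectable.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .ontology import MappingTable, OntologyGraph, Term
from .pheno_io import CaseRecord, Differential, DiseaseRef, PhenotypeFeature
from .promptgen import Prompt

__all__ = [
    "SyntheticSpec",
    "ResponderSpec",
    "ToyWorld",
    "make_toy_ontology",
    "make_cohort",
    "simulate_responses",
    "mock_responder_adapter",
    "format_differential_text",
    "write_cohort",
    "case_to_phenopacket_dict",
    "stage_rng",
]

_ORGANS = ("circulatory", "nervous", "immune")
PHENOTYPE_ROOT = "HP:9000000"
ORGAN_ROOTS = {
    organ: f"HP:900000{i + 1}" for i, organ in enumerate(_ORGANS)
}

_STEMS1 = (
    "velo", "gelo", "acro", "brachy", "campto", "chondro", "cranio", "dolicho",
    "ecto", "fibro", "glosso", "hemi", "kerato", "lepto", "macro", "micro",
    "neuro", "osteo", "pachy", "platy", "rhizo", "sclero", "spondylo", "thoraco",
)
_STEMS2 = (
    "dactylic", "melic", "physic", "cephalic", "somatic", "trophic", "plastic",
    "genic", "morphic", "metric", "costal", "dermal",
)
_KINDS = ("dysplasia", "syndrome", "dystrophy")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Per-stage child generator fanned out from one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a synthetic cohort.

    Defaults emulate the real benchmark's phenotyping depth: uniform
    disease-associated term counts of 10–19 plus 0–3 noise terms give a
    mean of about 16 observed terms per case, with per-case totals staying
    in the 1–50 range of the real data.
    """

    n_cases: int = 100
    n_diseases: int = 20
    subtypes_per_disease: tuple[int, int] = (2, 4)
    terms_per_case: tuple[int, int] = (10, 19)
    noise_terms_per_case: tuple[int, int] = (0, 3)
    excluded_terms_per_case: tuple[int, int] = (0, 2)
    sex_probabilities: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.5, "female": 0.5}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_diseases <= 0:
            raise ValueError("n_cases and n_diseases must be positive")
        for lo, hi in (
            self.subtypes_per_disease,
            self.terms_per_case,
            self.noise_terms_per_case,
            self.excluded_terms_per_case,
        ):
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid range ({lo}, {hi})")
        if abs(sum(self.sex_probabilities.values()) - 1.0) > 1e-9:
            raise ValueError("sex_probabilities must sum to 1")


@dataclass(frozen=True)
class ResponderSpec:
    """A simulated differential-diagnosis responder.

    ``rank_distribution`` maps the rank at which the correct diagnosis
    appears (or ``None`` for absent) to its probability. With probability
    ``p_grouping_label`` the correct answer is emitted as its clinical
    grouping label (exercising the roll-up rule); with ``p_typo`` as a
    one-letter typo variant (exercising similarity grounding). Filler items
    are other diseases' labels, each replaced by an ungroundable gibberish
    string with probability ``p_unmatchable_filler`` — emulating response
    items that no disease vocabulary covers.
    """

    rank_distribution: Mapping[int | None, float]
    list_length: int = 10
    p_grouping_label: float = 0.0
    p_typo: float = 0.0
    p_unmatchable_filler: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.rank_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("rank_distribution probabilities must sum to 1")
        ranks = [r for r in self.rank_distribution if r is not None]
        if any(r < 1 for r in ranks):
            raise ValueError("ranks must be >= 1")
        if ranks and self.list_length < max(
            r for r in ranks if self.rank_distribution[r] > 0
        ):
            raise ValueError("list_length below the largest reachable rank")
        if self.p_grouping_label + self.p_typo > 1.0:
            raise ValueError("p_grouping_label + p_typo must not exceed 1")


@dataclass
class ToyWorld:
    """A self-consistent synthetic universe for the full pipeline."""

    diseases: OntologyGraph
    phenotypes: OntologyGraph
    mappings: MappingTable
    #: leaf disease CURIE -> tuple of associated phenotype term ids
    associations: dict[str, tuple[str, ...]]
    grouping_of: dict[str, str]  # leaf -> grouping CURIE
    omim_of: dict[str, str]  # leaf -> synthetic OMIM id
    leaf_of_omim: dict[str, str]

    def leaves(self) -> list[str]:
        return sorted(self.grouping_of)


def _disease_name(rng: np.random.Generator, taken: set[str]) -> str:
    while True:
        name = (
            _STEMS1[rng.integers(len(_STEMS1))]
            + _STEMS2[rng.integers(len(_STEMS2))]
            + " "
            + _KINDS[rng.integers(len(_KINDS))]
        )
        if name not in taken:
            taken.add(name)
            return name


def make_toy_ontology(
    n_groupings: int = 20,
    subtypes_per_grouping: int | tuple[int, int] = 3,
    seed: int = 0,
    leaves_per_organ: int = 20,
    profile_size: int = 30,
) -> ToyWorld:
    """Build a two-level disease DAG, a phenotype DAG and exact mappings.

    Each grouping term carries leaf subtypes named after it (subtype labels
    and one synonym each); each leaf is paired with a synthetic OMIM-style
    identifier in the mapping table. The phenotype DAG has a single root
    with three organ-system subtrees for stratification. Each grouping is
    assigned a phenotype profile shared by its subtypes.
    """
    if n_groupings <= 0:
        raise ValueError("n_groupings must be positive")
    rng = stage_rng(seed, "toy-ontology")
    if isinstance(subtypes_per_grouping, int):
        sub_lo = sub_hi = subtypes_per_grouping
    else:
        sub_lo, sub_hi = subtypes_per_grouping
    if sub_lo <= 0:
        raise ValueError("subtypes_per_grouping must be positive")

    # phenotype DAG
    ph_nodes: dict[str, Term] = {
        PHENOTYPE_ROOT: Term("Phenotypic abnormality (synthetic)")
    }
    ph_edges: list[tuple[str, str]] = []
    organ_leaves: dict[str, list[str]] = {}
    for oi, organ in enumerate(_ORGANS):
        root = ORGAN_ROOTS[organ]
        ph_nodes[root] = Term(f"Abnormality of the {organ} system (synthetic)")
        ph_edges.append((root, PHENOTYPE_ROOT))
        organ_leaves[organ] = []
        for k in range(leaves_per_organ):
            curie = f"HP:9{oi + 1}{k:05d}"
            ph_nodes[curie] = Term(f"Synthetic {organ} finding {k}")
            ph_edges.append((curie, root))
            organ_leaves[organ].append(curie)
    phenotypes = OntologyGraph(ph_nodes, ph_edges)
    all_ph_leaves = sorted(c for leaves in organ_leaves.values() for c in leaves)
    profile_size = min(profile_size, len(all_ph_leaves))

    # disease DAG
    taken: set[str] = set()
    d_nodes: dict[str, Term] = {"MONDOX:0000001": Term("synthetic rare disease")}
    d_edges: list[tuple[str, str]] = []
    associations: dict[str, tuple[str, ...]] = {}
    grouping_of: dict[str, str] = {}
    omim_of: dict[str, str] = {}
    pairs: list[tuple[str, str]] = []
    omim_counter = 600000
    for gi in range(n_groupings):
        group_id = f"MONDOX:8{gi:06d}"
        group_label = _disease_name(rng, taken)
        d_nodes[group_id] = Term(
            group_label, synonyms=(f"{group_label} spectrum disorder",)
        )
        d_edges.append((group_id, "MONDOX:0000001"))
        profile = tuple(
            sorted(
                rng.choice(all_ph_leaves, size=profile_size, replace=False).tolist()
            )
        )
        n_sub = int(rng.integers(sub_lo, sub_hi + 1))
        for sj in range(1, n_sub + 1):
            leaf_id = f"MONDOX:7{gi:03d}{sj:03d}"
            d_nodes[leaf_id] = Term(
                f"{group_label} {sj}", synonyms=(f"{group_label} type {sj}",)
            )
            d_edges.append((leaf_id, group_id))
            associations[leaf_id] = profile
            grouping_of[leaf_id] = group_id
            omim_id = f"OMIMX:{omim_counter}"
            omim_counter += 1
            omim_of[leaf_id] = omim_id
            pairs.append((omim_id, leaf_id))
    diseases = OntologyGraph(d_nodes, d_edges)
    return ToyWorld(
        diseases=diseases,
        phenotypes=phenotypes,
        mappings=MappingTable.from_pairs(pairs),
        associations=associations,
        grouping_of=grouping_of,
        omim_of=omim_of,
        leaf_of_omim={v: k for k, v in omim_of.items()},
    )


# ---------------------------------------------------------------------------
# cohort generation


def _sample_range(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    lo, hi = bounds
    return int(rng.integers(lo, hi + 1))


def make_cohort(spec: SyntheticSpec, world: ToyWorld) -> list[CaseRecord]:
    """Draw a deterministic cohort of cases from the toy world.

    Each case picks a gold leaf disease uniformly, samples observed terms
    from that disease's phenotype profile plus organ-unspecific noise terms,
    samples excluded terms from outside the profile, and assigns sex, a
    disease onset age and an age at last examination. The gold diagnosis is
    recorded under the leaf's synthetic OMIM identifier, so scoring must
    exercise the equivalence-mapping route.
    """
    rng = stage_rng(spec.seed, "cohort")
    leaves = world.leaves()
    all_ph = sorted(
        t for t in world.phenotypes.terms()
        if not world.phenotypes.children(t)  # leaf phenotype terms only
    )
    profile_cap = min(len(world.associations[leaf]) for leaf in leaves)
    if spec.terms_per_case[1] > profile_cap:
        raise ValueError(
            f"terms_per_case upper bound {spec.terms_per_case[1]} exceeds the "
            f"disease profile vocabulary ({profile_cap} terms)"
        )
    sexes = sorted(spec.sex_probabilities)
    sex_p = [spec.sex_probabilities[s] for s in sexes]

    cases: list[CaseRecord] = []
    for i in range(spec.n_cases):
        leaf = leaves[int(rng.integers(len(leaves)))]
        profile = list(world.associations[leaf])
        n_terms = _sample_range(rng, spec.terms_per_case)
        observed = (
            rng.choice(profile, size=n_terms, replace=False).tolist()
            if n_terms
            else []
        )
        off_profile = [t for t in all_ph if t not in set(profile)]
        n_noise = min(_sample_range(rng, spec.noise_terms_per_case), len(off_profile))
        noise = (
            rng.choice(off_profile, size=n_noise, replace=False).tolist()
            if n_noise
            else []
        )
        remaining = [t for t in off_profile if t not in set(noise)]
        n_excl = min(_sample_range(rng, spec.excluded_terms_per_case), len(remaining))
        excl = (
            rng.choice(remaining, size=n_excl, replace=False).tolist()
            if n_excl
            else []
        )

        onset_years = int(rng.integers(0, 13))
        onset = f"P{onset_years}Y" if onset_years else f"P{int(rng.integers(1, 12))}M"
        exam_years = onset_years + int(rng.integers(1, 11))

        features = [
            PhenotypeFeature(t, world.phenotypes.label(t))
            for t in observed + noise
        ] + [
            PhenotypeFeature(t, world.phenotypes.label(t), excluded=True)
            for t in excl
        ]
        cases.append(
            CaseRecord(
                case_id=f"case-{i:04d}",
                sex=str(rng.choice(sexes, p=sex_p)),
                age_at_last_exam=f"P{exam_years}Y",
                disease_onset=onset,
                features=features,
                gold_diagnosis=DiseaseRef(
                    world.omim_of[leaf], world.diseases.label(leaf)
                ),
                source_publication=f"PMID:{30000000 + int(rng.integers(1000000))}",
            )
        )
    return cases


# ---------------------------------------------------------------------------
# simulated responders

_GIBBERISH_ALPHABET = list("qxzvwkj")


def _typo(label: str, rng: np.random.Generator) -> str:
    alpha_positions = [i for i, ch in enumerate(label) if ch.isalpha()]
    pos = alpha_positions[int(rng.integers(len(alpha_positions)))]
    old = label[pos]
    letters = [c for c in "abcdefghijklmnopqrstuvwxyz" if c != old.lower()]
    return label[:pos] + letters[int(rng.integers(len(letters)))] + label[pos + 1 :]


def _gibberish(rng: np.random.Generator) -> str:
    word = "".join(
        _GIBBERISH_ALPHABET[int(rng.integers(len(_GIBBERISH_ALPHABET)))]
        for _ in range(12)
    )
    return f"{word} {int(rng.integers(10 ** 6))}"


def simulate_responses(
    cohort: Sequence[CaseRecord],
    responder: ResponderSpec,
    world: ToyWorld,
    method_id: str = "simulated",
) -> list[Differential]:
    """Emit one free-text-style differential per case with controlled rank.

    The rank at which the gold disease's label appears is drawn from the
    responder's rank distribution; all other positions are filled with other
    diseases' labels sampled without replacement.
    """
    rng = stage_rng(responder.seed, "responses")
    outcomes = sorted(
        (r for r in responder.rank_distribution), key=lambda r: (r is None, r)
    )
    probs = [responder.rank_distribution[r] for r in outcomes]

    group_labels = {
        g: world.diseases.label(g) for g in set(world.grouping_of.values())
    }
    diffs: list[Differential] = []
    for case in cohort:
        leaf = world.leaf_of_omim[case.gold_diagnosis.id]
        gold_label = world.diseases.label(leaf)
        group = world.grouping_of[leaf]
        fillers_pool = sorted(
            lbl
            for term, lbl in (
                (t, world.diseases.label(t))
                for t in world.diseases.terms()
                if t != "MONDOX:0000001"
            )
            if term not in (leaf, group)
        )
        if len(fillers_pool) < responder.list_length:
            raise ValueError("not enough diseases to fill the response list")
        items = rng.choice(
            fillers_pool, size=responder.list_length, replace=False
        ).tolist()
        items = [
            _gibberish(rng)
            if rng.random() < responder.p_unmatchable_filler
            else it
            for it in items
        ]
        rank = outcomes[int(rng.choice(len(outcomes), p=probs))]
        u = rng.random()
        if rank is not None:
            if u < responder.p_grouping_label:
                answer = group_labels[group]
            elif u < responder.p_grouping_label + responder.p_typo:
                answer = _typo(gold_label, rng)
            else:
                answer = gold_label
            items[rank - 1] = answer
        diffs.append(Differential(case.case_id, method_id, items))
    return diffs


# ---------------------------------------------------------------------------
# mock LLM boundary

_DIALECTS = ("num_dot", "num_paren", "num_colon", "rank", "bullet", "star")


def format_differential_text(items: Sequence[str], dialect: str = "num_dot") -> str:
    """Render items in one of the list dialects the response parser accepts."""
    lines = []
    for i, item in enumerate(items, start=1):
        if dialect == "num_dot":
            lines.append(f"{i}. {item}")
        elif dialect == "num_paren":
            lines.append(f"{i}) {item}")
        elif dialect == "num_colon":
            lines.append(f"{i}: {item}")
        elif dialect == "rank":
            lines.append(f"Rank {i}: {item}")
        elif dialect == "bullet":
            lines.append(f"- {item}")
        elif dialect == "star":
            lines.append(f"* {item}")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    return "\n".join(lines)


_CANNED_ITEMS = (
    "geleophysic dysplasia",
    "acromicric dysplasia",
    "Weill-Marchesani syndrome",
)


def mock_responder_adapter(
    prompts: Sequence[Prompt],
    differentials: Mapping[str, Differential] | None = None,
) -> list[str]:
    """Deterministic stand-in for the model-API boundary.

    Returns one raw response text per prompt, keyed by case_id: the dialect
    is chosen by a stable digest of the case_id so every list dialect the
    parser accepts is exercised across a cohort, and a short prose preamble
    is prepended, as real model output tends to carry one.
    """
    texts = []
    for prompt in prompts:
        if differentials is not None and prompt.case_id in differentials:
            items = [str(it) for it in differentials[prompt.case_id].items]
        else:
            items = list(_CANNED_ITEMS)
        dialect = _DIALECTS[zlib.crc32(prompt.case_id.encode()) % len(_DIALECTS)]
        texts.append(
            "Here is a ranked differential diagnosis for this case:\n\n"
            + format_differential_text(items, dialect)
        )
    return texts


# ---------------------------------------------------------------------------
# phenopacket v2 emission

_SEX_UP = {"male": "MALE", "female": "FEMALE", "other": "OTHER_SEX", "unknown": "UNKNOWN_SEX"}


def case_to_phenopacket_dict(case: CaseRecord) -> dict:
    """Render a CaseRecord as a phenopacket v2 JSON document (dict)."""
    doc: dict = {
        "id": case.case_id,
        "subject": {"id": case.case_id, "sex": _SEX_UP[case.sex]},
        "phenotypicFeatures": [],
        "metaData": {
            "created": "2026-01-01T00:00:00Z",
            "createdBy": "phenogauge.synthcohort",
            "phenopacketSchemaVersion": "2.0",
        },
    }
    if case.age_at_last_exam:
        doc["subject"]["timeAtLastEncounter"] = {
            "age": {"iso8601duration": case.age_at_last_exam}
        }
    for f in case.features:
        pf: dict = {"type": {"id": f.term_id, "label": f.label}}
        if f.excluded:
            pf["excluded"] = True
        if f.onset_age:
            pf["onset"] = {"age": {"iso8601duration": f.onset_age}}
        doc["phenotypicFeatures"].append(pf)
    if case.gold_diagnosis:
        disease = {"id": case.gold_diagnosis.id, "label": case.gold_diagnosis.label}
        doc["interpretations"] = [
            {
                "id": f"{case.case_id}-interpretation",
                "progressStatus": "SOLVED",
                "diagnosis": {"disease": disease},
            }
        ]
        entry: dict = {"term": disease}
        if case.disease_onset:
            entry["onset"] = {"age": {"iso8601duration": case.disease_onset}}
        doc["diseases"] = [entry]
    if case.source_publication:
        doc["metaData"]["externalReferences"] = [{"id": case.source_publication}]
    return doc


def write_cohort(cases: Sequence[CaseRecord], out_dir: str | Path) -> list[Path]:
    """Write one phenopacket v2 JSON file per case; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for case in cases:
        path = out_dir / f"{case.case_id}.json"
        path.write_text(json.dumps(case_to_phenopacket_dict(case), indent=1))
        paths.append(path)
    return paths
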