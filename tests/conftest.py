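import json

import pytest
from hypothesis import HealthCheck, settings

from phenogauge import fixtures, synthcohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_graph():
    """Packaged geleophysic-dysplasia toy disease ontology."""
    return fixtures.toy_disease_ontology()


@pytest.fixture(scope="session")
def toy_mappings():
    return fixtures.toy_disease_mappings()


@pytest.fixture(scope="session")
def world():
    """A mid-sized synthetic universe shared across tests."""
    return synthcohort.make_toy_ontology(12, 3, seed=11)


def make_phenopacket(
    case_id="case-A",
    sex="FEMALE",
    last_exam="P6Y",
    features=(),
    disease=("OMIM:614185", "geleophysic dysplasia 2"),
    onset="P2Y",
    version="2.0",
):
    """Build a minimal phenopacket v2 document as a JSON string."""
    doc = {
        "id": case_id,
        "subject": {"id": case_id, "sex": sex},
        "phenotypicFeatures": [
            {
                "type": {"id": tid, "label": lbl},
                **({"excluded": True} if excluded else {}),
            }
            for tid, lbl, excluded in features
        ],
        "metaData": {
            "created": "2026-01-01T00:00:00Z",
            "createdBy": "tests",
            "phenopacketSchemaVersion": version,
        },
    }
    if last_exam:
        doc["subject"]["timeAtLastEncounter"] = {
            "age": {"iso8601duration": last_exam}
        }
    if disease:
        doc["interpretations"] = [
            {
                "id": f"{case_id}-i",
                "progressStatus": "SOLVED",
                "diagnosis": {"disease": {"id": disease[0], "label": disease[1]}},
            }
        ]
        entry = {"term": {"id": disease[0], "label": disease[1]}}
        if onset:
            entry["onset"] = {"age": {"iso8601duration": onset}}
        doc["diseases"] = [entry]
    return json.dumps(doc)


@pytest.fixture
def phenopacket_factory():
    return make_phenopacket
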