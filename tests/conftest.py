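import pytest

from ocuphen.retrieval import HashingNgramEmbedder, build_index
from ocuphen.simulate import build_fixture_catalog


@pytest.fixture(scope="session")
def fixture_catalog():
    return build_fixture_catalog()


@pytest.fixture(scope="session")
def embedder():
    return HashingNgramEmbedder()


@pytest.fixture(scope="session")
def fixture_index(fixture_catalog, embedder):
    return build_index(fixture_catalog, embedder)


TINY_OBO = """format-version: 1.2

[Term]
id: HP:0000541
name: Retinal detachment
synonym: "Amotio retinae" EXACT []

[Term]
id: HP:0011457
name: Loss of eyelashes
synonym: "Eyelash loss" EXACT []
synonym: "Madarosis of eyelashes" RELATED []

[Term]
id: HP:0031805
name: Roth spot
"""


@pytest.fixture
def tiny_obo(tmp_path):
    path = tmp_path / "tiny.obo"
    path.write_text(TINY_OBO, encoding="utf-8")
    return path


TINY_HPO_JSON = {
    "graphs": [
        {
            "nodes": [
                {
                    "id": "http://purl.obolibrary.org/obo/HP_0000541",
                    "lbl": "Retinal detachment",
                    "meta": {"synonyms": [{"pred": "hasExactSynonym", "val": "Amotio retinae"}]},
                },
                {
                    "id": "http://purl.obolibrary.org/obo/HP_0031805",
                    "lbl": "Roth spot",
                },
                {"id": "http://purl.obolibrary.org/obo/GO_0008150", "lbl": "not an HP node"},
            ]
        }
    ]
}


@pytest.fixture
def tiny_hpo_json(tmp_path):
    import json

    path = tmp_path / "tiny.json"
    path.write_text(json.dumps(TINY_HPO_JSON), encoding="utf-8")
    return path
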