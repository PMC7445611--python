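import json

import pytest

from seqreport import build_bundle, to_json, worked_example
from seqreport.generator import GeneratorConfig, generate_reports


@pytest.fixture(scope="session")
def example_report():
    return worked_example()


@pytest.fixture(scope="session")
def example_bundle(example_report):
    return build_bundle(example_report)


@pytest.fixture(scope="session")
def corpus():
    """Small deterministic conformant corpus, research block always present."""
    cfg = GeneratorConfig(seed=11, n_reports=25, include_research_block=1.0)
    return generate_reports(cfg)


# ---------------------------------------------------------------------------
# Independent placement walker: a brute-force interpreter over plain JSON,
# written separately from the package's own walker so bundle placement can be
# checked against it.

def independent_walk(bundle_json: dict, resource_json: dict, placement: str):
    steps = placement.split("/")
    if steps and steps[0] == resource_json.get("resourceType"):
        steps = steps[1:]
    node = resource_json
    for step in steps:
        if node is None:
            return None
        if step.startswith("@"):
            ref = node.get("reference") if isinstance(node, dict) else None
            node = None
            for entry in bundle_json.get("entry", []):
                res = entry["resource"]
                if f"{res['resourceType']}/{res['id']}" == ref:
                    node = res
                    break
        elif step.startswith("ext:"):
            name = step[4:]
            found = None
            for ext in (node.get("extension", []) if isinstance(node, dict) else []):
                url = ext.get("url", "")
                if url == name or url.split("/")[-1] == name:
                    found = ext
                    break
            node = found
        elif step.startswith("component{"):
            code = step[len("component{"):-1]
            found = None
            for comp in (node.get("component", []) if isinstance(node, dict) else []):
                codings = comp.get("code", {}).get("coding", [])
                if codings and codings[0].get("code") == code:
                    found = comp
                    break
            node = found
        elif step.isdigit():
            i = int(step)
            node = node[i] if isinstance(node, list) and i < len(node) else None
        else:
            node = node.get(step) if isinstance(node, dict) else None
    return node


def bundle_as_json(bundle) -> dict:
    return json.loads(to_json(bundle))
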