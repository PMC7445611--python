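"""Minimal generic FHIR (STU3-dialect) resource model.

Resources are a resource type, a logical id, a version counter, a body of
ordinary JSON-shaped data and a list of extensions.  Serialization is
canonical JSON: UTF-8, sorted keys, two-space indent, newline-terminated,
so that fixtures are byte-stable.  Only the eight resource types used by
the sequencing-report mapping (plus Bundle) are modeled; there is no full
FHIR metamodel, no XML and no FHIRPath engine.
"""

from __future__ import annotations

import copy
import json
import re
import uuid
from typing import Any, Iterator, Literal

from pydantic import BaseModel, Field

from .errors import FhirParseError, UnsupportedTypeError
from .mapping import RESOURCE_TYPES

__all__ = [
    "FhirResource",
    "Bundle",
    "make_resource",
    "add_extension",
    "to_json",
    "from_json",
    "validate_bundle_refs",
    "walk_placement",
    "set_placement",
]

_ABSOLUTE_URL = re.compile(r"^[a-z][a-z0-9+.-]*://", re.IGNORECASE)


class FhirResource(BaseModel):
    resource_type: str
    logical_id: str
    version_id: int = 1
    body: dict[str, Any] = Field(default_factory=dict)
    #: extension dicts: {"url": ..., "valueString": ...} or nested
    #: {"url": ..., "extension": [...]}
    extensions: list[dict[str, Any]] = Field(default_factory=list)

    @property
    def reference(self) -> str:
        return f"{self.resource_type}/{self.logical_id}"

    def as_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "resourceType": self.resource_type,
            "id": self.logical_id,
            "meta": {"versionId": str(self.version_id)},
        }
        out.update(copy.deepcopy(self.body))
        if self.extensions:
            out["extension"] = copy.deepcopy(self.extensions)
        return out

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "FhirResource":
        data = copy.deepcopy(data)
        rtype = data.pop("resourceType")
        rid = data.pop("id", None) or _fresh_id()
        meta = data.pop("meta", {})
        version = int(meta.get("versionId", 1))
        exts = data.pop("extension", [])
        return cls(resource_type=rtype, logical_id=rid, version_id=version,
                   body=data, extensions=exts)


class Bundle(BaseModel):
    bundle_type: Literal["collection", "transaction"] = "collection"
    logical_id: str = Field(default_factory=lambda: _fresh_id())
    entries: list[FhirResource] = Field(default_factory=list)

    def resources(self, resource_type: str | None = None) -> list[FhirResource]:
        if resource_type is None:
            return list(self.entries)
        return [e for e in self.entries if e.resource_type == resource_type]

    def resolve(self, reference: str) -> FhirResource | None:
        for e in self.entries:
            if e.reference == reference:
                return e
        return None

    def as_dict(self) -> dict[str, Any]:
        return {
            "resourceType": "Bundle",
            "id": self.logical_id,
            "type": self.bundle_type,
            "entry": [
                {"fullUrl": e.reference, "resource": e.as_dict()} for e in self.entries
            ],
        }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "Bundle":
        if data.get("resourceType") != "Bundle":
            raise FhirParseError("not a Bundle document")
        entries = [FhirResource.from_dict(e["resource"]) for e in data.get("entry", [])]
        return cls(bundle_type=data.get("type", "collection"),
                   logical_id=data.get("id") or _fresh_id(), entries=entries)


def _fresh_id() -> str:
    return uuid.uuid4().hex[:12]


def make_resource(resource_type: str, body: dict[str, Any] | None = None,
                  logical_id: str | None = None) -> FhirResource:
    """Create a version-1 resource of a supported type."""
    if resource_type not in RESOURCE_TYPES:
        raise UnsupportedTypeError(
            f"unsupported resource type {resource_type!r}; supported: "
            + ", ".join(RESOURCE_TYPES)
        )
    return FhirResource(resource_type=resource_type,
                        logical_id=logical_id or _fresh_id(),
                        body=dict(body or {}))


def add_extension(resource: FhirResource, url: str, value: Any) -> FhirResource:
    """Append an extension; repeated URLs are allowed and order-preserving.

    ``value`` is either a dict already carrying a FHIR ``value[x]`` member
    (or nested ``extension`` list), or a plain string stored as
    ``valueString``.
    """
    if not _ABSOLUTE_URL.match(url):
        raise FhirParseError(f"extension url must be absolute, got {url!r}")
    if isinstance(value, dict):
        ext = {"url": url, **copy.deepcopy(value)}
    else:
        ext = {"url": url, "valueString": str(value)}
    resource.extensions.append(ext)
    return resource


def to_json(obj: FhirResource | Bundle) -> str:
    """Canonical JSON: sorted keys, UTF-8, newline-terminated."""
    return json.dumps(obj.as_dict(), sort_keys=True, ensure_ascii=False, indent=2) + "\n"


def from_json(text: str) -> FhirResource | Bundle:
    """Parse a FHIR JSON document into a resource or bundle."""
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FhirParseError(
            f"malformed JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc
    if not isinstance(data, dict) or "resourceType" not in data:
        raise FhirParseError("document has no resourceType member")
    if data["resourceType"] == "Bundle":
        return Bundle.from_dict(data)
    if data["resourceType"] not in RESOURCE_TYPES:
        raise UnsupportedTypeError(
            f"unsupported resource type {data['resourceType']!r}"
        )
    return FhirResource.from_dict(data)


def _iter_references(node: Any) -> Iterator[str]:
    if isinstance(node, dict):
        ref = node.get("reference")
        if isinstance(ref, str):
            yield ref
        for v in node.values():
            yield from _iter_references(v)
    elif isinstance(node, list):
        for v in node:
            yield from _iter_references(v)


def validate_bundle_refs(bundle: Bundle) -> list[str]:
    """Return internal references that do not resolve to a bundle entry."""
    present = {e.reference for e in bundle.entries}
    unresolved = []
    for entry in bundle.entries:
        for ref in _iter_references(entry.as_dict()):
            if ref not in present and ref not in unresolved:
                unresolved.append(ref)
    return unresolved


# ------------------------------------------------------- placement paths
#
# A placement is a slash-separated structural path relative to a resource:
#   key            ordinary dict key
#   <int>          list index
#   ext:NAME       extension whose url (or sub-extension url) basename is NAME
#   @Patient       dereference a {"reference": "Patient/..."} node in a bundle
#   component{c}   list item whose code/coding/0/code equals c

def _ext_matches(ext: dict, name: str) -> bool:
    url = ext.get("url", "")
    return url == name or url.rsplit("/", 1)[-1] == name


def walk_placement(bundle: Bundle, resource: FhirResource, placement: str) -> Any:
    """Follow a placement path; return the value or None if absent."""
    steps = placement.split("/")
    if steps and steps[0] == resource.resource_type:
        steps = steps[1:]
    node: Any = resource.as_dict()
    for step in steps:
        if node is None:
            return None
        if step.startswith("@"):
            if not isinstance(node, dict) or "reference" not in node:
                return None
            target = bundle.resolve(node["reference"])
            node = target.as_dict() if target is not None else None
        elif step.startswith("ext:"):
            name = step[4:]
            exts = node.get("extension", []) if isinstance(node, dict) else []
            node = next((e for e in exts if _ext_matches(e, name)), None)
        elif step.startswith("component{"):
            code = step[len("component{"):-1]
            comps = node.get("component", []) if isinstance(node, dict) else []
            node = next(
                (c for c in comps
                 if c.get("code", {}).get("coding", [{}])[0].get("code") == code),
                None,
            )
        elif step.isdigit():
            idx = int(step)
            node = node[idx] if isinstance(node, list) and idx < len(node) else None
        else:
            node = node.get(step) if isinstance(node, dict) else None
    return node


def _ensure_ext(ext_list: list, name: str, full_url: str | None) -> dict:
    target = next((e for e in ext_list if _ext_matches(e, name)), None)
    if target is None:
        target = {"url": full_url or name}
        ext_list.append(target)
    return target


def set_placement(resource: FhirResource, placement: str, value: Any,
                  ext_url: str | None = None) -> None:
    """Create intermediate structure along a placement path and set the leaf.

    ``ext_url`` supplies the absolute URL for a top-level ``ext:`` step
    (sub-extension URLs stay relative names, as FHIR prescribes).
    Reference dereference steps (``@Type``) are not supported here — the
    builder writes those slots directly on the referenced resource.
    """
    steps = placement.split("/")
    if steps and steps[0] == resource.resource_type:
        steps = steps[1:]
    if not steps:
        raise ValueError(f"empty placement {placement!r}")

    def descend(cur: Any, remaining: list[str], top: bool) -> None:
        step, rest = remaining[0], remaining[1:]
        if step.startswith("@"):
            raise ValueError(f"cannot set through a reference step: {placement}")
        if step.startswith("ext:"):
            if top:
                ext_list = resource.extensions
                target = _ensure_ext(ext_list, step[4:], ext_url)
            else:
                target = _ensure_ext(cur.setdefault("extension", []), step[4:], None)
            descend(target, rest, False)
        elif step.startswith("component{"):
            code = step[len("component{"):-1]
            comps = cur.setdefault("component", [])
            target = next(
                (c for c in comps
                 if c.get("code", {}).get("coding", [{}])[0].get("code") == code),
                None,
            )
            if target is None:
                target = {"code": {"coding": [{"code": code}]}}
                comps.append(target)
            descend(target, rest, False)
        elif step.isdigit():
            idx = int(step)
            while len(cur) <= idx:
                cur.append({})
            if not rest:
                cur[idx] = value
            else:
                if not isinstance(cur[idx], (dict, list)) or (
                    isinstance(cur[idx], dict) and not cur[idx] and rest[0].isdigit()
                ):
                    cur[idx] = [] if rest[0].isdigit() else cur[idx] or {}
                descend(cur[idx], rest, False)
        else:
            if not rest:
                cur[step] = value
                return
            if step not in cur or cur[step] is None:
                cur[step] = [] if rest[0].isdigit() else {}
            descend(cur[step], rest, False)

    first = steps[0]
    if first.startswith("ext:"):
        target = _ensure_ext(resource.extensions, first[4:], ext_url)
        if not steps[1:]:
            raise ValueError(f"placement ends on an extension node: {placement}")
        descend(target, steps[1:], False)
    else:
        descend(resource.body, steps, False)
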