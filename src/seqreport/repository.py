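"""In-memory FHIR-style resource repository.

Supports the server operation set the report pipeline relies on — create,
history, read, search, update — with per-resource version chains and
AND-semantics search over a small fixed parameter set.  Delete exists only
as a soft-delete flag behind a config switch, off by default.  Access
control is a deterministic token-table stub standing in for bearer-token
authorization; it is disabled unless tokens are configured.
"""

from __future__ import annotations

import copy
import datetime as _dt
import json
from typing import Iterable, Optional

from .errors import (
    AuthorizationError,
    ConflictError,
    NotFoundError,
    SearchParameterError,
)
from .fhir_model import Bundle, FhirResource

__all__ = ["ResourceRepository", "SUPPORTED_SEARCH_PARAMS"]

SUPPORTED_SEARCH_PARAMS = ("subject", "gene", "date")

_GENE_EXT_NAME = "observation-geneticsGene"


class ResourceRepository:
    """Desk-scale FHIR resource store with version history."""

    def __init__(self, *, tokens: Optional[dict[str, set[str]]] = None,
                 allow_delete: bool = False) -> None:
        #: (type, id) -> list of versions, oldest first; latest is current
        self._store: dict[tuple[str, str], list[FhirResource]] = {}
        self._received: dict[tuple[str, str], str] = {}
        self._deleted: set[tuple[str, str]] = set()
        self._counter = 0
        self._tokens = tokens  # None => authorization disabled
        self._allow_delete = allow_delete

    # ------------------------------------------------------------- auth

    def authorize(self, token: Optional[str], operation: str) -> bool:
        """True iff *operation* is permitted for *token* (or auth is off)."""
        if self._tokens is None:
            return True
        if token is None or token not in self._tokens:
            return False
        return operation in self._tokens[token]

    def _check(self, token: Optional[str], operation: str) -> None:
        if not self.authorize(token, operation):
            raise AuthorizationError(f"operation {operation!r} denied")

    # ------------------------------------------------------------- CRUD

    def create(self, resource: FhirResource | Bundle,
               token: Optional[str] = None):
        """Store a resource (or unroll a bundle); returns (id, version)."""
        self._check(token, "create")
        if isinstance(resource, Bundle):
            return [self.create(entry, token) for entry in resource.entries]
        key = (resource.resource_type, resource.logical_id)
        if key in self._store and key not in self._deleted:
            raise ConflictError(f"{resource.reference} already exists")
        stored = copy.deepcopy(resource)
        stored.version_id = 1
        self._received[key] = _dt.datetime.now(_dt.timezone.utc).isoformat()
        self._deleted.discard(key)
        self._store[key] = [stored]
        return resource.logical_id, 1

    def read(self, resource_type: str, logical_id: str,
             token: Optional[str] = None) -> FhirResource:
        """Latest version, deep-copied."""
        self._check(token, "read")
        versions = self._versions(resource_type, logical_id)
        return copy.deepcopy(versions[-1])

    def update(self, resource_type: str, logical_id: str,
               resource: FhirResource, token: Optional[str] = None) -> int:
        """Supersede the current version; returns the new version id."""
        self._check(token, "update")
        versions = self._versions(resource_type, logical_id)
        new = copy.deepcopy(resource)
        new.resource_type = resource_type
        new.logical_id = logical_id
        new.version_id = versions[-1].version_id + 1
        versions.append(new)
        return new.version_id

    def history(self, resource_type: str, logical_id: str,
                token: Optional[str] = None) -> list[FhirResource]:
        """All versions, oldest first."""
        self._check(token, "history")
        return [copy.deepcopy(v) for v in self._versions(resource_type, logical_id)]

    def delete(self, resource_type: str, logical_id: str,
               token: Optional[str] = None) -> None:
        """Soft delete; available only when the repository allows it."""
        if not self._allow_delete:
            raise NotFoundError("delete is not enabled on this repository")
        self._check(token, "delete")
        self._versions(resource_type, logical_id)  # existence check
        self._deleted.add((resource_type, logical_id))

    # ----------------------------------------------------------- search

    def search(self, resource_type: str, token: Optional[str] = None,
               **params: str) -> Bundle:
        """Collection bundle of latest versions matching all filters."""
        self._check(token, "search")
        unknown = set(params) - set(SUPPORTED_SEARCH_PARAMS)
        if unknown:
            raise SearchParameterError(
                f"unsupported search parameter(s) {sorted(unknown)}; supported: "
                + ", ".join(SUPPORTED_SEARCH_PARAMS)
            )
        hits = [
            copy.deepcopy(versions[-1])
            for (rtype, rid), versions in self._store.items()
            if rtype == resource_type and (rtype, rid) not in self._deleted
            and all(_matches(versions[-1], k, v) for k, v in params.items())
        ]
        hits.sort(key=lambda r: r.logical_id)
        return Bundle(bundle_type="collection", entries=hits)

    # -------------------------------------------------------- internals

    def _versions(self, resource_type: str, logical_id: str) -> list[FhirResource]:
        key = (resource_type, logical_id)
        if key not in self._store or key in self._deleted:
            raise NotFoundError(f"{resource_type}/{logical_id} not found")
        return self._store[key]

    def types(self) -> list[str]:
        return sorted({t for t, _ in self._store})

    # ----------------------------------------------------- persistence

    def snapshot(self, path) -> None:
        """Write a JSON-lines snapshot of all latest versions."""
        with open(path, "w", encoding="utf-8") as fh:
            for (rtype, rid), versions in sorted(self._store.items()):
                fh.write(json.dumps(versions[-1].as_dict(), sort_keys=True) + "\n")

    def load_snapshot(self, path) -> int:
        with open(path, encoding="utf-8") as fh:
            n = 0
            for line in fh:
                if line.strip():
                    self.create(FhirResource.from_dict(json.loads(line)))
                    n += 1
        return n


def _matches(resource: FhirResource, key: str, value: str) -> bool:
    if key == "subject":
        ref = resource.body.get("subject", {})
        return isinstance(ref, dict) and ref.get("reference") == value
    if key == "gene":
        for ext in resource.extensions:
            if ext.get("url", "").rsplit("/", 1)[-1] == _GENE_EXT_NAME:
                coding = ext.get("valueCodeableConcept", {}).get("coding", [{}])[0]
                if value in (coding.get("code"), coding.get("display")):
                    return True
        return False
    if key == "date":
        for field in ("effectiveDateTime", "issued", "authoredOn", "birthDate"):
            v = resource.body.get(field)
            if isinstance(v, str) and v.startswith(value):
                return True
        return False
    raise SearchParameterError(f"unsupported search parameter {key!r}")
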