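"""Repository semantics: versioning, search-vs-scan oracle, authorization."""

import random

import pytest

from seqreport import Bundle, build_bundle, make_resource
from seqreport.errors import ConflictError, NotFoundError, SearchParameterError
from seqreport.repository import ResourceRepository


def _patient(pid, birth="1947-04-29"):
    return make_resource("Patient", {"birthDate": birth}, logical_id=pid)


def test_create_then_read_is_deep_equal():
    repo = ResourceRepository()
    p = _patient("p1")
    rid, version = repo.create(p)
    assert (rid, version) == ("p1", 1)
    got = repo.read("Patient", "p1")
    assert got.body == p.body
    assert got.version_id == 1
    got.body["birthDate"] = "mutated"  # copies must not alias the store
    assert repo.read("Patient", "p1").body["birthDate"] == "1947-04-29"


def test_duplicate_create_conflicts():
    repo = ResourceRepository()
    repo.create(_patient("p1"))
    with pytest.raises(ConflictError):
        repo.create(_patient("p1"))


def test_bundle_create_unrolls_entries(example_report):
    bundle = build_bundle(example_report)
    repo = ResourceRepository()
    created = repo.create(bundle)
    assert len(created) == len(bundle.entries)


def test_update_history_version_arithmetic():
    repo = ResourceRepository()
    repo.create(_patient("p1"))
    v2 = repo.update("Patient", "p1", _patient("p1", birth="1950-01-01"))
    assert v2 == 2
    assert repo.read("Patient", "p1").version_id == 2
    history = repo.history("Patient", "p1")
    assert [h.version_id for h in history] == [1, 2]
    assert [h.body["birthDate"] for h in history] == ["1947-04-29", "1950-01-01"]


def test_read_unknown_id_not_found():
    repo = ResourceRepository()
    with pytest.raises(NotFoundError):
        repo.read("Patient", "ghost")
    with pytest.raises(NotFoundError):
        repo.update("Patient", "ghost", _patient("ghost"))


def test_search_by_subject():
    repo = ResourceRepository()
    for i in range(3):
        repo.create(make_resource("Observation",
                                  {"subject": {"reference": "Patient/p1"}},
                                  logical_id=f"a{i}"))
    for i in range(2):
        repo.create(make_resource("Observation",
                                  {"subject": {"reference": "Patient/p2"}},
                                  logical_id=f"b{i}"))
    hits = repo.search("Observation", subject="Patient/p1")
    assert isinstance(hits, Bundle)
    assert len(hits.entries) == 3


def test_search_no_params_returns_all_latest():
    repo = ResourceRepository()
    repo.create(_patient("p1"))
    repo.create(_patient("p2"))
    repo.update("Patient", "p1", _patient("p1", birth="1950-01-01"))
    hits = repo.search("Patient")
    assert {(e.logical_id, e.version_id) for e in hits.entries} == {("p1", 2), ("p2", 1)}


def test_search_unsupported_parameter():
    repo = ResourceRepository()
    with pytest.raises(SearchParameterError, match="subject"):
        repo.search("Observation", frobnicate="x")


def test_search_equals_brute_force_scan_randomized():
    rng = random.Random(13)
    repo = ResourceRepository()
    stored = []
    for i in range(120):
        subj = f"Patient/p{rng.randrange(5)}"
        date = f"20{rng.randrange(18, 22)}-0{rng.randrange(1, 10)}-10"
        res = make_resource("Observation",
                            {"subject": {"reference": subj},
                             "effectiveDateTime": date},
                            logical_id=f"o{i}")
        repo.create(res)
        stored.append(res)
    for _ in range(20):
        subj = f"Patient/p{rng.randrange(5)}"
        date = f"20{rng.randrange(18, 22)}"
        expected = {r.logical_id for r in stored
                    if r.body["subject"]["reference"] == subj
                    and r.body["effectiveDateTime"].startswith(date)}
        got = {e.logical_id
               for e in repo.search("Observation", subject=subj, date=date).entries}
        assert got == expected


def test_soft_delete_behind_switch():
    repo = ResourceRepository(allow_delete=True)
    repo.create(_patient("p1"))
    repo.delete("Patient", "p1")
    with pytest.raises(NotFoundError):
        repo.read("Patient", "p1")
    locked = ResourceRepository()
    locked.create(_patient("p1"))
    with pytest.raises(NotFoundError, match="not enabled"):
        locked.delete("Patient", "p1")


def test_authorization_token_table():
    tokens = {"reader": {"read", "search", "history"},
              "admin": {"create", "read", "search", "history", "update"}}
    repo = ResourceRepository(tokens=tokens)
    assert repo.authorize("reader", "read")
    assert not repo.authorize("reader", "update")
    assert not repo.authorize("stranger", "read")
    repo.create(_patient("p1"), token="admin")
    assert repo.read("Patient", "p1", token="reader").logical_id == "p1"
    from seqreport.errors import AuthorizationError
    with pytest.raises(AuthorizationError):
        repo.update("Patient", "p1", _patient("p1"), token="reader")


def test_snapshot_roundtrip(tmp_path):
    repo = ResourceRepository()
    repo.create(_patient("p1"))
    repo.create(_patient("p2", birth="1950-01-01"))
    path = tmp_path / "store.jsonl"
    repo.snapshot(path)
    fresh = ResourceRepository()
    assert fresh.load_snapshot(path) == 2
    assert fresh.read("Patient", "p2").body["birthDate"] == "1950-01-01"
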