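"""Validated document store and campaign state machine.

Campaign metadata lives in an embedded, schema-less document store: one
JSON-lines file per account, one document per line, each tagged with its
collection. Collections ("Plates", "Wells", "Libraries") each carry a
validator over required keys — an insert is refused, naming the offending
key, if a required key is missing or has the wrong type; extra keys are
always allowed.

A campaign progresses through five consecutive stages — Plates, Cryo,
Soaking, Redissolve, Fishing — of which Cryo and Redissolve are optional
(they may be skipped outright). A later mandatory stage can never complete
while an earlier mandatory stage is still pending.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

from .config import COLLECTION_SCHEMAS
from .errors import DocumentValidationError, FragflowError, StateError

__all__ = ["STAGES", "OPTIONAL_STAGES", "CampaignDoc", "CampaignStore"]

STAGES: tuple[str, ...] = ("Plates", "Cryo", "Soaking", "Redissolve", "Fishing")
OPTIONAL_STAGES: frozenset[str] = frozenset({"Cryo", "Redissolve"})
_STATUSES = ("pending", "in_progress", "done", "skipped")
# forward-only transitions; "skipped" is terminal and optional-stage-only
_STATUS_RANK = {"pending": 0, "in_progress": 1, "done": 2, "skipped": 2}


@dataclass
class CampaignDoc:
    """One screening campaign; the name is the unique identifier."""

    name: str
    account: str
    created: datetime
    stage_status: dict[str, str] = field(
        default_factory=lambda: {s: "pending" for s in STAGES}
    )

    def to_json(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "account": self.account,
            "created": self.created.isoformat(),
            "stage_status": dict(self.stage_status),
        }

    @classmethod
    def from_json(cls, doc: dict[str, Any]) -> "CampaignDoc":
        return cls(
            name=doc["name"],
            account=doc["account"],
            created=datetime.fromisoformat(doc["created"]),
            stage_status=dict(doc["stage_status"]),
        )


def _type_ok(value: Any, expected: type) -> bool:
    if expected is float:
        # a JSON number may arrive as int; bool is not a number
        return isinstance(value, (int, float)) and not isinstance(value, bool)
    if expected is int:
        return isinstance(value, int) and not isinstance(value, bool)
    return isinstance(value, expected)


def validate_document(collection: str, doc: dict[str, Any]) -> None:
    """Check a document against its collection schema.

    Raises :class:`DocumentValidationError` naming the first required key
    that is missing or mistyped; returns silently when the document is
    acceptable. Total: every document is either accepted or rejected with
    a named key.
    """
    if collection not in COLLECTION_SCHEMAS:
        raise FragflowError(f"unknown collection {collection!r}")
    schema = COLLECTION_SCHEMAS[collection]
    for key, expected in schema.required.items():
        if key not in doc:
            raise DocumentValidationError(
                f"{collection} document missing required key {key!r}", key=key
            )
        if not _type_ok(doc[key], expected):
            raise DocumentValidationError(
                f"{collection} document key {key!r} has wrong type "
                f"{type(doc[key]).__name__} (expected {expected.__name__})",
                key=key,
            )


class CampaignStore:
    """JSON-lines-backed campaign metadata store for one account.

    Every mutation is validated, applied in memory and appended-rewritten to
    the backing file, so the file always reflects the full current state.
    Pass ``path=None`` for an in-memory store (tests, dry runs).
    """

    def __init__(self, path: str | Path | None, account: str = "group"):
        self.path = Path(path) if path is not None else None
        self.account = account
        self._docs: list[dict[str, Any]] = []
        self._campaigns: dict[str, CampaignDoc] = {}
        self._next_id = 1
        if self.path is not None and self.path.exists():
            self._load()

    # -- persistence -------------------------------------------------------

    def _load(self) -> None:
        assert self.path is not None
        with open(self.path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                if rec["_collection"] == "_campaigns":
                    camp = CampaignDoc.from_json(rec["doc"])
                    self._campaigns[camp.name] = camp
                else:
                    self._docs.append(rec)
                    self._next_id = max(self._next_id, rec["_id"] + 1)

    def _flush(self) -> None:
        if self.path is None:
            return
        self.path.parent.mkdir(parents=True, exist_ok=True)
        with open(self.path, "w") as fh:
            for camp in self._campaigns.values():
                fh.write(
                    json.dumps({"_collection": "_campaigns", "doc": camp.to_json()})
                    + "\n"
                )
            for rec in self._docs:
                fh.write(json.dumps(rec) + "\n")

    # -- document collections ---------------------------------------------

    def insert_document(self, collection: str, doc: dict[str, Any]) -> int:
        """Validate and persist a document; returns the stored id."""
        validate_document(collection, doc)
        rec = {"_id": self._next_id, "_collection": collection, "doc": dict(doc)}
        self._next_id += 1
        self._docs.append(rec)
        self._flush()
        return rec["_id"]

    def fetch(self, collection: str, **query: Any) -> list[dict[str, Any]]:
        """Documents of a collection matching all equality constraints."""
        return [
            dict(rec["doc"])
            for rec in self._docs
            if rec["_collection"] == collection
            and all(rec["doc"].get(k) == v for k, v in query.items())
        ]

    def get_document(self, doc_id: int) -> dict[str, Any]:
        for rec in self._docs:
            if rec["_id"] == doc_id:
                return dict(rec["doc"])
        raise FragflowError(f"no document with id {doc_id}")

    # -- campaigns ---------------------------------------------------------

    def create_campaign(self, name: str, account: str | None = None) -> CampaignDoc:
        if not name:
            raise FragflowError("campaign name must be non-empty")
        if name in self._campaigns:
            raise FragflowError(f"campaign name {name!r} already in use")
        camp = CampaignDoc(
            name=name,
            account=account or self.account,
            created=datetime.now(timezone.utc),
        )
        self._campaigns[name] = camp
        self._flush()
        return camp

    def get_campaign(self, name: str) -> CampaignDoc:
        try:
            return self._campaigns[name]
        except KeyError:
            raise FragflowError(f"unknown campaign {name!r}") from None

    def list_campaigns(self, account: str | None = None) -> list[str]:
        return sorted(
            c.name
            for c in self._campaigns.values()
            if account is None or c.account == account
        )

    def register_plate(
        self, campaign: str, barcode: str, kind: str = "crystal"
    ) -> int:
        """Add a plate to a campaign; moves the Plates stage to in_progress."""
        camp = self.get_campaign(campaign)
        if self.fetch("Plates", barcode=barcode, campaign=campaign):
            raise FragflowError(
                f"plate {barcode!r} already registered to campaign {campaign!r}"
            )
        doc_id = self.insert_document(
            "Plates", {"barcode": barcode, "kind": kind, "campaign": campaign}
        )
        if camp.stage_status["Plates"] == "pending":
            camp.stage_status["Plates"] = "in_progress"
            self._flush()
        return doc_id

    def advance_stage(self, campaign: str, stage: str, to: str) -> CampaignDoc:
        """Move one campaign stage to a new status.

        Stages advance in order; a stage may only start or complete when all
        earlier stages are resolved (done, or skipped for optional stages),
        and only optional stages may be skipped. Statuses never move
        backwards.
        """
        camp = self.get_campaign(campaign)
        if stage not in STAGES:
            raise StateError(f"unknown stage {stage!r}")
        if to not in _STATUSES:
            raise StateError(f"unknown status {to!r}")
        current = camp.stage_status[stage]
        if to == "skipped" and stage not in OPTIONAL_STAGES:
            raise StateError(f"mandatory stage {stage} cannot be skipped")
        if _STATUS_RANK[to] < _STATUS_RANK[current]:
            raise StateError(
                f"stage {stage} cannot move backwards from {current} to {to}"
            )
        if to in ("in_progress", "done"):
            for earlier in STAGES[: STAGES.index(stage)]:
                status = camp.stage_status[earlier]
                if status not in ("done", "skipped"):
                    raise StateError(
                        f"stage {stage} cannot be {to} while earlier stage "
                        f"{earlier} is {status}"
                    )
        camp.stage_status[stage] = to
        self._flush()
        return camp
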