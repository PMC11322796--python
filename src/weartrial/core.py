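"""Participant registry, study phases, device links, withdrawals.

The registry is event-sourced: every mutation appends a :class:`StudyEvent`
to an append-only log and updates the in-memory registry through a single
``_apply`` dispatcher. Replaying the log through :meth:`Study.from_events`
reconstructs the registry exactly, which is what makes CONSORT reporting
replayable and auditable.

Participants move along a fixed screening funnel::

    phase1_screen -> phase2_screen -> phase3_screen -> baseline
        -> randomized -> completed

with two terminal side states, ``withdrawn`` and ``ineligible``. No
operation moves a participant backward.
"""

from __future__ import annotations

import hashlib
from datetime import date, datetime
from enum import Enum
from typing import Any, Iterable, Optional

from pydantic import BaseModel, Field, SecretStr


class StudyPhase(str, Enum):
    PHASE1_SCREEN = "phase1_screen"
    PHASE2_SCREEN = "phase2_screen"
    PHASE3_SCREEN = "phase3_screen"
    BASELINE = "baseline"
    RANDOMIZED = "randomized"
    COMPLETED = "completed"
    WITHDRAWN = "withdrawn"
    INELIGIBLE = "ineligible"


#: The forward funnel, in order. Terminal side states are not part of it.
FUNNEL: tuple[StudyPhase, ...] = (
    StudyPhase.PHASE1_SCREEN,
    StudyPhase.PHASE2_SCREEN,
    StudyPhase.PHASE3_SCREEN,
    StudyPhase.BASELINE,
    StudyPhase.RANDOMIZED,
    StudyPhase.COMPLETED,
)

TERMINAL_PHASES = frozenset({StudyPhase.WITHDRAWN, StudyPhase.INELIGIBLE})


def funnel_index(phase: StudyPhase) -> int:
    """Position of a phase in the funnel; terminal states are not ranked."""
    return FUNNEL.index(phase)


def next_funnel_phase(phase: StudyPhase) -> StudyPhase:
    i = funnel_index(phase)
    if i + 1 >= len(FUNNEL):
        raise PhaseError(f"no phase after {phase.value}")
    return FUNNEL[i + 1]


class Vendor(str, Enum):
    WEARABLE_VENDOR = "wearable_vendor"
    SCALE_VENDOR = "scale_vendor"
    MOCK = "mock"


class EventKind(str, Enum):
    REGISTERED = "registered"
    SUBMITTED_QUESTIONNAIRE = "submitted_questionnaire"
    ELIGIBLE = "eligible"
    INELIGIBLE = "ineligible"
    RANDOMIZED = "randomized"
    ASSESSED = "assessed"
    WITHDRAWN = "withdrawn"
    PAID = "paid"
    LINKED_DEVICE = "linked_device"
    UNLINKED_DEVICE = "unlinked_device"


class StudyEvent(BaseModel):
    """One append-only entry of a participant's digital footprint."""

    study_id: str
    kind: EventKind
    timestamp: datetime
    payload: dict[str, Any] = Field(default_factory=dict)


class Withdrawal(BaseModel):
    date: date
    reason: str = ""


class Participant(BaseModel):
    study_id: str
    enrollment_date: date
    phase: StudyPhase = StudyPhase.PHASE1_SCREEN
    arm: Optional[str] = None
    factor_levels: dict[str, str] = Field(default_factory=dict)
    withdrawal: Optional[Withdrawal] = None

    @property
    def active(self) -> bool:
        return self.phase not in TERMINAL_PHASES


class DeviceLink(BaseModel):
    """An authorization to pull one participant's data from one vendor.

    The token is held as a :class:`~pydantic.SecretStr` so it never leaks
    through ``repr``, logs, or model dumps; only a salted fingerprint is
    written to the event log.
    """

    study_id: str
    vendor: Vendor
    token: SecretStr
    linked_date: date
    active: bool = True

    def token_fingerprint(self, salt: str = "") -> str:
        digest = hashlib.sha256(
            (salt + self.token.get_secret_value()).encode()
        ).hexdigest()
        return digest[:16]


class StudyError(Exception):
    """Base class for registry errors."""


class DuplicateRegistrationError(StudyError):
    pass


class UnknownParticipantError(StudyError):
    pass


class PhaseError(StudyError):
    pass


class WithdrawalError(StudyError):
    pass


class DeviceLinkError(StudyError):
    pass


class EventOrderError(StudyError):
    pass


def hash_contact(email: str, salt: str) -> str:
    """Salted hash of a contact email, the duplicate-registration key."""
    return hashlib.sha256((salt + email.strip().lower()).encode()).hexdigest()


class Study:
    """Event-sourced registry of participants, links, and study events.

    Parameters
    ----------
    id_prefix:
        Prefix for study-specific IDs; IDs are the prefix plus a
        zero-padded counter in registration order (``SM0001``, ...).
    salt:
        Salt for the contact-email duplicate-detection hash and for
        device-token fingerprints.
    """

    def __init__(self, id_prefix: str = "SM", salt: str = "weartrial") -> None:
        self.id_prefix = id_prefix
        self.salt = salt
        self.events: list[StudyEvent] = []
        self.participants: dict[str, Participant] = {}
        self.links: dict[tuple[str, Vendor], DeviceLink] = {}
        self._email_index: dict[str, str] = {}
        self._counter = 0
        self._last_ts: dict[str, datetime] = {}

    # ------------------------------------------------------------------ #
    # event plumbing

    def _append(self, event: StudyEvent) -> None:
        last = self._last_ts.get(event.study_id)
        if last is not None and event.timestamp < last:
            raise EventOrderError(
                f"event for {event.study_id} at {event.timestamp} precedes "
                f"the participant's last event at {last}"
            )
        self._apply(event)
        self.events.append(event)
        self._last_ts[event.study_id] = event.timestamp

    def _apply(self, ev: StudyEvent) -> None:
        sid = ev.study_id
        if ev.kind is EventKind.REGISTERED:
            p = Participant(
                study_id=sid,
                enrollment_date=ev.timestamp.date(),
                phase=StudyPhase.PHASE1_SCREEN,
                factor_levels=dict(ev.payload.get("factor_levels", {})),
            )
            self.participants[sid] = p
            key = ev.payload.get("contact_hash")
            if key:
                self._email_index[key] = sid
            self._counter = max(self._counter, int(ev.payload.get("seq", 0)))
        elif ev.kind is EventKind.ELIGIBLE:
            p = self.participants[sid]
            p.phase = next_funnel_phase(StudyPhase(ev.payload["phase"]))
        elif ev.kind is EventKind.INELIGIBLE:
            self.participants[sid].phase = StudyPhase.INELIGIBLE
        elif ev.kind is EventKind.RANDOMIZED:
            p = self.participants[sid]
            p.phase = StudyPhase.RANDOMIZED
            p.arm = ev.payload["arm"]
            if "factor_levels" in ev.payload:
                p.factor_levels.update(ev.payload["factor_levels"])
        elif ev.kind is EventKind.WITHDRAWN:
            p = self.participants[sid]
            p.phase = StudyPhase.WITHDRAWN
            p.withdrawal = Withdrawal(
                date=date.fromisoformat(ev.payload["date"]),
                reason=ev.payload.get("reason", ""),
            )
        elif ev.kind is EventKind.LINKED_DEVICE:
            vendor = Vendor(ev.payload["vendor"])
            self.links[(sid, vendor)] = DeviceLink(
                study_id=sid,
                vendor=vendor,
                token=SecretStr(ev.payload.get("_token", "")),
                linked_date=ev.timestamp.date(),
            )
        elif ev.kind is EventKind.UNLINKED_DEVICE:
            vendor = Vendor(ev.payload["vendor"])
            link = self.links.get((sid, vendor))
            if link is not None:
                link.active = False
        # submitted_questionnaire / assessed / paid leave the registry as-is

    # ------------------------------------------------------------------ #
    # operations

    def register_participant(
        self,
        profile: dict[str, Any],
        timestamp: datetime,
        required: Iterable[str] = ("email",),
    ) -> Participant:
        """Register a new candidate in the first screening phase.

        The profile must carry the configured required demographics; the
        contact email is hashed (salted) for duplicate detection and never
        stored in clear in the event log.
        """
        missing = [k for k in required if k not in profile]
        if missing:
            raise StudyError(f"profile missing required fields: {missing}")
        contact_hash = None
        if "email" in profile:
            contact_hash = hash_contact(str(profile["email"]), self.salt)
            if contact_hash in self._email_index:
                raise DuplicateRegistrationError(
                    "a participant with this contact is already registered; "
                    "re-registration is not allowed"
                )
        self._counter += 1
        sid = f"{self.id_prefix}{self._counter:04d}"
        payload: dict[str, Any] = {"seq": self._counter}
        if contact_hash:
            payload["contact_hash"] = contact_hash
        factor_levels = profile.get("factor_levels")
        if factor_levels:
            payload["factor_levels"] = dict(factor_levels)
        self._append(
            StudyEvent(
                study_id=sid,
                kind=EventKind.REGISTERED,
                timestamp=timestamp,
                payload=payload,
            )
        )
        return self.participants[sid]

    def get(self, study_id: str) -> Participant:
        try:
            return self.participants[study_id]
        except KeyError:
            raise UnknownParticipantError(study_id) from None

    def record_submission(
        self, study_id: str, qid: str, timestamp: datetime
    ) -> None:
        self.get(study_id)
        self._append(
            StudyEvent(
                study_id=study_id,
                kind=EventKind.SUBMITTED_QUESTIONNAIRE,
                timestamp=timestamp,
                payload={"qid": qid},
            )
        )

    def mark_eligible(self, study_id: str, timestamp: datetime) -> Participant:
        """Advance an active participant one step along the funnel."""
        p = self.get(study_id)
        if not p.active:
            raise PhaseError(f"{study_id} is {p.phase.value}")
        if p.phase not in (StudyPhase.PHASE1_SCREEN, StudyPhase.PHASE2_SCREEN,
                           StudyPhase.PHASE3_SCREEN):
            raise PhaseError(
                f"{study_id} is in {p.phase.value}; advancing out of baseline "
                "happens through randomize()"
            )
        self._append(
            StudyEvent(
                study_id=study_id,
                kind=EventKind.ELIGIBLE,
                timestamp=timestamp,
                payload={"phase": p.phase.value},
            )
        )
        return self.get(study_id)

    def mark_ineligible(
        self,
        study_id: str,
        timestamp: datetime,
        failed_criteria: Optional[list[str]] = None,
    ) -> Participant:
        p = self.get(study_id)
        if not p.active:
            raise PhaseError(f"{study_id} is {p.phase.value}")
        self._append(
            StudyEvent(
                study_id=study_id,
                kind=EventKind.INELIGIBLE,
                timestamp=timestamp,
                payload={
                    "phase": p.phase.value,
                    "failed_criteria": failed_criteria or [],
                },
            )
        )
        return self.get(study_id)

    def randomize(
        self,
        study_id: str,
        arm: str,
        timestamp: datetime,
        factor_levels: Optional[dict[str, str]] = None,
    ) -> Participant:
        p = self.get(study_id)
        if p.phase is not StudyPhase.BASELINE:
            raise PhaseError(
                f"{study_id} is in {p.phase.value}, not baseline; "
                "cannot randomize"
            )
        payload: dict[str, Any] = {"arm": arm}
        if factor_levels:
            payload["factor_levels"] = dict(factor_levels)
        self._append(
            StudyEvent(
                study_id=study_id,
                kind=EventKind.RANDOMIZED,
                timestamp=timestamp,
                payload=payload,
            )
        )
        return self.get(study_id)

    def record_assessment(
        self, study_id: str, label: str, timestamp: datetime
    ) -> None:
        self.get(study_id)
        self._append(
            StudyEvent(
                study_id=study_id,
                kind=EventKind.ASSESSED,
                timestamp=timestamp,
                payload={"label": label},
            )
        )

    def record_payment(
        self, study_id: str, amount: float, timestamp: datetime
    ) -> None:
        self.get(study_id)
        self._append(
            StudyEvent(
                study_id=study_id,
                kind=EventKind.PAID,
                timestamp=timestamp,
                payload={"amount": float(amount)},
            )
        )

    def record_withdrawal(
        self,
        study_id: str,
        when: date,
        reason: str = "",
        timestamp: Optional[datetime] = None,
    ) -> Participant:
        """Mark a withdrawal; the participant leaves every future scan and
        retention denominator."""
        p = self.get(study_id)
        if p.phase is StudyPhase.WITHDRAWN:
            raise WithdrawalError(f"{study_id} already withdrawn")
        ts = timestamp or datetime(when.year, when.month, when.day)
        self._append(
            StudyEvent(
                study_id=study_id,
                kind=EventKind.WITHDRAWN,
                timestamp=ts,
                payload={"date": when.isoformat(), "reason": reason},
            )
        )
        return self.get(study_id)

    def link_device(
        self,
        study_id: str,
        vendor: Vendor,
        token: str,
        when: date,
        timestamp: Optional[datetime] = None,
    ) -> DeviceLink:
        """Store a vendor authorization; the sync scheduler includes it.

        Linking requires the participant to be randomized or in phase-3
        screening (the food-diary review already needs vendor data).
        """
        p = self.get(study_id)
        if p.phase not in (StudyPhase.PHASE3_SCREEN, StudyPhase.BASELINE,
                           StudyPhase.RANDOMIZED):
            raise DeviceLinkError(
                f"{study_id} in phase {p.phase.value} cannot link a device"
            )
        vendor = Vendor(vendor)
        existing = self.links.get((study_id, vendor))
        if existing is not None and existing.active:
            raise DeviceLinkError(
                f"{study_id} already has an active {vendor.value} link; "
                "unlink first"
            )
        fingerprint = hashlib.sha256((self.salt + token).encode()).hexdigest()[:16]
        self._append(
            StudyEvent(
                study_id=study_id,
                kind=EventKind.LINKED_DEVICE,
                timestamp=timestamp or datetime(when.year, when.month, when.day),
                payload={
                    "vendor": vendor.value,
                    "token_fingerprint": fingerprint,
                    "_token": token,
                },
            )
        )
        return self.links[(study_id, vendor)]

    def unlink_device(self, study_id: str, vendor: Vendor, when: date) -> None:
        vendor = Vendor(vendor)
        link = self.links.get((study_id, vendor))
        if link is None or not link.active:
            raise DeviceLinkError(f"no active {vendor.value} link for {study_id}")
        self._append(
            StudyEvent(
                study_id=study_id,
                kind=EventKind.UNLINKED_DEVICE,
                timestamp=datetime(when.year, when.month, when.day),
                payload={"vendor": vendor.value},
            )
        )

    def active_links(self) -> list[DeviceLink]:
        return [l for l in self.links.values() if l.active]

    # ------------------------------------------------------------------ #
    # replay / persistence

    def registry_state(self) -> dict[str, dict[str, Any]]:
        """Serializable snapshot of the participant registry (no secrets)."""
        return {
            sid: p.model_dump(mode="json") for sid, p in self.participants.items()
        }

    @classmethod
    def from_events(
        cls,
        events: Iterable[StudyEvent],
        id_prefix: str = "SM",
        salt: str = "weartrial",
    ) -> "Study":
        study = cls(id_prefix=id_prefix, salt=salt)
        for ev in events:
            study._append(ev)
        return study

    def dump_events(self) -> list[dict[str, Any]]:
        """Event log as JSON-ready dicts, with device tokens redacted."""
        out = []
        for ev in self.events:
            d = ev.model_dump(mode="json")
            d["payload"].pop("_token", None)
            out.append(d)
        return out
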