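"""Lightweight audit trail.

Rules that decline to fire for lack of evidence (missing email, an IP
prefix absent from the geo table, a missing duration) leave a note here so
the run remains explainable to study staff without polluting strikes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union


@dataclass(frozen=True)
class AuditNote:
    submission_id: str
    context: str
    message: str


@dataclass
class AuditLog:
    notes: list[AuditNote] = field(default_factory=list)

    def note(self, submission_id: str, context: str, message: str) -> None:
        self.notes.append(AuditNote(submission_id, context, message))

    def lines(self) -> list[str]:
        return [f"{n.submission_id}\t{n.context}\t{n.message}" for n in self.notes]

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text("\n".join(self.lines()) + ("\n" if self.notes else ""), encoding="utf-8")
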