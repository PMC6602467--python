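"""Shared warning record emitted into the curation warning file."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Warning:  # noqa: A001 - domain term, re-exported by the trna module
    category: str
    subject: str
    message: str
    severity: str = "warn"  # info | warn

    def __post_init__(self) -> None:
        if not self.message:
            raise ValueError("warning message must be non-empty")
        if self.severity not in ("info", "warn"):
            raise ValueError(f"bad severity {self.severity!r}")
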