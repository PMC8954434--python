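"""Shared tri-state result container for the four dispersal-signal detectors."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

DETECTED = "detected"
NOT_DETECTED = "not_detected"
NOT_ASSESSABLE = "not_assessable"

_STATUSES = (DETECTED, NOT_DETECTED, NOT_ASSESSABLE)


@dataclass
class SignalResult:
    """Outcome of one dispersal-signal test.

    ``status`` is tri-state: a signal is *not assessable* only when the data
    layer it needs is absent (no chloroplast data, fewer than three sites for
    an isolation-by-distance test, a single inferred ancestral population for
    the admixture tests) — never as a silent stand-in for "not detected".
    ``evidence`` preserves the numbers behind the call.
    """

    status: str
    evidence: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in _STATUSES:
            raise ValueError(f"status must be one of {_STATUSES}, got {self.status!r}")

    @property
    def detected(self) -> bool:
        return self.status == DETECTED
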