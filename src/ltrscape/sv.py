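"""Structural-variation events and their table dialect.

An event is an indel or duplication of a copy relative to its family
consensus.  In emitted tables events are written in the census dialect:
events comma-separated, size in bp appended to the type, and an affected
LTR parenthesized — e.g. ``del120(5′), ins45``; ``No`` means no event and
``ND`` means the SV could not be determined.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

LTR_FLAGS = ("none", "LTR5", "LTR3")
_FLAG_TO_TOKEN = {"LTR5": "(5′)", "LTR3": "(3′)"}
_TOKEN_RE = re.compile(r"^(del|ins|dup)(\d+)(?:\((5|3)[′']\))?$")


@dataclass(frozen=True)
class SVEvent:
    type: str  # del | ins | dup
    size: int  # bp
    offset: int  # 0-based consensus offset of the event
    ltr_flag: str = "none"  # none | LTR5 | LTR3

    def __post_init__(self):
        if self.type not in ("del", "ins", "dup"):
            raise ValueError(f"bad SV type {self.type!r}")
        if self.ltr_flag not in LTR_FLAGS:
            raise ValueError(f"bad ltr_flag {self.ltr_flag!r}")


def format_sv(events, determined: bool = True) -> str:
    """Render an event list in the census SV dialect."""
    if not determined:
        return "ND"
    if not events:
        return "No"
    toks = []
    for ev in events:
        toks.append(f"{ev.type}{ev.size}{_FLAG_TO_TOKEN.get(ev.ltr_flag, '')}")
    return ", ".join(toks)


def parse_sv(text: str) -> tuple[list[SVEvent] | None, bool]:
    """Parse a census SV string.

    Returns ``(events, determined)``; a malformed token downgrades the whole
    field to undetermined with a warning (row-level tolerance on import).
    Offsets are not part of the dialect and come back as -1.
    """
    text = str(text).strip()
    if text in ("ND", "nd", "n. d.", ""):
        return None, False
    if text in ("No", "no", "NO"):
        return [], True
    events = []
    # dash separates co-located events in the dialect; treat like a comma
    for tok in re.split(r"[,–-]| - ", text.replace("—", "-")):
        tok = tok.strip()
        if not tok:
            continue
        m = _TOKEN_RE.match(tok)
        if not m:
            warnings.warn(f"malformed SV token {tok!r}; SV set to ND")
            return None, False
        kind, size, flag = m.groups()
        ltr_flag = {"5": "LTR5", "3": "LTR3", None: "none"}[flag]
        events.append(SVEvent(kind, int(size), -1, ltr_flag))
    return events, True
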