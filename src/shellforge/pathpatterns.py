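"""Filename pattern matching producing sorted filename lists.

Patterns match entry names inside a single directory — no recursion, no
directory crossing. Two dialects:

* ``wildcard`` — ``*`` matches any run of characters, ``?`` exactly one;
  everything else is literal.
* ``regex`` — a full-match regular expression applied to each entry name.

Hidden entries (dot-prefixed) match only when the pattern's first character
is ``.``, in either mode.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass

from .errors import PatternError


@dataclass(frozen=True)
class PathPattern:
    directory: str
    pattern: str
    mode: str = "wildcard"  # "wildcard" | "regex"

    def __post_init__(self) -> None:
        if self.mode not in ("wildcard", "regex"):
            raise PatternError(f"unknown match mode {self.mode!r}")
        if not self.pattern:
            raise PatternError("empty pattern")


def wildcard_to_regex(pattern: str) -> str:
    parts = []
    for ch in pattern:
        if ch == "*":
            parts.append(".*")
        elif ch == "?":
            parts.append(".")
        else:
            parts.append(re.escape(ch))
    return "".join(parts)


def compile_pattern(p: PathPattern) -> re.Pattern:
    if p.mode == "wildcard":
        return re.compile(wildcard_to_regex(p.pattern))
    try:
        return re.compile(p.pattern)
    except re.error as exc:
        raise PatternError(f"invalid regular expression {p.pattern!r}: {exc}") from exc


def matches_entry(p: PathPattern, name: str) -> bool:
    """Whether a single directory-entry name matches the pattern."""
    if name.startswith(".") and not p.pattern.startswith("."):
        return False
    return compile_pattern(p).fullmatch(name) is not None


def match_paths(p: PathPattern) -> list[str]:
    """Entry names in ``p.directory`` matching ``p.pattern``, sorted.

    Zero matches is an empty list, not an error. An unreadable or missing
    directory raises :class:`PatternError`.
    """
    regex = compile_pattern(p)  # validate before touching the filesystem
    try:
        entries = os.listdir(p.directory)
    except OSError as exc:
        raise PatternError(f"cannot list directory {p.directory}: {exc}") from exc
    hidden_ok = p.pattern.startswith(".")
    return sorted(
        name
        for name in entries
        if (hidden_ok or not name.startswith(".")) and regex.fullmatch(name)
    )
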