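"""Interpolated strings with lazy evaluation (GStrings).

A :class:`GString` is an ordered list of components — literal text, references
to program variables, and reads of environment variables — written in marker
syntax::

    "aligning ${sample} for ${USER}"

Evaluation is lazy: a GString stores references, not values, so re-evaluating
after a variable is rebound yields the new value. The marker is exactly
``${name}``; interior whitespace is tolerated and trimmed (``${ b}`` reads
variable ``b``); ``\\${`` escapes a literal ``${``; a ``$`` not followed by
``{`` is an ordinary character.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from ._ids import new_id
from .errors import EvaluationError, GStringParseError

_IDENTIFIER_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def is_identifier(name: str) -> bool:
    """True when ``name`` is a valid shell-style identifier."""
    return bool(_IDENTIFIER_RE.match(name))


@dataclass
class GStringComponent:
    node_id: str = field(default_factory=new_id, compare=False, kw_only=True)


@dataclass
class Literal(GStringComponent):
    """A run of plain text."""

    text: str = ""


@dataclass
class VarRef(GStringComponent):
    """A reference to a program variable declaration.

    ``declaration_id`` is the node id of the targeted declaration when known;
    ``None`` marks an unresolved reference (flagged later by the checker).
    """

    name: str = ""
    declaration_id: str | None = None


@dataclass
class EnvRead(GStringComponent):
    """A read of an environment variable at evaluation time."""

    name: str = ""


@dataclass
class GString:
    components: list[GStringComponent] = field(default_factory=list)
    node_id: str = field(default_factory=new_id, compare=False, kw_only=True)

    def is_literal_only(self) -> bool:
        return all(isinstance(c, Literal) for c in self.components)

    def literal_text(self) -> str:
        if not self.is_literal_only():
            raise ValueError("GString contains non-literal components")
        return "".join(c.text for c in self.components)  # type: ignore[union-attr]

    @classmethod
    def from_text(cls, text: str) -> "GString":
        """A literal-only GString holding ``text`` verbatim (no parsing)."""
        return cls([Literal(text)] if text else [])


def parse_gstring(
    text: str,
    scope: Iterable[str] = (),
    env_names: Iterable[str] = (),
    *,
    scope_ids: Mapping[str, str] | None = None,
    shell_quotes: bool = False,
) -> GString:
    """Parse marker syntax into a GString.

    ``${name}`` becomes a :class:`VarRef` when ``name`` is in ``scope``, an
    :class:`EnvRead` when it is in ``env_names`` (scope shadows the
    environment on collision), and an unresolved :class:`VarRef` otherwise.
    ``scope_ids`` optionally maps in-scope names to declaration node ids.

    With ``shell_quotes=True``, markers inside single-quoted regions are kept
    literal (the shell convention for suppressing expansion); double quotes
    leave markers live. The quote characters themselves are preserved in the
    literal text — they matter later for word splitting.

    Raises :class:`GStringParseError` (with the marker's offset) for an
    unterminated ``${`` or a non-identifier name.
    """
    scope = set(scope)
    env_names = set(env_names)
    scope_ids = scope_ids or {}
    components: list[GStringComponent] = []
    buf: list[str] = []
    i = 0
    in_single = False

    def flush() -> None:
        if buf:
            components.append(Literal("".join(buf)))
            buf.clear()

    n = len(text)
    while i < n:
        ch = text[i]
        if shell_quotes and ch == "'":
            in_single = not in_single
            buf.append(ch)
            i += 1
            continue
        if in_single:
            buf.append(ch)
            i += 1
            continue
        if ch == "\\" and text[i : i + 3] == "\\${":
            buf.append("${")
            i += 3
            continue
        if ch == "$" and i + 1 < n and text[i + 1] == "{":
            end = text.find("}", i + 2)
            if end < 0:
                raise GStringParseError("unterminated '${' marker", offset=i)
            name = text[i + 2 : end].strip()
            if not is_identifier(name):
                raise GStringParseError(
                    f"invalid variable name {name!r} in marker", offset=i
                )
            flush()
            if name in scope:
                components.append(VarRef(name, scope_ids.get(name)))
            elif name in env_names:
                components.append(EnvRead(name))
            else:
                components.append(VarRef(name, None))
            i = end + 1
            continue
        buf.append(ch)
        i += 1
    flush()
    return GString(components)


def evaluate_gstring(
    g: GString, bindings: Mapping[str, str], env: Mapping[str, str]
) -> str:
    """Concatenate literals with the *current* values of all references.

    Pure in ``(bindings, env)``: rebinding a variable and re-evaluating
    reflects the new value. Raises :class:`EvaluationError` naming the first
    unbound reference.
    """
    parts: list[str] = []
    for comp in g.components:
        if isinstance(comp, Literal):
            parts.append(comp.text)
        elif isinstance(comp, VarRef):
            if comp.name not in bindings:
                raise EvaluationError(f"unbound variable {comp.name}")
            parts.append(bindings[comp.name])
        elif isinstance(comp, EnvRead):
            if comp.name not in env:
                raise EvaluationError(f"unbound environment variable {comp.name}")
            parts.append(env[comp.name])
        else:  # pragma: no cover - closed variant set
            raise TypeError(f"unknown component {type(comp).__name__}")
    return "".join(parts)


def normalize_gstring(g: GString) -> GString:
    """Merge adjacent literals and drop empty ones.

    Idempotent and evaluation-equivalent to the input; the input is not
    mutated.
    """
    out: list[GStringComponent] = []
    for comp in g.components:
        if isinstance(comp, Literal):
            if not comp.text:
                continue
            if out and isinstance(out[-1], Literal):
                out[-1] = Literal(out[-1].text + comp.text)
                continue
            out.append(Literal(comp.text))
        else:
            out.append(comp)
    return GString(out)


def render_gstring(g: GString) -> str:
    """Render back to marker syntax.

    Occurrences of ``${`` inside literals are re-escaped as ``\\${`` so that
    the output re-parses to an equivalent GString. For inputs without escapes,
    ``render_gstring(parse_gstring(t, ...)) == t``.
    """
    parts: list[str] = []
    for comp in g.components:
        if isinstance(comp, Literal):
            parts.append(comp.text.replace("${", "\\${"))
        elif isinstance(comp, (VarRef, EnvRead)):
            parts.append("${" + comp.name + "}")
    return "".join(parts)
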