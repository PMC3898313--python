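"""Micro-parsing: import raw shell text into well-formed AST fragments.

Two operations, both with the same contract: the raw text is parsed into an
AST fragment, and on *any* error the input model is left byte-identical —
raw text is only ever cleared after a fully successful parse.

* :func:`parse_pipeline` turns one shell command line into an
  :class:`~shellforge.model.ExecuteCommand` — commands separated by the
  binary operators ``| && || ; &`` with an optional trailing ``> file``
  redirect. Operators are tokenized maximal-munch (``||`` before ``|``,
  ``&&`` before ``&``) and are inert inside quotes; single quotes also keep
  ``${`` markers literal, double quotes keep them live.
* :func:`extract_variables` replaces ``${name}`` markers in a pasted literal
  with variable references, declaring any name not already in scope
  immediately before the containing statement.
"""

from __future__ import annotations

from typing import Iterable

from .errors import GStringParseError, ModelError, PipelineParseError
from .gstring import GString, VarRef, parse_gstring, render_gstring
from .model import (
    ExecuteCommand,
    GStringCommand,
    Operator,
    RedirectToFile,
    ScriptModel,
    Statement,
    VariableDeclaration,
)

_TWO_CHAR_OPS = {"||": "or", "&&": "and"}
_ONE_CHAR_OPS = {"|": "pipe", "&": "background", ";": "seq"}


def _tokenize(text: str):
    """Split pipeline text into ('text'|'op'|'redirect', value, offset)
    tokens, quote-aware. Offsets are 0-based into ``text``."""
    tokens: list[tuple[str, str, int]] = []
    buf: list[str] = []
    buf_start = 0
    in_single = in_double = False
    quote_offset = 0
    i, n = 0, len(text)

    def flush() -> None:
        nonlocal buf
        raw = "".join(buf)
        stripped = raw.strip()
        if stripped:
            lead = len(raw) - len(raw.lstrip())
            tokens.append(("text", stripped, buf_start + lead))
        buf = []

    while i < n:
        ch = text[i]
        if in_single:
            if ch == "'":
                in_single = False
            buf.append(ch)
            i += 1
            continue
        if in_double:
            if ch == '"':
                in_double = False
            buf.append(ch)
            i += 1
            continue
        if ch == "'" or ch == '"':
            if not buf:
                buf_start = i
            in_single = ch == "'"
            in_double = ch == '"'
            quote_offset = i
            buf.append(ch)
            i += 1
            continue
        two = text[i : i + 2]
        if two in _TWO_CHAR_OPS:
            flush()
            tokens.append(("op", _TWO_CHAR_OPS[two], i))
            i += 2
            continue
        if ch in _ONE_CHAR_OPS:
            flush()
            tokens.append(("op", _ONE_CHAR_OPS[ch], i))
            i += 1
            continue
        if ch == ">":
            if text[i + 1 : i + 2] == ">":
                raise PipelineParseError(
                    "unsupported redirect '>>' (only overwrite '>' is modeled)",
                    offset=i,
                )
            stripped = "".join(buf).rstrip()
            if (
                stripped
                and stripped[-1].isdigit()
                and (len(stripped) == 1 or stripped[-2] in " \t")
            ):
                raise PipelineParseError(
                    "unsupported numbered redirect (only stdout '>' is modeled)",
                    offset=i - 1,
                )
            flush()
            tokens.append(("redirect", ">", i))
            i += 1
            continue
        if ch == "<":
            raise PipelineParseError(
                "unsupported redirect '<' (only stdout '>' is modeled)", offset=i
            )
        if not buf:
            buf_start = i
        buf.append(ch)
        i += 1
    if in_single or in_double:
        raise PipelineParseError("unbalanced quote", offset=quote_offset)
    flush()
    return tokens


def _segment_gstring(
    seg: str, offset: int, scope, env_names, scope_ids
) -> GString:
    try:
        return parse_gstring(
            seg, scope, env_names, scope_ids=scope_ids, shell_quotes=True
        )
    except GStringParseError as exc:
        rel = exc.offset or 0
        raise PipelineParseError(
            str(exc).split(" (at offset")[0], offset=offset + rel
        ) from exc


def parse_pipeline(
    text: str,
    scope: Iterable[str] = (),
    env_names: Iterable[str] = (),
    scope_ids=None,
) -> ExecuteCommand:
    """Parse one shell command line into an ExecuteCommand.

    The result satisfies the pipeline alternation invariants by
    construction: command segments become GStringCommands (their text run
    through the GString parser), operators map 1:1 to the surface tokens,
    a trailing ``> target`` becomes a RedirectToFile, and a final lone ``&``
    marks the last command as a background launch.

    Any defect — consecutive operators, a leading/trailing operator, an
    empty command segment, an unbalanced quote, an unsupported redirect —
    raises :class:`PipelineParseError` with the character offset; the
    function never partially succeeds.
    """
    if not text.strip():
        raise PipelineParseError("empty pipeline", offset=0)
    tokens = _tokenize(text)
    if not tokens:
        raise PipelineParseError("empty pipeline", offset=0)

    background_final = False
    if tokens[-1][0] == "op" and tokens[-1][1] == "background":
        # a lone trailing '&' backgrounds the final command
        if len(tokens) >= 2 and tokens[-2][0] == "text":
            background_final = True
            tokens = tokens[:-1]

    nodes: list = []
    commands: list[GStringCommand] = []
    i = 0
    expect_command = True
    redirect_seen = False
    while i < len(tokens):
        kind, value, offset = tokens[i]
        if redirect_seen:
            raise PipelineParseError(
                "file redirect must be the last element", offset=offset
            )
        if expect_command:
            if kind != "text":
                if kind == "op" and nodes:
                    raise PipelineParseError(
                        "consecutive operators (empty command segment)",
                        offset=offset,
                    )
                if kind == "op":
                    raise PipelineParseError(
                        "pipeline begins with an operator", offset=offset
                    )
                raise PipelineParseError(
                    "empty command segment before redirect", offset=offset
                )
            cmd = GStringCommand(
                line=_segment_gstring(value, offset, scope, env_names, scope_ids)
            )
            nodes.append(cmd)
            commands.append(cmd)
            expect_command = False
        else:
            if kind == "op":
                nodes.append(Operator(value))
                expect_command = True
            elif kind == "redirect":
                if i + 1 >= len(tokens) or tokens[i + 1][0] != "text":
                    raise PipelineParseError(
                        "missing redirect target", offset=offset
                    )
                target_kind, target, target_offset = tokens[i + 1]
                nodes.append(
                    RedirectToFile(
                        target=_segment_gstring(
                            target, target_offset, scope, env_names, scope_ids
                        )
                    )
                )
                i += 1
                redirect_seen = True
            else:
                raise PipelineParseError(
                    "expected an operator between commands", offset=offset
                )
        i += 1
    if expect_command:
        last_op = tokens[-1]
        raise PipelineParseError(
            "pipeline ends with an operator", offset=last_op[2]
        )
    if background_final and commands:
        commands[-1].background = True
    return ExecuteCommand(nodes=nodes)


def render_pipeline(pipeline: ExecuteCommand) -> str:
    """Render an ExecuteCommand back to shell surface syntax.

    ``parse_pipeline(render_pipeline(p))`` is structurally equal to ``p``
    for every pipeline the parser can produce.
    """
    parts: list[str] = []
    background = False
    for node in pipeline.nodes:
        if isinstance(node, GStringCommand):
            parts.append(render_gstring(node.line))
            if node.background:
                background = True
        elif isinstance(node, Operator):
            parts.append(node.token)
        elif isinstance(node, RedirectToFile):
            parts.append("> " + render_gstring(node.target))
        else:
            raise ModelError(
                f"cannot render domain command {type(node).__name__}; "
                f"reduce the model first"
            )
    rendered = " ".join(parts)
    if background:
        rendered += " &"
    return rendered


def _declarations_in_scope(model: ScriptModel, stmt: Statement):
    """Names (with node ids) of declarations visible just before ``stmt``."""
    scope: dict[str, str] = {}
    container = model.find_statement_list(stmt)
    if container is not model.statements:
        # entry points run after the main statement list
        for s in model.statements:
            if isinstance(s, VariableDeclaration):
                scope[s.name] = s.node_id
    for s in container:
        if s is stmt:
            return scope
        if isinstance(s, VariableDeclaration):
            scope[s.name] = s.node_id
    return scope


def extract_variables(
    stmt: Statement, model: ScriptModel
) -> tuple[GString, list[VariableDeclaration]]:
    """Replace ``${name}`` markers in a pasted literal with variable refs.

    ``stmt`` must be a variable declaration whose initializer is still in
    raw literal form. Each distinct undeclared name gets one new (empty)
    declaration inserted immediately before ``stmt``, in first-occurrence
    order; names already in scope are referenced, not redeclared. On a parse
    error the model is left completely unchanged.
    """
    if not isinstance(stmt, VariableDeclaration):
        raise ModelError("extract_variables expects a variable declaration")
    if not stmt.initializer.is_literal_only():
        raise ModelError("initializer already contains non-literal components")
    container = model.find_statement_list(stmt)
    text = stmt.initializer.literal_text()
    scope_ids = _declarations_in_scope(model, stmt)

    # parse completely before touching the model (failure atomicity)
    parsed = parse_gstring(text, scope=scope_ids.keys(), scope_ids=scope_ids)

    new_decls: list[VariableDeclaration] = []
    created: dict[str, VariableDeclaration] = {}
    for comp in parsed.components:
        if isinstance(comp, VarRef) and comp.declaration_id is None:
            if comp.name not in created:
                decl = VariableDeclaration(
                    name=comp.name, initializer=GString.from_text("")
                )
                created[comp.name] = decl
                new_decls.append(decl)
            comp.declaration_id = created[comp.name].node_id

    index = next(i for i, s in enumerate(container) if s is stmt)
    container[index:index] = new_decls
    stmt.initializer = parsed
    return parsed, new_decls
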