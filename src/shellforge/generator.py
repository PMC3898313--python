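"""Generation: lower domain commands, render runnable programs, and build
phrase templates for configuration files.

Three facilities:

* :func:`reduce_model` — model-to-model lowering: plugin fetch/push commands
  become ordinary execute commands instantiating the descriptor's SDK
  command-line templates (``{slot}`` is the only substitution token). Pure
  core models pass through structurally unchanged; reduction is idempotent.
* :func:`render_program` — renders a reduced, check-clean model to a
  self-contained Python program plus a thin POSIX launcher. Rendering is
  byte-deterministic, and running the launcher reproduces the library
  executor's observable behaviour (stdout and exit code).
* :class:`PhraseTemplate` — mostly-unstructured text where only selected
  lines are split at a character delimiter into fixed text and named slots;
  rendering substitutes bindings and rejoins everything verbatim.
"""

from __future__ import annotations

import copy
import json
import os
import stat
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

from .errors import GenerationError, ReductionError, TemplateError
from .gstring import GString, Literal
from .model import (
    ExecuteStatement,
    FetchCommand,
    GStringCommand,
    PushCommand,
    ScriptModel,
    check_script,
    to_dict,
)
from .plugins import PluginDescriptor


# ---------------------------------------------------------------------------
# Reduction
# ---------------------------------------------------------------------------

def _domain_nodes(model: ScriptModel):
    for _, stmts in model.statement_lists():
        for stmt in stmts:
            if isinstance(stmt, ExecuteStatement):
                for node in stmt.pipeline.nodes:
                    if isinstance(node, (FetchCommand, PushCommand)):
                        yield stmt, node


def has_domain_commands(model: ScriptModel) -> bool:
    return next(_domain_nodes(model), None) is not None


def reduce_model(
    model: ScriptModel, descriptor: PluginDescriptor | None = None
) -> ScriptModel:
    """Lower every fetch/push command to a core execute command.

    Fetch commands must name a declared input slot, push commands a declared
    output slot; the descriptor's ``fetch``/``push`` SDK templates are
    instantiated with the slot name. Models without domain commands are
    returned as a structurally equal copy, so ``reduce(reduce(m))`` equals
    ``reduce(m)``.
    """
    reduced = copy.deepcopy(model)
    pending = list(_domain_nodes(reduced))
    if not pending:
        return reduced
    if descriptor is None:
        raise ReductionError(
            "model contains fetch/push commands but no plugin descriptor "
            "was supplied"
        )
    for stmt, node in pending:
        op = "fetch" if isinstance(node, FetchCommand) else "push"
        slots = (
            descriptor.input_slots if op == "fetch" else descriptor.output_slots
        )
        names = {name for name, _ in slots}
        if node.slot not in names:
            raise ReductionError(
                f"{op} command names unknown slot '{node.slot}' "
                f"(declared: {sorted(names)})"
            )
        template = descriptor.sdk_templates.get(op)
        if not template:
            raise ReductionError(
                f"plugin descriptor has no sdk template for '{op}'"
            )
        line = template.replace("{slot}", node.slot)
        replacement = GStringCommand(
            line=GString([Literal(line)]), node_id=node.node_id
        )
        index = next(
            i for i, n in enumerate(stmt.pipeline.nodes) if n is node
        )
        stmt.pipeline.nodes[index] = replacement
    return reduced


# ---------------------------------------------------------------------------
# Program rendering
# ---------------------------------------------------------------------------

_LAUNCHER = """#!/bin/sh
# thin launcher: runs the rendered program by relative path
exec python3 "$(dirname "$0")/program.py" "$@"
"""


def _runtime_source() -> str:
    return (
        resources.files("shellforge")
        .joinpath("_standalone_runtime.py")
        .read_text(encoding="utf-8")
    )


def render_program(core: ScriptModel, out_dir: str | os.PathLike) -> dict[str, str]:
    """Render ``core`` to ``<out_dir>/<name>/{program.py, launcher}``.

    ``core`` must already be reduced (no fetch/push commands) and free of
    checker errors. Output is byte-deterministic for equal input: the model
    is embedded in canonical JSON and the runtime text is fixed. Returns the
    paths of the two artifacts.
    """
    if has_domain_commands(core):
        raise GenerationError(
            "model still contains domain commands; run reduce_model first"
        )
    errors = [d for d in check_script(core) if d.severity == "error"]
    if errors:
        raise GenerationError(
            f"model has checker errors; first: {errors[0].code} "
            f"{errors[0].message}"
        )
    target = os.path.join(os.fspath(out_dir), core.name)
    try:
        os.makedirs(target, exist_ok=True)
    except OSError as exc:
        raise GenerationError(f"cannot create output directory: {exc}") from exc

    model_json = json.dumps(to_dict(core), indent=2, sort_keys=True)
    program = (
        "#!/usr/bin/env python3\n"
        f"# rendered from script model '{core.name}' — self-contained, "
        "no runtime library required\n\n"
        "import json as _json\n"
        f"MODEL = _json.loads({model_json!r})\n\n"
        f"{_runtime_source()}\n"
        'if __name__ == "__main__":\n'
        "    sys.exit(main(MODEL))\n"
    )
    program_path = os.path.join(target, "program.py")
    launcher_path = os.path.join(target, "launcher")
    try:
        with open(program_path, "w", encoding="utf-8") as fh:
            fh.write(program)
        with open(launcher_path, "w", encoding="utf-8") as fh:
            fh.write(_LAUNCHER)
    except OSError as exc:
        raise GenerationError(f"cannot write artifacts: {exc}") from exc
    mode = stat.S_IRWXU | stat.S_IRGRP | stat.S_IXGRP | stat.S_IROTH | stat.S_IXOTH
    os.chmod(launcher_path, mode)
    os.chmod(program_path, mode)
    return {"program": program_path, "launcher": launcher_path}


# ---------------------------------------------------------------------------
# Phrase templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Phrase:
    """A line split at a delimiter; segments are fixed text or named slots."""

    segments: tuple[tuple[str, str], ...]  # ("text"|"slot", value-or-name)
    delimiter: str


@dataclass
class PhraseTemplate:
    lines: list  # str (raw) | Phrase
    slot_names: tuple[str, ...] = field(default_factory=tuple)


def build_template(
    text: str,
    delimiter: str,
    phrase_lines: Mapping[int, Sequence[int]] | Sequence[int],
) -> PhraseTemplate:
    """Build a template from mostly-unstructured text.

    Only the designated lines are split at ``delimiter``. ``phrase_lines``
    maps a 0-based line index to the segment indexes that become slots; a
    plain sequence of line indexes designates *every* segment of those lines
    as a slot. A slot is named by its original (stripped) segment text; slot
    names must be unique in the template.
    """
    if len(delimiter) != 1:
        raise TemplateError("delimiter must be a single character")
    raw_lines = text.split("\n")
    if not isinstance(phrase_lines, Mapping):
        phrase_lines = {int(i): None for i in phrase_lines}
    for index in phrase_lines:
        if not 0 <= index < len(raw_lines):
            raise TemplateError(
                f"phrase line index {index} out of range (text has "
                f"{len(raw_lines)} lines)"
            )
    lines: list = []
    names: list[str] = []
    for i, raw in enumerate(raw_lines):
        if i not in phrase_lines:
            lines.append(raw)
            continue
        segments = raw.split(delimiter)
        slot_indexes = phrase_lines[i]
        chosen = (
            set(range(len(segments)))
            if slot_indexes is None
            else set(int(j) for j in slot_indexes)
        )
        out = []
        for j, seg in enumerate(segments):
            if j in chosen:
                name = seg.strip()
                if not name:
                    raise TemplateError(
                        f"empty slot name at line {i}, segment {j}"
                    )
                if name in names:
                    raise TemplateError(f"duplicate slot name '{name}'")
                names.append(name)
                out.append(("slot", name))
            else:
                out.append(("text", seg))
        lines.append(Phrase(tuple(out), delimiter))
    return PhraseTemplate(lines, tuple(names))


def render_template(t: PhraseTemplate, bindings: Mapping[str, str]) -> str:
    """Substitute slot bindings and rejoin with the original delimiters and
    newlines. With no phrase lines this is the identity on the input text."""
    rendered: list[str] = []
    for line in t.lines:
        if isinstance(line, str):
            rendered.append(line)
            continue
        parts = []
        for kind, value in line.segments:
            if kind == "text":
                parts.append(value)
            else:
                if value not in bindings:
                    raise TemplateError(f"no binding for slot '{value}'")
                parts.append(bindings[value])
        rendered.append(line.delimiter.join(parts))
    return "\n".join(rendered)
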