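"""Execution engine: run pipelines and whole scripts with shell-equivalent
operator semantics.

``|`` connects stdout to stdin of concurrently running commands; ``&&`` runs
its right side only when the left exited 0; ``||`` only when it exited
non-zero; ``;`` always; ``&`` launches the left side without waiting. A
trailing ``> file`` redirect overwrites the target with the final command's
stdout. The pipeline exit code is the last command's exit code (no pipefail
by default; a toggle is exposed).

Commands are launched directly (no shell). The evaluated command line is
split into words on unquoted whitespace; values produced by variable or
environment interpolation are never re-split — a deliberate, safer deviation
from the shell, documented in the methods note.
"""

from __future__ import annotations

import os
import subprocess
import tempfile
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .environment import EnvironmentSource, merged_mapping
from .errors import EvaluationError, ExecutionError
from .gstring import EnvRead, GString, Literal, VarRef, evaluate_gstring
from .model import (
    ExecuteCommand,
    ExecuteStatement,
    EnvAssignStatement,
    GStringCommand,
    LoadEnvironmentStatement,
    Operator,
    RedirectToFile,
    ScriptModel,
    VariableDeclaration,
    check_script,
    pipeline_diagnostics,
)


@dataclass
class CommandRecord:
    """One launched command: its evaluated text, exit code and stderr."""

    evaluated_text: str
    exit_code: int | None
    captured_stderr: str = ""
    background: bool = False


@dataclass
class ExecutionResult:
    exit_code: int
    records: list[CommandRecord] = field(default_factory=list)
    log_lines: list[str] = field(default_factory=list)
    stdout: str = ""


def split_words(
    g: GString, bindings: Mapping[str, str], env: Mapping[str, str]
) -> list[str]:
    """Split an evaluated command line into argv words.

    Literal text is split on unquoted whitespace; single- and double-quoted
    runs are kept together (quotes removed). Interpolated values join the
    current word verbatim, whatever characters they contain.
    """
    words: list[str] = []
    cur: list[str] = []
    has_word = False
    state = ""  # "", "'", '"'

    def flush() -> None:
        nonlocal cur, has_word
        if has_word:
            words.append("".join(cur))
        cur = []
        has_word = False

    for comp in g.components:
        if isinstance(comp, Literal):
            for ch in comp.text:
                if state:
                    if ch == state:
                        state = ""
                    else:
                        cur.append(ch)
                elif ch in "'\"":
                    state = ch
                    has_word = True
                elif ch.isspace():
                    flush()
                else:
                    cur.append(ch)
                    has_word = True
        else:
            if isinstance(comp, VarRef):
                if comp.name not in bindings:
                    raise EvaluationError(f"unbound variable {comp.name}")
                value = bindings[comp.name]
            elif isinstance(comp, EnvRead):
                if comp.name not in env:
                    raise EvaluationError(
                        f"unbound environment variable {comp.name}"
                    )
                value = env[comp.name]
            else:  # pragma: no cover
                raise TypeError(type(comp).__name__)
            cur.append(value)
            has_word = True
    if state:
        raise ExecutionError("unbalanced quote in evaluated command line")
    flush()
    return words


def _exit_status(returncode: int) -> int:
    # negative returncodes are deaths by signal; report 128+sig as a shell does
    return 128 - returncode if returncode < 0 else returncode


class _Group:
    """A maximal run of commands joined by pipes, plus how it is joined to
    the next group."""

    def __init__(self):
        self.commands: list[GStringCommand] = []
        self.connector: str | None = None  # operator after the group
        self.detached = False


def _split_groups(pipeline: ExecuteCommand):
    groups: list[_Group] = []
    cur = _Group()
    redirect: RedirectToFile | None = None
    for node in pipeline.nodes:
        if isinstance(node, GStringCommand):
            cur.commands.append(node)
            if node.background:
                cur.detached = True
        elif isinstance(node, Operator):
            if node.kind == "pipe":
                continue
            cur.connector = node.kind
            if node.kind == "background":
                cur.detached = True
            groups.append(cur)
            cur = _Group()
        elif isinstance(node, RedirectToFile):
            redirect = node
        else:
            raise ExecutionError(
                f"cannot execute domain command {type(node).__name__}; "
                f"reduce the model first"
            )
    if cur.commands:
        groups.append(cur)
    return groups, redirect


def run_pipeline(
    pipeline: ExecuteCommand,
    bindings: Mapping[str, str] | None = None,
    sources: Sequence[EnvironmentSource] = (),
    workdir: str | None = None,
    env: Mapping[str, str] | None = None,
    pipefail: bool = False,
) -> ExecutionResult:
    """Execute one pipeline and capture stdout, stderr and exit codes.

    ``env`` is the child-process environment (defaults to a copy of the
    ambient environment); variables from ``sources`` overlay it and also
    serve environment reads in the command GStrings. Evaluation errors abort
    before anything is launched; a command that cannot be found yields the
    conventional exit code 127.
    """
    bindings = dict(bindings or {})
    child_env = dict(os.environ if env is None else env)
    child_env.update(merged_mapping(sources))

    errors = [d for d in pipeline_diagnostics(pipeline) if d.severity == "error"]
    if errors:
        raise ExecutionError(f"pipeline is not executable: {errors[0].message}")

    groups, redirect = _split_groups(pipeline)

    # evaluate everything up front: an unbound reference launches nothing
    plan: list[list[tuple[str, list[str]]]] = []
    for group in groups:
        entries = []
        for cmd in group.commands:
            text = evaluate_gstring(cmd.line, bindings, child_env)
            words = split_words(cmd.line, bindings, child_env)
            if not words:
                raise ExecutionError(f"command evaluates to no words: {text!r}")
            entries.append((text, words))
        plan.append(entries)
    redirect_path = None
    if redirect is not None:
        redirect_path = evaluate_gstring(redirect.target, bindings, child_env)
        if not redirect_path:
            raise ExecutionError("redirect target evaluates to an empty path")
        if workdir is not None and not os.path.isabs(redirect_path):
            redirect_path = os.path.join(workdir, redirect_path)

    result = ExecutionResult(exit_code=0)
    pending: list[tuple[list, list[CommandRecord]]] = []  # detached groups
    last_exit = 0
    prev_connector: str | None = None

    for gi, group in enumerate(groups):
        run_this = True
        if prev_connector == "and":
            run_this = last_exit == 0
        elif prev_connector == "or":
            run_this = last_exit != 0
        prev_connector = group.connector
        if not run_this:
            continue

        is_last_group = gi == len(groups) - 1
        redirect_here = redirect_path if is_last_group else None

        procs = []  # (proc|None, record, stderr_file)
        records_here: list[CommandRecord] = []
        prev_stdout = None
        redirect_handle = None
        if redirect_here is not None:
            redirect_handle = open(redirect_here, "wb")
        try:
            for ci, (text, words) in enumerate(plan[gi]):
                last_cmd = ci == len(plan[gi]) - 1
                stdin = subprocess.DEVNULL if prev_stdout is None else prev_stdout
                if last_cmd and redirect_handle is not None:
                    stdout = redirect_handle
                else:
                    stdout = subprocess.PIPE
                stderr_file = tempfile.TemporaryFile()
                record = CommandRecord(text, None, background=group.detached)
                result.log_lines.append(f"run: {text}")
                try:
                    proc = subprocess.Popen(
                        words,
                        stdin=stdin,
                        stdout=stdout,
                        stderr=stderr_file,
                        env=child_env,
                        cwd=workdir,
                    )
                except FileNotFoundError:
                    proc = None
                    record.exit_code = 127
                    record.captured_stderr = f"{words[0]}: command not found"
                except PermissionError:
                    proc = None
                    record.exit_code = 126
                    record.captured_stderr = f"{words[0]}: permission denied"
                if prev_stdout is not None:
                    prev_stdout.close()
                prev_stdout = (
                    proc.stdout if (proc is not None and not last_cmd) else None
                )
                if proc is None and not last_cmd:
                    prev_stdout = None  # downstream reads empty input
                procs.append((proc, record, stderr_file))
                records_here.append(record)
        finally:
            result.records.extend(records_here)

        if group.detached:
            pending.append((procs, records_here))
            last_exit = 0  # backgrounding itself succeeds
            continue

        group_exit = _wait_group(procs, result, pipefail)
        if redirect_handle is not None:
            redirect_handle.close()
        last_exit = group_exit

    # reap detached groups so tests and callers see deterministic state
    for procs, _records in pending:
        _wait_group(procs, result, pipefail, collect_stdout=True)

    result.exit_code = last_exit
    result.log_lines.append(f"exit: {last_exit}")
    return result


def _wait_group(procs, result: ExecutionResult, pipefail: bool,
                collect_stdout: bool = True) -> int:
    # drain the final stdout before waiting on anything, otherwise a full
    # pipe buffer would deadlock the whole chain
    last_proc = procs[-1][0] if procs else None
    if last_proc is not None and last_proc.stdout is not None:
        out = last_proc.stdout.read()
        last_proc.stdout.close()
        if collect_stdout:
            result.stdout += out.decode("utf-8", "replace")
    exits: list[int] = []
    for proc, record, stderr_file in procs:
        if proc is not None:
            record.exit_code = _exit_status(proc.wait())
            stderr_file.seek(0)
            record.captured_stderr = stderr_file.read().decode("utf-8", "replace")
        stderr_file.close()
        exits.append(record.exit_code)
    if pipefail:
        failing = [e for e in exits if e != 0]
        return failing[-1] if failing else 0
    return exits[-1] if exits else 0


def run_script(
    model: ScriptModel,
    entry_point: str | None = None,
    sources: Sequence[EnvironmentSource] = (),
    workdir: str | None = None,
    base_env: Mapping[str, str] | None = None,
) -> ExecutionResult:
    """Run a script model (optionally one of its entry points).

    The main statement list always runs first; for plugin scripts the named
    entry point's statements follow it. Load-environment statements make
    their sources' variables resolvable (and exported to child processes)
    for all subsequent statements; environment assignments mutate the child
    environment the same way. The aggregate exit code is the last executed
    statement's.
    """
    errors = [d for d in check_script(model) if d.severity == "error"]
    if errors:
        raise ExecutionError(
            f"script has checker errors; first: {errors[0].code} "
            f"{errors[0].message}"
        )
    if entry_point is not None and entry_point not in model.entry_points:
        raise ExecutionError(f"unknown entry point '{entry_point}'")

    env = dict(os.environ if base_env is None else base_env)
    env.update(merged_mapping(sources))
    source_map = {s.id: s for s in model.sources}
    for s in sources:
        source_map.setdefault(s.id, s)

    bindings: dict[str, str] = {}
    result = ExecutionResult(exit_code=0)

    stmts = list(model.statements)
    if entry_point is not None:
        stmts += model.entry_points[entry_point]

    for stmt in stmts:
        if isinstance(stmt, VariableDeclaration):
            bindings[stmt.name] = evaluate_gstring(stmt.initializer, bindings, env)
        elif isinstance(stmt, LoadEnvironmentStatement):
            for ref in stmt.source_refs:
                source = source_map.get(ref)
                if source is None:
                    raise ExecutionError(f"unknown environment source '{ref}'")
                env.update(merged_mapping([source]))
                result.log_lines.append(f"load: {ref}")
        elif isinstance(stmt, EnvAssignStatement):
            name = evaluate_gstring(stmt.var_name, bindings, env)
            env[name] = evaluate_gstring(stmt.value, bindings, env)
            result.log_lines.append(f"setenv: {name}")
        elif isinstance(stmt, ExecuteStatement):
            sub = run_pipeline(
                stmt.pipeline, bindings, workdir=workdir, env=env
            )
            result.records.extend(sub.records)
            result.log_lines.extend(sub.log_lines)
            result.stdout += sub.stdout
            result.exit_code = sub.exit_code
        else:
            raise ExecutionError(f"cannot execute {type(stmt).__name__}")
    return result
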