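"""The script model: AST concepts, persistence, and the semantic checker.

A :class:`ScriptModel` is the tree a script is stored and manipulated as:
environment sources, an ordered statement list, and (for plugin scripts)
named entry points. Pipelines are :class:`ExecuteCommand` nodes holding an
alternating sequence of commands and binary operators with an optional
trailing file redirect — the same surface operators a shell user writes
(``| && || ; &``).

The checker (:func:`check_script`) reports, never repairs. Rule codes are
stable across releases:

========  ==========================================================
SF001     malformed pipeline alternation (consecutive, leading or
          terminal operators; adjacent commands; empty pipeline)
SF002     file redirect not in final position
SF003     reference to an undeclared (or later-declared) variable
SF010     environment read with no declaring source loaded
SF011     load statement references an unknown source id
SF020     plugin script contract violation (missing plugin binding,
          missing entry point, or binding/type mismatch)
========  ==========================================================
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Iterator

from ._ids import advance_past, new_id
from .contracts import PLAIN, PLUGIN_TYPES, SCRIPT_TYPES, load_entry_point_contract
from .environment import EnvironmentSource, EnvironmentVariable
from .errors import ModelError, ModelFormatError, ModelVersionError
from .gstring import EnvRead, GString, GStringComponent, Literal, VarRef, is_identifier

FORMAT_VERSION = 1

OPERATOR_KINDS = ("pipe", "and", "or", "seq", "background")
OPERATOR_TOKENS = {
    "pipe": "|",
    "and": "&&",
    "or": "||",
    "seq": ";",
    "background": "&",
}
TOKEN_OPERATORS = {v: k for k, v in OPERATOR_TOKENS.items()}


# ---------------------------------------------------------------------------
# AST concepts
# ---------------------------------------------------------------------------

@dataclass
class PluginBinding:
    plugin_id: str
    plugin_type: str
    config_path: str = ""
    node_id: str = field(default_factory=new_id, compare=False, kw_only=True)


@dataclass
class Statement:
    node_id: str = field(default_factory=new_id, compare=False, kw_only=True)


@dataclass
class VariableDeclaration(Statement):
    name: str = ""
    initializer: GString = field(default_factory=GString)


@dataclass
class ExecuteStatement(Statement):
    pipeline: "ExecuteCommand" = None  # type: ignore[assignment]


@dataclass
class LoadEnvironmentStatement(Statement):
    source_refs: list[str] = field(default_factory=list)


@dataclass
class EnvAssignStatement(Statement):
    var_name: GString = field(default_factory=GString)
    value: GString = field(default_factory=GString)


@dataclass
class CommandNode:
    node_id: str = field(default_factory=new_id, compare=False, kw_only=True)


@dataclass
class GStringCommand(CommandNode):
    line: GString = field(default_factory=GString)
    background: bool = False


@dataclass
class Operator(CommandNode):
    kind: str = "pipe"

    def __post_init__(self) -> None:
        if self.kind not in OPERATOR_KINDS:
            raise ModelError(f"unknown operator kind {self.kind!r}")

    @property
    def token(self) -> str:
        return OPERATOR_TOKENS[self.kind]


@dataclass
class RedirectToFile(CommandNode):
    target: GString = field(default_factory=GString)


@dataclass
class FetchCommand(CommandNode):
    """Domain command: fetch the files bound to a plugin input slot.

    Lowered by the generator to a core execute command; never run directly.
    """

    slot: str = ""


@dataclass
class PushCommand(CommandNode):
    """Domain command: push produced files to a plugin output slot."""

    slot: str = ""


@dataclass
class ExecuteCommand:
    nodes: list[CommandNode] = field(default_factory=list)
    node_id: str = field(default_factory=new_id, compare=False, kw_only=True)


@dataclass(frozen=True)
class Diagnostic:
    severity: str  # "error" | "warning"
    code: str
    node_id: str
    message: str

    def render(self, file: str = "<model>") -> str:
        return f"{file}:{self.node_id}: {self.code} {self.message}"


@dataclass
class ScriptModel:
    name: str
    script_type: str = PLAIN
    plugin_header: PluginBinding | None = None
    sources: list[EnvironmentSource] = field(default_factory=list)
    statements: list[Statement] = field(default_factory=list)
    entry_points: dict[str, list[Statement]] = field(default_factory=dict)
    format_version: int = FORMAT_VERSION
    node_id: str = field(default_factory=new_id, compare=False, kw_only=True)

    def statement_lists(self) -> Iterator[tuple[str | None, list[Statement]]]:
        """Main list first (labelled ``None``), then entry points in order."""
        yield None, self.statements
        for name, stmts in self.entry_points.items():
            yield name, stmts

    def find_statement_list(self, stmt: Statement) -> list[Statement]:
        for _, stmts in self.statement_lists():
            if any(s is stmt for s in stmts):
                return stmts
        raise ModelError(f"statement {stmt.node_id} not found in model")


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def new_script(name: str, script_type: str = PLAIN) -> ScriptModel:
    """Create an empty script model.

    Plain scripts start check-clean. Plugin script types get the empty
    entry-point skeleton of their contract; they stay incomplete (checker
    rule SF020) until a plugin binding is attached — use the scaffolder to
    get a check-clean plugin script in one step.
    """
    if not is_identifier(name):
        raise ModelError(f"invalid script name {name!r}: must be an identifier")
    if script_type not in SCRIPT_TYPES:
        raise ModelError(
            f"unknown script type {script_type!r}; expected one of {SCRIPT_TYPES}"
        )
    model = ScriptModel(name=name, script_type=script_type)
    if script_type in PLUGIN_TYPES:
        contract = load_entry_point_contract()
        model.entry_points = {ep: [] for ep in contract[script_type]}
    return model


# ---------------------------------------------------------------------------
# Persistence (versioned JSON, explicit node ids)
# ---------------------------------------------------------------------------

def _gstring_to_dict(g: GString) -> dict:
    comps = []
    for c in g.components:
        if isinstance(c, Literal):
            comps.append({"kind": "Literal", "id": c.node_id, "text": c.text})
        elif isinstance(c, VarRef):
            comps.append(
                {
                    "kind": "VarRef",
                    "id": c.node_id,
                    "name": c.name,
                    "declarationId": c.declaration_id,
                }
            )
        elif isinstance(c, EnvRead):
            comps.append({"kind": "EnvRead", "id": c.node_id, "name": c.name})
        else:
            raise ModelError(f"unknown GString component {type(c).__name__}")
    return {"kind": "GString", "id": g.node_id, "components": comps}


def _command_node_to_dict(node: CommandNode) -> dict:
    if isinstance(node, GStringCommand):
        return {
            "kind": "GStringCommand",
            "id": node.node_id,
            "line": _gstring_to_dict(node.line),
            "background": node.background,
        }
    if isinstance(node, Operator):
        return {"kind": "Operator", "id": node.node_id, "operator": node.kind}
    if isinstance(node, RedirectToFile):
        return {
            "kind": "RedirectToFile",
            "id": node.node_id,
            "target": _gstring_to_dict(node.target),
        }
    if isinstance(node, FetchCommand):
        return {"kind": "FetchCommand", "id": node.node_id, "slot": node.slot}
    if isinstance(node, PushCommand):
        return {"kind": "PushCommand", "id": node.node_id, "slot": node.slot}
    raise ModelError(f"unknown command node {type(node).__name__}")


def _statement_to_dict(stmt: Statement) -> dict:
    if isinstance(stmt, VariableDeclaration):
        return {
            "kind": "VariableDeclaration",
            "id": stmt.node_id,
            "name": stmt.name,
            "initializer": _gstring_to_dict(stmt.initializer),
        }
    if isinstance(stmt, ExecuteStatement):
        return {
            "kind": "ExecuteStatement",
            "id": stmt.node_id,
            "pipeline": {
                "kind": "ExecuteCommand",
                "id": stmt.pipeline.node_id,
                "nodes": [_command_node_to_dict(n) for n in stmt.pipeline.nodes],
            },
        }
    if isinstance(stmt, LoadEnvironmentStatement):
        return {
            "kind": "LoadEnvironmentStatement",
            "id": stmt.node_id,
            "sourceRefs": list(stmt.source_refs),
        }
    if isinstance(stmt, EnvAssignStatement):
        return {
            "kind": "EnvAssignStatement",
            "id": stmt.node_id,
            "varName": _gstring_to_dict(stmt.var_name),
            "value": _gstring_to_dict(stmt.value),
        }
    raise ModelError(f"unknown statement {type(stmt).__name__}")


def _source_to_dict(source: EnvironmentSource) -> dict:
    return {
        "id": source.id,
        "kind": source.kind,
        "params": dict(source.params),
        "variables": [{"name": v.name, "value": v.value} for v in source.variables],
    }


def to_dict(model: ScriptModel) -> dict:
    """Serializable form of a model; also the canonical structure for
    fingerprinting and byte-deterministic rendering."""
    return {
        "formatVersion": model.format_version,
        "kind": "ScriptModel",
        "id": model.node_id,
        "name": model.name,
        "scriptType": model.script_type,
        "pluginHeader": (
            None
            if model.plugin_header is None
            else {
                "id": model.plugin_header.node_id,
                "pluginId": model.plugin_header.plugin_id,
                "pluginType": model.plugin_header.plugin_type,
                "configPath": model.plugin_header.config_path,
            }
        ),
        "sources": [_source_to_dict(s) for s in model.sources],
        "statements": [_statement_to_dict(s) for s in model.statements],
        "entryPoints": {
            name: [_statement_to_dict(s) for s in stmts]
            for name, stmts in model.entry_points.items()
        },
    }


def model_fingerprint(model: ScriptModel) -> str:
    """SHA-256 of the canonical serialized form, node ids included.

    Two calls return the same digest iff the model (including ids) is
    unchanged — used to assert failure atomicity of micro-parse operations.
    """
    blob = json.dumps(to_dict(model), sort_keys=True).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()


class _Reader:
    """Strict deserializer: any malformed node raises ModelFormatError
    naming the offending node; nothing partial escapes."""

    def _require(self, d: dict, key: str, where: str):
        if not isinstance(d, dict) or key not in d:
            raise ModelFormatError(f"malformed node in {where}: missing {key!r}")
        return d[key]

    def gstring(self, d: dict) -> GString:
        kind = self._require(d, "kind", "GString")
        if kind != "GString":
            raise ModelFormatError(f"expected GString node, got {kind!r}")
        comps: list[GStringComponent] = []
        for cd in self._require(d, "components", d.get("id", "?")):
            ckind = self._require(cd, "kind", "GString component")
            cid = self._require(cd, "id", ckind)
            if ckind == "Literal":
                comps.append(Literal(self._require(cd, "text", cid), node_id=cid))
            elif ckind == "VarRef":
                comps.append(
                    VarRef(
                        self._require(cd, "name", cid),
                        cd.get("declarationId"),
                        node_id=cid,
                    )
                )
            elif ckind == "EnvRead":
                comps.append(EnvRead(self._require(cd, "name", cid), node_id=cid))
            else:
                raise ModelFormatError(f"unknown component kind {ckind!r} at {cid}")
        return GString(comps, node_id=self._require(d, "id", "GString"))

    def command_node(self, d: dict) -> CommandNode:
        kind = self._require(d, "kind", "command node")
        cid = self._require(d, "id", kind)
        if kind == "GStringCommand":
            return GStringCommand(
                line=self.gstring(self._require(d, "line", cid)),
                background=bool(d.get("background", False)),
                node_id=cid,
            )
        if kind == "Operator":
            op = self._require(d, "operator", cid)
            if op not in OPERATOR_KINDS:
                raise ModelFormatError(f"unknown operator {op!r} at {cid}")
            return Operator(op, node_id=cid)
        if kind == "RedirectToFile":
            return RedirectToFile(
                target=self.gstring(self._require(d, "target", cid)), node_id=cid
            )
        if kind == "FetchCommand":
            return FetchCommand(self._require(d, "slot", cid), node_id=cid)
        if kind == "PushCommand":
            return PushCommand(self._require(d, "slot", cid), node_id=cid)
        raise ModelFormatError(f"unknown command node kind {kind!r} at {cid}")

    def statement(self, d: dict) -> Statement:
        kind = self._require(d, "kind", "statement")
        sid = self._require(d, "id", kind)
        if kind == "VariableDeclaration":
            return VariableDeclaration(
                name=self._require(d, "name", sid),
                initializer=self.gstring(self._require(d, "initializer", sid)),
                node_id=sid,
            )
        if kind == "ExecuteStatement":
            pd = self._require(d, "pipeline", sid)
            pipeline = ExecuteCommand(
                nodes=[self.command_node(n) for n in self._require(pd, "nodes", sid)],
                node_id=self._require(pd, "id", sid),
            )
            return ExecuteStatement(pipeline=pipeline, node_id=sid)
        if kind == "LoadEnvironmentStatement":
            return LoadEnvironmentStatement(
                source_refs=[str(r) for r in self._require(d, "sourceRefs", sid)],
                node_id=sid,
            )
        if kind == "EnvAssignStatement":
            return EnvAssignStatement(
                var_name=self.gstring(self._require(d, "varName", sid)),
                value=self.gstring(self._require(d, "value", sid)),
                node_id=sid,
            )
        raise ModelFormatError(f"unknown statement kind {kind!r} at {sid}")

    def source(self, d: dict) -> EnvironmentSource:
        sid = self._require(d, "id", "source")
        variables = tuple(
            EnvironmentVariable(
                self._require(v, "name", sid), self._require(v, "value", sid), sid
            )
            for v in self._require(d, "variables", sid)
        )
        return EnvironmentSource(
            id=sid,
            kind=self._require(d, "kind", sid),
            params=dict(self._require(d, "params", sid)),
            variables=variables,
        )


def from_dict(data: dict) -> ScriptModel:
    if not isinstance(data, dict):
        raise ModelFormatError("model file does not contain an object")
    version = data.get("formatVersion")
    if not isinstance(version, int) or version < 1:
        raise ModelFormatError(f"missing or invalid formatVersion: {version!r}")
    if version > FORMAT_VERSION:
        raise ModelVersionError(
            f"model formatVersion {version} is newer than supported "
            f"version {FORMAT_VERSION}"
        )
    reader = _Reader()
    header = data.get("pluginHeader")
    binding = None
    if header is not None:
        binding = PluginBinding(
            plugin_id=reader._require(header, "pluginId", "pluginHeader"),
            plugin_type=reader._require(header, "pluginType", "pluginHeader"),
            config_path=header.get("configPath", ""),
            node_id=reader._require(header, "id", "pluginHeader"),
        )
    name = data.get("name")
    if not isinstance(name, str) or not name:
        raise ModelFormatError("model has no name")
    script_type = data.get("scriptType")
    if script_type not in SCRIPT_TYPES:
        raise ModelFormatError(f"unknown scriptType {script_type!r}")
    model = ScriptModel(
        name=name,
        script_type=script_type,
        plugin_header=binding,
        sources=[reader.source(s) for s in data.get("sources", [])],
        statements=[reader.statement(s) for s in data.get("statements", [])],
        entry_points={
            ep: [reader.statement(s) for s in stmts]
            for ep, stmts in data.get("entryPoints", {}).items()
        },
        format_version=version,
        node_id=reader._require(data, "id", "model"),
    )
    advance_past(nid for nid, _ in iter_nodes(model))
    return model


def save_script(model: ScriptModel, path: str | os.PathLike) -> None:
    """Persist a model as a versioned JSON document (one file per script)."""
    blob = json.dumps(to_dict(model), indent=2, sort_keys=False)
    tmp = os.fspath(path) + ".tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        fh.write(blob + "\n")
    os.replace(tmp, path)


def load_script(path: str | os.PathLike) -> ScriptModel:
    """Load a persisted model; ``load(save(m))`` equals ``m`` including ids.

    A truncated or malformed file raises :class:`ModelFormatError` without
    returning a partial model; a future formatVersion raises
    :class:`ModelVersionError`.
    """
    try:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    except OSError as exc:
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"malformed model file {path}: {exc}") from exc
    return from_dict(data)


# ---------------------------------------------------------------------------
# Node traversal
# ---------------------------------------------------------------------------

def _iter_gstring(g: GString):
    yield g.node_id, g
    for c in g.components:
        yield c.node_id, c


def _iter_statement(stmt: Statement):
    yield stmt.node_id, stmt
    if isinstance(stmt, VariableDeclaration):
        yield from _iter_gstring(stmt.initializer)
    elif isinstance(stmt, ExecuteStatement):
        yield stmt.pipeline.node_id, stmt.pipeline
        for node in stmt.pipeline.nodes:
            yield node.node_id, node
            if isinstance(node, GStringCommand):
                yield from _iter_gstring(node.line)
            elif isinstance(node, RedirectToFile):
                yield from _iter_gstring(node.target)
    elif isinstance(stmt, EnvAssignStatement):
        yield from _iter_gstring(stmt.var_name)
        yield from _iter_gstring(stmt.value)


def iter_nodes(model: ScriptModel):
    """Pre-order traversal yielding ``(node_id, node)`` pairs."""
    yield model.node_id, model
    if model.plugin_header is not None:
        yield model.plugin_header.node_id, model.plugin_header
    for _, stmts in model.statement_lists():
        for stmt in stmts:
            yield from _iter_statement(stmt)


# ---------------------------------------------------------------------------
# Semantic checker
# ---------------------------------------------------------------------------

def _check_pipeline(
    pipeline: ExecuteCommand,
    positions: dict[str, int],
    findings: list[Diagnostic],
) -> None:
    nodes = pipeline.nodes
    if not nodes:
        findings.append(
            Diagnostic("error", "SF001", pipeline.node_id, "empty pipeline")
        )
        return
    for idx, node in enumerate(nodes):
        if isinstance(node, RedirectToFile) and idx != len(nodes) - 1:
            findings.append(
                Diagnostic(
                    "error",
                    "SF002",
                    node.node_id,
                    "file redirect must be the final element of the pipeline",
                )
            )
    body = [n for n in nodes if not isinstance(n, RedirectToFile)]
    prev: CommandNode | None = None
    for node in body:
        if isinstance(node, Operator):
            if prev is None:
                findings.append(
                    Diagnostic(
                        "error",
                        "SF001",
                        node.node_id,
                        f"pipeline begins with operator '{node.token}'",
                    )
                )
            elif isinstance(prev, Operator):
                findings.append(
                    Diagnostic(
                        "error",
                        "SF001",
                        node.node_id,
                        f"consecutive operators '{prev.token}' '{node.token}'",
                    )
                )
        else:
            if prev is not None and not isinstance(prev, Operator):
                findings.append(
                    Diagnostic(
                        "error",
                        "SF001",
                        node.node_id,
                        "missing operator between commands",
                    )
                )
        prev = node
    if isinstance(prev, Operator):
        findings.append(
            Diagnostic(
                "error",
                "SF001",
                prev.node_id,
                f"pipeline ends with operator '{prev.token}'",
            )
        )


def pipeline_diagnostics(pipeline: ExecuteCommand) -> list[Diagnostic]:
    """Structural findings (SF001/SF002) for a single pipeline node."""
    findings: list[Diagnostic] = []
    _check_pipeline(pipeline, {}, findings)
    return findings


def _check_gstring(
    g: GString,
    declared: dict[str, str],
    env_names: set[str],
    findings: list[Diagnostic],
) -> None:
    for comp in g.components:
        if isinstance(comp, VarRef):
            if comp.name not in declared:
                findings.append(
                    Diagnostic(
                        "error",
                        "SF003",
                        comp.node_id,
                        f"reference to undeclared variable '{comp.name}'",
                    )
                )
        elif isinstance(comp, EnvRead):
            if comp.name not in env_names:
                findings.append(
                    Diagnostic(
                        "error",
                        "SF010",
                        comp.node_id,
                        f"environment variable '{comp.name}' is read but no "
                        f"loaded source declares it",
                    )
                )


def check_script(
    model: ScriptModel, contract_path: str | None = None
) -> list[Diagnostic]:
    """Run every checking rule over the model and return all findings.

    Pure: the model is not modified and repeated calls return identical
    results. Findings are ordered by node position (pre-order traversal),
    ties broken by code. An empty list means the script is clean.
    """
    positions = {nid: i for i, (nid, _) in enumerate(iter_nodes(model))}
    findings: list[Diagnostic] = []
    source_ids = {s.id for s in model.sources}
    sources_by_id = {s.id: s for s in model.sources}

    # SF020 — plugin contract
    if model.script_type in PLUGIN_TYPES:
        contract = load_entry_point_contract(contract_path)
        if model.plugin_header is None:
            findings.append(
                Diagnostic(
                    "error",
                    "SF020",
                    model.node_id,
                    f"plugin script of type '{model.script_type}' has no "
                    f"plugin binding",
                )
            )
        elif model.plugin_header.plugin_type != model.script_type:
            findings.append(
                Diagnostic(
                    "error",
                    "SF020",
                    model.plugin_header.node_id,
                    f"plugin binding type '{model.plugin_header.plugin_type}' "
                    f"does not match script type '{model.script_type}'",
                )
            )
        for entry in contract[model.script_type]:
            if entry not in model.entry_points:
                findings.append(
                    Diagnostic(
                        "error",
                        "SF020",
                        model.node_id,
                        f"missing entry point '{entry}' required by plugin "
                        f"type '{model.script_type}'",
                    )
                )
    elif model.plugin_header is not None:
        findings.append(
            Diagnostic(
                "warning",
                "SF020",
                model.plugin_header.node_id,
                "plain script carries a plugin binding",
            )
        )

    def walk(stmts: list[Statement], declared: dict[str, str], env_names: set[str]):
        for stmt in stmts:
            if isinstance(stmt, VariableDeclaration):
                _check_gstring(stmt.initializer, declared, env_names, findings)
                declared[stmt.name] = stmt.node_id
            elif isinstance(stmt, ExecuteStatement):
                _check_pipeline(stmt.pipeline, positions, findings)
                for node in stmt.pipeline.nodes:
                    if isinstance(node, GStringCommand):
                        _check_gstring(node.line, declared, env_names, findings)
                    elif isinstance(node, RedirectToFile):
                        _check_gstring(node.target, declared, env_names, findings)
            elif isinstance(stmt, LoadEnvironmentStatement):
                for ref in stmt.source_refs:
                    if ref not in source_ids:
                        findings.append(
                            Diagnostic(
                                "error",
                                "SF011",
                                stmt.node_id,
                                f"load statement references unknown source "
                                f"'{ref}'",
                            )
                        )
                    else:
                        env_names |= sources_by_id[ref].addressable_names()
            elif isinstance(stmt, EnvAssignStatement):
                _check_gstring(stmt.var_name, declared, env_names, findings)
                _check_gstring(stmt.value, declared, env_names, findings)

    declared: dict[str, str] = {}
    env_names: set[str] = set()
    walk(model.statements, declared, env_names)
    # entry points see the state established by the main statement list
    for _, stmts in model.entry_points.items():
        walk(stmts, dict(declared), set(env_names))

    findings.sort(key=lambda d: (positions.get(d.node_id, -1), d.code, d.message))
    return findings
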