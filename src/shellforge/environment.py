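"""Environment sources: discoverable, reloadable origins of variables.

A source is a snapshot of configuration taken from one of three origins —
the ambient process environment, a ``KEY=VALUE`` file, or a plugin
descriptor. Scripts declare which sources they use; loading a source makes
its variables readable from GStrings as ``${NAME}``. Sources can be reloaded
to pick up changes in the underlying origin without changing their identity.

File dialect: one ``KEY=VALUE`` per line, ``#`` comments and blank lines
ignored, the last duplicate of a key wins, values are taken verbatim after
the first ``=`` (no quote expansion), UTF-8.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .errors import EnvFileParseError, ResolutionError, ShellforgeError
from .gstring import is_identifier


@dataclass(frozen=True)
class EnvironmentVariable:
    name: str
    value: str
    source_ref: str

    @property
    def addressable(self) -> bool:
        """Only identifier-shaped names can be read from a GString."""
        return is_identifier(self.name)


@dataclass(frozen=True)
class EnvironmentSource:
    id: str
    kind: str  # one of {"process", "file", "plugin-config"}
    params: dict = field(default_factory=dict)
    variables: tuple[EnvironmentVariable, ...] = ()

    def get(self, name: str) -> str | None:
        """Value of ``name`` in this source (last declaration wins)."""
        value = None
        for var in self.variables:
            if var.name == name:
                value = var.value
        return value

    def addressable_names(self) -> set[str]:
        return {v.name for v in self.variables if v.addressable}


def _make_vars(source_id: str, pairs: Iterable[tuple[str, str]]):
    # last duplicate wins, order preserved by name of final occurrence
    merged: dict[str, str] = {}
    for key, value in pairs:
        merged[key] = value
    return tuple(
        EnvironmentVariable(k, v, source_id) for k, v in merged.items()
    )


def load_process_source() -> EnvironmentSource:
    """Snapshot the ambient process environment.

    Non-identifier names (e.g. containing dots) are stored but are not
    addressable from GStrings.
    """
    source_id = "process"
    pairs = sorted(os.environ.items())
    return EnvironmentSource(
        id=source_id,
        kind="process",
        params={},
        variables=_make_vars(source_id, pairs),
    )


def parse_env_file_text(text: str, source_id: str):
    pairs: list[tuple[str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise EnvFileParseError(f"expected KEY=VALUE, got {raw!r}", lineno)
        key, _, value = line.partition("=")
        key = key.strip()
        if not key:
            raise EnvFileParseError("empty key", lineno)
        pairs.append((key, value.strip()))
    return _make_vars(source_id, pairs)


def load_file_source(path: str | os.PathLike) -> EnvironmentSource:
    """Load a ``KEY=VALUE`` environment-definition file."""
    path = os.fspath(path)
    source_id = f"file:{path}"
    try:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    except OSError as exc:
        raise ShellforgeError(f"cannot read environment file {path}: {exc}") from exc
    return EnvironmentSource(
        id=source_id,
        kind="file",
        params={"path": path},
        variables=parse_env_file_text(text, source_id),
    )


def reload_source(source: EnvironmentSource) -> EnvironmentSource:
    """Re-read a source from its origin, keeping its id.

    Returns a new source; on failure (e.g. the backing file was deleted) the
    caller's source is untouched and still usable. Idempotent when the origin
    has not changed.
    """
    if source.kind == "process":
        fresh = load_process_source()
        return replace(fresh, id=source.id)
    if source.kind == "file":
        fresh = load_file_source(source.params["path"])
        return replace(fresh, id=source.id)
    if source.kind == "plugin-config":
        from .plugins import load_plugin_config, plugin_environment_source

        descriptor = load_plugin_config(source.params["path"])
        fresh = plugin_environment_source(descriptor)
        return replace(fresh, id=source.id)
    raise ShellforgeError(f"unknown source kind {source.kind!r}")


def resolve_variable(name: str, sources: Sequence[EnvironmentSource]) -> str:
    """Resolve ``name`` scanning sources last-to-first (later source wins).

    Only addressable (identifier-shaped) names resolve; anything else raises
    :class:`ResolutionError` — the runtime twin of checker rule SF010.
    """
    if is_identifier(name):
        for source in reversed(sources):
            for var in reversed(source.variables):
                if var.name == name and var.addressable:
                    return var.value
    raise ResolutionError(f"variable {name!r} is not declared by any source")


def available_names(sources: Sequence[EnvironmentSource]) -> list[str]:
    """Sorted union of all addressable names across ``sources``."""
    names: set[str] = set()
    for source in sources:
        names |= source.addressable_names()
    return sorted(names)


def merged_mapping(sources: Sequence[EnvironmentSource]) -> dict[str, str]:
    """Addressable name→value mapping with later sources overriding earlier."""
    out: dict[str, str] = {}
    for source in sources:
        for var in source.variables:
            if var.addressable:
                out[var.name] = var.value
    return out
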