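"""Plugin contract: descriptors, scaffolds and environment injection.

An analysis-grid plugin is described by an XML descriptor (schema shipped in
``data/plugin.xsd``): its identity, one of five plugin types (``aligner``,
``alignment-analysis``, ``resource``, ``artifact-install``, ``task``), its
named input/output slots (the files a plugin consumes and produces),
environment entries injected into plugin scripts, and the SDK command-line
templates that fetch/push slot contents. The descriptor format is a
repo-defined stand-in, not a claim about any deployed grid's real schema.

:func:`scaffold_script` produces a check-clean plugin script skeleton: the
plugin binding filled in, the type's entry points created empty, and a
load-environment statement wiring in the plugin's variables.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

from lxml import etree

from .contracts import PLUGIN_TYPES, load_entry_point_contract
from .environment import EnvironmentSource, EnvironmentVariable
from .errors import PluginConfigError
from .model import (
    LoadEnvironmentStatement,
    PluginBinding,
    ScriptModel,
    check_script,
)


@dataclass
class PluginDescriptor:
    plugin_id: str
    plugin_type: str
    input_slots: list[tuple[str, str]] = field(default_factory=list)
    output_slots: list[tuple[str, str]] = field(default_factory=list)
    env_entries: list[tuple[str, str]] = field(default_factory=list)
    sdk_templates: dict[str, str] = field(default_factory=dict)
    error_management: str | None = None
    config_path: str = ""

    def __post_init__(self) -> None:
        if not self.plugin_id:
            raise PluginConfigError("plugin descriptor has no id")
        if self.plugin_type not in PLUGIN_TYPES:
            raise PluginConfigError(
                f"unknown plugin type {self.plugin_type!r}; expected one of "
                f"{PLUGIN_TYPES}"
            )
        seen: set[str] = set()
        for name, _ in self.input_slots + self.output_slots:
            if name in seen:
                raise PluginConfigError(f"duplicate slot name {name!r}")
            seen.add(name)
        for key in self.sdk_templates:
            if key not in ("fetch", "push"):
                raise PluginConfigError(f"unknown sdk template {key!r}")


def schema_path() -> str:
    from importlib import resources

    return str(resources.files("shellforge").joinpath("data/plugin.xsd"))


def load_plugin_config(path: str | os.PathLike) -> PluginDescriptor:
    """Parse and validate a plugin descriptor XML file.

    Validation errors name the offending element or attribute.
    """
    path = os.fspath(path)
    try:
        tree = etree.parse(path)
    except OSError as exc:
        raise PluginConfigError(f"cannot read plugin config {path}: {exc}") from exc
    except etree.XMLSyntaxError as exc:
        raise PluginConfigError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "plugin":
        raise PluginConfigError(f"root element must be <plugin>, got <{root.tag}>")
    plugin_id = root.get("id")
    if not plugin_id:
        raise PluginConfigError("<plugin> is missing the required 'id' attribute")
    plugin_type = root.get("type")
    if plugin_type not in PLUGIN_TYPES:
        raise PluginConfigError(
            f"<plugin type={plugin_type!r}> is not one of {PLUGIN_TYPES}"
        )

    def slots(direction: str) -> list[tuple[str, str]]:
        out = []
        for el in root.findall(f"slots/{direction}"):
            name = el.get("name")
            if not name:
                raise PluginConfigError(
                    f"<{direction}> slot is missing the 'name' attribute"
                )
            out.append((name, el.get("fileType", "")))
        return out

    env_entries = []
    for el in root.findall("env/entry"):
        name, value = el.get("name"), el.get("value")
        if name is None or value is None:
            raise PluginConfigError("<entry> requires 'name' and 'value'")
        env_entries.append((name, value))

    sdk_templates = {}
    for key in ("fetch", "push"):
        el = root.find(f"sdk/{key}")
        if el is not None and el.text and el.text.strip():
            sdk_templates[key] = el.text.strip()

    err = root.find("errorManagement")
    return PluginDescriptor(
        plugin_id=plugin_id,
        plugin_type=plugin_type,
        input_slots=slots("input"),
        output_slots=slots("output"),
        env_entries=env_entries,
        sdk_templates=sdk_templates,
        error_management=err.get("policy") if err is not None else None,
        config_path=path,
    )


def plugin_environment_source(descriptor: PluginDescriptor) -> EnvironmentSource:
    """Expose a descriptor's environment entries as an environment source."""
    source_id = f"plugin:{descriptor.plugin_id}"
    return EnvironmentSource(
        id=source_id,
        kind="plugin-config",
        params={"path": descriptor.config_path},
        variables=tuple(
            EnvironmentVariable(name, value, source_id)
            for name, value in descriptor.env_entries
        ),
    )


def slot_names(descriptor: PluginDescriptor, direction: str) -> list[str]:
    """Sorted slot names for ``direction`` ('input' or 'output')."""
    if direction == "input":
        return sorted(name for name, _ in descriptor.input_slots)
    if direction == "output":
        return sorted(name for name, _ in descriptor.output_slots)
    raise PluginConfigError(f"direction must be 'input' or 'output', got {direction!r}")


def _script_name(plugin_id: str) -> str:
    name = re.sub(r"[^A-Za-z0-9_]", "_", plugin_id)
    if not name or name[0].isdigit():
        name = "_" + name
    return name


def scaffold_script(
    plugin_type: str,
    descriptor: PluginDescriptor,
    contract_path: str | None = None,
) -> ScriptModel:
    """Create the skeleton script for a plugin: binding, empty entry points
    of the type's contract, and a pre-inserted load of the plugin source.

    The scaffold passes the checker with zero errors.
    """
    if plugin_type not in PLUGIN_TYPES:
        raise PluginConfigError(f"unknown plugin type {plugin_type!r}")
    if plugin_type != descriptor.plugin_type:
        raise PluginConfigError(
            f"requested type '{plugin_type}' does not match descriptor type "
            f"'{descriptor.plugin_type}'"
        )
    contract = load_entry_point_contract(contract_path)
    source = plugin_environment_source(descriptor)
    model = ScriptModel(
        name=_script_name(descriptor.plugin_id),
        script_type=plugin_type,
        plugin_header=PluginBinding(
            plugin_id=descriptor.plugin_id,
            plugin_type=plugin_type,
            config_path=descriptor.config_path,
        ),
        sources=[source],
        statements=[LoadEnvironmentStatement(source_refs=[source.id])],
        entry_points={ep: [] for ep in contract[plugin_type]},
    )
    errors = [d for d in check_script(model, contract_path) if d.severity == "error"]
    if errors:  # pragma: no cover - scaffold contract
        raise PluginConfigError(f"scaffold is not check-clean: {errors[0]}")
    return model
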