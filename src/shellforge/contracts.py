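"""Script-type inventory and the entry-point contract.

A script is either ``plain`` (a free-standing script whose statements run
top to bottom) or one of five plugin types understood by the analysis-grid
plugin system: ``aligner``, ``alignment-analysis``, ``resource``,
``artifact-install`` and ``task``. Plugin scripts expose named entry points
(hooks) the grid runner calls; the hook set per type lives in a shipped
contract file users may override.
"""

from __future__ import annotations

import functools
from importlib import resources

import yaml

from .errors import ShellforgeError

PLAIN = "plain"
PLUGIN_TYPES: tuple[str, ...] = (
    "aligner",
    "alignment-analysis",
    "resource",
    "artifact-install",
    "task",
)
SCRIPT_TYPES: tuple[str, ...] = (PLAIN,) + PLUGIN_TYPES


@functools.lru_cache(maxsize=8)
def load_entry_point_contract(path: str | None = None) -> dict[str, tuple[str, ...]]:
    """Entry-point names required per plugin type.

    Reads the shipped contract file by default; ``path`` overrides it.
    """
    if path is None:
        text = (
            resources.files("shellforge").joinpath("data/entry_points.yaml").read_text()
        )
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ShellforgeError("entry-point contract file must map type -> names")
    contract: dict[str, tuple[str, ...]] = {}
    for script_type, names in raw.items():
        if script_type not in PLUGIN_TYPES:
            raise ShellforgeError(
                f"unknown plugin type {script_type!r} in entry-point contract"
            )
        contract[script_type] = tuple(str(n) for n in names)
    missing = set(PLUGIN_TYPES) - set(contract)
    if missing:
        raise ShellforgeError(
            f"entry-point contract missing types: {sorted(missing)}"
        )
    return contract
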