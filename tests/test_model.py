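"""Script-model construction, persistence round-trips and checker rules."""

import json
import random

import pytest

from shellforge import (
    EnvRead,
    ExecuteCommand,
    ExecuteStatement,
    GString,
    GStringCommand,
    Literal,
    LoadEnvironmentStatement,
    ModelError,
    ModelFormatError,
    ModelVersionError,
    Operator,
    PluginBinding,
    RedirectToFile,
    VarRef,
    VariableDeclaration,
    check_script,
    load_script,
    model_fingerprint,
    new_script,
    save_script,
)
from shellforge.corpus import random_script_model
from shellforge.environment import EnvironmentSource, EnvironmentVariable
from shellforge.model import iter_nodes, to_dict


def _cmd(text: str) -> GStringCommand:
    return GStringCommand(line=GString([Literal(text)]))


class TestNewScript:
    def test_plain_script_is_empty_and_clean(self):
        model = new_script("demo", "plain")
        assert model.statements == [] and check_script(model) == []

    def test_aligner_gets_entry_point_skeleton(self):
        model = new_script("demo", "aligner")
        assert set(model.entry_points) == {"setup", "align", "teardown"}
        assert all(stmts == [] for stmts in model.entry_points.values())

    def test_invalid_identifier_rejected(self):
        with pytest.raises(ModelError, match="identifier"):
            new_script("1bad", "plain")

    def test_unknown_script_type_rejected(self):
        with pytest.raises(ModelError, match="script type"):
            new_script("demo", "mapper")


class TestPersistence:
    def test_round_trip_preserves_structure_and_node_ids(self, tmp_path):
        rng = random.Random(7)
        model = random_script_model(rng)
        path = tmp_path / "m.script.json"
        save_script(model, path)
        loaded = load_script(path)
        assert to_dict(loaded) == to_dict(model)  # includes node ids

    def test_future_format_version_rejected(self, tmp_path):
        path = tmp_path / "m.script.json"
        save_script(new_script("demo"), path)
        data = json.loads(path.read_text())
        data["formatVersion"] = 999
        path.write_text(json.dumps(data))
        with pytest.raises(ModelVersionError):
            load_script(path)

    def test_truncated_file_yields_parse_error_not_partial_model(self, tmp_path):
        path = tmp_path / "m.script.json"
        save_script(new_script("demo"), path)
        path.write_text(path.read_text()[: len(path.read_text()) // 2])
        with pytest.raises(ModelFormatError):
            load_script(path)

    def test_unknown_node_kind_names_offender(self, tmp_path):
        path = tmp_path / "m.script.json"
        model = new_script("demo")
        model.statements.append(VariableDeclaration(name="a"))
        save_script(model, path)
        data = json.loads(path.read_text())
        data["statements"][0]["kind"] = "Teleport"
        path.write_text(json.dumps(data))
        with pytest.raises(ModelFormatError, match="Teleport"):
            load_script(path)

    def test_fresh_nodes_never_collide_with_loaded_ids(self, tmp_path):
        path = tmp_path / "m.script.json"
        save_script(random_script_model(random.Random(1)), path)
        loaded = load_script(path)
        existing = {nid for nid, _ in iter_nodes(loaded)}
        fresh = VariableDeclaration(name="zz")
        assert fresh.node_id not in existing


class TestCheckerRules:
    def test_consecutive_operators_flagged(self):
        model = new_script("demo")
        pipeline = ExecuteCommand(
            [_cmd("cmd"), Operator("pipe"), Operator("pipe"), _cmd("cmd")]
        )
        model.statements.append(ExecuteStatement(pipeline=pipeline))
        codes = [d.code for d in check_script(model)]
        assert codes == ["SF001"]

    def test_terminal_and_leading_operator_flagged(self):
        model = new_script("demo")
        model.statements.append(
            ExecuteStatement(
                pipeline=ExecuteCommand([Operator("and"), _cmd("a"), Operator("seq")])
            )
        )
        codes = [d.code for d in check_script(model)]
        assert codes.count("SF001") == 2

    def test_redirect_not_last_flagged(self):
        model = new_script("demo")
        model.statements.append(
            ExecuteStatement(
                pipeline=ExecuteCommand(
                    [
                        _cmd("a"),
                        RedirectToFile(target=GString([Literal("f")])),
                        Operator("seq"),
                        _cmd("b"),
                    ]
                )
            )
        )
        assert "SF002" in [d.code for d in check_script(model)]

    def test_undeclared_variable_reference_flagged(self):
        model = new_script("demo")
        model.statements.append(
            ExecuteStatement(
                pipeline=ExecuteCommand(
                    [GStringCommand(line=GString([Literal("echo "), VarRef("nope")]))]
                )
            )
        )
        diags = check_script(model)
        assert [d.code for d in diags] == ["SF003"]
        assert "nope" in diags[0].message

    def test_reference_before_declaration_flagged(self):
        model = new_script("demo")
        model.statements.append(
            VariableDeclaration(name="a", initializer=GString([VarRef("b")]))
        )
        model.statements.append(VariableDeclaration(name="b"))
        assert [d.code for d in check_script(model)] == ["SF003"]

    def test_env_read_without_declaring_source_flagged(self):
        model = new_script("demo")
        model.statements.append(
            ExecuteStatement(
                pipeline=ExecuteCommand(
                    [GStringCommand(line=GString([EnvRead("FOO")]))]
                )
            )
        )
        assert [d.code for d in check_script(model)] == ["SF010"]

    def test_env_read_after_load_is_clean(self):
        model = new_script("demo")
        source = EnvironmentSource(
            id="file:x.env",
            kind="file",
            params={"path": "x.env"},
            variables=(EnvironmentVariable("FOO", "1", "file:x.env"),),
        )
        model.sources = [source]
        model.statements.append(LoadEnvironmentStatement(source_refs=[source.id]))
        model.statements.append(
            ExecuteStatement(
                pipeline=ExecuteCommand(
                    [GStringCommand(line=GString([EnvRead("FOO")]))]
                )
            )
        )
        assert check_script(model) == []

    def test_unknown_source_reference_flagged(self):
        model = new_script("demo")
        model.statements.append(LoadEnvironmentStatement(source_refs=["ghost"]))
        assert [d.code for d in check_script(model)] == ["SF011"]

    def test_plugin_script_without_binding_flagged(self):
        model = new_script("demo", "aligner")
        assert "SF020" in [d.code for d in check_script(model)]

    def test_binding_type_mismatch_flagged(self):
        model = new_script("demo", "aligner")
        model.plugin_header = PluginBinding("p", "task")
        assert any(
            d.code == "SF020" and "does not match" in d.message
            for d in check_script(model)
        )

    def test_missing_entry_point_flagged(self):
        model = new_script("demo", "aligner")
        model.plugin_header = PluginBinding("p", "aligner")
        del model.entry_points["align"]
        diags = check_script(model)
        assert any(d.code == "SF020" and "align" in d.message for d in diags)

    def test_empty_plain_script_is_clean(self):
        assert check_script(new_script("demo")) == []


class TestCheckerProperties:
    def test_checker_is_pure(self):
        model = random_script_model(random.Random(3))
        model.statements.append(
            ExecuteStatement(
                pipeline=ExecuteCommand([Operator("pipe"), _cmd("x")])
            )
        )
        before = model_fingerprint(model)
        first = check_script(model)
        second = check_script(model)
        assert first == second
        assert model_fingerprint(model) == before

    def test_diagnostics_ordered_by_node_position(self):
        model = new_script("demo")
        model.statements.append(
            ExecuteStatement(
                pipeline=ExecuteCommand(
                    [GStringCommand(line=GString([VarRef("z")])), Operator("seq")]
                )
            )
        )
        model.statements.append(
            ExecuteStatement(
                pipeline=ExecuteCommand([GStringCommand(line=GString([VarRef("a")]))])
            )
        )
        diags = check_script(model)
        positions = {nid: i for i, (nid, _) in enumerate(iter_nodes(model))}
        assert [positions[d.node_id] for d in diags] == sorted(
            positions[d.node_id] for d in diags
        )

    def test_every_diagnostic_references_an_existing_node(self):
        model = new_script("demo", "task")
        model.statements.append(
            ExecuteStatement(pipeline=ExecuteCommand([Operator("or")]))
        )
        node_ids = {nid for nid, _ in iter_nodes(model)}
        for diag in check_script(model):
            assert diag.node_id in node_ids
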