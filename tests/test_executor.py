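"""Execution semantics, checked against the system shell as oracle."""

import random

import pytest

from shellforge import (
    EvaluationError,
    ExecuteStatement,
    ExecutionError,
    GString,
    Literal,
    LoadEnvironmentStatement,
    VarRef,
    VariableDeclaration,
    load_file_source,
    new_script,
    parse_pipeline,
    run_pipeline,
    run_script,
)
from shellforge.corpus import random_pipeline_text
from shellforge.executor import split_words
from shellforge.model import EnvAssignStatement

from conftest import oracle_env, shell_oracle


def _run(line: str, **kwargs):
    return run_pipeline(parse_pipeline(line), env=oracle_env(), **kwargs)


class TestOperatorSemantics:
    @pytest.mark.parametrize(
        "line",
        [
            "false && echo hi",
            "false || echo hi",
            "true && echo hi",
            "true || echo hi",
            "printf 'b\\na\\n' | sort",
            "echo one ; echo two",
            "false ; echo after",
            "grep nothing | sort || echo fallback",
        ],
    )
    def test_exit_code_and_stdout_match_the_shell(self, line):
        expected_exit, expected_out = shell_oracle(line)
        result = _run(line)
        assert (result.exit_code, result.stdout) == (expected_exit, expected_out)

    def test_pipe_runs_concurrently_and_exit_is_last_commands(self):
        result = _run("false | true")
        assert result.exit_code == 0
        assert [r.exit_code for r in result.records] == [1, 0]

    def test_pipefail_toggle_reports_failing_member(self):
        result = _run("false | true", pipefail=True)
        assert result.exit_code == 1

    def test_redirect_overwrites_target_file(self, tmp_path):
        target = tmp_path / "f"
        target.write_text("old content\n")
        result = run_pipeline(
            parse_pipeline("echo x > f"), env=oracle_env(), workdir=str(tmp_path)
        )
        assert result.exit_code == 0
        assert target.read_text() == "x\n"
        assert result.stdout == ""

    def test_background_command_is_reaped(self):
        result = _run("echo bg &")
        assert result.exit_code == 0
        assert result.records[0].background
        assert result.records[0].exit_code == 0


class TestFailureModes:
    def test_command_not_found_records_127(self):
        result = _run("definitely_not_a_command_xyz")
        assert result.exit_code == 127
        assert result.records[0].exit_code == 127

    def test_unbound_variable_aborts_before_launching(self):
        pipeline = parse_pipeline("echo ${missing} ; echo side-effect")
        with pytest.raises(EvaluationError, match="missing"):
            run_pipeline(pipeline, env=oracle_env())

    def test_structurally_broken_pipeline_refused(self):
        from shellforge import ExecuteCommand, Operator

        with pytest.raises(ExecutionError):
            run_pipeline(ExecuteCommand([Operator("pipe")]), env=oracle_env())

    def test_stderr_captured_per_command(self, tmp_path):
        result = run_pipeline(
            parse_pipeline("cat no_such_file.txt"),
            env=oracle_env(),
            workdir=str(tmp_path),
        )
        assert result.exit_code != 0
        assert "no_such_file.txt" in result.records[0].captured_stderr


class TestWordSplitting:
    def test_quoted_whitespace_kept_in_one_word(self):
        g = parse_pipeline("echo 'a b'  c").nodes[0].line
        assert split_words(g, {}, {}) == ["echo", "a b", "c"]

    def test_interpolated_values_are_not_resplit(self):
        g = GString([Literal("echo "), VarRef("v")])
        assert split_words(g, {"v": "two words"}, {}) == ["echo", "two words"]

    def test_interpolation_joins_current_word(self):
        g = GString([Literal("pre"), VarRef("v"), Literal("post")])
        assert split_words(g, {"v": "X"}, {}) == ["preXpost"]


class TestRunScript:
    def test_declaration_then_interpolated_echo(self):
        model = new_script("demo")
        model.statements.append(
            VariableDeclaration(name="a", initializer=GString.from_text("hi"))
        )
        model.statements.append(
            ExecuteStatement(pipeline=parse_pipeline("echo ${a}", scope=["a"]))
        )
        result = run_script(model, base_env=oracle_env())
        assert (result.stdout, result.exit_code) == ("hi\n", 0)

    def test_loaded_source_feeds_environment_reads(self, tmp_path):
        env_file = tmp_path / "u.env"
        env_file.write_text("USER=alice\n")
        source = load_file_source(env_file)
        model = new_script("demo")
        model.sources = [source]
        model.statements.append(LoadEnvironmentStatement(source_refs=[source.id]))
        model.statements.append(
            ExecuteStatement(
                pipeline=parse_pipeline("echo ${USER}", env_names=["USER"])
            )
        )
        result = run_script(model, base_env=oracle_env())
        assert result.stdout == "alice\n"

    def test_env_assignment_visible_to_later_commands(self, tmp_path):
        env_file = tmp_path / "s.env"
        env_file.write_text("GREETING=x\n")
        source = load_file_source(env_file)
        model = new_script("demo")
        model.sources = [source]
        model.statements.append(LoadEnvironmentStatement(source_refs=[source.id]))
        model.statements.append(
            EnvAssignStatement(
                var_name=GString.from_text("GREETING"),
                value=GString.from_text("hello"),
            )
        )
        model.statements.append(
            ExecuteStatement(
                pipeline=parse_pipeline("echo ${GREETING}", env_names=["GREETING"])
            )
        )
        result = run_script(model, base_env=oracle_env())
        assert result.stdout == "hello\n"

    def test_unknown_entry_point_errors_before_running(self):
        model = new_script("demo")
        model.statements.append(ExecuteStatement(pipeline=parse_pipeline("echo hi")))
        with pytest.raises(ExecutionError, match="frobnicate"):
            run_script(model, entry_point="frobnicate", base_env=oracle_env())

    def test_checker_errors_block_execution(self):
        model = new_script("demo")
        model.statements.append(
            ExecuteStatement(
                pipeline=parse_pipeline("echo ${ghost}")  # undeclared
            )
        )
        with pytest.raises(ExecutionError, match="SF003"):
            run_script(model, base_env=oracle_env())


class TestShellOracleEquivalence:
    def test_seeded_random_pipelines_agree_with_the_shell(self):
        rng = random.Random(1234)
        disagreements = []
        for _ in range(60):
            line = random_pipeline_text(rng)
            expected = shell_oracle(line)
            result = _run(line)
            if (result.exit_code, result.stdout) != expected:
                disagreements.append((line, expected, (result.exit_code, result.stdout)))
        assert disagreements == []

    def test_determinism_of_repeated_runs(self):
        line = "printf 'b\\na\\n' | sort && echo done"
        first = _run(line)
        second = _run(line)
        assert (first.exit_code, first.stdout) == (second.exit_code, second.stdout)
        assert [r.evaluated_text for r in first.records] == [
            r.evaluated_text for r in second.records
        ]

    def test_one_record_per_launched_command(self):
        result = _run("echo a | cat | cat ; echo b")
        assert len(result.records) == 4
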