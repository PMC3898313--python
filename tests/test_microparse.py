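"""Micro-parsing: pipeline import, variable extraction, failure atomicity."""

import random

import pytest

from shellforge import (
    EnvRead,
    GString,
    GStringCommand,
    Literal,
    Operator,
    PipelineParseError,
    RedirectToFile,
    VarRef,
    VariableDeclaration,
    evaluate_gstring,
    extract_variables,
    model_fingerprint,
    new_script,
    parse_pipeline,
    render_pipeline,
)
from shellforge.corpus import malformed_pipeline_text, random_pipeline_text
from shellforge.errors import ModelError


class TestParsePipeline:
    def test_three_command_pipe_with_trailing_redirect(self):
        p = parse_pipeline("a | b | c > md-alignment.sam")
        kinds = [type(n) for n in p.nodes]
        assert kinds == [
            GStringCommand,
            Operator,
            GStringCommand,
            Operator,
            GStringCommand,
            RedirectToFile,
        ]
        assert all(n.kind == "pipe" for n in p.nodes if isinstance(n, Operator))
        target = p.nodes[-1].target
        assert evaluate_gstring(target, {}, {}) == "md-alignment.sam"

    def test_and_operator(self):
        p = parse_pipeline("true && echo ok")
        assert [type(n) for n in p.nodes] == [GStringCommand, Operator, GStringCommand]
        assert p.nodes[1].kind == "and"

    @pytest.mark.parametrize(
        "text,kind",
        [("a | b", "pipe"), ("a || b", "or"), ("a && b", "and"),
         ("a ; b", "seq"), ("a & b", "background")],
    )
    def test_operator_tokens_map_one_to_one(self, text, kind):
        p = parse_pipeline(text)
        assert p.nodes[1].kind == kind

    def test_maximal_munch_prefers_double_operators(self):
        p = parse_pipeline("a||b&&c")
        assert [n.kind for n in p.nodes if isinstance(n, Operator)] == ["or", "and"]

    def test_quoted_pipe_is_not_an_operator(self):
        p = parse_pipeline("echo 'a | b'")
        assert len(p.nodes) == 1
        assert isinstance(p.nodes[0], GStringCommand)

    def test_double_quotes_keep_markers_live(self):
        p = parse_pipeline('echo "${x}"', scope=["x"])
        comps = p.nodes[0].line.components
        assert any(isinstance(c, VarRef) and c.name == "x" for c in comps)

    def test_single_quotes_keep_markers_literal(self):
        p = parse_pipeline("echo '${x}'", scope=["x"])
        comps = p.nodes[0].line.components
        assert all(isinstance(c, Literal) for c in comps)

    def test_scope_and_env_classification(self):
        p = parse_pipeline("echo ${a} ${USER}", scope=["a"], env_names=["USER"])
        comps = p.nodes[0].line.components
        assert [type(c) for c in comps] == [Literal, VarRef, Literal, EnvRead]

    def test_trailing_ampersand_marks_background(self):
        p = parse_pipeline("sort &")
        assert len(p.nodes) == 1 and p.nodes[0].background

    @pytest.mark.parametrize(
        "text,fragment",
        [
            ("a && && b", "consecutive"),
            ("| a", "begins"),
            ("a |", "ends with"),
            ("a > f > g", "last"),
            ("a >", "redirect target"),
            ("echo 'oops", "quote"),
            ("a >> f", ">>"),
            ("a 2> f", "numbered"),
            ("a < f", "<"),
            ("", "empty"),
        ],
    )
    def test_malformed_input_rejected_with_offset(self, text, fragment):
        with pytest.raises(PipelineParseError, match=fragment) as exc:
            parse_pipeline(text)
        assert exc.value.offset is not None

    def test_error_offsets_point_at_the_problem(self):
        with pytest.raises(PipelineParseError) as exc:
            parse_pipeline("a && && b")
        assert exc.value.offset == 5
        with pytest.raises(PipelineParseError) as exc:
            parse_pipeline("echo 'oops")
        assert exc.value.offset == 5


class TestRenderRoundTrip:
    def test_random_corpus_round_trips(self):
        rng = random.Random(20260901)
        for _ in range(150):
            text = random_pipeline_text(rng)
            first = parse_pipeline(text)
            again = parse_pipeline(render_pipeline(first))
            assert again == first

    def test_redirect_and_background_round_trip(self):
        for text in ("a | b > out.sam", "sort &", "a & b"):
            p = parse_pipeline(text)
            assert parse_pipeline(render_pipeline(p)) == p


class TestExtractVariables:
    def _model_with_literal(self, text):
        model = new_script("demo")
        stmt = VariableDeclaration(name="cmd", initializer=GString.from_text(text))
        model.statements.append(stmt)
        return model, stmt

    def test_markers_become_refs_and_declarations(self):
        model, stmt = self._model_with_literal("run ${N} of ${M}")
        g, decls = extract_variables(stmt, model)
        assert [type(c) for c in g.components] == [Literal, VarRef, Literal, VarRef]
        assert [d.name for d in decls] == ["N", "M"]
        # inserted immediately before the statement, in first-occurrence order
        assert model.statements[:2] == decls and model.statements[2] is stmt

    def test_plain_text_unchanged(self):
        model, stmt = self._model_with_literal("plain text")
        g, decls = extract_variables(stmt, model)
        assert decls == [] and g.components == [Literal("plain text")]

    def test_repeated_name_declared_once_referenced_twice(self):
        model, stmt = self._model_with_literal("${N} ${N}")
        g, decls = extract_variables(stmt, model)
        assert len(decls) == 1
        refs = [c for c in g.components if isinstance(c, VarRef)]
        assert len(refs) == 2
        assert {r.declaration_id for r in refs} == {decls[0].node_id}

    def test_existing_declaration_referenced_not_redeclared(self):
        model = new_script("demo")
        existing = VariableDeclaration(name="N", initializer=GString.from_text("1"))
        stmt = VariableDeclaration(name="cmd", initializer=GString.from_text("${N}"))
        model.statements.extend([existing, stmt])
        g, decls = extract_variables(stmt, model)
        assert decls == []
        assert g.components[0].declaration_id == existing.node_id

    def test_parse_error_leaves_model_untouched(self):
        model, stmt = self._model_with_literal("broken ${N")
        before = model_fingerprint(model)
        with pytest.raises(Exception):
            extract_variables(stmt, model)
        assert model_fingerprint(model) == before

    def test_non_literal_initializer_rejected(self):
        model = new_script("demo")
        stmt = VariableDeclaration(name="x", initializer=GString([VarRef("y")]))
        model.statements.append(stmt)
        with pytest.raises(ModelError):
            extract_variables(stmt, model)


class TestFailureAtomicity:
    def test_malformed_corpus_never_mutates_the_model(self):
        rng = random.Random(42)
        model = new_script("demo")
        stmt = VariableDeclaration(name="cmd", initializer=GString.from_text("x"))
        model.statements.append(stmt)
        before = model_fingerprint(model)
        rejected = 0
        for _ in range(100):
            text = malformed_pipeline_text(rng)
            try:
                parse_pipeline(text)
            except PipelineParseError:
                rejected += 1
            assert model_fingerprint(model) == before
        assert rejected == 100
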