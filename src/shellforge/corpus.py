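"""Seeded generators of test corpora.

Everything here is driven by a caller-supplied :class:`random.Random`, so
corpora are reproducible from a single seed. Three kinds of material:

* pipeline text over a *safe command alphabet* (``true``, ``false``,
  ``echo``, ``printf``, ``cat``, ``sort``, ``grep``) joined by the binary
  operators ``| && || ;`` — safe to actually execute and compare against a
  real shell;
* deliberately malformed pipeline text, for failure-atomicity checks;
* random script models (declarations, loads, assignments, pipelines) for
  persistence round-trips and generator-equivalence runs.
"""

from __future__ import annotations

import random

from .environment import EnvironmentSource, EnvironmentVariable
from .gstring import EnvRead, GString, Literal, VarRef
from .microparse import parse_pipeline
from .model import (
    EnvAssignStatement,
    ExecuteStatement,
    LoadEnvironmentStatement,
    ScriptModel,
    VariableDeclaration,
)

WORDS = [
    "alpha", "beta", "gamma", "delta", "reads", "hits",
    "sample1", "x42", "ref", "lane2",
]

SAFE_OPERATORS = ["|", "&&", "||", ";"]


def random_word(rng: random.Random) -> str:
    return rng.choice(WORDS)


def random_command(rng: random.Random) -> str:
    kind = rng.randrange(8)
    if kind == 0:
        return "true"
    if kind == 1:
        return "false"
    if kind == 2:
        return f"echo {random_word(rng)}"
    if kind == 3:
        return f"echo {random_word(rng)} {random_word(rng)}"
    if kind == 4:
        return f"printf '{random_word(rng)}\\n{random_word(rng)}\\n'"
    if kind == 5:
        return "cat"
    if kind == 6:
        return "sort"
    return f"grep {random_word(rng)}"


def random_pipeline_text(rng: random.Random, max_commands: int = 4) -> str:
    """One well-formed shell line over the safe alphabet."""
    n = rng.randint(1, max_commands)
    parts = [random_command(rng)]
    for _ in range(n - 1):
        parts.append(rng.choice(SAFE_OPERATORS))
        parts.append(random_command(rng))
    if rng.random() < 0.15:
        # a quoted argument containing operator characters must stay inert
        parts[0] = f"echo '{random_word(rng)} | {random_word(rng)}'"
    return " ".join(parts)


def malformed_pipeline_text(rng: random.Random) -> str:
    """One line the micro-parser must reject without side effects."""
    a, b = random_command(rng), random_command(rng)
    op1, op2 = rng.choice(SAFE_OPERATORS), rng.choice(SAFE_OPERATORS)
    shapes = [
        f"{a} {op1} {op2} {b}",        # consecutive operators
        f"{op1} {a}",                   # leading operator
        f"{a} {op1}",                   # trailing operator
        f"{a} >> out.txt",              # unsupported append redirect
        f"{a} 2> err.txt",              # unsupported numbered redirect
        f"{a} < in.txt",                # unsupported input redirect
        f"echo '{random_word(rng)}",    # unbalanced quote
        f"{a} > out.txt {op1} {b}",     # redirect not last
        f"{a} >",                       # missing redirect target
        "   ",                          # empty pipeline
    ]
    return rng.choice(shapes)


def random_gstring(
    rng: random.Random,
    var_names=("a", "b", "c"),
    env_names=("USER", "REF"),
    max_components: int = 6,
) -> GString:
    comps = []
    for _ in range(rng.randint(1, max_components)):
        kind = rng.randrange(3)
        if kind == 0:
            comps.append(Literal(" ".join(
                random_word(rng) for _ in range(rng.randint(1, 2))
            )))
        elif kind == 1:
            comps.append(VarRef(rng.choice(list(var_names))))
        else:
            comps.append(EnvRead(rng.choice(list(env_names))))
    return GString(comps)


def random_env_source(rng: random.Random, index: int) -> EnvironmentSource:
    source_id = f"file:corpus{index}.env"
    names = rng.sample(["REF", "GENOME", "THREADS", "LANE"], rng.randint(1, 3))
    return EnvironmentSource(
        id=source_id,
        kind="file",
        params={"path": f"corpus{index}.env"},
        variables=tuple(
            EnvironmentVariable(n, random_word(rng), source_id) for n in names
        ),
    )


def random_script_model(rng: random.Random, index: int = 0) -> ScriptModel:
    """A structurally valid, checker-clean plain script model."""
    model = ScriptModel(name=f"corpus_{index}")
    model.sources = [random_env_source(rng, i) for i in range(rng.randint(0, 2))]
    declared: list[str] = []
    loaded_env: list[str] = []
    if model.sources:
        refs = [s.id for s in model.sources]
        model.statements.append(LoadEnvironmentStatement(source_refs=refs))
        for s in model.sources:
            loaded_env.extend(sorted(s.addressable_names()))
    for i in range(rng.randint(1, 5)):
        roll = rng.random()
        if roll < 0.4 or not declared:
            name = f"v{len(declared)}"
            init = GString([Literal(random_word(rng))])
            if declared and rng.random() < 0.3:
                init.components.append(VarRef(rng.choice(declared)))
            if loaded_env and rng.random() < 0.3:
                init.components.append(EnvRead(rng.choice(loaded_env)))
            model.statements.append(VariableDeclaration(name=name, initializer=init))
            declared.append(name)
        elif roll < 0.55 and loaded_env:
            model.statements.append(
                EnvAssignStatement(
                    var_name=GString([Literal("EXTRA")]),
                    value=GString([VarRef(rng.choice(declared))]),
                )
            )
        else:
            text = random_pipeline_text(rng)
            pipeline = parse_pipeline(text, scope=declared, env_names=loaded_env)
            model.statements.append(ExecuteStatement(pipeline=pipeline))
    return model


def random_executable_model(rng: random.Random, index: int = 0) -> ScriptModel:
    """A checker-clean model whose every pipeline is safe to run."""
    model = ScriptModel(name=f"runnable_{index}")
    model.statements.append(
        VariableDeclaration(
            name="word", initializer=GString([Literal(random_word(rng))])
        )
    )
    for _ in range(rng.randint(1, 3)):
        text = random_pipeline_text(rng)
        pipeline = parse_pipeline(text, scope=["word"])
        model.statements.append(ExecuteStatement(pipeline=pipeline))
    if rng.random() < 0.5:
        model.statements.append(
            ExecuteStatement(
                pipeline=parse_pipeline("echo ${word}", scope=["word"])
            )
        )
    return model
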