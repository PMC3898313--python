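# Standalone script runtime. This file is embedded verbatim into every
# rendered program artifact, so it must stay dependency-free (stdlib only)
# and must not import the rest of the package. It interprets the serialized
# model found in the global MODEL with the same semantics as the library's
# execution engine: shell binary operators, pipes, trailing redirect,
# environment sources and lazy string interpolation.

import os
import subprocess
import sys
import tempfile


class RunError(Exception):
    pass


def _value(comp, bindings, env):
    kind = comp["kind"]
    if kind == "Literal":
        return comp["text"]
    if kind == "VarRef":
        if comp["name"] not in bindings:
            raise RunError("unbound variable %s" % comp["name"])
        return bindings[comp["name"]]
    if kind == "EnvRead":
        if comp["name"] not in env:
            raise RunError("unbound environment variable %s" % comp["name"])
        return env[comp["name"]]
    raise RunError("unknown component %s" % kind)


def evaluate(gstring, bindings, env):
    return "".join(_value(c, bindings, env) for c in gstring["components"])


def split_words(gstring, bindings, env):
    # unquoted whitespace splits words; quoted runs stay together;
    # interpolated values are never re-split
    words, cur, has_word, state = [], [], False, ""
    for comp in gstring["components"]:
        if comp["kind"] == "Literal":
            for ch in comp["text"]:
                if state:
                    if ch == state:
                        state = ""
                    else:
                        cur.append(ch)
                elif ch in "'\"":
                    state = ch
                    has_word = True
                elif ch.isspace():
                    if has_word:
                        words.append("".join(cur))
                    cur, has_word = [], False
                else:
                    cur.append(ch)
                    has_word = True
        else:
            cur.append(_value(comp, bindings, env))
            has_word = True
    if state:
        raise RunError("unbalanced quote in command line")
    if has_word:
        words.append("".join(cur))
    return words


def _exit_status(returncode):
    return 128 - returncode if returncode < 0 else returncode


def run_pipeline(pipeline, bindings, env, workdir=None):
    # split nodes into pipe-connected groups joined by control operators
    groups, cur, redirect = [], {"cmds": [], "op": None, "bg": False}, None
    for node in pipeline["nodes"]:
        kind = node["kind"]
        if kind == "GStringCommand":
            cur["cmds"].append(node)
            if node.get("background"):
                cur["bg"] = True
        elif kind == "Operator":
            if node["operator"] == "pipe":
                continue
            cur["op"] = node["operator"]
            if node["operator"] == "background":
                cur["bg"] = True
            groups.append(cur)
            cur = {"cmds": [], "op": None, "bg": False}
        elif kind == "RedirectToFile":
            redirect = node["target"]
        else:
            raise RunError("cannot execute node %s" % kind)
    if cur["cmds"]:
        groups.append(cur)

    plan = []
    for group in groups:
        plan.append([split_words(c["line"], bindings, env) for c in group["cmds"]])
    redirect_path = None
    if redirect is not None:
        redirect_path = evaluate(redirect, bindings, env)
        if workdir and not os.path.isabs(redirect_path):
            redirect_path = os.path.join(workdir, redirect_path)

    last_exit, prev_op, pending = 0, None, []
    for gi, group in enumerate(groups):
        run_this = True
        if prev_op == "and":
            run_this = last_exit == 0
        elif prev_op == "or":
            run_this = last_exit != 0
        prev_op = group["op"]
        if not run_this:
            continue
        redirect_handle = None
        if redirect_path is not None and gi == len(groups) - 1:
            redirect_handle = open(redirect_path, "wb")
        procs, prev_stdout = [], None
        for ci, words in enumerate(plan[gi]):
            last_cmd = ci == len(plan[gi]) - 1
            stdin = subprocess.DEVNULL if prev_stdout is None else prev_stdout
            stdout = redirect_handle if (last_cmd and redirect_handle) else subprocess.PIPE
            stderr = tempfile.TemporaryFile()
            try:
                proc = subprocess.Popen(
                    words, stdin=stdin, stdout=stdout, stderr=stderr,
                    env=env, cwd=workdir,
                )
            except FileNotFoundError:
                proc = None
                sys.stderr.write("%s: command not found\n" % words[0])
            except PermissionError:
                proc = None
                sys.stderr.write("%s: permission denied\n" % words[0])
            if prev_stdout is not None:
                prev_stdout.close()
            prev_stdout = proc.stdout if (proc is not None and not last_cmd) else None
            procs.append((proc, stderr))
        if group["bg"]:
            pending.append(procs)
            last_exit = 0
            continue
        last_exit = _wait(procs)
        if redirect_handle is not None:
            redirect_handle.close()
    for procs in pending:
        _wait(procs)
    return last_exit


def _wait(procs):
    last_proc = procs[-1][0] if procs else None
    if last_proc is not None and last_proc.stdout is not None:
        out = last_proc.stdout.read()
        last_proc.stdout.close()
        sys.stdout.buffer.write(out)
        sys.stdout.buffer.flush()
    exits = []
    for proc, stderr in procs:
        if proc is None:
            exits.append(127)
        else:
            exits.append(_exit_status(proc.wait()))
            stderr.seek(0)
            sys.stderr.buffer.write(stderr.read())
        stderr.close()
    return exits[-1] if exits else 0


def main(model, argv=None):
    argv = sys.argv[1:] if argv is None else argv
    entry = None
    if argv[:1] == ["--entry"]:
        if len(argv) < 2:
            sys.stderr.write("--entry requires a name\n")
            return 2
        entry = argv[1]
    sources = {s["id"]: s for s in model.get("sources", [])}
    statements = list(model.get("statements", []))
    if entry is not None:
        if entry not in model.get("entryPoints", {}):
            sys.stderr.write("unknown entry point '%s'\n" % entry)
            return 1
        statements += model["entryPoints"][entry]
    env = dict(os.environ)
    bindings = {}
    last_exit = 0
    try:
        for stmt in statements:
            kind = stmt["kind"]
            if kind == "VariableDeclaration":
                bindings[stmt["name"]] = evaluate(stmt["initializer"], bindings, env)
            elif kind == "LoadEnvironmentStatement":
                for ref in stmt["sourceRefs"]:
                    if ref not in sources:
                        raise RunError("unknown environment source '%s'" % ref)
                    for var in sources[ref]["variables"]:
                        env[var["name"]] = var["value"]
            elif kind == "EnvAssignStatement":
                name = evaluate(stmt["varName"], bindings, env)
                env[name] = evaluate(stmt["value"], bindings, env)
            elif kind == "ExecuteStatement":
                last_exit = run_pipeline(stmt["pipeline"], bindings, env)
            else:
                raise RunError("cannot execute statement %s" % kind)
    except RunError as exc:
        sys.stderr.write("error: %s\n" % exc)
        return 1
    return last_exit
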