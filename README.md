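# shellforge

Structured shell scripting for bioinformatics pipelines: scripts as typed
models instead of fragile text.

Analysis pipelines in genomics are still mostly glued together with shell
scripts, and shell interpreters only discover an error when execution
reaches the broken line — a syntax slip in a rarely-taken branch of a
clinical pipeline can hide for months. `shellforge` addresses this by
representing a script as a typed abstract syntax tree (AST) that can be
checked *before* anything runs, while keeping the expressiveness shell
users rely on:

- **Pipelines** are `ExecuteCommand` nodes: commands alternating with the
  familiar binary operators `| && || ; &` plus an optional trailing
  `> file` redirect. At run time the operators have the interpreter's
  semantics: `a | b` pipes stdout to stdin of concurrent processes,
  `a && b` runs `b` iff `a` exited 0, `a || b` iff it did not, `;` always,
  `&` launches without waiting; the pipeline's exit code is its last
  command's.
- **GStrings** are interpolated strings built from literal, program-variable
  and environment-variable components, written `"align ${sample} for
  ${USER}"`. Evaluation is lazy: rebinding `sample` and re-evaluating yields
  the new value.
- **Environment sources** (process snapshot, `KEY=VALUE` files, plugin
  descriptors) make configuration discoverable: scripts declare what they
  load, tooling can enumerate every readable name, and the checker flags
  reads nothing declares.
- **Micro-parsing** imports raw shell lines developed interactively at the
  prompt into well-formed AST fragments — and refuses to touch the model at
  all if any part of the line does not parse.
- The **checker** reports stable diagnostic codes (`SF001` operator
  misuse, `SF002` misplaced redirect, `SF003` undeclared variable, `SF010`
  unsourced environment read, `SF020` plugin-contract violations).
- The **generator** lowers plugin fetch/push commands to their SDK command
  lines and renders any check-clean model to a standalone runnable program
  plus a POSIX launcher, byte-deterministically.
- A **plugin contract** models analysis-grid plugins (five script types:
  aligner, alignment-analysis, resource, artifact-install, task) with XML
  descriptors, slot declarations and check-clean script scaffolds.

## Worked example

```sh
$ cat pipeline.bash
printf 'b\na\n' | sort > sorted.txt
true && echo aligned ${sample}

$ shellforge import pipeline.bash --name demo -o demo.script.json
$ shellforge check demo.script.json
demo.script.json:n19: SF003 reference to undeclared variable 'sample'
```

`import` micro-parsed each line into a pipeline (the first has two commands,
one pipe operator and a redirect whose target evaluates to `sorted.txt`);
`check` then caught the use of `${sample}` before any declaration — at model
time, not at minute 40 of a pipeline run. After declaring the variable (or
extracting it automatically with `extract_variables`), the script runs and
generates:

```sh
$ shellforge run demo.script.json
aligned NA12878
$ echo $?
0
$ shellforge generate demo.script.json -o out    # prints out/demo/launcher
$ out/demo/launcher                              # same output, no library needed
```

The same API is available in Python (`parse_pipeline`, `check_script`,
`run_script`, `render_program`, …); see the module docstrings.

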