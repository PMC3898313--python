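# Methods

## The script model

A script is stored and manipulated as a typed AST (`ScriptModel`): a name, a
script type (`plain` or one of five plugin types), an optional plugin
binding, an ordered list of environment sources, an ordered statement list,
and — for plugin scripts — a map of named entry points to statement lists.
Four statement forms are modeled: variable declarations (initialized by a
GString), execute statements (one pipeline each), load-environment
statements, and environment assignments whose *name* is itself a GString
(so an environment variable's name can be computed). Control flow (loops,
conditionals) is deliberately out of scope: the model targets the
command-orchestration layer of a script, and anything beyond it belongs in
a host language.

Every node carries a model-unique id (`n<k>`). Ids matter only for
persistence and cross-references (a variable reference records the id of
its declaration); structural equality of nodes ignores them, so two
independent parses of the same text compare equal. Models persist as
versioned JSON, one file per script. Loading is strict and atomic: a
malformed or truncated file raises an error naming the offending node and
never yields a partial model, and a `formatVersion` newer than the library
understands is refused outright rather than guessed at.

## GStrings and lazy evaluation

A GString is an ordered list of components: literals, program-variable
references and environment reads. The marker syntax is exactly `${name}`;
interior whitespace is trimmed (`${ b}` reads `b`), `\${` escapes a literal
`${`, and a `$` not followed by `{` is ordinary text. At parse time a name
resolves to a variable reference when it is in scope, an environment read
when a source declares it, and scope shadows the environment on collision —
the inner binding wins, as in ordinary lexical scoping. Evaluation is lazy
and pure in `(bindings, environment)`: a GString stores references, so
re-evaluating after a rebinding yields the new text. Normal form (no empty
or adjacent literals) is maintained by `normalize_gstring`, which is
idempotent and evaluation-equivalent.

Nested expressions inside `${…}` are not supported — only identifier names.

## Pipelines and micro-parsing

`parse_pipeline` converts one raw shell line into a pipeline node.
Tokenization is maximal-munch (`||` before `|`, `&&` before `&`) and
quote-aware: single quotes suppress both operators and `${}` markers,
double quotes suppress operators but keep markers live — mirroring the
shell, which is the declared semantic reference. Only the overwrite
redirect `>` is modeled; `>>`, `2>` and `<` are *rejected* with an
"unsupported redirect" error rather than silently mis-parsed. A lone
trailing `&` does not become a dangling operator: it marks the final
command as a background launch, which keeps the alternation invariant
(command, operator, command, …) true by construction.

Micro-parsing is all-or-nothing: the parser builds the complete fragment
before any model mutation, so a failure — consecutive operators, an
unterminated quote or marker, a misplaced redirect — leaves the model
byte-identical (asserted by fingerprint in the tests). The same contract
covers `extract_variables`, which converts `${name}` markers in a pasted
literal into references and inserts one declaration per distinct undeclared
name immediately before the statement, in first-occurrence order.

## Semantic checking

`check_script` is pure and exhaustive; it reports, never repairs.
Rules: SF001 (alternation violations: consecutive, leading or terminal
operators, adjacent commands, empty pipeline), SF002 (redirect not final),
SF003 (reference to a variable not declared earlier in statement order),
SF010 (environment read that no *loaded* source declares — loads are
tracked positionally, so reading before loading is flagged), SF011 (load of
an unknown source id), SF020 (plugin scripts: missing binding, binding/type
mismatch, missing contract entry point). Diagnostics are ordered by node
position in a pre-order traversal, ties by code, making output stable for
tooling. Entry points are checked against the scope and environment state
left by the main statement list, because that is what precedes them at run
time. An environment assignment does not satisfy SF010 for later reads —
the rule is deliberately source-based, since an assigned name is only
knowable statically when its name-GString is a constant.

## Execution

The executor launches commands directly (no intermediate shell), connecting
pipe groups with real pipes and applying `&& || ; &` with the interpreter's
short-circuit semantics; the pipeline exit code is the last command's, with
an off-by-default `pipefail` toggle that reports the last failing member.
A command that cannot be found records the conventional exit 127 (126 for a
permission failure); death by signal is reported as 128+signal. Evaluation
errors abort before *anything* is launched. Stderr is captured per command
into an ordered `CommandRecord` list — one record per launch — and every
command line is logged after GString evaluation.

Word splitting is component-aware: literal text splits on unquoted
whitespace with quotes grouping (and removed), while interpolated values
join the current word verbatim and are never re-split. This is safer than
the shell's re-splitting of expanded values and is the executor's one
deliberate semantic deviation; a value containing spaces arrives at the
program as a single argument.

Background (`&`) launches are recorded as detached but reaped before
`run_pipeline` returns, so results are deterministic and no orphans
survive a run. Their stdout is appended after the foreground output.

`run_script` executes the main statement list, then the chosen entry
point's. Load-environment statements overlay their source's variables onto
the child environment (later sources win, matching the resolution order of
the environment module); assignments mutate it for subsequent commands. The
base child environment defaults to the interpreter's own (so `PATH` works)
but is an explicit parameter for hermetic runs.

## Environment sources

Three source kinds: a process snapshot, `KEY=VALUE` files (dotenv dialect:
`#` comments, blank lines ignored, last duplicate wins, values verbatim —
no quote expansion), and plugin descriptors. Sources are immutable
snapshots with stable ids; `reload_source` returns a fresh snapshot from
the origin and fails without touching the caller's copy. Resolution scans
sources last-to-first so that later-declared sources override earlier ones;
the paper's precedence among multiple sources was an open design point and
this ordering is this package's documented choice. Names that are not
identifiers (e.g. containing dots) are stored but not addressable from
GStrings, keeping the interpolation lexicon closed.

## Path patterns

Patterns match entry names within one directory — no recursion, no brace or
tilde expansion. Wildcards support `*` and `?` only; regex mode is a
full-match expression. Hidden (dot-prefixed) entries match only when the
pattern's first character is `.`, in either mode. Results are
lexicographically sorted and an empty match is an empty list. The test
oracle is the definitionally simple route: list everything, filter with the
documented predicate, sort.

## Reduction and generation

Plugin scripts may use two domain commands inside pipelines: fetch (bind a
plugin *input slot*'s files) and push (deliver results to an *output
slot*). `reduce_model` lowers each to an execute command by instantiating
the descriptor's SDK template (`{slot}` is the only substitution token),
validating the slot against the right direction's declarations. Reduction
is a pure model-to-model transformation: core models pass through as
structurally equal copies and the operation is idempotent.

`render_program` emits `<outDir>/<name>/program.py` — the canonical JSON of
the model concatenated with a fixed, dependency-free runtime
(`_standalone_runtime.py`, embedded verbatim) — plus a two-line POSIX
launcher that invokes the program by relative path. Output is
byte-deterministic: canonical JSON, fixed runtime text, no timestamps. The
embedded runtime re-implements the executor's semantics over the serialized
form; behavioural equivalence (stdout and exit code) with `run_script` is
asserted over a random executable corpus. Rendered programs carry their
sources' variable *snapshots*; regenerate after changing a source file.

Phrase templates capture mostly-unstructured configuration text: only
designated lines are split at a single-character delimiter, designated
segments become named slots (named by their original text), and rendering
substitutes bindings and rejoins with the original delimiters — with no
phrase lines it is the identity. Which lines are "select" is an explicit
argument rather than a guessed heuristic.

## Plugin contract

The five plugin types and their entry-point sets are configuration, not
code: a shipped contract file (`data/entry_points.yaml`) maps each type to
its hooks (aligner: setup/align/teardown; alignment-analysis:
setup/combine/teardown; resource and artifact-install: install; task:
setup/run/teardown) and can be overridden per call. The XML descriptor
schema (`data/plugin.xsd`) is repo-defined and versioned — a stand-in
modelling the information a grid plugin needs (identity, type, slots,
environment entries, SDK templates), not a claim about any deployed
system's real schema. The descriptor's `errorManagement` policy is stored
and surfaced but not acted on at run time, since no runtime semantics are
defined for it here. Scaffolded scripts bind the plugin, pre-load its
environment source and create the contract's entry points empty; every
scaffold is checker-clean by construction.

## Test corpora and what they show

Randomized corpora are generated by `shellforge.corpus` from a caller
seed. The executable corpus uses a safe command alphabet — `true`, `false`,
`echo`, `printf`, `cat`, `sort`, `grep` over fixed word lists, joined by
`| && || ;` (1–4 commands per line, occasionally with quoted arguments
containing operator characters) — chosen so that lines are deterministic,
instant and side-effect-free, with `LC_ALL=C` pinning collation for `sort`.
The shell-oracle suite compares exit code and stdout against `bash -c` on
200 such lines; the generator-equivalence suite runs a dozen rendered
programs. Problem sizes (200 pipelines, 100 models, 40 directory trees)
keep the whole suite in seconds while exercising every operator pair and
quoting mode many times over.

These corpora emulate the *structure* of pipeline scripts, not their
payloads: no large files, no long-running tools, no `&` in the oracle
corpus (background timing is asserted separately and deterministically),
and no adversarial binaries. Agreement on them demonstrates operator
semantics, quoting and word-splitting fidelity — not the behaviour of any
particular bioinformatics tool.

## Known limitations

- No functions, subshells, here-docs, globbing-in-place or arithmetic
  expansion in pipelines; unsupported redirects are rejected, not emulated.
- The checker cannot statically validate environment reads satisfied only
  by a computed environment assignment (by design, see SF010 above).
- Rendered programs freeze source snapshots at render time.
- Pipelines whose single-quoted text contains `${` render back with an
  escape that re-parses equivalently only outside quotes; round-trip
  guarantees therefore exclude quoted marker text.
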