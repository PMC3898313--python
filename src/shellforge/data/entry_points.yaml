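# Entry-point contract: the named hooks each plugin script type must provide.
# The grid plugin runner invokes these hooks by name; a plugin script is
# considered complete only when every hook of its type exists. Override by
# passing an alternative contract file to the checker or scaffolder.
aligner: [setup, align, teardown]
alignment-analysis: [setup, combine, teardown]
resource: [install]
artifact-install: [install]
task: [setup, run, teardown]
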