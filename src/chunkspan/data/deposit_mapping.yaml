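# Column mapping for loading a locally downloaded trial-level data deposit
# into the chunkspan trial-log schema.  The deposit's exact layout is not
# fixed by this package: edit the source column names (and value maps) below
# to match your copy.  The defaults describe a plausible synthetic layout
# used by the test suite; they are a stand-in, not the authoritative layout.
#
# columns: {schema column: source column}
# values:  {schema column: {source value: schema value}}
# defaults: constants for schema columns absent from the deposit
columns:
  participant_id: subject
  block_order_index: block_order
  task_type: task
  condition: condition
  trial_index: trial
  is_practice: practice
  length: list_length
  memoranda: memoranda
  recalled_sequence: response
  correct: accuracy
  eq_correct_count: operations_correct
  eq_total: operations_total
values:
  task_type:
    simple: simple
    complex: complex
    SS: simple
    OS: complex
  condition:
    chunkable: chunkable
    nonchunkable: nonchunkable
    c: chunkable
    nc: nonchunkable
  correct:
    1: true
    0: false
defaults:
  lures: ""
  complexity: -1
  seed: -1
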