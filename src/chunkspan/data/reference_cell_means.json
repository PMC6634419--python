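{
  "description": "Reference human cell means (and standard errors) of span by task type and condition, used as the printed-table input to the ratio analysis.",
  "n": 94,
  "means": {
    "simple": {"nonchunkable": 2.49, "chunkable": 4.05},
    "complex": {"nonchunkable": 1.45, "chunkable": 2.2}
  },
  "standard_errors": {
    "simple": {"nonchunkable": 0.06, "chunkable": 0.11},
    "complex": {"nonchunkable": 0.06, "chunkable": 0.09}
  },
  "individual_chunking_scores": {
    "simple": {"mean": 1.7, "se": 0.05},
    "complex": {"mean": 1.76, "se": 0.12}
  }
}
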