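{
  "title": "bayesahc run report",
  "type": "object",
  "required": [
    "version",
    "method",
    "n_vars",
    "n_eff",
    "seed",
    "stop_level",
    "n_merges",
    "cumulative_evidence",
    "merges",
    "partition"
  ],
  "properties": {
    "version": {"type": "string"},
    "method": {"type": "string"},
    "input": {"type": ["string", "null"]},
    "n_vars": {"type": "integer"},
    "n_eff": {"type": "number"},
    "seed": {"type": ["integer", "null"]},
    "stop_level": {"type": "integer"},
    "n_merges": {"type": "integer"},
    "names": {"type": ["array", "null"]},
    "cumulative_evidence": {"type": ["array", "null"]},
    "merges": {"type": "array"},
    "partition": {"type": ["array", "null"]}
  }
}
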