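{
  "title": "pbcurves report",
  "type": "object",
  "required": ["report_type"],
  "properties": {
    "report_type": {"type": "string"},
    "c_hat": {"type": "number"},
    "prevalence_hat": {"type": "number"},
    "j": {"type": "integer"},
    "window": {"type": "array"},
    "window_values": {"type": "array"},
    "p_naive_max": {"type": "number"},
    "spread": {"type": "number"},
    "kind": {"type": "string"},
    "auc": {"type": "object"},
    "auc_diff": {"type": "object"},
    "rank_correlation": {"type": "object"},
    "config": {"type": "object"}
  }
}
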