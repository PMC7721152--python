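{
  "_comment": [
    "Dropout-by-condition 2x2 table reconstructed from printed marginals:",
    "initial sample 1629, 98 item-nonresponse dropouts; dropout rate 7.65%",
    "in the direct-questioning arm and 5.19% in the ECWM arm.",
    "42/549 = 7.65% and 56/1080 = 5.19% are the unique integer solutions",
    "with 549 + 1080 = 1629 and 42 + 56 = 98.",
    "Rows: DQ, ECWM; columns: dropped out, completed."
  ],
  "rows": ["dq", "ecwm"],
  "columns": ["dropout", "completed"],
  "table": [[42, 507], [56, 1024]]
}
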