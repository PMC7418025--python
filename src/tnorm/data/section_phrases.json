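{
  "入院诊断": "ADMISSION",
  "入院情况": "ADMISSION",
  "出院诊断": "DISCHARGE",
  "出院情况": "DISCHARGE",
  "出院医嘱": "DISCHARGE"
}
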