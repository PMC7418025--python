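{
  "入院": "ADMISSION",
  "出院": "DISCHARGE",
  "手术": "SURGERY",
  "术后": "SURGERY",
  "化疗": "CHEMOTHERAPY",
  "返院": "RETURN",
  "回院": "RETURN"
}
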