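{
  "version": "1.0",
  "preamble_prefixes": [
    "sure,",
    "here is the",
    "here are",
    "### response:",
    "the probable",
    "the differential",
    "the most probable",
    "based on"
  ],
  "numbering_patterns": [
    "^\\s*\\d+\\s*[\\.\\)\\:\\-]\\s*",
    "^\\s*\\(\\d+\\)\\s*",
    "^\\s*[ivxlIVXL]+\\s*[\\.\\)]\\s+",
    "^\\s*[a-hA-H]\\s*[\\.\\)]\\s+",
    "^\\s*[-*•]\\s+"
  ]
}
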