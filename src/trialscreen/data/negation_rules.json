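{
  "pre_triggers": [
    "no",
    "not",
    "denies",
    "denied",
    "without",
    "no history of",
    "no evidence of",
    "no signs of",
    "negative for",
    "free of",
    "rules out",
    "ruled out",
    "never had",
    "never developed"
  ],
  "post_triggers": [
    "was ruled out",
    "is ruled out",
    "ruled out",
    "unlikely",
    "not present",
    "was negative",
    "is negative",
    "absent",
    "was excluded"
  ],
  "terminators": [
    "but",
    "however",
    "although",
    "though",
    "except",
    "apart",
    "aside",
    "yet",
    "nevertheless"
  ],
  "scope_window": 6
}
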