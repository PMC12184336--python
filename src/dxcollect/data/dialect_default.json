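{
  "version": "1.0",
  "case_folding": true,
  "punctuation_strip": true,
  "stop_words": [
    "of", "the", "and", "a", "an", "in", "on", "to", "with",
    "due", "by", "for", "at", "from", "or", "nos", "unspecified"
  ],
  "british_to_us": {
    "tumour": "tumor",
    "tumours": "tumors",
    "anaemia": "anemia",
    "anaemic": "anemic",
    "oedema": "edema",
    "oesophagus": "esophagus",
    "oesophageal": "esophageal",
    "diarrhoea": "diarrhea",
    "haemorrhage": "hemorrhage",
    "haemorrhagic": "hemorrhagic",
    "haematoma": "hematoma",
    "haemoglobin": "hemoglobin",
    "haematuria": "hematuria",
    "coeliac": "celiac",
    "paediatric": "pediatric",
    "foetal": "fetal",
    "foetus": "fetus",
    "leukaemia": "leukemia",
    "ischaemia": "ischemia",
    "ischaemic": "ischemic",
    "gynaecology": "gynecology",
    "faeces": "feces",
    "goitre": "goiter",
    "fibre": "fiber",
    "litre": "liter",
    "oestrogen": "estrogen",
    "paralyse": "paralyze",
    "anaesthesia": "anesthesia",
    "dyspnoea": "dyspnea",
    "apnoea": "apnea"
  },
  "acronym_map": {
    "mi": "myocardial infarction",
    "copd": "chronic obstructive pulmonary disease",
    "uti": "urinary tract infection",
    "tb": "tuberculosis",
    "dm": "diabetes mellitus",
    "htn": "hypertension",
    "cva": "cerebrovascular accident",
    "chf": "congestive heart failure",
    "gerd": "gastroesophageal reflux disease",
    "dvt": "deep vein thrombosis",
    "uri": "upper respiratory infection",
    "ckd": "chronic kidney disease"
  },
  "plural_rules": [
    ["itides", "itis"],
    ["omata", "oma"],
    ["oses", "osis"],
    ["ies", "y"],
    ["xes", "x"],
    ["zes", "z"],
    ["ches", "ch"],
    ["shes", "sh"],
    ["sses", "ss"],
    ["s", ""]
  ]
}
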