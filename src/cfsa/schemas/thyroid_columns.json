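{
  "description": "Column spec for the UCI-style thyroid-function screening schema (28 attributes): demographic fields, medication/history booleans, measured-flag booleans and hormone assay values. Ships as metadata only; no download is attempted by any code path.",
  "target": "class",
  "na_tokens": ["?"],
  "columns": [
    {"name": "age", "kind": "numeric"},
    {"name": "sex", "kind": "categorical"},
    {"name": "on thyroxine", "kind": "boolean"},
    {"name": "query on thyroxine", "kind": "boolean"},
    {"name": "on antithyroid medication", "kind": "boolean"},
    {"name": "sick", "kind": "boolean"},
    {"name": "pregnant", "kind": "boolean"},
    {"name": "thyroid surgery", "kind": "boolean"},
    {"name": "I131 treatment", "kind": "boolean"},
    {"name": "query hypothyroid", "kind": "boolean"},
    {"name": "query hyperthyroid", "kind": "boolean"},
    {"name": "lithium", "kind": "boolean"},
    {"name": "goitre", "kind": "boolean"},
    {"name": "tumor", "kind": "boolean"},
    {"name": "hypopituitary", "kind": "boolean"},
    {"name": "psych", "kind": "boolean"},
    {"name": "TSH measured", "kind": "boolean"},
    {"name": "TSH", "kind": "numeric"},
    {"name": "T3 measured", "kind": "boolean"},
    {"name": "T3", "kind": "numeric"},
    {"name": "TT4 measured", "kind": "boolean"},
    {"name": "TT4", "kind": "numeric"},
    {"name": "T4U measured", "kind": "boolean"},
    {"name": "T4U", "kind": "numeric"},
    {"name": "FTI measured", "kind": "boolean"},
    {"name": "FTI", "kind": "numeric"},
    {"name": "TBG measured", "kind": "boolean"},
    {"name": "TBG", "kind": "numeric"}
  ]
}
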