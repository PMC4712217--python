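{
  "set_id": "gender_transition",
  "description": "Acting out (GAD->DA) versus failure (DA->GAD) across the sexes.",
  "space": {"kind": "transition", "subgroups": ["males", "females"], "rows": ["GAD", "DA"]},
  "models": [
    {
      "name": "M1",
      "label": "No gender differences",
      "constraints": [
        {"lhs": [[1, "males.GAD", "DA"]], "op": "~", "rhs": [[1, "females.GAD", "DA"]]},
        {"lhs": [[1, "males.DA", "GAD"]], "op": "~", "rhs": [[1, "females.DA", "GAD"]]}
      ]
    },
    {
      "name": "M2",
      "label": "Acting out in males",
      "constraints": [
        {"lhs": [[1, "males.DA", "GAD"]], "op": "<", "rhs": [[1, "males.GAD", "DA"]]},
        {"lhs": [[1, "females.DA", "GAD"]], "op": "~", "rhs": [[1, "females.GAD", "DA"]]}
      ]
    },
    {"name": "M3", "label": "Unconstrained", "constraints": []}
  ]
}
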