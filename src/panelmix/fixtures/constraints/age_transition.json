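{
  "set_id": "age_transition",
  "description": "Acting out (GAD->DA) versus failure (DA->GAD) across the two cohorts.",
  "space": {"kind": "transition", "subgroups": ["early_to_middle", "middle_to_late"], "rows": ["GAD", "DA"]},
  "models": [
    {
      "name": "M1",
      "label": "No age group differences",
      "constraints": [
        {"lhs": [[1, "early_to_middle.GAD", "DA"]], "op": "~", "rhs": [[1, "middle_to_late.GAD", "DA"]]},
        {"lhs": [[1, "early_to_middle.DA", "GAD"]], "op": "~", "rhs": [[1, "middle_to_late.DA", "GAD"]]}
      ]
    },
    {
      "name": "M2",
      "label": "Acting out in early-to-middle adolescence",
      "constraints": [
        {"lhs": [[1, "early_to_middle.DA", "GAD"]], "op": "<", "rhs": [[1, "early_to_middle.GAD", "DA"]]},
        {"lhs": [[1, "middle_to_late.DA", "GAD"]], "op": "~", "rhs": [[1, "middle_to_late.GAD", "DA"]]}
      ]
    },
    {"name": "M3", "label": "Unconstrained", "constraints": []}
  ]
}
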