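{
  "set_id": "age_prevalence",
  "description": "Cohort differences in the wave-5 minus wave-1 prevalence change of the four types.",
  "space": {"kind": "prevalence", "subgroups": ["early_to_middle", "middle_to_late"], "waves": [1, 5]},
  "models": [
    {
      "name": "M1",
      "label": "No age group difference in increase or decrease",
      "constraints": [
        {"lhs": [[1, "middle_to_late.w5", "GAD"], [-1, "middle_to_late.w1", "GAD"]], "op": "~",
         "rhs": [[1, "early_to_middle.w5", "GAD"], [-1, "early_to_middle.w1", "GAD"]]},
        {"lhs": [[1, "middle_to_late.w5", "DA"], [-1, "middle_to_late.w1", "DA"]], "op": "~",
         "rhs": [[1, "early_to_middle.w5", "DA"], [-1, "early_to_middle.w1", "DA"]]},
        {"lhs": [[1, "middle_to_late.w5", "C-DA"], [-1, "middle_to_late.w1", "C-DA"]], "op": "~",
         "rhs": [[1, "early_to_middle.w5", "C-DA"], [-1, "early_to_middle.w1", "C-DA"]]},
        {"lhs": [[1, "middle_to_late.w5", "Np"], [-1, "middle_to_late.w1", "Np"]], "op": "~",
         "rhs": [[1, "early_to_middle.w5", "Np"], [-1, "early_to_middle.w1", "Np"]]}
      ]
    },
    {
      "name": "M2",
      "label": "Accelerated development in middle-to-late adolescence",
      "constraints": [
        {"lhs": [[1, "middle_to_late.w5", "DA"], [-1, "middle_to_late.w1", "DA"]], "op": "<",
         "rhs": [[1, "early_to_middle.w5", "DA"], [-1, "early_to_middle.w1", "DA"]]},
        {"lhs": [[1, "middle_to_late.w5", "C-DA"], [-1, "middle_to_late.w1", "C-DA"]], "op": "<",
         "rhs": [[1, "early_to_middle.w5", "C-DA"], [-1, "early_to_middle.w1", "C-DA"]]},
        {"lhs": [[1, "middle_to_late.w5", "Np"], [-1, "middle_to_late.w1", "Np"]], "op": ">",
         "rhs": [[1, "early_to_middle.w5", "Np"], [-1, "early_to_middle.w1", "Np"]]},
        {"lhs": [[1, "middle_to_late.w5", "GAD"], [-1, "middle_to_late.w1", "GAD"]], "op": "~",
         "rhs": [[1, "early_to_middle.w5", "GAD"], [-1, "early_to_middle.w1", "GAD"]]}
      ]
    },
    {"name": "M3", "label": "Unconstrained", "constraints": []}
  ]
}
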