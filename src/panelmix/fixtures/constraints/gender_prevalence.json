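{
  "set_id": "gender_prevalence",
  "description": "Gender differences in the wave-5 minus wave-1 prevalence change of the four types.",
  "space": {"kind": "prevalence", "subgroups": ["males", "females"], "waves": [1, 5]},
  "models": [
    {
      "name": "M1",
      "label": "No gender difference in increase or decrease",
      "constraints": [
        {"lhs": [[1, "females.w5", "GAD"], [-1, "females.w1", "GAD"]], "op": "~",
         "rhs": [[1, "males.w5", "GAD"], [-1, "males.w1", "GAD"]]},
        {"lhs": [[1, "females.w5", "DA"], [-1, "females.w1", "DA"]], "op": "~",
         "rhs": [[1, "males.w5", "DA"], [-1, "males.w1", "DA"]]},
        {"lhs": [[1, "females.w5", "C-DA"], [-1, "females.w1", "C-DA"]], "op": "~",
         "rhs": [[1, "males.w5", "C-DA"], [-1, "males.w1", "C-DA"]]},
        {"lhs": [[1, "females.w5", "Np"], [-1, "females.w1", "Np"]], "op": "~",
         "rhs": [[1, "males.w5", "Np"], [-1, "males.w1", "Np"]]}
      ]
    },
    {
      "name": "M2",
      "label": "Growth of gender differentiation",
      "constraints": [
        {"lhs": [[1, "females.w5", "GAD"], [-1, "females.w1", "GAD"]], "op": ">",
         "rhs": [[1, "males.w5", "GAD"], [-1, "males.w1", "GAD"]]},
        {"lhs": [[1, "females.w5", "DA"], [-1, "females.w1", "DA"]], "op": "<",
         "rhs": [[1, "males.w5", "DA"], [-1, "males.w1", "DA"]]},
        {"lhs": [[1, "females.w5", "C-DA"], [-1, "females.w1", "C-DA"]], "op": "<",
         "rhs": [[1, "males.w5", "C-DA"], [-1, "males.w1", "C-DA"]]}
      ]
    },
    {"name": "M3", "label": "Unconstrained", "constraints": []}
  ]
}
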