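{
  "set_id": "friendship_transition_strength",
  "description": "Strength of acting out (GAD->DA) across friendship-quality groups.",
  "space": {"kind": "transition", "subgroups": ["higher_quality", "poorer_quality"], "rows": ["GAD", "DA"]},
  "models": [
    {
      "name": "M1",
      "label": "No differences between friendship groups",
      "constraints": [
        {"lhs": [[1, "poorer_quality.GAD", "DA"]], "op": "~", "rhs": [[1, "higher_quality.GAD", "DA"]]}
      ]
    },
    {
      "name": "M2",
      "label": "Acting out stronger in poorer-quality friendships",
      "constraints": [
        {"lhs": [[1, "poorer_quality.GAD", "DA"]], "op": ">", "rhs": [[1, "higher_quality.GAD", "DA"]]}
      ]
    },
    {"name": "M3", "label": "Unconstrained", "constraints": []}
  ]
}
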