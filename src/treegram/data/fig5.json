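[
 {"format": "treegram-tree", "version": 1, "tree_id": "T1", "ordered": true,
  "_note": "Transcription of a drawn figure: a chain edge 'a' over a two-leaf star (a,b). Validated in tests against the printed combined optimum (7 rules, size 11).",
  "parent": {"2": 1, "3": 2, "4": 2},
  "edge_label": {"2": "a", "3": "a", "4": "b"},
  "child_order": {"1": [2], "2": [3, 4]}},
 {"format": "treegram-tree", "version": 1, "tree_id": "T2", "ordered": true,
  "_note": "Transcription of a drawn figure: root with children [a-edge over star(a,b)] and [a-leaf].",
  "parent": {"2": 1, "3": 2, "4": 2, "5": 1},
  "edge_label": {"2": "a", "3": "a", "4": "b", "5": "a"},
  "child_order": {"1": [2, 5], "2": [3, 4]}},
 {"format": "treegram-tree", "version": 1, "tree_id": "T3", "ordered": true,
  "_note": "Fixed by the printed Euler string a a- a a- b b-: a root with leaf children a, a, b.",
  "parent": {"2": 1, "3": 1, "4": 1},
  "edge_label": {"2": "a", "3": "a", "4": "b"},
  "child_order": {"1": [2, 3, 4]}}
]
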