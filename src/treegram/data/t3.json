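[
 {"format": "treegram-tree", "version": 1, "tree_id": "T3", "ordered": true,
  "_note": "The tree whose printed Euler string is a a- a a- b b-: root with leaf children a, a, b.",
  "parent": {"2": 1, "3": 1, "4": 1},
  "edge_label": {"2": "a", "3": "a", "4": "b"},
  "child_order": {"1": [2, 3, 4]}}
]
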