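[
 {"format": "treegram-tree", "version": 1, "tree_id": "T", "ordered": true,
  "_note": "Transcription of a drawn figure: root with three a-labeled leaf children. Validated in tests: minimum 3 nonterminals, with two optimal grammars differing in the first rule.",
  "parent": {"2": 1, "3": 1, "4": 1},
  "edge_label": {"2": "a", "3": "a", "4": "a"},
  "child_order": {"1": [2, 3, 4]}}
]
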