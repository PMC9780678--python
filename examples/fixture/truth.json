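{
  "active_ids": [
    "C_0002",
    "C_0004",
    "C_0025",
    "C_0027",
    "C_0031"
  ],
  "expected_edges": 15,
  "n_after_class": 35,
  "n_after_inorganic": 35,
  "n_after_mw": 29,
  "n_initial": 50,
  "removed_by_class": [
    "C_0003",
    "C_0008",
    "C_0009",
    "C_0011",
    "C_0012",
    "C_0017",
    "C_0019",
    "C_0020",
    "C_0022",
    "C_0030",
    "C_0034",
    "C_0041",
    "C_0043",
    "C_0044",
    "C_0050"
  ],
  "removed_by_inorganic": [],
  "removed_by_mw": [
    "C_0014",
    "C_0016",
    "C_0023",
    "C_0037",
    "C_0039",
    "C_0045"
  ],
  "seed": 20221209,
  "top_k": 5
}
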