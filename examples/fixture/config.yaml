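seed: 20221209
inputs:
  library: library.csv
  library_format: csv
  descriptors: descriptors.csv
  admet: admet.csv
  predictions:
  - tool_id: tool_1
    path: predictions_tool_1.tsv
  - tool_id: tool_2
    path: predictions_tool_2.tsv
  - tool_id: tool_3
    path: predictions_tool_3.tsv
  - tool_id: tool_4
    path: predictions_tool_4.tsv
  - tool_id: tool_5
    path: predictions_tool_5.tsv
  - tool_id: tool_6
    path: predictions_tool_6.tsv
  manifests: manifests.yaml
filters:
  excluded_classes:
  - diacylglycerol
  - phosphatidylethanolamine
  - triacylglycerol
  min_mw: 100.0
scoring:
  top_k: 5
targets:
  targets_of_interest:
  - P05067
  - P22303
  - P42574
  top_k: 20
  min_votes: 1
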