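tool_1:
- P05067
- P22303
- P42574
tool_2:
- P05067
- P22303
- P42574
tool_3:
- P05067
- P22303
- P42574
tool_4:
- P05067
- P22303
- P42574
tool_5:
- P05067
- P22303
- P42574
tool_6:
- P05067
- P22303
- P42574
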