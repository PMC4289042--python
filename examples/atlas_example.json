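{
  "11": {"lobe": "frontal",   "hemisphere": "left"},
  "12": {"lobe": "parietal",  "hemisphere": "left"},
  "13": {"lobe": "temporal",  "hemisphere": "left"},
  "14": {"lobe": "occipital", "hemisphere": "left"},
  "21": {"lobe": "frontal",   "hemisphere": "right"},
  "22": {"lobe": "parietal",  "hemisphere": "right"},
  "23": {"lobe": "temporal",  "hemisphere": "right"},
  "24": {"lobe": "occipital", "hemisphere": "right"}
}
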