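{
  "dfmm": 6.3671047436527815,
  "dmm": 6.056823644058634,
  "le": 21.828354640994682,
  "mmfree_le": 9.404426253283265,
  "mmle": 12.423928387711415,
  "none": 2.7798953139490448,
  "one": 6.624530939334221,
  "pct_mmle": 56.91646755811219
}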