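{
  "RHD*01": {
    "upstream_box": 1,
    "downstream_box": 1,
    "RHD_wt": 1,
    "RHD_var": 0,
    "RHCE": 1
  },
  "RHD*01N.01": {
    "upstream_box": 0,
    "downstream_box": 1,
    "RHD_wt": 0,
    "RHD_var": 0,
    "RHCE": 1
  },
  "RHD*01EL.01": {
    "upstream_box": 1,
    "downstream_box": 1,
    "RHD_wt": 0,
    "RHD_var": 1,
    "RHCE": 1
  },
  "RHD*01N.04": {
    "upstream_box": 1,
    "downstream_box": 1,
    "RHD_wt": 0,
    "RHD_var": 0,
    "RHCE": 2
  }
}
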