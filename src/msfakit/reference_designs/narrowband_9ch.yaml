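# Application-independent 9-channel 3x3 MSFA with 10 nm bandwidths.
# NOTE: bandwidths here are Gaussian standard deviations (sigma convention).
name: narrowband_9ch
filters:
  - {center_nm: 410, bandwidth_nm: 10, convention: sigma}
  - {center_nm: 580, bandwidth_nm: 10, convention: sigma}
  - {center_nm: 680, bandwidth_nm: 10, convention: sigma}
  - {center_nm: 520, bandwidth_nm: 10, convention: sigma}
  - {center_nm: 650, bandwidth_nm: 10, convention: sigma}
  - {center_nm: 460, bandwidth_nm: 10, convention: sigma}
  - {center_nm: 610, bandwidth_nm: 10, convention: sigma}
  - {center_nm: 700, bandwidth_nm: 10, convention: sigma}
  - {center_nm: 540, bandwidth_nm: 10, convention: sigma}
pattern:
  - [0, 1, 2]
  - [3, 4, 5]
  - [6, 7, 8]
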