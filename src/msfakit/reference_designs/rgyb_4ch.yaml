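# Empirically designed 4-channel 2x2 MSFA: Bayer-like RGYB (yellow replaces
# the second green).  Bandwidths are FWHM.
name: rgyb_4ch
filters:
  - {center_nm: 455, bandwidth_nm: 47, convention: fwhm}
  - {center_nm: 575, bandwidth_nm: 47, convention: fwhm}
  - {center_nm: 520, bandwidth_nm: 47, convention: fwhm}
  - {center_nm: 640, bandwidth_nm: 47, convention: fwhm}
pattern:
  - [0, 1]
  - [2, 3]
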