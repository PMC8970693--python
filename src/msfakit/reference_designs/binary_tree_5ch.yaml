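# 5-channel MSFA optimized for spectral recovery with a binary-tree mosaic.
# The tree layout is encoded here as a fixed 4x4 cell (channel 0 at half
# density, channels 1-4 at 1/8 density); the generation algorithm itself is
# out of scope.  Bandwidths are FWHM.
name: binary_tree_5ch
filters:
  - {center_nm: 400, bandwidth_nm: 153, convention: fwhm}
  - {center_nm: 485, bandwidth_nm: 117, convention: fwhm}
  - {center_nm: 550, bandwidth_nm: 106, convention: fwhm}
  - {center_nm: 615, bandwidth_nm: 117, convention: fwhm}
  - {center_nm: 700, bandwidth_nm: 153, convention: fwhm}
pattern:
  - [2, 0, 2, 1]
  - [3, 2, 4, 2]
  - [2, 1, 2, 0]
  - [4, 2, 3, 2]
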