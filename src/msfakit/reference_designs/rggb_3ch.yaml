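# Commercial 2x2 RGGB color filter array.  Off-the-shelf camera RGB
# responses are not Gaussian and are not bundled: supply measured response
# curves via 'response' entries (length matching your scene's wavelength
# axis) before using this design.
name: rggb_3ch
requires_user_responses: true
filters:
  - {response_file: REQUIRED, name: red}
  - {response_file: REQUIRED, name: green}
  - {response_file: REQUIRED, name: green}
  - {response_file: REQUIRED, name: blue}
pattern:
  - [0, 1]
  - [2, 3]
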