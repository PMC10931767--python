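# Simulator parameters per experimental group.  Unset fields take the
# package defaults (25 Hz, 5.5 mm well, beat-and-glide swimming).
scrambled:
  p_seizure: 0.05
scn1lab:
  p_seizure: 0.30
gabra1:
  p_seizure: 0.12
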